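fine_region	macro_region
Precentral_L	frontal_L
Precentral_R	frontal_R
Frontal_Sup_L	frontal_L
Frontal_Sup_R	frontal_R
Frontal_Sup_Orb_L	frontal_L
Frontal_Sup_Orb_R	frontal_R
Frontal_Mid_L	frontal_L
Frontal_Mid_R	frontal_R
Frontal_Mid_Orb_L	frontal_L
Frontal_Mid_Orb_R	frontal_R
Frontal_Inf_Oper_L	frontal_L
Frontal_Inf_Oper_R	frontal_R
Frontal_Inf_Tri_L	frontal_L
Frontal_Inf_Tri_R	frontal_R
Frontal_Inf_Orb_L	frontal_L
Frontal_Inf_Orb_R	frontal_R
Rolandic_Oper_L	frontal_L
Rolandic_Oper_R	frontal_R
Supp_Motor_Area_L	frontal_L
Supp_Motor_Area_R	frontal_R
Olfactory_L	frontal_L
Olfactory_R	frontal_R
Frontal_Sup_Medial_L	frontal_L
Frontal_Sup_Medial_R	frontal_R
Frontal_Med_Orb_L	frontal_L
Frontal_Med_Orb_R	frontal_R
Rectus_L	frontal_L
Rectus_R	frontal_R
Cingulum_Ant_L	frontal_L
Cingulum_Ant_R	frontal_R
Cingulum_Mid_L	frontal_L
Cingulum_Mid_R	frontal_R
Caudate_L	frontal_L
Caudate_R	frontal_R
Putamen_L	frontal_L
Putamen_R	frontal_R
Pallidum_L	frontal_L
Pallidum_R	frontal_R
Hippocampus_L	temporomedial_L
Hippocampus_R	temporomedial_R
ParaHippocampal_L	temporomedial_L
ParaHippocampal_R	temporomedial_R
Amygdala_L	temporomedial_L
Amygdala_R	temporomedial_R
Temporal_Pole_Sup_L	temporomedial_L
Temporal_Pole_Sup_R	temporomedial_R
Temporal_Pole_Mid_L	temporomedial_L
Temporal_Pole_Mid_R	temporomedial_R
Insula_L	temporolateral_L
Insula_R	temporolateral_R
Heschl_L	temporolateral_L
Heschl_R	temporolateral_R
Temporal_Sup_L	temporolateral_L
Temporal_Sup_R	temporolateral_R
Temporal_Mid_L	temporolateral_L
Temporal_Mid_R	temporolateral_R
Temporal_Inf_L	temporolateral_L
Temporal_Inf_R	temporolateral_R
Fusiform_L	temporolateral_L
Fusiform_R	temporolateral_R
Postcentral_L	parietal_L
Postcentral_R	parietal_R
Parietal_Sup_L	parietal_L
Parietal_Sup_R	parietal_R
Parietal_Inf_L	parietal_L
Parietal_Inf_R	parietal_R
SupraMarginal_L	parietal_L
SupraMarginal_R	parietal_R
Angular_L	parietal_L
Angular_R	parietal_R
Precuneus_L	parietal_L
Precuneus_R	parietal_R
Paracentral_Lobule_L	parietal_L
Paracentral_Lobule_R	parietal_R
Cingulum_Post_L	parietal_L
Cingulum_Post_R	parietal_R
Calcarine_L	occipital_L
Calcarine_R	occipital_R
Cuneus_L	occipital_L
Cuneus_R	occipital_R
Lingual_L	occipital_L
Lingual_R	occipital_R
Occipital_Sup_L	occipital_L
Occipital_Sup_R	occipital_R
Occipital_Mid_L	occipital_L
Occipital_Mid_R	occipital_R
Occipital_Inf_L	occipital_L
Occipital_Inf_R	occipital_R
Thal_AV_L	thalamus_L
Thal_AV_R	thalamus_R
Thal_LP_L	thalamus_L
Thal_LP_R	thalamus_R
Thal_VA_L	thalamus_L
Thal_VA_R	thalamus_R
Thal_VL_L	thalamus_L
Thal_VL_R	thalamus_R
Thal_MD_L	thalamus_L
Thal_MD_R	thalamus_R
Thal_PuA_L	thalamus_L
Thal_PuA_R	thalamus_R
Thal_PuM_L	thalamus_L
Thal_PuM_R	thalamus_R
Thal_PuL_L	thalamus_L
Thal_PuL_R	thalamus_R
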