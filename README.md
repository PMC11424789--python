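# restflow

Source-space directed connectivity for resting-state HD-EEG, built around a
question from epilepsy surgery: does the region containing the seizure
onset zone (SOZ) show a different directed-connectivity and network profile
*before* surgery in patients who go on to become seizure-free than in those
who do not?

The package implements the full analysis chain and, because the clinical
recordings such analyses target are confidential, a seeded synthetic-cohort
generator with known directed ground truth, so that every stage can be
verified by parameter and direction recovery.

## The method

1. **Preprocessing** — zero-phase 0.5 Hz high-pass, robust bad-channel
   rejection, ICA-based removal of blink/cardiac components (identified by
   correlation with reference traces), extraction of ten artifact-free 5 s
   epochs.
2. **Source imaging** — weighted minimum-norm estimate
   K = R Gᵀ (G R Gᵀ + λ²C)⁻¹ with depth weighting R_ii = ‖g_i‖^(−2γ),
   aggregated to 12 cortical/subcortical regions by a sign-aligned mean
   source course.
3. **Directed connectivity** — one MVAR(40) per epoch via the
   Nuttall-Strand multichannel Burg lattice (unbiased covariances,
   stationary by construction), partial directed coherence

       π_ij(f) = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²),
       Ā(f) = I − Σ_r A_r e^(−i2πfr/fs),

   averaged within delta (1–4), theta (5–8), alpha (9–12) and beta
   (13–30 Hz); region **inflow**/**outflow** are off-diagonal row/column
   means of the band matrices.
4. **Graph metrics** — proportional threshold (density 0.15) on the
   symmetrized band matrix; per node: degree, cost, clustering, local
   efficiency, betweenness, average path length.
5. **Statistics** — two-sided Wilcoxon rank-sum test (exact for tie-free
   groups ≤ 12) per measure × band at the SOZ region, uncorrected, plus
   boxplot summaries.

See `docs/methods.md` for the model details, the synthetic-cohort design
and its limitations.

## Worked example

```python
import numpy as np
from restflow import CohortSpec, generate_cohort, cohort_features, compare_groups
from restflow.io import PipelineConfig

spec = CohortSpec(n_per_group=10, n_regions=12, fs_hz=250.0, n_epochs=10,
                  epoch_s=5.0, n_sensors=64, snr_db=10.0, seed=1)
cohort = generate_cohort(spec, include_artifacts=False)
config = PipelineConfig(mvar_order=40, analysis_fs_hz=250.0)
stats = compare_groups(cohort_features(cohort, config))
row = stats.set_index(["measure", "band"]).loc[("inflow", "delta")]
print(f"delta inflow at SOZ: seizure-free median {row['median_sf']:.3f}, "
      f"non-seizure-free median {row['median_nsf']:.3f}, p = {row['p_value']:.5f}")
```

prints

```
delta inflow at SOZ: seizure-free median 0.181, non-seizure-free median 0.318, p = 0.00001
```

— the seizure-free archetype (weakly fed, well-clustered SOZ) shows less
delta-band information inflow into the SOZ region than the diffuse
archetype, and with 10 patients per group the exact rank-sum test resolves
the difference. The full 32-row measure × band table is in `stats`;
`stats.loc[(("clustering", "delta"))]` shows the complementary pattern
(higher SOZ clustering in the seizure-free group).

The same analysis runs from the shell over an on-disk cohort (EDF files +
TSV manifest):

```bash
restflow simulate --out cohort/ --seed 1
restflow run-all --manifest cohort/manifest.tsv --out results/ --figures
```

`results/` then contains per-patient band connectivity matrices,
`features.tsv` (one row per patient), `group_stats.tsv` (32 rows),
`boxplots.json` and a frozen copy of the configuration.

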