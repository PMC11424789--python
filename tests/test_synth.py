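"""Synthetic cohorts: archetype networks, sensor projection, determinism."""

import numpy as np
import pytest

from restflow.mvar import simulate_mvar
from restflow.synth import (
    DIFFUSE_SOZ,
    ISOLATED_SOZ,
    CohortSpec,
    LeadField,
    NetworkArchetype,
    build_archetype_mvar,
    generate_cohort,
    project_to_sensors,
    random_leadfield,
)


def _coupling_into(model, region):
    row = np.abs(model.coeffs[:, region, :]).sum(axis=0)
    return row.sum() - np.abs(model.coeffs[:, region, region]).sum()


class TestArchetypes:
    def test_archetype_gain_ordering(self):
        assert ISOLATED_SOZ.soz_in_gain < DIFFUSE_SOZ.soz_in_gain

    def test_zero_gains_give_block_diagonal(self):
        arche = NetworkArchetype("isolated_soz", 0.0, 0.0, 0.0)
        m = build_archetype_mvar(12, arche, 3, 1000.0, seed=1,
                                 bg_gain=0.0)
        off = m.coeffs * (1 - np.eye(12))[None]
        assert np.all(off == 0.0)
        assert m.spectral_radius() < 1.0

    def test_spectral_radius_within_margin_by_direct_eigendecomposition(self):
        """Independent check: assemble the (p n) x (p n) companion matrix
        by hand and bound its eigenvalue moduli."""
        m = build_archetype_mvar(12, ISOLATED_SOZ, 0, 1000.0, seed=1)
        p, n = m.order, m.n_channels
        C = np.zeros((p * n, p * n))
        C[:n, : n * p] = m.coeffs.transpose(1, 0, 2).reshape(n, p * n)
        C[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        assert np.abs(np.linalg.eigvals(C)).max() <= 0.97 + 1e-9

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_diffuse_receives_more_than_isolated(self, seed):
        iso = build_archetype_mvar(12, ISOLATED_SOZ, 4, 1000.0, seed=seed)
        dif = build_archetype_mvar(12, DIFFUSE_SOZ, 4, 1000.0, seed=seed)
        assert _coupling_into(dif, 4) > _coupling_into(iso, 4)

    def test_soz_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            build_archetype_mvar(5, ISOLATED_SOZ, 5, 1000.0)


class TestProjection:
    def test_identity_mixing_noiseless(self):
        x = np.random.default_rng(0).standard_normal((4, 100))
        lf = LeadField(np.eye(4), np.arange(4))
        rec = project_to_sensors(x, lf, snr_db=np.inf, seed=0, fs_hz=100.0)
        assert np.array_equal(rec.data, x)

    def test_snr_zero_db_power_ratio(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 50_000))
        lf = random_leadfield(16, 4, 2, seed=1)
        rec = project_to_sensors(x, lf, snr_db=0.0, seed=2, fs_hz=100.0)
        src = lf.source_signs[:, None] * x[lf.source_region_map]
        clean = lf.gain @ src
        noise = rec.data - clean
        snr_db = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
        assert abs(snr_db) < 0.5

    def test_gain_linearity(self):
        x = np.random.default_rng(2).standard_normal((3, 200))
        lf = LeadField(np.random.default_rng(3).standard_normal((5, 3)),
                       np.arange(3))
        lf2 = LeadField(2.0 * lf.gain, lf.source_region_map,
                        lf.source_signs)
        r1 = project_to_sensors(x, lf, np.inf, seed=0, fs_hz=100.0)
        r2 = project_to_sensors(x, lf2, np.inf, seed=0, fs_hz=100.0)
        assert np.allclose(r2.data, 2.0 * r1.data)

    def test_region_count_mismatch_rejected(self):
        lf = LeadField(np.eye(4), np.arange(4))
        with pytest.raises(ValueError, match="inconsistent"):
            project_to_sensors(np.zeros((3, 10)), lf, 10.0, 0, 100.0)


class TestCohort:
    def test_default_shape_counts(self, tiny_spec):
        ds = generate_cohort(tiny_spec)
        assert len(ds.patients) == 2 * tiny_spec.n_per_group
        assert len(ds.by_group("seizure_free")) == tiny_spec.n_per_group
        assert len(ds.by_group("non_seizure_free")) == tiny_spec.n_per_group
        for p in ds.patients:
            assert p.truth.n_channels == tiny_spec.n_regions
            assert 0 <= p.soz_region < tiny_spec.n_regions
            assert p.recording.clean_mask is not None

    def test_paper_scale_defaults(self):
        spec = CohortSpec()
        assert (spec.n_per_group, spec.n_regions, spec.fs_hz,
                spec.n_epochs, spec.epoch_s) == (10, 12, 1000.0, 10, 5.0)

    def test_same_seed_identical_cohorts(self, tiny_spec):
        a = generate_cohort(tiny_spec)
        b = generate_cohort(tiny_spec)
        for pa, pb in zip(a.patients, b.patients):
            assert pa.patient_id == pb.patient_id
            assert pa.soz_region == pb.soz_region
            assert np.array_equal(pa.recording.data, pb.recording.data)
            assert np.array_equal(pa.truth.coeffs, pb.truth.coeffs)

    def test_truth_level_group_separation_many_patients(self):
        """Mean ground-truth coupling into the SOZ is lower for the
        seizure-free archetype, before any estimation (50 per group)."""
        spec = CohortSpec(n_per_group=50, n_regions=12, fs_hz=128.0,
                          n_epochs=1, epoch_s=1.0, n_sensors=4,
                          sources_per_region=1, seed=0)
        ds = generate_cohort(spec, include_artifacts=False)
        by = {"seizure_free": [], "non_seizure_free": []}
        for p in ds.patients:
            by[p.group].append(_coupling_into(p.truth, p.soz_region))
        assert np.mean(by["seizure_free"]) < np.mean(by["non_seizure_free"])

    def test_artifact_segments_excluded_from_clean_mask(self, tiny_spec):
        ds = generate_cohort(tiny_spec, include_artifacts=True)
        rec = ds.patients[0].recording
        win = int(tiny_spec.epoch_s * tiny_spec.fs_hz)
        assert rec.artifact_refs is not None
        assert (~rec.clean_mask).sum() == 2 * win
        assert rec.clean_mask.sum() >= tiny_spec.n_epochs * win

    def test_every_truth_model_is_stationary(self, tiny_spec):
        ds = generate_cohort(tiny_spec, include_artifacts=False)
        for p in ds.patients:
            assert p.truth.spectral_radius() < 1.0
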