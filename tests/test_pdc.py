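"""PDC spectra, band averaging and flow measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restflow.mvar import MVARModel
from restflow.pdc import (
    DEFAULT_BANDS,
    FrequencyBands,
    PDCSpectrum,
    band_average,
    default_freq_grid,
    inflow_outflow,
    pdc_spectrum,
)


class TestPDCSpectrum:
    def test_closed_form_bivariate_at_dc(self, bivariate_var1):
        """Abar(0) = [[0.5, 0], [-0.3, 0.6]] gives pi21 = 0.3/sqrt(0.34)."""
        sp = pdc_spectrum(bivariate_var1, np.array([0.0]), fs_hz=100.0)
        v = sp.values[0]
        assert v[1, 0] == pytest.approx(0.3 / np.sqrt(0.34), abs=1e-12)
        assert v[0, 0] == pytest.approx(0.5 / np.sqrt(0.34), abs=1e-12)
        assert v[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert v[1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_model_has_no_cross_flow(self):
        A = np.zeros((2, 3, 3))
        A[0] = 0.4 * np.eye(3)
        A[1] = -0.2 * np.eye(3)
        sp = pdc_spectrum(MVARModel(A, np.eye(3)), default_freq_grid(200.0), 200.0)
        off = sp.values * (1 - np.eye(3))[None]
        assert np.abs(off).max() < 1e-14
        assert np.allclose(np.diagonal(sp.values, axis1=1, axis2=2), 1.0)

    def test_column_normalization_identity(self, bivariate_var1):
        sp = pdc_spectrum(bivariate_var1, default_freq_grid(250.0), 250.0)
        colsum = (sp.values**2).sum(axis=1)
        assert np.abs(colsum - 1.0).max() < 1e-10

    def test_grid_above_nyquist_rejected(self, bivariate_var1):
        with pytest.raises(ValueError, match="Nyquist"):
            pdc_spectrum(bivariate_var1, np.array([60.0]), fs_hz=100.0)

    def test_unknown_variant_rejected(self, bivariate_var1):
        with pytest.raises(ValueError, match="variant"):
            pdc_spectrum(bivariate_var1, np.array([1.0]), 100.0, variant="dtf")


class TestBands:
    def test_default_band_edges(self):
        assert DEFAULT_BANDS.as_dict() == {
            "delta": (1.0, 4.0), "theta": (5.0, 8.0),
            "alpha": (9.0, 12.0), "beta": (13.0, 30.0),
        }

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            FrequencyBands(delta=(1.0, 6.0))

    def test_band_average_of_constant_spectrum(self):
        grid = default_freq_grid(250.0)
        vals = np.full((len(grid), 2, 2), 0.37)
        conn = band_average(PDCSpectrum(vals, grid))
        for M in conn.values():
            assert np.allclose(M, 0.37)

    def test_delta_mean_over_seven_grid_points(self):
        """Grid 0.5 Hz from 0.5: the closed delta band holds exactly the 7
        points 1.0 .. 4.0 and the average is their arithmetic mean."""
        grid = default_freq_grid(250.0)
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=(len(grid), 2, 2))
        conn = band_average(PDCSpectrum(vals, grid))
        mask = (grid >= 1.0) & (grid <= 4.0)
        assert mask.sum() == 7
        assert np.allclose(conn["delta"], vals[mask].mean(axis=0))

    def test_epoch_mean_after_band_mean(self):
        """Averaging runs over in-band frequencies first, then epochs."""
        grid = default_freq_grid(250.0)
        s1 = PDCSpectrum(np.full((len(grid), 2, 2), 0.2), grid)
        s2 = PDCSpectrum(np.full((len(grid), 2, 2), 0.6), grid)
        conn = band_average([s1, s2])
        for M in conn.values():
            assert np.allclose(M, 0.4)

    def test_empty_band_rejected(self):
        grid = np.array([1.0, 2.0])  # theta band has no point here
        s = PDCSpectrum(np.full((2, 2, 2), 0.2), grid)
        with pytest.raises(ValueError, match="no grid point"):
            band_average(s)

    def test_mismatched_grids_rejected(self):
        s1 = PDCSpectrum(np.full((2, 2, 2), 0.2), np.array([1.0, 2.0]))
        s2 = PDCSpectrum(np.full((2, 2, 2), 0.2), np.array([1.0, 3.0]))
        with pytest.raises(ValueError, match="share"):
            band_average([s1, s2])


class TestEpochAveraging:
    def test_null_offdiagonal_concentrates_with_more_epochs(self):
        """Averaging |PDC| over epochs concentrates the null (uncoupled)
        model's off-diagonal estimates: the spread of each entry across
        seeds shrinks markedly from 1 to 10 epochs (the entrywise mean is
        the estimator's noise-floor bias and is unchanged by averaging)."""
        from restflow.mvar import MVARModel, fit_mvar_epochs, simulate_mvar

        fs = 250.0
        A = np.zeros((2, 3, 3))
        A[0], A[1] = 0.5 * np.eye(3), -0.3 * np.eye(3)
        truth = MVARModel(A, np.eye(3))
        grid = default_freq_grid(fs)
        one_ep, ten_ep = [], []
        for seed in range(8):
            x = simulate_mvar(truth, 10 * 1250, seed=seed)
            epochs = x.reshape(3, 10, 1250).transpose(1, 0, 2)
            spectra = [pdc_spectrum(m, grid, fs)
                       for m in fit_mvar_epochs(epochs, order=8)]
            mask = ~np.eye(3, dtype=bool)
            one_ep.append(np.concatenate(
                [M[mask] for M in band_average(spectra[:1]).values()]))
            ten_ep.append(np.concatenate(
                [M[mask] for M in band_average(spectra).values()]))
        spread1 = np.std(np.array(one_ep), axis=0).mean()
        spread10 = np.std(np.array(ten_ep), axis=0).mean()
        assert spread10 < 0.6 * spread1


class TestFlows:
    def test_uncoupled_network_zero_flow(self):
        conn = {b: np.eye(4) for b in ("delta", "theta", "alpha", "beta")}
        fl = inflow_outflow(conn)
        assert np.all(fl.inflow == 0) and np.all(fl.outflow == 0)

    def test_bivariate_worked_case(self, bivariate_var1):
        """Single-frequency band at DC reproduces the hand-evaluated flows."""
        sp = pdc_spectrum(bivariate_var1, np.array([0.0]), 100.0)
        conn = {b: sp.values[0] for b in ("delta", "theta", "alpha", "beta")}
        fl = inflow_outflow(conn)
        assert fl.inflow[1, 0] == pytest.approx(0.51450, abs=1e-5)
        assert fl.outflow[0, 0] == pytest.approx(0.51450, abs=1e-5)
        assert fl.inflow[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_inflow_outflow_means_coincide(self):
        rng = np.random.default_rng(2)
        conn = {b: rng.uniform(size=(5, 5))
                for b in ("delta", "theta", "alpha", "beta")}
        fl = inflow_outflow(conn)
        assert np.allclose(fl.inflow.mean(axis=0), fl.outflow.mean(axis=0))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        conn = {b: rng.uniform(size=(6, 6))
                for b in ("delta", "theta", "alpha", "beta")}
        perm = rng.permutation(6)
        fl = inflow_outflow(conn)
        fl_p = inflow_outflow({b: M[np.ix_(perm, perm)]
                               for b, M in conn.items()})
        assert np.allclose(fl_p.inflow, fl.inflow[perm])
        assert np.allclose(fl_p.outflow, fl.outflow[perm])

    def test_single_region_rejected(self):
        with pytest.raises(ValueError, match="2 regions"):
            inflow_outflow({b: np.ones((1, 1))
                            for b in ("delta", "theta", "alpha", "beta")})
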