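"""Sensor conditioning: filtering, bad channels, artifact ICA, epoching."""

import numpy as np
import pytest
from scipy import signal as sps

from restflow.preproc import (
    SensorRecording,
    detect_bad_channels,
    extract_epochs,
    highpass_filter,
    remove_artifact_components,
)


def _rec(data, fs=1000.0, **kw):
    labels = [f"E{k + 1:03d}" for k in range(np.atleast_2d(data).shape[0])]
    return SensorRecording(data=data, fs_hz=fs, channel_labels=labels, **kw)


class TestHighpass:
    def test_dc_rejected(self):
        rec = _rec(np.full((2, 4000), 7.5))
        out = highpass_filter(rec).data[:, 500:-500]
        assert np.sqrt((out**2).mean()) < 1e-6 * 7.5

    def test_passband_amplitude_matches_designed_response(self):
        """10 Hz sinusoid: output amplitude equals |H(10 Hz)|^2 of the
        4th-order design (forward-backward squares the magnitude)."""
        fs = 1000.0
        t = np.arange(60000) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        mid = slice(20000, 40000)
        out = highpass_filter(_rec(x[None], fs)).data[0, mid]
        # projection onto the complex exponential: robust amplitude estimate
        amp = 2 * np.abs(np.mean(out * np.exp(-2j * np.pi * 10.0 * t[mid])))
        sos = sps.butter(4, 0.5, btype="highpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[10.0], fs=fs)
        expected = np.abs(h[0]) ** 2  # forward-backward squares |H|
        assert abs(amp / expected - 1) < 0.01
        assert 0.99 <= amp <= 1.01  # and the band is truly passed

    def test_slow_drift_attenuated(self):
        fs = 1000.0
        t = np.arange(120_000) / fs
        x = np.sin(2 * np.pi * 0.05 * t)
        out = highpass_filter(_rec(x[None], fs)).data[0, 30_000:-30_000]
        atten_db = 20 * np.log10(1.0 / max(out.max(), 1e-12))
        assert atten_db > 20

    def test_zero_phase_pulse_keeps_center(self):
        fs = 500.0
        c = 10000
        x = np.zeros(2 * c + 1)
        x[c] = 1.0  # symmetric impulse far from the edges
        out = highpass_filter(_rec(x[None], fs)).data[0]
        assert np.argmax(out) == c
        assert np.allclose(out[c - 200 : c], out[c + 1 : c + 201][::-1],
                           atol=1e-7)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_filter(_rec(np.zeros((2, 100)), fs=100.0), cutoff_hz=50.0)


class TestBadChannels:
    def test_homogeneous_noise_flags_nothing(self):
        rng = np.random.default_rng(0)
        assert detect_bad_channels(_rec(rng.standard_normal((8, 5000)))) == set()

    def test_high_variance_channel_flagged(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 5000))
        data[3] *= 100
        assert detect_bad_channels(_rec(data)) == {"E004"}

    def test_flatline_channel_flagged(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((8, 5000))
        data[5] = 0.0
        assert "E006" in detect_bad_channels(_rec(data))

    def test_few_channels_rejected(self):
        with pytest.raises(ValueError, match="4 channels"):
            detect_bad_channels(_rec(np.zeros((3, 100))))


class TestArtifactRemoval:
    def _blinky_recording(self, amp, seed=0):
        rng = np.random.default_rng(seed)
        n_ch, T, fs = 12, 6000, 500.0
        base = rng.standard_normal((n_ch, T))
        t = np.arange(T) / fs
        blink = np.zeros(T)
        for c in np.arange(0.5, T / fs - 0.5, 1.0):
            blink += np.exp(-0.5 * ((t - c) / 0.05) ** 2)
        topo = rng.standard_normal(n_ch)
        data = base + amp * np.outer(topo, blink)
        return _rec(data, fs, artifact_refs=blink[None]), blink

    def test_injected_template_removed(self):
        rec, blink = self._blinky_recording(amp=8.0)
        out = remove_artifact_components(rec, seed=0)
        b0 = blink - blink.mean()
        for ch in out.data:
            c = np.dot(ch - ch.mean(), b0) / (
                np.linalg.norm(ch - ch.mean()) * np.linalg.norm(b0))
            assert abs(c) < 0.2

    def test_nothing_above_threshold_is_identity(self):
        rng = np.random.default_rng(3)
        rec = _rec(rng.standard_normal((10, 4000)), 500.0,
                   artifact_refs=rng.standard_normal((1, 4000)))
        out = remove_artifact_components(rec, corr_thresh=0.95, seed=0)
        assert np.allclose(out.data, rec.data, rtol=1e-6)

    def test_same_seed_identical(self):
        rec, _ = self._blinky_recording(amp=8.0, seed=4)
        a = remove_artifact_components(rec, seed=1)
        b = remove_artifact_components(rec, seed=1)
        assert np.array_equal(a.data, b.data)

    def test_shape_never_changes(self):
        rec, _ = self._blinky_recording(amp=8.0, seed=5)
        out = remove_artifact_components(rec, seed=0)
        assert out.data.shape == rec.data.shape

    def test_missing_refs_rejected(self):
        rec = _rec(np.zeros((10, 1000)), 500.0)
        with pytest.raises(ValueError, match="reference"):
            remove_artifact_components(rec)


class TestEpochs:
    def test_paper_epoch_geometry(self):
        rec = _rec(np.random.default_rng(0).standard_normal((3, 60_000)),
                   fs=1000.0)
        ep = extract_epochs(rec, n_epochs=10, epoch_len_s=5.0)
        assert ep.epochs.shape == (10, 3, 5000)

    def test_all_clean_tiling_is_disjoint_in_order(self):
        fs = 1000.0
        data = np.arange(60_000, dtype=float)[None]
        ep = extract_epochs(_rec(data, fs), n_epochs=10, epoch_len_s=5.0)
        for k in range(10):
            assert ep.epochs[k, 0, 0] == k * 5000  # tiles [0,5000), [5000,...)

    def test_masked_samples_never_included(self):
        fs = 100.0
        data = np.arange(3000, dtype=float)[None]
        mask = np.ones(3000, dtype=bool)
        mask[250:400] = False
        ep = extract_epochs(_rec(data, fs), n_epochs=3, epoch_len_s=2.0,
                            clean_mask=mask)
        used = set()
        for k in range(3):
            s = int(ep.epochs[k, 0, 0])
            assert mask[s : s + 200].all()
            assert not (set(range(s, s + 200)) & used)
            used |= set(range(s, s + 200))

    def test_insufficient_clean_data_names_shortfall(self):
        rec = _rec(np.zeros((2, 40_000)), fs=1000.0)
        with pytest.raises(ValueError, match="8 of 10"):
            extract_epochs(rec, n_epochs=10, epoch_len_s=5.0)
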