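"""Partial directed coherence (PDC) spectra, band averaging and inflow/outflow.

PDC factorizes the MVAR coefficient stack in the frequency domain,

    Abar(f) = I - sum_{r=1..p} A_r exp(-i 2 pi f r / fs),

and quantifies directed influence from source channel j to target i as the
column-normalized magnitude

    pi_ij(f) = |Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2),

so that, for every source column j and frequency, sum_i pi_ij(f)^2 == 1.
Inflow/outflow of a region are means of the band-averaged PDC over the
off-diagonal entries of its row/column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import MVARModel

__all__ = [
    "FrequencyBands",
    "DEFAULT_BANDS",
    "BAND_ORDER",
    "default_freq_grid",
    "pdc_spectrum",
    "PDCSpectrum",
    "band_average",
    "inflow_outflow",
    "FlowMeasures",
]

BAND_ORDER = ("delta", "theta", "alpha", "beta")


@dataclass(frozen=True)
class FrequencyBands:
    """Closed frequency intervals (Hz) of the four standard EEG bands."""

    delta: tuple[float, float] = (1.0, 4.0)
    theta: tuple[float, float] = (5.0, 8.0)
    alpha: tuple[float, float] = (9.0, 12.0)
    beta: tuple[float, float] = (13.0, 30.0)

    def __post_init__(self) -> None:
        items = self.as_dict()
        prev_hi = 0.0
        for name in BAND_ORDER:
            lo, hi = items[name]
            if not (0.0 < lo <= hi):
                raise ValueError(f"band {name} must satisfy 0 < lo <= hi")
            if lo <= prev_hi:
                raise ValueError("bands must be ordered and non-overlapping")
            prev_hi = hi

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in BAND_ORDER}


DEFAULT_BANDS = FrequencyBands()


def default_freq_grid(fs_hz: float, lo: float = 0.5, hi: float = 45.0,
                      step: float = 0.5) -> np.ndarray:
    """Evaluation grid: ``step``-spaced frequencies in [lo, hi], below Nyquist."""
    grid = np.arange(lo, hi + step / 2, step)
    return grid[grid < fs_hz / 2.0]


@dataclass
class PDCSpectrum:
    """Directed connectivity per frequency: values[f, i, j] = pi_{i<-j}(f)."""

    values: np.ndarray  # (n_freqs, n, n), real, in [0, 1]
    freq_grid_hz: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freq_grid_hz = np.asarray(self.freq_grid_hz, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must have shape (n_freqs, n, n)")
        if len(self.freq_grid_hz) != self.values.shape[0]:
            raise ValueError("freq grid length mismatch")
        if np.any(np.diff(self.freq_grid_hz) <= 0):
            raise ValueError("freq grid must be strictly increasing")


def _afbar(model: MVARModel, freqs: np.ndarray, fs_hz: float) -> np.ndarray:
    """Abar(f) = I - sum_r A_r e^{-i 2 pi f r / fs}, shape (n_freqs, n, n)."""
    p = model.order
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / fs_hz)  # (F, p)
    af = np.tensordot(phase, model.coeffs, axes=(1, 0))  # (F, n, n)
    return np.eye(model.n_channels)[None, :, :] - af


def pdc_spectrum(
    model: MVARModel,
    freq_grid_hz: np.ndarray,
    fs_hz: float,
    variant: str = "pdc",
) -> PDCSpectrum:
    """Compute the PDC spectrum of a fitted (or true) MVAR model.

    Parameters
    ----------
    variant : {"pdc", "gpdc", "sq"}
        "pdc" is the original column-normalized magnitude (default); "gpdc"
        weights rows by inverse innovation standard deviations before
        normalizing; "sq" squares the "pdc" values.
    """
    freqs = np.asarray(freq_grid_hz, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if freqs.max() >= fs_hz / 2.0:
        raise ValueError("frequency grid must stay below Nyquist")
    A = _afbar(model, freqs, fs_hz)
    if variant == "gpdc":
        w = 1.0 / np.sqrt(np.diag(model.noise_cov))
        num = np.abs(A) * w[None, :, None]
    elif variant in ("pdc", "sq"):
        num = np.abs(A)
    else:
        raise ValueError(f"unknown PDC variant {variant!r}")
    col_norm = np.sqrt((num**2).sum(axis=1, keepdims=True))
    if np.any(col_norm == 0):
        raise ValueError("zero column norm in Abar(f); model degenerate")
    pi = num / col_norm
    if variant == "sq":
        pi = pi**2
    return PDCSpectrum(values=pi, freq_grid_hz=freqs)


def band_average(
    pdc_per_epoch: list[PDCSpectrum] | PDCSpectrum,
    bands: FrequencyBands = DEFAULT_BANDS,
) -> dict[str, np.ndarray]:
    """Entrywise mean |PDC| over in-band grid frequencies, then over epochs.

    Grid points falling between band edges (e.g. 4.5 Hz) belong to no band
    and are ignored. Returns a dict band name -> (n, n) matrix in [0, 1].
    """
    if isinstance(pdc_per_epoch, PDCSpectrum):
        pdc_per_epoch = [pdc_per_epoch]
    if len(pdc_per_epoch) == 0:
        raise ValueError("need at least one epoch spectrum")
    grid = pdc_per_epoch[0].freq_grid_hz
    for s in pdc_per_epoch[1:]:
        if not np.array_equal(s.freq_grid_hz, grid):
            raise ValueError("epoch spectra must share the frequency grid")
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.as_dict().items():
        mask = (grid >= lo) & (grid <= hi)
        if not mask.any():
            raise ValueError(f"band {name} [{lo}, {hi}] contains no grid point")
        out[name] = np.mean([s.values[mask].mean(axis=0) for s in pdc_per_epoch],
                            axis=0)
    return out


@dataclass
class FlowMeasures:
    """inflow[region, band_idx] / outflow[region, band_idx], bands in BAND_ORDER."""

    inflow: np.ndarray
    outflow: np.ndarray
    bands: tuple[str, ...] = field(default=BAND_ORDER)


def inflow_outflow(band_conn: dict[str, np.ndarray]) -> FlowMeasures:
    """Off-diagonal means of band connectivity: directed flow per region.

    inflow_i = mean_{j != i} conn[i, j]; outflow_j = mean_{i != j} conn[i, j].
    The means of the two vectors coincide (both equal the off-diagonal mean).
    """
    bands = tuple(band_conn.keys())
    n = next(iter(band_conn.values())).shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions for flow measures")
    inflow = np.empty((n, len(bands)))
    outflow = np.empty((n, len(bands)))
    for k, name in enumerate(bands):
        M = np.asarray(band_conn[name], dtype=float)
        if M.shape != (n, n):
            raise ValueError("band matrices must be square and consistent")
        off = M - np.diag(np.diag(M))
        inflow[:, k] = off.sum(axis=1) / (n - 1)
        outflow[:, k] = off.sum(axis=0) / (n - 1)
    return FlowMeasures(inflow=inflow, outflow=outflow, bands=bands)
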