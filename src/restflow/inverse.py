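"""Weighted minimum-norm source estimation and region aggregation.

The linear inverse maps sensor epochs to source epochs with the
depth-weighted Tikhonov kernel

    K = R G^T (G R G^T + lambda^2 C)^{-1},

where G is the lead field, C the sensor noise covariance and R a diagonal
source-covariance prior with R_ii = ||g_i||^(-2*gamma) (depth weighting;
gamma = 0 disables it). By default R is trace-normalized against C and
lambda is set from an assumed power SNR of 3 (lambda^2 = 1/9), the common
minimum-norm convention. Source courses are then aggregated into one
representative course per region as the sign-aligned mean: each source is
flipped so it correlates nonnegatively with the region's first principal
temporal component, which prevents oppositely oriented sources from
cancelling while keeping the series signed and zero-phase — a requirement
for the downstream MVAR/PDC estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .preproc import EpochSet
from .synth import LeadField

__all__ = [
    "InverseOperator",
    "compute_wmne_operator",
    "apply_inverse",
    "Parcellation",
    "load_default_parcellation",
    "RegionEpochs",
    "aggregate_regions",
    "MACRO_LABELS",
]

MACRO_LABELS = (
    "frontal_R", "frontal_L",
    "temporomedial_R", "temporomedial_L",
    "temporolateral_R", "temporolateral_L",
    "parietal_R", "parietal_L",
    "occipital_R", "occipital_L",
    "thalamus_R", "thalamus_L",
)


@dataclass
class InverseOperator:
    kernel: np.ndarray  # (n_sources, n_sensors)
    lambda_reg: float
    depth_gamma: float


def compute_wmne_operator(
    leadfield: LeadField,
    noise_cov: np.ndarray | None = None,
    lambda_reg: float | None = None,
    depth_gamma: float = 0.5,
) -> InverseOperator:
    """Build the depth-weighted minimum-norm kernel R G^T (G R G^T + l^2 C)^-1.

    ``noise_cov`` defaults to identity. When ``lambda_reg`` is None the
    source prior is scaled so trace(G R G^T) = trace(C) and lambda = 1/3
    (power SNR 3). ``lambda_reg=0`` is the unregularized limit and raises if
    the Gram matrix is singular.
    """
    G = leadfield.gain
    n_sensors, n_sources = G.shape
    C = np.eye(n_sensors) if noise_cov is None else np.asarray(noise_cov, float)
    if C.shape != (n_sensors, n_sensors):
        raise ValueError("noise_cov shape inconsistent with lead field")
    if not np.allclose(C, C.T) or np.linalg.eigvalsh(C).min() <= 0:
        raise ValueError("noise_cov must be symmetric positive definite")
    col_norms = np.linalg.norm(G, axis=0)
    if np.any(col_norms == 0):
        raise ValueError("lead field has all-zero columns")
    r = col_norms ** (-2.0 * depth_gamma)
    GR = G * r[None, :]
    gram = GR @ G.T  # G R G^T
    if lambda_reg is None:
        scale = np.trace(C) / np.trace(gram)
        r = r * scale
        gram = gram * scale
        GR = GR * scale
        lam = 1.0 / 3.0
    else:
        lam = float(lambda_reg)
    M = gram + lam**2 * C
    try:
        inv = np.linalg.inv(M)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "regularized Gram matrix is singular; the lead field is "
            "rank-deficient and lambda_reg = 0"
        ) from err
    if lam == 0 and np.linalg.matrix_rank(M) < n_sensors:
        raise np.linalg.LinAlgError(
            "Gram matrix rank-deficient at lambda_reg = 0"
        )
    kernel = GR.T @ inv
    return InverseOperator(kernel=kernel, lambda_reg=lam, depth_gamma=depth_gamma)


def apply_inverse(epoch_set: EpochSet | np.ndarray, operator: InverseOperator
                  ) -> np.ndarray:
    """Per-epoch matrix product (no temporal mixing): (E, n_sources, T)."""
    epochs = epoch_set.epochs if isinstance(epoch_set, EpochSet) else np.asarray(epoch_set)
    if epochs.ndim == 2:
        epochs = epochs[None]
    if epochs.shape[1] != operator.kernel.shape[1]:
        raise ValueError(
            f"epochs have {epochs.shape[1]} channels, operator expects "
            f"{operator.kernel.shape[1]}"
        )
    return np.einsum("sc,ect->est", operator.kernel, epochs)


@dataclass
class Parcellation:
    """Fine-to-macro region mapping (synthetic AAL-style stand-in by default)."""

    fine_regions: list[str]
    macro_map: dict[str, str]

    def __post_init__(self) -> None:
        missing = [f for f in self.fine_regions if f not in self.macro_map]
        if missing:
            raise ValueError(f"unmapped fine regions: {missing[:5]}")
        macros = set(self.macro_map.values())
        if macros != set(MACRO_LABELS):
            raise ValueError(
                f"macro labels must be exactly the 12 standard labels, got "
                f"{sorted(macros)}"
            )

    def macro_index(self, fine: str) -> int:
        return MACRO_LABELS.index(self.macro_map[fine])


def load_default_parcellation() -> Parcellation:
    """The packaged 104-fine-region table (synthetic stand-in mapping)."""
    with resources.files("restflow.data").joinpath(
        "aal_macro_map_synthetic.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return Parcellation(
        fine_regions=list(df["fine_region"]),
        macro_map=dict(zip(df["fine_region"], df["macro_region"])),
    )


@dataclass
class RegionEpochs:
    epochs: np.ndarray  # (n_epochs, n_regions, n_samples)
    fs_hz: float
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.shape[1] != len(self.region_labels):
            raise ValueError("one label per region required")


def aggregate_regions(
    source_epochs: np.ndarray,
    region_of_source: np.ndarray,
    fs_hz: float,
    region_labels: list[str] | None = None,
) -> RegionEpochs:
    """Sign-aligned mean source course per region.

    For each region the first principal temporal component of its sources
    (across concatenated epochs) defines the reference polarity; sources
    whose correlation with it is negative are flipped before averaging.
    Raises if a region has no sources.
    """
    src = np.asarray(source_epochs, dtype=float)
    if src.ndim == 2:
        src = src[None]
    E, n_src, T = src.shape
    region_of_source = np.asarray(region_of_source, dtype=int)
    if region_of_source.size != n_src:
        raise ValueError("one region index per source required")
    n_regions = int(region_of_source.max()) + 1
    if region_labels is None:
        region_labels = [f"region{r:02d}" for r in range(n_regions)]
    empty = [region_labels[r] for r in range(n_regions)
             if not np.any(region_of_source == r)]
    if empty:
        raise ValueError(f"regions without sources: {empty}")
    out = np.zeros((E, n_regions, T))
    for r in range(n_regions):
        idx = np.flatnonzero(region_of_source == r)
        block = src[:, idx, :]  # (E, k, T)
        flat = block.transpose(1, 0, 2).reshape(len(idx), E * T)
        flat = flat - flat.mean(axis=1, keepdims=True)
        # first principal temporal component defines the reference polarity
        u, s, vt = np.linalg.svd(flat, full_matrices=False)
        pc = vt[0]
        signs = np.sign(flat @ pc)
        signs[signs == 0] = 1.0
        # the PC's own sign is arbitrary; anchor polarity so the majority of
        # sources (first source on ties) keep theirs
        if signs.sum() < 0 or (signs.sum() == 0 and signs[0] < 0):
            signs = -signs
        out[:, r, :] = np.mean(signs[None, :, None] * block, axis=1)
    return RegionEpochs(epochs=out, fs_hz=fs_hz, region_labels=list(region_labels))
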