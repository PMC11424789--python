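"""Multivariate autoregressive (MVAR) models: containers, simulation and estimation.

An MVAR(p) model on n channels is

    x(t) = sum_{r=1..p} A_r x(t-r) + e(t),        e(t) ~ N(0, Sigma)

with coefficient matrices ``A_r`` (n x n) and innovation covariance ``Sigma``.
Stationarity is equivalent to the companion matrix having spectral radius < 1.

Estimation uses the Nuttall-Strand algorithm, a multichannel Burg-type lattice:
at each stage the partial cross-covariance between forward and (delayed)
backward prediction errors is chosen to minimize the sum of the two error
powers normalized by the previous-stage error covariances, which leads to a
Sylvester equation per stage. Unlike least squares, the lattice recursion
yields estimates that are stationary by construction, which matters when
short (5 s) epochs are fitted at high model order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_sylvester

__all__ = [
    "MVARModel",
    "companion_matrix",
    "spectral_radius",
    "simulate_mvar",
    "fit_mvar_nuttall_strand",
    "fit_mvar_epochs",
]


@dataclass
class MVARModel:
    """MVAR coefficient stack plus innovation covariance.

    Parameters
    ----------
    coeffs : ndarray, shape (order, n_channels, n_channels)
        ``coeffs[r-1, i, j]`` is the influence of channel j at lag r on
        channel i at lag 0 (dimensionless).
    noise_cov : ndarray, shape (n_channels, n_channels)
        Symmetric positive-definite innovation covariance (signal units^2).
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    order: int = field(init=False)
    n_channels: int = field(init=False)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (order, n, n)")
        self.order = int(self.coeffs.shape[0])
        self.n_channels = int(self.coeffs.shape[1])
        if self.order < 1 or self.n_channels < 1:
            raise ValueError("order and n_channels must be positive")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coeffs must be finite")
        if self.noise_cov.shape != (self.n_channels, self.n_channels):
            raise ValueError("noise_cov shape inconsistent with coeffs")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise ValueError("noise_cov must be positive definite")

    def companion(self) -> np.ndarray:
        return companion_matrix(self.coeffs)

    def spectral_radius(self) -> float:
        return spectral_radius(self.coeffs)

    def is_stable(self, margin: float = 1.0) -> bool:
        """True if the companion spectral radius is < ``margin``."""
        return self.spectral_radius() < margin


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Assemble the (p n) x (p n) companion matrix of an MVAR coefficient stack."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    C = np.zeros((p * n, p * n))
    C[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        C[n:, :-n] = np.eye(n * (p - 1))
    return C


def spectral_radius(coeffs: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(companion_matrix(coeffs))).max())


def simulate_mvar(
    model: MVARModel,
    n_samples: int,
    burn_in: int = 500,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate ``n_samples`` of the AR recursion with Gaussian innovations.

    The first ``burn_in`` samples are discarded so the returned series is
    (approximately) a draw from the stationary distribution. The same seed
    always yields the identical output.

    Returns
    -------
    ndarray, shape (n_channels, n_samples)
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not model.is_stable():
        raise ValueError(
            f"model is not stationary (companion spectral radius "
            f"{model.spectral_radius():.4f} >= 1)"
        )
    rng = np.random.default_rng(seed)
    n, p = model.n_channels, model.order
    total = n_samples + burn_in
    chol = np.linalg.cholesky(model.noise_cov)
    e = rng.standard_normal((total, n)) @ chol.T
    # coefficients flattened lag-major so each step is one matrix-vector product
    A2d = np.concatenate(list(model.coeffs), axis=1)  # (n, p*n)
    x = np.zeros((total + p, n))
    hist = np.zeros(p * n)
    for t in range(total):
        for r in range(p):
            hist[r * n : (r + 1) * n] = x[p + t - 1 - r]
        x[p + t] = A2d @ hist + e[t]
    return x[p + burn_in :].T.copy()


def _stage_matrices(f: np.ndarray, b: np.ndarray, m: int) -> tuple[np.ndarray, ...]:
    """Unbiased forward/backward/cross covariances of stage-(m-1) errors."""
    fm = f[..., m:]  # f_{m-1}(t), t = m..T-1
    bm = b[..., m - 1 : -1]  # b_{m-1}(t-1)
    cnt = fm.shape[-1]
    fmT = fm.swapaxes(-1, -2)
    bmT = bm.swapaxes(-1, -2)
    Rff = (fm @ fmT) / cnt
    Rbb = (bm @ bmT) / cnt
    Rfb = (fm @ bmT) / cnt
    return fm, bm, Rff, Rbb, Rfb


def fit_mvar_epochs(epochs: np.ndarray, order: int) -> list[MVARModel]:
    """Fit one Nuttall-Strand MVAR per epoch, batched over the epoch axis.

    Parameters
    ----------
    epochs : ndarray, shape (n_epochs, n_channels, n_samples)

    Notes
    -----
    All epochs share the lattice stage loop so the heavy covariance/update
    products run as batched matrix multiplies; the per-stage Sylvester solves
    (n x n) are done per epoch. Numerically identical to fitting each epoch
    separately.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must have shape (n_epochs, n_channels, n_samples)")
    E, n, T = epochs.shape
    if T <= order * 3:
        raise ValueError(
            f"need n_samples > 3*order ({order * 3}), got {T}"
        )
    x = epochs - epochs.mean(axis=-1, keepdims=True)
    f = x.copy()
    b = x.copy()
    pef = np.einsum("ect,edt->ecd", x, x) / T
    peb = pef.copy()
    eye = np.eye(n)
    A = np.zeros((E, order, n, n))
    B = np.zeros((E, order, n, n))
    for m in range(1, order + 1):
        fm, bm, Rff, Rbb, Rfb = _stage_matrices(f, b, m)
        Kf = np.empty((E, n, n))
        Kb = np.empty((E, n, n))
        for e in range(E):
            try:
                pef_inv = np.linalg.inv(pef[e])
                peb_inv = np.linalg.inv(peb[e])
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"singular prediction-error covariance at stage {m} "
                    f"(epoch {e}); check for rank-deficient/duplicated channels"
                ) from err
            delta = solve_sylvester(Rff[e] @ pef_inv, peb_inv @ Rbb[e], 2.0 * Rfb[e])
            Kf[e] = delta @ peb_inv
            Kb[e] = delta.T @ pef_inv
        # Levinson / Whittle-Wiggins-Robinson coefficient update
        if m > 1:
            Aprev = A[:, : m - 1].copy()
            Bprev = B[:, : m - 1].copy()
            A[:, : m - 1] = Aprev - Kf[:, None] @ Bprev[:, ::-1]
            B[:, : m - 1] = Bprev - Kb[:, None] @ Aprev[:, ::-1]
        A[:, m - 1] = Kf
        B[:, m - 1] = Kb
        fn = fm - Kf @ bm
        bn = bm - Kb @ fm
        pad = np.zeros((E, n, m))
        f = np.concatenate([pad, fn], axis=-1)
        b = np.concatenate([pad, bn], axis=-1)
        pef = (eye - Kf @ Kb) @ pef
        peb = (eye - Kb @ Kf) @ peb
    models = []
    for e in range(E):
        sig = 0.5 * (pef[e] + pef[e].T)
        # at high order the recursion can leave tiny negative eigenvalues;
        # clip to a small positive floor so the covariance stays usable
        w, V = np.linalg.eigh(sig)
        floor = max(w.max(), 1.0e-30) * 1e-10
        if w.min() < floor:
            sig = (V * np.maximum(w, floor)) @ V.T
            sig = 0.5 * (sig + sig.T)
        models.append(MVARModel(coeffs=A[e], noise_cov=sig))
    return models


def fit_mvar_nuttall_strand(series: np.ndarray, order: int = 40) -> MVARModel:
    """Fit an MVAR(order) model to one multichannel series by Nuttall-Strand.

    Parameters
    ----------
    series : ndarray, shape (n_channels, n_samples)
        The series is de-meaned internally. Covariance estimates use the
        unbiased normalization (division by the number of summed lag
        products at each stage).
    order : int
        Model order p (number of lags).

    Returns
    -------
    MVARModel
        Estimated coefficients and innovation covariance; the estimate is
        stationary by construction of the lattice recursion.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    return fit_mvar_epochs(series[None, :, :], order)[0]
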