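"""Seeded synthetic cohorts: directed source networks projected to sensors.

The patient recordings the analysis was designed for are confidential, so
this module generates cohorts from known ground truth. Each patient is a
stable MVAR network over 12 source regions whose diagonal blocks are damped
AR(2) oscillators (band centers assigned round-robin over the four standard
bands) and whose cross-couplings follow one of two archetypes around the
seizure onset zone (SOZ):

* ``isolated_soz`` ("seizure-free" outcome): weak couplings into the SOZ,
  restricted to a small SOZ-adjacent cluster that is itself densely
  interconnected — a structured, well-clustered epileptic network.
* ``diffuse_soz`` ("non-seizure-free"): strong couplings into the SOZ from
  every other region, with no extra cluster structure — an extensive,
  scattered network.

Region series are mixed to sensors through a synthetic lead field with
additive white noise at a configured SNR, and optional blink/cardiac-like
artifact segments exercise the preprocessing contract with known ground
truth. Every draw is a pure function of the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scipy.linalg import solve_discrete_lyapunov

from .mvar import MVARModel, companion_matrix, simulate_mvar, spectral_radius
from .preproc import SensorRecording

__all__ = [
    "NetworkArchetype",
    "ISOLATED_SOZ",
    "DIFFUSE_SOZ",
    "BAND_CENTERS",
    "CohortSpec",
    "LeadField",
    "PatientRecord",
    "CohortDataset",
    "build_archetype_mvar",
    "random_leadfield",
    "project_to_sensors",
    "generate_cohort",
    "simulate_mvar",
]

#: round-robin diagonal oscillator centers, one per standard band (Hz)
BAND_CENTERS = (2.5, 6.5, 10.5, 21.5)


@dataclass(frozen=True)
class NetworkArchetype:
    """Cross-coupling structure around the SOZ region.

    ``soz_in_gain``/``soz_out_gain`` scale couplings into/out of the SOZ;
    ``intra_cluster_gain`` scales couplings among the SOZ-adjacent cluster
    (isolated archetype only); ``band_center_hz`` tunes the oscillators of
    the SOZ (and its cluster) so SOZ-related structure lives in a known band.
    """

    label: str
    soz_in_gain: float
    soz_out_gain: float
    intra_cluster_gain: float
    band_center_hz: float = 2.5

    def __post_init__(self) -> None:
        if self.label not in ("isolated_soz", "diffuse_soz"):
            raise ValueError("label must be isolated_soz or diffuse_soz")
        for g in (self.soz_in_gain, self.soz_out_gain, self.intra_cluster_gain):
            if g < 0:
                raise ValueError("gains must be nonnegative")


ISOLATED_SOZ = NetworkArchetype("isolated_soz", soz_in_gain=0.08,
                                soz_out_gain=0.30, intra_cluster_gain=0.35)
DIFFUSE_SOZ = NetworkArchetype("diffuse_soz", soz_in_gain=0.35,
                               soz_out_gain=0.30, intra_cluster_gain=0.0)

# construction guarantee: the isolated archetype receives strictly less
assert ISOLATED_SOZ.soz_in_gain < DIFFUSE_SOZ.soz_in_gain


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic cohort."""

    n_per_group: int = 10
    n_regions: int = 12
    fs_hz: float = 1000.0
    n_epochs: int = 10
    epoch_s: float = 5.0
    n_sensors: int = 64
    snr_db: float = 10.0
    seed: int = 0
    sources_per_region: int = 3

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_regions", "n_epochs", "n_sensors",
                     "sources_per_region"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.fs_hz <= 0 or self.epoch_s <= 0:
            raise ValueError("fs_hz and epoch_s must be positive")
        n = self.epoch_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_s * fs_hz must be an integer sample count")

    def with_(self, **kw) -> "CohortSpec":
        return replace(self, **kw)


@dataclass
class LeadField:
    """Linear forward operator from sources to sensors.

    ``source_region_map[s]`` is the region index of source s and
    ``source_signs[s]`` its orientation sign relative to the region course.
    """

    gain: np.ndarray  # (n_sensors, n_sources)
    source_region_map: np.ndarray
    source_signs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_region_map = np.asarray(self.source_region_map, dtype=int)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain must be finite")
        if np.any(np.linalg.norm(self.gain, axis=0) == 0):
            raise ValueError("gain has all-zero columns")
        if self.gain.shape[1] != self.source_region_map.size:
            raise ValueError("one region index per source required")
        if self.source_signs is None:
            self.source_signs = np.ones(self.gain.shape[1])


def _ar2_block(center_hz: float, fs_hz: float, radius: float) -> tuple[float, float]:
    """Damped resonator: poles radius*exp(+-i 2 pi f0 / fs)."""
    w0 = 2.0 * np.pi * center_hz / fs_hz
    return 2.0 * radius * np.cos(w0), -radius * radius


def build_archetype_mvar(
    n_regions: int,
    archetype: NetworkArchetype,
    soz_region: int,
    fs_hz: float,
    seed: int | np.random.Generator | None = 0,
    n_cluster: int = 3,
    bg_density: float = 0.15,
    bg_gain: float = 0.10,
    pole_radius: float = 0.90,
    margin: float = 0.97,
    shrink: float = 0.95,
    max_iter: int = 200,
    inject_exponent: float = 0.0,
) -> MVARModel:
    """Assemble a stationary archetype network as an MVAR(2) ground truth.

    Diagonal blocks are damped AR(2) resonators; lag-1 cross-couplings
    follow the archetype plus a sparse random background among non-SOZ
    regions (density ``bg_density``, gain ``bg_gain``) so graphs are
    non-degenerate. All couplings respect a random topological order with
    the SOZ placed centrally (feeder regions rank before it, receiver
    regions after), making the coupling digraph acyclic: the companion
    spectrum then equals the diagonal oscillator poles exactly, so the
    model is stationary by construction and the configured gains are
    preserved verbatim in the ground truth. Low-frequency resonators have
    nearly defective pole pairs whose eigenvalues move like sqrt(coupling)
    under feedback, so acyclicity is what keeps strong couplings and
    stationarity compatible. A geometric down-scaling loop (factor
    ``shrink``, at most ``max_iter`` iterations) remains as a guard for
    pathological user gains and raises if it cannot reach the margin.
    """
    if n_regions < 3:
        raise ValueError("need at least 3 regions")
    if not (0 <= soz_region < n_regions):
        raise ValueError("soz_region out of range")
    rng = np.random.default_rng(seed)
    others = [r for r in range(n_regions) if r != soz_region]
    rng.shuffle(others)
    mid = len(others) // 2
    order = others[:mid] + [soz_region] + others[mid:]  # rank -> region
    rank = {r: k for k, r in enumerate(order)}
    feeders = others[:mid]
    receivers = others[mid:]
    # SOZ-adjacent cluster: one feeder, two receivers (rank-adjacent)
    cluster = [feeders[-1], receivers[0], receivers[1]] if len(receivers) >= 2 \
        else [feeders[-1]] + receivers

    centers = [BAND_CENTERS[k % len(BAND_CENTERS)] for k in range(n_regions)]
    centers[soz_region] = archetype.band_center_hz
    if archetype.label == "isolated_soz":
        for c in cluster:
            centers[c] = archetype.band_center_hz

    A = np.zeros((2, n_regions, n_regions))
    for k in range(n_regions):
        a1, a2 = _ar2_block(centers[k], fs_hz, pole_radius)
        A[0, k, k], A[1, k, k] = a1, a2

    coupling = np.zeros((n_regions, n_regions))  # coupling[i, j]: j -> i
    for j in range(n_regions):
        for i in range(n_regions):
            if i == j or i == soz_region or j == soz_region:
                continue
            if rank[j] < rank[i] and rng.random() < bg_density:
                coupling[i, j] = bg_gain
    if archetype.label == "isolated_soz":
        fdr, rcv = cluster[0], cluster[1:]
        coupling[soz_region, fdr] = archetype.soz_in_gain
        for c in rcv:
            coupling[c, soz_region] = archetype.soz_out_gain
        for a in cluster:
            for b in cluster:
                if a != b and rank[a] < rank[b]:
                    coupling[b, a] = archetype.intra_cluster_gain
    else:  # diffuse_soz: in-edges from every feeder, out-edges to every receiver
        for j in feeders:
            coupling[soz_region, j] = archetype.soz_in_gain
        for i in receivers:
            coupling[i, soz_region] = archetype.soz_out_gain

    # Source-normalized coupling: each edge j -> i injects the source signal
    # scaled to a fixed fraction (the nominal gain) of the receiver's
    # intrinsic oscillator amplitude. Without this, resonator chains amplify
    # variance multiplicatively, leaving downstream regions orders of
    # magnitude louder than their drivers — no sensor-noise level would then
    # be fair to all regions. With it, variances stay within about one
    # decade and the nominal gains keep their meaning in the coefficients.
    if coupling.any():
        sigma0 = _stationary_std(A * np.where(np.eye(n_regions, dtype=bool),
                                              1.0, 0.0)[None])
        inject = sigma0 ** inject_exponent
        sigma = sigma0.copy()
        for _ in range(3):
            A[0] = np.diag(np.diag(A[0])) + coupling * (
                inject[:, None] / sigma[None, :])
            sigma = _stationary_std(A)
    for _ in range(max_iter):
        if spectral_radius(A) <= margin:
            break
        if not coupling.any():
            raise RuntimeError(
                "diagonal blocks alone exceed the stability margin"
            )
        coupling *= shrink
        A[0] = np.diag(np.diag(A[0])) + coupling * (
            inject[:, None] / sigma[None, :])
    else:
        raise RuntimeError(
            f"failed to stabilize archetype model within {max_iter} scalings"
        )
    return MVARModel(coeffs=A, noise_cov=np.eye(n_regions))


def _stationary_std(coeffs: np.ndarray) -> np.ndarray:
    """Stationary per-channel standard deviations of an MVAR with unit
    innovations (companion-form discrete Lyapunov solve)."""
    p, n, _ = coeffs.shape
    comp = companion_matrix(coeffs)
    Q = np.zeros_like(comp)
    Q[:n, :n] = np.eye(n)
    P = solve_discrete_lyapunov(comp, Q)
    return np.sqrt(np.diag(P)[:n])


def random_leadfield(
    n_sensors: int,
    n_regions: int,
    sources_per_region: int = 3,
    seed: int | np.random.Generator | None = 0,
) -> LeadField:
    """Synthetic gain matrix: random sensor topographies with depth variation.

    Each region contributes ``sources_per_region`` sources whose columns are
    i.i.d. Gaussian topographies scaled by a random depth factor in
    [0.5, 1.6] (exercising depth weighting) and a random orientation sign.
    """
    rng = np.random.default_rng(seed)
    n_src = n_regions * sources_per_region
    gain = rng.standard_normal((n_sensors, n_src)) / np.sqrt(n_sensors)
    depth = rng.uniform(0.5, 1.6, size=n_src)
    gain *= depth
    region_map = np.repeat(np.arange(n_regions), sources_per_region)
    signs = rng.choice([-1.0, 1.0], size=n_src)
    return LeadField(gain=gain, source_region_map=region_map, source_signs=signs)


def project_to_sensors(
    region_series: np.ndarray,
    leadfield: LeadField,
    snr_db: float,
    seed: int | np.random.Generator | None = 0,
    fs_hz: float = 1000.0,
) -> SensorRecording:
    """Mix region courses to sensors and add white noise at the given SNR.

    Sources within a region share the region time course up to their
    orientation sign. Noise power is set so that
    10*log10(signal power / noise power) = ``snr_db``; ``snr_db=inf`` is
    noiseless.
    """
    region_series = np.asarray(region_series, dtype=float)
    n_regions = int(leadfield.source_region_map.max()) + 1
    if region_series.shape[0] != n_regions:
        raise ValueError(
            f"region count {region_series.shape[0]} inconsistent with "
            f"lead-field map ({n_regions} regions)"
        )
    rng = np.random.default_rng(seed)
    src = leadfield.source_signs[:, None] * region_series[leadfield.source_region_map]
    clean = leadfield.gain @ src
    if np.isinf(snr_db):
        data = clean
    else:
        p_sig = np.mean(clean**2)
        p_noise = p_sig * 10.0 ** (-snr_db / 10.0)
        data = clean + rng.standard_normal(clean.shape) * np.sqrt(p_noise)
    labels = [f"E{k + 1:03d}" for k in range(data.shape[0])]
    return SensorRecording(data=data, fs_hz=fs_hz, channel_labels=labels)


@dataclass
class PatientRecord:
    patient_id: str
    group: str
    soz_region: int
    recording: SensorRecording
    truth: MVARModel
    leadfield: LeadField
    seed: int


@dataclass
class CohortDataset:
    spec: CohortSpec
    patients: list[PatientRecord] = field(default_factory=list)

    def by_group(self, group: str) -> list[PatientRecord]:
        return [p for p in self.patients if p.group == group]


def _artifact_refs(n_samples: int, fs: float, segments: list[tuple[int, int]],
                   rng: np.random.Generator) -> np.ndarray:
    """Blink-like (~1 Hz bumps) and ECG-like (1.2 Hz spikes) reference traces,
    nonzero only inside the flagged segments."""
    t = np.arange(n_samples) / fs
    blink = np.zeros(n_samples)
    ecg = np.zeros(n_samples)
    for s0, s1 in segments:
        seg_t = t[s0:s1]
        for center in np.arange(seg_t[0] + 0.3, seg_t[-1] - 0.2, 1.0):
            blink[s0:s1] += np.exp(-0.5 * ((seg_t - center) / 0.06) ** 2)
        for center in np.arange(seg_t[0] + 0.2, seg_t[-1] - 0.1, 1.0 / 1.2):
            ecg[s0:s1] += (
                np.exp(-0.5 * ((seg_t - center) / 0.012) ** 2)
                - 0.4 * np.exp(-0.5 * ((seg_t - center - 0.03) / 0.02) ** 2)
            )
    return np.stack([blink, ecg])


def generate_cohort(
    spec: CohortSpec,
    include_artifacts: bool = True,
    archetypes: tuple[NetworkArchetype, NetworkArchetype] | None = None,
) -> CohortDataset:
    """Generate a full two-group cohort from the archetype networks.

    Seizure-free patients use ``ISOLATED_SOZ`` truth networks,
    non-seizure-free patients ``DIFFUSE_SOZ``; per-patient seeds derive
    deterministically from ``spec.seed``, so the cohort is a pure function
    of its spec. With ``include_artifacts`` two flagged artifact segments
    (one epoch long each) are inserted so that preprocessing has known
    ground truth to remove; the clean portion always holds exactly
    ``n_epochs`` disjoint epochs. ``archetypes`` overrides the
    (seizure_free, non_seizure_free) truth archetypes — e.g. the same
    archetype twice for a null cohort.
    """
    if archetypes is None:
        archetypes = (ISOLATED_SOZ, DIFFUSE_SOZ)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 * spec.n_per_group)
    win = int(round(spec.epoch_s * spec.fs_hz))
    dataset = CohortDataset(spec=spec)
    configs = [("sf", "seizure_free", archetypes[0]),
               ("nsf", "non_seizure_free", archetypes[1])]
    for gi, (prefix, group, archetype) in enumerate(configs):
        for k in range(spec.n_per_group):
            child = children[gi * spec.n_per_group + k]
            sub = child.spawn(5)
            rng_meta = np.random.default_rng(sub[0])
            soz = int(rng_meta.integers(spec.n_regions))
            truth = build_archetype_mvar(
                spec.n_regions, archetype, soz, spec.fs_hz, seed=sub[1]
            )
            if include_artifacts:
                n_blocks = spec.n_epochs + 2
                art_blocks = {max(1, n_blocks // 3), max(2, 2 * n_blocks // 3)}
            else:
                n_blocks = spec.n_epochs
                art_blocks = set()
            total = n_blocks * win
            series = simulate_mvar(truth, total, burn_in=500, seed=sub[2])
            lf = random_leadfield(spec.n_sensors, spec.n_regions,
                                  spec.sources_per_region, seed=sub[3])
            rec = project_to_sensors(series, lf, spec.snr_db, seed=sub[4],
                                     fs_hz=spec.fs_hz)
            clean_mask = np.ones(total, dtype=bool)
            if art_blocks:
                segments = [(b * win, (b + 1) * win) for b in sorted(art_blocks)]
                for s0, s1 in segments:
                    clean_mask[s0:s1] = False
                refs = _artifact_refs(total, spec.fs_hz, segments, rng_meta)
                amp = 8.0 * np.sqrt(np.mean(rec.data**2))
                topo_b = rng_meta.standard_normal(spec.n_sensors)
                topo_b /= np.linalg.norm(topo_b)
                topo_e = rng_meta.standard_normal(spec.n_sensors)
                topo_e /= np.linalg.norm(topo_e)
                rec.data += amp * np.outer(topo_b, refs[0])
                rec.data += 0.6 * amp * np.outer(topo_e, refs[1])
                rec.artifact_refs = refs
            rec.clean_mask = clean_mask
            dataset.patients.append(PatientRecord(
                patient_id=f"{prefix}{k + 1:02d}", group=group, soz_region=soz,
                recording=rec, truth=truth,
                leadfield=lf, seed=int(child.generate_state(1)[0] % (2**31)),
            ))
    return dataset
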