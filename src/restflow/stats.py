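"""Two-group comparison of connectivity measures: rank-sum tests and boxplots.

The two patient groups (seizure-free vs non-seizure-free) are compared for
every measure x band cell with the two-sided Wilcoxon rank-sum /
Mann-Whitney U test for independent samples. With the study's group sizes
(10 vs 10) and continuous measures the exact null distribution is
enumerated; ties or larger samples fall back to the normal approximation
with tie and continuity corrections. P-values are reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import MEASURE_NAMES, PatientFeatures
from .pdc import BAND_ORDER

__all__ = [
    "TestResult",
    "rank_sum_test",
    "compare_groups",
    "BoxplotSummary",
    "boxplot_summary",
    "GROUP_LABELS",
]

GROUP_LABELS = ("seizure_free", "non_seizure_free")

#: largest per-group size at which the exact null enumeration is used
EXACT_N_MAX = 12


@dataclass
class TestResult:
    u_statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U test (mid-ranks for ties).

    Exact p-value by full enumeration of the null rank distribution when the
    data are tie-free and max(n1, n2) <= 12; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (not has_ties) and max(x.size, y.size) <= EXACT_N_MAX
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        u_statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approx",
        n1=int(x.size),
        n2=int(y.size),
    )


def features_to_frame(features: list[PatientFeatures]) -> pd.DataFrame:
    """Long-format table: one row per patient x band x measure."""
    rows = []
    for f in features:
        for band, vals in f.values.items():
            for measure, v in vals.items():
                rows.append(
                    dict(patient_id=f.patient_id, group=f.group,
                         soz_region=f.soz_region, band=band,
                         measure=measure, value=v)
                )
    return pd.DataFrame(rows)


def compare_groups(features: list[PatientFeatures]) -> pd.DataFrame:
    """One uncorrected two-sided rank-sum test per measure x band (32 rows).

    Rows are ordered measure-major (inflow, outflow, degree, cost,
    clustering, local_efficiency, betweenness, avg_path_length) then by band
    (delta, theta, alpha, beta). The ``direction`` column flags whether the
    seizure-free group median is lower/higher than the non-seizure-free one.
    """
    groups = {g: [f for f in features if f.group == g] for g in GROUP_LABELS}
    for g, fs in groups.items():
        if len(fs) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 patients")
    unknown = {f.group for f in features} - set(GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    rows = []
    for measure in MEASURE_NAMES:
        for band in BAND_ORDER:
            samples = {}
            for g in GROUP_LABELS:
                vals = np.array(
                    [f.values[band][measure] for f in
                     sorted(groups[g], key=lambda f: f.patient_id)]
                )
                samples[g] = vals
            x, y = samples[GROUP_LABELS[0]], samples[GROUP_LABELS[1]]
            t = rank_sum_test(x, y)
            med = {g: float(np.median(v)) for g, v in samples.items()}
            q = {g: np.percentile(v, [25, 75]) for g, v in samples.items()}
            if med[GROUP_LABELS[0]] < med[GROUP_LABELS[1]]:
                direction = "sf_lower"
            elif med[GROUP_LABELS[0]] > med[GROUP_LABELS[1]]:
                direction = "sf_higher"
            else:
                direction = "equal"
            rows.append(dict(
                measure=measure, band=band,
                median_sf=med[GROUP_LABELS[0]],
                q1_sf=float(q[GROUP_LABELS[0]][0]), q3_sf=float(q[GROUP_LABELS[0]][1]),
                median_nsf=med[GROUP_LABELS[1]],
                q1_nsf=float(q[GROUP_LABELS[1]][0]), q3_nsf=float(q[GROUP_LABELS[1]][1]),
                u_statistic=t.u_statistic, p_value=t.p_two_sided,
                method=t.method, n1=t.n1, n2=t.n2, direction=direction,
            ))
    return pd.DataFrame(rows)


@dataclass
class BoxplotSummary:
    """Tukey five-number summary: whiskers at 1.5*IQR, type-7 quartiles."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def boxplot_summary(values: np.ndarray) -> BoxplotSummary:
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotSummary(
        minimum=float(v[0]), q1=float(q1), median=float(med), q3=float(q3),
        maximum=float(v[-1]),
        whisker_low=float(inside[0]), whisker_high=float(inside[-1]),
        outliers=[float(o) for o in outliers],
    )
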