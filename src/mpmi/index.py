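"""The Microbiome Protein Metabolism Index (MPMI).

For each sample the index is

    MPMI = 100 * a * (sum_i w_i C_i(N)) / (sum_i w_i C_i(D))

where C_i(N) and C_i(D) are the normalized abundances of the catalog's
numerator (desirable assimilation) and denominator (putrefaction)
reactions, w_i their stoichiometric weights (1 by default) and ``a`` a
global stoichiometric normalization constant.  With a = 1, MPMI = 100 marks
a balance between favorable and unfavorable protein metabolism; higher is
better.

The module also carries the thin statistical operations used to compare the
index between treatments and body-weight cohorts: Tukey-style outlier
fencing at 2×IQR, rank-based two-group and k-group tests, and the
mean-split / 10%-band cohort labelling of birds by body weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MarkerReaction
from .profiles import ECAbundanceMatrix


@dataclass(frozen=True)
class MpmiResult:
    sample_id: str
    mpmi_value: float  # NaN when the denominator sum is zero
    numerator_sum: float
    denominator_sum: float
    excluded_as_outlier: bool = False


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    test_name: str  # "mann_whitney" or "kruskal_wallis"


def compute_mpmi(
    matrix: ECAbundanceMatrix,
    markers: list[MarkerReaction],
    a: float = 1.0,
) -> tuple[list[MpmiResult], dict[str, list[str]]]:
    """Compute the index per sample.

    Catalog reactions absent from the matrix contribute 0 and are listed in
    the returned coverage report ``{"missing_numerator": [...],
    "missing_denominator": [...]}``.  A sample whose denominator sum is zero
    gets ``mpmi_value = NaN`` (flagged, never silently dropped).
    """
    if a <= 0:
        raise ValueError("normalization constant a must be > 0")
    num = [m for m in markers if m.role == "N"]
    den = [m for m in markers if m.role == "D"]
    cols = set(matrix.ec_ids)
    coverage = {
        "missing_numerator": sorted(m.ec_number for m in num if m.ec_number not in cols),
        "missing_denominator": sorted(m.ec_number for m in den if m.ec_number not in cols),
    }

    def weighted_sum(group: list[MarkerReaction]) -> pd.Series:
        total = pd.Series(0.0, index=matrix.abundance.index)
        for m in group:
            if m.ec_number in cols:
                total = total + m.stoich_weight * matrix.abundance[m.ec_number]
        return total

    num_sum = weighted_sum(num)
    den_sum = weighted_sum(den)
    results = []
    for sample in matrix.sample_ids:
        ns, ds = float(num_sum[sample]), float(den_sum[sample])
        value = 100.0 * a * ns / ds if ds > 0 else float("nan")
        results.append(
            MpmiResult(
                sample_id=str(sample),
                mpmi_value=value,
                numerator_sum=ns,
                denominator_sum=ds,
            )
        )
    return results, coverage


def exclude_outliers(
    values: list[float] | np.ndarray,
    k: float = 2.0,
    mode: str = "tukey",
) -> tuple[list[float], list[float]]:
    """Split values into (kept, excluded) by an IQR fence.

    ``mode="tukey"`` (default): exclude outside [Q1 − k·IQR, Q3 + k·IQR],
    quartiles by linear interpolation.  ``mode="median"``: the alternative
    reading — exclude outside median ± k·IQR.  Fewer than 4 values: no
    exclusion (a warning-level degenerate case).
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        return vals, []
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
    iqr = q3 - q1
    if mode == "tukey":
        lo, hi = q1 - k * iqr, q3 + k * iqr
    elif mode == "median":
        med = float(np.median(vals))
        lo, hi = med - k * iqr, med + k * iqr
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    kept = [v for v in vals if lo <= v <= hi]
    excluded = [v for v in vals if not (lo <= v <= hi)]
    return kept, excluded


def compare_groups(*groups: list[float], labels: list[str] | None = None) -> GroupComparison:
    """Rank-based comparison of 2 (Mann-Whitney U) or more (Kruskal-Wallis)
    groups of index values.

    Two-sided throughout.  For two groups with both n ≤ 8 and no ties the
    exact small-sample null is used; otherwise the normal approximation
    with tie correction.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    if len(groups) == 2:
        a, b = groups
        method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
        try:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:  # ties make the exact null unavailable
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return GroupComparison(labels[0], labels[1], float(res.statistic),
                               float(res.pvalue), "mann_whitney")
    res = stats.kruskal(*groups)
    return GroupComparison(labels[0], labels[-1], float(res.statistic),
                           float(res.pvalue), "kruskal_wallis")


def cohort_split(
    weights: pd.Series,
    mode: str = "mean-split",
    tie: str = "low",
) -> pd.Series:
    """Label birds Low/High body weight relative to the group mean.

    ``mode="mean-split"``: below the mean → ``"Low"``, above → ``"High"``;
    a weight exactly at the mean goes to the side named by ``tie``
    ("low", default, or "high").  ``mode="10pct"``: ≤ 0.9×mean → ``"Low"``,
    ≥ 1.1×mean → ``"High"``, the middle band is left unlabeled (NaN).
    """
    if len(weights) == 0:
        raise ValueError("empty weights")
    if (np.asarray(weights, dtype=float) <= 0).any():
        raise ValueError("weights must be positive")
    mean = float(np.mean(weights))
    labels = pd.Series(index=weights.index, dtype=object)
    for idx, w in weights.items():
        w = float(w)
        if mode == "mean-split":
            if w < mean:
                labels[idx] = "Low"
            elif w > mean:
                labels[idx] = "High"
            else:
                labels[idx] = "Low" if tie == "low" else "High"
        elif mode == "10pct":
            if w <= 0.9 * mean:
                labels[idx] = "Low"
            elif w >= 1.1 * mean:
                labels[idx] = "High"
            else:
                labels[idx] = None
        else:
            raise ValueError(f"unknown cohort mode {mode!r}")
    return labels


def results_frame(results: list[MpmiResult]) -> pd.DataFrame:
    """Results as a one-row-per-sample DataFrame (the CLI's output table)."""
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "mpmi": [r.mpmi_value for r in results],
            "numerator_sum": [r.numerator_sum for r in results],
            "denominator_sum": [r.denominator_sum for r in results],
            "excluded_as_outlier": [r.excluded_as_outlier for r in results],
        }
    ).set_index("sample")


def flag_outliers(
    results: list[MpmiResult], k: float = 2.0, mode: str = "tukey"
) -> list[MpmiResult]:
    """Return results with ``excluded_as_outlier`` set by the IQR fence
    over the finite index values."""
    finite = [r.mpmi_value for r in results if math.isfinite(r.mpmi_value)]
    _, excluded = exclude_outliers(finite, k=k, mode=mode)
    excluded_set = set(excluded)
    return [
        MpmiResult(
            r.sample_id,
            r.mpmi_value,
            r.numerator_sum,
            r.denominator_sum,
            excluded_as_outlier=math.isfinite(r.mpmi_value)
            and r.mpmi_value in excluded_set,
        )
        for r in results
    ]
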