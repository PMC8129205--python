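"""Rank-based group comparisons with FDR control.

Morphometric and projection-density features are compared between groups
with two-sided Wilcoxon rank-sum (Mann-Whitney) tests — exact null
distribution for small untied samples, normal approximation with
continuity correction otherwise — and Benjamini-Hochberg FDR adjustment
applied jointly across the whole feature-by-group-pair family.  Effect
sizes are Hodges-Lehmann location-shift estimates (median of pairwise
differences) with the standard order-statistic confidence interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    pvalue: float
    shift: float  # Hodges-Lehmann estimate, first minus second sample
    ci_low: float
    ci_high: float


def hodges_lehmann(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Median of pairwise differences x_i - y_j with order-statistic CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    est = float(np.median(diffs))
    n1, n2 = len(x), len(y)
    npairs = n1 * n2
    z = sps.norm.ppf(1 - alpha / 2)
    k = int(np.floor(npairs / 2 - z * np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)))
    k = max(k, 0)
    lo = diffs[min(k, npairs - 1)]
    hi = diffs[max(npairs - 1 - k, 0)]
    return est, float(lo), float(hi)


def rank_sum_test(x, y, alpha: float = 0.05) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with Hodges-Lehmann shift.

    The statistic is the Mann-Whitney U of the first sample (its rank sum
    minus the minimum possible).  Samples in which every value is tied give
    p = 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    est, lo, hi = hodges_lehmann(x, y, alpha=alpha)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankSumResult(
            statistic=len(x) * len(y) / 2.0, pvalue=1.0, shift=est,
            ci_low=lo, ci_high=hi,
        )
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="auto", use_continuity=True
    )
    return RankSumResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        shift=est,
        ci_low=lo,
        ci_high=hi,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pairwise_wilcoxon_fdr(
    features: pd.DataFrame,
    groups,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise rank-sum tests for every feature, BH-adjusted jointly.

    ``features`` holds one row per observation and one numeric column per
    feature; ``groups`` is the per-row group label.  Every (feature, group
    pair) combination is tested and the BH adjustment runs across the full
    family.  Returns a table with statistic W, raw and adjusted p, and the
    Hodges-Lehmann shift (group1 minus group2) with its CI.
    """
    groups = np.asarray(list(groups), dtype=object)
    if len(groups) != len(features):
        raise ValueError("groups must label every feature row")
    names, counts = np.unique(groups.astype(str), return_counts=True)
    if len(names) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    num = features.select_dtypes(include=[np.number])
    records = []
    for feat in num.columns:
        col = num[feat].to_numpy(float)
        for g1, g2 in itertools.combinations(names, 2):
            x = col[(groups.astype(str) == g1) & ~np.isnan(col)]
            y = col[(groups.astype(str) == g2) & ~np.isnan(col)]
            if len(x) < 2 or len(y) < 2:
                continue
            r = rank_sum_test(x, y, alpha=alpha)
            records.append(
                {
                    "feature": feat,
                    "group1": g1,
                    "group2": g2,
                    "W": r.statistic,
                    "p": r.pvalue,
                    "shift": r.shift,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                }
            )
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    return table
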