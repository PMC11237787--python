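"""Two-group feature statistics with a normality-gated test choice.

For every feature the comparison proceeds as the original analysis did:

1. Kolmogorov-Smirnov normality check in each group.  Because the
   normal's parameters are estimated from the sample, the plain KS
   p-value would be anticonservative; the Lilliefors-corrected variant
   is used.
2. If *both* groups look normal at alpha = .05, a two-tailed t test
   (Welch by default; a pooled-variance flag is exposed since the
   original software's choice is ambiguous).  Otherwise the Mann-Whitney
   U test: exact enumeration when both samples are small (n <= 12,
   no ties), else the tie-corrected normal approximation with
   continuity correction.
3. The Hodges-Lehmann location-shift estimate (median of all pairwise
   MCI - HC differences) with its distribution-free 95% CI is reported
   in every case.

No multiple-testing correction is applied: features are filtered at raw
P < .05, faithfully to the analysis being reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .errors import InsufficientDataError, UndefinedStatisticError

ALPHA = 0.05


@dataclass
class HodgesLehmann:
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


@dataclass
class GroupComparison:
    feature_id: str
    n_hc: int
    n_mci: int
    normality_p_hc: float
    normality_p_mci: float
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p_value: float
    hl: HodgesLehmann
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def normality_test(values: Sequence[float]) -> float:
    """Lilliefors-corrected Kolmogorov-Smirnov p against a fitted normal.

    A constant sample is degenerate non-normal and returns p = 0.0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InsufficientDataError(
            f"normality test needs n >= 4 observations, got {x.size}"
        )
    if np.ptp(x) == 0:
        return 0.0
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


def hodges_lehmann(
    hc_values: Sequence[float],
    mci_values: Sequence[float],
    confidence: float = 0.95,
) -> HodgesLehmann:
    """Median of all pairwise (MCI - HC) differences, with a
    distribution-free CI from the ordered pairwise differences.

    The CI rank uses the large-sample normal approximation to the
    Mann-Whitney count: k = floor(nm/2 - z * sqrt(nm(n+m+1)/12)).
    """
    hc = np.asarray(hc_values, dtype=float)
    mci = np.asarray(mci_values, dtype=float)
    if hc.size == 0 or mci.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    diffs = np.sort((mci[:, None] - hc[None, :]).ravel())
    est = float(np.median(diffs))
    n, m = hc.size, mci.size
    nm = n * m
    z = sps.norm.ppf(0.5 + confidence / 2)
    k = int(math.floor(nm / 2 - z * math.sqrt(nm * (n + m + 1) / 12.0)))
    k = max(k, 0)
    lo = float(diffs[min(k, nm - 1)])
    hi = float(diffs[max(nm - 1 - k, 0)])
    return HodgesLehmann(estimate=est, ci_low=lo, ci_high=hi, confidence=confidence)


def mann_whitney(
    hc_values: Sequence[float], mci_values: Sequence[float]
) -> tuple[float, float, str]:
    """(z or U statistic, two-sided p, method used).

    Exact enumeration when both n <= 12 and there are no ties across the
    pooled sample; otherwise the tie-corrected normal approximation with
    continuity correction.  The reported statistic is the approximation's
    z score (0.0 under the exact method for identical samples yields no z;
    the U statistic is returned instead).
    """
    hc = np.asarray(hc_values, dtype=float)
    mci = np.asarray(mci_values, dtype=float)
    pooled = np.concatenate([hc, mci])
    no_ties = np.unique(pooled).size == pooled.size
    if hc.size <= 12 and mci.size <= 12 and no_ties:
        res = sps.mannwhitneyu(mci, hc, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(
        mci, hc, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    # convert U back to the z score for reporting
    n, m = hc.size, mci.size
    u = float(res.statistic)
    mu = n * m / 2.0
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n + m) * (n + m - 1.0)) if n + m > 1 else 0.0
    var = n * m / 12.0 * ((n + m + 1) - tie_term)
    z = 0.0 if var == 0 else (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)
    return float(z), float(res.pvalue), "asymptotic"


def compare_feature(
    hc_values: Sequence[float],
    mci_values: Sequence[float],
    alpha: float = ALPHA,
    feature_id: str = "",
    pooled_t: bool = False,
) -> GroupComparison:
    """Normality-gated two-group comparison of one feature."""
    hc = np.asarray(hc_values, dtype=float)
    mci = np.asarray(mci_values, dtype=float)
    if hc.size < 4 or mci.size < 4:
        raise InsufficientDataError(
            f"compare_feature needs n >= 4 per group, got {hc.size}/{mci.size}"
        )
    p_hc = normality_test(hc)
    p_mci = normality_test(mci)
    hl = hodges_lehmann(hc, mci)
    if p_hc >= alpha and p_mci >= alpha:
        res = sps.ttest_ind(mci, hc, equal_var=pooled_t)
        return GroupComparison(
            feature_id=feature_id,
            n_hc=hc.size,
            n_mci=mci.size,
            normality_p_hc=p_hc,
            normality_p_mci=p_mci,
            test_used="t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            hl=hl,
            alpha=alpha,
        )
    stat, p, _ = mann_whitney(hc, mci)
    return GroupComparison(
        feature_id=feature_id,
        n_hc=hc.size,
        n_mci=mci.size,
        normality_p_hc=p_hc,
        normality_p_mci=p_mci,
        test_used="mann_whitney",
        statistic=stat,
        p_value=p,
        hl=hl,
        alpha=alpha,
    )


def significant_features(
    comparisons: Sequence[GroupComparison] | Sequence[tuple[str, float]],
    alpha: float = ALPHA,
) -> list[str]:
    """Feature ids with p < alpha, preserving the input (catalog) order.

    Accepts either :class:`GroupComparison` objects or (id, p) pairs.
    """
    out = []
    for c in comparisons:
        if isinstance(c, GroupComparison):
            fid, p = c.feature_id, c.p_value
        else:
            fid, p = c
        if p < alpha:
            out.append(fid)
    return out


def chi_square(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2 x k table."""
    arr = np.asarray(table, dtype=float)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if np.any(expected <= 0):
        raise UndefinedStatisticError(
            "zero expected cell count; an exact test would be required"
        )
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientDataError("x and y must be paired (equal length)")
    if x.size < 5:
        raise InsufficientDataError(f"spearman needs n >= 5 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
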