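"""Splicing metrics and exact contingency comparisons.

Over the informative reads of a sample — canonical-junction count *j* and
intron-contained count *i* — intron-retention percent-spliced-in is

    PSI = i / (j + i)

and splicing efficiency is its complement j / (j + i).  Both are undefined
(reported as not-available, never coerced to 0) when j + i = 0: a silenced
locus must remain distinguishable from a perfectly spliced one.
Cryptic-junction reads are excluded from both terms and reported separately.

Group differences are assessed on pooled (j, i) counts with a two-sided
Fisher exact test using the point-probability rule: the p-value is the sum of
hypergeometric probabilities, over all tables with the observed margins, that
do not exceed the probability of the observed table.  The test here is
computed with exact integer arithmetic, so ties are decided exactly and the
returned p-value is the correctly rounded double of an exact rational.  The
reported odds ratio is the sample (cross-product) odds ratio (a·d)/(b·c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ReadClassCounts
from .errors import ContractError

__all__ = [
    "SplicingMetrics",
    "ComparisonResult",
    "ReplicateSummary",
    "compute_metrics",
    "clopper_pearson",
    "fisher_exact_two_sided",
    "compare_groups",
    "summarize_replicates",
    "metrics_to_frame",
    "comparisons_to_frame",
    "significance_stars",
]


@dataclass(frozen=True)
class SplicingMetrics:
    """PSI, efficiency and an exact binomial CI for one sample or pooled group."""

    sample_or_group_id: str
    junction: int
    intron: int
    psi: Optional[float]
    efficiency: Optional[float]
    psi_ci: Optional[Tuple[float, float]]
    ci_level: float = 0.95

    @property
    def informative(self) -> int:
        return self.junction + self.intron


def clopper_pearson(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for k successes of n."""
    if not 0 <= k <= n or n < 1:
        raise ContractError(f"invalid Clopper-Pearson input k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


def compute_metrics(counts: ReadClassCounts, ci_level: float = 0.95) -> SplicingMetrics:
    """PSI and efficiency from classified counts; undefined on zero denominator."""
    j, i = counts.canonical_junction, counts.intron_contained
    n = j + i
    if n == 0:
        return SplicingMetrics(counts.sample_id, j, i, None, None, None, ci_level)
    psi = i / n
    return SplicingMetrics(
        sample_or_group_id=counts.sample_id,
        junction=j,
        intron=i,
        psi=psi,
        efficiency=j / n,
        psi_ci=clopper_pearson(i, n, ci_level),
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# Fisher exact test, point-probability two-sided rule, exact arithmetic
# ---------------------------------------------------------------------------

# Above this grand total the exact integer path would multiply thousands of
# huge binomials; point-mass ties are then resolved with the 1e-7 relative
# tolerance conventional for exact tests (as in scipy and R).
_EXACT_TOTAL_LIMIT = 1024


def _margin_pvalues_float(r1: int, c1: int, n: int) -> Tuple[int, Tuple[float, ...]]:
    a_min = max(0, r1 + c1 - n)
    a_max = min(r1, c1)
    support = np.arange(a_min, a_max + 1)
    pmf = np.exp(stats.hypergeom.logpmf(support, n, r1, c1))
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1 + 1e-7), side="right")
    pvals = np.clip(csum[idx - 1], 5e-324, 1.0)
    return a_min, tuple(float(p) for p in pvals)


@lru_cache(maxsize=4096)
def _margin_pvalues(r1: int, c1: int, n: int) -> Tuple[int, Tuple[float, ...]]:
    """Two-sided p-values for every table with margins (r1, n-r1) x (c1, n-c1).

    Returns ``(a_min, pvalues)`` where ``pvalues[a - a_min]`` is the p-value
    for top-left cell ``a``.  For grand totals up to ``_EXACT_TOTAL_LIMIT``
    the hypergeometric point masses share the denominator C(n, c1);
    numerators C(r1, a)·C(n-r1, c1-a) are exact integers, so the
    "probability not exceeding the observed" rule involves only integer
    comparisons and the final division is a single correctly rounded float
    operation.  Larger tables use a vectorized hypergeometric evaluation.
    """
    if n > _EXACT_TOTAL_LIMIT:
        return _margin_pvalues_float(r1, c1, n)
    a_min = max(0, r1 + c1 - n)
    a_max = min(r1, c1)
    comb = math.comb
    nums = [comb(r1, a) * comb(n - r1, c1 - a) for a in range(a_min, a_max + 1)]
    denom = comb(n, c1)
    order = sorted(range(len(nums)), key=nums.__getitem__)
    pvals: List[float] = [0.0] * len(nums)
    running = 0
    k = 0
    m = len(order)
    while k < m:
        # advance over a tie-group of exactly equal point masses
        j = k
        v = nums[order[k]]
        tie_sum = 0
        while j < m and nums[order[j]] == v:
            tie_sum += v
            j += 1
        running += tie_sum
        p = running / denom
        if p > 1.0:
            p = 1.0
        elif p == 0.0:
            p = 5e-324  # observed table always has positive mass
        for t in range(k, j):
            pvals[order[t]] = p
        k = j
    return a_min, tuple(pvals)


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p_value)``.  The odds ratio is (a·d)/(b·c):
    ``inf`` when b·c = 0 with a·d > 0, ``nan`` (not-available) when both
    cross products are 0.  Raises on negative cells or an all-zero table.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ContractError("contingency cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ContractError("all-zero contingency table")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    a_min, pvals = _margin_pvalues(a + b, a + c, n)
    return odds, pvals[a - a_min]


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise group comparison on pooled junction/intron counts."""

    group_a: str
    group_b: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: Optional[float]
    p_value: Optional[float]
    adjusted_p: Optional[float]
    method: str = "fisher_exact_two_sided"

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def _adjust_pvalues(pvals: List[float], method: str) -> List[float]:
    """Bonferroni or Benjamini-Hochberg adjustment over the full pair set."""
    m = len(pvals)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if method == "bh":
        order = sorted(range(m), key=pvals.__getitem__)
        adjusted = [0.0] * m
        running_min = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running_min = min(running_min, pvals[idx] * m / (rank + 1))
            adjusted[idx] = running_min
        return adjusted
    raise ContractError(f"unknown adjustment method {method!r}")


def compare_groups(groups: Sequence[Tuple[str, ReadClassCounts]],
                   adjust: str = "none") -> List[ComparisonResult]:
    """Two-sided Fisher exact test for every unordered pair of groups.

    Tables are built from pooled canonical-junction and intron-contained
    counts: ``[[junction_a, intron_a], [junction_b, intron_b]]``.  A group
    with no informative reads makes its pairs not-testable (p and odds
    reported as not-available); other pairs are unaffected.  Optional
    Bonferroni or BH adjustment is applied over the testable pairs.
    """
    if len(groups) < 2:
        raise ContractError("compare_groups requires at least 2 groups")
    if adjust not in ("none", "bonferroni", "bh"):
        raise ContractError(f"unknown adjustment {adjust!r}")
    results: List[ComparisonResult] = []
    for (ga, ca), (gb, cb) in combinations(groups, 2):
        tbl = ((ca.canonical_junction, ca.intron_contained),
               (cb.canonical_junction, cb.intron_contained))
        if sum(tbl[0]) == 0 or sum(tbl[1]) == 0:
            results.append(ComparisonResult(ga, gb, tbl, None, None, None))
            continue
        odds, p = fisher_exact_two_sided(tbl)
        results.append(ComparisonResult(ga, gb, tbl, odds, p, None))
    if adjust != "none":
        testable_idx = [k for k, r in enumerate(results) if r.testable]
        adjusted = _adjust_pvalues([results[k].p_value for k in testable_idx], adjust)
        for k, adj in zip(testable_idx, adjusted):
            r = results[k]
            results[k] = ComparisonResult(
                r.group_a, r.group_b, r.table, r.odds_ratio, r.p_value, adj,
                method=f"{r.method}+{adjust}",
            )
    return results


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean/SD of per-replicate PSI and efficiency (figure-style summaries)."""

    group_id: str
    n_replicates: int
    n_undefined: int
    mean_psi: Optional[float]
    sd_psi: Optional[float]
    mean_efficiency: Optional[float]
    sd_efficiency: Optional[float]


def summarize_replicates(per_replicate: Sequence[SplicingMetrics],
                         group_id: str) -> ReplicateSummary:
    """Mean and sample SD (n-1 denominator) over defined replicate values.

    Replicates with undefined PSI are excluded and their number reported;
    SD is not-available with fewer than two defined replicates.
    """
    if not per_replicate:
        raise ContractError("summarize_replicates requires >= 1 replicate")
    psis = [m.psi for m in per_replicate if m.psi is not None]
    effs = [m.efficiency for m in per_replicate if m.efficiency is not None]
    n_undef = len(per_replicate) - len(psis)
    if not psis:
        return ReplicateSummary(group_id, 0, n_undef, None, None, None, None)
    sd_psi = float(np.std(psis, ddof=1)) if len(psis) >= 2 else None
    sd_eff = float(np.std(effs, ddof=1)) if len(effs) >= 2 else None
    return ReplicateSummary(
        group_id=group_id,
        n_replicates=len(psis),
        n_undefined=n_undef,
        mean_psi=float(np.mean(psis)),
        sd_psi=sd_psi,
        mean_efficiency=float(np.mean(effs)),
        sd_efficiency=sd_eff,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def significance_stars(p: Optional[float]) -> str:
    """Figure-legend convention: * P<0.05, ** P<0.01, *** P<0.001."""
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def metrics_to_frame(metrics: Sequence[SplicingMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        ci = m.psi_ci or (None, None)
        rows.append({
            "id": m.sample_or_group_id,
            "junction": m.junction,
            "intron": m.intron,
            "psi": m.psi,
            "efficiency": m.efficiency,
            "ci_low": ci[0],
            "ci_high": ci[1],
        })
    return pd.DataFrame(
        rows, columns=["id", "junction", "intron", "psi", "efficiency",
                       "ci_low", "ci_high"]
    )


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        (a, b), (c, d) = r.table
        odds = r.odds_ratio
        rows.append({
            "group_a": r.group_a,
            "group_b": r.group_b,
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": None if odds is None or math.isnan(odds) else odds,
            "p_value": r.p_value,
            "adjusted_p": r.adjusted_p,
            "method": r.method,
            "stars": significance_stars(r.p_value),
        })
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "a", "b", "c", "d", "odds_ratio",
                       "p_value", "adjusted_p", "method", "stars"]
    )
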