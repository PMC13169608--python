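"""PSI/efficiency, exact Fisher test, group comparisons, replicate summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from splicequant.classify import ReadClassCounts
from splicequant.errors import ContractError
from splicequant.metrics import (
    clopper_pearson,
    compare_groups,
    comparisons_to_frame,
    compute_metrics,
    fisher_exact_two_sided,
    metrics_to_frame,
    significance_stars,
    summarize_replicates,
)


def _counts(j, i, cryptic=0, other=0, sid="s"):
    return ReadClassCounts(sample_id=sid, canonical_junction=j,
                           cryptic_junction=cryptic, intron_contained=i,
                           unclassified=other)


# --- PSI / efficiency ------------------------------------------------------

@pytest.mark.parametrize("j,i,psi,eff", [
    (90, 10, 0.10, 0.90),
    (0, 25, 1.0, 0.0),
    (25, 0, 0.0, 1.0),
])
def test_psi_and_efficiency(j, i, psi, eff):
    m = compute_metrics(_counts(j, i))
    assert m.psi == pytest.approx(psi)
    assert m.efficiency == pytest.approx(eff)
    assert m.psi + m.efficiency == 1.0  # exact complement


def test_zero_informative_reads_gives_undefined_not_zero():
    m = compute_metrics(_counts(0, 0, cryptic=5, other=100))
    assert m.psi is None and m.efficiency is None and m.psi_ci is None


def test_cryptic_reads_excluded_from_psi_terms():
    assert compute_metrics(_counts(90, 10, cryptic=900)).psi == pytest.approx(0.10)


@given(j=st.integers(0, 10_000), i=st.integers(0, 10_000))
def test_psi_plus_efficiency_is_exactly_one(j, i):
    m = compute_metrics(_counts(j, i))
    if m.psi is None:
        assert j + i == 0
    else:
        assert m.psi + m.efficiency == 1.0
        lo, hi = m.psi_ci
        assert 0.0 <= lo <= m.psi <= hi <= 1.0


@given(j=st.integers(0, 500), i=st.integers(0, 500))
def test_psi_strictly_increases_with_intron_reads(j, i):
    base = compute_metrics(_counts(j, i))
    bumped = compute_metrics(_counts(j, i + 1))
    if base.psi is None:
        assert bumped.psi == 1.0
    elif j > 0:
        assert bumped.psi > base.psi
    else:
        assert bumped.psi == base.psi == 1.0  # already all-intron


def test_clopper_pearson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint
    for k, n in [(10, 100), (0, 50), (50, 50), (3, 7)]:
        lo, hi = clopper_pearson(k, n)
        slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(slo, abs=1e-12)
        assert hi == pytest.approx(shi, abs=1e-12)


# --- Fisher exact ----------------------------------------------------------

def _enumeration_pvalue(a, b, c, d):
    """Independent oracle: exact hypergeometric enumeration (transposed margins)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    a_min, a_max = max(0, r1 + c1 - n), min(r1, c1)
    nums = [math.comb(c1, x) * math.comb(n - c1, r1 - x)
            for x in range(a_min, a_max + 1)]
    obs = nums[a - a_min]
    return sum(v for v in nums if v <= obs) / math.comb(n, r1)


def test_fisher_61_table_example_matches_enumeration():
    _, p = fisher_exact_two_sided([[10, 90], [50, 50]])
    assert p == pytest.approx(_enumeration_pvalue(10, 90, 50, 50), abs=1e-14)
    assert p < 1e-8  # strongly unbalanced table


@pytest.mark.parametrize("table,p", [
    ([[5, 5], [5, 5]], 1.0),     # modal symmetric table
    ([[0, 10], [0, 20]], 1.0),   # degenerate column: single attainable table
])
def test_fisher_degenerate_tables(table, p):
    assert fisher_exact_two_sided(table)[1] == p


def test_fisher_odds_ratio_conventions():
    assert fisher_exact_two_sided([[10, 90], [50, 50]])[0] == pytest.approx(
        (10 * 50) / (90 * 50))
    assert fisher_exact_two_sided([[5, 0], [5, 5]])[0] == math.inf
    assert math.isnan(fisher_exact_two_sided([[0, 10], [0, 20]])[0])


def test_fisher_rejects_invalid_tables():
    with pytest.raises(ContractError):
        fisher_exact_two_sided([[0, 0], [0, 0]])
    with pytest.raises(ContractError):
        fisher_exact_two_sided([[-1, 2], [3, 4]])


@given(a=st.integers(0, 80), b=st.integers(0, 80),
       c=st.integers(0, 80), d=st.integers(0, 80))
def test_fisher_properties(a, b, c, d):
    if a + b + c + d == 0:
        return
    _, p = fisher_exact_two_sided([[a, b], [c, d]])
    assert 0.0 < p <= 1.0
    # invariant under simultaneous row swap and column swap
    _, p_swapped = fisher_exact_two_sided([[d, c], [b, a]])
    assert p == pytest.approx(p_swapped, abs=1e-14)
    # exact enumeration agreement
    assert p == pytest.approx(_enumeration_pvalue(a, b, c, d), abs=1e-13)


def test_fisher_agrees_with_scipy_cross_check():
    rng = np.random.default_rng(7)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 200, size=4)
        if a + b + c + d == 0:
            continue
        _, p = fisher_exact_two_sided([[a, b], [c, d]])
        assert p == pytest.approx(
            stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12)


# --- group comparisons -----------------------------------------------------

def test_three_groups_give_three_pairs():
    groups = [("H1", _counts(900, 100)), ("KO", _counts(850, 150)),
              ("FXS", _counts(500, 500))]
    results = compare_groups(groups)
    assert len(results) == 3
    assert {(r.group_a, r.group_b) for r in results} == {
        ("H1", "KO"), ("H1", "FXS"), ("KO", "FXS")}


def test_identical_groups_have_p_one():
    results = compare_groups([("a", _counts(120, 30)), ("b", _counts(120, 30))])
    assert results[0].p_value == 1.0
    assert significance_stars(results[0].p_value) == ""


def test_pairwise_p_matches_enumeration_and_direction():
    results = compare_groups([("A", _counts(900, 100)), ("B", _counts(500, 500))])
    r = results[0]
    assert r.p_value == pytest.approx(_enumeration_pvalue(900, 100, 500, 500),
                                      abs=1e-13)
    psi_a = compute_metrics(_counts(900, 100)).psi
    psi_b = compute_metrics(_counts(500, 500)).psi
    assert psi_b > psi_a
    assert r.p_value < 1e-10


def test_untestable_group_flags_only_its_pairs():
    groups = [("ok1", _counts(90, 10)), ("empty", _counts(0, 0)),
              ("ok2", _counts(60, 40))]
    results = {(r.group_a, r.group_b): r for r in compare_groups(groups)}
    assert results[("ok1", "empty")].p_value is None
    assert results[("empty", "ok2")].p_value is None
    assert results[("ok1", "ok2")].p_value is not None


@pytest.mark.parametrize("method,sm_method", [("bonferroni", "bonferroni"),
                                              ("bh", "fdr_bh")])
def test_adjustment_matches_statsmodels(method, sm_method):
    from statsmodels.stats.multitest import multipletests
    groups = [("a", _counts(900, 100)), ("b", _counts(870, 130)),
              ("c", _counts(500, 500)), ("d", _counts(880, 120))]
    results = compare_groups(groups, adjust=method)
    raw = [r.p_value for r in results]
    adjusted = [r.adjusted_p for r in results]
    expected = multipletests(raw, method=sm_method)[1]
    assert adjusted == pytest.approx(list(expected), abs=1e-12)
    for p, q in zip(raw, adjusted):
        assert p <= q


def test_fewer_than_two_groups_rejected():
    with pytest.raises(ContractError):
        compare_groups([("only", _counts(1, 1))])


# --- replicate summaries ---------------------------------------------------

def test_replicate_summary_mean_and_sd():
    reps = [compute_metrics(_counts(90, 10)), compute_metrics(_counts(88, 12)),
            compute_metrics(_counts(92, 8)), compute_metrics(_counts(90, 10))]
    s = summarize_replicates(reps, "H1")
    assert s.mean_psi == pytest.approx(0.10)
    assert s.sd_psi == pytest.approx(np.std([0.10, 0.12, 0.08, 0.10], ddof=1))
    assert s.n_replicates == 4 and s.n_undefined == 0


def test_single_replicate_has_no_sd():
    s = summarize_replicates([compute_metrics(_counts(90, 10))], "g")
    assert s.mean_psi == pytest.approx(0.10)
    assert s.sd_psi is None


def test_undefined_replicates_excluded_and_counted():
    reps = [compute_metrics(_counts(90, 10)), compute_metrics(_counts(0, 0)),
            compute_metrics(_counts(80, 20)), compute_metrics(_counts(85, 15))]
    s = summarize_replicates(reps, "g")
    assert s.n_replicates == 3 and s.n_undefined == 1
    assert s.mean_psi == pytest.approx(np.mean([0.10, 0.20, 0.15]))


def test_all_undefined_summary_not_available():
    s = summarize_replicates([compute_metrics(_counts(0, 0))] * 3, "silenced")
    assert s.mean_psi is None and s.n_undefined == 3


@given(st.lists(st.tuples(st.integers(0, 200), st.integers(0, 200)),
                min_size=2, max_size=8))
def test_pooled_psi_within_replicate_range(counts_list):
    """Pooled PSI lies within [min, max] of the per-replicate PSIs."""
    reps = [compute_metrics(_counts(j, i)) for j, i in counts_list]
    defined = [m.psi for m in reps if m.psi is not None]
    pooled_j = sum(j for j, _ in counts_list)
    pooled_i = sum(i for _, i in counts_list)
    pooled = compute_metrics(_counts(pooled_j, pooled_i))
    if defined and pooled.psi is not None:
        assert min(defined) - 1e-12 <= pooled.psi <= max(defined) + 1e-12


# --- tabular output --------------------------------------------------------

def test_frames_have_documented_columns():
    mf = metrics_to_frame([compute_metrics(_counts(90, 10))])
    assert list(mf.columns) == ["id", "junction", "intron", "psi", "efficiency",
                                "ci_low", "ci_high"]
    cf = comparisons_to_frame(compare_groups(
        [("a", _counts(90, 10)), ("b", _counts(50, 50))]))
    assert list(cf.columns) == ["group_a", "group_b", "a", "b", "c", "d",
                                "odds_ratio", "p_value", "adjusted_p",
                                "method", "stars"]
    assert cf.loc[0, "stars"] in {"", "*", "**", "***"}
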