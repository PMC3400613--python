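"""Correlations, box-fence statistics, group tests and subject selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitocohort.cohortstats import (
    box_stats,
    compare_groups,
    correlate,
    select_representative_subjects,
)


# ---------------------------------------------------------------------------
# correlate

def test_perfect_linear_relation():
    x = np.arange(10.0)
    res = correlate(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    assert res.p_value < 1e-10


def test_independent_variables_near_zero():
    rng = np.random.default_rng(0)
    res = correlate(rng.normal(size=1000), rng.normal(size=1000))
    assert abs(res.r) < 0.1


def test_matches_direct_covariance_formula():
    rng = np.random.default_rng(1)
    x = rng.normal(size=10)
    y = 0.4 * x + rng.normal(size=10)
    res = correlate(x, y)
    ref = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    assert res.r == pytest.approx(ref, abs=1e-12)
    t = ref * np.sqrt(8 / (1 - ref**2))
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 8), rel=1e-10)


def test_log_transform_and_exclusions():
    x = np.array([10.0, 100.0, 1000.0, -5.0, np.nan])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = correlate(x, y, log_x=True)
    assert res.n == 3 and res.n_excluded == 2
    assert res.r == pytest.approx(1.0)
    with pytest.raises(ValueError):
        correlate([1.0, 2.0], [1.0, 2.0])


def test_affine_invariance_of_r():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    r0 = correlate(x, y).r
    assert correlate(3 * x + 7, 0.5 * y - 2).r == pytest.approx(r0, abs=1e-12)


# ---------------------------------------------------------------------------
# box_stats

def brute_limits(v, q1, q3):
    """Exhaustive scan for the observed values closest to (and inside) the
    1.5 IQR fences, exactly as the whisker definition states."""
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo_candidates = [x for x in v if x >= lo_f]
    hi_candidates = [x for x in v if x <= hi_f]
    return min(lo_candidates), max(hi_candidates)


def test_fences_not_binding_on_uniform_run():
    v = np.arange(1.0, 101.0)
    bs = box_stats(v)
    assert bs.q1 == pytest.approx(25.75)
    assert bs.q3 == pytest.approx(75.25)
    assert bs.lower_limit == 1.0 and bs.upper_limit == 100.0
    assert bs.q1 <= bs.median <= bs.q3


def test_outlier_excluded_from_upper_limit():
    bs = box_stats([1, 2, 3, 4, 1000])
    assert bs.upper_limit == 4.0
    assert bs.lower_limit == 1.0


def test_limits_match_exhaustive_scan_on_random_samples():
    rng = np.random.default_rng(3)
    for i in range(200):
        n = rng.integers(4, 60)
        v = rng.standard_t(df=3, size=n) * rng.uniform(0.5, 20)
        bs = box_stats(v)
        lo, hi = brute_limits(v, bs.q1, bs.q3)
        assert bs.lower_limit == lo
        assert bs.upper_limit == hi
        # limits are observed values inside the fences
        assert bs.lower_limit in v and bs.upper_limit in v
        assert bs.lower_limit >= bs.q1 - 1.5 * (bs.q3 - bs.q1) - 1e-12
        assert bs.upper_limit <= bs.q3 + 1.5 * (bs.q3 - bs.q1) + 1e-12


def test_type6_quartile_option():
    v = np.arange(1.0, 101.0)
    bs = box_stats(v, quartile_method="weibull")
    assert bs.q1 == pytest.approx(np.quantile(v, 0.25, method="weibull"))


def test_too_few_values():
    with pytest.raises(ValueError):
        box_stats([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# compare_groups

def test_identical_groups_nonsignificant():
    rng = np.random.default_rng(4)
    pooled = rng.normal(size=300)
    groups = {k: pooled[i::3] for i, k in enumerate("abc")}
    res = compare_groups(groups, method="kruskal")
    assert res.p_value > 0.05


def test_single_shifted_group_flags_only_its_pairs():
    rng = np.random.default_rng(5)
    groups = {f"g{i}": rng.normal(0, 1, 80) for i in range(4)}
    groups["shifted"] = rng.normal(2.5, 1, 80)
    res = compare_groups(groups, method="anova")
    assert res.p_value < 1e-6
    sig = res.pairwise_significant
    for g in ("g0", "g1", "g2", "g3"):
        assert sig.loc[g, "shifted"]
    assert not sig.loc["g0", "g1"]


def test_kruskal_statistic_matches_rank_formula():
    groups = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0], "c": [7.0, 8.0, 9.0]}
    res = compare_groups(groups, method="kruskal")
    # hand computation: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2, no ties
    ranks = {"a": [1, 3, 5], "b": [2, 4, 6], "c": [7, 8, 9]}
    N = 9
    H = 12 / (N * (N + 1)) * sum(
        len(r) * (np.mean(r) - (N + 1) / 2) ** 2 for r in ranks.values()
    )
    assert res.statistic == pytest.approx(H, rel=1e-10)


def test_bonferroni_flag_iff_raw_below_threshold():
    rng = np.random.default_rng(6)
    groups = {f"g{i}": rng.normal(0.3 * i, 1, 40) for i in range(4)}
    res = compare_groups(groups, method="anova")
    n_pairs = res.n_pairs
    for a in groups:
        for b in groups:
            if a >= b:
                continue
            _, p_raw = stats.f_oneway(groups[a], groups[b])
            assert res.pairwise_significant.loc[a, b] == (p_raw < 0.05 / n_pairs)
            assert res.pairwise_p.loc[a, b] == pytest.approx(min(1.0, p_raw * n_pairs))


# ---------------------------------------------------------------------------
# representative subjects

def test_three_subjects_all_selected():
    sel = select_representative_subjects(pd.Series({"s1": 10.0, "s2": 20.0, "s3": 30.0}))
    assert sel == {"min": "s1", "med": "s2", "max": "s3"}


def test_median_is_rank_three_of_five():
    values = pd.Series({"a": 5.0, "b": 1.0, "c": 9.0, "d": 3.0, "e": 7.0})
    sel = select_representative_subjects(values)
    assert sel["med"] == "a"  # 5.0 is the 3rd of 5 ranked values
    assert sel["min"] == "b" and sel["max"] == "c"


def test_selection_matches_sorting_oracle_and_breaks_ties_low():
    rng = np.random.default_rng(7)
    vals = rng.integers(0, 5, size=9).astype(float)  # forced ties
    s = pd.Series(vals, index=[f"s{i}" for i in range(9)])
    sel = select_representative_subjects(s)
    order = sorted(s.items(), key=lambda kv: (kv[1], kv[0]))
    assert sel["min"] == order[0][0]
    # brute force: max = highest value, lowest id among ties
    top = max(s.values)
    assert sel["max"] == min(k for k, v in s.items() if v == top)
    med = order[(len(s) - 1) // 2]
    assert sel["med"] == med[0]
    with pytest.raises(ValueError):
        select_representative_subjects(pd.Series({"a": 1.0, "b": 2.0}))
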