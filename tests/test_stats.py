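"""Statistical primitives against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabomod import stats as ms


# ---------------------------------------------------------------- Welch t


def test_welch_from_summary_reproduces_cohort_age_p():
    res = ms.welch_t_from_summary(56.2, 8.0, 56, 53.1, 7.4, 68)
    assert round(res.p_value, 3) == 0.028


def test_welch_from_summary_identical_groups():
    res = ms.welch_t_from_summary(10.0, 2.0, 20, 10.0, 2.0, 20)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_welch_from_summary_matches_raw_vectors():
    # vectors constructed to have exact requested mean/SD
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    x = (x - x.mean()) / x.std(ddof=1) * 1.7 + 5.0
    y = rng.normal(size=9)
    y = (y - y.mean()) / y.std(ddof=1) * 2.4 + 4.1
    raw = ms.welch_t(x, y)
    summ = ms.welch_t_from_summary(5.0, 1.7, 12, 4.1, 2.4, 9)
    assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
    assert raw.p_value == pytest.approx(summ.p_value, abs=1e-10)


def test_welch_t_symmetry_and_degenerate():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.5, 3.5, 1.5])
    a, b = ms.welch_t(x, y), ms.welch_t(y, x)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_value == pytest.approx(b.p_value)
    same = ms.welch_t(x, x.copy())
    assert same.statistic == 0.0 and same.p_value == 1.0
    const = ms.welch_t(np.ones(4), np.ones(3))
    assert const.p_value == 1.0
    with pytest.raises(ValueError):
        ms.welch_t(np.array([1.0]), y)


def test_welch_t_close_to_exhaustive_permutation_p():
    pooled = np.array([0.1, 1.4, 2.3, 0.9, 3.1, 2.8])
    obs = abs(ms.welch_t(pooled[:3], pooled[3:]).statistic)
    count = total = 0
    for idx in itertools.combinations(range(6), 3):
        rest = [i for i in range(6) if i not in idx]
        t = abs(ms.welch_t(pooled[list(idx)], pooled[rest]).statistic)
        count += t >= obs - 1e-12
        total += 1
    perm_p = count / total
    assert abs(ms.welch_t(pooled[:3], pooled[3:]).p_value - perm_p) < 0.2


# ------------------------------------------------------------ chi-squared


@pytest.mark.parametrize(
    "table, expected",
    [((51, 5, 57, 11), 0.353), ((35, 4, 41, 8), 0.609), ((16, 1, 16, 3), 0.680)],
)
def test_chi2_yates_reproduces_cohort_race_p(table, expected):
    assert round(ms.chi2_yates_2x2(*table).p_value, 3) == expected


def test_chi2_yates_transpose_invariant():
    a = ms.chi2_yates_2x2(12, 5, 9, 14)
    b = ms.chi2_yates_2x2(12, 9, 5, 14)  # rows swapped with columns
    assert a.statistic == pytest.approx(b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_chi2_yates_zero_margin_errors():
    with pytest.raises(ValueError):
        ms.chi2_yates_2x2(0, 0, 3, 4)


# -------------------------------------------------------------------- BH


def _bh_oracle(p):
    """Direct definition: q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    running = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
    q[order] = np.minimum(running, 1.0)
    return q


def test_bh_single_and_uniform_vectors():
    assert ms.bh_fdr([0.05]) == pytest.approx([0.05])
    assert ms.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_matches_bruteforce_on_grid():
    grid = [0.001, 0.01, 0.04, 0.2, 0.5, 0.9, 1.0]
    for n in (1, 2, 3):
        for combo in itertools.product(grid, repeat=n):
            assert ms.bh_fdr(list(combo)) == pytest.approx(_bh_oracle(combo))
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(2, 7))
        assert ms.bh_fdr(p) == pytest.approx(_bh_oracle(p))


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
@settings(max_examples=100, deadline=None)
def test_bh_is_monotone_and_bounded(p):
    q = ms.bh_fdr(p)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q <= 1.0) and np.all(q >= np.min(p) - 1e-12)


def test_bh_controls_fdr_on_null_simulations():
    """All-null uniform p at cut 0.1: average FDP stays near/below 0.1."""
    rng = np.random.default_rng(12)
    fdp = []
    for _ in range(500):
        p = rng.uniform(size=800)
        rejected = ms.bh_fdr(p) < 0.1
        fdp.append(1.0 if rejected.any() else 0.0)
    assert np.mean(fdp) <= 0.12


# -------------------------------------------------------------------- OLS


def test_ols_exact_line_and_intercept_only():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    design = pd.DataFrame({"const": np.ones(4), "x": x})
    fit = ms.ols_regression(2 * x + 1, design)
    assert fit.coefficients["x"] == pytest.approx(2.0)
    assert fit.coefficients["const"] == pytest.approx(1.0)
    y = np.array([3.0, 5.0, 4.0, 9.0, 2.0])
    only = ms.ols_regression(y, pd.DataFrame({"const": np.ones(5)}))
    assert only.coefficients["const"] == pytest.approx(y.mean())


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 4))
    design = pd.DataFrame(X, columns=list("abcd"))
    y = rng.normal(size=30)
    fit = ms.ols_regression(y, design)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert list(fit.coefficients.values()) == pytest.approx(list(beta), abs=1e-8)
    assert fit.residual_df == 30 - 4


def test_ols_rank_deficiency_names_columns():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8], "c": [1.0, 0, 1, 0]})
    with pytest.raises(ValueError, match="collinear"):
        ms.ols_regression(np.zeros(4), X)


# ---------------------------------------------------------------- Pearson


def test_pearson_identity_orthogonal_and_errors():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert ms.pearson_test(x, x).estimate == pytest.approx(1.0)
    y = np.array([1.0, -2.0, 1.0, 0.0])  # orthogonal to centered x
    y = y - np.polyfit(x, y, 1)[0] * x
    res = ms.pearson_test(x, y)
    assert res.estimate == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ms.pearson_test(np.ones(5), x[:5] if len(x) >= 5 else np.arange(5.0))


def test_pearson_close_to_permutation_p():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=10), rng.normal(size=10)
    obs = abs(ms.pearson_test(x, y).estimate)
    count = 0
    n_perm = 4000
    for _ in range(n_perm):
        count += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= obs - 1e-12
    assert abs(ms.pearson_test(x, y).p_value - count / n_perm) < 0.05


# ----------------------------------------------------------- hypergeometric


def _enumerate_overrep(N, k, m, x):
    hits = total = 0
    pathway = set(range(k))
    for draw in itertools.combinations(range(N), m):
        total += 1
        hits += len(pathway & set(draw)) >= x
    return hits / total


def test_hypergeom_basics():
    inp = ms.EnrichmentInputs(overlap_x=0, module_size_m=4, pathway_size_k=5, universe_N=10)
    assert ms.hypergeom_overrep(inp) == pytest.approx(1.0)
    inp = ms.EnrichmentInputs(overlap_x=4, module_size_m=4, pathway_size_k=5, universe_N=10)
    assert ms.hypergeom_overrep(inp) == pytest.approx(1 / 42)
    # degenerate universe: module is the whole universe, overlap forced = k
    inp = ms.EnrichmentInputs(overlap_x=5, module_size_m=8, pathway_size_k=5, universe_N=8)
    assert ms.hypergeom_overrep(inp) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ms.EnrichmentInputs(overlap_x=6, module_size_m=4, pathway_size_k=5, universe_N=10)


def test_hypergeom_equals_enumeration_for_small_universes():
    rng = np.random.default_rng(2)
    for N in range(2, 13):
        for _ in range(6):
            k = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            x = int(rng.integers(0, min(m, k) + 1))
            inp = ms.EnrichmentInputs(x, m, k, N)
            assert ms.hypergeom_overrep(inp) == pytest.approx(
                _enumerate_overrep(N, k, m, x), abs=1e-12
            ), (N, k, m, x)


# -------------------------------------------------------------------- ROC


def _pair_count_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_and_all_ties():
    auc, _ = ms.roc_auc(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1]))
    assert auc == 1.0
    auc, _ = ms.roc_auc(np.ones(6), np.array([0, 1, 0, 1, 0, 1]))
    assert auc == 0.5
    with pytest.raises(ValueError):
        ms.roc_auc(np.arange(4.0), np.zeros(4, dtype=int))


def test_auc_matches_pair_counting_all_small_labelings():
    rng = np.random.default_rng(9)
    for n in range(2, 9):
        scores = np.round(rng.normal(size=n), 1)  # rounding forces some ties
        for bits in range(1, 2**n - 1):
            labels = np.array([(bits >> i) & 1 for i in range(n)])
            auc, _ = ms.roc_auc(scores, labels)
            assert auc == pytest.approx(_pair_count_auc(scores, labels))


@given(
    st.lists(st.floats(-50, 50).map(lambda v: round(v, 2)), min_size=4, max_size=25),
    st.floats(0.1, 5.0),
)
@settings(max_examples=60, deadline=None)
def test_auc_invariant_under_increasing_transforms(scores, slope):
    # scores on a 0.01 grid so the strictly increasing transform cannot
    # collapse distinct values to floating-point ties
    scores = np.asarray(scores)
    labels = (np.arange(len(scores)) % 2).astype(int)
    a1, _ = ms.roc_auc(scores, labels)
    a2, _ = ms.roc_auc(np.exp(slope * scores / 50.0), labels)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_youden_perfect_ties_and_bruteforce():
    scores = np.array([1.0, 2.0, 10.0, 11.0])
    labels = np.array([0, 0, 1, 1])
    _, curve = ms.roc_auc(scores, labels)
    pt = ms.youden_point(curve, scores, labels)
    assert pt["J"] == pytest.approx(1.0)
    assert pt["sensitivity"] == pt["specificity"] == 1.0
    flat = np.ones(6)
    lab = np.array([0, 1, 0, 1, 0, 1])
    _, c2 = ms.roc_auc(flat, lab)
    assert ms.youden_point(c2, flat, lab)["J"] == pytest.approx(0.0)

    rng = np.random.default_rng(4)
    s = rng.normal(size=20)
    y = rng.integers(0, 2, size=20)
    y[0], y[1] = 0, 1
    _, c3 = ms.roc_auc(s, y)
    pt = ms.youden_point(c3, s, y)
    best = max(
        np.mean(s[y == 1] >= thr) + np.mean(s[y == 0] < thr) - 1
        for thr in np.unique(s)
    )
    assert pt["J"] == pytest.approx(best)
    assert pt["J"] == pytest.approx(pt["sensitivity"] + pt["specificity"] - 1)
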