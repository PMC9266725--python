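"""Relevance-filter tests: the IG statistic against an independent
plug-in entropy oracle, discretization contracts, permutation p-values,
Holm correction, and end-to-end filter behavior on planted data."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stratmark import (DiscretizationScheme, NullModel, discretize,
                       holm_adjust, information_gain, max_ig, null_pvalue,
                       select_relevant)
from stratmark.relevance import (_draw_cut_ranks, _max_ig_many,
                                 _tie_adjusted_boundaries)


# --------------------------------------------------------------------------
# independent oracle: naive entropy computation on a 2 x c table
# --------------------------------------------------------------------------

def _entropy(probs):
    probs = np.asarray(probs, float)
    probs = probs[probs > 0]
    return float(-(probs * np.log(probs)).sum())


def oracle_ig(table, pseudocount):
    """Direct plug-in 2*N*[H(y) - H(y|x)] from a 2 x c count table."""
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]  # only observed categories
    t = t + pseudocount
    n = t.sum()
    h_y = _entropy(t.sum(axis=1) / n)
    h_yx = sum((t[:, j].sum() / n) * _entropy(t[:, j] / t[:, j].sum())
               for j in range(t.shape[1]))
    return 2.0 * n * (h_y - h_yx)


def _table_to_vectors(table):
    x, y = [], []
    for j in range(table.shape[1]):
        for cls in (0, 1):
            x.extend([j] * table[cls, j])
            y.extend([cls] * table[cls, j])
    return np.array(x), np.array(y)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(2, 4).flatmap(
    lambda c: st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)),
                       min_size=c, max_size=c)),
    st.sampled_from([0.0, 0.5]))
def test_information_gain_matches_entropy_oracle(cols, pc):
    table = np.array(cols).T  # 2 x c
    if table.sum(axis=1).min() == 0 or table.sum() < 2:
        return  # y needs both levels
    x, y = _table_to_vectors(table)
    assert information_gain(x, y, pseudocount=pc) == \
        pytest.approx(oracle_ig(table, pc), rel=1e-10, abs=1e-12)


def test_information_gain_worked_examples():
    # perfect 2x2 association, counts (5,0 / 0,5): 2*10*ln2
    x = np.array([0] * 5 + [1] * 5)
    y = np.array([0] * 5 + [1] * 5)
    assert information_gain(x, y, pseudocount=0) == \
        pytest.approx(2 * 10 * np.log(2), rel=1e-12)
    # counts (3,1 / 1,3): 2*8*[H(1/2) - H(1/4)]
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
    expect = 2 * 8 * (np.log(2) - _entropy([0.25, 0.75]))
    assert information_gain(x, y, pseudocount=0) == pytest.approx(expect, rel=1e-12)
    assert expect == pytest.approx(2.09, abs=0.01)


def test_information_gain_length_mismatch():
    with pytest.raises(ValueError):
        information_gain([0, 1], [0, 1, 1])


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------

def test_discretize_constant_single_category():
    cats = discretize(np.full(10, 3.3), n_cuts=2, rng=0)
    assert len(np.unique(cats)) == 1


def test_discretize_forced_split_sizes():
    # 6 values, any single admissible cut gives bins of sizes summing to 6
    # with neither side empty; a cut at rank 3 gives {3, 3}
    values = np.array([1.0, 2, 3, 4, 5, 6])
    for seed in range(20):
        cats = discretize(values, n_cuts=1, rng=seed)
        sizes = np.bincount(cats)
        assert sizes.sum() == 6 and (sizes > 0).all()
    # thresholding semantics: 3 lowest vs 3 highest when cut lands at rank 3
    assert ((values <= 3).sum(), (values > 3).sum()) == (3, 3)


def test_discretize_deterministic():
    vals = np.random.default_rng(1).normal(size=30)
    a = discretize(vals, 2, rng=42)
    b = discretize(vals, 2, rng=42)
    assert (a == b).all()


def test_discretize_category_budget():
    vals = np.random.default_rng(2).normal(size=50)
    for k in (1, 2, 3):
        cats = discretize(vals, n_cuts=k, rng=7)
        assert len(np.unique(cats)) <= k + 1


# --------------------------------------------------------------------------
# max over discretizations
# --------------------------------------------------------------------------

def test_max_ig_constant_feature_zero():
    y = np.array([0, 1] * 10)
    scheme = DiscretizationScheme(rng_seed=5)
    assert max_ig(np.ones(20), y, scheme) == 0.0


def test_max_ig_single_discretization_reduces():
    rng = np.random.default_rng(3)
    vals, y = rng.normal(size=40), rng.integers(0, 2, size=40)
    scheme = DiscretizationScheme(n_discretizations=1, rng_seed=9)
    cats = discretize(vals, 1, rng=np.random.default_rng(9))
    assert max_ig(vals, y, scheme) == pytest.approx(
        information_gain(cats, y, scheme.pseudocount))


def test_max_ig_monotone_in_n_discretizations():
    rng = np.random.default_rng(4)
    vals, y = rng.normal(size=60), rng.integers(0, 2, size=60)
    igs = [max_ig(vals, y, DiscretizationScheme(n_discretizations=t, rng_seed=2))
           for t in (1, 5, 15, 30)]
    assert igs == sorted(igs)


def test_vectorized_kernel_matches_reference_path():
    """The batched max-IG used by the filter equals per-feature
    discretize + information_gain with the same cuts (incl. tied data)."""
    rng = np.random.default_rng(8)
    X = rng.normal(size=(35, 6))
    X[:, 2] = np.round(X[:, 2])  # introduce ties
    y = rng.integers(0, 2, size=35)
    scheme = DiscretizationScheme(n_cuts=2, n_discretizations=7)
    cut_ranks = _draw_cut_ranks(np.random.default_rng(0), 35, 6, scheme)
    x_sorted = np.sort(X, axis=0)
    order = np.argsort(X, axis=0, kind="stable")
    got = _max_ig_many(_tie_adjusted_boundaries(x_sorted, cut_ranks),
                       order, y, scheme.pseudocount)
    for f in range(6):
        best = -np.inf
        for t in range(scheme.n_discretizations):
            thresholds = x_sorted[cut_ranks[f, t] - 1, f]
            cats = (X[:, f][:, None] > thresholds[None, :]).sum(axis=1)
            best = max(best, information_gain(cats, y, scheme.pseudocount))
        assert got[f] == pytest.approx(best, rel=1e-12)


def test_scale_invariance_monotone_transform(small_planted):
    """Rank-space cuts make the statistic invariant under strictly
    monotone transforms of every feature."""
    ds = small_planted.dataset
    a = select_relevant(ds, DiscretizationScheme(rng_seed=1), n_permutations=10)
    import pandas as pd
    from stratmark import ExpressionDataset
    transformed = ExpressionDataset(np.exp(ds.values * 0.5), ds.labels)
    b = select_relevant(transformed, DiscretizationScheme(rng_seed=1),
                        n_permutations=10)
    common = [f for f in a.table.index]
    assert np.allclose(a.table.loc[common, "ig_max"],
                       b.table.loc[common, "ig_max"])
    assert np.allclose(a.table.loc[common, "p_value"],
                       b.table.loc[common, "p_value"])


# --------------------------------------------------------------------------
# p-values
# --------------------------------------------------------------------------

def test_null_pvalue_formula_cases():
    null = NullModel(999, np.arange(999, dtype=float))
    assert null_pvalue(1e9, null) == pytest.approx(1 / 1000)
    assert null_pvalue(0.0, null) == pytest.approx(1.0)
    # halfway: exactly 499 null values >= 500
    assert null_pvalue(500.0, null) == pytest.approx((1 + 499) / 1000)


def test_null_pvalue_requires_samples():
    with pytest.raises(ValueError):
        NullModel(0, np.array([]))


def test_holm_worked_example():
    adj, rej = holm_adjust([0.01, 0.04], alpha=0.05)
    assert adj == pytest.approx([0.02, 0.04])
    assert rej.tolist() == [True, True]


def test_holm_single_and_all_ones():
    adj, rej = holm_adjust([0.3])
    assert adj == pytest.approx([0.3]) and not rej[0]
    adj, rej = holm_adjust([1.0, 1.0, 1.0])
    assert np.all(adj == 1.0) and not rej.any()


def test_holm_rejects_invalid_p():
    for bad in ([0.0, 0.5], [0.5, 1.5], [-0.1]):
        with pytest.raises(ValueError):
            holm_adjust(bad)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
def test_holm_matches_stepdown_formula(ps):
    """Adjusted p equals the hand-applied step-down maximum, and is
    monotone with adjusted >= raw."""
    adj, rej = holm_adjust(ps, alpha=0.05)
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    expect = np.empty(m)
    running = 0.0
    for i, j in enumerate(order):
        running = max(running, min(1.0, (m - i) * ps[j]))
        expect[j] = running
    assert adj == pytest.approx(expect, rel=1e-12)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(rej == (adj <= 0.05))


# --------------------------------------------------------------------------
# the filter end to end
# --------------------------------------------------------------------------

def test_select_relevant_excludes_zero_variance(small_planted):
    ds = small_planted.dataset
    res = select_relevant(ds, DiscretizationScheme(rng_seed=2), n_permutations=10)
    assert len(res.zero_variance) == 6
    assert len(res.table) == ds.n_features - 6
    assert not set(res.zero_variance) & set(res.table.index)


def test_select_relevant_recovers_planted(small_planted):
    res = select_relevant(small_planted.dataset,
                          DiscretizationScheme(rng_seed=2), n_permutations=30)
    assert small_planted.truth <= set(res.relevant_features)


def test_select_relevant_null_few_rejections(null_dataset):
    res = select_relevant(null_dataset, DiscretizationScheme(rng_seed=4),
                          n_permutations=30)
    assert len(res.relevant_features) <= 2  # family-wise control
    frac = (res.table["p_value"] < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / len(res.table))
    assert abs(frac - 0.05) <= 3 * se


def test_select_relevant_invariants(small_planted):
    res = select_relevant(small_planted.dataset,
                          DiscretizationScheme(rng_seed=2), n_permutations=20)
    t = res.table
    assert (t["p_adjusted"] >= t["p_value"] - 1e-15).all()
    assert (t["relevant"] == (t["p_adjusted"] <= res.alpha)).all()
    assert (t["ig_max"] >= 0).all()
    assert ((t["p_value"] > 0) & (t["p_value"] <= 1)).all()


def test_select_relevant_deterministic(small_planted):
    a = select_relevant(small_planted.dataset,
                        DiscretizationScheme(rng_seed=6), n_permutations=15)
    b = select_relevant(small_planted.dataset,
                        DiscretizationScheme(rng_seed=6), n_permutations=15)
    assert a.table.equals(b.table)


def test_select_relevant_single_class_rejected(tiny_dataset):
    from stratmark import ExpressionDataset
    bad = ExpressionDataset(tiny_dataset.values,
                            tiny_dataset.labels * 0)
    with pytest.raises(ValueError):
        select_relevant(bad, n_permutations=5)


def test_power_monotone_in_effect_size():
    """Mean max-IG of planted features grows with the planted effect."""
    from stratmark import SimulationConfig, generate
    means = []
    for effect in (0.0, 0.75, 1.5):
        cfg = SimulationConfig(n_samples=150, n_features=40, n_blocks=2,
                               block_size=5, effect_size=effect,
                               n_zero_variance=0, rng_seed=21)
        synth = generate(cfg)
        res = select_relevant(synth.dataset, DiscretizationScheme(rng_seed=2),
                              n_permutations=5)
        means.append(res.table.loc[sorted(synth.truth), "ig_max"].mean())
    assert means[0] < means[1] < means[2]
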