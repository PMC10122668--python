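import numpy as np
import pandas as pd
import pytest

import illusiongame as ig


def test_cor_bf_identity():
    x = np.linspace(0, 1, 50)
    res = ig.cor_bf(x, x)
    assert res.r == pytest.approx(1.0, abs=1e-5)
    assert res.bf10 > 100
    assert not res.rank_based


def test_cor_bf_sign_flip_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    y = 0.4 * x + rng.normal(size=200)
    a = ig.cor_bf(x, y)
    b = ig.cor_bf(x, -y)
    assert a.r == pytest.approx(-b.r, abs=1e-12)
    assert a.bf10 == pytest.approx(b.bf10, rel=1e-8)


def test_cor_bf_null_evidence():
    rng = np.random.default_rng(1)
    res = ig.cor_bf(rng.normal(size=1000), rng.normal(size=1000))
    assert res.bf10 < 1.0
    assert res.n == 1000


def test_cor_bf_errors_and_missing():
    with pytest.raises(ValueError):
        ig.cor_bf([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # n < 4
    with pytest.raises(ValueError):
        ig.cor_bf(np.arange(10.0), np.arange(10.0), prior_scale=0.0)
    res = ig.cor_bf(np.ones(10), np.arange(10.0))  # zero variance -> missing
    assert res.missing and np.isnan(res.bf10)


def test_cor_bf_prior_scale_matters():
    rng = np.random.default_rng(2)
    x = rng.normal(size=100)
    y = 0.3 * x + rng.normal(size=100)
    narrow = ig.cor_bf(x, y, prior_scale=1 / 3)
    wide = ig.cor_bf(x, y, prior_scale=1.0)
    assert narrow.bf10 != pytest.approx(wide.bf10, rel=1e-3)


def test_rank_cor_monotone_invariance():
    x = np.linspace(-2, 2, 60)
    res = ig.rank_cor_bf(x, x**3)
    assert res.r == pytest.approx(1.0, abs=1e-9)
    assert res.rank_based


def test_rank_cor_outlier_robustness():
    # hand-built 20-point fixture: one huge outlier flips the Pearson sign
    x = np.concatenate([np.arange(19.0), [1000.0]])
    y = np.concatenate([np.arange(19.0), [-4000.0]])
    pearson = ig.cor_bf(x, y)
    rank = ig.rank_cor_bf(x, y)
    assert pearson.r < 0 < rank.r
    assert rank.r > 0.7


def test_rank_cor_tie_handling_matches_average_ranks():
    x = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 4.0, 7.0])
    y = np.array([0.5, 1.0, 1.2, 1.2, 2.0, 2.0, 3.0, 3.5])
    # brute-force average ranks
    def avg_rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    expected = ig.cor_bf(avg_rank(x), avg_rank(y))
    got = ig.rank_cor_bf(x, y)
    assert got.r == pytest.approx(expected.r, abs=1e-12)
    assert got.bf10 == pytest.approx(expected.bf10, rel=1e-10)


def test_bf_monotone_in_r_and_n():
    from illusiongame.correlates import _cor_likelihood, _stretched_beta_pdf
    from scipy import integrate

    def bf(r, n):
        return integrate.quad(
            lambda rho: _cor_likelihood(rho, r, n) * _stretched_beta_pdf(rho, 1 / 3),
            -1, 1, epsabs=1e-8, limit=200)[0]

    bfs_r = [bf(r, 50) for r in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)]
    assert np.all(np.diff(bfs_r) > 0)
    bfs_n = [bf(0.3, n) for n in (10, 25, 50, 100, 200)]
    assert np.all(np.diff(bfs_n) > 0)


def test_ttest_identical_groups():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=200)
    labels = np.repeat(["a", "b"], 100)
    res = ig.ttest_bf(np.concatenate([vals[:100], vals[:100]]), labels)
    assert res.delta == pytest.approx(0.0, abs=1e-12)
    assert res.bf10 < 1.0
    assert res.ci_low < 0 < res.ci_high


def test_ttest_detects_large_effect():
    rng = np.random.default_rng(4)
    vals = np.concatenate([rng.normal(0, 1, 125), rng.normal(0.8, 1, 125)])
    labels = np.repeat([0, 1], 125)
    res = ig.ttest_bf(vals, labels)
    assert res.bf10 > 10
    assert res.delta < 0  # group 0 minus group 1
    assert res.ci_low < res.delta < res.ci_high


def test_ttest_label_swap_symmetry():
    rng = np.random.default_rng(5)
    vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(0.5, 1, 60)])
    labels = np.repeat(["m", "f"], [50, 60])
    a = ig.ttest_bf(vals, labels)
    swapped = np.where(labels == "m", "aa", "zz")  # reverses the sort order
    b = ig.ttest_bf(vals, swapped)
    assert a.delta == pytest.approx(-b.delta, abs=1e-12)
    assert a.bf10 == pytest.approx(b.bf10, rel=1e-8)
    assert (a.n1, a.n2) == (b.n2, b.n1)


def test_ttest_errors():
    with pytest.raises(ValueError):
        ig.ttest_bf([1.0, 2.0, 3.0], ["a", "a", "a"])  # one group
    with pytest.raises(ValueError):
        ig.ttest_bf([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"])  # n < 3


def test_correlate_scores_batch():
    rng = np.random.default_rng(6)
    scores = pd.DataFrame({
        "participant": np.arange(80),
        "ponzo_strength": rng.normal(size=80),
        "white_strength": rng.normal(size=80),
    })
    traits = pd.DataFrame({
        "participant": np.arange(80),
        "age": rng.integers(18, 70, 80).astype(float),
        "site": ["x"] * 80,  # non-numeric, skipped
    })
    table = ig.correlate_scores(scores, traits)
    assert len(table) == 2
    assert set(table["trait"]) == {"age"}
    assert np.isfinite(table["bf10"]).all()
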