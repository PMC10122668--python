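import numpy as np
import pandas as pd
import pytest

import illusiongame as ig
from tests.conftest import make_factor_table


def one_factor_data(n=2000, lam=0.65, p=8, seed=4):
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n)
    X = np.column_stack([lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n)
                         for _ in range(p)])
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)]), f


def test_efa_recovers_single_factor_loadings():
    data, _ = one_factor_data()
    sol = ig.efa(data, n_factors=1, rotation="none")
    assert sol.converged
    assert np.all(np.abs(sol.loadings["F1"] - 0.65) < 0.1)
    assert np.all((sol.communalities >= 0) & (sol.communalities <= 1))
    assert 0 <= sol.variance_explained <= 1


def test_varimax_orthonormal_and_communality_conserving():
    rng = np.random.default_rng(8)
    f1, f2 = rng.normal(size=2000), rng.normal(size=2000)
    cols = {f"a{i}": 0.7 * f1 + 0.6 * rng.normal(size=2000) for i in range(4)}
    cols |= {f"b{i}": 0.7 * f2 + 0.6 * rng.normal(size=2000) for i in range(4)}
    data = pd.DataFrame(cols)
    unrot = ig.efa(data, 2, rotation="none")
    rot = ig.efa(data, 2, rotation="varimax")
    assert np.allclose(rot.factor_corr, np.eye(2), atol=1e-8)
    assert np.allclose(np.sort(rot.communalities.to_numpy()),
                       np.sort(unrot.communalities.to_numpy()), atol=1e-8)
    # simple structure: each variable loads on exactly one factor
    main = rot.loadings.abs().max(axis=1)
    cross = rot.loadings.abs().min(axis=1)
    assert (main > 0.5).all() and (cross < 0.2).all()


def test_oblimin_near_orthogonal_when_factors_independent():
    rng = np.random.default_rng(9)
    f1, f2 = rng.normal(size=3000), rng.normal(size=3000)
    cols = {f"a{i}": 0.7 * f1 + 0.6 * rng.normal(size=3000) for i in range(4)}
    cols |= {f"b{i}": 0.7 * f2 + 0.6 * rng.normal(size=3000) for i in range(4)}
    sol = ig.efa(pd.DataFrame(cols), 2, rotation="oblimin")
    assert abs(sol.factor_corr[0, 1]) < 0.15
    assert np.allclose(np.diag(sol.factor_corr), 1.0, atol=1e-8)


def test_efa_sign_alignment():
    data, _ = one_factor_data()
    sol = ig.efa(-data, n_factors=1, rotation="none")
    j = np.argmax(np.abs(sol.loadings["F1"]))
    assert sol.loadings["F1"].iloc[j] > 0


def test_efa_input_validation():
    data, _ = one_factor_data(n=200, p=4)
    with pytest.raises(ValueError):
        ig.efa(data, 0)
    with pytest.raises(ValueError):
        ig.efa(data, 2, rotation="promax")
    dup = data.copy()
    dup["v0_copy"] = dup["v0"]  # singular correlation matrix
    with pytest.raises(np.linalg.LinAlgError):
        ig.efa(dup, 1)


def test_suggest_n_factors_null_and_structured():
    rng = np.random.default_rng(10)
    null = pd.DataFrame(rng.normal(size=(1000, 8)))
    n_null, votes_null = ig.suggest_n_factors(null, seed=0)
    assert n_null <= 1
    rng = np.random.default_rng(11)
    fs = rng.normal(size=(2000, 3))
    cols = {}
    for j in range(3):
        for i in range(4):
            cols[f"f{j}v{i}"] = 0.8 * fs[:, j] + 0.4 * rng.normal(size=2000)
    n3, votes3 = ig.suggest_n_factors(pd.DataFrame(cols), seed=0)
    assert n3 == 3
    # deterministic given seed
    assert ig.suggest_n_factors(pd.DataFrame(cols), seed=0) == (n3, votes3)


def test_suggest_n_factors_too_small():
    data, _ = one_factor_data(n=6, p=8)
    with pytest.raises(ValueError):
        ig.suggest_n_factors(data, seed=0)


def test_hierarchical_scores_standardized_and_recovering():
    table, g = make_factor_table(1500, loadings=0.6, seed=12)
    hier = ig.hierarchical_factor_scores(table)
    assert hier.general.mean() == pytest.approx(0.0, abs=1e-9)
    assert hier.general.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    for col in hier.level1:
        assert hier.level1[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    assert np.corrcoef(hier.general, g)[0, 1] > 0.8
    assert 0 < hier.variance_explained < 1
    assert hier.dropped_participants == []


def test_hierarchical_drops_incomplete_participants():
    table, _ = make_factor_table(300, loadings=0.6, seed=13)
    table.iloc[5, 0] = np.nan
    hier = ig.hierarchical_factor_scores(table)
    assert hier.dropped_participants == [5]
    assert len(hier.general) == 299


def test_hierarchical_identical_indicators_degenerate_weights():
    rng = np.random.default_rng(14)
    base = {ill: rng.normal(size=400) for ill in ig.ILLUSIONS}
    cols = {}
    for ill in ig.ILLUSIONS:
        cols[f"{ill}_strength"] = base[ill]
        cols[f"{ill}_interaction"] = base[ill].copy()  # identical indicator
    table = pd.DataFrame(cols, index=pd.RangeIndex(400, name="participant"))
    hier = ig.hierarchical_factor_scores(table)
    for ill in ig.ILLUSIONS:
        z = (base[ill] - base[ill].mean()) / base[ill].std()
        r = abs(np.corrcoef(hier.level1[ill], z)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-9)


def test_second_order_efa_orthogonal_and_permutation_invariant():
    table, _ = make_factor_table(800, loadings=0.5, seed=15)
    hier = ig.hierarchical_factor_scores(table)
    sol = ig.second_order_efa(hier.level1)
    assert sol.rotation == "varimax"
    assert np.allclose(sol.factor_corr, np.eye(2), atol=1e-8)
    shuffled = hier.level1.sample(frac=1, random_state=1)
    sol2 = ig.second_order_efa(shuffled)
    assert np.allclose(sol.loadings.to_numpy(), sol2.loadings.to_numpy(),
                       atol=1e-9)
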