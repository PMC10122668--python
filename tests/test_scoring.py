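import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import illusiongame as ig
from illusiongame import scoring


def logistic_data(n=5000, seed=0, coefs=(-1.0, 0.8, -0.5)):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.normal(size=n) for _ in coefs[1:]])
    eta = coefs[0] + X @ np.asarray(coefs[1:])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def test_penalized_logistic_matches_statsmodels_at_zero_ridge():
    X, y = logistic_data()
    coef, cov = scoring.penalized_logistic(X, y, ridge=0.0)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert np.allclose(coef, ref.params, atol=1e-6)
    assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, atol=1e-5)


def test_penalized_logistic_shrinks_slopes_not_intercept():
    X, y = logistic_data(n=400, seed=3)
    free, _ = scoring.penalized_logistic(X, y, ridge=0.0)
    pen, _ = scoring.penalized_logistic(X, y, ridge=5.0)
    assert np.all(np.abs(pen[1:]) < np.abs(free[1:]))


def test_penalized_logistic_handles_separation():
    # perfectly separable data: the ridge keeps the solution finite
    X = np.linspace(-1, 1, 20).reshape(-1, 1)
    y = (X[:, 0] > 0).astype(float)
    coef, _ = scoring.penalized_logistic(X, y, ridge=0.5)
    assert np.all(np.isfinite(coef)) and np.all(np.abs(coef) < 50)


def test_transform_specs_cover_all_illusions():
    for ill in ig.ILLUSIONS:
        spec = ig.spec_for(ill)
        assert spec.illusion == ill
        assert spec.t_difficulty in scoring.TRANSFORMS
        assert spec.t_strength in scoring.TRANSFORMS
    with pytest.raises(ValueError):
        ig.spec_for("spiral")


def test_raw_features_reject_nonpositive():
    trials = pd.DataFrame({"strength": [1.0, -0.5], "difficulty": [0.2, 0.3]})
    with pytest.raises(ValueError):
        scoring.raw_features(trials, ig.spec_for("ponzo"))


def test_design_matrix_standardization():
    rng = np.random.default_rng(1)
    trials = pd.DataFrame({
        "strength": rng.uniform(1, 30, 500),
        "difficulty": rng.uniform(0.05, 0.75, 500),
        "error": rng.random(500) < 0.2,
    })
    X, y, scaler = scoring.design_matrix(trials, ig.spec_for("ponzo"))
    assert X.shape == (500, 3)
    assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(X.std(axis=0), 1.0, atol=1e-12)
    # reusing the standardizer reproduces identical features
    X2, _, _ = scoring.design_matrix(trials, ig.spec_for("ponzo"),
                                     standardizer=scaler)
    assert np.array_equal(X, X2)


def test_shrink_scores_properties():
    rng = np.random.default_rng(5)
    est = rng.normal(0, 2, 100)
    ses = rng.uniform(0.1, 1.0, 100)
    shrunk, w = scoring.shrink_scores(est, ses)
    assert np.all((w >= 0) & (w <= 1))
    # shrinkage pulls toward the mean
    mean = est.mean()
    assert np.all(np.abs(shrunk - mean) <= np.abs(est - mean) + 1e-12)
    # zero heterogeneity: everything collapses to the mean
    shrunk0, w0 = scoring.shrink_scores(np.full(10, 1.0) +
                                        rng.normal(0, 1e-6, 10),
                                        np.ones(10))
    assert np.allclose(shrunk0, shrunk0.mean(), atol=1e-5)


def test_fit_participant_glm_min_trials():
    trials = pd.DataFrame({
        "strength": np.linspace(1, 30, 10),
        "difficulty": np.linspace(0.05, 0.75, 10),
        "error": [0, 1] * 5,
    })
    assert scoring.fit_participant_glm(trials, ig.spec_for("ponzo"),
                                       min_trials=20) is None


def test_score_all_output_shape(small_clean):
    kept, truth, _ = small_clean
    scores = ig.score_all(kept)
    assert scores.scores.shape[1] == 20
    assert scores.scores.index.name == "participant"
    assert set(scores.flipped) == set(scores.scores.columns)
    assert scores.raw.shape == scores.scores.shape
    # standard errors positive where defined
    ses = scores.standard_errors.to_numpy()
    assert np.all(ses[np.isfinite(ses)] > 0)


def test_compare_transforms_consistent_on_study_data(manifest):
    # On the study design the adjacent warps (sqrt vs cbrt) correlate
    # > 0.998 over the stimulus grid, so exact selection is not decidable;
    # the generating pair must however never be decisively rejected.
    pop = ig.PopulationConfig(n_participants=100, seed=31)
    people, _ = ig.sample_population(pop)
    trials = ig.simulate_study(people, manifest, seed=32)
    table, best = ig.compare_transforms(trials, "vertical_horizontal")
    assert len(table) == 16
    assert table["converged"].all()
    assert {"bic", "pseudo_r2"} <= set(table.columns)
    truth = ig.spec_for("vertical_horizontal")
    ranked = table.sort_values("bic").reset_index(drop=True)
    pos = ranked.index[(ranked["t_difficulty"] == truth.t_difficulty)
                       & (ranked["t_strength"] == truth.t_strength)][0]
    delta = ranked.loc[pos, "bic"] - ranked.loc[0, "bic"]
    assert delta < 10  # truth within the BIC indecision band


def test_compare_transforms_exact_recovery_when_separable():
    # Wide difficulty range + large pooled n make the warps separable;
    # here the generating pair must win outright.
    rng = np.random.default_rng(33)
    n = 60000
    d = rng.choice(np.geomspace(0.01, 1.0, 16), size=n)
    levels = np.geomspace(1.0, 90.0, 7)
    s = rng.choice(np.concatenate([-levels, [0.0], levels]), size=n)
    # anchored at the smallest magnitude, matching the fitted feature family
    fpos = np.where(s > 0, np.sqrt(np.abs(s)) - 1.0, 0.0)
    fneg = np.where(s < 0, np.sqrt(np.abs(s)) - 1.0, 0.0)
    eta = -1.0 - 3.0 * np.sqrt(d) + 0.35 * fpos - 0.8 * np.sqrt(d) * fpos \
        - 0.15 * fneg
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    trials = pd.DataFrame({
        "illusion": "vertical_horizontal", "series": "A",
        "difficulty": d, "strength": s, "error": y.astype(float)})
    _, best = ig.compare_transforms(trials, "vertical_horizontal")
    assert (best.t_difficulty, best.t_strength) == ("sqrt", "sqrt")


def test_validate_scores_format(small_clean):
    kept, _, _ = small_clean
    scores = ig.score_all(kept)
    table = ig.validate_scores(scores.scores, kept)
    assert {"score", "criterion", "spearman_r", "n"} <= set(table.columns)
    assert set(table["criterion"]) == {"error_rate", "mean_rt"}
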