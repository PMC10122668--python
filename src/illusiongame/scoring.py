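"""Participant-level illusion-sensitivity scores.

For each illusion, errors on incongruent trials are modelled by a
logistic regression on transformed task difficulty, transformed illusion
strength and their product. Per-participant coefficients are estimated
by ridge-penalized maximum likelihood (which keeps estimates finite
under separation) and then pulled toward the population mean by
empirical-Bayes shrinkage, a deterministic two-stage analogue of a
random-slope mixed model. The two retained coefficients per illusion
(strength slope and strength-by-difficulty interaction) give 20 scores
per participant, oriented so that higher = more illusion-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import spearmanr

from . import constants as C

__all__ = [
    "TRANSFORMS",
    "ModelSpec",
    "spec_for",
    "design_matrix",
    "penalized_logistic",
    "fit_participant_glm",
    "shrink_scores",
    "score_all",
    "compare_transforms",
    "validate_scores",
    "ScoreSet",
]

TRANSFORMS = {
    "identity": lambda x: np.asarray(x, dtype=float),
    "log": np.log,
    "sqrt": np.sqrt,
    "cbrt": np.cbrt,
}


@dataclass(frozen=True)
class ModelSpec:
    illusion: str
    t_difficulty: str
    t_strength: str

    def transform_difficulty(self, d):
        return TRANSFORMS[self.t_difficulty](d)

    def transform_strength(self, s):
        return TRANSFORMS[self.t_strength](s)


# Best error-model transform pair per illusion (difficulty, strength).
ERROR_MODEL_SPECS = {
    "delboeuf": ("log", "identity"),
    "ebbinghaus": ("sqrt", "identity"),
    "rod_frame": ("log", "log"),
    "vertical_horizontal": ("sqrt", "sqrt"),
    "zollner": ("cbrt", "identity"),
    "white": ("identity", "sqrt"),
    "muller_lyer": ("sqrt", "sqrt"),
    "ponzo": ("cbrt", "identity"),
    "poggendorff": ("cbrt", "sqrt"),
    "contrast": ("sqrt", "sqrt"),
}


def spec_for(illusion: str) -> ModelSpec:
    """The selected error-model transforms for one illusion."""
    try:
        td, ts = ERROR_MODEL_SPECS[illusion]
    except KeyError:
        raise ValueError(f"unknown illusion: {illusion!r}") from None
    return ModelSpec(illusion=illusion, t_difficulty=td, t_strength=ts)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Standardizer:
    means: np.ndarray
    sds: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.sds


FEATURES = ("t_difficulty", "t_strength", "t_interaction")


def raw_features(trials: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Columns (T_d(d), T_s(s), product) for incongruent trials."""
    s = trials["strength"].to_numpy(dtype=float)
    d = trials["difficulty"].to_numpy(dtype=float)
    if np.any(s <= 0):
        raise ValueError("scores are fit on incongruent trials (strength > 0)")
    if np.any(d <= 0):
        raise ValueError("difficulty must be > 0")
    td = spec.transform_difficulty(d)
    ts = spec.transform_strength(s)
    return np.column_stack([td, ts, td * ts])


def design_matrix(trials: pd.DataFrame, spec: ModelSpec,
                  standardizer: Standardizer | None = None):
    """Standardized design columns plus the error indicator.

    Returns ``(X, y, standardizer)``; pass the returned standardizer back
    in to reuse whole-sample moments for per-participant subsets.
    """
    X = raw_features(trials, spec)
    if standardizer is None:
        sds = X.std(axis=0, ddof=0)
        sds[sds == 0] = 1.0
        standardizer = Standardizer(means=X.mean(axis=0), sds=sds)
    y = trials["error"].to_numpy(dtype=float)
    return standardizer.apply(X), y, standardizer


# ---------------------------------------------------------------------------
# Penalized logistic regression (Newton / IRLS)
# ---------------------------------------------------------------------------
def penalized_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.5,
                       penalize_intercept: bool = False,
                       max_iter: int = 200, tol: float = 1e-10):
    """Ridge-penalized logistic regression with an unpenalized intercept.

    Maximizes sum(y*log p + (1-y)*log(1-p)) - ridge/2 * ||beta_slopes||^2.
    Returns (coefficients including leading intercept, covariance matrix).
    """
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    pen = np.full(k + 1, float(ridge))
    if not penalize_intercept:
        pen[0] = 0.0
    P = np.diag(pen)
    beta = np.zeros(k + 1)

    def objective(b):
        eta = Xd @ b
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * np.sum(pen * b**2)

    obj = objective(beta)
    for _ in range(max_iter):
        p = expit(Xd @ beta)
        grad = Xd.T @ (y - p) - pen * beta
        W = p * (1 - p)
        H = (Xd * W[:, None]).T @ Xd + P
        step = np.linalg.solve(H, grad)
        new = beta + step
        new_obj = objective(new)
        halvings = 0
        while new_obj < obj - 1e-12 and halvings < 30:
            step /= 2
            new = beta + step
            new_obj = objective(new)
            halvings += 1
        if not np.isfinite(new_obj):
            raise FloatingPointError("penalized logistic fit diverged")
        converged = np.max(np.abs(new - beta)) < tol
        beta, obj = new, new_obj
        if converged:
            break
    p = expit(Xd @ beta)
    W = p * (1 - p)
    F = (Xd * W[:, None]).T @ Xd  # Fisher information of the likelihood
    Hinv = np.linalg.inv(F + P)
    # Sandwich form: asymptotic covariance of the penalized estimator.
    # inv(F + P) alone overstates the sampling variance of a ridge-shrunk
    # estimate, because the penalty both curves the objective and shrinks
    # the estimator; the correct delta-method variance is
    # inv(F+P) F inv(F+P).
    cov = Hinv @ F @ Hinv
    return beta, cov


@dataclass(frozen=True)
class ParticipantFit:
    participant: object
    coef: np.ndarray          # (intercept, t_d, t_s, t_ds)
    se: np.ndarray
    n_trials: int


def fit_participant_glm(participant_trials: pd.DataFrame, spec: ModelSpec,
                        ridge: float = 0.5,
                        standardizer: Standardizer | None = None,
                        min_trials: int = 20) -> ParticipantFit | None:
    """Penalized logistic fit for one participant-illusion cell.

    Returns None when the cell has fewer than ``min_trials`` incongruent
    trials (flagged missing downstream).
    """
    if len(participant_trials) < min_trials:
        return None
    X, y, _ = design_matrix(participant_trials, spec, standardizer)
    beta, cov = penalized_logistic(X, y, ridge=ridge)
    return ParticipantFit(
        participant=participant_trials["participant"].iloc[0],
        coef=beta, se=np.sqrt(np.diag(cov)), n_trials=len(participant_trials),
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes shrinkage
# ---------------------------------------------------------------------------
def shrink_scores(estimates: np.ndarray, ses: np.ndarray):
    """Shrink noisy per-participant estimates toward their population mean.

    Method-of-moments: population variance tau^2 = max(var(est) - mean(se^2), 0);
    weight w_p = tau^2 / (tau^2 + se_p^2); score = mean + w_p (est_p - mean).
    Returns (shrunk, weights).
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(estimates) < 2:
        return estimates.copy(), np.ones_like(estimates)
    mean = estimates.mean()
    tau2 = max(estimates.var(ddof=1) - np.mean(ses**2), 0.0)
    if tau2 == 0.0:
        return np.full_like(estimates, mean), np.zeros_like(estimates)
    w = tau2 / (tau2 + ses**2)
    return mean + w * (estimates - mean), w


# ---------------------------------------------------------------------------
# Full scoring pipeline
# ---------------------------------------------------------------------------
@dataclass
class ScoreSet:
    scores: pd.DataFrame          # shrunk, oriented; participants x 20
    raw: pd.DataFrame             # unshrunk penalized-ML estimates
    standard_errors: pd.DataFrame
    weights: pd.DataFrame         # shrinkage weights in [0, 1]
    flipped: dict = field(default_factory=dict)  # column -> bool orientation flip


def _incongruent(trials: pd.DataFrame) -> pd.DataFrame:
    keep = (trials["strength"] > 0) & (trials["series"] != "practice")
    return trials.loc[keep]


def score_all(clean_trials: pd.DataFrame, ridge: float = 0.5,
              min_trials: int = 20) -> ScoreSet:
    """Estimate the 20 participant-level sensitivity scores.

    Expects cleaned trials with columns participant, illusion, series,
    strength, difficulty, error, rt.
    """
    illusions = [i for i in C.ILLUSIONS if i in set(clean_trials["illusion"])]
    participants = pd.Index(np.sort(clean_trials["participant"].unique()),
                            name="participant")
    raw = pd.DataFrame(index=participants, dtype=float)
    ses = pd.DataFrame(index=participants, dtype=float)
    shrunk = pd.DataFrame(index=participants, dtype=float)
    weights = pd.DataFrame(index=participants, dtype=float)

    for illusion in illusions:
        spec = spec_for(illusion)
        sub = _incongruent(clean_trials[clean_trials["illusion"] == illusion])
        if sub.empty:
            continue
        _, _, scaler = design_matrix(sub, spec)  # whole-sample moments
        fits = {}
        for pid, ptrials in sub.groupby("participant"):
            fit = fit_participant_glm(ptrials, spec, ridge=ridge,
                                      standardizer=scaler,
                                      min_trials=min_trials)
            if fit is not None:
                fits[pid] = fit
        if len(fits) < 2:
            continue
        idx = list(fits)
        for col, j in ((f"{illusion}_strength", 2), (f"{illusion}_interaction", 3)):
            est = np.array([fits[p].coef[j] for p in idx])
            se = np.array([fits[p].se[j] for p in idx])
            sh, w = shrink_scores(est, se)
            raw.loc[idx, col] = est
            ses.loc[idx, col] = se
            shrunk.loc[idx, col] = sh
            weights.loc[idx, col] = w

    # orient every column so that higher = more errors on that illusion's
    # incongruent trials (= more illusion-sensitive)
    flipped = {}
    err = _incongruent(clean_trials).groupby(["participant", "illusion"])["error"].mean()
    for col in shrunk.columns:
        illusion = col.rsplit("_", 1)[0]
        rates = err.xs(illusion, level="illusion").reindex(shrunk.index)
        mask = shrunk[col].notna() & rates.notna()
        if (mask.sum() >= 3 and shrunk.loc[mask, col].nunique() > 1
                and rates[mask].nunique() > 1):
            rho = spearmanr(shrunk.loc[mask, col], rates[mask]).statistic
        else:
            rho = np.nan
        flip = bool(np.isfinite(rho) and rho < 0)
        flipped[col] = flip
        if flip:
            for frame in (raw, shrunk):
                frame[col] = -frame[col]
    return ScoreSet(scores=shrunk, raw=raw, standard_errors=ses,
                    weights=weights, flipped=flipped)


# ---------------------------------------------------------------------------
# Transform-pair comparison (pooled models)
# ---------------------------------------------------------------------------
def _pooled_features(trials: pd.DataFrame, td_name: str, ts_name: str):
    """Pooled design: transformed difficulty, signed-strength features.

    Positive and negative strength parts enter separately; the transform
    is anchored at the smallest non-zero strength magnitude so that the
    zero-strength level contributes a zero feature even for log.
    """
    d = trials["difficulty"].to_numpy(dtype=float)
    s = trials["strength"].to_numpy(dtype=float)
    Td = TRANSFORMS[td_name]
    Ts = TRANSFORMS[ts_name]
    mags = np.abs(s[s != 0])
    smin = mags.min() if len(mags) else 1.0

    def part(x):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = Ts(np.maximum(x[pos], smin)) - Ts(smin)
        return out

    td = Td(d)
    fpos = part(s)
    fneg = part(-s)
    return np.column_stack([td, fpos, td * fpos, fneg])


def compare_transforms(trials: pd.DataFrame, illusion: str) -> tuple:
    """Fit all 16 transform pairs as pooled logistic models.

    Returns (table, best ModelSpec); table rows carry BIC and McFadden
    pseudo-R^2. Ties break toward fewer transforms (identity preferred).
    """
    sub = trials[(trials["illusion"] == illusion) & (trials["series"] != "practice")]
    if sub.empty:
        raise ValueError(f"no trials for illusion {illusion!r}")
    y = sub["error"].to_numpy(dtype=float)
    null_ll = sm.GLM(y, np.ones((len(y), 1)),
                     family=sm.families.Binomial()).fit().llf
    names = ["identity", "log", "sqrt", "cbrt"]
    complexity = {"identity": 0, "log": 1, "sqrt": 1, "cbrt": 1}
    rows = []
    for td in names:
        for ts in names:
            X = sm.add_constant(_pooled_features(sub, td, ts))
            try:
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                llf = float(fit.llf)
                if not np.isfinite(llf):
                    raise ValueError("non-finite likelihood")
                bic = -2 * llf + X.shape[1] * np.log(len(y))
                rows.append({"illusion": illusion, "t_difficulty": td,
                             "t_strength": ts, "bic": bic,
                             "pseudo_r2": 1 - llf / null_ll, "converged": True})
            except Exception:
                rows.append({"illusion": illusion, "t_difficulty": td,
                             "t_strength": ts, "bic": np.nan,
                             "pseudo_r2": np.nan, "converged": False})
    table = pd.DataFrame(rows)
    ok = table[table["converged"]].copy()
    ok["complexity"] = (ok["t_difficulty"].map(complexity)
                        + ok["t_strength"].map(complexity))
    best = ok.sort_values(["bic", "complexity"]).iloc[0]
    return table, ModelSpec(illusion=illusion, t_difficulty=best["t_difficulty"],
                            t_strength=best["t_strength"])


# ---------------------------------------------------------------------------
# Score validation against simple empirical summaries
# ---------------------------------------------------------------------------
def validate_scores(scores: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Rank correlations of each score with error rate and mean RT."""
    inc = _incongruent(trials)
    err = inc.groupby(["participant", "illusion"])["error"].mean()
    mean_rt = trials.groupby("participant")["rt"].mean()
    rows = []
    for col in scores.columns:
        illusion = col.rsplit("_", 1)[0]
        rates = err.xs(illusion, level="illusion").reindex(scores.index)
        rts = mean_rt.reindex(scores.index)
        vals = scores[col]
        for name, other in (("error_rate", rates), ("mean_rt", rts)):
            mask = vals.notna() & other.notna()
            if (mask.sum() < 3 or vals[mask].nunique() <= 1
                    or other[mask].nunique() <= 1):
                rho = np.nan
            else:
                rho = spearmanr(vals[mask], other[mask]).statistic
            rows.append({"score": col, "criterion": name,
                         "spearman_r": rho, "n": int(mask.sum())})
    return pd.DataFrame(rows)
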