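"""Exploratory factor analysis and the hierarchical general factor.

Principal-axis factoring (iterated communalities) on the score
correlation matrix, with varimax or oblimin (direct quartimin) rotation,
a simple method-agreement vote for the number of factors (Horn's
parallel analysis, Kaiser eigenvalue > 1, acceleration-factor scree),
and a two-level score computation: per-illusion composites of the two
sensitivity coefficients, then a single general factor of illusion
sensitivity extracted from the ten composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorSolution",
    "HierarchicalScores",
    "efa",
    "suggest_n_factors",
    "hierarchical_factor_scores",
    "second_order_efa",
]


@dataclass
class FactorSolution:
    loadings: pd.DataFrame        # variables x factors
    rotation: str                 # "oblimin" | "varimax" | "none"
    factor_corr: np.ndarray       # identity for orthogonal rotations
    communalities: pd.Series
    variance_explained: float     # proportion of total variance
    eigenvalues: np.ndarray       # of the original correlation matrix
    n_iter: int
    converged: bool


@dataclass
class HierarchicalScores:
    level1: pd.DataFrame          # participants x 10 illusion composites
    general: pd.Series            # Factor i score per participant
    level2_loadings: pd.Series    # correlation of each composite with Factor i
    variance_explained: float     # share of the 20 columns' variance
    dropped_participants: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Principal-axis factoring
# ---------------------------------------------------------------------------
def _principal_axis(R: np.ndarray, n_factors: int, tol: float = 1e-6,
                    max_iter: int = 200, smc_fallback: bool = False):
    p = R.shape[0]
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        if not smc_fallback:
            raise np.linalg.LinAlgError(
                "singular correlation matrix; drop redundant columns") from None
        # largest absolute off-diagonal correlation per row as the start
        off = np.abs(R - np.eye(p))
        smc = np.max(off, axis=1)
    h2 = np.clip(smc, 0.0, 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        eigval, eigvec = np.linalg.eigh(Rr)
        order = np.argsort(eigval)[::-1][:n_factors]
        lam = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0.0, None))
        new_h2 = np.clip(np.sum(lam**2, axis=1), 0.0, 1.0)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            converged = True
            break
        h2 = new_h2
    Rr = R.copy()
    np.fill_diagonal(Rr, h2)
    eigval, eigvec = np.linalg.eigh(Rr)
    order = np.argsort(eigval)[::-1][:n_factors]
    lam = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0.0, None))
    return lam, h2, it, converged


def _as_corr(score_matrix) -> tuple:
    if isinstance(score_matrix, pd.DataFrame):
        X = score_matrix.dropna().to_numpy(dtype=float)
        names = list(score_matrix.columns)
    else:
        X = np.asarray(score_matrix, dtype=float)
        names = [f"v{i}" for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("complete cases required")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance columns: {bad}")
    R = np.corrcoef(X, rowvar=False)
    return R, names, X


def efa(score_matrix, n_factors: int, rotation: str = "oblimin") -> FactorSolution:
    """Principal-axis EFA with oblimin (gamma=0) or varimax rotation.

    Loadings are sign-aligned so each factor's largest |loading| is
    positive; for oblique rotations ``factor_corr`` holds the factor
    correlation matrix.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    R, names, _ = _as_corr(score_matrix)
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    lam, h2, n_iter, converged = _principal_axis(R, n_factors)
    phi = np.eye(n_factors)
    if n_factors > 1 and rotation == "varimax":
        lam, _ = rotate_factors(lam, "varimax")
    elif n_factors > 1 and rotation == "oblimin":
        lam, T = rotate_factors(lam, "oblimin", 0.0, "oblique")
        phi = T.T @ T
    elif rotation not in ("none", "varimax", "oblimin"):
        raise ValueError(f"unknown rotation: {rotation!r}")
    # sign alignment
    for j in range(n_factors):
        i = np.argmax(np.abs(lam[:, j]))
        if lam[i, j] < 0:
            lam[:, j] = -lam[:, j]
            phi[j, :] = -phi[j, :]
            phi[:, j] = -phi[:, j]
    communalities = np.sum((lam @ phi) * lam, axis=1)
    return FactorSolution(
        loadings=pd.DataFrame(lam, index=names,
                              columns=[f"F{j + 1}" for j in range(n_factors)]),
        rotation=rotation if n_factors > 1 else "none",
        factor_corr=phi,
        communalities=pd.Series(communalities, index=names),
        variance_explained=float(np.sum(communalities) / len(names)),
        eigenvalues=eigenvalues,
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Number of factors: simplified method agreement
# ---------------------------------------------------------------------------
def suggest_n_factors(score_matrix, seed: int = 0,
                      n_resamples: int = 100) -> tuple:
    """Majority vote of parallel analysis, Kaiser rule and scree acceleration.

    Returns (n_factors, votes dict). Ties break toward parallel analysis.
    """
    R, _, X = _as_corr(score_matrix)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("matrix too small for resampling")
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]

    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_resamples, p))
    for b in range(n_resamples):
        Z = rng.normal(size=(n, p))
        null_eigs[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    null_mean = null_eigs.mean(axis=0)
    below = eig <= null_mean  # sequential rule: stop at the first failure
    n_pa = int(np.argmax(below)) if below.any() else p

    n_kaiser = int(np.sum(eig > 1.0))

    if p >= 3:
        accel = eig[:-2] - 2 * eig[1:-1] + eig[2:]  # second differences
        n_af = int(np.argmax(accel)) + 1
    else:
        n_af = 1

    votes = {"parallel_analysis": n_pa, "kaiser": n_kaiser,
             "acceleration_factor": n_af}
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index
    n_factors = n_pa if n_pa in top else int(top[0])
    return n_factors, votes


# ---------------------------------------------------------------------------
# Hierarchical scores (Factor i)
# ---------------------------------------------------------------------------
def _safe_corr(a, b) -> float:
    """Pearson correlation, 0.0 when either input is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0).replace(0.0, np.nan)
    return ((df - df.mean()) / sd).fillna(0.0)  # constant columns carry no signal


def hierarchical_factor_scores(score_set: pd.DataFrame) -> HierarchicalScores:
    """Two-level factor scores from the 20-column sensitivity matrix.

    Level 1: per illusion, the first principal factor of its two
    standardized indicators (weights from their 2x2 correlation, positive
    weight on the strength slope). Level 2: the first principal factor of
    the 10 level-1 composites, scored by the regression method and
    oriented so higher = more illusion-sensitive (positive mean loading).
    """
    complete = score_set.dropna()
    dropped = [p for p in score_set.index if p not in complete.index]
    Z = _zscore(complete)
    illusions = sorted({c.rsplit("_", 1)[0] for c in Z.columns})
    level1 = {}
    for ill in illusions:
        z1 = Z[f"{ill}_strength"]
        z2 = Z[f"{ill}_interaction"]
        r = _safe_corr(z1, z2)
        w2 = 1.0 if r >= 0 else -1.0
        comp = (z1 + w2 * z2) / np.sqrt(2 + 2 * abs(r))
        sd = comp.std(ddof=0)
        level1[ill] = comp / (sd if sd > 0 else 1.0)
    L1 = pd.DataFrame(level1, index=complete.index)

    with np.errstate(invalid="ignore", divide="ignore"):
        R10 = np.corrcoef(L1.to_numpy(), rowvar=False)
    R10 = np.nan_to_num(R10)
    np.fill_diagonal(R10, 1.0)
    lam, _, _, _ = _principal_axis(R10, 1, smc_fallback=True)
    lam = lam[:, 0]
    if lam.mean() < 0:
        lam = -lam
    weights = np.linalg.pinv(R10) @ lam  # regression-method score weights
    f = L1.to_numpy() @ weights
    sd = f.std(ddof=0)
    f = (f - f.mean()) / (sd if sd > 0 else 1.0)
    general = pd.Series(f, index=complete.index, name="factor_i")

    level2_loadings = pd.Series(
        [_safe_corr(L1[ill], general) for ill in illusions],
        index=illusions, name="loading")
    col_corr = np.array([_safe_corr(Z[c], general) for c in Z.columns])
    variance_explained = float(np.mean(col_corr**2))
    return HierarchicalScores(level1=L1, general=general,
                              level2_loadings=level2_loadings,
                              variance_explained=variance_explained,
                              dropped_participants=dropped)


def second_order_efa(level1_scores: pd.DataFrame,
                     n_factors: int = 2) -> FactorSolution:
    """Varimax-rotated principal-axis EFA of the level-1 composites."""
    return efa(level1_scores, n_factors=n_factors, rotation="varimax")
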