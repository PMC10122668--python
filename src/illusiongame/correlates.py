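"""Bayesian association tests between scores and external measures.

Correlation Bayes factors use Jeffreys' approximate marginal likelihood
for the sample correlation with a symmetric stretched-beta prior on rho
(default scale 1/3, a narrow prior appropriate for small
individual-difference effects). Rank (Spearman) variants apply the same
machinery to average-rank-transformed data. Group comparisons use the
JZS Bayes factor with a Cauchy prior (scale 0.707) on the standardized
effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = ["CorrelationResult", "TTestResult", "cor_bf", "rank_cor_bf",
           "ttest_bf", "correlate_scores"]

DEFAULT_PRIOR_SCALE = 1.0 / 3.0
DEFAULT_CAUCHY_SCALE = math.sqrt(2) / 2


@dataclass
class CorrelationResult:
    r: float
    n: int
    bf10: float
    p_value: float
    prior_scale: float
    rank_based: bool = False

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.r)


@dataclass
class TTestResult:
    delta: float          # standardized mean difference
    ci_low: float
    ci_high: float
    bf10: float
    p_value: float
    n1: int
    n2: int
    cauchy_scale: float


# ---------------------------------------------------------------------------
# Correlation Bayes factor
# ---------------------------------------------------------------------------
def _cor_likelihood(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """Jeffreys' approximate likelihood of rho given sample r, scaled so
    the value at rho = 0 is 1 (the common normalizing constant cancels in
    the Bayes factor)."""
    rho = np.asarray(rho, dtype=float)
    log_l = 0.5 * (n - 1) * np.log1p(-rho**2) - (n - 1.5) * np.log1p(-rho * r)
    return np.exp(log_l)


def _stretched_beta_pdf(rho: np.ndarray, scale: float) -> np.ndarray:
    """Symmetric beta(1/scale, 1/scale) prior stretched to (-1, 1)."""
    a = 1.0 / scale
    return stats.beta.pdf((np.asarray(rho) + 1.0) / 2.0, a, a) / 2.0


def cor_bf(x, y, prior_scale: float = DEFAULT_PRIOR_SCALE) -> CorrelationResult:
    """Pearson correlation with a Bayes factor against rho = 0.

    BF10 is the prior-weighted average of Jeffreys' likelihood over the
    stretched-beta prior, relative to the likelihood at rho = 0.
    Zero-variance input yields a result with NaN fields (``missing``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if not (0 < prior_scale <= 1):
        raise ValueError("prior_scale must be in (0, 1]")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=float("nan"), n=n, bf10=float("nan"),
                                 p_value=float("nan"),
                                 prior_scale=prior_scale)
    r, p = stats.pearsonr(x, y)
    r = float(r)
    r_like = float(np.clip(r, -0.999999, 0.999999))

    def integrand(rho):
        return _cor_likelihood(rho, r_like, n) * _stretched_beta_pdf(rho, prior_scale)

    bf10, _ = integrate.quad(integrand, -1.0, 1.0, epsabs=1e-8, limit=200,
                             points=[r_like])
    return CorrelationResult(r=r, n=n, bf10=float(bf10), p_value=float(p),
                             prior_scale=prior_scale)


def rank_cor_bf(x, y, prior_scale: float = DEFAULT_PRIOR_SCALE) -> CorrelationResult:
    """Rank (Spearman) correlation Bayes factor: cor_bf on average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    res = cor_bf(stats.rankdata(x[mask]), stats.rankdata(y[mask]),
                 prior_scale=prior_scale)
    res.rank_based = True
    return res


# ---------------------------------------------------------------------------
# Two-sample JZS Bayes factor
# ---------------------------------------------------------------------------
def _jzs_bf10(t: float, n_eff: float, df: float, scale: float) -> float:
    """Two-sample JZS Bayes factor (Cauchy prior on the effect size) by
    quadrature over the mixing parameter g ~ InverseGamma(1/2, scale^2/2)."""
    log_lik0 = -0.5 * (df + 1) * math.log1p(t * t / df)

    def integrand(g):
        c = 1.0 + n_eff * g
        log_lik1 = (-0.5 * math.log(c)
                    - 0.5 * (df + 1) * math.log1p(t * t / (c * df)))
        log_prior = (0.5 * math.log(scale**2 / 2.0)
                     - special.gammaln(0.5)
                     - 1.5 * math.log(g)
                     - scale**2 / (2.0 * g))
        return math.exp(log_lik1 + log_prior - log_lik0)

    bf, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-8, limit=200)
    return float(bf)


def ttest_bf(values, group_labels,
             cauchy_scale: float = DEFAULT_CAUCHY_SCALE) -> TTestResult:
    """Bayesian two-group comparison on the standardized score scale.

    Delta is the pooled standardized mean difference of the first group
    (in label sort order) minus the second, with a t-based 95% interval.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and group_labels must be 1-D and aligned")
    mask = np.isfinite(values)
    values, labels = values[mask], labels[mask]
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    n1, n2 = a.size, b.size
    if n1 < 3 or n2 < 3:
        raise ValueError("each group needs at least 3 observations")
    if cauchy_scale <= 0:
        raise ValueError("cauchy_scale must be positive")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    df = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    sp = math.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df)
    d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
    half = stats.t.ppf(0.975, df) * math.sqrt(1.0 / n1 + 1.0 / n2)
    bf10 = _jzs_bf10(float(t), n_eff, df, cauchy_scale)
    return TTestResult(delta=float(d), ci_low=float(d - half),
                       ci_high=float(d + half), bf10=bf10,
                       p_value=float(p), n1=n1, n2=n2,
                       cauchy_scale=cauchy_scale)


# ---------------------------------------------------------------------------
# Batch interface
# ---------------------------------------------------------------------------
def correlate_scores(scores: pd.DataFrame, traits: pd.DataFrame,
                     prior_scale: float = DEFAULT_PRIOR_SCALE,
                     rank_based: bool = False) -> pd.DataFrame:
    """Every score column against every numeric trait column.

    Both frames must carry a ``participant`` column (or index) used for
    the join; returns a tidy table with r, n, BF10 and p per pair.
    """
    s = scores.set_index("participant") if "participant" in scores else scores
    t = traits.set_index("participant") if "participant" in traits else traits
    joined = s.join(t, how="inner", lsuffix="", rsuffix="_trait")
    fn = rank_cor_bf if rank_based else cor_bf
    rows = []
    for sc in s.columns:
        for tr in t.columns:
            if not pd.api.types.is_numeric_dtype(joined[tr]):
                continue
            res = fn(joined[sc].to_numpy(), joined[tr].to_numpy(),
                     prior_scale=prior_scale)
            rows.append({"score": sc, "trait": tr, "r": res.r, "n": res.n,
                         "bf10": res.bf10, "p_value": res.p_value,
                         "rank_based": res.rank_based})
    return pd.DataFrame(rows)
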