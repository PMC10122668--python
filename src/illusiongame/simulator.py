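"""Synthetic responders with a latent general sensitivity factor.

Each simulated participant carries a baseline error tendency, an
illusion-specific strength sensitivity and strength-by-difficulty
interaction (both sharing variance through a single general factor g),
a congruent-facilitation coefficient, a lapse rate, and ex-Gaussian
reaction-time parameters. Error probabilities follow the logistic model
the scoring module fits; reaction times are ex-Gaussian with a
location shift that first rises then falls with illusion strength
(responses get fast again once the illusion fully biases the decision).

The generative features are min-max normalized versions of each
illusion's error-model transforms computed on its design grids, so the
scoring model family contains the generative model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from .design import DesignConfig, nonlinear_levels, strength_levels
from .geometry import response_axis
from .scoring import TRANSFORMS, spec_for

__all__ = [
    "ExGaussParams",
    "SimulatedParticipant",
    "PopulationConfig",
    "sample_population",
    "p_error",
    "sample_rt",
    "simulate_study",
    "inject_artifacts",
    "expected_level1_loading",
]


@dataclass(frozen=True)
class ExGaussParams:
    mu: float     # Gaussian location, ms
    sigma: float  # Gaussian spread, ms
    tau: float    # exponential tail mean, ms

    def __post_init__(self):
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be > 0")

    @property
    def mean(self) -> float:
        return self.mu + self.tau


@dataclass(frozen=True)
class SimulatedParticipant:
    id: int
    g: float                      # latent general sensitivity factor
    alpha: float                  # baseline log-odds of error
    beta_d: float                 # difficulty benefit
    beta_s: dict                  # illusion -> strength sensitivity
    beta_sd: dict                 # illusion -> strength x difficulty interaction
    congruent_facilitation: float
    lapse_rate: float
    exgauss: ExGaussParams
    rt_strength_slope: float      # ms per unit normalized strength
    rt_strength_quad: float       # curvature: fast wrong answers at extremes
    rt_difficulty_slope: float    # ms per unit normalized hardness

    def __post_init__(self):
        if not 0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5]")


@dataclass
class PopulationConfig:
    """Population distributions and contamination rates.

    Loadings are per-illusion correlations of the (standardized) strength
    sensitivity with the general factor; interaction coefficients load at
    ``interaction_loading_share`` times the same loading. Defaults emulate
    a moderately sensitive population: baseline errors a few percent,
    rising toward ~40-50% on the hardest, most strongly incongruent
    trials for the average participant, with ~600 ms ex-Gaussian reaction
    times. Individual differences in strength sensitivity are wide
    (``beta_s_sd``), spanning near-insensitive to strongly susceptible
    observers (a small tail shows reversed effects, as reported for some
    illusions); the spread is sized by a design-information calculation
    so that per-participant slopes are identifiable from the default
    manifest (see the study-design power notes).
    """

    n_participants: int = 250
    loadings: dict | float = field(default_factory=lambda: None)
    loading_range: tuple = (0.3, 0.8)
    interaction_loading_share: float = 0.7
    alpha_mean: float = -3.0
    alpha_sd: float = 0.5
    beta_d_mean: float = 2.2
    beta_d_sd: float = 0.4
    beta_s_mean: float = 2.8
    beta_s_sd: float = 2.0
    beta_sd_mean: float = -1.0
    beta_sd_sd: float = 0.6
    congruent_mean: float = 1.0
    congruent_sd: float = 0.3
    lapse_mean: float = 0.02
    mu_mean: float = 600.0
    mu_sd: float = 80.0
    sigma_mean: float = 80.0
    sigma_sd: float = 15.0
    tau_mean: float = 250.0
    tau_sd: float = 60.0
    rt_strength_slope: float = 150.0
    rt_strength_quad: float = 120.0
    rt_difficulty_slope: float = 100.0
    random_responder_rate: float = 0.0
    misunderstood_block_rate: float = 0.0
    fast_trial_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for rate in (self.random_responder_rate, self.misunderstood_block_rate,
                     self.fast_trial_rate):
            if not 0 <= rate < 1:
                raise ValueError("contamination rates must be in [0, 1)")

    def resolved_loadings(self, rng: np.random.Generator) -> dict:
        if isinstance(self.loadings, dict):
            lam = dict(self.loadings)
        elif self.loadings is not None:
            lam = {ill: float(self.loadings) for ill in C.ILLUSIONS}
        else:
            lo, hi = self.loading_range
            lam = {ill: float(v) for ill, v in
                   zip(C.ILLUSIONS, rng.uniform(lo, hi, len(C.ILLUSIONS)))}
        for v in lam.values():
            if not 0 <= v <= 1:
                raise ValueError("loadings must be in [0, 1]")
        return lam


# ---------------------------------------------------------------------------
# Normalized generative features
# ---------------------------------------------------------------------------
def _feature_norms(design: DesignConfig | None = None) -> dict:
    """Per-illusion min-max constants of the transformed design grids."""
    cfg = design or DesignConfig()
    norms = {}
    for ill in cfg.illusions:
        spec = spec_for(ill)
        s_grid = strength_levels(cfg.strength_max[ill], cfg.n_strength_levels)
        s_pos = s_grid[s_grid > 0]
        lo, hi = cfg.difficulty_range[ill]
        d_grid = nonlinear_levels(lo, hi, cfg.n_difficulty_levels,
                                  cfg.difficulty_spacing[ill])
        Ts = TRANSFORMS[spec.t_strength]
        Td = TRANSFORMS[spec.t_difficulty]
        norms[ill] = {
            "s_min": float(s_pos.min()), "Ts_lo": float(Ts(s_pos.min())),
            "Ts_hi": float(Ts(s_pos.max())),
            "Td_lo": float(Td(d_grid.min())), "Td_hi": float(Td(d_grid.max())),
            "t_strength": spec.t_strength, "t_difficulty": spec.t_difficulty,
        }
    return norms


def _f_strength(s: np.ndarray, norm: dict) -> np.ndarray:
    """Normalized strength feature in [0, 1]; zero at zero strength."""
    s = np.asarray(s, dtype=float)
    Ts = TRANSFORMS[norm["t_strength"]]
    out = np.zeros_like(s)
    pos = s > 0
    span = norm["Ts_hi"] - norm["Ts_lo"]
    out[pos] = (Ts(np.maximum(s[pos], norm["s_min"])) - norm["Ts_lo"]) / span
    return out


def _f_difficulty(d: np.ndarray, norm: dict) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    Td = TRANSFORMS[norm["t_difficulty"]]
    span = norm["Td_hi"] - norm["Td_lo"]
    return (Td(d) - norm["Td_lo"]) / span


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------
def sample_population(popconfig: PopulationConfig,
                      design: DesignConfig | None = None):
    """Draw participants and return them with their latent truth table.

    The strength sensitivity of participant p on illusion i is
    ``beta_s = mean + sd * (lambda_i * g_p + sqrt(1 - lambda_i^2) * e)``,
    so standardized sensitivities correlate lambda_i with g (and
    lambda_i * lambda_j with each other).
    """
    cfg = popconfig
    rng = np.random.default_rng(cfg.seed)
    lam = cfg.resolved_loadings(rng)
    n = cfg.n_participants
    g = rng.normal(size=n)
    alpha = rng.normal(cfg.alpha_mean, cfg.alpha_sd, n)
    beta_d = rng.normal(cfg.beta_d_mean, cfg.beta_d_sd, n)
    congruent = rng.normal(cfg.congruent_mean, cfg.congruent_sd, n)
    lapse = np.clip(rng.beta(2, 2 / max(cfg.lapse_mean, 1e-9) - 2, n), 0, 0.5) \
        if cfg.lapse_mean > 0 else np.zeros(n)
    mu = np.maximum(rng.normal(cfg.mu_mean, cfg.mu_sd, n), 200.0)
    sigma = np.maximum(rng.normal(cfg.sigma_mean, cfg.sigma_sd, n), 10.0)
    tau = np.maximum(rng.normal(cfg.tau_mean, cfg.tau_sd, n), 10.0)

    beta_s = {}
    beta_sd = {}
    for ill in C.ILLUSIONS:
        l1 = lam[ill]
        l2 = cfg.interaction_loading_share * l1
        e1 = rng.normal(size=n)
        e2 = rng.normal(size=n)
        beta_s[ill] = cfg.beta_s_mean + cfg.beta_s_sd * (
            l1 * g + np.sqrt(1 - l1**2) * e1)
        beta_sd[ill] = cfg.beta_sd_mean + cfg.beta_sd_sd * (
            l2 * g + np.sqrt(1 - l2**2) * e2)

    participants = []
    for p in range(n):
        participants.append(SimulatedParticipant(
            id=p,
            g=float(g[p]),
            alpha=float(alpha[p]),
            beta_d=float(beta_d[p]),
            beta_s={ill: float(beta_s[ill][p]) for ill in C.ILLUSIONS},
            beta_sd={ill: float(beta_sd[ill][p]) for ill in C.ILLUSIONS},
            congruent_facilitation=float(congruent[p]),
            lapse_rate=float(lapse[p]),
            exgauss=ExGaussParams(float(mu[p]), float(sigma[p]), float(tau[p])),
            rt_strength_slope=cfg.rt_strength_slope,
            rt_strength_quad=cfg.rt_strength_quad,
            rt_difficulty_slope=cfg.rt_difficulty_slope,
        ))
    truth = pd.DataFrame({"participant": np.arange(n), "g": g})
    for ill in C.ILLUSIONS:
        truth[f"{ill}_strength"] = beta_s[ill]
        truth[f"{ill}_interaction"] = beta_sd[ill]
    truth.attrs["loadings"] = lam
    return participants, truth


def expected_level1_loading(lam: float, share: float = 0.7) -> float:
    """Analytic correlation of an illusion's level-1 composite with g.

    The composite averages the standardized strength and interaction
    sensitivities, which load lam and share*lam on g and correlate
    share*lam^2 with each other.
    """
    r = share * lam**2
    return (lam + share * lam) / np.sqrt(2 + 2 * r)


# ---------------------------------------------------------------------------
# Trial-level model
# ---------------------------------------------------------------------------
_NORMS_CACHE: dict = {}


def _norms_for(design: DesignConfig | None) -> dict:
    key = id(design) if design is not None else None
    if key not in _NORMS_CACHE:
        _NORMS_CACHE[key] = _feature_norms(design)
    return _NORMS_CACHE[key]


def p_error(participant: SimulatedParticipant, strength, difficulty,
            illusion: str, design: DesignConfig | None = None) -> np.ndarray:
    """Error probability under the logistic model plus lapses."""
    norm = _norms_for(design)[illusion]
    s = np.asarray(strength, dtype=float)
    d = np.asarray(difficulty, dtype=float)
    fs = _f_strength(np.maximum(s, 0.0), norm)
    fc = _f_strength(np.maximum(-s, 0.0), norm)
    fd = _f_difficulty(d, norm)
    eta = (participant.alpha
           - participant.beta_d * fd
           + participant.beta_s[illusion] * fs
           + participant.beta_sd[illusion] * fd * fs
           - participant.congruent_facilitation * fc)
    core = 1.0 / (1.0 + np.exp(-eta))
    return participant.lapse_rate / 2 + (1 - participant.lapse_rate) * core


def sample_rt(participant: SimulatedParticipant, strength, difficulty,
              rng: np.random.Generator, illusion: str | None = None,
              design: DesignConfig | None = None) -> np.ndarray:
    """Ex-Gaussian reaction times with strength and difficulty shifts (ms)."""
    s = np.asarray(strength, dtype=float)
    d = np.asarray(difficulty, dtype=float)
    if illusion is not None:
        norm = _norms_for(design)[illusion]
        fs = _f_strength(np.abs(s), norm)
        fd = _f_difficulty(d, norm)
    else:  # bare ex-Gaussian (no design context)
        fs = np.zeros_like(s)
        fd = np.ones_like(d)
    eg = participant.exgauss
    loc = (eg.mu
           + participant.rt_strength_slope * fs
           - participant.rt_strength_quad * fs**2
           + participant.rt_difficulty_slope * (1 - fd))
    rt = rng.normal(loc, eg.sigma) + rng.exponential(eg.tau, size=loc.shape)
    return np.maximum(rt, 1.0)


def _opposite(response: str) -> str:
    return {"left": "right", "right": "left", "up": "down", "down": "up"}[response]


def simulate_study(participants, manifest: pd.DataFrame, seed: int,
                   design: DesignConfig | None = None) -> pd.DataFrame:
    """One trial record per manifest row per participant."""
    required = {"illusion", "series", "strength", "difficulty", "target"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    opposite = manifest["target"].map(_opposite).to_numpy()
    targets = manifest["target"].to_numpy()
    frames = []
    for part in participants:
        perr = np.empty(len(manifest))
        rt = np.empty(len(manifest))
        for ill, idx in manifest.groupby("illusion").indices.items():
            sub = manifest.iloc[idx]
            perr[idx] = p_error(part, sub["strength"].to_numpy(),
                                sub["difficulty"].to_numpy(), ill, design)
            rt[idx] = sample_rt(part, sub["strength"].to_numpy(),
                                sub["difficulty"].to_numpy(), rng, ill, design)
        err = rng.random(len(manifest)) < perr
        frames.append(pd.DataFrame({
            "participant": part.id,
            "illusion": manifest["illusion"].to_numpy(),
            "series": manifest["series"].to_numpy(),
            "trial_index": np.arange(len(manifest)),
            "strength": manifest["strength"].to_numpy(),
            "difficulty": manifest["difficulty"].to_numpy(),
            "target": targets,
            "response": np.where(err, opposite, targets),
            "error": err,
            "correct": ~err,
            "rt": rt,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Contaminants
# ---------------------------------------------------------------------------
def inject_artifacts(trials: pd.DataFrame, popconfig: PopulationConfig,
                     seed: int):
    """Inject the contaminants the cleaning rules are meant to catch.

    Returns (modified trials, audit) where audit holds the injected
    random-responder ids, inverted (participant, illusion, series) block
    keys, and fast-trial row indices.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    participants = np.sort(out["participant"].unique())

    random_ids = participants[rng.random(len(participants))
                              < popconfig.random_responder_rate]
    rand_mask = out["participant"].isin(random_ids).to_numpy()
    if rand_mask.any():
        axes = out.loc[rand_mask, "target"].map(
            lambda t: ("left", "right") if t in ("left", "right") else ("up", "down"))
        flips = rng.integers(2, size=int(rand_mask.sum()))
        out.loc[rand_mask, "response"] = [ax[f] for ax, f in zip(axes, flips)]

    blocks = out.loc[~rand_mask & (out["series"] != "practice"),
                     ["participant", "illusion", "series"]].drop_duplicates()
    chosen = blocks[rng.random(len(blocks)) < popconfig.misunderstood_block_rate]
    block_keys = set(map(tuple, chosen.to_numpy()))
    if block_keys:
        key = list(zip(out["participant"], out["illusion"], out["series"]))
        inv_mask = np.array([k in block_keys for k in key])
        out.loc[inv_mask, "response"] = out.loc[inv_mask, "response"].map(_opposite)
    else:
        inv_mask = np.zeros(len(out), dtype=bool)

    eligible = ~rand_mask & ~inv_mask
    fast_mask = eligible & (rng.random(len(out)) < popconfig.fast_trial_rate)
    out.loc[fast_mask, "rt"] = rng.uniform(30.0, 124.0, int(fast_mask.sum()))

    out["error"] = out["response"] != out["target"]
    out["correct"] = ~out["error"]
    audit = {
        "random_responders": list(map(int, random_ids)),
        "inverted_blocks": sorted(block_keys),
        "fast_trials": out.index[fast_mask].tolist(),
    }
    return out, audit
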