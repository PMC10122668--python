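"""Stimulus sets and per-participant trial manifests.

Each illusion contributes 134 stimuli: a 15-level strength grid crossed
with a 16-level difficulty grid, thinned to 128 main items split into
two series of 56 and 72 with alternating parameter levels, plus 6
extreme-easy practice items. A full session is 1340 trials: one practice
pass, then the 10 series-A blocks in seeded random order, then the 10
series-B blocks re-randomized.

Strength grids are arithmetic and symmetric about zero (7 congruent, 7
incongruent, 1 neutral level); difficulty grids are non-linearly spaced
(exponential-kind, square or cubic warps of an arithmetic base grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .geometry import StimulusSpec, response_axis

__all__ = [
    "DesignConfig",
    "linear_levels",
    "nonlinear_levels",
    "strength_levels",
    "build_stimulus_set",
    "build_full_design",
    "write_manifest",
    "read_manifest",
    "rows_to_specs",
]

MANIFEST_COLUMNS = [
    "illusion", "series", "strength", "difficulty", "target",
    "stimulus_id", "image_path",
]

SPACING_KINDS = ("exponential", "square", "cubic")


# ---------------------------------------------------------------------------
# Level grids
# ---------------------------------------------------------------------------
def linear_levels(lo: float, hi: float, n: int) -> np.ndarray:
    """Arithmetic sequence from lo to hi inclusive."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    return np.linspace(lo, hi, n)


def _warp(t: np.ndarray, kind: str) -> np.ndarray:
    # the "exponential" warp is the quadratic g(t) = 0.7 t + 0.3 t^2: it has
    # constant second differences and maps the documented worked example
    # [0.1, 0.4, 0.7, 1.0] -> [0.1, 0.34, 0.64, 1.0] exactly
    if kind == "exponential":
        return 0.7 * t + 0.3 * t**2
    if kind == "square":
        return t**2
    if kind == "cubic":
        return t**3
    raise ValueError(f"unknown spacing kind: {kind!r} (use one of {SPACING_KINDS})")


def nonlinear_levels(lo: float, hi: float, n: int, kind: str) -> np.ndarray:
    """Endpoint-preserving non-linear spacing of n levels on [lo, hi]."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    t = np.linspace(0.0, 1.0, n)
    return lo + (hi - lo) * _warp(t, kind)


def strength_levels(max_abs: float, n: int = C.N_STRENGTH_LEVELS) -> np.ndarray:
    """Symmetric signed strength grid: (n-1)/2 congruent, zero, (n-1)/2 incongruent."""
    if max_abs <= 0:
        raise ValueError("max_abs must be > 0")
    if n % 2 == 0:
        raise ValueError("n must be odd so the grid contains a neutral level")
    levels = np.linspace(-max_abs, max_abs, n)
    levels[n // 2] = 0.0  # exact zero at the midpoint
    return levels


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------
@dataclass
class DesignConfig:
    illusions: tuple = C.ILLUSIONS
    difficulty_range: dict = field(default_factory=lambda: dict(C.DIFFICULTY_RANGE))
    difficulty_spacing: dict = field(default_factory=lambda: dict(C.DIFFICULTY_SPACING))
    strength_max: dict = field(default_factory=lambda: dict(C.STRENGTH_MAX))
    n_strength_levels: int = C.N_STRENGTH_LEVELS
    n_difficulty_levels: int = C.N_DIFFICULTY_LEVELS
    series_sizes: tuple = C.SERIES_SIZES
    n_practice: int = C.N_PRACTICE
    seed: int = 0

    def __post_init__(self):
        if self.n_strength_levels % 2 == 0:
            raise ValueError("n_strength_levels must be odd")
        n_s, n_d = self.n_strength_levels, self.n_difficulty_levels
        half_d = n_d // 2
        size_a = half_d * (n_s // 2)
        size_b = (n_d - half_d) * ((n_s + 1) // 2 + 1)
        if (size_a, size_b) != tuple(self.series_sizes):
            raise ValueError(
                f"series sizes {self.series_sizes} inconsistent with the "
                f"{n_s} x {n_d} grid split (expected {(size_a, size_b)})"
            )
        for ill in self.illusions:
            lo, hi = self.difficulty_range[ill]
            if not 0 < lo < hi:
                raise ValueError(f"invalid difficulty range for {ill}")
            if self.strength_max[ill] <= 0:
                raise ValueError(f"invalid strength max for {ill}")
            if self.difficulty_spacing[ill] not in SPACING_KINDS:
                raise ValueError(f"invalid spacing kind for {ill}")

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "illusions" in data:
            data["illusions"] = tuple(data["illusions"])
        if "series_sizes" in data:
            data["series_sizes"] = tuple(data["series_sizes"])
        base = cls()
        for key in ("difficulty_range", "difficulty_spacing", "strength_max"):
            if key in data:
                merged = dict(getattr(base, key))
                merged.update({k: tuple(v) if isinstance(v, list) else v
                               for k, v in data[key].items()})
                data[key] = merged
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["illusions"] = list(data["illusions"])
        data["series_sizes"] = list(data["series_sizes"])
        data["difficulty_range"] = {k: list(v) for k, v in
                                    data["difficulty_range"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Stimulus sets
# ---------------------------------------------------------------------------
def build_stimulus_set(illusion: str, config: DesignConfig,
                       seed: int) -> pd.DataFrame:
    """All 134 manifest rows (56 + 72 main + 6 practice) for one illusion."""
    axis = response_axis(illusion)
    lo, hi = config.difficulty_range[illusion]
    difficulties = nonlinear_levels(lo, hi, config.n_difficulty_levels,
                                    config.difficulty_spacing[illusion])
    strengths = strength_levels(config.strength_max[illusion],
                                config.n_strength_levels)
    # alternating allocation: even-index difficulties pair with odd-index
    # strengths (which include the neutral 0) in series A; odd-index
    # difficulties pair with even-index strengths plus 0 in series B
    d_a, d_b = difficulties[0::2], difficulties[1::2]
    s_a = strengths[1::2]
    zero = strengths[config.n_strength_levels // 2]
    s_b = np.sort(np.append(strengths[0::2], zero))
    rng = np.random.default_rng(seed)

    rows = []

    def add(series, s, d, practice=False):
        target = axis[int(rng.integers(2))]
        rows.append({
            "illusion": illusion,
            "series": series,
            "strength": float(s),
            "difficulty": float(d),
            "target": target,
            "stimulus_id": f"{illusion}_{series}_{len(rows):03d}",
            "image_path": f"{illusion}/{series}_{len(rows):03d}.png",
        })

    for d in d_a:
        for s in s_a:
            add("A", s, d)
    for d in d_b:
        for s in s_b:
            add("B", s, d)
    # practice: the 3 easiest difficulty levels crossed with one moderate
    # congruent and one moderate incongruent strength
    practice_d = np.sort(difficulties)[-3:]
    k = config.n_strength_levels // 4
    practice_s = (strengths[config.n_strength_levels // 2 - k],
                  strengths[config.n_strength_levels // 2 + k])
    for d in practice_d:
        for s in practice_s:
            add("practice", s, d, practice=True)
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def build_stimulus_manifest(config: DesignConfig) -> pd.DataFrame:
    """Stimulus sets for every illusion, seeded from the config master seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.illusions))
    parts = [build_stimulus_set(ill, config, seed=int(ss.generate_state(1)[0] % 2**31))
             for ill, ss in zip(config.illusions, seeds)]
    return pd.concat(parts, ignore_index=True)


def build_full_design(config: DesignConfig, participant_seed: int) -> pd.DataFrame:
    """Ordered 1340-trial session: practice, series-A blocks, series-B blocks."""
    manifest = build_stimulus_manifest(config)
    rng = np.random.default_rng(participant_seed)
    chunks = []

    practice = manifest[manifest.series == "practice"]
    chunks.append(practice.sample(frac=1, random_state=rng))
    for series in ("A", "B"):
        block_order = list(config.illusions)
        rng.shuffle(block_order)
        for ill in block_order:
            block = manifest[(manifest.series == series) & (manifest.illusion == ill)]
            chunks.append(block.sample(frac=1, random_state=rng))
    out = pd.concat(chunks, ignore_index=True)
    out.insert(0, "trial_index", np.arange(len(out)))
    return out


def rows_to_specs(rows: pd.DataFrame) -> list:
    """Manifest rows as validated stimulus specs."""
    return [
        StimulusSpec(illusion_type=r.illusion, strength=r.strength,
                     difficulty=r.difficulty, target_assignment=r.target,
                     is_practice=(r.series == "practice"))
        for r in rows.itertuples()
    ]


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------
def write_manifest(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False, float_format="%.10g")


def read_manifest(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed manifest CSV: {err}") from err
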