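"""Participant-, block- and trial-level exclusion rules.

Order follows the cleaning narrative of the task: first whole
participants are screened (near-chance accuracy suggesting random
answers, or implausibly fast average responding), then whole
participant-blocks with more than 50% errors are discarded (instructions
likely misunderstood), then individual trials with extreme reaction
times (< 125 ms, or > 4 SD above that participant's mean RT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["ExclusionReport", "screen_participants", "filter_blocks",
           "filter_trials", "clean"]

BLOCK_KEYS = ["participant", "illusion", "series"]


@dataclass
class ExclusionReport:
    excluded_participants: dict = field(default_factory=dict)  # id -> reason
    dropped_blocks: list = field(default_factory=list)
    n_trials_dropped_blocks: int = 0
    dropped_trials: dict = field(default_factory=dict)  # reason -> count
    proportions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["excluded_participants"] = {
            str(k): v for k, v in self.excluded_participants.items()}
        payload["dropped_blocks"] = [list(b) for b in self.dropped_blocks]
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def screen_participants(trials: pd.DataFrame, error_band: float = 0.45,
                        fast_sd: float = 4.0):
    """Drop whole participants: near-chance error rate or implausibly fast.

    A participant is excluded when their overall error rate is >=
    ``error_band`` (chance performance is 0.5 in a 2AFC task) or when
    their mean RT lies more than ``fast_sd`` SDs below the sample mean of
    participant-mean RTs.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    report = ExclusionReport()
    by_p = trials.groupby("participant")
    err = by_p["error"].mean()
    mean_rt = by_p["rt"].mean()
    center, spread = mean_rt.mean(), mean_rt.std(ddof=1)
    excluded = {}
    for pid in err.index:
        if err[pid] >= error_band:
            excluded[pid] = "error_rate_near_chance"
        elif spread > 0 and mean_rt[pid] < center - fast_sd * spread:
            excluded[pid] = "implausibly_fast"
    report.excluded_participants = excluded
    kept = trials[~trials["participant"].isin(excluded)]
    report.proportions["participants_excluded"] = (
        len(excluded) / err.size if err.size else 0.0)
    return kept, report


def filter_blocks(trials: pd.DataFrame):
    """Remove every participant-block with strictly more than 50% errors."""
    if trials.empty:
        return trials, []
    block_err = trials.groupby(BLOCK_KEYS)["error"].mean()
    bad = block_err[block_err > 0.5].index
    if len(bad) == 0:
        return trials, []
    idx = trials.set_index(BLOCK_KEYS).index
    keep = ~idx.isin(bad)
    return trials[keep], [tuple(b) for b in bad]


def filter_trials(trials: pd.DataFrame):
    """Drop trials with extreme RTs: < 125 ms or > mean + 4 SD.

    The slow-tail rule uses each participant's own mean and SD over their
    surviving trials, iterated to a fixed point so that re-applying the
    filter leaves the table unchanged.
    """
    if trials.empty:
        return trials, {"fast": 0, "slow": 0}
    fast = trials["rt"] < 125.0
    kept = trials[~fast]
    n_slow = 0
    while True:
        stats = kept.groupby("participant")["rt"].agg(["mean", "std"])
        thresh = (stats["mean"] + 4.0 * stats["std"].fillna(np.inf))
        limit = kept["participant"].map(thresh)
        slow = kept["rt"] > limit
        if not slow.any():
            break
        n_slow += int(slow.sum())
        kept = kept[~slow]
    return kept, {"fast": int(fast.sum()), "slow": n_slow}


def clean(trials: pd.DataFrame, error_band: float = 0.45,
          fast_sd: float = 4.0):
    """Full pipeline: participant screening, block filter, trial filter."""
    kept, report = screen_participants(trials, error_band, fast_sd)
    kept, dropped_blocks = filter_blocks(kept)
    report.dropped_blocks = dropped_blocks
    n_before_trials = len(kept)
    # proportions relative to trials surviving the previous stage
    n_after_screen = len(trials[~trials["participant"].isin(
        report.excluded_participants)])
    report.proportions["block_trials_dropped"] = (
        (n_after_screen - n_before_trials) / n_after_screen
        if n_after_screen else 0.0)
    kept, dropped = filter_trials(kept)
    report.dropped_trials = dropped
    report.proportions["trials_dropped"] = (
        (dropped["fast"] + dropped["slow"]) / n_before_trials
        if n_before_trials else 0.0)
    report.n_trials_dropped_blocks = n_after_screen - n_before_trials
    return kept.reset_index(drop=True), report
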