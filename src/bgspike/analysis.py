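"""Performance and weight-trajectory statistics.

Success is the raw proportion of correct selections, so chance level is
``1/a`` (1/3 for the standard three-action task) and the maximum is 1.
Condition summaries follow the windowing used for the lesion comparisons:
per-run mean success over the first or last 20 trials of each block,
averaged across runs (sample SD, n-1), with an optional burn-in of blocks
excluded (default: the first four, where the reward-prediction weights are
still settling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSummary",
    "WeightLog",
    "success_curve",
    "summarize_condition",
    "weight_change_amplitude",
    "compare_conditions",
    "rescued_blocks",
    "success_in_blocks",
]


@dataclass
class ConditionSummary:
    condition: str
    n_runs: int
    window: str
    mean: float
    sd: float
    per_run_means: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0):
            raise ValueError("success mean must lie in [0, 1]")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


@dataclass
class WeightLog:
    """Time series of mean plastic weights sampled on a fixed grid."""

    times: np.ndarray                 # ms
    w_d1: np.ndarray
    w_d2: np.ndarray
    w_rp: np.ndarray
    rp_pairs: Optional[np.ndarray] = None
    expected_interval: float = 250.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.size >= 2:
            dts = np.diff(t)
            if np.any(dts <= 0):
                raise ValueError("sample times must be strictly increasing")
            if not np.allclose(dts, self.expected_interval):
                raise ValueError(
                    f"sample spacing must be {self.expected_interval} ms")

    @classmethod
    def from_session(cls, result) -> "WeightLog":
        return cls(result.weight_times, result.weights[:, 0],
                   result.weights[:, 1], result.weights[:, 2],
                   rp_pairs=result.rp_pair_weights,
                   expected_interval=result.config.weight_sample_interval)


def _rewards(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records["rewarded"].to_numpy(dtype=float)
    return np.array([float(r.rewarded) for r in records])


def success_curve(records, window: int = 10) -> np.ndarray:
    """Trailing moving average of the correct/incorrect indicator.

    Shorter-than-window prefixes average over the available trials, so the
    curve is defined from the first trial on.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = _rewards(records)
    if x.size == 0:
        raise ValueError("no trial records")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - window, 0)
    return (csum[idx] - csum[lo]) / (idx - lo)


def _block_window_mask(df: pd.DataFrame, window_spec: str, window: int,
                       trials_per_block: int, burn_in_blocks: int,
                       min_block: Optional[int]) -> pd.Series:
    if window > trials_per_block:
        raise ValueError("window exceeds block length")
    pos = df.groupby("block").cumcount()
    if window_spec == "first":
        sel = pos < window
    elif window_spec == "last":
        sel = pos >= trials_per_block - window
    elif window_spec == "all":
        sel = pos >= 0
    else:
        raise ValueError("window_spec must be 'first', 'last' or 'all'")
    lo = burn_in_blocks if min_block is None else min_block
    return sel & (df["block"] >= lo)


def summarize_condition(
    runs: Sequence,
    condition: str = "",
    window_spec: str = "last",
    window: int = 20,
    burn_in_blocks: int = 4,
    min_block: Optional[int] = None,
    blocks: Optional[Iterable[int]] = None,
) -> ConditionSummary:
    """Cross-run success summary over a per-block trial window.

    ``runs`` is a sequence of trial tables (DataFrames or TrialRecord
    lists).  ``window_spec`` selects the first/last ``window`` trials of
    each block; ``blocks`` optionally restricts to an explicit block set
    (e.g. the rescued blocks of the dopamine-depletion experiment),
    otherwise blocks before the burn-in are excluded.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    means = []
    for run in runs:
        df = run if isinstance(run, pd.DataFrame) else pd.DataFrame(
            [dict(block=t.block, rewarded=int(t.rewarded)) for t in run])
        tpb = df.groupby("block").size().max()
        mask = _block_window_mask(df, window_spec, window, int(tpb),
                                  burn_in_blocks, min_block)
        if blocks is not None:
            mask &= df["block"].isin(list(blocks))
        sel = df.loc[mask, "rewarded"]
        if sel.empty:
            raise ValueError("window selected no trials")
        means.append(sel.mean())
    means = np.asarray(means, float)
    sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
    label = f"{window_spec}-{window}" + (f"-blocks{sorted(set(blocks))}" if blocks else "")
    return ConditionSummary(condition=condition, n_runs=len(runs),
                            window=label, mean=float(means.mean()), sd=sd,
                            per_run_means=means)


def weight_change_amplitude(
    log: WeightLog | np.ndarray,
    trial_boundaries: Optional[np.ndarray] = None,
    pathway: str = "D1",
) -> float:
    """Mean absolute weight change between consecutive trials.

    If ``log`` is a 2-D array of per-synapse weight snapshots aligned to
    trial ends (rows = trials), the mean is taken over synapses and
    consecutive-trial pairs.  If it is a :class:`WeightLog` of mean
    weights, the sample nearest each trial end is used.
    """
    if isinstance(log, np.ndarray):
        snaps = np.atleast_2d(log)
        if snaps.shape[0] < 2:
            raise ValueError("need at least two trial-aligned samples")
        return float(np.abs(np.diff(snaps, axis=0)).mean())
    if trial_boundaries is None:
        raise ValueError("trial boundaries required with a WeightLog")
    series = {"D1": log.w_d1, "D2": log.w_d2, "RP": log.w_rp}[pathway]
    tb = np.asarray(trial_boundaries, float)
    if tb.size < 2:
        raise ValueError("need at least two trial boundaries")
    idx = np.clip(np.searchsorted(log.times, tb), 0, log.times.size - 1)
    # snap to nearest sample
    prev = np.clip(idx - 1, 0, log.times.size - 1)
    use_prev = np.abs(log.times[prev] - tb) < np.abs(log.times[idx] - tb)
    idx = np.where(use_prev, prev, idx)
    vals = series[idx]
    return float(np.abs(np.diff(vals)).mean())


def compare_conditions(summaries: List[ConditionSummary]) -> pd.DataFrame:
    """Means, SDs and pairwise mean differences, sorted by mean success."""
    if len(summaries) < 2:
        raise ValueError("need at least two condition summaries")
    rows = sorted(summaries, key=lambda s: -s.mean)
    df = pd.DataFrame([
        dict(condition=s.condition, n_runs=s.n_runs, window=s.window,
             mean=s.mean, sd=s.sd) for s in rows])
    for s in summaries:
        df[f"diff_vs_{s.condition}"] = df["mean"] - s.mean
    return df


def rescued_blocks(onset_block: int, n_blocks: int, n_actions: int = 3) -> list:
    """Post-deletion blocks whose reward mapping equals the last mapping
    learned before the dopaminergic deletion (i.e. block ``onset - 1``)."""
    last = onset_block - 1
    return [b for b in range(onset_block, n_blocks)
            if (b - last) % n_actions == 0]


def success_in_blocks(df: pd.DataFrame, blocks: Iterable[int],
                      window_spec: str = "all", window: int = 40) -> float:
    """Mean success over the given blocks (optionally windowed)."""
    blocks = list(blocks)
    sub = df[df["block"].isin(blocks)]
    if sub.empty:
        raise ValueError("no trials in the requested blocks")
    if window_spec == "all":
        return float(sub["rewarded"].mean())
    tpb = sub.groupby("block").size().max()
    mask = _block_window_mask(sub, window_spec, window, int(tpb), 0, 0)
    return float(sub.loc[mask, "rewarded"].mean())
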