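"""Trial protocol, action selection and session loops.

A trial lasts 1.5 s and has four phases:

1. **selection** (500 ms) — the current state's population fires at 30 Hz
   (3 Hz background elsewhere); GPi/SNr spike counts per action are
   collected and an action is drawn from a softmax over the *negated*
   normalized counts (the least active output population is the most
   likely selection, i.e. the most dis-inhibited action);
2. **efference** (300 ms) — the selected action's efference-copy source
   fires at a high rate onto its D1/D2 matrisomes, and — delayed by
   exactly this phase's duration — onto the (state, action) striosome
   subpopulation;
3. **learning** (400 ms) — the dopaminergic drive switches according to
   the reward outcome while the striosomal volley arrives; the
   receptor-gated BCPNN updates run at all plastic synapses;
4. **reset** (300 ms) — state and efference return to background and the
   dopaminergic drive to baseline, to avoid overlap between trials.

Reward: in state ``i`` at block ``b``, action ``j`` is rewarded iff
``(i + b) mod a == j`` — the mapping is a bijection within each block and
shifts at every block boundary.

Sessions iterate blocks of trials with states presented round-robin,
log mean plastic weights every 250 ms, and can delete a fraction of the
dopaminergic neurons at a configured onset block (simulated Parkinson's
degeneration; the RPE baseline stays frozen at its intact calibration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .dopamine import calibrate_baseline
from .network import (
    LesionSpec,
    NetworkConfig,
    NetworkModel,
    apply_lesion,
    build_network,
    delete_dopamine_neurons,
)

__all__ = [
    "SessionConfig",
    "TrialRecord",
    "SessionResult",
    "compute_reward",
    "select_action",
    "run_trial",
    "run_session",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SessionConfig:
    """Block/trial/phase protocol of one simulated session."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    n_blocks: int = 15
    trials_per_block: int = 40
    phase_durations: tuple = (500.0, 300.0, 400.0, 300.0)
    softmax_temperature: float = 0.04
    seed: int = 0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    state_schedule: str = "round_robin"  # or "random"
    weight_sample_interval: float = 250.0
    calibration_duration: float = 4000.0
    record_spikes: bool = False

    def __post_init__(self) -> None:
        if self.trials_per_block <= 0 or self.n_blocks <= 0:
            raise ValueError("blocks and trials per block must be positive")
        if len(self.phase_durations) != 4:
            raise ValueError("exactly four phase durations required")
        if self.state_schedule not in ("round_robin", "random"):
            raise ValueError("state_schedule must be round_robin or random")

    @property
    def trial_duration(self) -> float:
        return float(sum(self.phase_durations))


@dataclass
class TrialRecord:
    """Bookkeeping for a single trial."""

    block: int
    trial: int
    state: int
    action: int
    rewarded: bool
    action_counts: np.ndarray
    kappa_mean: float
    kappa_min: float
    kappa_max: float
    t_start: float
    phase_boundaries: tuple


@dataclass
class SessionResult:
    trials: List[TrialRecord]
    weight_times: np.ndarray
    weights: np.ndarray          # [n_samples, 3]: mean w of D1, D2, RP
    rp_pair_weights: np.ndarray  # [n_samples, n_states * n_actions]
    beta_dopa: float
    config: SessionConfig
    network: NetworkModel
    trial_dw_d1: np.ndarray = field(default_factory=lambda: np.empty(0))
    trial_dw_d2: np.ndarray = field(default_factory=lambda: np.empty(0))
    spikes: Optional[tuple] = None

    def trials_frame(self) -> pd.DataFrame:
        rows = [
            dict(block=t.block, trial=t.trial, state=t.state, action=t.action,
                 rewarded=int(t.rewarded), kappa_mean=t.kappa_mean,
                 kappa_min=t.kappa_min, kappa_max=t.kappa_max, t_start=t.t_start)
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    def weights_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_ms": self.weight_times, "w_d1": self.weights[:, 0],
             "w_d2": self.weights[:, 1], "w_rp": self.weights[:, 2]})
        n_actions = self.config.network.n_actions
        for sp in range(self.rp_pair_weights.shape[1]):
            df[f"w_rp_s{sp // n_actions}a{sp % n_actions}"] = (
                self.rp_pair_weights[:, sp])
        return df


def compute_reward(i: int, j: int, b: int, n_states: int = 3,
                   n_actions: int = 3) -> bool:
    """True iff action ``j`` is rewarded in state ``i`` during block ``b``:
    ``(i + b) mod a == j``, block numbering starting at zero."""
    if not (0 <= i < n_states):
        raise IndexError(f"state index {i} out of range")
    if not (0 <= j < n_actions):
        raise IndexError(f"action index {j} out of range")
    if b < 0:
        raise IndexError("block index must be non-negative")
    return ((i + b) % n_actions) == j


def select_action(
    spike_counts: Sequence[float],
    temperature: float,
    rng: np.random.Generator,
) -> int:
    """Softmax selection on the *inverse* spike-count distribution.

    Counts are normalized to sum to one (uniform if all are zero), negated
    and passed through a softmax at the given temperature, so the least
    active output population is the most probable selection.
    """
    counts = np.asarray(spike_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two actions")
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    total = counts.sum()
    norm = counts / total if total > 0 else np.full(counts.size, 1.0 / counts.size)
    logits = -norm / max(temperature, 1e-12)
    logits -= logits.max()
    probs = np.exp(logits)
    probs /= probs.sum()
    return int(rng.choice(counts.size, p=probs))


def selection_probabilities(spike_counts: Sequence[float],
                            temperature: float) -> np.ndarray:
    """Analytic selection probabilities of :func:`select_action`."""
    counts = np.asarray(spike_counts, dtype=float)
    total = counts.sum()
    norm = counts / total if total > 0 else np.full(counts.size, 1.0 / counts.size)
    logits = -norm / max(temperature, 1e-12)
    logits -= logits.max()
    probs = np.exp(logits)
    return probs / probs.sum()


def _phase_rates(cfg: NetworkConfig, active_state: int | None,
                 active_action: int | None):
    state = np.full(cfg.n_states, cfg.state_background_hz)
    if active_state is not None:
        state[active_state] = cfg.state_active_hz
    eff = np.full(cfg.n_actions, cfg.eff_background_hz)
    if active_action is not None:
        eff[active_action] = cfg.eff_active_hz
    return state, eff


def run_trial(
    network: NetworkModel,
    i: int,
    b: int,
    rng: np.random.Generator,
    session: SessionConfig,
    sample_times: Optional[np.ndarray] = None,
    record_spikes: bool = False,
) -> tuple:
    """Run the four-phase protocol for state ``i`` in block ``b``.

    Returns ``(TrialRecord, list_of_PhaseResult)``.
    """
    cfg = network.config
    d_sel, d_eff, d_learn, d_reset = session.phase_durations
    da = network.calibration["da_drive"]
    t_start = network.global_step * cfg.dt
    results = []

    state_r, eff_r = _phase_rates(cfg, i, None)
    results.append(network.run(
        d_sel, state_r, eff_r, da.baseline_rate, collect_counts=True,
        sample_times=sample_times, record_spikes=record_spikes))
    counts = results[-1].action_counts
    j = select_action(counts, session.softmax_temperature, rng)

    state_r, eff_r = _phase_rates(cfg, i, j)
    results.append(network.run(
        d_eff, state_r, eff_r, da.baseline_rate,
        sample_times=sample_times, record_spikes=record_spikes))

    rewarded = compute_reward(i, j, b, cfg.n_states, cfg.n_actions)
    da_rate = da.reward_rate if rewarded else da.omission_rate
    learn = network.run(
        d_learn, state_r, eff_r, da_rate,
        sample_times=sample_times, record_spikes=record_spikes)
    results.append(learn)

    state_r, eff_r = _phase_rates(cfg, None, None)
    results.append(network.run(
        d_reset, state_r, eff_r, da.baseline_rate,
        sample_times=sample_times, record_spikes=record_spikes))

    boundaries = tuple(np.cumsum([t_start, d_sel, d_eff, d_learn, d_reset]))
    record = TrialRecord(
        block=b, trial=-1, state=i, action=j, rewarded=rewarded,
        action_counts=counts.copy(),
        kappa_mean=float(learn.kappa_matrisome.mean()),
        kappa_min=float(learn.kappa_matrisome.min()),
        kappa_max=float(learn.kappa_matrisome.max()),
        t_start=t_start, phase_boundaries=boundaries,
    )
    return record, results


def run_session(session: SessionConfig,
                network: Optional[NetworkModel] = None) -> SessionResult:
    """Run a full multi-block session.

    Builds the network (unless one is supplied), applies the configured
    lesion, calibrates the RPE baseline on the intact dopaminergic
    population, then iterates blocks and trials.  If the lesion specifies a
    dopaminergic deletion fraction, the deletion is applied at the start of
    the onset block with the baseline left frozen.
    """
    ss = np.random.SeedSequence(session.seed)
    s_net, s_beta, s_sel, s_pd = [int(s.generate_state(1)[0] % 2 ** 31)
                                  for s in ss.spawn(4)]
    if network is None:
        net_cfg = session.network
        if net_cfg.eff_striosome_delay_ms != session.phase_durations[1]:
            from dataclasses import replace as _replace
            net_cfg = _replace(
                net_cfg, eff_striosome_delay_ms=session.phase_durations[1])
        network = build_network(net_cfg, seed=s_net)
    apply_lesion(network, session.lesion)
    network.beta_dopa = calibrate_baseline(
        network, duration=session.calibration_duration, seed=s_beta)
    network.q = -network.beta_dopa  # start the transmitter at baseline
    # settle conductances/rates before the first trial (avoids a spurious
    # negative-RPE transient while the network charges up)
    st0, ef0 = _phase_rates(network.config, None, None)
    network.run(300.0, st0, ef0, network.calibration["da_drive"].baseline_rate)
    sel_rng = np.random.default_rng(s_sel)

    cfg = network.config
    total_ms = session.n_blocks * session.trials_per_block * session.trial_duration
    grid = np.arange(session.weight_sample_interval, total_ms + 1e-9,
                     session.weight_sample_interval)

    records: List[TrialRecord] = []
    w_times, w_means, w_pairs = [], [], []
    all_spikes_id, all_spikes_t = [], []
    dw_d1, dw_d2 = [], []
    prev_snap = None
    n_d1 = network.n_d1
    trial_global = 0
    deleted = False
    for b in range(session.n_blocks):
        if (session.lesion.pd_fraction > 0 and not deleted
                and b >= session.lesion.pd_onset_block):
            delete_dopamine_neurons(network, session.lesion.pd_fraction, seed=s_pd)
            deleted = True
            logger.info("deleted %.0f%% of dopaminergic neurons at block %d",
                        100 * session.lesion.pd_fraction, b)
        n_correct = 0
        for t in range(session.trials_per_block):
            if session.state_schedule == "round_robin":
                i = trial_global % cfg.n_states
            else:
                i = int(sel_rng.integers(cfg.n_states))
            rec, results = run_trial(
                network, i, b, sel_rng, session, sample_times=grid,
                record_spikes=session.record_spikes)
            rec.trial = trial_global
            records.append(rec)
            n_correct += rec.rewarded
            for r in results:
                if r.weight_samples.shape[0]:
                    w_times.append(r.weight_sample_times)
                    w_means.append(r.weight_samples)
                    w_pairs.append(r.rp_pair_samples)
                if r.spikes is not None:
                    all_spikes_id.append(r.spikes[0])
                    all_spikes_t.append(r.spikes[1])
            snap = network.cortical_weight_matrix()
            if prev_snap is not None:
                diff = np.abs(snap - prev_snap)
                dw_d1.append(diff[:, :n_d1].mean())
                dw_d2.append(diff[:, n_d1:].mean())
            prev_snap = snap
            trial_global += 1
        logger.info("block %d: success %.2f", b,
                    n_correct / session.trials_per_block)

    spikes = None
    if all_spikes_id:
        spikes = (np.concatenate(all_spikes_id), np.concatenate(all_spikes_t))
    return SessionResult(
        trials=records,
        weight_times=np.concatenate(w_times) if w_times else np.empty(0),
        weights=np.vstack(w_means) if w_means else np.empty((0, 3)),
        rp_pair_weights=np.vstack(w_pairs) if w_pairs else np.empty((0, 0)),
        beta_dopa=network.beta_dopa,
        config=session,
        network=network,
        trial_dw_d1=np.asarray(dw_d1),
        trial_dw_d2=np.asarray(dw_d2),
        spikes=spikes,
    )
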