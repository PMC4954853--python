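"""Dopamine volume transmission and the reward prediction error (RPE).

The dopaminergic population broadcasts a single global signal: its spike
train is low-pass filtered into ``q``, a proxy for the extracellular
dopamine concentration (units: population-summed spikes/s).  The signed
learning signal is

    kappa = (sigma * (beta_dopa + q)) ** lam

where ``beta_dopa`` (< 0) offsets the intact baseline so that kappa is zero
at baseline firing, ``sigma`` is a gain and ``lam`` an integer exponent.
Matrisomes use an odd exponent (default 7) so kappa keeps the sign of the
dopamine deviation while small fluctuations are strongly suppressed;
striosomes use an even exponent (default 2) so their learning rate is
always non-negative and plasticity in the reward-prediction pathway is
enabled by bursts and dips alike.

``beta_dopa`` is calibrated once on the intact network and deliberately
*not* recalibrated after dopaminergic cell loss: with fewer neurons the
summed rate q drops below ``-beta_dopa`` and the matrisomal RPE becomes
tonically negative, which is the mechanism behind the simulated
Parkinsonian learning deficits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "RpeState",
    "DopamineDrive",
    "update_q",
    "compute_rpe",
    "signed_power",
    "filter_q",
    "calibrate_baseline",
    "set_reward_drive",
]

logger = logging.getLogger(__name__)

Compartment = Literal["matrisome", "striosome"]
Outcome = Literal["reward", "omission", "baseline"]


@dataclass
class RpeState:
    """Filtered dopaminergic activity and per-compartment RPE.

    ``q`` is the population-summed filtered rate in spikes/s; ``sigma``
    gains absorb population size (see :func:`sigma_for_population`).
    """

    tau_q: float = 100.0            # ms, volume-transmission time constant
    beta_dopa: float = 0.0          # spikes/s, negative of intact baseline q
    sigma_matrisome: float = 1.0    # 1/(spikes/s)
    sigma_striosome: float = 1.0
    lambda_matrisome: int = 7
    lambda_striosome: int = 2
    kappa_clamp: float = 2.0
    q: float = 0.0
    kappa_matrisome: float = 0.0
    kappa_striosome: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_q <= 0:
            raise ValueError("tau_q must be positive")
        if self.lambda_matrisome % 2 != 1:
            raise ValueError("matrisome exponent must be odd (sign-preserving)")
        if self.lambda_striosome % 2 != 0:
            raise ValueError("striosome exponent must be even (non-negative)")


@dataclass
class DopamineDrive:
    """External Poisson drive settings for the dopaminergic population.

    Rates are per-neuron drive rates (Hz) calibrated so that the
    free-running dopaminergic output is ~10 Hz at baseline, ~14 Hz on
    reward and ~6 Hz on reward omission.
    """

    baseline_rate: float
    reward_rate: float
    omission_rate: float

    def __post_init__(self) -> None:
        if not (self.omission_rate < self.baseline_rate < self.reward_rate):
            raise ValueError("drive rates must satisfy omission < baseline < reward")


def sigma_for_population(n_da: int, per_neuron_hz_span: float = 4.0,
                         gain: float = 1.0) -> float:
    """Gain such that a full burst/dip (+-``per_neuron_hz_span`` Hz per
    neuron across ``n_da`` neurons) maps to ``sigma * dq = gain``."""
    if n_da <= 0:
        raise ValueError("population size must be positive")
    return gain / (per_neuron_hz_span * n_da)


def update_q(state: RpeState, n_da_spikes_this_step: int, dt: float) -> RpeState:
    """Advance the volume-transmitter trace one step.

    q decays with time constant ``tau_q`` and jumps by ``1000 / tau_q``
    (1/tau_q in 1/ms, scaled to spikes/s) per dopaminergic spike, so the
    long-run mean of q equals the summed population spike rate.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_da_spikes_this_step < 0:
        raise ValueError("spike count must be non-negative")
    q = state.q * math.exp(-dt / state.tau_q)
    q += n_da_spikes_this_step * 1000.0 / state.tau_q
    return replace(state, q=q)


def signed_power(x: float, lam: int) -> float:
    """``x ** lam`` computed as sign-preserving magnitude power.

    Identical to the plain integer power (odd exponents keep the sign,
    even ones discard it); written explicitly to avoid overflow surprises
    with large bases.
    """
    mag = abs(x) ** lam
    if lam % 2 == 1 and x < 0:
        return -mag
    return mag


def compute_rpe(state: RpeState, compartment: Compartment) -> float:
    """Current learning signal kappa for a striatal compartment.

    ``kappa = (sigma * (beta_dopa + q)) ** lam`` with the compartment's
    gain and exponent; values beyond ``kappa_clamp`` in magnitude are
    clamped (with a debug log) to guard the high exponent.
    """
    if compartment == "matrisome":
        sigma, lam = state.sigma_matrisome, state.lambda_matrisome
    elif compartment == "striosome":
        sigma, lam = state.sigma_striosome, state.lambda_striosome
    else:
        raise ValueError(f"unknown compartment: {compartment!r}")
    kappa = signed_power(sigma * (state.beta_dopa + state.q), lam)
    if abs(kappa) > state.kappa_clamp:
        logger.debug("kappa %.3g clamped to +-%.3g", kappa, state.kappa_clamp)
        kappa = math.copysign(state.kappa_clamp, kappa)
    return kappa


def filter_q(spike_counts: np.ndarray, dt: float, tau_q: float,
             q0: float = 0.0) -> np.ndarray:
    """Vectorized trajectory of q given per-step population spike counts."""
    if dt <= 0 or tau_q <= 0:
        raise ValueError("dt and tau_q must be positive")
    counts = np.asarray(spike_counts, dtype=float)
    decay = math.exp(-dt / tau_q)
    jumps = counts * 1000.0 / tau_q
    # q[k] = decay * q[k-1] + jumps[k]  (scan via scipy-free recursion)
    q = np.empty_like(jumps)
    acc = q0
    for k in range(jumps.size):
        acc = acc * decay + jumps[k]
        q[k] = acc
    return q


def calibrate_baseline(network, duration: float = 5000.0, seed: int = 0,
                       dt: float | None = None, settle: float = 500.0) -> float:
    """Calibrate ``beta_dopa`` on the intact network.

    Simulates the dopaminergic population under its baseline drive with no
    striosomal input nor reward for ``duration`` ms, filters the summed
    spike train into q, and returns minus its time average (discarding the
    first ``settle`` ms).  The value is stored once per session and never
    recalibrated after dopaminergic deletion.
    """
    counts = network.simulate_dopamine_baseline(duration, seed=seed, dt=dt)
    if counts.sum() == 0:
        raise RuntimeError("no dopaminergic activity during the calibration window")
    dt_eff = dt if dt is not None else network.dt
    q = filter_q(counts, dt_eff, network.rpe_state.tau_q)
    skip = int(settle / dt_eff)
    return -float(q[skip:].mean())


def set_reward_drive(drive: DopamineDrive, outcome: Outcome) -> float:
    """Per-neuron external Poisson rate for a trial outcome."""
    if outcome == "reward":
        return drive.reward_rate
    if outcome == "omission":
        return drive.omission_rate
    if outcome == "baseline":
        return drive.baseline_rate
    raise ValueError(f"unknown outcome: {outcome!r}")
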