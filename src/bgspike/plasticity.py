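"""Spike-based BCPNN plasticity kernel.

The learning rule estimates, per synapse, the probabilities of pre-synaptic
activity, post-synaptic activity and their coincidence through a cascade of
three exponentially smoothed traces:

* ``Z`` — fast low-pass filters of the pre/post spike trains, scaled so that
  sustained firing at ``f_max`` corresponds to a trace value of 1 (absolute
  certainty) and silence decays to the floor ``eps`` (doubt).
* ``E`` — eligibility traces: low-pass filters of ``Z_i``, ``Z_j`` and of the
  product ``Z_i * Z_j`` (coincidence), with time constant ``tau_e``.
* ``P`` — probability estimates that relax toward their ``E`` trace at a rate
  proportional to the neuromodulatory learning signal ``kappa`` (the reward
  prediction error).  When ``kappa`` is zero the ``P`` traces — and hence the
  weights — are frozen.

The synaptic weight is the log-odds read-out ``w_ij = log(P_ij / (P_i P_j))``
and the intrinsic bias of the post-synaptic unit is ``beta_j = log(P_j)``.

Receptor classes gate the learning signal: D1 synapses learn only on positive
reward prediction error, D2 synapses only on negative (using its magnitude as
the rate), and the reward-prediction (RP) pathway receives an always
non-negative signal.

A spike is represented as a rectangular pulse of duration ``delta_t`` ms and
height ``1 / (f_max * delta_t)`` (with ``f_max`` converted to spikes/ms), so
each spike contributes a normalized unit of evidence and the time-averaged
``Z`` of a neuron firing at rate ``r`` approaches ``r / f_max + eps``.

All updates use the exponential-Euler closed form, which is exact for
piecewise-constant drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SpikeTrain",
    "PlasticityTraces",
    "BcpnnSynapse",
    "update_z_traces",
    "update_e_traces",
    "update_p_traces",
    "gate_kappa",
    "compute_weight_and_bias",
    "run_cascade",
    "P_FLOOR",
]

ReceptorClass = Literal["D1", "D2", "RP"]

#: Hard floor applied to P traces before taking logarithms.
P_FLOOR = 1e-6


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered spike train of a single source neuron.

    Attributes
    ----------
    source_id:
        Integer identifier of the emitting neuron.
    times:
        Strictly increasing spike times in ms, all non-negative.
    """

    source_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if times.size and times[0] < 0:
            raise ValueError("spike times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class PlasticityTraces:
    """State of the Z/E/P trace cascade for one synapse.

    Time constants are in ms, ``f_max`` in Hz; traces are unitless
    probability-scale quantities.
    """

    tau_zi: float = 10.0
    tau_zj: float = 10.0
    tau_e: float = 100.0
    tau_p: float = 1000.0
    f_max: float = 30.0
    eps: float = 0.01
    delta_t: float = 1.0  # spike pulse duration, ms

    z_i: float = 0.01
    z_j: float = 0.01
    e_i: float = 0.01
    e_j: float = 0.01
    e_ij: float = 0.0001
    p_i: float = 0.01
    p_j: float = 0.01
    p_ij: float = 0.0001

    def __post_init__(self) -> None:
        if self.tau_zi <= 0 or self.tau_zj <= 0:
            raise ValueError("Z time constants must be positive")
        if self.tau_e <= 0:
            raise ValueError("tau_e must be positive")
        if self.tau_p <= 0:
            raise ValueError("tau_p must be positive")
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")

    @property
    def pulse_height(self) -> float:
        """Drive amplitude of a spike pulse: 1 / (f_max * delta_t)."""
        return 1000.0 / (self.f_max * self.delta_t)


@dataclass
class BcpnnSynapse:
    """A plastic synapse with BCPNN traces and receptor-typed gating."""

    pre_id: int
    post_id: int
    traces: PlasticityTraces = field(default_factory=PlasticityTraces)
    receptor_class: ReceptorClass = "D1"
    sign_convention: Literal["normal", "inverted"] = "normal"
    lower_bound: Optional[float] = None
    w_ij: float = 0.0

    def refresh_weight(self) -> Tuple[float, float]:
        """Recompute ``w_ij``/``beta_j`` from the current traces."""
        w, beta = compute_weight_and_bias(self.traces, lower_bound=self.lower_bound)
        self.w_ij = w
        return w, beta


def update_z_traces(
    traces: PlasticityTraces,
    pre_spiking: bool,
    post_spiking: bool,
    dt: float,
) -> PlasticityTraces:
    """Advance the Z traces one step of ``dt`` ms.

    ``pre_spiking``/``post_spiking`` flag whether the neuron is inside a
    spike pulse (of duration ``delta_t``) during this step.  The update is
    the exponential-Euler closed form of
    ``tau_z dZ/dt = s(t) - Z + eps`` where ``s`` is the pulse drive.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > traces.delta_t + 1e-12:
        raise ValueError("dt must not exceed the spike pulse duration delta_t")
    h = traces.pulse_height
    s_i = h if pre_spiking else 0.0
    s_j = h if post_spiking else 0.0
    ai = math.exp(-dt / traces.tau_zi)
    aj = math.exp(-dt / traces.tau_zj)
    z_i = (s_i + traces.eps) + (traces.z_i - (s_i + traces.eps)) * ai
    z_j = (s_j + traces.eps) + (traces.z_j - (s_j + traces.eps)) * aj
    return replace(traces, z_i=z_i, z_j=z_j)


def update_e_traces(traces: PlasticityTraces, dt: float) -> PlasticityTraces:
    """Advance the eligibility traces: low-pass of Z_i, Z_j and Z_i*Z_j."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = math.exp(-dt / traces.tau_e)
    e_i = traces.z_i + (traces.e_i - traces.z_i) * a
    e_j = traces.z_j + (traces.e_j - traces.z_j) * a
    zij = traces.z_i * traces.z_j
    e_ij = zij + (traces.e_ij - zij) * a
    return replace(traces, e_i=e_i, e_j=e_j, e_ij=e_ij)


def update_p_traces(
    traces: PlasticityTraces, kappa_eff: float, dt: float
) -> PlasticityTraces:
    """Relax P traces toward their E traces at rate ``kappa_eff / tau_p``.

    ``kappa_eff`` must already be gated (non-negative); zero leaves the P
    traces bit-identical.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if kappa_eff < 0:
        raise ValueError("kappa_eff must be gated non-negative before the P update")
    if kappa_eff == 0.0:
        return traces
    a = math.exp(-kappa_eff * dt / traces.tau_p)
    p_i = traces.e_i + (traces.p_i - traces.e_i) * a
    p_j = traces.e_j + (traces.p_j - traces.e_j) * a
    p_ij = traces.e_ij + (traces.p_ij - traces.e_ij) * a
    return replace(traces, p_i=p_i, p_j=p_j, p_ij=p_ij)


def gate_kappa(kappa_raw: float, receptor_class: ReceptorClass) -> float:
    """Receptor-typed gating of the signed learning signal.

    D1 synapses learn only on positive reward prediction error; D2 synapses
    only on negative, using its magnitude as the learning rate; the RP
    pathway's signal is already non-negative (even exponent) and passes
    through.
    """
    if receptor_class == "D1":
        return kappa_raw if kappa_raw > 0 else 0.0
    if receptor_class == "D2":
        return -kappa_raw if kappa_raw < 0 else 0.0
    if receptor_class == "RP":
        if kappa_raw < 0:
            raise ValueError("RP learning signal must be non-negative")
        return kappa_raw
    raise ValueError(f"unknown receptor class: {receptor_class!r}")


def compute_weight_and_bias(
    traces: PlasticityTraces, lower_bound: Optional[float] = None
) -> Tuple[float, float]:
    """Log-odds weight and log-probability bias read-out.

    ``w_ij = log(P_ij / (P_i P_j))``; ``beta_j = log(P_j)``.  P traces are
    floored at ``P_FLOOR`` before the logarithms; an optional lower bound
    clamps the weight afterwards (cortico-matrisomal synapses use 0).
    """
    for name, value in (("p_i", traces.p_i), ("p_j", traces.p_j), ("p_ij", traces.p_ij)):
        if value <= 0:
            raise ValueError(f"P trace {name} must be positive (got {value})")
    p_i = max(traces.p_i, P_FLOOR)
    p_j = max(traces.p_j, P_FLOOR)
    p_ij = max(traces.p_ij, P_FLOOR)
    w = math.log(p_ij / (p_i * p_j))
    if lower_bound is not None:
        w = max(w, lower_bound)
    beta = math.log(p_j)
    return w, beta


def run_cascade(
    pre_train: SpikeTrain | Sequence[float],
    post_train: SpikeTrain | Sequence[float],
    duration: float,
    dt: float,
    kappa: float | Sequence[float] = 0.0,
    receptor_class: ReceptorClass = "D1",
    traces: Optional[PlasticityTraces] = None,
    lower_bound: Optional[float] = None,
    record_every: int = 1,
) -> dict:
    """Integrate the full trace cascade over scripted spike trains.

    Reference integrator used by the kernel test harness and as the oracle
    for the accelerated network engine.  ``kappa`` may be a scalar or a
    per-step array of the *raw* signed learning signal; gating by
    ``receptor_class`` is applied here.

    Returns a dict of trajectories sampled every ``record_every`` steps,
    including times, all traces, the weight and the bias.
    """
    if traces is None:
        traces = PlasticityTraces()
    pre_times = pre_train.times if isinstance(pre_train, SpikeTrain) else np.asarray(pre_train, float)
    post_times = post_train.times if isinstance(post_train, SpikeTrain) else np.asarray(post_train, float)
    n_steps = int(round(duration / dt))
    kappa_arr = np.broadcast_to(np.asarray(kappa, float), (n_steps,))

    # pulse bookkeeping: a spike is snapped to the step grid and drives the
    # Z trace for exactly round(delta_t / dt) steps, so every spike carries
    # the same integrated evidence regardless of grid alignment
    pulse_steps = max(int(round(traces.delta_t / dt)), 1)

    def pulse_mask(times: np.ndarray) -> np.ndarray:
        mask = np.zeros(n_steps, dtype=bool)
        for t in times:
            k0 = int(round(t / dt))
            mask[max(k0, 0) : min(k0 + pulse_steps, n_steps)] = True
        return mask

    pre_mask = pulse_mask(pre_times)
    post_mask = pulse_mask(post_times)

    out: dict = {k: [] for k in
                 ("t", "z_i", "z_j", "e_i", "e_j", "e_ij", "p_i", "p_j", "p_ij", "w", "beta")}
    for k in range(n_steps):
        traces = update_z_traces(traces, bool(pre_mask[k]), bool(post_mask[k]), dt)
        traces = update_e_traces(traces, dt)
        traces = update_p_traces(traces, gate_kappa(kappa_arr[k], receptor_class), dt)
        if (k + 1) % record_every == 0:
            w, beta = compute_weight_and_bias(traces, lower_bound=lower_bound)
            out["t"].append((k + 1) * dt)
            for name, val in (
                ("z_i", traces.z_i), ("z_j", traces.z_j),
                ("e_i", traces.e_i), ("e_j", traces.e_j), ("e_ij", traces.e_ij),
                ("p_i", traces.p_i), ("p_j", traces.p_j), ("p_ij", traces.p_ij),
                ("w", w), ("beta", beta),
            ):
                out[name].append(val)
    return {k: np.asarray(v) for k, v in out.items()}
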