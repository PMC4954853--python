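"""Leaky integrate-and-fire neurons with alpha-function conductance synapses.

Membrane equation (units: mV, ms, pF, nS, pA):

    C_m dV/dt = -g_L (V - E_L) - g_ex (V - E_ex) - g_inh (V - E_inh) + phi * beta_j

``beta_j`` is the BCPNN bias (a log-probability, <= 0 for sub-certain
activity), scaled by ``phi`` into an intrinsic hyperpolarizing current: a
more negative bias never increases the firing rate.  On threshold crossing
the neuron spikes, resets to ``V_res`` and is clamped there for the absolute
refractory period ``t_ref``.

Each synaptic event injects an alpha-shaped conductance transient

    g(t) = g_max * w * (t / tau) * exp(1 - t / tau)

that peaks at ``g_max * w`` one time constant after arrival.  The kernel is
realized as two coupled first-order states (y, g) advanced with the exact
discrete propagator, so superposition of events is exact.

This module is the plain reference implementation used by the kernel tests
and calibration oracles; the network engine integrates the same dynamics in
vectorized form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "HeterogeneitySpreads",
    "step_membrane",
    "deliver_spike",
    "sample_heterogeneous_params",
    "simulate_neuron",
]


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical parameters of one LIF neuron."""

    c_m: float = 250.0      # pF
    g_l: float = 16.7       # nS
    e_l: float = -70.0      # mV
    e_ex: float = 0.0       # mV
    e_inh: float = -80.0    # mV
    v_th: float = -55.0     # mV
    v_res: float = -70.0    # mV
    t_ref: float = 2.0      # ms
    tau_ex: float = 3.0     # ms
    tau_inh: float = 3.0    # ms
    g_max: float = 1.0      # nS, peak conductance scale per unit weight
    phi: float = 10.0       # pA per log-unit of bias

    def __post_init__(self) -> None:
        if self.v_res >= self.v_th:
            raise ValueError("V_res must be below V_th")
        if not (self.e_inh <= self.e_l < self.v_th < self.e_ex):
            raise ValueError("require E_inh <= E_L < V_th < E_ex")
        for name in ("c_m", "g_l", "tau_ex", "tau_inh", "t_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NeuronState:
    """Dynamic state of one LIF neuron (membrane + two alpha channels)."""

    v_m: float = -70.0
    refractory_remaining: float = 0.0
    beta_j: float = 0.0
    g_ex: float = 0.0
    y_ex: float = 0.0
    g_inh: float = 0.0
    y_inh: float = 0.0


@dataclass(frozen=True)
class HeterogeneitySpreads:
    """Gaussian SDs for per-neuron parameter sampling (mV / ms units)."""

    v_th: float = 0.5
    v_res: float = 0.5
    v_init: float = 2.0
    weight_frac: float = 0.1   # relative SD on static weights
    delay: float = 0.1         # ms, SD on transmission delays

    def __post_init__(self) -> None:
        for name in ("v_th", "v_res", "v_init", "weight_frac", "delay"):
            if getattr(self, name) < 0:
                raise ValueError(f"spread {name} must be non-negative")


def step_membrane(
    state: NeuronState, params: NeuronParams, dt: float
) -> Tuple[NeuronState, bool]:
    """Advance one step of ``dt`` ms; returns (new state, spiked).

    Conductances follow the exact alpha propagator; the membrane uses
    exponential Euler with start-of-step conductances (exact for constant
    conductance, which makes RC-decay tests closed-form).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    ax = math.exp(-dt / params.tau_ex)
    ai = math.exp(-dt / params.tau_inh)
    g_ex = ax * (state.g_ex + dt * state.y_ex)
    y_ex = ax * state.y_ex
    g_inh = ai * (state.g_inh + dt * state.y_inh)
    y_inh = ai * state.y_inh

    spiked = False
    if state.refractory_remaining > 1e-12:
        v = params.v_res
        refr = max(state.refractory_remaining - dt, 0.0)
    else:
        g_tot = params.g_l + state.g_ex + state.g_inh
        i_ss = (
            params.g_l * params.e_l
            + state.g_ex * params.e_ex
            + state.g_inh * params.e_inh
            + params.phi * state.beta_j
        )
        v_inf = i_ss / g_tot
        v = v_inf + (state.v_m - v_inf) * math.exp(-dt * g_tot / params.c_m)
        refr = 0.0
        if not math.isfinite(v):
            raise FloatingPointError("membrane potential diverged")
        if v >= params.v_th:
            spiked = True
            v = params.v_res
            refr = params.t_ref

    new_state = replace(
        state, v_m=v, refractory_remaining=refr,
        g_ex=g_ex, y_ex=y_ex, g_inh=g_inh, y_inh=y_inh,
    )
    return new_state, spiked


def deliver_spike(
    state: NeuronState,
    weight: float,
    params: NeuronParams,
    sign_convention: Literal["normal", "inverted"] = "normal",
) -> NeuronState:
    """Register an arriving synaptic event (already delayed by the caller).

    Injects an impulse so the conductance peaks at ``g_max * |w|`` one tau
    after arrival.  Routing: under the normal convention positive weights
    excite and negative weights inhibit; the inverted convention (used by
    the striosome-to-dopamine pathway) swaps the channels so positive
    learned weights inhibit their targets.
    """
    excitatory = weight > 0
    if sign_convention == "inverted":
        excitatory = not excitatory
    elif sign_convention != "normal":
        raise ValueError(f"unknown sign convention: {sign_convention!r}")
    if weight == 0:
        return state
    mag = abs(weight) * params.g_max
    if excitatory:
        return replace(state, y_ex=state.y_ex + mag * math.e / params.tau_ex)
    return replace(state, y_inh=state.y_inh + mag * math.e / params.tau_inh)


def sample_heterogeneous_params(
    base: NeuronParams,
    spreads: HeterogeneitySpreads,
    n: int,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Draw per-neuron thresholds, resets and initial potentials.

    Returns arrays ``v_th``, ``v_res``, ``v_init`` of length ``n``.
    Draws with ``v_res >= v_th`` are rejected and resampled (error after
    100 attempts per neuron).  Identical seeds give identical draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v_th = np.empty(n)
    v_res = np.empty(n)
    for i in range(n):
        for attempt in range(100):
            th = rng.normal(base.v_th, spreads.v_th)
            res = rng.normal(base.v_res, spreads.v_res)
            if res < th:
                v_th[i] = th
                v_res[i] = res
                break
        else:
            raise RuntimeError("could not sample V_res < V_th in 100 attempts")
    v_init = rng.normal(base.e_l, spreads.v_init, size=n)
    return {"v_th": v_th, "v_res": v_res, "v_init": np.minimum(v_init, v_th - 0.1)}


def simulate_neuron(
    params: NeuronParams,
    duration: float,
    dt: float,
    exc_events: dict[float, float] | None = None,
    inh_events: dict[float, float] | None = None,
    beta_j: float = 0.0,
    v_init: float | None = None,
) -> dict:
    """Integrate a single neuron against scripted synaptic event times.

    ``exc_events``/``inh_events`` map event time (ms) to weight.  Returns
    trajectories of V, g_ex, g_inh and the emitted spike times.
    """
    state = NeuronState(v_m=params.e_l if v_init is None else v_init, beta_j=beta_j)
    n_steps = int(round(duration / dt))
    exc_events = exc_events or {}
    inh_events = inh_events or {}
    exc_steps = {int(round(t / dt)): w for t, w in exc_events.items()}
    inh_steps = {int(round(t / dt)): w for t, w in inh_events.items()}
    t_out = np.arange(1, n_steps + 1) * dt
    v = np.empty(n_steps)
    g_ex = np.empty(n_steps)
    g_inh = np.empty(n_steps)
    spikes = []
    for k in range(n_steps):
        if k in exc_steps:
            state = deliver_spike(state, exc_steps[k], params)
        if k in inh_steps:
            state = deliver_spike(state, -abs(inh_steps[k]), params)
        state, spiked = step_membrane(state, params, dt)
        if spiked:
            spikes.append((k + 1) * dt)
        v[k] = state.v_m
        g_ex[k] = state.g_ex
        g_inh[k] = state.g_inh
    return {"t": t_out, "v": v, "g_ex": g_ex, "g_inh": g_inh,
            "spikes": np.asarray(spikes)}
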