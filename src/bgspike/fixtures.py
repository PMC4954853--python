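"""Scripted protocols and reduced-scale presets for deterministic testing.

Spike-train fixtures use a plain-text two-column format (neuron_id,
time_ms); protocols pair scripted schedules with analytic expectations so
the plasticity and neuron kernels can be validated against closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional

import numpy as np

from .network import NetworkConfig, NetworkModel, build_network

__all__ = [
    "ScriptedProtocol",
    "save_spike_trains",
    "load_spike_trains",
    "make_kernel_protocols",
    "make_mini_network",
]


@dataclass
class ScriptedProtocol:
    """A deterministic kernel-test scenario.

    ``schedules`` maps source names (``pre``, ``post``, ``dopamine`` ...)
    to spike-time arrays (ms); ``kappa`` is the raw learning signal
    (scalar or per-step); ``expected`` holds named analytic expectations
    (closed-form trajectories or scalar targets) with ``tolerance``.
    """

    name: str
    duration: float
    dt: float
    schedules: Dict[str, np.ndarray]
    kappa: float | np.ndarray = 0.0
    receptor_class: str = "D1"
    expected: Dict[str, object] = field(default_factory=dict)
    tolerance: float = 1e-6
    description: str = ""


def save_spike_trains(path, trains: Dict[int, np.ndarray]) -> None:
    """Write spike trains as two-column text (neuron_id, time_ms)."""
    rows = []
    for nid, times in sorted(trains.items()):
        for t in np.asarray(times, float):
            rows.append((nid, t))
    rows.sort(key=lambda r: (r[1], r[0]))
    with open(path, "w") as fh:
        fh.write("# neuron_id time_ms\n")
        for nid, t in rows:
            fh.write(f"{nid} {t:.6f}\n")


def load_spike_trains(path) -> Dict[int, np.ndarray]:
    """Read the two-column text raster back into per-neuron time arrays."""
    trains: Dict[int, list] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        nid_s, t_s = line.split()
        trains.setdefault(int(nid_s), []).append(float(t_s))
    return {nid: np.asarray(sorted(ts)) for nid, ts in trains.items()}


def regular_train(rate_hz: float, duration: float, t0: float = 0.0) -> np.ndarray:
    period = 1000.0 / rate_hz
    return np.arange(t0, duration, period)


def make_kernel_protocols(dt: float = 0.1) -> List[ScriptedProtocol]:
    """Deterministic protocols covering the plasticity/neuron kernels:

    silent decay, saturation at ``f_max``, correlated vs independent
    pre/post pairs, learning-signal gating by receptor class, the
    inverted-sign reward-prediction pathway, and alpha-kernel peak timing.
    """
    dur = 2000.0
    protos = [
        ScriptedProtocol(
            name="silent-decay",
            duration=dur, dt=dt,
            schedules={"pre": np.empty(0), "post": np.empty(0)},
            kappa=0.0,
            expected={"z_i": lambda t, tr: tr.eps + (1.0 - tr.eps)
                      * np.exp(-t / tr.tau_zi)},
            description="no input: Z decays from 1 toward eps with tau_z",
        ),
        ScriptedProtocol(
            name="fmax-saturation",
            duration=20000.0, dt=dt,
            schedules={"pre": regular_train(30.0, 20000.0),
                       "post": np.empty(0)},
            kappa=0.0,
            expected={"z_i_mean": 1.01},  # r / f_max + eps at r = f_max
            tolerance=0.05,
            description="sustained firing at f_max drives mean Z to ~1 + eps",
        ),
        ScriptedProtocol(
            name="correlated-pair",
            duration=10000.0, dt=dt,
            schedules={"pre": regular_train(15.0, 10000.0),
                       "post": regular_train(15.0, 10000.0)},
            kappa=1.0,
            expected={"w_sign": 1.0},
            description="synchronous pre/post at kappa>0 drives w positive",
        ),
        ScriptedProtocol(
            name="anti-phase",
            duration=20000.0, dt=dt,
            schedules={
                "pre": np.array([t for t in regular_train(30.0, 20000.0)
                                 if (t % 1000.0) < 500.0]),
                "post": np.array([t for t in regular_train(30.0, 20000.0)
                                  if (t % 1000.0) >= 500.0]),
            },
            kappa=1.0,
            expected={"w_sign": -1.0},
            description="anti-correlated pre/post firing at kappa>0 drives "
                        "w negative",
        ),
        ScriptedProtocol(
            name="kappa-freeze",
            duration=5000.0, dt=dt,
            schedules={"pre": regular_train(20.0, 5000.0),
                       "post": regular_train(20.0, 5000.0, t0=5.0)},
            kappa=0.0,
            expected={"p_frozen": True},
            description="zero learning signal leaves P traces bit-identical",
        ),
        ScriptedProtocol(
            name="da-burst",
            duration=400.0, dt=dt,
            schedules={"dopamine": regular_train(1400.0, 400.0)},
            kappa=0.0,
            expected={"kappa_matrisome_sign": 1.0},
            description="dopaminergic burst above baseline gives positive "
                        "matrisomal RPE throughout the burst window",
        ),
        ScriptedProtocol(
            name="alpha-peak",
            duration=20.0, dt=dt,
            schedules={"exc_event": np.array([2.0])},
            expected={"g_peak_time": 2.0 + 3.0, "g_peak": 1.0},
            tolerance=1e-3,
            description="a unit-weight event peaks at g_max one tau after "
                        "arrival",
        ),
    ]
    return protos


def make_mini_network(seed: int = 0,
                      config: Optional[NetworkConfig] = None) -> NetworkModel:
    """2-state / 2-action miniature network with the full topology rules.

    Small enough that a two-block session runs in seconds; used for
    integration tests of the selection/learning loop and the qualitative
    lesion signatures.
    """
    return build_network(config or NetworkConfig.mini(), seed=seed)
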