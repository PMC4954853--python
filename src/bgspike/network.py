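"""Construction of the basal-ganglia network model.

Architecture (states ``i``, actions ``j``):

* state-coding input populations — Poisson generators at 30 Hz when the
  state is active, 3 Hz background otherwise;
* matrisomal MSN populations, one D1 and one D2 per action, receiving
  plastic full connectivity from every state neuron (receptor-gated BCPNN,
  weights bounded below by 0);
* striosomal subpopulations, one per (state, action) pair, receiving static
  input from their state's neurons and from the efference-copy source of
  their action (the latter delayed by the efference-phase duration); either
  input alone is subthreshold, their conjunction drives ~15 Hz;
* GPi/SNr output populations, one per action, driven by background Poisson
  to ~35 Hz; D1 matrisomes inhibit and D2 matrisomes excite their action's
  output population; matrisomes laterally inhibit same-receptor rivals;
* dopaminergic neurons driven by external Poisson (baseline ~10 Hz, reward
  ~14 Hz, omission ~6 Hz) and by the plastic, sign-inverted
  striosome-to-dopamine (RP) projection.

Static synaptic strengths that realize the target population rates are
*calibrated*, not hand-set: bisection against a compiled LIF-pool oracle
finds background drive rates and synaptic peak conductances reproducing the
stated operating points for the configured neuron model, time step and
population sizes.  Calibrations are cached per parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from . import engine
from .dopamine import DopamineDrive, RpeState, sigma_for_population
from .neurons import HeterogeneitySpreads, NeuronParams, sample_heterogeneous_params
from .plasticity import PlasticityTraces

__all__ = [
    "NetworkConfig",
    "PopulationSpec",
    "LesionSpec",
    "NetworkModel",
    "PhaseResult",
    "build_network",
    "apply_lesion",
    "delete_dopamine_neurons",
    "LESION_CONDITIONS",
    "PD_PRESETS",
]

LESION_CONDITIONS = ("intact", "noD1", "noD2", "noRP", "noEfference", "noSF", "noLI")
PD_PRESETS = {"PD16": 0.16, "PD33": 0.33, "PD66": 0.66}


@dataclass(frozen=True)
class LesionSpec:
    """A lesion/degeneration condition.

    ``condition`` silences a pathway's *output* (the population itself stays
    active); ``pd_fraction`` deletes that fraction of dopaminergic neurons
    (incoming and outgoing connections removed) at the start of block
    ``pd_onset_block``.
    """

    condition: str = "intact"
    pd_fraction: float = 0.0
    pd_onset_block: int = 8

    def __post_init__(self) -> None:
        if self.condition not in LESION_CONDITIONS:
            raise ValueError(f"unknown lesion condition: {self.condition!r}")
        if not (0.0 <= self.pd_fraction < 1.0):
            raise ValueError("pd_fraction must lie in [0, 1)")

    @classmethod
    def from_name(cls, name: str, pd_onset_block: int = 8) -> "LesionSpec":
        if name in PD_PRESETS:
            return cls("intact", PD_PRESETS[name], pd_onset_block)
        return cls(name)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    role: str
    coding: tuple
    size: int


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, rates and kernel parameters of the model.

    Defaults give the standard 3-state / 3-action network: 120 state
    neurons, 180 matrisomal and 180 striosomal MSNs, 120 output neurons and
    125 dopaminergic neurons (725 total, ~70,000 synapses).
    ``desk_scale()`` returns a reduced network with identical topology used
    for session-level experiments.
    """

    n_states: int = 3
    n_actions: int = 3
    n_sn_per_state: int = 40
    n_msn_size: int = 30
    n_str_size: int = 20
    n_out_size: int = 40
    n_da: int = 125

    dt: float = 0.1  # ms

    # source rates (Hz)
    state_active_hz: float = 30.0
    state_background_hz: float = 3.0
    eff_active_hz: float = 300.0
    eff_background_hz: float = 3.0

    # operating points realized by calibration
    output_baseline_hz: float = 35.0
    da_baseline_hz: float = 10.0
    da_reward_hz: float = 14.0
    da_omission_hz: float = 6.0
    striosome_gated_hz: float = 15.0
    msn_efference_hz: float = 25.0
    msn_selection_hz: float = 8.0
    msn_spontaneous_hz: float = 0.75
    output_suppressed_hz: float = 12.0
    output_excited_hz: float = 80.0

    neuron: NeuronParams = field(default_factory=NeuronParams)
    spreads: HeterogeneitySpreads = field(default_factory=HeterogeneitySpreads)
    traces: PlasticityTraces = field(default_factory=PlasticityTraces)

    tau_q: float = 100.0
    gain_matrisome: float = 1.2     # sigma_dopa * (full burst deviation)
    gain_striosome: float = 0.4
    lambda_matrisome: int = 7
    lambda_striosome: int = 2
    kappa_clamp: float = 3.0
    kappa_min: float = 1e-7

    # reference learned weights used when calibrating conductance scales
    w_ref_cortical: float = 1.0
    w_ref_cortical_d2: float = 0.6
    w_ref_rp: float = 0.4
    lateral_suppressed_hz: float = 2.0  # rival-matrisome rate under lateral inhibition
    lateral_rival_w: float = 1.0        # rival weight assumed when calibrating laterals
    bg_weight_ns: float = 1.0       # nS per background Poisson event

    init_p_marginal: float = 0.2
    init_w_sd: float = 0.1

    delay_mean_ms: float = 1.0
    delay_sd_ms: float = 0.1
    eff_striosome_delay_ms: float = 300.0  # locked to the efference phase

    @property
    def n_state_neurons(self) -> int:
        return self.n_states * self.n_sn_per_state

    @property
    def n_msn_tot(self) -> int:
        return 2 * self.n_actions * self.n_msn_size

    @property
    def n_str_tot(self) -> int:
        return self.n_states * self.n_actions * self.n_str_size

    @property
    def n_out_tot(self) -> int:
        return self.n_actions * self.n_out_size

    @property
    def n_lif(self) -> int:
        return self.n_msn_tot + self.n_str_tot + self.n_out_tot + self.n_da

    @property
    def total_neurons(self) -> int:
        """All neurons including the Poisson state-coding layer."""
        return self.n_state_neurons + self.n_lif

    @property
    def total_synapses(self) -> int:
        c = self.n_state_neurons * self.n_msn_tot          # plastic cortico-striatal
        c += self.n_str_tot * self.n_da                    # plastic RP
        c += self.n_sn_per_state * self.n_str_tot          # state -> striosome
        c += self.n_actions * 2 * self.n_msn_size          # efference -> matrisome
        c += self.n_actions * self.n_states * self.n_str_size  # efference -> striosome
        c += 2 * self.n_actions * self.n_msn_size * self.n_out_size  # D1/D2 -> output
        c += 2 * self.n_actions * self.n_msn_size * (self.n_actions - 1) * self.n_msn_size  # lateral
        c += self.n_lif                                    # background drive
        return c

    @classmethod
    def desk_scale(cls, **overrides) -> "NetworkConfig":
        """Reduced network for session-scale experiments (same topology)."""
        kw = dict(
            n_sn_per_state=16, n_msn_size=12, n_str_size=8, n_out_size=16,
            n_da=50, dt=0.5,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def mini(cls, **overrides) -> "NetworkConfig":
        """2-state / 2-action miniature for fast integration tests."""
        kw = dict(
            n_states=2, n_actions=2, n_sn_per_state=10, n_msn_size=8,
            n_str_size=6, n_out_size=10, n_da=24, dt=0.5,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PhaseResult:
    """Outputs of one engine call."""

    duration: float
    action_counts: np.ndarray
    pop_counts: np.ndarray            # [D1, D2, striosome, output, DA] spikes
    striosome_sub_counts: np.ndarray  # per (state, action) subpopulation
    kappa_matrisome: np.ndarray       # per step
    kappa_striosome: np.ndarray
    q: np.ndarray
    weight_samples: np.ndarray        # [n_samples, 3] mean w (D1, D2, RP)
    weight_sample_times: np.ndarray   # ms, absolute
    rp_pair_samples: np.ndarray       # [n_samples, n_states*n_actions]
    spikes: Optional[tuple] = None    # (neuron_id, time_ms) arrays


# --------------------------------------------------------------------------
# calibration oracles
# --------------------------------------------------------------------------

_CAL_CACHE: dict = {}


def _inc(peak_ns: float, tau_syn: float) -> float:
    """Convert an alpha-kernel peak conductance (nS) to a y-impulse."""
    return peak_ns * math.e / tau_syn


def _pool_rate_simple(cfg, bg_rate, bg_peak, src_rates, src_peaks, seed=12345,
                      n=40, duration=4000.0, settle=300.0, bias_pa=0.0):
    """Mean single-neuron rate (Hz) of a calibration pool."""
    p = cfg.neuron
    n_steps = int(round(duration / cfg.dt))
    settle_steps = int(round(settle / cfg.dt))
    src_peaks = np.asarray(src_peaks, float)
    incs = np.sign(src_peaks) * _inc(1.0, p.tau_ex) * np.abs(src_peaks)
    count = engine.sim_pool(
        seed, n, n_steps, cfg.dt,
        p.c_m, p.g_l, p.e_l, p.e_ex, p.e_inh, p.v_th, p.v_res,
        int(round(p.t_ref / cfg.dt)), p.tau_ex, bias_pa,
        bg_rate, _inc(bg_peak, p.tau_ex),
        np.asarray(src_rates, float), incs, settle_steps,
    )
    return count / n / ((duration - settle) * 1e-3)


def _bisect_monotone(f, target: float, lo: float, hi: float, iters: int = 22) -> float:
    """Root of ``f(x) = target`` for non-decreasing stochastic ``f``."""
    f_hi = f(hi)
    expand = 0
    while f_hi < target and expand < 12:
        lo, hi = hi, hi * 2.0
        f_hi = f(hi)
        expand += 1
    if f_hi < target:
        raise RuntimeError("calibration target unreachable within bracket")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_operating_points(cfg: NetworkConfig) -> dict:
    """Solve for drive rates and synaptic peaks hitting the configured
    population operating points.  Results are cached per parameter set.

    Returns a dict with keys: ``bg_rate_output``, ``da_drive``
    (:class:`DopamineDrive`), ``w_state_striosome``, ``w_eff_striosome``,
    ``w_eff_msn``, ``gmax_cortical``, ``w_d1_output``, ``w_d2_output``,
    ``gmax_rp``.
    """
    key = (
        cfg.dt, cfg.neuron, cfg.n_sn_per_state, cfg.n_msn_size, cfg.n_str_size,
        cfg.state_active_hz, cfg.eff_active_hz, cfg.output_baseline_hz,
        cfg.da_baseline_hz, cfg.da_reward_hz, cfg.da_omission_hz,
        cfg.striosome_gated_hz, cfg.msn_efference_hz, cfg.msn_selection_hz,
        cfg.msn_spontaneous_hz, cfg.w_ref_cortical,
        cfg.w_ref_cortical_d2,
        cfg.w_ref_rp, cfg.bg_weight_ns, cfg.output_suppressed_hz,
        cfg.output_excited_hz, cfg.lateral_suppressed_hz, cfg.lateral_rival_w,
    )
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]

    empty = np.zeros(0)

    def bg_for(target_hz):
        return _bisect_monotone(
            lambda r: _pool_rate_simple(cfg, r, cfg.bg_weight_ns, empty, empty),
            target_hz, 0.0, 2000.0,
        )

    bg_out = bg_for(cfg.output_baseline_hz)
    bg_msn = bg_for(cfg.msn_spontaneous_hz)
    da_base = bg_for(cfg.da_baseline_hz)
    da_rew = bg_for(cfg.da_reward_hz)
    da_omi = bg_for(cfg.da_omission_hz)
    da_drive = DopamineDrive(da_base, da_rew, da_omi)

    # striosome gating: state (n_sn_per_state sources @ 30 Hz) and efference
    # (1 source @ eff rate) contribute equal mean conductance; a common
    # scale is bisected so the conjunction fires at the gated rate.
    n_ss = cfg.n_sn_per_state
    state_total = n_ss * cfg.state_active_hz
    ratio = state_total / cfg.eff_active_hz

    def gated_rate(scale):
        rates = np.concatenate([
            np.full(n_ss, cfg.state_active_hz), [cfg.eff_active_hz]])
        peaks = np.concatenate([np.full(n_ss, scale), [scale * ratio]])
        return _pool_rate_simple(cfg, 0.0, 0.0, rates, peaks)

    w_ss = _bisect_monotone(gated_rate, cfg.striosome_gated_hz, 0.0, 0.5)
    w_es = w_ss * ratio

    # efference -> matrisome: single high-rate source driving MSNs
    def eff_rate_fn(w):
        return _pool_rate_simple(
            cfg, bg_msn, cfg.bg_weight_ns,
            np.array([cfg.eff_active_hz]), np.array([w]))

    w_em = _bisect_monotone(eff_rate_fn, cfg.msn_efference_hz, 0.0, 1.0)

    # plastic cortical conductance scale: a fully learned state (all its
    # neurons at 30 Hz, weight w_ref) drives an MSN at the modest selection
    # rate; the efference copy, not the state input, dominates matrisome
    # firing during the learning phase
    def cort_rate_fn(gmax):
        rates = np.full(n_ss, cfg.state_active_hz)
        peaks = np.full(n_ss, gmax * cfg.w_ref_cortical)
        return _pool_rate_simple(cfg, bg_msn, cfg.bg_weight_ns, rates, peaks)

    gmax_c = _bisect_monotone(cort_rate_fn, cfg.msn_selection_hz, 0.0, 1.0)

    def cort_rate_fn_d2(gmax):
        rates = np.full(n_ss, cfg.state_active_hz)
        peaks = np.full(n_ss, gmax * cfg.w_ref_cortical_d2)
        return _pool_rate_simple(cfg, bg_msn, cfg.bg_weight_ns, rates, peaks)

    gmax_c_d2 = _bisect_monotone(cort_rate_fn_d2, cfg.msn_selection_hz, 0.0, 2.0)

    # D1 -> output inhibition: an active matrisome at its selection-phase
    # rate pulls the background-driven output population down to the
    # suppressed point; D2 -> output excitation pushes it up to the excited
    # point.
    msn_rates = np.full(cfg.n_msn_size, cfg.msn_selection_hz)

    def d1_fn(w):
        return -_pool_rate_simple(cfg, bg_out, cfg.bg_weight_ns,
                                  msn_rates, np.full(cfg.n_msn_size, -w))

    w_d1o = _bisect_monotone(d1_fn, -cfg.output_suppressed_hz, 0.0, 2.0)

    def d2_fn(w):
        return _pool_rate_simple(cfg, bg_out, cfg.bg_weight_ns,
                                 msn_rates, np.full(cfg.n_msn_size, w))

    w_d2o = _bisect_monotone(d2_fn, cfg.output_excited_hz, 0.0, 2.0)

    # lateral inhibition: a rival matrisome driven at a learned-weight
    # operating point is pushed down to the suppressed rate by the selected
    # matrisome firing at the efference rate
    half_state = np.full(n_ss, cfg.state_active_hz)

    def lat_fn(w):
        rates = np.concatenate([half_state, np.full(cfg.n_msn_size, cfg.msn_efference_hz)])
        peaks = np.concatenate([
            np.full(n_ss, gmax_c_d2 * cfg.lateral_rival_w),
            np.full(cfg.n_msn_size, -w)])
        return -_pool_rate_simple(cfg, bg_msn, cfg.bg_weight_ns, rates, peaks)

    w_lat = _bisect_monotone(lat_fn, -cfg.lateral_suppressed_hz, 0.0, 16.0)

    # RP conductance scale: a learned striosome subpopulation (n_str_size @
    # gated rate, weight w_ref) cancels the reward increment of dopamine
    str_rates = np.full(cfg.n_str_size, cfg.striosome_gated_hz)

    def rp_fn(gmax):
        return -_pool_rate_simple(
            cfg, da_rew, cfg.bg_weight_ns, str_rates,
            np.full(cfg.n_str_size, -gmax * cfg.w_ref_rp))

    gmax_r = _bisect_monotone(rp_fn, -cfg.da_baseline_hz, 0.0, 2.0)

    out = {
        "bg_rate_output": bg_out,
        "bg_rate_msn": bg_msn,
        "da_drive": da_drive,
        "w_state_striosome": w_ss,
        "w_eff_striosome": w_es,
        "w_eff_msn": w_em,
        "gmax_cortical": gmax_c,
        "gmax_cortical_d2": gmax_c_d2,
        "w_d1_output": w_d1o,
        "w_d2_output": w_d2o,
        "w_lateral": w_lat,
        "gmax_rp": gmax_r,
    }
    _CAL_CACHE[key] = out
    return out


# --------------------------------------------------------------------------
# the model object
# --------------------------------------------------------------------------


class NetworkModel:
    """Stateful network simulator (populations, projections, traces).

    Built by :func:`build_network`; advanced in phases via :meth:`run`.
    All randomness derives from the seed passed at build time.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.global_step = 0
        self.q = 0.0
        self.lesion = LesionSpec()
        self.calibration = calibrate_operating_points(config)
        self._build()

    # -- construction -----------------------------------------------------

    def _build(self) -> None:
        cfg = self.config
        p = cfg.neuron
        cal = self.calibration
        rng = self.rng
        dt = cfg.dt

        n_sn = cfg.n_state_neurons
        n_d1 = cfg.n_actions * cfg.n_msn_size
        n_msn = cfg.n_msn_tot
        n_str = cfg.n_str_tot
        n_out = cfg.n_out_tot
        n_da = cfg.n_da
        n_lif = cfg.n_lif
        self.n_d1 = n_d1
        self.str0 = n_msn
        self.out0 = n_msn + n_str
        self.da0 = n_msn + n_str + n_out

        het = sample_heterogeneous_params(p, cfg.spreads, n_lif, rng)
        self.v = het["v_init"].copy()
        self.vth = het["v_th"]
        self.vres = het["v_res"]
        self.ref_until = np.full(n_lif, -1, dtype=np.int64)
        self.gex = np.zeros(n_lif)
        self.yex = np.zeros(n_lif)
        self.ginh = np.zeros(n_lif)
        self.yinh = np.zeros(n_lif)
        self.bg_p = np.zeros(n_lif)
        self.bg_inc = np.full(n_lif, _inc(cfg.bg_weight_ns, p.tau_ex))

        ring_len = 64
        self.ring_ex = np.zeros((ring_len, n_lif))
        self.ring_inh = np.zeros((ring_len, n_lif))

        def delays(shape):
            d = rng.normal(cfg.delay_mean_ms, cfg.delay_sd_ms, size=shape)
            steps = np.clip(np.round(d / dt), 1, ring_len - 1).astype(np.int32)
            return steps

        def jitter(mean, shape):
            w = rng.normal(mean, cfg.spreads.weight_frac * mean, size=shape)
            return np.clip(w, 0.1 * mean, None)

        # plastic cortico-striatal
        self.delay_c = delays((n_sn, n_msn))
        tr = cfg.traces
        p0 = cfg.init_p_marginal
        self.p_state_d1 = np.clip(rng.normal(p0, 0.02, n_sn), tr.eps ** 2, 1.0)
        self.p_state_d2 = np.clip(rng.normal(p0, 0.02, n_sn), tr.eps ** 2, 1.0)
        self.p_msn = np.clip(rng.normal(p0, 0.02, n_msn), tr.eps ** 2, 1.0)
        self.p_c = np.clip(
            np.outer(0.5 * (self.p_state_d1 + self.p_state_d2), self.p_msn)
            * np.exp(rng.normal(0.0, cfg.init_w_sd, (n_sn, n_msn))),
            tr.eps ** 2, 1.0,
        )
        self.z_state = np.full(n_sn, tr.eps)
        self.e_state = np.full(n_sn, tr.eps)
        self.z_msn = np.full(n_msn, tr.eps)
        self.e_msn = np.full(n_msn, tr.eps)
        self.e_c = np.full((n_sn, n_msn), tr.eps ** 2)
        self.pulse_until_state = np.full(n_sn, -1, dtype=np.int64)
        self.pulse_until_msn = np.full(n_msn, -1, dtype=np.int64)

        # plastic RP
        self.delay_r = delays((n_str, n_da))
        self.p_str = np.clip(rng.normal(p0, 0.02, n_str), tr.eps ** 2, 1.0)
        self.p_da = np.clip(rng.normal(p0, 0.02, n_da), tr.eps ** 2, 1.0)
        self.p_r = np.clip(
            np.outer(self.p_str, self.p_da)
            * np.exp(rng.normal(0.0, cfg.init_w_sd, (n_str, n_da))),
            tr.eps ** 2, 1.0,
        )
        self.z_str = np.full(n_str, tr.eps)
        self.e_str = np.full(n_str, tr.eps)
        self.z_da = np.full(n_da, tr.eps)
        self.e_da = np.full(n_da, tr.eps)
        self.e_r = np.full((n_str, n_da), tr.eps ** 2)
        self.pulse_until_str = np.full(n_str, -1, dtype=np.int64)
        self.pulse_until_da = np.full(n_da, -1, dtype=np.int64)

        self.gmax_c_inc = _inc(cal["gmax_cortical"], p.tau_ex)
        self.gmax_c_inc_d2 = _inc(cal["gmax_cortical_d2"], p.tau_ex)
        self.gmax_r_inc = _inc(cal["gmax_rp"], p.tau_ex)
        self.rp_gain = 1.0

        # static adjacency: MSN -> outputs (signed), MSN -> lateral MSNs
        ptr = [0]
        post, inc, sign, dly = [], [], [], []
        for m in range(n_msn):
            is_d1 = m < n_d1
            a = (m % n_d1) // cfg.n_msn_size
            # to own action's output population
            w_o = jitter(cal["w_d1_output"] if is_d1 else cal["w_d2_output"],
                         cfg.n_out_size)
            d_o = delays(cfg.n_out_size)
            for u in range(cfg.n_out_size):
                post.append(self.out0 + a * cfg.n_out_size + u)
                inc.append(_inc(w_o[u], p.tau_ex))
                sign.append(-1 if is_d1 else 1)
                dly.append(d_o[u])
            # lateral inhibition to same-receptor rival actions
            blk = 0 if is_d1 else n_d1
            n_lat = (cfg.n_actions - 1) * cfg.n_msn_size
            w_l = jitter(cal["w_lateral"], n_lat)
            d_l = delays(n_lat)
            u = 0
            for b in range(cfg.n_actions):
                if b == a:
                    continue
                for t in range(cfg.n_msn_size):
                    post.append(blk + b * cfg.n_msn_size + t)
                    inc.append(_inc(w_l[u], p.tau_ex))
                    sign.append(-1)
                    dly.append(d_l[u])
                    u += 1
            ptr.append(len(post))
        self.out_ptr = np.asarray(ptr, dtype=np.int64)
        self.out_post = np.asarray(post, dtype=np.int64)
        self.out_inc = np.asarray(inc, dtype=np.float64)
        self.out_sign = np.asarray(sign, dtype=np.int8)
        self.out_delay = np.asarray(dly, dtype=np.int32)

        # state -> striosome (state i targets subpopulations (i, *))
        self.w_ss_inc = np.zeros((n_sn, n_str))
        self.d_ss = np.ones((n_sn, n_str), dtype=np.int32)
        blk_str = cfg.n_actions * cfg.n_str_size
        for s in range(n_sn):
            i = s // cfg.n_sn_per_state
            cols = slice(i * blk_str, (i + 1) * blk_str)
            self.w_ss_inc[s, cols] = _inc(1.0, p.tau_ex) * jitter(
                cal["w_state_striosome"], blk_str)
            self.d_ss[s, cols] = delays(blk_str)

        # efference -> matrisome (action j targets D1_j and D2_j)
        self.w_em_inc = np.zeros((cfg.n_actions, n_msn))
        self.d_em = np.ones((cfg.n_actions, n_msn), dtype=np.int32)
        for a in range(cfg.n_actions):
            for blk in (0, n_d1):
                cols = slice(blk + a * cfg.n_msn_size,
                             blk + (a + 1) * cfg.n_msn_size)
                self.w_em_inc[a, cols] = _inc(1.0, p.tau_ex) * jitter(
                    cal["w_eff_msn"], cfg.n_msn_size)
                self.d_em[a, cols] = delays(cfg.n_msn_size)

        # efference -> striosome (action j targets subpopulations (*, j)),
        # delayed by the efference-phase duration
        self.w_es_inc = np.zeros((cfg.n_actions, n_str))
        for a in range(cfg.n_actions):
            for i in range(cfg.n_states):
                sp = i * cfg.n_actions + a
                cols = slice(sp * cfg.n_str_size, (sp + 1) * cfg.n_str_size)
                self.w_es_inc[a, cols] = _inc(1.0, p.tau_ex) * jitter(
                    cal["w_eff_striosome"], cfg.n_str_size)
        self.eff_delay_steps = max(int(round(cfg.eff_striosome_delay_ms / dt)), 1)
        self.eff_buf = np.zeros((cfg.n_actions, self.eff_delay_steps), dtype=np.int8)

        self.da_alive = np.ones(n_da, dtype=np.int8)
        self.sf_enabled = True
        self.eff_enabled = True

        self.rpe_state = RpeState(
            tau_q=cfg.tau_q,
            sigma_matrisome=sigma_for_population(
                n_da, cfg.da_reward_hz - cfg.da_baseline_hz, cfg.gain_matrisome),
            sigma_striosome=sigma_for_population(
                n_da, cfg.da_reward_hz - cfg.da_baseline_hz, cfg.gain_striosome),
            lambda_matrisome=cfg.lambda_matrisome,
            lambda_striosome=cfg.lambda_striosome,
            kappa_clamp=cfg.kappa_clamp,
        )
        self.beta_dopa = 0.0  # calibrated by the session runner

        self.populations = self._population_table()
        self.projections = self._projection_table()

    def _population_table(self):
        cfg = self.config
        pops = []
        for i in range(cfg.n_states):
            pops.append(PopulationSpec(f"state_{i}", "state", (i,), cfg.n_sn_per_state))
        for a in range(cfg.n_actions):
            pops.append(PopulationSpec(f"D1_{a}", "D1_matrisome", (a,), cfg.n_msn_size))
        for a in range(cfg.n_actions):
            pops.append(PopulationSpec(f"D2_{a}", "D2_matrisome", (a,), cfg.n_msn_size))
        for i in range(cfg.n_states):
            for a in range(cfg.n_actions):
                pops.append(PopulationSpec(
                    f"striosome_{i}{a}", "striosome", (i, a), cfg.n_str_size))
        for a in range(cfg.n_actions):
            pops.append(PopulationSpec(
                f"GPiSNr_{a}", "output_GPiSNr", (a,), cfg.n_out_size))
        pops.append(PopulationSpec("dopamine", "dopamine", (), cfg.n_da))
        for a in range(cfg.n_actions):
            pops.append(PopulationSpec(f"efference_{a}", "efference_source", (a,), 1))
        return pops

    def _projection_table(self):
        cfg = self.config
        rows = []

        def add(pre, post, plastic, receptor, sign, n):
            rows.append(dict(pre=pre, post=post, plastic=plastic,
                             receptor_class=receptor, sign=sign, n=n))

        for i in range(cfg.n_states):
            for a in range(cfg.n_actions):
                add(f"state_{i}", f"D1_{a}", True, "D1", "normal",
                    cfg.n_sn_per_state * cfg.n_msn_size)
                add(f"state_{i}", f"D2_{a}", True, "D2", "normal",
                    cfg.n_sn_per_state * cfg.n_msn_size)
                add(f"state_{i}", f"striosome_{i}{a}", False, None, "excitatory",
                    cfg.n_sn_per_state * cfg.n_str_size)
                add(f"striosome_{i}{a}", "dopamine", True, "RP", "inverted",
                    cfg.n_str_size * cfg.n_da)
                add(f"efference_{a}", f"striosome_{i}{a}", False, None,
                    "excitatory", cfg.n_str_size)
        for a in range(cfg.n_actions):
            add(f"D1_{a}", f"GPiSNr_{a}", False, None, "inhibitory",
                cfg.n_msn_size * cfg.n_out_size)
            add(f"D2_{a}", f"GPiSNr_{a}", False, None, "excitatory",
                cfg.n_msn_size * cfg.n_out_size)
            add(f"efference_{a}", f"D1_{a}", False, None, "excitatory", cfg.n_msn_size)
            add(f"efference_{a}", f"D2_{a}", False, None, "excitatory", cfg.n_msn_size)
            for b in range(cfg.n_actions):
                if b != a:
                    add(f"D1_{a}", f"D1_{b}", False, None, "inhibitory",
                        cfg.n_msn_size * cfg.n_msn_size)
                    add(f"D2_{a}", f"D2_{b}", False, None, "inhibitory",
                        cfg.n_msn_size * cfg.n_msn_size)
        return rows

    def dump(self) -> dict:
        """JSON-able structural summary for audits."""
        return {
            "populations": [vars(p) | {"coding": list(p.coding)} for p in self.populations],
            "projections": self.projections,
            "total_neurons": self.config.total_neurons,
            "total_synapses": self.config.total_synapses,
            "lesion": vars(self.lesion) if not isinstance(self.lesion, dict) else self.lesion,
        }

    # -- running ----------------------------------------------------------

    def run(
        self,
        duration: float,
        state_rates: np.ndarray | list,
        eff_rates: np.ndarray | list,
        da_rate: float,
        collect_counts: bool = False,
        sample_times: Optional[np.ndarray] = None,
        record_spikes: bool = False,
    ) -> PhaseResult:
        """Advance the network ``duration`` ms under constant drive settings.

        ``sample_times`` are absolute times (ms) at which mean plastic
        weights are logged.
        """
        cfg = self.config
        p = cfg.neuron
        tr = cfg.traces
        dt = cfg.dt
        n_steps = int(round(duration / dt))
        state_p = np.asarray(state_rates, float) * dt * 1e-3
        eff = np.asarray(eff_rates, float) * dt * 1e-3
        if not self.eff_enabled:
            eff = np.zeros_like(eff)
        self.bg_p[:] = 0.0
        self.bg_p[:self.str0] = self.calibration["bg_rate_msn"] * dt * 1e-3
        if self.sf_enabled:
            self.bg_p[self.out0:self.da0] = (
                self.calibration["bg_rate_output"] * dt * 1e-3)
        self.bg_p[self.da0:] = np.where(
            self.da_alive == 1, da_rate * dt * 1e-3, 0.0)

        if sample_times is None:
            sample_steps = np.empty(0, dtype=np.int64)
        else:
            rel = np.round(np.asarray(sample_times) / dt).astype(np.int64) - (
                self.global_step + 1)
            sample_steps = rel[(rel >= 0) & (rel < n_steps)]
        n_samp = sample_steps.size
        w_means = np.zeros((n_samp, 3))
        w_rp_pairs = np.zeros((n_samp, cfg.n_states * cfg.n_actions))

        act_counts = np.zeros(cfg.n_actions, dtype=np.int64)
        pop_counts = np.zeros(5, dtype=np.int64)
        sub_counts = np.zeros(cfg.n_states * cfg.n_actions, dtype=np.int64)
        kap_m = np.zeros(n_steps)
        kap_s = np.zeros(n_steps)
        q_out = np.zeros(n_steps)
        rec_cap = 2_000_000 if record_spikes else 0
        rec_id = np.zeros(max(rec_cap, 1), dtype=np.int64)
        rec_step = np.zeros(max(rec_cap, 1), dtype=np.int64)
        rec_n = np.zeros(1, dtype=np.int64)

        rpe = self.rpe_state
        seed = int(self.rng.integers(2 ** 31))
        self.q = engine.run_steps(
            seed, self.global_step, n_steps, dt,
            cfg.n_states, cfg.n_actions, cfg.n_sn_per_state, cfg.n_msn_size,
            cfg.n_str_size, cfg.n_out_size, cfg.n_da,
            p.c_m, p.g_l, p.e_l, p.e_ex, p.e_inh,
            int(round(p.t_ref / dt)), p.tau_ex, p.phi,
            self.v, self.vth, self.vres, self.ref_until,
            self.gex, self.yex, self.ginh, self.yinh,
            self.bg_p, self.bg_inc,
            self.ring_ex, self.ring_inh,
            self.delay_c, self.e_c, self.p_c,
            self.p_state_d1, self.p_state_d2,
            self.z_state, self.e_state, self.pulse_until_state,
            self.z_msn, self.e_msn, self.p_msn, self.pulse_until_msn,
            self.gmax_c_inc, self.gmax_c_inc_d2,
            self.delay_r, self.e_r, self.p_r,
            self.z_str, self.e_str, self.p_str, self.pulse_until_str,
            self.z_da, self.e_da, self.p_da, self.pulse_until_da,
            self.gmax_r_inc, self.rp_gain,
            self.out_ptr, self.out_post, self.out_inc, self.out_sign,
            self.out_delay,
            self.w_ss_inc, self.d_ss, self.w_em_inc, self.d_em, self.w_es_inc,
            self.eff_buf, self.eff_delay_steps,
            state_p, eff,
            self.q, math.exp(-dt / rpe.tau_q), 1000.0 / rpe.tau_q,
            self.beta_dopa, rpe.sigma_matrisome, rpe.sigma_striosome,
            rpe.lambda_matrisome, rpe.lambda_striosome, rpe.kappa_clamp,
            self.da_alive,
            math.exp(-dt / tr.tau_zi), math.exp(-dt / tr.tau_e),
            dt / tr.tau_p, tr.eps, tr.pulse_height,
            max(int(round(tr.delta_t / dt)), 1), cfg.kappa_min,
            1 if collect_counts else 0,
            act_counts, pop_counts, sub_counts,
            kap_m, kap_s, q_out,
            sample_steps, w_means, w_rp_pairs,
            rec_cap, rec_id, rec_step, rec_n,
        )
        t0 = self.global_step * dt
        self.global_step += n_steps
        spikes = None
        if record_spikes:
            n = int(rec_n[0])
            spikes = (rec_id[:n].copy(), rec_step[:n] * dt)
        return PhaseResult(
            duration=duration,
            action_counts=act_counts,
            pop_counts=pop_counts,
            striosome_sub_counts=sub_counts,
            kappa_matrisome=kap_m,
            kappa_striosome=kap_s,
            q=q_out,
            weight_samples=w_means,
            weight_sample_times=t0 + (sample_steps + 1) * dt,
            rp_pair_samples=w_rp_pairs,
            spikes=spikes,
        )

    def cortical_weight_matrix(self) -> np.ndarray:
        """Current state-to-matrisome weights [n_state_neurons, n_msn_tot],
        read out from the P traces with the lower bound of 0 applied."""
        p_pre = np.concatenate([
            np.repeat(self.p_state_d1[:, None], self.n_d1, axis=1),
            np.repeat(self.p_state_d2[:, None],
                      self.config.n_msn_tot - self.n_d1, axis=1)], axis=1)
        num = np.maximum(self.p_c, 1e-6)
        den = np.maximum(p_pre, 1e-6) * np.maximum(self.p_msn[None, :], 1e-6)
        return np.maximum(np.log(num / den), 0.0)

    def rp_weight_matrix(self) -> np.ndarray:
        """Current striosome-to-dopamine weights (alive targets only)."""
        num = np.maximum(self.p_r, 1e-6)
        den = (np.maximum(self.p_str[:, None], 1e-6)
               * np.maximum(self.p_da[None, :], 1e-6))
        w = np.log(num / den)
        return w[:, self.da_alive == 1]

    def simulate_dopamine_baseline(
        self, duration: float, seed: int = 0, dt: float | None = None
    ) -> np.ndarray:
        """Per-step spike counts of the free-running dopaminergic population
        (baseline drive, no striosomal input, no reward)."""
        cfg = self.config
        p = cfg.neuron
        dt_eff = dt if dt is not None else cfg.dt
        n_steps = int(round(duration / dt_eff))
        counts = np.zeros(n_steps, dtype=np.int64)
        engine.sim_pool_counts(
            int(seed) % 2 ** 31, n_steps, dt_eff,
            p.c_m, p.g_l, p.e_l, p.e_ex, p.e_inh,
            self.vth[self.da0:], self.vres[self.da0:], self.da_alive,
            int(round(p.t_ref / dt_eff)), p.tau_ex,
            self.calibration["da_drive"].baseline_rate,
            _inc(cfg.bg_weight_ns, p.tau_ex), counts,
        )
        return counts

    @property
    def dt(self) -> float:
        return self.config.dt


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> NetworkModel:
    """Construct the full model (populations, projections, generators)."""
    if config is None:
        config = NetworkConfig()
    if config.n_states < 1 or config.n_actions < 2:
        raise ValueError("need at least one state and two actions")
    return NetworkModel(config, seed=seed)


def apply_lesion(network: NetworkModel, spec: LesionSpec) -> NetworkModel:
    """Apply a lesion condition in place (and return the network).

    Pathway lesions zero the population's *outgoing* weights while leaving
    the population itself active; ``noEfference`` removes the efference
    sources (which also silences the striosomes); ``noSF`` removes the
    output layer's spontaneous-firing drive; ``noLI`` removes matrisomal
    lateral inhibition.  Dopaminergic deletion is applied separately at its
    onset block via :func:`delete_dopamine_neurons`.
    """
    network.lesion = spec
    cond = spec.condition
    if cond == "intact":
        return network
    if cond in ("noD1", "noD2"):
        n_d1 = network.n_d1
        for m in range(network.config.n_msn_tot):
            is_d1 = m < n_d1
            if (cond == "noD1") == is_d1:
                network.out_inc[network.out_ptr[m]:network.out_ptr[m + 1]] = 0.0
    elif cond == "noRP":
        network.rp_gain = 0.0
    elif cond == "noEfference":
        network.eff_enabled = False
    elif cond == "noSF":
        network.sf_enabled = False
    elif cond == "noLI":
        for m in range(network.config.n_msn_tot):
            lo, hi = network.out_ptr[m], network.out_ptr[m + 1]
            lateral = network.out_post[lo:hi] < network.config.n_msn_tot
            idx = np.arange(lo, hi)[lateral]
            network.out_inc[idx] = 0.0
    else:  # pragma: no cover - guarded by LesionSpec validation
        raise ValueError(f"unknown condition tag: {cond!r}")
    return network


def delete_dopamine_neurons(
    network: NetworkModel, fraction: float, seed: int = 0
) -> NetworkModel:
    """Silence ``floor(fraction * N_da)`` dopaminergic neurons.

    Deleted neurons lose their incoming (external drive, striosomal) and
    outgoing (volume-transmitter) connections; the RPE baseline offset is
    deliberately *not* recalibrated, and deleted targets are dropped from
    weight statistics.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    n_del = int(math.floor(fraction * network.config.n_da))
    if n_del == 0:
        return network
    rng = np.random.default_rng(seed)
    alive_idx = np.flatnonzero(network.da_alive == 1)
    kill = rng.choice(alive_idx, size=n_del, replace=False)
    network.da_alive[kill] = 0
    return network
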