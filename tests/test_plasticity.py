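"""Unit and property tests for the BCPNN trace cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgspike.plasticity import (
    PlasticityTraces,
    SpikeTrain,
    compute_weight_and_bias,
    gate_kappa,
    run_cascade,
    update_e_traces,
    update_p_traces,
    update_z_traces,
)


def advance(traces, n, dt, pre=False, post=False, kappa=0.0, receptor="D1"):
    for _ in range(n):
        traces = update_z_traces(traces, pre, post, dt)
        traces = update_e_traces(traces, dt)
        traces = update_p_traces(traces, gate_kappa(kappa, receptor), dt)
    return traces


class TestZTraces:
    def test_silent_decay_closed_form(self):
        tr = PlasticityTraces(z_i=1.0)
        tr = advance(tr, 100, 0.1)  # 10 ms = one tau_z
        expected = 0.01 + 0.99 * math.exp(-1.0)
        assert tr.z_i == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("rate_frac,expected", [(1.0, 1.0), (0.5, 0.5)])
    def test_poisson_mean_tracks_rate_over_fmax(self, rate_frac, expected, rng):
        """Time-averaged Z approaches r / f_max + eps for Poisson drive."""
        tr = PlasticityTraces()
        dt = 0.1
        rate = rate_frac * tr.f_max
        duration = 60000.0
        n = int(duration / dt)
        pulse_steps = int(tr.delta_t / dt)
        spikes = rng.random(n) < rate * dt * 1e-3
        z_sum = 0.0
        pulse_until = -1
        for k in range(n):
            if spikes[k]:
                pulse_until = k + pulse_steps
            tr = update_z_traces(tr, k < pulse_until, False, dt)
            z_sum += tr.z_i
        mean_z = z_sum / n
        assert mean_z == pytest.approx(expected + tr.eps, abs=0.06)

    def test_dt_must_not_exceed_pulse_duration(self, traces):
        with pytest.raises(ValueError):
            update_z_traces(traces, True, False, dt=2.0)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            PlasticityTraces(tau_zi=-1.0)
        with pytest.raises(ValueError):
            PlasticityTraces(f_max=0.0)


class TestETraces:
    def test_joint_fixed_point_is_square(self):
        """Constant Z_i = Z_j = c drives E_ij to c^2 (and keeps the joint
        estimate below the marginals for c <= 1)."""
        c = 0.6
        tr = PlasticityTraces(z_i=c, z_j=c)
        for _ in range(30000):  # 3 s >> tau_e with Z held (no z update)
            tr = update_e_traces(tr, 0.1)
        assert tr.e_ij == pytest.approx(c * c, abs=1e-9)
        assert tr.e_i == pytest.approx(c, abs=1e-9)
        assert tr.e_ij <= min(tr.e_i, tr.e_j) + 1e-9

    def test_decay_closed_form(self):
        tr = PlasticityTraces(z_i=0.0, z_j=0.0, e_ij=0.5)
        for _ in range(1000):  # advance tau_e = 100 ms
            tr = update_e_traces(tr, 0.1)
        assert tr.e_ij == pytest.approx(0.5 * math.exp(-1.0), abs=1e-9)

    def test_matches_fine_step_reference(self, rng):
        """Piecewise-constant Z trajectory: coarse dt equals a 10x finer
        integration (exponential Euler is exact for held drive)."""
        dt = 0.5
        segments = rng.random((20, 2))
        tr_c = PlasticityTraces()
        tr_f = PlasticityTraces()
        for z_i, z_j in segments:
            tr_c = PlasticityTraces(**{**vars(tr_c), "z_i": z_i, "z_j": z_j})
            tr_f = PlasticityTraces(**{**vars(tr_f), "z_i": z_i, "z_j": z_j})
            for _ in range(20):
                tr_c = update_e_traces(tr_c, dt)
            for _ in range(200):
                tr_f = update_e_traces(tr_f, dt / 10)
        assert tr_c.e_ij == pytest.approx(tr_f.e_ij, abs=1e-6)
        assert tr_c.e_i == pytest.approx(tr_f.e_i, abs=1e-6)


class TestPTraces:
    def test_zero_kappa_freezes_bit_identical(self):
        tr = PlasticityTraces(p_i=0.123456789, p_j=0.3, p_ij=0.05,
                              z_i=0.9, z_j=0.9)
        tr2 = advance(tr, 5000, 0.1, pre=True, post=True, kappa=0.0)
        assert tr2.p_i == tr.p_i
        assert tr2.p_j == tr.p_j
        assert tr2.p_ij == tr.p_ij

    def test_asymptote(self):
        tr = PlasticityTraces(e_ij=0.8, p_ij=0.2)
        for _ in range(200000):  # 20 s >> tau_p, E held (only P updated)
            tr = update_p_traces(tr, 1.0, 0.1)
        assert tr.p_ij == pytest.approx(0.8, abs=1e-6)

    def test_efold_gap_closure(self):
        tr = PlasticityTraces(e_ij=0.8, p_ij=0.2)
        for _ in range(10000):  # exactly tau_p at kappa = 1
            tr = update_p_traces(tr, 1.0, 0.1)
        expected = 0.8 + (0.2 - 0.8) * math.exp(-1.0)
        assert tr.p_ij == pytest.approx(expected, abs=1e-9)

    def test_negative_kappa_rejected(self, traces):
        with pytest.raises(ValueError):
            update_p_traces(traces, -0.1, 0.1)


class TestGating:
    @pytest.mark.parametrize("kappa,receptor,expected", [
        (0.5, "D1", 0.5), (0.5, "D2", 0.0),
        (-0.3, "D2", 0.3), (-0.3, "D1", 0.0),
        (0.0, "D1", 0.0), (0.0, "D2", 0.0), (0.0, "RP", 0.0),
        (0.7, "RP", 0.7),
    ])
    def test_receptor_gating(self, kappa, receptor, expected):
        assert gate_kappa(kappa, receptor) == expected

    def test_unknown_receptor_rejected(self):
        with pytest.raises(ValueError):
            gate_kappa(0.1, "D3")


class TestWeightReadout:
    def test_independence_gives_zero(self):
        tr = PlasticityTraces(p_i=0.2, p_j=0.3, p_ij=0.06)
        w, _ = compute_weight_and_bias(tr)
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_log_odds_and_bias(self):
        tr = PlasticityTraces(p_i=0.5, p_j=0.5, p_ij=0.5)
        w, beta = compute_weight_and_bias(tr)
        assert w == pytest.approx(math.log(2.0), abs=1e-12)
        assert beta == pytest.approx(math.log(0.5), abs=1e-12)

    def test_certain_post_gives_zero_bias(self):
        tr = PlasticityTraces(p_i=0.5, p_j=1.0, p_ij=0.5)
        _, beta = compute_weight_and_bias(tr)
        assert beta == 0.0

    def test_clamp_applies_lower_bound(self):
        tr = PlasticityTraces(p_i=0.5, p_j=0.5, p_ij=0.01)
        w, _ = compute_weight_and_bias(tr, lower_bound=0.0)
        assert w == 0.0

    def test_nonpositive_p_rejected(self):
        tr = PlasticityTraces()
        tr.p_ij = 0.0
        with pytest.raises(ValueError):
            compute_weight_and_bias(tr)


class TestCascadeSignatures:
    def test_independent_pair_weight_converges_to_zero(self, rng):
        """Independent Poisson pre/post at equal rates with kappa > 0:
        long-run weight within sampling error of zero."""
        dur = 40000.0
        pre = np.sort(rng.uniform(0, dur, size=rng.poisson(15e-3 * dur)))
        post = np.sort(rng.uniform(0, dur, size=rng.poisson(15e-3 * dur)))
        out = run_cascade(pre, post, dur, dt=0.5, kappa=1.0)
        tail = out["w"][out["t"] > dur / 2]
        assert abs(tail.mean()) < 0.25

    def test_correlation_sign(self):
        """Synchronous firing drives w positive; anti-phase firing (pre and
        post active in alternating windows) drives w negative; pre-only
        firing leaves w near zero, since the silent side sits at the doubt
        floor, which is exactly its independence level."""
        dur = 20000.0
        sync = np.arange(0.0, dur, 1000.0 / 15.0)
        out_sync = run_cascade(sync, sync, dur, dt=0.5, kappa=1.0)
        assert out_sync["w"][-1] > 0.5
        period = 1000.0
        base = np.arange(0.0, dur, 1000.0 / 30.0)
        pre = base[(base % period) < period / 2]
        post = base[(base % period) >= period / 2]
        out_anti = run_cascade(pre, post, dur, dt=0.5, kappa=1.0)
        assert out_anti["w"][-1] < -0.3
        out_pre = run_cascade(sync, [], dur, dt=0.5, kappa=1.0)
        assert abs(out_pre["w"][-1]) < 0.4

    def test_clamped_weight_never_below_zero(self):
        dur = 10000.0
        sync = np.arange(0.0, dur, 1000.0 / 15.0)
        out = run_cascade(sync, [], dur, dt=0.5, kappa=1.0, lower_bound=0.0)
        assert np.all(out["w"] >= 0.0)

    def test_cascade_converges_to_fine_step_reference(self):
        """Full cascade on a scripted train: the coarse integration
        converges linearly to a 10x finer reference (the E drive Z_i*Z_j
        varies within a step, so agreement is first-order in dt)."""
        pre = np.array([5.0, 20.0, 21.0, 50.0, 90.0])
        post = np.array([6.0, 20.0, 52.0])
        ref = run_cascade(pre, post, 200.0, dt=0.01, kappa=0.8,
                          record_every=20000)
        errs = []
        for dt, rec in ((0.4, 500), (0.1, 2000)):
            a = run_cascade(pre, post, 200.0, dt=dt, kappa=0.8,
                            record_every=rec)
            errs.append(max(abs(a[k][-1] - ref[k][-1])
                            for k in ("z_i", "z_j", "e_ij", "p_ij", "w")))
        assert errs[1] < errs[0] / 2  # ~linear convergence
        assert errs[1] < 5e-3


class TestSpikeTrain:
    def test_validation(self):
        SpikeTrain(0, np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            SpikeTrain(0, np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            SpikeTrain(0, np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            SpikeTrain(0, np.array([1.0, 1.0]))


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.booleans(), st.booleans(),
                          st.floats(0.0, 2.0)), min_size=1, max_size=60))
def test_traces_stay_positive_and_finite(steps):
    """Any pattern of pulses and non-negative learning rates keeps every
    trace positive and finite (numerical-floor invariant)."""
    tr = PlasticityTraces()
    for pre, post, kappa in steps:
        tr = update_z_traces(tr, pre, post, 0.5)
        tr = update_e_traces(tr, 0.5)
        tr = update_p_traces(tr, kappa, 0.5)
    for v in (tr.z_i, tr.z_j, tr.e_i, tr.e_j, tr.e_ij, tr.p_i, tr.p_j, tr.p_ij):
        assert v > 0.0 and math.isfinite(v)
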