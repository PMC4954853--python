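"""Accelerated network integrator.

The reference kernels in :mod:`bgspike.plasticity` and :mod:`bgspike.neurons`
define the semantics of one synapse / one neuron; this module integrates the
whole network — Poisson sources, LIF populations, static and plastic
projections, the dopamine trace and the receptor-gated BCPNN updates — in a
single compiled time-stepping loop.  Equivalence with the reference kernels
on scripted spike trains is asserted by the test suite.

Conventions baked into the loop (documented here because the compiled code
cannot express them):

* time step ``dt`` ms; all exponential updates use closed-form
  (exponential-Euler) propagators, exact for piecewise-constant drive;
* a spike drives the Z traces for ``pulse_steps`` steps starting at the step
  the spike is emitted;
* excitatory and inhibitory alpha channels share one time constant;
* plastic weights are *read out* from the P traces at every delivery and at
  every weight sample — there is no separately stored weight state;
* the cortico-matrisomal lower bound of 0 is applied at read-out, so
  sub-independence synapses simply deliver nothing;
* the striosome-to-dopamine projection uses the inverted sign convention:
  positive learned weights inhibit dopaminergic targets;
* the global learning signals (kappa for D1, D2 and the RP pathway) are
  computed once per step from the shared volume-transmitter trace q and
  broadcast to every synapse of the class.

Neuron indexing (LIF block): D1 matrisomes by action, then D2 matrisomes by
action, then striosome subpopulations in (state, action) row-major order,
then GPi/SNr output populations by action, then dopaminergic neurons.
State-coding neurons and efference-copy sources are Poisson generators, not
LIF neurons.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_steps", "sim_pool", "sim_pool_counts"]

P_FLOOR = 1e-6


@njit(cache=True)
def _signed_pow(x, lam):
    m = abs(x) ** lam
    if lam % 2 == 1 and x < 0.0:
        return -m
    return m


@njit(cache=True)
def run_steps(
    seed,
    g0,
    n_steps,
    dt,
    # --- layout ---
    n_states,
    n_actions,
    n_sn_per_state,
    n_msn_size,
    n_str_size,
    n_out_size,
    n_da,
    # --- neuron scalars ---
    c_m,
    g_l,
    e_l,
    e_ex,
    e_inh,
    ref_steps,
    tau_syn,
    phi,
    # --- per-LIF-neuron state ---
    v,
    vth,
    vres,
    ref_until,
    gex,
    yex,
    ginh,
    yinh,
    bg_p,
    bg_inc,
    # --- conductance ring buffers [ring_len, n_lif] ---
    ring_ex,
    ring_inh,
    # --- plastic cortico-striatal projection ---
    delay_c,
    e_c,
    p_c,
    p_state_d1,
    p_state_d2,
    z_state,
    e_state,
    pulse_until_state,
    z_msn,
    e_msn,
    p_msn,
    pulse_until_msn,
    gmax_c_inc_d1,
    gmax_c_inc_d2,
    # --- plastic striosome->dopamine (RP) projection ---
    delay_r,
    e_r,
    p_r,
    z_str,
    e_str,
    p_str,
    pulse_until_str,
    z_da,
    e_da,
    p_da,
    pulse_until_da,
    gmax_r_inc,
    rp_gain,
    # --- static adjacency (MSN outgoing: outputs + lateral) ---
    out_ptr,
    out_post,
    out_inc,
    out_sign,
    out_delay,
    # --- static dense projections ---
    w_ss_inc,
    d_ss,
    w_em_inc,
    d_em,
    w_es_inc,
    eff_buf,
    eff_delay_steps,
    # --- per-step source firing probabilities ---
    state_p,
    eff_p,
    # --- dopamine / RPE ---
    q_in,
    dec_q,
    jump_q,
    beta_dopa,
    sigma_m,
    sigma_s,
    lam_m,
    lam_s,
    kappa_clamp,
    da_alive,
    # --- plasticity scalars ---
    a_z,
    a_e,
    dt_over_taup,
    eps,
    pulse_h,
    pulse_steps,
    kappa_min,
    # --- outputs ---
    collect_counts,
    act_counts,
    pop_counts,
    str_sub_counts,
    kappa_mat_out,
    kappa_str_out,
    q_out,
    sample_steps,
    w_means_out,
    w_rp_pairs_out,
    rec_cap,
    rec_id,
    rec_step,
    rec_n,
):
    np.random.seed(seed)

    n_d1 = n_actions * n_msn_size
    n_msn_tot = 2 * n_d1
    n_str_tot = n_states * n_actions * n_str_size
    n_out_tot = n_actions * n_out_size
    str0 = n_msn_tot
    out0 = str0 + n_str_tot
    da0 = out0 + n_out_tot
    n_lif = da0 + n_da
    ring_len = ring_ex.shape[0]
    n_sn = n_states * n_sn_per_state

    dec_syn = math.exp(-dt / tau_syn)
    q = q_in
    sample_ptr = 0
    n_sub = n_states * n_actions

    for k in range(n_steps):
        g = g0 + k
        slot = g % ring_len

        # ---- 1. state-coding Poisson sources ----
        for s in range(n_sn):
            i_state = s // n_sn_per_state
            if np.random.random() < state_p[i_state]:
                pulse_until_state[s] = g + pulse_steps
                if rec_cap > 0 and rec_n[0] < rec_cap:
                    rec_id[rec_n[0]] = n_lif + s
                    rec_step[rec_n[0]] = g
                    rec_n[0] += 1
                # plastic delivery to every matrisomal MSN
                pd1 = p_state_d1[s]
                if pd1 < P_FLOOR:
                    pd1 = P_FLOOR
                pd2 = p_state_d2[s]
                if pd2 < P_FLOOR:
                    pd2 = P_FLOOR
                for m in range(n_msn_tot):
                    ppre = pd1 if m < n_d1 else pd2
                    pij = p_c[s, m]
                    if pij < P_FLOOR:
                        pij = P_FLOOR
                    ppost = p_msn[m]
                    if ppost < P_FLOOR:
                        ppost = P_FLOOR
                    w = math.log(pij / (ppre * ppost))
                    if w > 0.0:  # hard lower bound of 0 on cortico-matrisomal weights
                        gsc = gmax_c_inc_d1 if m < n_d1 else gmax_c_inc_d2
                        ring_ex[(g + delay_c[s, m]) % ring_len, m] += w * gsc
                # static delivery to this state's striosome subpopulations
                st_lo = i_state * n_actions * n_str_size
                st_hi = st_lo + n_actions * n_str_size
                for st in range(st_lo, st_hi):
                    inc = w_ss_inc[s, st]
                    if inc > 0.0:
                        ring_ex[(g + d_ss[s, st]) % ring_len, str0 + st] += inc

        # ---- 2. efference-copy sources (immediate to MSNs, delayed to striosomes) ----
        for a in range(n_actions):
            dslot = g % eff_delay_steps
            if eff_buf[a, dslot] == 1:
                # spike emitted eff_delay_steps ago arrives at striosomes now
                for i_state in range(n_states):
                    sp = i_state * n_actions + a
                    base = sp * n_str_size
                    for u in range(n_str_size):
                        yex[str0 + base + u] += w_es_inc[a, base + u]
            fired = np.random.random() < eff_p[a]
            eff_buf[a, dslot] = 1 if fired else 0
            if fired:
                if rec_cap > 0 and rec_n[0] < rec_cap:
                    rec_id[rec_n[0]] = n_lif + n_sn + a
                    rec_step[rec_n[0]] = g
                    rec_n[0] += 1
                for blk in range(2):
                    m_lo = blk * n_d1 + a * n_msn_size
                    for m in range(m_lo, m_lo + n_msn_size):
                        inc = w_em_inc[a, m]
                        if inc > 0.0:
                            ring_ex[(g + d_em[a, m]) % ring_len, m] += inc

        # ---- 3. apply matured ring events + background drive ----
        for i in range(n_lif):
            yex[i] += ring_ex[slot, i]
            yinh[i] += ring_inh[slot, i]
            ring_ex[slot, i] = 0.0
            ring_inh[slot, i] = 0.0
            if bg_p[i] > 0.0 and np.random.random() < bg_p[i]:
                yex[i] += bg_inc[i]

        # ---- 4. LIF update ----
        n_da_spikes = 0
        for i in range(n_lif):
            ge = dec_syn * (gex[i] + dt * yex[i])
            ye = dec_syn * yex[i]
            gi = dec_syn * (ginh[i] + dt * yinh[i])
            yi = dec_syn * yinh[i]
            gex[i] = ge
            yex[i] = ye
            ginh[i] = gi
            yinh[i] = yi
            spiked = False
            if ref_until[i] > g:
                v[i] = vres[i]
            else:
                bias = 0.0
                if i < n_msn_tot:
                    pj = p_msn[i]
                    if pj < P_FLOOR:
                        pj = P_FLOOR
                    bias = phi * math.log(pj)
                g_tot = g_l + ge + gi
                v_inf = (g_l * e_l + ge * e_ex + gi * e_inh + bias) / g_tot
                vv = v_inf + (v[i] - v_inf) * math.exp(-dt * g_tot / c_m)
                if vv >= vth[i]:
                    spiked = True
                    vv = vres[i]
                    ref_until[i] = g + ref_steps
                v[i] = vv
            if not spiked:
                continue
            if rec_cap > 0 and rec_n[0] < rec_cap:
                rec_id[rec_n[0]] = i
                rec_step[rec_n[0]] = g
                rec_n[0] += 1
            if i < n_msn_tot:
                # matrisomal MSN: Z pulse + static outgoing (outputs, lateral)
                pulse_until_msn[i] = g + pulse_steps
                pop_counts[0 if i < n_d1 else 1] += 1
                for p in range(out_ptr[i], out_ptr[i + 1]):
                    tgt = out_post[p]
                    inc = out_inc[p]
                    if inc > 0.0:
                        sl = (g + out_delay[p]) % ring_len
                        if out_sign[p] > 0:
                            ring_ex[sl, tgt] += inc
                        else:
                            ring_inh[sl, tgt] += inc
            elif i < out0:
                # striosome: Z pulse + plastic inverted delivery to dopamine
                st = i - str0
                pulse_until_str[st] = g + pulse_steps
                pop_counts[2] += 1
                str_sub_counts[st // n_str_size] += 1
                if rp_gain > 0.0:
                    pi = p_str[st]
                    if pi < P_FLOOR:
                        pi = P_FLOOR
                    for dn in range(n_da):
                        if da_alive[dn] == 0:
                            continue
                        pij = p_r[st, dn]
                        if pij < P_FLOOR:
                            pij = P_FLOOR
                        pj = p_da[dn]
                        if pj < P_FLOOR:
                            pj = P_FLOOR
                        w = math.log(pij / (pi * pj))
                        if w == 0.0:
                            continue
                        inc = abs(w) * gmax_r_inc * rp_gain
                        sl = (g + delay_r[st, dn]) % ring_len
                        if w > 0.0:  # inverted convention: positive weight inhibits
                            ring_inh[sl, da0 + dn] += inc
                        else:
                            ring_ex[sl, da0 + dn] += inc
            elif i < da0:
                # GPi/SNr output neuron
                pop_counts[3] += 1
                if collect_counts == 1:
                    act_counts[(i - out0) // n_out_size] += 1
            else:
                # dopaminergic neuron
                dn = i - da0
                pulse_until_da[dn] = g + pulse_steps
                pop_counts[4] += 1
                if da_alive[dn] == 1:
                    n_da_spikes += 1

        # ---- 5. volume transmitter and learning signals ----
        q = q * dec_q + n_da_spikes * jump_q
        dev = beta_dopa + q
        kap_m = _signed_pow(sigma_m * dev, lam_m)
        if kap_m > kappa_clamp:
            kap_m = kappa_clamp
        elif kap_m < -kappa_clamp:
            kap_m = -kappa_clamp
        kap_s = _signed_pow(sigma_s * dev, lam_s)
        if kap_s > kappa_clamp:
            kap_s = kappa_clamp
        kappa_mat_out[k] = kap_m
        kappa_str_out[k] = kap_s
        q_out[k] = q
        kap_d1 = kap_m if kap_m > 0.0 else 0.0
        kap_d2 = -kap_m if kap_m < 0.0 else 0.0

        # ---- 6. Z and E traces (closed-form per step) ----
        for s in range(n_sn):
            drive = pulse_h if pulse_until_state[s] > g else 0.0
            tgt = drive + eps
            zz = tgt + (z_state[s] - tgt) * a_z
            z_state[s] = zz
            e_state[s] = zz + (e_state[s] - zz) * a_e
        for m in range(n_msn_tot):
            drive = pulse_h if pulse_until_msn[m] > g else 0.0
            tgt = drive + eps
            zz = tgt + (z_msn[m] - tgt) * a_z
            z_msn[m] = zz
            e_msn[m] = zz + (e_msn[m] - zz) * a_e
        for st in range(n_str_tot):
            drive = pulse_h if pulse_until_str[st] > g else 0.0
            tgt = drive + eps
            zz = tgt + (z_str[st] - tgt) * a_z
            z_str[st] = zz
            e_str[st] = zz + (e_str[st] - zz) * a_e
        for dn in range(n_da):
            drive = pulse_h if pulse_until_da[dn] > g else 0.0
            tgt = drive + eps
            zz = tgt + (z_da[dn] - tgt) * a_z
            z_da[dn] = zz
            e_da[dn] = zz + (e_da[dn] - zz) * a_e
        for s in range(n_sn):
            zs = z_state[s]
            for m in range(n_msn_tot):
                prod = zs * z_msn[m]
                e_c[s, m] = prod + (e_c[s, m] - prod) * a_e
        for st in range(n_str_tot):
            zs = z_str[st]
            for dn in range(n_da):
                prod = zs * z_da[dn]
                e_r[st, dn] = prod + (e_r[st, dn] - prod) * a_e

        # ---- 7. receptor-gated P updates ----
        if kap_d1 > kappa_min:
            ap = math.exp(-kap_d1 * dt_over_taup)
            for s in range(n_sn):
                p_state_d1[s] = e_state[s] + (p_state_d1[s] - e_state[s]) * ap
                for m in range(n_d1):
                    p_c[s, m] = e_c[s, m] + (p_c[s, m] - e_c[s, m]) * ap
            for m in range(n_d1):
                p_msn[m] = e_msn[m] + (p_msn[m] - e_msn[m]) * ap
        if kap_d2 > kappa_min:
            ap = math.exp(-kap_d2 * dt_over_taup)
            for s in range(n_sn):
                p_state_d2[s] = e_state[s] + (p_state_d2[s] - e_state[s]) * ap
                for m in range(n_d1, n_msn_tot):
                    p_c[s, m] = e_c[s, m] + (p_c[s, m] - e_c[s, m]) * ap
            for m in range(n_d1, n_msn_tot):
                p_msn[m] = e_msn[m] + (p_msn[m] - e_msn[m]) * ap
        if kap_s > kappa_min:
            ap = math.exp(-kap_s * dt_over_taup)
            for st in range(n_str_tot):
                p_str[st] = e_str[st] + (p_str[st] - e_str[st]) * ap
                for dn in range(n_da):
                    p_r[st, dn] = e_r[st, dn] + (p_r[st, dn] - e_r[st, dn]) * ap
            for dn in range(n_da):
                p_da[dn] = e_da[dn] + (p_da[dn] - e_da[dn]) * ap

        # ---- 8. weight sampling ----
        if sample_ptr < sample_steps.shape[0] and k == sample_steps[sample_ptr]:
            sum_d1 = 0.0
            sum_d2 = 0.0
            for s in range(n_sn):
                pd1 = max(p_state_d1[s], P_FLOOR)
                pd2 = max(p_state_d2[s], P_FLOOR)
                for m in range(n_d1):
                    w = math.log(
                        max(p_c[s, m], P_FLOOR) / (pd1 * max(p_msn[m], P_FLOOR))
                    )
                    if w > 0.0:
                        sum_d1 += w
                for m in range(n_d1, n_msn_tot):
                    w = math.log(
                        max(p_c[s, m], P_FLOOR) / (pd2 * max(p_msn[m], P_FLOOR))
                    )
                    if w > 0.0:
                        sum_d2 += w
            w_means_out[sample_ptr, 0] = sum_d1 / (n_sn * n_d1)
            w_means_out[sample_ptr, 1] = sum_d2 / (n_sn * n_d1)
            sum_rp = 0.0
            n_alive = 0
            for dn in range(n_da):
                if da_alive[dn] == 1:
                    n_alive += 1
            for sp in range(n_sub):
                sub_sum = 0.0
                for u in range(n_str_size):
                    st = sp * n_str_size + u
                    pi = max(p_str[st], P_FLOOR)
                    for dn in range(n_da):
                        if da_alive[dn] == 0:
                            continue
                        w = math.log(
                            max(p_r[st, dn], P_FLOOR) / (pi * max(p_da[dn], P_FLOOR))
                        )
                        sub_sum += w
                if n_alive > 0:
                    w_rp_pairs_out[sample_ptr, sp] = sub_sum / (n_str_size * n_alive)
                sum_rp += sub_sum
            if n_alive > 0:
                w_means_out[sample_ptr, 2] = sum_rp / (n_str_tot * n_alive)
            sample_ptr += 1

    return q


@njit(cache=True)
def sim_pool(
    seed,
    n,
    n_steps,
    dt,
    c_m,
    g_l,
    e_l,
    e_ex,
    e_inh,
    v_th,
    v_res,
    ref_steps,
    tau_syn,
    bias_pa,
    bg_rate_hz,
    bg_inc,
    src_rates_hz,
    src_incs,
    settle_steps,
):
    """Pool of identical LIF neurons under private background Poisson drive
    plus shared Poisson sources (positive ``src_incs`` excite, negative
    inhibit).  Returns the summed spike count after ``settle_steps``.

    Used as the oracle for drive-rate and weight calibration.
    """
    np.random.seed(seed)
    dec_syn = math.exp(-dt / tau_syn)
    bg_pp = bg_rate_hz * dt * 1e-3
    n_src = src_rates_hz.shape[0]
    v = np.full(n, e_l)
    ge = np.zeros(n)
    ye = np.zeros(n)
    gi = np.zeros(n)
    yi = np.zeros(n)
    refr = np.full(n, -1, dtype=np.int64)
    count = 0
    for k in range(n_steps):
        exc_shared = 0.0
        inh_shared = 0.0
        for src in range(n_src):
            if np.random.random() < src_rates_hz[src] * dt * 1e-3:
                if src_incs[src] > 0.0:
                    exc_shared += src_incs[src]
                else:
                    inh_shared += -src_incs[src]
        for i in range(n):
            if bg_pp > 0.0 and np.random.random() < bg_pp:
                ye[i] += bg_inc
            ye[i] += exc_shared
            yi[i] += inh_shared
            ge[i] = dec_syn * (ge[i] + dt * ye[i])
            ye[i] = dec_syn * ye[i]
            gi[i] = dec_syn * (gi[i] + dt * yi[i])
            yi[i] = dec_syn * yi[i]
            if refr[i] > k:
                v[i] = v_res
                continue
            g_tot = g_l + ge[i] + gi[i]
            v_inf = (g_l * e_l + ge[i] * e_ex + gi[i] * e_inh + bias_pa) / g_tot
            vv = v_inf + (v[i] - v_inf) * math.exp(-dt * g_tot / c_m)
            if vv >= v_th:
                vv = v_res
                refr[i] = k + ref_steps
                if k >= settle_steps:
                    count += 1
            v[i] = vv
    return count


@njit(cache=True)
def sim_pool_counts(
    seed,
    n_steps,
    dt,
    c_m,
    g_l,
    e_l,
    e_ex,
    e_inh,
    v_th,
    v_res,
    alive,
    ref_steps,
    tau_syn,
    bg_rate_hz,
    bg_inc,
    counts_out,
):
    """Heterogeneous LIF pool under private Poisson drive; writes the summed
    spike count of alive neurons per step into ``counts_out``.

    Used to free-run the dopaminergic population for baseline calibration
    and isolated rate measurements.
    """
    np.random.seed(seed)
    n = v_th.shape[0]
    dec_syn = math.exp(-dt / tau_syn)
    bg_pp = bg_rate_hz * dt * 1e-3
    v = np.full(n, e_l)
    ge = np.zeros(n)
    ye = np.zeros(n)
    refr = np.full(n, -1, dtype=np.int64)
    for k in range(n_steps):
        c = 0
        for i in range(n):
            if alive[i] == 1 and np.random.random() < bg_pp:
                ye[i] += bg_inc
            ge[i] = dec_syn * (ge[i] + dt * ye[i])
            ye[i] = dec_syn * ye[i]
            if refr[i] > k:
                v[i] = v_res[i]
                continue
            g_tot = g_l + ge[i]
            v_inf = (g_l * e_l + ge[i] * e_ex) / g_tot
            vv = v_inf + (v[i] - v_inf) * math.exp(-dt * g_tot / c_m)
            if vv >= v_th[i]:
                vv = v_res[i]
                refr[i] = k + ref_steps
                if alive[i] == 1:
                    c += 1
            v[i] = vv
        counts_out[k] = c
    return counts_out
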