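"""Structural audits, lesions and calibration of the network builder."""

import numpy as np
import pytest

from bgspike.network import (
    LesionSpec,
    NetworkConfig,
    apply_lesion,
    build_network,
    delete_dopamine_neurons,
)


class TestStructure:
    def test_default_sizing_matches_reported_network(self):
        cfg = NetworkConfig()
        assert cfg.total_neurons == 725
        assert abs(cfg.total_synapses - 70000) < 1500

    def test_population_inventory(self, desk_network):
        pops = desk_network.populations
        cfg = desk_network.config
        roles = {}
        for p in pops:
            roles.setdefault(p.role, []).append(p)
        assert len(roles["D1_matrisome"]) == cfg.n_actions
        assert len(roles["D2_matrisome"]) == cfg.n_actions
        assert len(roles["output_GPiSNr"]) == cfg.n_actions
        assert len(roles["striosome"]) == cfg.n_states * cfg.n_actions
        assert len(roles["state"]) == cfg.n_states
        # exactly one striosome subpopulation per (state, action) pair
        codings = {p.coding for p in roles["striosome"]}
        assert codings == {(i, a) for i in range(cfg.n_states)
                           for a in range(cfg.n_actions)}
        # all state populations equal-sized
        assert len({p.size for p in roles["state"]}) == 1

    def test_projection_topology(self, desk_network):
        rows = desk_network.projections
        plastic = {(r["pre"], r["post"]) for r in rows if r["plastic"]}
        # plastic projections exist only for state->matrisome, striosome->DA
        for pre, post in plastic:
            assert (pre.startswith("state_") and
                    (post.startswith("D1_") or post.startswith("D2_"))) or \
                   (pre.startswith("striosome_") and post == "dopamine")
        d1_out = [r for r in rows if r["pre"].startswith("D1_")
                  and r["post"].startswith("GPiSNr")]
        d2_out = [r for r in rows if r["pre"].startswith("D2_")
                  and r["post"].startswith("GPiSNr")]
        assert all(r["sign"] == "inhibitory" for r in d1_out)
        assert all(r["sign"] == "excitatory" for r in d2_out)
        # same-action convergence
        assert all(r["pre"][-1] == r["post"][-1] for r in d1_out + d2_out)
        rp = [r for r in rows if r["post"] == "dopamine"]
        assert all(r["sign"] == "inverted" for r in rp)

    def test_striosome_receives_only_matching_state_and_action(self, desk_network):
        cfg = desk_network.config
        blk = cfg.n_actions * cfg.n_str_size
        for s in range(cfg.n_state_neurons):
            i = s // cfg.n_sn_per_state
            mask = desk_network.w_ss_inc[s] > 0
            cols = np.flatnonzero(mask)
            assert np.all(cols // blk == i)
        for a in range(cfg.n_actions):
            mask = desk_network.w_es_inc[a] > 0
            sub = np.flatnonzero(mask) // cfg.n_str_size
            assert np.all(sub % cfg.n_actions == a)

    def test_efference_delay_locked_to_config(self, desk_network):
        cfg = desk_network.config
        assert desk_network.eff_delay_steps == int(
            round(cfg.eff_striosome_delay_ms / cfg.dt))

    def test_determinism_same_seed(self, desk_config):
        a = build_network(desk_config, seed=77)
        b = build_network(desk_config, seed=77)
        for attr in ("vth", "vres", "p_c", "p_r", "out_inc", "w_ss_inc"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr)), attr

    def test_dump_is_json_able(self, desk_network):
        import json
        json.dumps(desk_network.dump())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_network(NetworkConfig(n_actions=1))


class TestLesions:
    def test_intact_is_identity(self, desk_config):
        net = build_network(desk_config, seed=5)
        before = net.out_inc.copy()
        apply_lesion(net, LesionSpec("intact"))
        assert np.array_equal(net.out_inc, before)

    def test_noD2_zeroes_outgoing_but_population_still_fires(self, desk_config):
        net = build_network(desk_config, seed=5)
        apply_lesion(net, LesionSpec("noD2"))
        cfg = net.config
        n_d1 = net.n_d1
        for m in range(cfg.n_msn_tot):
            lo, hi = net.out_ptr[m], net.out_ptr[m + 1]
            if m >= n_d1:
                assert np.all(net.out_inc[lo:hi] == 0.0)
            else:
                assert np.any(net.out_inc[lo:hi] > 0.0)
        # D2 neurons still spike when driven by the efference copy
        da = net.calibration["da_drive"].baseline_rate
        r = net.run(500.0, [30, 3, 3], [cfg.eff_active_hz, 3, 3], da)
        assert r.pop_counts[1] > 0

    def test_noLI_removes_only_lateral(self, desk_config):
        net = build_network(desk_config, seed=5)
        apply_lesion(net, LesionSpec("noLI"))
        lateral = net.out_post < net.config.n_msn_tot
        assert np.all(net.out_inc[lateral] == 0.0)
        assert np.all(net.out_inc[~lateral] > 0.0)

    def test_noRP_gates_delivery(self, desk_config):
        net = build_network(desk_config, seed=5)
        apply_lesion(net, LesionSpec("noRP"))
        assert net.rp_gain == 0.0

    def test_noEfference_silences_striosomes(self, desk_config):
        """Without the efference copy the striosomes never reach threshold
        (single-source input is subthreshold by calibration)."""
        net = build_network(desk_config, seed=5)
        apply_lesion(net, LesionSpec("noEfference"))
        da = net.calibration["da_drive"].baseline_rate
        cfg = net.config
        r = net.run(1000.0, [30, 3, 3], [cfg.eff_active_hz, 3, 3], da)
        rate = r.pop_counts[2] / cfg.n_str_tot / 1.0
        assert rate < 1.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            LesionSpec("noSTN")

    def test_pd_fraction_validated(self):
        with pytest.raises(ValueError):
            LesionSpec(pd_fraction=1.0)
        assert LesionSpec.from_name("PD33").pd_fraction == 0.33


class TestDopamineDeletion:
    def test_floor_arithmetic(self, desk_config):
        net = build_network(desk_config, seed=5)
        delete_dopamine_neurons(net, 0.33, seed=1)
        assert int((net.da_alive == 0).sum()) == int(0.33 * desk_config.n_da)

    def test_zero_fraction_identity(self, desk_config):
        net = build_network(desk_config, seed=5)
        delete_dopamine_neurons(net, 0.0, seed=1)
        assert net.da_alive.all()

    def test_out_of_range_rejected(self, desk_config):
        net = build_network(desk_config, seed=5)
        with pytest.raises(ValueError):
            delete_dopamine_neurons(net, 1.0)


class TestCalibratedOperatingPoints:
    """The builder's calibration reproduces the stated population rates."""

    def test_output_baseline_without_matrisomal_input(self, desk_config):
        net = build_network(desk_config, seed=8)
        cfg = net.config
        for m in range(cfg.n_msn_tot):  # remove matrisome->output entirely
            lo, hi = net.out_ptr[m], net.out_ptr[m + 1]
            net.out_inc[lo:hi] = 0.0
        da = net.calibration["da_drive"].baseline_rate
        r = net.run(5000.0, [3, 3, 3], [3, 3, 3], da)
        rate = r.pop_counts[3] / cfg.n_out_tot / 5.0
        assert rate == pytest.approx(cfg.output_baseline_hz, abs=5.0)

    def test_dopamine_baseline_rate(self, desk_network):
        counts = desk_network.simulate_dopamine_baseline(5000.0, seed=3)
        rate = counts.sum() / desk_network.config.n_da / 5.0
        assert rate == pytest.approx(desk_network.config.da_baseline_hz, abs=1.0)
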