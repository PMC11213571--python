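"""Generator correctness: protocols, analytic oracles, determinism, cohorts."""

import math

import numpy as np
import pytest

from raphephys import features, stats, synth
from raphephys.sweeps import (
    BRIEF_PULSE,
    RAMP_FAMILY,
    STEP_FAMILY,
    ZERO_CURRENT,
    bundles_equal,
    read_bundle,
    write_bundle,
)


class TestProtocols:
    def test_default_set_has_stated_durations(self):
        p = synth.make_protocols()
        assert p["zero"]["duration_s"] == 10.0
        assert p["steps"]["dur_s"] == 1.0
        assert p["pulse"]["dur_s"] == 0.005
        assert p["steps"]["amplitudes_pa"][0] == -100.0
        assert p["steps"]["amplitudes_pa"][-1] == 150.0

    def test_increment_10pa_gives_26_sweeps(self):
        p = synth.make_protocols({"step_increment_pa": 10})
        assert len(p["steps"]["amplitudes_pa"]) == 26

    def test_simulated_bundle_round_trips_through_io(self, tmp_path, serotonergic_cell):
        write_bundle(serotonergic_cell.bundle, tmp_path / "cell")
        b2 = read_bundle(tmp_path / "cell")
        # TSV carries 9 significant digits
        assert bundles_equal(serotonergic_cell.bundle, b2, atol=1e-5)


class TestAnalyticRC:
    def test_asymptote(self):
        t = np.linspace(0, 5, 1000)
        v = synth.analytic_rc_response(200, 100, 50.0, t, e_l=-60.0)
        assert v[-1] == pytest.approx(-60.0 + 10.0, abs=1e-6)

    def test_efold_at_tau(self):
        tau = 0.02
        t = np.array([0.0, tau])
        v = synth.analytic_rc_response(200, 100, 50.0, t, e_l=-60.0)
        deflect = (v[1] + 60.0) / 10.0
        assert deflect == pytest.approx(1.0 - math.exp(-1.0), abs=1e-9)

    def test_simulator_subthreshold_matches_closed_form(self):
        p = synth.PhenotypeParams(
            name="rc", r_mohm=200, c_pf=100, e_l=-60, adapt_a_ns=0.0,
            gh_ns=0.0, wa_max_pa=0.0, noise_sd_mv=0.0, v_threshold=-20.0,
        )
        protocols = synth.make_protocols(
            {"skip_zero": True, "skip_ramp": True, "skip_pulse": True}
        )
        protocols["steps"]["amplitudes_pa"] = [-50.0, 30.0]
        cell = synth.simulate_neuron(p, protocols, seed=0)
        for amp, sw in zip([-50.0, 30.0], cell.bundle.get(STEP_FAMILY).sweeps):
            va = synth.analytic_rc_response(
                200, 100, amp, sw.time, e_l=-60.0, t_onset=0.2, t_offset=1.2
            )
            assert np.max(np.abs(sw.voltage - va)) < 0.05

    def test_tonic_lif_rate_matches_closed_form(self):
        p = synth.PhenotypeParams(
            name="lif", r_mohm=200, c_pf=100, e_l=-60, v_threshold=-45,
            v_reset=-55, adapt_a_ns=0, adapt_b_pa=0, ahp_increment_pa=0,
            gh_ns=0, wa_max_pa=0, noise_sd_mv=0, drive_pa=120.0,
        )
        protocols = synth.make_protocols(
            {"skip_steps": True, "skip_ramp": True, "skip_pulse": True}
        )
        cell = synth.simulate_neuron(p, protocols, seed=0)
        res = features.classify_spontaneous(cell.bundle.get(ZERO_CURRENT))
        v_inf = -60.0 + 120.0 * 200.0 / 1000.0
        isi_ms = p.template_duration_ms() + 20.0 * math.log((v_inf + 55) / (v_inf + 45))
        assert res.spontaneous
        assert res.rate == pytest.approx(1000.0 / isi_ms, rel=0.05)

    def test_same_seed_is_bit_identical(self):
        a = synth.simulate_neuron(synth.PHENOTYPES["serotonergic"], seed=5)
        b = synth.simulate_neuron(synth.PHENOTYPES["serotonergic"], seed=5)
        assert bundles_equal(a.bundle, b.bundle, atol=0.0)


class TestFullLoopRecovery:
    def test_passive_properties_recovered_noiseless_within_one_percent(self):
        p = synth.PhenotypeParams(
            name="passive", r_mohm=220.0, c_pf=90.0, e_l=-61.0, v_threshold=-42.0,
            adapt_a_ns=0.0, gh_ns=0.0, wa_max_pa=0.0, noise_sd_mv=0.0,
        )
        cell = synth.simulate_neuron(
            p, synth.make_adapted_protocols(p, fine_rheobase=True, include_zero=False),
            seed=0,
        )
        panel = features.extract_panel(cell.bundle, target_rate=1.0)
        assert abs(panel.tau - p.tau_ms) / p.tau_ms < 0.01
        assert abs(panel.input_resistance - p.r_mohm) / p.r_mohm < 0.01
        assert abs(panel.capacitance - p.c_pf) / p.c_pf < 0.01
        ref = synth.reference_rheobase(p)
        margins = np.diff(
            sorted(a for a in cell.bundle.get(STEP_FAMILY).amplitudes if a > 0)
        ).max()
        assert abs(panel.rheobase - ref) <= margins

    @pytest.mark.parametrize("seed", range(8))
    def test_noisy_recovery_within_ten_percent(self, seed):
        p = synth.PhenotypeParams(
            name="passive", r_mohm=220.0, c_pf=90.0, e_l=-61.0, v_threshold=-42.0,
            adapt_a_ns=0.0, gh_ns=0.0, wa_max_pa=0.0, noise_sd_mv=0.2,
        )
        cell = synth.simulate_neuron(
            p, synth.make_adapted_protocols(p, include_zero=False), seed=seed
        )
        panel = features.extract_panel(cell.bundle, target_rate=1.0)
        assert abs(panel.tau - p.tau_ms) / p.tau_ms < 0.10
        assert abs(panel.input_resistance - p.r_mohm) / p.r_mohm < 0.10
        assert abs(panel.capacitance - p.c_pf) / p.c_pf < 0.10
        assert abs(panel.rheobase - p.rheobase_current()) / p.rheobase_current() < 0.10


class TestPhenotypeSeparation:
    def test_five_feature_directions_between_default_phenotypes(self):
        cells = synth.make_typed_cohort(
            {"serotonergic": 6, "dopaminergic": 6}, seed=31, include_zero=False
        )
        panels = {c.cell_id: features.extract_panel(c.bundle, c.params.target_rate_hz)
                  for c in cells}
        sero = [panels[c.cell_id] for c in cells if c.phenotype == "serotonergic"]
        dopa = [panels[c.cell_id] for c in cells if c.phenotype == "dopaminergic"]

        def mean(group, attr):
            vals = [getattr(p, attr) for p in group if getattr(p, attr) is not None]
            return np.mean(vals)

        assert mean(sero, "delay_first_spike") < mean(dopa, "delay_first_spike")
        assert abs(mean(sero, "ap_drop_rate")) < abs(mean(dopa, "ap_drop_rate"))
        assert mean(sero, "max_rise_rate") > mean(dopa, "max_rise_rate")
        assert mean(sero, "ahp_duration") > mean(dopa, "ahp_duration")
        assert mean(sero, "capacitance") > mean(dopa, "capacitance")


class TestCohorts:
    def test_zero_cells_gives_empty_list(self):
        assert synth.make_cohort(0, {"g": {}}, seed=0) == []

    def test_null_effects_are_statistically_indistinguishable(self):
        # ground-truth tau compared between two untouched groups: the gated
        # two-group test should stay non-significant in >= 90% of seeds
        n_sig = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cells = synth.make_cohort(
                15, {"a": {}, "b": {}}, seed=seed, simulate=False
            )
            groups = {
                g: np.array([c.ground_truth["tau_ms"] for c in cells if c.group == g])
                for g in ("a", "b")
            }
            if stats.compare("tau", groups).p_value < 0.05:
                n_sig += 1
        assert n_sig <= 0.1 * n_seeds

    def test_thirty_percent_tau_shift_is_detected(self):
        n_sig = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cells = synth.make_cohort(
                20, {"a": {}, "b": {"r_mohm": {"mul": 0.7}}}, seed=seed, simulate=False
            )
            groups = {
                g: np.array([c.ground_truth["tau_ms"] for c in cells if c.group == g])
                for g in ("a", "b")
            }
            if stats.compare("tau", groups).p_value < 0.05:
                n_sig += 1
        assert n_sig >= 0.9 * n_seeds

    def test_spontaneous_fraction_effect_shifts_activity(self):
        lo = synth.make_cohort(40, {"g": {"spontaneous_fraction": 0.2}},
                               seed=0, simulate=False)
        hi = synth.make_cohort(40, {"g": {"spontaneous_fraction": 0.8}},
                               seed=0, simulate=False)
        f_lo = np.mean([c.ground_truth["spontaneous"] for c in lo])
        f_hi = np.mean([c.ground_truth["spontaneous"] for c in hi])
        assert f_lo < 0.45 < f_hi


class TestMorphologyFixtures:
    @pytest.mark.parametrize("target", [1.0, 0.85, 0.6])
    def test_soma_polygon_hits_target_circularity(self, target):
        from raphephys.morpho import SomaContour, soma_metrics

        poly = synth.make_soma_polygon(target, scale=8.0, seed=3)
        m = soma_metrics(SomaContour(poly))
        assert abs(m.circularity - target) <= 0.02

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError):
            synth.make_soma_polygon(1.2)

    def test_tree_identity_example(self):
        tree = synth.make_tree(2, 3, seed=0)
        from raphephys.morpho import tree_metrics

        assert tree_metrics(tree).n_terminations == 5
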