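"""Passive-property estimators: steady state, input resistance, sag, tau,
capacitance, rheobase."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from raphephys import features, synth
from raphephys.features import (
    capacitance,
    fit_tau,
    input_resistance,
    rheobase,
    sag_amplitude,
    steady_state_voltage,
)
from raphephys.sweeps import STEP_FAMILY, ProtocolEpoch, Sweep

from conftest import FS, rc_pulse, rc_step_family, splice_spikes


class TestSteadyState:
    def test_settled_rc_response_returns_asymptote(self):
        epoch = rc_step_family(r_mohm=200.0, c_pf=100.0, amps=(-50.0,))
        ss = steady_state_voltage(epoch, epoch.sweeps[0])
        assert ss.value == pytest.approx(-70.0, abs=0.1)
        assert not ss.flagged

    def test_spiking_sweep_is_flagged(self):
        sweep = splice_spikes((0.8,), duration_s=1.5, v_base=-50.0)
        epoch = ProtocolEpoch(
            kind=STEP_FAMILY, sweeps=[sweep], holding_potential=-60.0,
            step_onset=0.2, step_offset=1.2, amplitudes=[50.0],
        )
        ss = steady_state_voltage(epoch, sweep)
        assert ss.flagged

    def test_linear_drift_gives_window_midpoint_mean(self):
        fs = FS
        t = np.arange(int(1.5 * fs) + 1) / fs
        v = -70.0 + 4.0 * t  # linear drift, 4 mV/s
        epoch = ProtocolEpoch(
            kind=STEP_FAMILY, sweeps=[Sweep(t, v, np.zeros_like(t), fs)],
            holding_potential=-60.0, step_onset=0.2, step_offset=1.2, amplitudes=[0.0],
        )
        ss = steady_state_voltage(epoch, epoch.sweeps[0])
        # mean over [0.7, 1.2] = value at the window midpoint 0.95 s
        assert ss.value == pytest.approx(-70.0 + 4.0 * 0.95, abs=1e-6)


class TestInputResistance:
    def test_exact_linear_iv_recovers_slope(self):
        epoch = rc_step_family(r_mohm=150.0, c_pf=100.0, amps=(-100, -50, 50))
        res = input_resistance(epoch)
        assert res.resolved
        assert res.value == pytest.approx(150.0, rel=1e-6)

    def test_steps_outside_range_are_excluded(self):
        # -95 and -40 mV steady states violate the [-90, -50] gate
        epoch = rc_step_family(r_mohm=200.0, c_pf=100.0,
                               amps=(-200.0, -150.0, -50.0, 25.0, 120.0))
        res = input_resistance(epoch)
        assert res.resolved
        # only -150 (-90), -50 (-70), 25 (-55) qualify; slope still exact
        assert res.value == pytest.approx(200.0, rel=1e-6)

    def test_single_qualifying_step_is_unresolved(self):
        epoch = rc_step_family(amps=(-50.0,))
        assert not input_resistance(epoch).resolved

    def test_analytic_rc_oracle_within_one_percent(self):
        epoch = rc_step_family(r_mohm=200.0, c_pf=100.0, noise_sd=0.0)
        res = input_resistance(epoch)
        assert abs(res.value - 200.0) / 200.0 < 0.01


class TestSag:
    def test_dip_then_settle_is_difference(self):
        fs = FS
        t = np.arange(int(1.5 * fs) + 1) / fs
        v = np.full_like(t, -60.0)
        in_step = (t >= 0.2) & (t <= 1.2)
        v[in_step] = -90.0
        dip = (t >= 0.25) & (t <= 0.45)
        v[dip] = -96.0
        epoch = ProtocolEpoch(
            kind=STEP_FAMILY, sweeps=[Sweep(t, v, np.zeros_like(t), fs)],
            holding_potential=-60.0, step_onset=0.2, step_offset=1.2, amplitudes=[-150.0],
        )
        res = sag_amplitude(epoch)
        assert res.resolved
        assert res.value == pytest.approx(6.0, abs=0.3)

    def test_pure_rc_has_no_sag(self):
        epoch = rc_step_family(r_mohm=200.0, c_pf=100.0, amps=(-150.0,))
        res = sag_amplitude(epoch)
        assert res.resolved
        assert res.value == pytest.approx(0.0, abs=0.05)

    def test_no_step_reaching_minus_ninety_is_unresolved(self):
        epoch = rc_step_family(amps=(-50.0, 25.0))
        assert not sag_amplitude(epoch).resolved

    def test_sag_strictly_increases_with_ih_conductance(self):
        sags = []
        for gh in (0.0, 1.0, 3.0):
            p = synth.PhenotypeParams(
                name="x", r_mohm=250, c_pf=80, e_l=-62, gh_ns=gh,
                adapt_a_ns=0.0, wa_max_pa=0.0, noise_sd_mv=0.0,
            )
            cell = synth.simulate_neuron(p, seed=0)
            sags.append(sag_amplitude(cell.bundle.get(STEP_FAMILY)).value)
        assert sags[0] == pytest.approx(0.0, abs=0.1)
        assert sags[0] < sags[1] < sags[2]


class TestTauFit:
    def test_noiseless_rc_recovery_is_exact(self):
        res = fit_tau(rc_pulse(r_mohm=200.0, c_pf=100.0))
        assert res.resolved
        assert res.tau == pytest.approx(20.0, abs=0.2)
        assert res.k0 == pytest.approx(-60.0, abs=0.1)

    def test_monte_carlo_with_noise_recovers_tau_within_five_percent(self):
        taus = []
        for seed in range(100):
            res = fit_tau(rc_pulse(noise_sd=0.3, seed=seed))
            assert res.resolved
            taus.append(res.tau)
        assert abs(np.mean(taus) - 20.0) / 20.0 < 0.05

    def test_flat_recovery_is_degenerate(self):
        epoch = rc_pulse(amp=-0.5)  # 0.02 mV deflection: no identifiable peak
        res = fit_tau(epoch)
        assert not res.resolved


class TestCapacitance:
    def test_unit_arithmetic(self):
        assert capacitance(10.0, 100.0) == pytest.approx(100.0)

    def test_zero_tau_gives_zero(self):
        assert capacitance(0.0, 100.0) == 0.0

    def test_missing_inputs_propagate(self):
        assert capacitance(None, 100.0) is None
        assert capacitance(10.0, None) is None

    @given(
        tau=st.floats(0.1, 500.0, allow_nan=False),
        r=st.floats(10.0, 2000.0, allow_nan=False),
    )
    def test_identity_c_equals_tau_over_r(self, tau, r):
        c = capacitance(tau, r)
        assert c == pytest.approx(tau / r * 1000.0, rel=1e-12)


class TestRheobase:
    def _family(self, amps, spiking_amps):
        sweeps = []
        for a in amps:
            if a in spiking_amps:
                sw = splice_spikes((0.6,), duration_s=1.5)
            else:
                sw = splice_spikes((), duration_s=1.5)
            sweeps.append(sw)
        return ProtocolEpoch(
            kind=STEP_FAMILY, sweeps=sweeps, holding_potential=-60.0,
            step_onset=0.2, step_offset=1.2, amplitudes=list(amps),
        )

    def test_minimum_of_spiking_set(self):
        res = rheobase(self._family((25.0, 50.0, 75.0), {50.0, 75.0}))
        assert res.resolved
        assert res.value == 50.0

    def test_all_spiking_flags_lower_bound(self):
        res = rheobase(self._family((25.0, 50.0), {25.0, 50.0}))
        assert res.value == 25.0
        assert "lower-bound" in res.note

    def test_no_spiking_sweep_is_unresolved(self):
        res = rheobase(self._family((25.0, 50.0), set()))
        assert not res.resolved

    def test_lif_closed_form_within_one_increment(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            r = rng.uniform(150, 450)
            theta = rng.uniform(-46, -40)
            p = synth.PhenotypeParams(
                name="lif", r_mohm=r, c_pf=rng.uniform(40, 110), e_l=-60.0,
                v_threshold=theta, v_reset=-55.0, adapt_a_ns=0.0, adapt_b_pa=0.0,
                ahp_increment_pa=0.0, gh_ns=0.0, wa_max_pa=0.0,
                noise_sd_mv=0.0, droop_mv_per_pa=0.0,
            )
            closed = (theta + 60.0) * 1000.0 / r
            inc = max(2.0, 0.05 * closed)
            protocols = synth.make_protocols(
                {"skip_zero": True, "skip_ramp": True, "skip_pulse": True}
            )
            protocols["steps"]["amplitudes_pa"] = [
                closed + (j - 4 + 0.5) * inc for j in range(9)
            ]
            cell = synth.simulate_neuron(p, protocols, seed=0)
            res = rheobase(cell.bundle.get(STEP_FAMILY))
            assert res.resolved
            assert abs(res.value - closed) <= inc * (1 + 1e-9)
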