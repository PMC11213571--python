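import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from raphephys.sweeps import (
    BRIEF_PULSE,
    STEP_FAMILY,
    ProtocolEpoch,
    Sweep,
)
from raphephys.synth import analytic_rc_response

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 20_000.0


def make_flat_sweep(duration_s=1.0, level_mv=-60.0, noise_sd=0.0, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    v = np.full(n, level_mv)
    if noise_sd:
        v = v + rng.normal(0.0, noise_sd, n)
    return Sweep(time=t, voltage=v, current=np.zeros(n), sampling_rate=fs)


def spike_template(fs=FS, v_base=-60.0, v_thresh=-45.0, rise_vps=300.0, v_peak=20.0,
                   ahp_depth=10.0, ahp_tau_ms=30.0, tail_ms=400.0):
    """A stylized AP waveform sampled on the grid: sharp rise at *rise_vps*,
    linear fall to (base - ahp_depth), exponential AHP recovery to base."""
    dt = 1.0 / fs
    rise = np.arange(v_thresh, v_peak, rise_vps * 1000 * dt)
    fall = np.arange(v_peak, v_base - ahp_depth, -rise_vps * 500 * dt)
    n_tail = int(round(tail_ms / 1000 * fs))
    t_tail = np.arange(n_tail) * dt
    tail = v_base - ahp_depth * np.exp(-t_tail / (ahp_tau_ms / 1000.0))
    return np.concatenate([rise, fall, tail])


def splice_spikes(spike_times_s, duration_s=10.0, v_base=-60.0, fs=FS, **tmpl_kw):
    """Flat trace with template spikes pasted at known onset times."""
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    v = np.full(n, v_base)
    tmpl = spike_template(fs=fs, v_base=v_base, **tmpl_kw)
    for ts in spike_times_s:
        i = int(round(ts * fs))
        seg = tmpl[: n - i]
        v[i:i + len(seg)] = seg
    return Sweep(time=t, voltage=v, current=np.zeros(n), sampling_rate=fs)


def rc_step_family(r_mohm=200.0, c_pf=100.0, amps=(-150, -100, -50, -25, 25, 50),
                   noise_sd=0.0, seed=0, e_l=-60.0, fs=FS):
    """Analytic passive-membrane responses to a 1-s step family."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(1.5 * fs) + 1) / fs
    sweeps = []
    for a in amps:
        v = analytic_rc_response(r_mohm, c_pf, a, t, e_l=e_l, t_onset=0.2, t_offset=1.2)
        if noise_sd:
            v = v + rng.normal(0.0, noise_sd, v.shape)
        i = np.zeros_like(t)
        i[(t >= 0.2) & (t < 1.2)] = a
        sweeps.append(Sweep(t, v, i, fs))
    return ProtocolEpoch(
        kind=STEP_FAMILY, sweeps=sweeps, holding_potential=e_l,
        step_onset=0.2, step_offset=1.2, amplitudes=list(map(float, amps)),
    )


def rc_pulse(r_mohm=200.0, c_pf=100.0, amp=-50.0, noise_sd=0.0, seed=0,
             e_l=-60.0, fs=FS):
    """Analytic response to the 5-ms hyperpolarizing pulse."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(0.5 * fs) + 1) / fs
    v = analytic_rc_response(r_mohm, c_pf, amp, t, e_l=e_l, t_onset=0.1, t_offset=0.105)
    if noise_sd:
        v = v + rng.normal(0.0, noise_sd, v.shape)
    i = np.zeros_like(t)
    i[(t >= 0.1) & (t < 0.105)] = amp
    return ProtocolEpoch(
        kind=BRIEF_PULSE, sweeps=[Sweep(t, v, i, fs)], holding_potential=e_l,
        step_onset=0.1, step_offset=0.105, amplitudes=[amp],
    )


@pytest.fixture(scope="session")
def serotonergic_cell():
    from raphephys.synth import PHENOTYPES, simulate_neuron

    return simulate_neuron(PHENOTYPES["serotonergic"], seed=11, cell_id="s11")


@pytest.fixture(scope="session")
def dopaminergic_cell():
    from raphephys.synth import PHENOTYPES, simulate_neuron

    return simulate_neuron(PHENOTYPES["dopaminergic"], seed=12, cell_id="d12")
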