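"""Synthetic current-clamp data with known ground truth.

The generator integrates an adaptive leaky integrate-and-fire neuron
(exponential-Euler update on the membrane equation, dt = 0.05 ms) with

* a stylized AP template (parametrized rise rate, peak, width) pasted at
  threshold crossings, giving exact ground truth for amplitude, duration,
  rise rate and ramp-evoked amplitude droop;
* a spike-triggered outward AHP current with exponential decay (sets AHP
  amplitude and duration);
* a subthreshold adaptation current (slow ramp-to-spike, long first-spike
  delays);
* an Ih-like conductance activated by hyperpolarization (sag and rebound);
* additive Gaussian measurement noise on the voltage (default 0.2 mV SD).

Two default phenotypes emulate the serotonergic ("large capacitance, fast
AP rise, long AHP, short spike delay, constant AP amplitude") and
dopaminergic ("small capacitance, long ramping spike delay, AP amplitude
droop, sag, rebound") profiles of dorsal-raphe neurons; two further presets
(rebound-spiking interneuron-like, slow-regular) support four-type
clustering experiments. Cohort builders apply multiplicative/additive
group effects with between-cell lognormal variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .swc import DENDRITE_TYPE, SOMA_TYPE, DendriteTree
from .sweeps import (
    BRIEF_PULSE,
    RAMP_FAMILY,
    STEP_FAMILY,
    ZERO_CURRENT,
    ProtocolEpoch,
    Sweep,
    SweepBundle,
)

DT_MS = 0.05              # reference integration grid
DEFAULT_SAMPLING_HZ = 20_000.0
HOLDING_MV = -60.0

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@dataclass(frozen=True)
class PhenotypeParams:
    """Simulator parameter set for one electrophysiological phenotype.

    Membrane: resistance R (MOhm), capacitance C (pF) -> tau = R*C (us scale,
    exposed in ms), leak reversal E_L (mV). Spiking: threshold and the AP
    template (rise V/s, peak mV, width ms as onset-to-offset duration),
    post-spike reset voltage. Adaptation: subthreshold coupling a (nS),
    spike increment b (pA), time constant (ms). AHP: spike-triggered outward
    current increment (pA) and decay (ms). Droop: AP peak reduction per pA
    of instantaneous command above holding (mV/pA). Ih: conductance gh (nS)
    with fixed activation curve (half -80 mV, slope 6 mV, tau 150 ms,
    reversal -30 mV). drive_pA is a constant intrinsic depolarizing current
    setting spontaneous activity.
    """

    name: str = "custom"
    r_mohm: float = 250.0
    c_pf: float = 80.0
    e_l: float = -62.0
    v_threshold: float = -42.0
    v_reset: float = -52.0
    adapt_a_ns: float = 0.5
    adapt_b_pa: float = 12.0
    adapt_tau_ms: float = 250.0
    ahp_increment_pa: float = 50.0
    ahp_tau_ms: float = 120.0
    droop_mv_per_pa: float = 0.01
    # A-type-like transient outward current: instantaneous sigmoidal
    # activation (on with depolarization), slow inactivation with tau_a;
    # de-inactivated at rest, it clamps the step response below threshold
    # until it inactivates -> long, ramping first-spike delays
    wa_max_pa: float = 0.0
    va_act_half_mv: float = -50.0
    va_act_slope_mv: float = 4.0
    va_inact_half_mv: float = -55.0
    va_inact_slope_mv: float = 6.0
    tau_a_ms: float = 150.0
    gh_ns: float = 0.3
    eh_mv: float = -30.0
    vh_half_mv: float = -80.0
    vh_slope_mv: float = 6.0
    tau_h_ms: float = 150.0
    drive_pa: float = 0.0
    ap_rise_vps: float = 300.0
    ap_peak_mv: float = 25.0
    ap_width_ms: float = 2.5
    noise_sd_mv: float = 0.2
    sampling_hz: float = DEFAULT_SAMPLING_HZ
    target_rate_hz: float = 1.0

    def __post_init__(self):
        for f_ in ("r_mohm", "c_pf", "adapt_tau_ms", "ahp_tau_ms", "tau_h_ms",
                   "ap_rise_vps", "ap_width_ms", "sampling_hz"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be positive")
        if self.ap_peak_mv <= self.v_threshold:
            raise ValueError("AP peak must exceed threshold")

    @property
    def tau_ms(self) -> float:
        return self.r_mohm * self.c_pf / 1000.0

    @property
    def gl_ns(self) -> float:
        return 1000.0 / self.r_mohm

    def h_inf(self, v: float) -> float:
        x = (v - self.vh_half_mv) / self.vh_slope_mv
        return 1.0 / (1.0 + math.exp(min(60.0, max(-60.0, x))))

    def a_act(self, v: float) -> float:
        """Instantaneous activation of the A-type-like current."""
        x = (self.va_act_half_mv - v) / self.va_act_slope_mv
        return 1.0 / (1.0 + math.exp(min(60.0, max(-60.0, x))))

    def a_inact_inf(self, v: float) -> float:
        """Steady-state inactivation gate (1 = fully primed)."""
        x = (v - self.va_inact_half_mv) / self.va_inact_slope_mv
        return 1.0 / (1.0 + math.exp(min(60.0, max(-60.0, x))))

    def wa_inf(self, v: float) -> float:
        """Steady-state (window) A-type-like outward current (pA)."""
        if self.wa_max_pa == 0.0:
            return 0.0
        return self.wa_max_pa * self.a_act(v) * self.a_inact_inf(v)

    def steady_state_current(self, v: float) -> float:
        """Injected current (pA) whose steady state sits at voltage *v*."""
        return (
            self.gl_ns * (v - self.e_l)
            + self.adapt_a_ns * (v - self.e_l)
            + self.wa_inf(v)
            - self.gh_ns * self.h_inf(v) * (self.eh_mv - v)
        )

    def rheobase_current(self, holding: float = HOLDING_MV) -> float:
        """Asymptotic rheobase (pA) relative to the holding level: the
        largest steady-state current barrier between holding and threshold
        (equals I_ss(threshold) - I_ss(holding) for a monotone I-V)."""
        grid = np.linspace(holding, self.v_threshold, 200)
        barrier = max(self.steady_state_current(float(v)) for v in grid)
        return barrier - self.steady_state_current(holding)

    def current_for_voltage(self, v_target: float, holding: float = HOLDING_MV) -> float:
        """Step amplitude (pA, relative to holding) whose steady state is
        *v_target*."""
        return self.steady_state_current(v_target) - self.steady_state_current(holding)

    def template_duration_ms(self, peak: float | None = None) -> float:
        peak = self.ap_peak_mv if peak is None else peak
        t_rise = (peak - self.v_threshold) / self.ap_rise_vps  # mV / (mV/ms)
        fall_rate = (peak - self.v_threshold) / max(1e-3, self.ap_width_ms - t_rise)
        return t_rise + (peak - self.v_reset) / fall_rate


#: default phenotype presets
PHENOTYPES: dict[str, PhenotypeParams] = {
    "serotonergic": PhenotypeParams(
        name="serotonergic", r_mohm=250.0, c_pf=80.0, e_l=-62.0,
        v_threshold=-42.0, v_reset=-52.0,
        adapt_a_ns=0.5, adapt_b_pa=12.0, adapt_tau_ms=250.0,
        ahp_increment_pa=55.0, ahp_tau_ms=200.0,
        droop_mv_per_pa=0.01, gh_ns=0.3,
        ap_rise_vps=300.0, ap_peak_mv=25.0, ap_width_ms=2.5,
        target_rate_hz=1.0,
    ),
    "dopaminergic": PhenotypeParams(
        name="dopaminergic", r_mohm=500.0, c_pf=35.0, e_l=-58.0,
        v_threshold=-42.0, v_reset=-50.0,
        adapt_a_ns=0.5, adapt_b_pa=10.0, adapt_tau_ms=2000.0,
        ahp_increment_pa=60.0, ahp_tau_ms=25.0,
        droop_mv_per_pa=0.08,
        wa_max_pa=160.0, tau_a_ms=80.0,
        va_inact_half_mv=-62.0, va_inact_slope_mv=4.0,
        gh_ns=0.4,
        ap_rise_vps=130.0, ap_peak_mv=15.0, ap_width_ms=3.5,
        target_rate_hz=2.0,
    ),
    "interneuron": PhenotypeParams(
        name="interneuron", r_mohm=300.0, c_pf=25.0, e_l=-60.0,
        v_threshold=-46.0, v_reset=-54.0,
        adapt_a_ns=1.0, adapt_b_pa=35.0, adapt_tau_ms=250.0,
        ahp_increment_pa=80.0, ahp_tau_ms=15.0,
        droop_mv_per_pa=0.02, gh_ns=2.6, tau_h_ms=100.0,
        ap_rise_vps=400.0, ap_peak_mv=30.0, ap_width_ms=1.2,
        target_rate_hz=2.0,
    ),
    "slow_regular": PhenotypeParams(
        name="slow_regular", r_mohm=350.0, c_pf=45.0, e_l=-61.0,
        v_threshold=-43.0, v_reset=-51.0,
        adapt_a_ns=1.5, adapt_b_pa=15.0, adapt_tau_ms=300.0,
        ahp_increment_pa=45.0, ahp_tau_ms=80.0,
        droop_mv_per_pa=0.015, gh_ns=0.8,
        ap_rise_vps=200.0, ap_peak_mv=20.0, ap_width_ms=2.8,
        target_rate_hz=1.0,
    ),
}

#: default spontaneous fraction per phenotype (slice conditions)
SPONT_FRACTION = {
    "serotonergic": 0.37,
    "dopaminergic": 0.58,
    "interneuron": 0.30,
    "slow_regular": 0.50,
}


# ---------------------------------------------------------------------------
# integrator


def _integrate_py(
    i_input, dt, v0, w0, h0, ha0,
    gl, c, el, a, tau_w, b, ahp_inc, tau_ahp,
    gh, eh, vh_half, vh_slope, tau_h,
    wa_max, va_act_half, va_act_slope, va_inact_half, va_inact_slope, tau_a,
    theta, v_reset, peak, rise, fall_rate, droop, i_ref,
):
    n = i_input.shape[0]
    v_out = np.empty(n)
    spike_idx = np.empty(n // 4 + 8, dtype=np.int64)
    n_spk = 0
    ew = math.exp(-dt / tau_w)
    eahp = math.exp(-dt / tau_ahp)
    ehh = 1.0 - math.exp(-dt / tau_h)
    ea = 1.0 - math.exp(-dt / tau_a)
    v = v0
    w = w0
    wahp = 0.0
    h = h0
    ha = ha0
    v_out[0] = v
    i = 1
    while i < n:
        ia = 0.0
        if wa_max > 0.0:
            xact = (va_act_half - v) / va_act_slope
            if xact > 60.0:
                xact = 60.0
            elif xact < -60.0:
                xact = -60.0
            ia = wa_max * ha / (1.0 + math.exp(xact))
        g_tot = gl + gh * h
        v_inf = (gl * el + gh * h * eh - w - wahp - ia + i_input[i - 1]) / g_tot
        v_new = v_inf + (v - v_inf) * math.exp(-dt * g_tot / c)
        # gate updates from the pre-step voltage
        x = (v - vh_half) / vh_slope
        if x > 60.0:
            x = 60.0
        elif x < -60.0:
            x = -60.0
        hinf = 1.0 / (1.0 + math.exp(x))
        h += (hinf - h) * ehh
        if wa_max > 0.0:
            xa = (v - va_inact_half) / va_inact_slope
            if xa > 60.0:
                xa = 60.0
            elif xa < -60.0:
                xa = -60.0
            ha += (1.0 / (1.0 + math.exp(xa)) - ha) * ea
        w_target = a * (v - el)
        w = w_target + (w - w_target) * ew
        wahp *= eahp
        v = v_new
        if v < theta:
            v_out[i] = v
            i += 1
            continue
        # threshold crossing: paste the AP template
        spike_idx[n_spk] = i
        n_spk += 1
        i_cross = i
        rel = i_input[i] - i_ref
        if rel < 0.0:
            rel = 0.0
        peak_eff = peak - droop * rel
        if peak_eff < theta + 5.0:
            peak_eff = theta + 5.0
        n_r = int(round((peak_eff - theta) / (rise * dt)))
        if n_r < 1:
            n_r = 1
        rise_step = (peak_eff - theta) / n_r
        vv = theta
        for k in range(n_r):
            if i >= n:
                break
            vv += rise_step
            if k == n_r - 1:
                vv = peak_eff
            v_out[i] = vv
            i += 1
        while i < n and vv > v_reset:
            vv -= fall_rate * dt
            if vv < v_reset:
                vv = v_reset
            v_out[i] = vv
            i += 1
        elapsed = (i - i_cross) * dt
        w = w * math.exp(-elapsed / tau_w) + b
        wahp = wahp * math.exp(-elapsed / tau_ahp) + ahp_inc
        ha = ha * math.exp(-elapsed / tau_a)  # inactivates at spike voltages
        v = v_reset
    return v_out, spike_idx[:n_spk]


_integrate = njit(cache=True)(_integrate_py) if _HAVE_NUMBA else _integrate_py


def _run(
    params: PhenotypeParams, i_input: np.ndarray, v0: float, w0: float, h0: float,
    ha0: float | None = None,
):
    p = params
    t_rise = (p.ap_peak_mv - p.v_threshold) / p.ap_rise_vps
    fall_rate = (p.ap_peak_mv - p.v_threshold) / max(1e-3, p.ap_width_ms - t_rise)
    i_ref = float(i_input[0])
    if ha0 is None:
        ha0 = p.a_inact_inf(v0)
    v, spikes = _integrate(
        np.ascontiguousarray(i_input, dtype=np.float64), DT_MS, v0, w0, h0, ha0,
        p.gl_ns, p.c_pf, p.e_l, p.adapt_a_ns, p.adapt_tau_ms, p.adapt_b_pa,
        p.ahp_increment_pa, p.ahp_tau_ms,
        p.gh_ns, p.eh_mv, p.vh_half_mv, p.vh_slope_mv, p.tau_h_ms,
        p.wa_max_pa, p.va_act_half_mv, p.va_act_slope_mv,
        p.va_inact_half_mv, p.va_inact_slope_mv, p.tau_a_ms,
        p.v_threshold, p.v_reset, p.ap_peak_mv, p.ap_rise_vps, fall_rate,
        p.droop_mv_per_pa, i_ref,
    )
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(f"numerical blow-up simulating {params}")
    return v, spikes


# ---------------------------------------------------------------------------
# protocols


def make_protocols(config: dict | None = None) -> dict:
    """Build the stimulus-protocol set.

    Defaults: a 10-s zero-current recording; a family of 1-s steps from
    -100 to +150 pA in 25-pA increments at -60 mV holding; a 0-to-300 pA
    ramp over 2 s; a 5-ms, -50 pA hyperpolarizing pulse. ``config`` can
    override any entry (e.g. ``{"step_increment_pa": 10}``).
    """
    cfg = dict(config or {})
    inc = float(cfg.pop("step_increment_pa", 25.0))
    lo = float(cfg.pop("step_min_pa", -100.0))
    hi = float(cfg.pop("step_max_pa", 150.0))
    n = int(round((hi - lo) / inc)) + 1
    protocols = {
        "sampling_hz": float(cfg.pop("sampling_hz", DEFAULT_SAMPLING_HZ)),
        "zero": {"duration_s": float(cfg.pop("zero_duration_s", 10.0))},
        "steps": {
            "pre_s": 0.2, "dur_s": 1.0, "post_s": 0.3,
            "amplitudes_pa": [lo + k * inc for k in range(n)],
        },
        "ramp": {"pre_s": 0.2, "dur_s": float(cfg.pop("ramp_duration_s", 2.0)),
                 "post_s": 0.3, "peak_pa": float(cfg.pop("ramp_peak_pa", 300.0))},
        "pulse": {"pre_s": 0.2, "dur_s": 0.005, "post_s": 0.3,
                  "amplitude_pa": float(cfg.pop("pulse_amplitude_pa", -50.0))},
    }
    for key in ("zero", "steps", "ramp", "pulse"):
        if key in cfg:
            protocols[key] = cfg.pop(key)
        if cfg.pop(f"skip_{key}", False):
            protocols.pop(key)
    if cfg:
        raise ValueError(f"unknown protocol config keys: {sorted(cfg)}")
    return protocols


#: suprathreshold amplitude ladder as multiples of the analytic rheobase;
#: emulates the per-cell scaling of step amplitudes to a test pulse evoking
#: one to two APs, so a rate-matched (1-2 spikes / s) sweep exists
SUPRA_MARGINS = (0.93, 0.96, 0.985, 1.01, 1.03, 1.06, 1.10, 1.15, 1.25, 1.40, 1.60, 1.85)
FINE_MARGINS = (0.97, 0.99, 1.005, 1.01, 1.02, 1.04, 1.08, 1.15, 1.3, 1.5)


def make_adapted_protocols(
    params: PhenotypeParams,
    fine_rheobase: bool = False,
    include_zero: bool = True,
    config: dict | None = None,
) -> dict:
    """Per-cell scaled protocols: hyperpolarizing steps targeting -90/-80/-72
    mV steady state (the -90 one qualifies for sag), subthreshold steps at
    0.4/0.7/0.9 of the analytic rheobase, and a suprathreshold ladder of
    rheobase multiples."""
    protocols = make_protocols(config)
    if not include_zero:
        protocols.pop("zero", None)
    i_theta = params.rheobase_current()
    hyper = [params.current_for_voltage(v) for v in (-90.0, -80.0, -72.0)]
    sub = [f * i_theta for f in (0.4, 0.7)]
    margins = FINE_MARGINS if fine_rheobase else SUPRA_MARGINS
    supra = [m * i_theta for m in margins]
    protocols["steps"]["amplitudes_pa"] = [round(a, 2) for a in hyper + sub + supra]
    protocols["ramp"]["peak_pa"] = round(max(300.0, 2.5 * i_theta), 1)
    return protocols


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SyntheticCell:
    """A simulated cell: parameters, generated bundle, and ground truth."""

    params: PhenotypeParams
    bundle: SweepBundle | None
    ground_truth: dict
    cell_id: str = "cell"
    group: str = "none"
    phenotype: str = "custom"


def _resting_state(params: PhenotypeParams) -> tuple[float, float, float, bool]:
    """(v0, w0, h0, spontaneous) with zero injected current."""
    p = params

    def f(v):
        return (
            p.gl_ns * (p.e_l - v)
            + p.gh_ns * p.h_inf(v) * (p.eh_mv - v)
            - p.adapt_a_ns * (v - p.e_l)
            - p.wa_inf(v)
            + p.drive_pa
        )

    if f(p.v_threshold) > 0:  # no resting point below threshold: tonic firing
        return p.v_reset, 0.0, p.h_inf(p.e_l), True
    v_rest = optimize.brentq(f, -120.0, p.v_threshold)
    return v_rest, p.adapt_a_ns * (v_rest - p.e_l), p.h_inf(v_rest), False


def _held_state(params: PhenotypeParams, holding: float = HOLDING_MV):
    return holding, params.adapt_a_ns * (holding - params.e_l), params.h_inf(holding)


def _decimate(arr: np.ndarray, factor: int) -> np.ndarray:
    return arr[::factor] if factor > 1 else arr


def simulate_neuron(
    params: PhenotypeParams,
    protocols: dict | None = None,
    seed: int = 0,
    cell_id: str = "cell",
    group: str = "none",
) -> SyntheticCell:
    """Simulate the full protocol set for one cell and return the bundle
    plus analytic ground truth. Deterministic for fixed (params, protocols,
    seed)."""
    p = params
    if protocols is None:
        protocols = make_adapted_protocols(p)
    rng = np.random.default_rng(seed)
    fs = float(protocols.get("sampling_hz", p.sampling_hz))
    factor = int(round(20_000.0 / fs * (DT_MS / 0.05)))
    if not math.isclose(20_000.0 / factor, fs, rel_tol=1e-6):
        raise ValueError(f"sampling_hz {fs} must divide the 20 kHz reference grid")
    dt_s = DT_MS / 1000.0
    i_hold_abs = p.steady_state_current(HOLDING_MV) - p.drive_pa

    def build_sweep(i_cmd: np.ndarray, v0, w0, h0) -> Sweep:
        v, _ = _run(p, i_cmd + p.drive_pa, v0, w0, h0)
        if p.noise_sd_mv > 0:
            v = v + rng.normal(0.0, p.noise_sd_mv, size=v.shape)
        v = _decimate(v, factor)
        i_rec = _decimate(i_cmd, factor)
        time = np.arange(len(v)) / fs
        return Sweep(time=time, voltage=v, current=i_rec, sampling_rate=fs)

    epochs: dict[str, ProtocolEpoch] = {}

    if "zero" in protocols:
        n = int(round(protocols["zero"]["duration_s"] / dt_s)) + 1
        v0, w0, h0, _ = _resting_state(p)
        sweep = build_sweep(np.zeros(n), v0, w0, h0)
        epochs[ZERO_CURRENT] = ProtocolEpoch(kind=ZERO_CURRENT, sweeps=[sweep])

    v0h, w0h, h0h = _held_state(p)

    if "steps" in protocols:
        spec = protocols["steps"]
        pre, dur, post = spec["pre_s"], spec["dur_s"], spec["post_s"]
        n_pre, n_dur = int(round(pre / dt_s)), int(round(dur / dt_s))
        n_tot = n_pre + n_dur + int(round(post / dt_s))
        sweeps = []
        for amp in spec["amplitudes_pa"]:
            i_cmd = np.full(n_tot, i_hold_abs)
            i_cmd[n_pre:n_pre + n_dur] += amp
            sweeps.append(build_sweep(i_cmd, v0h, w0h, h0h))
        epochs[STEP_FAMILY] = ProtocolEpoch(
            kind=STEP_FAMILY, sweeps=sweeps, holding_potential=HOLDING_MV,
            step_onset=pre, step_offset=pre + dur,
            amplitudes=list(spec["amplitudes_pa"]),
        )

    if "ramp" in protocols:
        spec = protocols["ramp"]
        pre, dur, post = spec["pre_s"], spec["dur_s"], spec["post_s"]
        n_pre, n_dur = int(round(pre / dt_s)), int(round(dur / dt_s))
        n_tot = n_pre + n_dur + int(round(post / dt_s))
        i_cmd = np.full(n_tot, i_hold_abs)
        i_cmd[n_pre:n_pre + n_dur] += np.linspace(0.0, spec["peak_pa"], n_dur)
        epochs[RAMP_FAMILY] = ProtocolEpoch(
            kind=RAMP_FAMILY, sweeps=[build_sweep(i_cmd, v0h, w0h, h0h)],
            holding_potential=HOLDING_MV,
            step_onset=pre, step_offset=pre + dur, amplitudes=[spec["peak_pa"]],
        )

    if "pulse" in protocols:
        spec = protocols["pulse"]
        pre, dur, post = spec["pre_s"], spec["dur_s"], spec["post_s"]
        n_pre, n_dur = int(round(pre / dt_s)), int(round(dur / dt_s))
        n_tot = n_pre + n_dur + int(round(post / dt_s))
        i_cmd = np.full(n_tot, i_hold_abs)
        i_cmd[n_pre:n_pre + n_dur] += spec["amplitude_pa"]
        epochs[BRIEF_PULSE] = ProtocolEpoch(
            kind=BRIEF_PULSE, sweeps=[build_sweep(i_cmd, v0h, w0h, h0h)],
            holding_potential=HOLDING_MV,
            step_onset=pre, step_offset=pre + dur, amplitudes=[spec["amplitude_pa"]],
        )

    bundle = SweepBundle(
        cell_id=cell_id, epochs=epochs, group=group, putative_type=p.name,
        metadata={"seed": int(seed), "phenotype": p.name},
    )
    _, _, _, spont = _resting_state(p)
    truth = {
        "tau_ms": p.tau_ms,
        "input_resistance_mohm": p.r_mohm,
        "capacitance_pf": p.c_pf,
        "rheobase_pa": p.rheobase_current(),
        "drop_rate_mv_per_pa": -p.droop_mv_per_pa,
        "ap_amplitude_mv": p.ap_peak_mv - p.v_threshold,
        "ap_rise_vps": p.ap_rise_vps,
        "ap_width_ms": p.ap_width_ms,
        "spontaneous": spont,
        "drive_pa": p.drive_pa,
    }
    return SyntheticCell(params=p, bundle=bundle, ground_truth=truth,
                         cell_id=cell_id, group=group, phenotype=p.name)


def reference_rheobase(params: PhenotypeParams, tol_pa: float = 0.25) -> float:
    """Noiseless-simulation rheobase (pA relative to holding) of a 1-s step,
    located by bisection; the protocol-dependent counterpart of the analytic
    asymptotic value."""
    p = replace(params, noise_sd_mv=0.0)
    v0, w0, h0 = _held_state(p)
    i_hold_abs = p.steady_state_current(HOLDING_MV) - p.drive_pa
    n_pre, n_dur = int(round(0.2 / (DT_MS / 1000))), int(round(1.0 / (DT_MS / 1000)))

    def spikes(amp: float) -> bool:
        i_cmd = np.full(n_pre + n_dur, i_hold_abs + p.drive_pa)
        i_cmd[n_pre:] += amp
        _, spk = _run(p, i_cmd, v0, w0, h0)
        return len(spk) > 0

    i0 = p.rheobase_current()
    lo, hi = 0.7 * i0, 1.6 * i0
    while not spikes(hi):
        hi *= 1.5
        if hi > 20 * i0:
            raise RuntimeError("reference rheobase search failed")
    while hi - lo > tol_pa:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi


def analytic_rc_response(
    r_mohm: float,
    c_pf: float,
    i_step_pa: float,
    t: np.ndarray,
    e_l: float = HOLDING_MV,
    t_onset: float = 0.0,
    t_offset: float | None = None,
) -> np.ndarray:
    """Closed-form passive RC membrane response to a current step:
    ``V = E_L + I*R*(1 - exp(-(t-t_onset)/tau))`` during the step, symmetric
    exponential decay after it. Times in s, output in mV."""
    t = np.asarray(t, float)
    tau_s = r_mohm * c_pf * 1e-6  # MOhm * pF = us
    v_inf = i_step_pa * r_mohm / 1000.0  # mV deflection
    v = np.full_like(t, e_l)
    on = t >= t_onset
    v[on] = e_l + v_inf * (1.0 - np.exp(-(t[on] - t_onset) / tau_s))
    if t_offset is not None:
        off = t >= t_offset
        v_at_off = e_l + v_inf * (1.0 - math.exp(-(t_offset - t_onset) / tau_s))
        v[off] = e_l + (v_at_off - e_l) * np.exp(-(t[off] - t_offset) / tau_s)
    return v


# ---------------------------------------------------------------------------
# cohorts


_VARIABLE_FIELDS = ("r_mohm", "c_pf", "ahp_increment_pa", "ahp_tau_ms", "adapt_b_pa")


def apply_effects(params: PhenotypeParams, effects: dict) -> PhenotypeParams:
    """Apply group effects: ``{"tau_field": {"mul": 0.7}}`` or ``{"e_l":
    {"add": 3.0}}`` on any PhenotypeParams field."""
    updates = {}
    for name, eff in effects.items():
        val = getattr(params, name)
        if "mul" in eff:
            val = val * eff["mul"]
        if "add" in eff:
            val = val + eff["add"]
        updates[name] = val
    return replace(params, **updates) if updates else params


def draw_cell_params(
    base: PhenotypeParams,
    rng: np.random.Generator,
    cv: float = 0.12,
    spontaneous_fraction: float | None = None,
    margin_sigma: float = 0.3,
) -> PhenotypeParams:
    """One cell's parameters: lognormal between-cell variability on the
    passive/AHP/adaptation magnitudes, and a spontaneous drive drawn so that
    the population fraction of cells whose drive exceeds the from-rest
    rheobase equals *spontaneous_fraction*."""
    updates = {
        f: getattr(base, f) * rng.lognormal(0.0, cv) for f in _VARIABLE_FIELDS
    }
    if base.droop_mv_per_pa > 0:
        updates["droop_mv_per_pa"] = base.droop_mv_per_pa * rng.lognormal(0.0, cv)
    if spontaneous_fraction is None:
        spontaneous_fraction = SPONT_FRACTION.get(base.name, 0.4)
    cell = replace(base, **updates)
    # current needed to fire from rest (no holding): steady state at threshold
    i_crit = cell.steady_state_current(cell.v_threshold)
    from scipy.stats import norm

    mu = margin_sigma * norm.ppf(spontaneous_fraction)
    margin = rng.lognormal(mu, margin_sigma)
    return replace(cell, drive_pa=margin * i_crit)


def make_cohort(
    n_per_group: int | dict,
    group_effects: dict | None = None,
    seed: int = 0,
    phenotype: PhenotypeParams | str = "serotonergic",
    cv: float = 0.12,
    spontaneous_fraction: float | None = None,
    simulate: bool = True,
    include_zero: bool = True,
) -> list[SyntheticCell]:
    """Generate labeled cells for one phenotype across treatment groups.

    *group_effects* maps group label -> field effects (see
    :func:`apply_effects`); an int *n_per_group* is applied to every group.
    With ``simulate=False`` only parameters and ground truth are drawn
    (fast path for statistical-power experiments on true values).
    """
    if isinstance(phenotype, str):
        phenotype = PHENOTYPES[phenotype]
    group_effects = group_effects or {"none": {}}
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in group_effects}
    ss = np.random.SeedSequence(seed)
    cells: list[SyntheticCell] = []
    for group, effects in group_effects.items():
        effects = dict(effects)
        group_spont = effects.pop("spontaneous_fraction", spontaneous_fraction)
        base = apply_effects(phenotype, effects)
        n = n_per_group.get(group, 0)
        child_seeds = ss.spawn(1)[0].generate_state(2 * max(n, 1))
        for k in range(n):
            rng = np.random.default_rng(child_seeds[2 * k])
            cell_params = draw_cell_params(
                base, rng, cv=cv, spontaneous_fraction=group_spont
            )
            cid = f"{phenotype.name}_{group}_{k:03d}"
            if simulate:
                protocols = make_adapted_protocols(cell_params, include_zero=include_zero)
                cell = simulate_neuron(
                    cell_params, protocols,
                    seed=int(child_seeds[2 * k + 1] % (2**31)),
                    cell_id=cid, group=group,
                )
            else:
                _, _, _, spont = _resting_state(cell_params)
                cell = SyntheticCell(
                    params=cell_params, bundle=None,
                    ground_truth={
                        "tau_ms": cell_params.tau_ms,
                        "input_resistance_mohm": cell_params.r_mohm,
                        "capacitance_pf": cell_params.c_pf,
                        "rheobase_pa": cell_params.rheobase_current(),
                        "drop_rate_mv_per_pa": -cell_params.droop_mv_per_pa,
                        "ap_amplitude_mv": cell_params.ap_peak_mv - cell_params.v_threshold,
                        "spontaneous": spont,
                    },
                    cell_id=cid, group=group, phenotype=phenotype.name,
                )
            cells.append(cell)
    return cells


def make_typed_cohort(
    n_per_type: dict[str, int],
    seed: int = 0,
    cv: float = 0.12,
    simulate: bool = True,
    include_zero: bool = True,
) -> list[SyntheticCell]:
    """Cells drawn from several phenotype presets (for cell-type
    classification experiments); keys of *n_per_type* name presets in
    :data:`PHENOTYPES`."""
    ss = np.random.SeedSequence(seed)
    subseeds = ss.generate_state(len(n_per_type))
    cells = []
    for sub, (name, n) in zip(subseeds, sorted(n_per_type.items())):
        cells.extend(
            make_cohort(
                {"none": n}, {"none": {}}, seed=int(sub % (2**31)),
                phenotype=name, cv=cv, simulate=simulate, include_zero=include_zero,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# morphology fixtures


def make_soma_polygon(
    target_circularity: float,
    scale: float = 10.0,
    seed: int = 0,
    n_vertices: int = 256,
) -> np.ndarray:
    """Elliptical soma contour whose measured circularity
    (4*pi*area/perimeter^2) is within 0.02 of *target_circularity*; *scale*
    sets the semi-major axis in um. Returns an (n, 2) closed-ring vertex
    array (last vertex not repeated)."""
    if not (0.0 < target_circularity <= 1.0):
        raise ValueError("target circularity must lie in (0, 1]")
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)

    def measured(ratio: float) -> float:
        x = np.cos(theta)
        y = ratio * np.sin(theta)
        area = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        per = np.sum(np.hypot(np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0]))))
        return 4.0 * math.pi * area / per**2

    if target_circularity > measured(1.0):
        ratio = 1.0
    else:
        ratio = optimize.brentq(
            lambda r: measured(r) - target_circularity, 1e-3, 1.0, xtol=1e-10
        )
    rng = np.random.default_rng(seed)
    rot = rng.uniform(0.0, math.pi)
    x = scale * np.cos(theta)
    y = scale * ratio * np.sin(theta)
    cosr, sinr = math.cos(rot), math.sin(rot)
    return np.column_stack([x * cosr - y * sinr, x * sinr + y * cosr])


def make_tree(
    n_stems: int,
    n_bifurcations: int,
    seed: int = 0,
    segment_um: float = 20.0,
    nodes_per_neurite: int = 3,
    return_truth: bool = False,
):
    """Random 3-D dendritic tree with exactly *n_stems* primary dendrites and
    *n_bifurcations* branch points (hence n_stems + n_bifurcations
    terminations). Optionally also returns ground truth (counts and total
    length)."""
    if n_stems < 1:
        raise ValueError("need at least one stem")
    if n_bifurcations < 0:
        raise ValueError("n_bifurcations must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [1]
    types = [SOMA_TYPE]
    xyz = [np.zeros(3)]
    radius = [5.0]
    parent = [-1]
    total_length = 0.0

    def add_neurite(parent_row: int) -> int:
        nonlocal total_length
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        row = parent_row
        for _ in range(nodes_per_neurite):
            step = direction + 0.3 * rng.normal(size=3)
            step *= (segment_um / nodes_per_neurite) / np.linalg.norm(step)
            new = xyz[row] + step
            total_length += float(np.linalg.norm(new - xyz[row]))
            ids.append(len(ids) + 1)
            types.append(DENDRITE_TYPE)
            xyz.append(new)
            radius.append(0.8)
            parent.append(row)
            row = len(ids) - 1
        return row

    leaves = [add_neurite(0) for _ in range(n_stems)]
    for _ in range(n_bifurcations):
        leaf = leaves.pop(int(rng.integers(len(leaves))))
        leaves.append(add_neurite(leaf))
        leaves.append(add_neurite(leaf))

    tree = DendriteTree(
        ids=np.array(ids), types=np.array(types), xyz=np.array(xyz),
        radius=np.array(radius), parent_index=np.array(parent),
    )
    if return_truth:
        truth = {
            "n_stems": n_stems,
            "n_bifurcations": n_bifurcations,
            "n_terminations": n_stems + n_bifurcations,
            "total_length_um": total_length,
        }
        return tree, truth
    return tree
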