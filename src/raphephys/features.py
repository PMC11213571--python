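"""Intrinsic-property estimators: from raw current-clamp sweeps to a per-cell
feature panel.

Definitions implemented here follow the standard slice-electrophysiology
conventions for dorsal-raphe recordings:

* AP onset: first sample of the contiguous pre-peak run where the raw
  centered-difference dV/dt reaches 5 V/s; AP offset: return to the onset
  voltage; amplitude = peak - onset voltage; duration = onset-to-offset time.
* AHP: trough = post-offset local minimum; amplitude = offset voltage minus
  trough voltage; end = left edge of the first 50-ms window (slid
  sample-by-sample from the trough) whose least-squares slope magnitude has
  decayed to 0.005 V/s or less.
* Rheobase: minimum step amplitude evoking at least one AP.
* Input resistance: least-squares slope of steady-state voltage (mean over
  the second half of a 1-s step) versus injected current, over steps whose
  steady state lies in [-90, -50] mV.
* Sag: steady-state minus peak (minimum of the first 0.5 s) for steps
  hyperpolarizing the cell to -90 +/- 5 mV, averaged over qualifying steps.
* Membrane time constant: offset-exponential fit
  ``v = K0 + K1*exp(-(t - t0)/K2)`` to the recovery from a 5-ms
  hyperpolarizing pulse, from 1 ms after the negative peak until the voltage
  has returned to the pre-pulse baseline; tau = K2.
* Capacitance: C = tau / R.

Every estimator degrades to an "unresolved" result rather than guessing;
:func:`extract_panel` collects results with per-feature presence flags and
never emits silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import optimize, signal

from .sweeps import (
    BRIEF_PULSE,
    RAMP_FAMILY,
    STEP_FAMILY,
    ZERO_CURRENT,
    ProtocolEpoch,
    Sweep,
    SweepBundle,
)

ONSET_SLOPE_VPS = 5.0       # V/s, AP onset criterion on raw dV/dt
AHP_WINDOW_MS = 50.0        # sliding-window length for the AHP end criterion
AHP_END_SLOPE_VPS = 0.005   # V/s
PEAK_FLOOR_MV = -20.0       # candidate AP peaks must exceed this
RATE_TOL_HZ = 0.3           # rate-matched sweep selection window
SS_WINDOW_START_S = 0.5     # steady state averaged from 0.5 s into the step
IR_RANGE_MV = (-90.0, -50.0)
SAG_RANGE_MV = (-95.0, -85.0)
TAU_BOUNDS_MS = (0.1, 500.0)


def dvdt(voltage: np.ndarray, dt: float) -> np.ndarray:
    """Centered-difference first derivative of a mV trace, in V/s.

    No smoothing: the onset threshold is defined on the raw slope.
    """
    return np.gradient(np.asarray(voltage, float), dt) / 1000.0


# ---------------------------------------------------------------------------
# events


@dataclass
class APEvent:
    i_onset: int
    i_peak: int
    i_offset: int | None
    t_onset: float
    t_peak: float
    t_offset: float | None
    v_onset: float
    v_peak: float
    v_offset: float | None
    amplitude: float          # mV, v_peak - v_onset
    duration: float | None    # ms, onset -> offset
    max_rise_rate: float      # V/s
    truncated: bool = False


@dataclass
class AHPEvent:
    t_start: float            # = AP t_offset
    t_trough: float
    t_end: float | None
    amplitude: float          # mV, v(t_start) - v(t_trough)
    duration: float | None    # ms, t_end - t_start
    v_trough: float = math.nan
    unbounded: bool = False


#: per-sweep event cache (detection is deterministic; keyed by sweep identity)
_EVENT_CACHE: "weakref.WeakKeyDictionary" = None  # type: ignore[assignment]


def detect_aps(
    sweep: Sweep,
    onset_slope_threshold: float = ONSET_SLOPE_VPS,
    peak_floor: float = PEAK_FLOOR_MV,
    max_lookback_ms: float = 5.0,
) -> list[APEvent]:
    """Detect action potentials in one sweep.

    Candidate peaks are local maxima above *peak_floor*; each peak is
    accepted only if the raw dV/dt reaches *onset_slope_threshold* within
    *max_lookback_ms* before it, and the onset is the first sample of that
    contiguous suprathreshold run. The offset is the first post-peak sample
    at or below the onset voltage; events whose offset is not found before
    the next onset (or the sweep end) are flagged truncated.
    """
    global _EVENT_CACHE
    if _EVENT_CACHE is None:
        import weakref

        _EVENT_CACHE = weakref.WeakKeyDictionary()
    cache_key = (onset_slope_threshold, peak_floor, max_lookback_ms)
    cached = _EVENT_CACHE.get(sweep)
    if cached is not None and cached[0] == cache_key:
        return cached[1]
    v = sweep.voltage
    t = sweep.time
    dt = sweep.dt
    s = dvdt(v, dt)
    peaks, _ = signal.find_peaks(v, height=peak_floor)
    if len(peaks) == 0:
        _EVENT_CACHE[sweep] = (cache_key, [])
        return []
    lookback = max(2, int(round(max_lookback_ms / 1000.0 / dt)))

    # onset per candidate peak
    raw: list[tuple[int, int]] = []  # (onset, peak)
    for p in peaks:
        lo = max(0, p - lookback)
        win = s[lo:p]
        above = win >= onset_slope_threshold
        if not above.any():
            continue  # sub-threshold rise (e.g. slow ramps)
        # first sample of the contiguous suprathreshold run closest to the peak
        end = int(np.flatnonzero(above)[-1])
        run_start = end
        k = end
        while k >= 0 and above[k]:
            run_start = k
            k -= 1
        raw.append((lo + run_start, int(p)))

    # merge candidates sharing an onset (noise double-peaks): keep highest peak
    events_ix: dict[int, int] = {}
    for onset, p in raw:
        if onset not in events_ix or v[p] > v[events_ix[onset]]:
            events_ix[onset] = p
    pairs = sorted(events_ix.items())

    events: list[APEvent] = []
    for k, (onset, p) in enumerate(pairs):
        limit = pairs[k + 1][0] if k + 1 < len(pairs) else len(v)
        v_on = v[onset]
        seg = v[p:limit]
        below = np.flatnonzero(seg <= v_on)
        if len(below) > 0:
            off = p + int(below[0])
            t_off, v_off = t[off], v[off]
            duration = (t_off - t[onset]) * 1000.0
            truncated = False
        else:
            off, t_off, v_off, duration = None, None, None, None
            truncated = True
        events.append(
            APEvent(
                i_onset=onset, i_peak=p, i_offset=off,
                t_onset=t[onset], t_peak=t[p], t_offset=t_off,
                v_onset=v_on, v_peak=v[p], v_offset=v_off,
                amplitude=v[p] - v_on,
                duration=duration,
                max_rise_rate=float(np.max(s[onset:p + 1])),
                truncated=truncated,
            )
        )
    _EVENT_CACHE[sweep] = (cache_key, events)
    return events


def ap_metrics(event: APEvent) -> tuple[float, float, float]:
    """(amplitude mV, duration ms, max rise rate V/s) of a non-truncated AP."""
    if event.truncated:
        raise ValueError("AP event is truncated; metrics undefined")
    return event.amplitude, event.duration, event.max_rise_rate


def _sliding_slopes(v: np.ndarray, dt: float, nwin: int) -> np.ndarray:
    """OLS slope (mV/s) of every length-*nwin* window of *v*, left edges
    ``0..len(v)-nwin``, via running sums (O(n))."""
    v = np.asarray(v, float)
    v = v - v.mean()  # constant shift: slope-invariant, better conditioning
    n = len(v)
    m = n - nwin + 1
    if m <= 0:
        return np.empty(0)
    k = np.arange(n, dtype=float)
    csum_v = np.concatenate(([0.0], np.cumsum(v)))
    csum_kv = np.concatenate(([0.0], np.cumsum(k * v)))
    j = np.arange(m, dtype=float)
    S1 = csum_v[nwin:] - csum_v[:m]                    # sum v over window
    Skv = csum_kv[nwin:] - csum_kv[:m]                 # sum k*v
    St = Skv - j * S1                                  # sum (k - j) * v
    x_mean = (nwin - 1) / 2.0
    Sxx = nwin * (nwin * nwin - 1.0) / 12.0            # sum (x - x_mean)^2, x in samples
    slope_per_sample = (St - x_mean * S1) / Sxx
    return slope_per_sample / dt                       # mV/s


def ahp_metrics(
    sweep: Sweep,
    event: APEvent,
    limit_index: int | None = None,
    window_ms: float = AHP_WINDOW_MS,
    end_slope_threshold: float = AHP_END_SLOPE_VPS,
) -> AHPEvent:
    """Afterhyperpolarization metrics for the AHP following *event*.

    *limit_index* bounds the search (next AP onset or end of the stimulus);
    if the sliding-window slope criterion is never met before it, the AHP is
    flagged unbounded and excluded from per-cell averages.
    """
    if event.truncated or event.i_offset is None:
        raise ValueError("cannot measure AHP after a truncated AP")
    v, t, dt = sweep.voltage, sweep.time, sweep.dt
    if limit_index is None:
        limit_index = len(v)
    region = slice(event.i_offset, limit_index)
    seg = v[region]
    if len(seg) < 2:
        return AHPEvent(event.t_offset, event.t_offset, None, 0.0, None, unbounded=True)
    i_trough = event.i_offset + int(np.argmin(seg))
    amplitude = v[event.i_offset] - v[i_trough]
    nwin = max(2, int(round(window_ms / 1000.0 / dt)))
    tail = v[i_trough:limit_index]
    slopes = _sliding_slopes(tail, dt, nwin) / 1000.0  # V/s
    hit = np.flatnonzero(np.abs(slopes) <= end_slope_threshold)
    if len(hit) == 0:
        return AHPEvent(
            event.t_offset, t[i_trough], None, amplitude, None,
            v_trough=v[i_trough], unbounded=True,
        )
    i_end = i_trough + int(hit[0])
    return AHPEvent(
        t_start=event.t_offset,
        t_trough=t[i_trough],
        t_end=t[i_end],
        amplitude=amplitude,
        duration=(t[i_end] - event.t_offset) * 1000.0,
        v_trough=v[i_trough],
        unbounded=False,
    )


# ---------------------------------------------------------------------------
# zero-current epoch


@dataclass
class SpontaneousResult:
    spontaneous: bool
    rate: float | None = None        # Hz
    resting_vm: float | None = None  # mV


def classify_spontaneous(zero_epoch: ProtocolEpoch) -> SpontaneousResult:
    """Spontaneously active iff at least one AP in the zero-current
    recording; silent cells report the mean voltage as resting Vm."""
    if zero_epoch.kind != ZERO_CURRENT:
        raise ValueError("classify_spontaneous needs a zero-current epoch")
    sweep = zero_epoch.sweeps[0]
    events = detect_aps(sweep)
    if events:
        return SpontaneousResult(True, rate=len(events) / sweep.duration)
    return SpontaneousResult(False, resting_vm=float(np.mean(sweep.voltage)))


# ---------------------------------------------------------------------------
# step families


def _step_window(epoch: ProtocolEpoch, sweep: Sweep) -> tuple[int, int]:
    i0 = int(np.searchsorted(sweep.time, sweep.time[0] + epoch.step_onset))
    i1 = int(np.searchsorted(sweep.time, sweep.time[0] + epoch.step_offset))
    return i0, i1


def events_in_step(epoch: ProtocolEpoch, sweep: Sweep) -> list[APEvent]:
    """APs whose onset falls within the stimulus window of *sweep* (with a
    two-sample tolerance at the leading edge: the centered-difference onset
    of a spike evoked right at step onset can land one sample early)."""
    t0 = sweep.time[0] + epoch.step_onset - 2.0 * sweep.dt
    t1 = sweep.time[0] + epoch.step_offset
    return [e for e in detect_aps(sweep) if t0 <= e.t_onset < t1]


def evoked_rate(epoch: ProtocolEpoch, sweep: Sweep) -> float:
    """Mean evoked rate: spike count over the step duration, Hz."""
    return len(events_in_step(epoch, sweep)) / epoch.step_duration


@dataclass
class SteadyState:
    value: float    # mV
    n_spikes: int   # > 0 flags spike contamination

    @property
    def flagged(self) -> bool:
        return self.n_spikes > 0


def steady_state_voltage(epoch: ProtocolEpoch, sweep: Sweep) -> SteadyState:
    """Mean voltage from 0.5 s after step onset to the step offset."""
    t = sweep.time - sweep.time[0]
    mask = (t >= epoch.step_onset + SS_WINDOW_START_S) & (t <= epoch.step_offset)
    return SteadyState(
        value=float(np.mean(sweep.voltage[mask])),
        n_spikes=len(events_in_step(epoch, sweep)),
    )


@dataclass
class ScalarResult:
    """A feature estimate with an explicit resolution status."""

    value: float | None
    resolved: bool
    note: str = ""


def rheobase(epoch: ProtocolEpoch) -> ScalarResult:
    """Minimum step amplitude (pA) evoking at least one AP."""
    if epoch.kind != STEP_FAMILY or epoch.amplitudes is None:
        raise ValueError("rheobase needs a step_family epoch with amplitudes")
    spiking, silent_depol = [], []
    for amp, sweep in zip(epoch.amplitudes, epoch.sweeps):
        if events_in_step(epoch, sweep):
            spiking.append(amp)
        elif amp > 0:
            silent_depol.append(amp)
    if not spiking:
        return ScalarResult(None, False, "no spiking sweep")
    value = float(min(spiking))
    if not silent_depol:
        return ScalarResult(value, True, "lower-bound-only: no silent depolarizing sweep")
    return ScalarResult(value, True)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    return float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))


def drop_rate(epoch: ProtocolEpoch, sweep: Sweep | None = None) -> ScalarResult:
    """AP amplitude accommodation on a ramp: OLS slope of AP amplitude (mV)
    versus the instantaneous command current (pA) at each AP onset."""
    if epoch.kind != RAMP_FAMILY:
        raise ValueError("drop_rate needs a ramp_family epoch")
    sweep = sweep or epoch.sweeps[0]
    events = events_in_step(epoch, sweep)
    if len(events) < 3:
        return ScalarResult(None, False, f"only {len(events)} APs on ramp")
    currents = [sweep.current[e.i_onset] for e in events]
    amps = [e.amplitude for e in events]
    return ScalarResult(_ols_slope(currents, amps), True)


def delay_to_first_spike(epoch: ProtocolEpoch, sweep: Sweep) -> ScalarResult:
    """Time (s) from step onset to the onset of the first evoked AP."""
    events = events_in_step(epoch, sweep)
    if not events:
        return ScalarResult(None, False, "no AP in step window")
    t0 = sweep.time[0] + epoch.step_onset
    return ScalarResult(max(0.0, events[0].t_onset - t0), True)


def input_resistance(epoch: ProtocolEpoch) -> ScalarResult:
    """Steady-state I-V slope (MOhm) over non-spiking steps whose steady
    state lies in [-90, -50] mV."""
    if epoch.kind != STEP_FAMILY or epoch.amplitudes is None:
        raise ValueError("input_resistance needs a step_family epoch with amplitudes")
    xs, ys = [], []
    lo, hi = IR_RANGE_MV
    for amp, sweep in zip(epoch.amplitudes, epoch.sweeps):
        ss = steady_state_voltage(epoch, sweep)
        if ss.flagged or not (lo <= ss.value <= hi):
            continue
        xs.append(amp)
        ys.append(ss.value)
    if len(xs) < 2 or len(set(xs)) < 2:
        return ScalarResult(None, False, f"only {len(xs)} qualifying steps")
    return ScalarResult(_ols_slope(xs, ys) * 1000.0, True)  # mV/pA -> MOhm


def sag_amplitude(epoch: ProtocolEpoch) -> ScalarResult:
    """Mean (steady state - peak) over steps reaching -90 +/- 5 mV; peak is
    the minimum voltage of the first 0.5 s of the step. >= 0; 0 when the
    response is monotone."""
    if epoch.kind != STEP_FAMILY:
        raise ValueError("sag_amplitude needs a step_family epoch")
    lo, hi = SAG_RANGE_MV
    sags = []
    for sweep in epoch.sweeps:
        ss = steady_state_voltage(epoch, sweep)
        if not (lo <= ss.value <= hi):
            continue
        t = sweep.time - sweep.time[0]
        mask = (t >= epoch.step_onset) & (t <= epoch.step_onset + 0.5)
        peak = float(np.min(sweep.voltage[mask]))
        sags.append(ss.value - peak)
    if not sags:
        return ScalarResult(None, False, "no step reaching -90 +/- 5 mV")
    return ScalarResult(max(0.0, float(np.mean(sags))), True)


# ---------------------------------------------------------------------------
# brief pulse: membrane time constant


@dataclass
class TauFit:
    k0: float | None      # mV, fitted baseline
    k1: float | None      # mV, fitted (negative) deflection
    tau: float | None     # ms
    resolved: bool
    note: str = ""


def fit_tau(epoch: ProtocolEpoch, sweep: Sweep | None = None) -> TauFit:
    """Single-exponential fit to the recovery from the 5-ms hyperpolarizing
    pulse: ``v = K0 + K1*exp(-(t - t0)/K2)``, fitted from 1 ms after the
    negative peak until the voltage first returns to the pre-pulse baseline
    (or the sweep end when it never crosses); tau = K2 in ms."""
    if epoch.kind != BRIEF_PULSE:
        raise ValueError("fit_tau needs a brief_hyperpolarizing_pulse epoch")
    sweep = sweep or epoch.sweeps[0]
    v, dt = sweep.voltage, sweep.dt
    t = sweep.time - sweep.time[0]
    pre = v[t < epoch.step_onset]
    if len(pre) < 10:
        return TauFit(None, None, None, False, "insufficient pre-pulse baseline")
    baseline = float(np.mean(pre))
    # negative peak: within the pulse or just after it
    search = (t >= epoch.step_onset) & (t <= epoch.step_offset + 0.002)
    idx_search = np.flatnonzero(search)
    i_peak = idx_search[int(np.argmin(v[idx_search]))]
    if baseline - v[i_peak] < 0.5:
        return TauFit(None, None, None, False, "no identifiable negative peak (flat recovery)")
    i_start = i_peak + max(1, int(round(0.001 / dt)))
    # window end: first return to baseline, judged on a 1-ms boxcar-smoothed
    # copy so a single noise excursion cannot truncate the fit window
    tail = v[i_start:]
    nbox = max(1, int(round(0.001 / dt)))
    if nbox > 1:
        from scipy.ndimage import uniform_filter1d

        smooth = uniform_filter1d(tail, nbox, mode="nearest")
    else:
        smooth = tail
    crossed = np.flatnonzero(smooth >= baseline)
    i_end = i_start + int(crossed[0]) if len(crossed) else len(v)
    if i_end - i_start < 10:
        return TauFit(None, None, None, False, "recovery window too short")
    tt = t[i_start:i_end] - t[i_start]
    vv = v[i_start:i_end]

    # log-linear initial guess for tau
    y0 = baseline - vv
    pos = y0 > max(0.05, 0.05 * y0[0])
    if pos.sum() >= 5:
        slope = _ols_slope(tt[pos], np.log(y0[pos]))
        tau0 = -1.0 / slope if slope < 0 else 0.02
    else:
        tau0 = 0.02
    tau0 = float(np.clip(tau0, TAU_BOUNDS_MS[0] / 1000.0, TAU_BOUNDS_MS[1] / 1000.0))

    def model(x, k0, k1, tau):
        return k0 + k1 * np.exp(-x / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, tt, vv,
            p0=[baseline, vv[0] - baseline, tau0],
            bounds=([-120.0, -80.0, TAU_BOUNDS_MS[0] / 1000.0],
                    [20.0, 80.0, TAU_BOUNDS_MS[1] / 1000.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return TauFit(None, None, None, False, "fit non-convergent")
    k0, k1, tau_s = popt
    tau_ms = tau_s * 1000.0
    if not (TAU_BOUNDS_MS[0] < tau_ms < TAU_BOUNDS_MS[1]):
        return TauFit(None, None, None, False, f"tau {tau_ms:.3g} ms outside bounds")
    return TauFit(float(k0), float(k1), float(tau_ms), True)


def capacitance(tau_ms: float | None, input_resistance_mohm: float | None) -> float | None:
    """C = tau / R; ms / MOhm = nF, reported in pF. None propagates."""
    if tau_ms is None or input_resistance_mohm is None:
        return None
    if input_resistance_mohm <= 0:
        raise ValueError("input resistance must be positive")
    if tau_ms < 0:
        raise ValueError("tau must be non-negative")
    return tau_ms / input_resistance_mohm * 1000.0


def if_slope(epoch: ProtocolEpoch) -> ScalarResult:
    """Slope (Hz/pA) of the OLS line through the current-frequency plot over
    suprathreshold steps."""
    if epoch.kind != STEP_FAMILY or epoch.amplitudes is None:
        raise ValueError("if_slope needs a step_family epoch with amplitudes")
    xs, ys = [], []
    for amp, sweep in zip(epoch.amplitudes, epoch.sweeps):
        r = evoked_rate(epoch, sweep)
        if r > 0:
            xs.append(amp)
            ys.append(r)
    if len(xs) < 3:
        return ScalarResult(None, False, f"only {len(xs)} suprathreshold steps")
    return ScalarResult(_ols_slope(xs, ys), True)


def rate_matched_sweep(
    epoch: ProtocolEpoch, target_rate: float, tol: float = RATE_TOL_HZ
) -> int | None:
    """Index of the sweep whose evoked rate is closest to *target_rate* and
    within +/- *tol* Hz; ties broken toward lower current. None if no sweep
    qualifies."""
    best, best_key = None, None
    for j, sweep in enumerate(epoch.sweeps):
        r = evoked_rate(epoch, sweep)
        err = abs(r - target_rate)
        if err > tol:
            continue
        amp = epoch.amplitudes[j] if epoch.amplitudes else 0.0
        key = (err, amp)
        if best_key is None or key < best_key:
            best, best_key = j, key
    return best


# ---------------------------------------------------------------------------
# the per-cell panel

_PANEL_FIELDS = (
    "spont_rate", "resting_vm", "rheobase", "ap_amplitude", "ap_duration",
    "ahp_amplitude", "ahp_duration", "ap_drop_rate", "delay_first_spike",
    "input_resistance", "sag_amplitude", "tau", "capacitance", "if_slope",
    "max_rise_rate", "ap_threshold_v", "ap_peak_v", "ahp_trough_v",
    "rebound_spiking", "max_step_rate", "min_hyperpol_v",
)


@dataclass
class FeaturePanel:
    """Per-cell vector of intrinsic properties with presence flags.

    Units: rates Hz, voltages mV, currents pA, rheobase pA, durations ms
    (delay_first_spike in s), resistance MOhm, tau ms, capacitance pF,
    drop rate mV/pA, IF slope Hz/pA, rise rate V/s. A ``None`` value means
    the feature could not be resolved from the available sweeps; the
    companion flag in :meth:`to_dict` makes that explicit.
    """

    cell_id: str = ""
    group: str = "none"
    putative_type: str | None = None
    spontaneous: bool | None = None
    spont_rate: float | None = None
    resting_vm: float | None = None
    rheobase: float | None = None
    ap_amplitude: float | None = None
    ap_duration: float | None = None
    ahp_amplitude: float | None = None
    ahp_duration: float | None = None
    ap_drop_rate: float | None = None
    delay_first_spike: float | None = None
    input_resistance: float | None = None
    sag_amplitude: float | None = None
    tau: float | None = None
    capacitance: float | None = None
    if_slope: float | None = None
    max_rise_rate: float | None = None
    ap_threshold_v: float | None = None
    ap_peak_v: float | None = None
    ahp_trough_v: float | None = None
    rebound_spiking: float | None = None   # 0/1 presence heuristic
    max_step_rate: float | None = None
    min_hyperpol_v: float | None = None
    notes: dict = field(default_factory=dict)

    def present(self, name: str) -> bool:
        return getattr(self, name) is not None

    def to_dict(self) -> dict:
        out = {"cell_id": self.cell_id, "group": self.group,
               "putative_type": self.putative_type, "spontaneous": self.spontaneous}
        for name in _PANEL_FIELDS:
            val = getattr(self, name)
            out[name] = val
            out[f"{name}_present"] = val is not None
        return out


def panels_to_frame(panels: list[FeaturePanel]):
    """One row per cell; numeric columns plus companion *_present booleans."""
    import pandas as pd

    return pd.DataFrame([p.to_dict() for p in panels])


def extract_panel(
    bundle: SweepBundle,
    target_rate: float = 1.0,
    rate_tol: float = RATE_TOL_HZ,
) -> FeaturePanel:
    """Run every estimator on *bundle* and assemble the feature panel.

    AP and AHP metrics are per-cell averages over the events of the
    rate-matched step sweep (the sweep firing within *rate_tol* of
    *target_rate*); truncated APs and unbounded AHPs are excluded from the
    averages. Missing epochs or unresolved estimators leave the
    corresponding fields None.
    """
    panel = FeaturePanel(
        cell_id=bundle.cell_id, group=bundle.group, putative_type=bundle.putative_type
    )

    zero = bundle.get(ZERO_CURRENT)
    if zero is not None:
        sp = classify_spontaneous(zero)
        panel.spontaneous = sp.spontaneous
        panel.spont_rate = sp.rate
        panel.resting_vm = sp.resting_vm
    else:
        panel.notes["spontaneous"] = "zero-current epoch absent"

    steps = bundle.get(STEP_FAMILY)
    if steps is not None:
        rb = rheobase(steps)
        panel.rheobase = rb.value if rb.resolved else None
        if not rb.resolved:
            panel.notes["rheobase"] = rb.note
        ir = input_resistance(steps)
        panel.input_resistance = ir.value if ir.resolved else None
        sag = sag_amplitude(steps)
        panel.sag_amplitude = sag.value if sag.resolved else None
        fi = if_slope(steps)
        panel.if_slope = fi.value if fi.resolved else None

        j = rate_matched_sweep(steps, target_rate, rate_tol)
        if j is not None:
            sweep = steps.sweeps[j]
            events = events_in_step(steps, sweep)
            good = [e for e in events if not e.truncated]
            if good:
                panel.ap_amplitude = float(np.mean([e.amplitude for e in good]))
                panel.ap_duration = float(np.mean([e.duration for e in good]))
                panel.max_rise_rate = float(np.mean([e.max_rise_rate for e in good]))
                panel.ap_threshold_v = float(np.mean([e.v_onset for e in good]))
                panel.ap_peak_v = float(np.mean([e.v_peak for e in good]))
                i_step_end = _step_window(steps, sweep)[1]
                ahps = []
                for k, e in enumerate(good):
                    nxt = good[k + 1].i_onset if k + 1 < len(good) else i_step_end
                    ahps.append(ahp_metrics(sweep, e, limit_index=min(nxt, i_step_end)))
                bounded = [a for a in ahps if not a.unbounded]
                if bounded:
                    panel.ahp_amplitude = float(np.mean([a.amplitude for a in bounded]))
                    panel.ahp_duration = float(np.mean([a.duration for a in bounded]))
                    panel.ahp_trough_v = float(np.mean([a.v_trough for a in bounded]))
            dl = delay_to_first_spike(steps, sweep)
            panel.delay_first_spike = dl.value if dl.resolved else None
        else:
            panel.notes["rate_match"] = f"no sweep within {rate_tol} Hz of {target_rate} Hz"

        # auxiliary descriptors over the family extremes
        if steps.amplitudes:
            amps = np.asarray(steps.amplitudes, float)
            j_max = int(np.argmax(amps))
            panel.max_step_rate = evoked_rate(steps, steps.sweeps[j_max])
            j_min = int(np.argmin(amps))
            if amps[j_min] < 0:
                sweep = steps.sweeps[j_min]
                i0, i1 = _step_window(steps, sweep)
                panel.min_hyperpol_v = float(np.min(sweep.voltage[i0:i1]))
                # rebound heuristic: any AP onset within 250 ms after step offset
                post0 = sweep.time[0] + steps.step_offset
                rb_events = [
                    e for e in detect_aps(sweep) if post0 <= e.t_onset <= post0 + 0.25
                ]
                panel.rebound_spiking = 1.0 if rb_events else 0.0
    else:
        panel.notes["steps"] = "step_family epoch absent"

    ramp = bundle.get(RAMP_FAMILY)
    if ramp is not None:
        dr = drop_rate(ramp)
        panel.ap_drop_rate = dr.value if dr.resolved else None
    else:
        panel.notes["ramp"] = "ramp_family epoch absent"

    pulse = bundle.get(BRIEF_PULSE)
    if pulse is not None:
        tf = fit_tau(pulse)
        panel.tau = tf.tau if tf.resolved else None
    else:
        panel.notes["pulse"] = "brief pulse epoch absent"

    panel.capacitance = capacitance(panel.tau, panel.input_resistance)
    return panel
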