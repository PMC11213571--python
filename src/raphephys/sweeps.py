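"""Domain types for current-clamp recordings and on-disk sweep bundles.

A *sweep* is one synchronized (time, voltage, current) triple on a uniform
grid; a *protocol epoch* groups the sweeps acquired under one stimulus
protocol (the 10-s zero-current recording, a family of 1-s current steps
from a -60 mV holding potential, current ramps, or a brief 5-ms
hyperpolarizing pulse used for the membrane time constant).

Canonical units are millivolts, picoamperes and seconds throughout;
readers normalize declared units on load. The on-disk format is one JSON
manifest per cell plus one TSV table (time/voltage/current columns) per
sweep; see :func:`write_bundle` for the schema.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = 1

ZERO_CURRENT = "zero_current_10s"
STEP_FAMILY = "step_family"
RAMP_FAMILY = "ramp_family"
BRIEF_PULSE = "brief_hyperpolarizing_pulse"
EPOCH_KINDS = (ZERO_CURRENT, STEP_FAMILY, RAMP_FAMILY, BRIEF_PULSE)

#: scale factors into canonical units (mV, pA, s)
_UNIT_SCALE = {
    "mV": 1.0, "V": 1000.0, "uV": 1e-3,
    "pA": 1.0, "nA": 1000.0, "A": 1e12,
    "s": 1.0, "ms": 1e-3,
}


class FormatError(ValueError):
    """Manifest missing/invalid or schema violation."""


class DataError(ValueError):
    """Sweep-level data violates an invariant (non-uniform grid, NaN, ...)."""


@dataclass(frozen=True, eq=False)
class Sweep:
    """One voltage recording with its command-current waveform.

    time is in seconds on a strictly increasing uniform grid; voltage in mV;
    current in pA (the full command waveform, holding current included).
    Compared by identity (use :func:`sweeps_equal` for value comparison).
    """

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    sampling_rate: float  # Hz

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.voltage, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if not (len(t) == len(v) == len(i)):
            raise DataError("time, voltage and current must have equal length")
        if len(t) < 2:
            raise DataError("sweep needs at least 2 samples")
        for name, arr in (("time", t), ("voltage", v), ("current", i)):
            if not np.all(np.isfinite(arr)):
                raise DataError(f"non-finite samples in {name}; sweeps with NaN are rejected")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise DataError("time grid is not uniform")
        expected_dt = 1.0 / self.sampling_rate
        if not math.isclose(dt[0], expected_dt, rel_tol=1e-4):
            raise DataError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with grid step {dt[0]:.3g} s"
            )
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "voltage", v)
        object.__setattr__(self, "current", i)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.time[-1] - self.time[0]


@dataclass
class ProtocolEpoch:
    """A stimulus protocol and its attached sweeps.

    ``amplitudes`` holds the per-sweep step/ramp amplitude in pA *relative to
    the holding current* (None for the zero-current epoch). ``step_onset`` /
    ``step_offset`` delimit the stimulus within each sweep, in seconds.
    """

    kind: str
    sweeps: list[Sweep] = field(default_factory=list)
    holding_potential: float | None = None  # mV
    step_onset: float | None = None
    step_offset: float | None = None
    amplitudes: list[float] | None = None

    def __post_init__(self):
        if self.kind not in EPOCH_KINDS:
            raise FormatError(f"unknown epoch kind {self.kind!r}")
        self.validate()

    def validate(self) -> None:
        if self.kind == ZERO_CURRENT:
            for s in self.sweeps:
                if not np.allclose(s.current, 0.0, atol=1e-9):
                    raise DataError("zero-current epoch has a nonzero command waveform")
                if s.duration < 10.0 - 1e-6:
                    raise DataError("zero-current epoch must record >= 10 s")
        if self.kind in (STEP_FAMILY, RAMP_FAMILY, BRIEF_PULSE):
            if self.step_onset is None or self.step_offset is None:
                raise FormatError(f"{self.kind} epoch requires step_onset/step_offset")
            dur = self.step_offset - self.step_onset
            if self.kind == STEP_FAMILY and not math.isclose(dur, 1.0, rel_tol=1e-6):
                raise DataError("step_family steps must last 1 s")
            if self.kind == BRIEF_PULSE and not math.isclose(dur, 0.005, rel_tol=1e-6):
                raise DataError("brief pulse must last 5 ms")
            if self.amplitudes is not None and len(self.amplitudes) != len(self.sweeps):
                raise FormatError("amplitudes must match number of sweeps")

    @property
    def step_duration(self) -> float | None:
        if self.step_onset is None:
            return None
        return self.step_offset - self.step_onset


@dataclass
class SweepBundle:
    """All recordings for one cell, organized by protocol epoch.

    A full feature panel needs at least a zero-current epoch and a step
    family; missing epochs are simply absent from ``epochs`` and the
    downstream panel flags the affected features, never silently zeroing.
    """

    cell_id: str
    epochs: dict[str, ProtocolEpoch] = field(default_factory=dict)
    group: str = "none"          # Sham | 6-OHDA | DMI+6-OHDA | none
    putative_type: str | None = None
    metadata: dict = field(default_factory=dict)

    def has_epoch(self, kind: str) -> bool:
        return kind in self.epochs

    @property
    def missing_epochs(self) -> list[str]:
        return [k for k in EPOCH_KINDS if k not in self.epochs]

    def get(self, kind: str) -> ProtocolEpoch | None:
        return self.epochs.get(kind)


def sweeps_equal(a: Sweep, b: Sweep, atol: float = 0.0) -> bool:
    """Value equality of two sweeps (exact by default)."""
    return (
        a.sampling_rate == b.sampling_rate
        and np.allclose(a.time, b.time, atol=atol, rtol=0)
        and np.allclose(a.voltage, b.voltage, atol=atol, rtol=0)
        and np.allclose(a.current, b.current, atol=atol, rtol=0)
    )


def bundles_equal(a: SweepBundle, b: SweepBundle, atol: float = 0.0) -> bool:
    """Value equality of two bundles (metadata, epochs and all sweeps)."""
    if (a.cell_id, a.group, a.putative_type, sorted(a.epochs)) != (
        b.cell_id, b.group, b.putative_type, sorted(b.epochs)
    ):
        return False
    for kind, ea in a.epochs.items():
        eb = b.epochs[kind]
        if (ea.holding_potential, ea.step_onset, ea.step_offset) != (
            eb.holding_potential, eb.step_onset, eb.step_offset
        ):
            return False
        if (ea.amplitudes is None) != (eb.amplitudes is None):
            return False
        if ea.amplitudes is not None and not np.allclose(
            ea.amplitudes, eb.amplitudes, atol=atol, rtol=0
        ):
            return False
        if len(ea.sweeps) != len(eb.sweeps):
            return False
        if not all(sweeps_equal(x, y, atol) for x, y in zip(ea.sweeps, eb.sweeps)):
            return False
    return True


# ---------------------------------------------------------------------------
# unit normalization


def normalize_units(values: np.ndarray, unit: str, kind: str) -> np.ndarray:
    """Scale *values* with declared *unit* into the canonical unit for *kind*
    ('voltage' -> mV, 'current' -> pA, 'time' -> s). Idempotent when the
    declared unit is already canonical."""
    if unit not in _UNIT_SCALE:
        raise FormatError(f"unknown unit {unit!r} for {kind}")
    return np.asarray(values, dtype=float) * _UNIT_SCALE[unit]


# ---------------------------------------------------------------------------
# bundle I/O


def write_bundle(bundle: SweepBundle, path: str | Path) -> None:
    """Write *bundle* as ``manifest.json`` + one TSV per sweep under *path*.

    Numeric values are written with 9 significant digits (round-trips well
    beyond the 6 the format guarantees). Refuses to write a bundle with no
    epochs or an epoch with no sweeps.
    """
    if not bundle.epochs:
        raise FormatError("refusing to write a bundle with no epochs")
    for kind, epoch in bundle.epochs.items():
        if not epoch.sweeps:
            raise FormatError(f"refusing to write empty epoch {kind!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "cell_id": bundle.cell_id,
        "group": bundle.group,
        "putative_type": bundle.putative_type,
        "metadata": bundle.metadata,
        "units": {"time": "s", "voltage": "mV", "current": "pA"},
        "epochs": [],
    }
    for kind, epoch in bundle.epochs.items():
        entry = {
            "kind": kind,
            "holding_potential_mV": epoch.holding_potential,
            "step_onset_s": epoch.step_onset,
            "step_offset_s": epoch.step_offset,
            "amplitudes_pA": epoch.amplitudes,
            "sweeps": [],
        }
        for j, sweep in enumerate(epoch.sweeps):
            fname = f"{kind}_{j:03d}.tsv"
            df = pd.DataFrame(
                {"time": sweep.time, "voltage": sweep.voltage, "current": sweep.current}
            )
            df.to_csv(path / fname, sep="\t", index=False, float_format="%.9g")
            entry["sweeps"].append({"file": fname, "sampling_rate_Hz": sweep.sampling_rate})
        manifest["epochs"].append(entry)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_bundle(path: str | Path) -> SweepBundle:
    """Read a bundle written by :func:`write_bundle` (or any conforming
    directory), normalizing declared units to mV/pA/s and checking every
    sweep invariant."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest.json in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != FORMAT_VERSION:
        raise FormatError(f"unsupported format_version {manifest.get('format_version')!r}")
    for key in ("cell_id", "epochs", "units"):
        if key not in manifest:
            raise FormatError(f"manifest missing required key {key!r}")
    units = manifest["units"]
    epochs: dict[str, ProtocolEpoch] = {}
    for entry in manifest["epochs"]:
        sweeps = []
        for s in entry["sweeps"]:
            f = path / s["file"]
            if not f.exists():
                raise FormatError(f"referenced sweep table {s['file']} does not exist")
            df = pd.read_csv(f, sep="\t")
            for col in ("time", "voltage", "current"):
                if col not in df.columns:
                    raise FormatError(f"{s['file']}: missing column {col!r}")
            try:
                sweeps.append(
                    Sweep(
                        time=normalize_units(df["time"].to_numpy(), units["time"], "time"),
                        voltage=normalize_units(df["voltage"].to_numpy(), units["voltage"], "voltage"),
                        current=normalize_units(df["current"].to_numpy(), units["current"], "current"),
                        sampling_rate=float(s["sampling_rate_Hz"]),
                    )
                )
            except DataError as err:
                raise DataError(f"sweep {s['file']}: {err}") from err
        epochs[entry["kind"]] = ProtocolEpoch(
            kind=entry["kind"],
            sweeps=sweeps,
            holding_potential=entry.get("holding_potential_mV"),
            step_onset=entry.get("step_onset_s"),
            step_offset=entry.get("step_offset_s"),
            amplitudes=entry.get("amplitudes_pA"),
        )
    return SweepBundle(
        cell_id=manifest["cell_id"],
        epochs=epochs,
        group=manifest.get("group", "none"),
        putative_type=manifest.get("putative_type"),
        metadata=manifest.get("metadata", {}),
    )
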