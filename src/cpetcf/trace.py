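"""Domain types and I/O for breath-by-breath cardiopulmonary exercise test traces.

A ramp-incremental CPET is stored as a :class:`CPETTrace`: time-stamped channels
for work rate, oxygen uptake (VO2), carbon-dioxide output (VCO2), minute
ventilation (VE), breathing frequency (BF) and tidal volume (VT), plus the
protocol phase markers (warm-up start, ramp start, volitional exhaustion,
recovery end).  A :class:`PatientRecord` bundles a trace with spirometry (FVC,
FEV1), age and the ramp rate; synthetic records additionally carry a
:class:`GroundTruth` with the generator's true threshold.

Canonical units throughout the package: flows in L/min, tidal volume in L,
breathing frequency in 1/min, time in seconds, work in watts.

The on-disk format is a plain CSV with a ``#``-prefixed ``key: value`` metadata
header — diffable and dependency-free.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CPETTrace",
    "PatientRecord",
    "GroundTruth",
    "CPETFormatError",
    "CPETValidationError",
    "read_trace",
    "write_trace",
    "resample_uniform",
    "TRACE_COLUMNS",
]

#: CSV column names, in canonical order.
TRACE_COLUMNS = ("t_s", "work_W", "vo2_Lmin", "vco2_Lmin", "ve_Lmin", "bf_permin", "vt_L")

_CHANNEL_ATTRS = {
    "t_s": "time",
    "work_W": "work_rate",
    "vo2_Lmin": "vo2",
    "vco2_Lmin": "vco2",
    "ve_Lmin": "ve",
    "bf_permin": "bf",
    "vt_L": "vt",
}

_META_KEYS = (
    "patient_id",
    "age_y",
    "fvc_L",
    "fev1_L",
    "ramp_W_per_min",
    "warmup_start_s",
    "ramp_start_s",
    "exhaustion_s",
    "recovery_end_s",
)

#: Supported unit conversions for dialects whose files are not in canonical units.
_UNIT_FACTORS = {
    ("mL/min", "L/min"): 1e-3,
    ("L/s", "L/min"): 60.0,
    ("L/min", "L/min"): 1.0,
    ("mL", "L"): 1e-3,
    ("L", "L"): 1.0,
    ("1/min", "1/min"): 1.0,
    ("1/s", "1/min"): 60.0,
}


class CPETFormatError(ValueError):
    """File does not conform to the documented trace format."""


class CPETValidationError(ValueError):
    """Trace or record violates a physiological/structural invariant."""


@dataclass
class CPETTrace:
    """Breath-by-breath CPET time series with protocol phase markers."""

    time: np.ndarray  # s, strictly increasing
    work_rate: np.ndarray  # W
    vo2: np.ndarray  # L/min
    vco2: np.ndarray  # L/min
    ve: np.ndarray  # L/min
    bf: np.ndarray  # 1/min
    vt: np.ndarray  # L
    warmup_start_s: float
    ramp_start_s: float
    exhaustion_s: float
    recovery_end_s: float

    def __post_init__(self) -> None:
        for name in ("time", "work_rate", "vo2", "vco2", "ve", "bf", "vt"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_samples(self) -> int:
        return self.time.size

    def channels(self) -> dict[str, np.ndarray]:
        return {col: getattr(self, attr) for col, attr in _CHANNEL_ATTRS.items()}

    def validate(self, identity_tol: float = 0.05, eps: float = 1e-12) -> "CPETTrace":
        """Check structural invariants; return self on success.

        ``identity_tol`` bounds the relative residual of the identity
        VE = BF * VT, which holds up to measurement noise on real carts.
        """
        n = self.time.size
        for name in ("work_rate", "vo2", "vco2", "ve", "bf", "vt"):
            arr = getattr(self, name)
            if arr.size != n:
                raise CPETValidationError(
                    f"channel {name!r} has length {arr.size}, expected {n}"
                )
        if n < 2:
            raise CPETValidationError("trace needs at least two samples")
        if not np.all(np.diff(self.time) > 0):
            idx = int(np.flatnonzero(np.diff(self.time) <= 0)[0]) + 1
            raise CPETValidationError(f"time not strictly increasing at row {idx}")
        for name in ("ve", "vo2", "vco2", "bf", "vt"):
            arr = getattr(self, name)
            bad = np.flatnonzero(arr < 0)
            if bad.size:
                raise CPETValidationError(
                    f"negative value in channel {name!r} at row {int(bad[0])}"
                )
        if not (
            self.warmup_start_s <= self.ramp_start_s < self.exhaustion_s <= self.recovery_end_s
        ):
            raise CPETValidationError(
                "phase markers must satisfy warmup <= ramp_start < exhaustion <= recovery_end"
            )
        resid = np.abs(self.ve - self.bf * self.vt) / np.maximum(self.ve, eps)
        if np.any(resid > identity_tol):
            idx = int(np.argmax(resid))
            raise CPETValidationError(
                f"VE = BF*VT identity violated at row {idx} "
                f"(relative residual {resid[idx]:.3g} > {identity_tol})"
            )
        return self


@dataclass
class GroundTruth:
    """Generator-side labels attached to synthetic records only."""

    true_get_vo2: float  # L/min
    true_get_time_s: float
    true_vo2max: float  # L/min
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.true_get_vo2 < self.true_vo2max):
            raise CPETValidationError(
                "ground truth requires 0 < true_get_vo2 < true_vo2max"
            )


@dataclass
class PatientRecord:
    """A patient's CPET trace together with spirometry and demographics."""

    patient_id: str
    age: float  # years
    fvc: float  # L
    fev1: float  # L
    ramp_rate: float  # W/min
    trace: CPETTrace
    truth: Optional[GroundTruth] = None

    def validate(self, allow_ramp_outside_protocol: bool = False, **trace_kwargs) -> "PatientRecord":
        if self.fev1 > self.fvc:
            raise CPETValidationError(
                f"FEV1 ({self.fev1}) exceeds FVC ({self.fvc}) for {self.patient_id}"
            )
        if not allow_ramp_outside_protocol and not (10.0 <= self.ramp_rate <= 25.0):
            raise CPETValidationError(
                f"ramp rate {self.ramp_rate} W/min outside protocol range [10, 25]"
            )
        self.trace.validate(**trace_kwargs)
        return self


def _convert(values: np.ndarray, unit_from: str, unit_to: str, column: str) -> np.ndarray:
    try:
        return values * _UNIT_FACTORS[(unit_from, unit_to)]
    except KeyError:
        raise CPETFormatError(
            f"no conversion from {unit_from!r} to {unit_to!r} for column {column!r}"
        ) from None


_CANONICAL_UNITS = {
    "vo2_Lmin": "L/min",
    "vco2_Lmin": "L/min",
    "ve_Lmin": "L/min",
    "bf_permin": "1/min",
    "vt_L": "L",
}


def read_trace(path, dialect: Optional[dict] = None) -> PatientRecord:
    """Read a trace CSV (``#`` metadata header + channel columns) into a record.

    ``dialect`` may carry ``delimiter`` (default ``,``) and ``units``, a mapping
    from column name to the unit used in the file (e.g. ``{"vo2_Lmin":
    "mL/min"}``); values are converted to canonical units on read.
    """
    dialect = dialect or {}
    delimiter = dialect.get("delimiter", ",")
    units = dialect.get("units", {})

    text = Path(path).read_text()
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise CPETFormatError(f"{path}: no tabular data found")

    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep=delimiter)
    missing = sorted(set(TRACE_COLUMNS) - set(df.columns))
    if missing:
        raise CPETFormatError(f"{path}: missing required channel(s): {', '.join(missing)}")

    missing_meta = sorted(set(_META_KEYS) - set(meta))
    if missing_meta:
        raise CPETFormatError(f"{path}: missing metadata key(s): {', '.join(missing_meta)}")

    data = {}
    for col in TRACE_COLUMNS:
        values = df[col].to_numpy(dtype=float)
        if col in _CANONICAL_UNITS and col in units:
            values = _convert(values, units[col], _CANONICAL_UNITS[col], col)
        data[_CHANNEL_ATTRS[col]] = values

    trace = CPETTrace(
        warmup_start_s=float(meta["warmup_start_s"]),
        ramp_start_s=float(meta["ramp_start_s"]),
        exhaustion_s=float(meta["exhaustion_s"]),
        recovery_end_s=float(meta["recovery_end_s"]),
        **data,
    )
    record = PatientRecord(
        patient_id=meta["patient_id"],
        age=float(meta["age_y"]),
        fvc=float(meta["fvc_L"]),
        fev1=float(meta["fev1_L"]),
        ramp_rate=float(meta["ramp_W_per_min"]),
        trace=trace,
    )
    record.validate(allow_ramp_outside_protocol=True)
    return record


def write_trace(record: PatientRecord, path) -> None:
    """Write a record to the documented CSV-with-metadata-header format."""
    t = record.trace
    meta = {
        "patient_id": record.patient_id,
        "age_y": repr(record.age),
        "fvc_L": repr(record.fvc),
        "fev1_L": repr(record.fev1),
        "ramp_W_per_min": repr(record.ramp_rate),
        "warmup_start_s": repr(t.warmup_start_s),
        "ramp_start_s": repr(t.ramp_start_s),
        "exhaustion_s": repr(t.exhaustion_s),
        "recovery_end_s": repr(t.recovery_end_s),
    }
    df = pd.DataFrame({col: getattr(t, attr) for col, attr in _CHANNEL_ATTRS.items()})
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        # repr-level float formatting keeps the round-trip lossless
        df.to_csv(fh, index=False, float_format="%.17g")


def resample_uniform(trace: CPETTrace, dt: float) -> CPETTrace:
    """Linearly interpolate all channels onto a uniform ``dt`` grid.

    The grid spans [warmup_start_s, recovery_end_s]; phase markers are kept.
    Linear interpolation is exact for piecewise-linear signals, so no smoothing
    happens at this layer.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t0, t1 = trace.warmup_start_s, trace.recovery_end_s
    if dt > (t1 - t0):
        raise ValueError(f"dt={dt} exceeds trace duration {t1 - t0}")
    grid = np.arange(t0, t1 + 0.5 * dt, dt)
    grid = grid[grid <= t1]
    out = {
        attr: np.interp(grid, trace.time, getattr(trace, attr))
        for attr in ("work_rate", "vo2", "vco2", "ve", "bf", "vt")
    }
    return replace(trace, time=grid, **out)
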