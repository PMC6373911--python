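"""Performance metric and emulator inputs extracted from a CPET trace.

The test's performance metric is the total mechanical energy transferred
(trapezoidal integral of work rate to exhaustion).  The seven emulator inputs
are: baseline breathing frequency and tidal volume (warm-up means), the VO2 at
a fixed reference ventilation (from the log-linear VE-VO2 fit), FVC, FEV1, and
the rates of change of BF and VT during the ramp.

All ramp-phase fits use the same exclusion window: the first 180 s (warm-up,
work rate not yet increasing) and the final 60 s before volitional exhaustion
(past the respiratory compensation point, where hyperventilation sets in) are
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .trace import CPETTrace, PatientRecord

__all__ = [
    "LogLinearFit",
    "FeatureVector",
    "PREDICTOR_FIELDS",
    "VE_REF_LMIN",
    "total_energy",
    "ramp_fit_window",
    "fit_loglinear_ve_vo2",
    "vo2_at_fixed_ve",
    "baseline_ventilation",
    "ventilatory_slopes",
    "build_feature_vector",
    "vo2_ve_ratio_series",
    "feature_table",
]

#: Reference ventilation 0.822 L/s expressed in the package's canonical L/min.
VE_REF_LMIN = 0.822 * 60.0  # = 49.32

#: The seven emulator input variables, in fixed order (d = 7).
PREDICTOR_FIELDS = (
    "baseline_bf",
    "baseline_vt",
    "vo2_at_fixed_ve",
    "fvc",
    "fev1",
    "bf_slope",
    "vt_slope",
)


@dataclass
class LogLinearFit:
    """OLS fit of ln(VE) on VO2 over the ramp exclusion window."""

    alpha: float  # intercept, ln(L/min)
    beta: float  # slope per L/min of VO2
    r2: float
    window: tuple  # (start_s, end_s) actually used


@dataclass
class FeatureVector:
    """Seven emulator inputs + threshold output + auxiliary performance metrics."""

    patient_id: str
    baseline_bf: float  # 1/min
    baseline_vt: float  # L
    vo2_at_fixed_ve: float  # L/min
    fvc: float  # L
    fev1: float  # L
    bf_slope: float  # 1/min per L/min of VO2
    vt_slope: float  # L per L/min of VO2
    get_vo2: Optional[float] = None  # L/min, the emulator output
    total_energy_kJ: Optional[float] = None
    exhaustion_time_s: Optional[float] = None
    get_time_s: Optional[float] = None
    fit_window: Optional[tuple] = None  # provenance of the ramp fits

    def predictors(self) -> np.ndarray:
        x = np.array([getattr(self, f) for f in PREDICTOR_FIELDS], dtype=float)
        if not np.all(np.isfinite(x)):
            bad = [f for f, v in zip(PREDICTOR_FIELDS, x) if not np.isfinite(v)]
            raise ValueError(f"non-finite predictor(s): {', '.join(bad)}")
        return x


def total_energy(trace: CPETTrace) -> float:
    """Total energy transferred during the test, in kJ.

    Trapezoidal integral of the work rate (W) over [warm-up start, exhaustion].
    """
    if not np.isfinite(trace.exhaustion_s):
        raise ValueError("exhaustion marker missing")
    t0, t1 = trace.warmup_start_s, trace.exhaustion_s
    mask = (trace.time >= t0) & (trace.time <= t1)
    t = trace.time[mask]
    w = trace.work_rate[mask]
    # include the exact boundary points even if off-grid
    if t.size == 0 or t[0] > t0:
        t = np.insert(t, 0, t0)
        w = np.insert(w, 0, np.interp(t0, trace.time, trace.work_rate))
    if t[-1] < t1:
        t = np.append(t, t1)
        w = np.append(w, np.interp(t1, trace.time, trace.work_rate))
    return float(np.trapezoid(w, t) / 1000.0)


def ramp_fit_window(trace: CPETTrace) -> tuple[float, float]:
    """The shared fit window: ramp start (first 180 s dropped) to exhaustion - 60 s."""
    return (trace.ramp_start_s, trace.exhaustion_s - 60.0)


def _window_mask(trace: CPETTrace, window: tuple[float, float]) -> np.ndarray:
    return (trace.time >= window[0]) & (trace.time <= window[1])


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b x; returns (a, b, r2)."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), float(coef[1]), r2


def fit_loglinear_ve_vo2(trace: CPETTrace, min_samples: int = 10) -> LogLinearFit:
    """Fit ln(VE) = alpha + beta * VO2 over the ramp window by OLS.

    The warm-up (first 180 s) and the final 60 s before exhaustion are excluded
    — the former because work rate is not increasing, the latter because the
    respiratory compensation point induces erratic hyperventilation.
    """
    window = ramp_fit_window(trace)
    mask = _window_mask(trace, window)
    if mask.sum() < min_samples:
        raise ValueError(
            f"fit window {window} holds {int(mask.sum())} samples; need >= {min_samples}"
        )
    ve = trace.ve[mask]
    nonpos = np.flatnonzero(ve <= 0)
    if nonpos.size:
        idx = int(np.flatnonzero(mask)[nonpos[0]])
        raise ValueError(f"non-positive VE at sample {idx}; cannot take logarithm")
    alpha, beta, r2 = _ols_line(trace.vo2[mask], np.log(ve))
    return LogLinearFit(alpha=alpha, beta=beta, r2=max(0.0, min(1.0, r2)), window=window)


def vo2_at_fixed_ve(fit: LogLinearFit, ve_ref: float = VE_REF_LMIN) -> float:
    """VO2 at which the fitted VE-VO2 curve reaches the reference ventilation.

    Inverts ln(ve_ref) = alpha + beta * VO2.  The default reference is
    0.822 L/s = 49.32 L/min; a patient who reaches the reference ventilation at
    higher VO2 is extracting more oxygen per litre breathed.
    """
    if fit.beta == 0:
        raise ZeroDivisionError("degenerate fit: beta = 0, reference ventilation never crossed")
    return float((np.log(ve_ref) - fit.alpha) / fit.beta)


def baseline_ventilation(trace: CPETTrace) -> tuple[float, float]:
    """Warm-up means of breathing frequency (1/min) and tidal volume (L)."""
    mask = (trace.time >= trace.warmup_start_s) & (trace.time < trace.ramp_start_s)
    if not mask.any():
        raise ValueError("empty warm-up window")
    return float(trace.bf[mask].mean()), float(trace.vt[mask].mean())


def ventilatory_slopes(
    trace: CPETTrace, against: str = "vo2", min_samples: int = 10
) -> tuple[float, float]:
    """Rates of change of BF and VT over the ramp fit window.

    By default slopes are regressed against VO2, mirroring the VE-VO2 fitting
    convention; ``against="time"`` regresses against time in minutes instead.
    """
    window = ramp_fit_window(trace)
    mask = _window_mask(trace, window)
    if mask.sum() < min_samples:
        raise ValueError(f"fit window {window} too short for slope estimation")
    if against == "vo2":
        x = trace.vo2[mask]
    elif against == "time":
        x = trace.time[mask] / 60.0
    else:
        raise ValueError(f"unknown regressor {against!r}; use 'vo2' or 'time'")
    _, bf_slope, _ = _ols_line(x, trace.bf[mask])
    _, vt_slope, _ = _ols_line(x, trace.vt[mask])
    return float(bf_slope), float(vt_slope)


def build_feature_vector(
    record: PatientRecord,
    get_result=None,
    ve_ref: float = VE_REF_LMIN,
    slope_against: str = "vo2",
) -> FeatureVector:
    """Assemble the seven emulator inputs and auxiliary metrics for one patient.

    ``get_result`` may be a :class:`~cpetcf.threshold.GETResult` (or anything
    with ``get_vo2``/``get_time_s``) supplying the output variable.
    """
    trace = record.trace
    bf0, vt0 = baseline_ventilation(trace)
    fit = fit_loglinear_ve_vo2(trace)
    bf_slope, vt_slope = ventilatory_slopes(trace, against=slope_against)
    return FeatureVector(
        patient_id=record.patient_id,
        baseline_bf=bf0,
        baseline_vt=vt0,
        vo2_at_fixed_ve=vo2_at_fixed_ve(fit, ve_ref),
        fvc=record.fvc,
        fev1=record.fev1,
        bf_slope=bf_slope,
        vt_slope=vt_slope,
        get_vo2=getattr(get_result, "get_vo2", None),
        get_time_s=getattr(get_result, "get_time_s", None),
        total_energy_kJ=total_energy(trace),
        exhaustion_time_s=float(trace.exhaustion_s),
        fit_window=fit.window,
    )


def vo2_ve_ratio_series(trace: CPETTrace) -> pd.Series:
    """Dimensionless VO2/VE ratio over the whole test (oxygen-extraction trace)."""
    zero = np.flatnonzero(trace.ve == 0)
    if zero.size:
        raise ValueError(f"zero VE at sample {int(zero[0])}")
    s = pd.Series(trace.vo2 / trace.ve, index=pd.Index(trace.time, name="t_s"), name="vo2_over_ve")
    s.attrs["exhaustion_s"] = trace.exhaustion_s
    return s


def feature_table(features: list[FeatureVector]) -> pd.DataFrame:
    """Cohort feature vectors as a tidy DataFrame (one row per patient)."""
    return pd.DataFrame([asdict(f) for f in features])
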