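"""Ventilatory dead-space model and a compartmental cardiorespiratory ODE core.

Dead-space ventilation — the part of each breath that never reaches gas
exchange — rises during exercise, and markedly so in cystic fibrosis, where a
limited tidal volume forces compensatory increases in breathing frequency.
The dead-space rate is modelled as a linear function of work rate,

    VD(t) = VDB + a * W(t),

with the base level VDB = BF(rest) * V_D(rest) and the severity scaling
a = BF(exercise) * V_D(exercise) / W(exercise), both built from measured
rest/peak-exercise values.  Alveolar ventilation follows as VA = VE - VD.

The ODE core is a compartmental cardiopulmonary model in the
Timischl/Batzel tradition: lung and tissue mass balances for O2 and CO2
(alveolar partial pressures, mixed-venous concentrations), a cardiac output
rising linearly with metabolic rate, a first-order metabolic response to the
imposed work profile, and a ventilation controller combining central CO2
feedback with an exercise feedforward drive.  Parameter values are documented
physiological defaults (standard textbook magnitudes for storage volumes,
dissociation constants and controller gains); the model's testable surface is
its dead-space algebra, conservation laws and solver convergence, not
patient-specific parameter fidelity.  Units: pressures mmHg, flows L/min
(gas volumes STPD, hence the 863 mmHg conversion factor), work W.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .trace import PatientRecord

__all__ = [
    "DeadSpaceParams",
    "VentilatorySplit",
    "CardioRespParams",
    "deadspace_params",
    "deadspace_rate",
    "split_ventilation",
    "steady_state",
    "simulate_cardioresp",
    "cohort_ventilatory_split",
]


@dataclass
class DeadSpaceParams:
    """Linear dead-space ventilation model VD(t) = vdb + a * W(t)."""

    vdb: float  # L/min, base dead-space ventilation
    a: float  # L/min per W, severity scaling

    def __post_init__(self) -> None:
        if self.vdb < 0 or self.a < 0:
            raise ValueError("dead-space parameters must be non-negative")


@dataclass
class VentilatorySplit:
    """Total, dead-space and alveolar ventilation on a shared time grid."""

    time: np.ndarray
    ve: np.ndarray
    vd: np.ndarray
    va: np.ndarray
    negative_va_count: int  # flagged, never silently clipped


def deadspace_params(
    bf_rest: float, vd_rest: float, bf_ex: float, vd_ex: float, w_ex: float
) -> DeadSpaceParams:
    """Build the linear dead-space model from rest and peak-exercise measurements.

    vdb = BF(rest) * V_D(rest);  a = BF(exercise) * V_D(exercise) / W(exercise).
    """
    if min(bf_rest, vd_rest, bf_ex, vd_ex) < 0:
        raise ValueError("measurements must be non-negative")
    if w_ex <= 0:
        raise ZeroDivisionError("exercise work rate must be positive")
    return DeadSpaceParams(vdb=bf_rest * vd_rest, a=(bf_ex * vd_ex) / w_ex)


def deadspace_rate(params: DeadSpaceParams, work: np.ndarray) -> np.ndarray:
    """Dead-space ventilation time series for a work-rate profile."""
    work = np.asarray(work, dtype=float)
    if np.any(work < 0):
        raise ValueError("work rate must be non-negative")
    return params.vdb + params.a * work


def split_ventilation(
    time: np.ndarray, ve: np.ndarray, vd: np.ndarray
) -> VentilatorySplit:
    """Split total ventilation into dead-space and alveolar parts, VA = VE - VD."""
    time = np.asarray(time, dtype=float)
    ve = np.asarray(ve, dtype=float)
    vd = np.asarray(vd, dtype=float)
    if not (time.shape == ve.shape == vd.shape):
        raise ValueError("time, VE and VD must share one grid")
    va = ve - vd
    return VentilatorySplit(
        time=time, ve=ve, vd=vd, va=va, negative_va_count=int(np.sum(va < 0))
    )


# --------------------------------------------------------------------- ODE core


@dataclass
class CardioRespParams:
    """Parameters of the compartmental model (documented physiological defaults)."""

    v_alv_o2: float = 2.5  # L, alveolar O2 storage volume
    v_alv_co2: float = 3.2  # L, alveolar CO2 storage volume
    v_tis_o2: float = 6.0  # L, effective tissue O2 store
    v_tis_co2: float = 15.0  # L, effective tissue CO2 store
    p_insp_o2: float = 150.0  # mmHg, inspired O2 tension (humidified air)
    p_insp_co2: float = 0.0  # mmHg
    k1_o2: float = 0.2  # L/L, O2 dissociation capacity
    k2_o2: float = 0.046  # 1/mmHg, O2 dissociation shape
    k_co2: float = 0.0057  # L/L/mmHg, linear CO2 dissociation slope
    kk_co2: float = 0.224  # L/L, CO2 dissociation intercept
    mr_o2_rest: float = 0.30  # L/min STPD, resting O2 consumption
    efficiency: float = 0.010  # L/min per W of external work
    rq: float = 0.85  # metabolic respiratory quotient
    tau_metabolic_s: float = 30.0  # s, first-order metabolic response
    q_rest: float = 6.0  # L/min, resting cardiac output
    q_slope: float = 5.0  # L/min per L/min of extra O2 uptake
    gain_central: float = 1.8  # L/min/mmHg, central CO2 controller gain
    setpoint_co2: float = 35.0  # mmHg, controller apnoeic threshold
    gain_exercise: float = 20.0  # L/min per L/min of extra CO2 output (feedforward)
    va_min: float = 0.5  # L/min, controller output floor
    conversion: float = 863.0  # mmHg, STPD flow <-> partial-pressure factor

    def as_dict(self) -> dict:
        return asdict(self)


def _dissociation_o2(p: CardioRespParams, pao2: np.ndarray) -> np.ndarray:
    return p.k1_o2 * (1.0 - np.exp(-p.k2_o2 * pao2)) ** 2


def _dissociation_co2(p: CardioRespParams, paco2: np.ndarray) -> np.ndarray:
    return p.k_co2 * paco2 + p.kk_co2


def _algebraic(p: CardioRespParams, state: np.ndarray):
    """Derived quantities (arterial contents, cardiac output, ventilation)."""
    pao2, paco2, cvo2, cvco2, mro2 = state
    cao2 = _dissociation_o2(p, pao2)
    caco2 = _dissociation_co2(p, paco2)
    mrco2 = p.rq * mro2
    q = p.q_rest + p.q_slope * (mro2 - p.mr_o2_rest)
    drive = p.gain_central * (paco2 - p.setpoint_co2) + p.gain_exercise * (
        mrco2 - p.rq * p.mr_o2_rest
    )
    va = np.maximum(drive, p.va_min)
    return cao2, caco2, mrco2, q, va


def _rhs(t: float, state: np.ndarray, p: CardioRespParams, work: Callable[[float], float]):
    pao2, paco2, cvo2, cvco2, mro2 = state
    cao2, caco2, mrco2, q, va = _algebraic(p, state)
    mro2_target = p.mr_o2_rest + p.efficiency * work(t)
    tau_min = max(p.tau_metabolic_s, 1e-6) / 60.0  # states evolve in minutes
    return [
        (p.conversion * q * (cvo2 - cao2) + va * (p.p_insp_o2 - pao2)) / p.v_alv_o2,
        (p.conversion * q * (cvco2 - caco2) + va * (p.p_insp_co2 - paco2)) / p.v_alv_co2,
        (q * (cao2 - cvo2) - mro2) / p.v_tis_o2,
        (mrco2 - q * (cvco2 - caco2)) / p.v_tis_co2,
        (mro2_target - mro2) / tau_min,
    ]


def steady_state(params: CardioRespParams, work_rate: float = 0.0) -> np.ndarray:
    """Equilibrium state [PaO2, PaCO2, CvO2, CvCO2, MRO2] at constant work."""
    mro2 = params.mr_o2_rest + params.efficiency * work_rate
    x0 = np.array([100.0, 40.0, 0.15, 0.50, mro2])
    sol = optimize.root(
        lambda x: _rhs(0.0, x, params, lambda t: work_rate), x0, method="hybr", tol=1e-13
    )
    if not sol.success:
        raise RuntimeError(f"steady-state solve failed: {sol.message}")
    return sol.x


def _work_callable(work_profile) -> Callable[[float], float]:
    if callable(work_profile):
        return work_profile
    t_knots, w_knots = work_profile
    t_knots = np.asarray(t_knots, dtype=float)
    w_knots = np.asarray(w_knots, dtype=float)
    return lambda t: float(np.interp(t, t_knots, w_knots))


def simulate_cardioresp(
    params: CardioRespParams,
    work_profile,
    deadspace: Optional[DeadSpaceParams] = None,
    t_span: tuple[float, float] = (0.0, 900.0),
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    x0: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Integrate the cardiorespiratory model under a work-rate profile.

    ``work_profile`` is a callable W(t) in seconds, or a ``(t_knots, w_knots)``
    pair interpolated piecewise-linearly.  ``deadspace=None`` reproduces the
    original zero-dead-space formulation (VE = VA); with a
    :class:`DeadSpaceParams`, VE = VA + VD(t) while gas exchange remains driven
    by VA = VE - VD.  Time is reported in seconds; internal dynamics are per
    minute.  Returns a uniform-grid table of ventilation, gas tensions and
    metabolic fluxes.  Deterministic; negative states raise.
    """
    work = _work_callable(work_profile)
    if x0 is None:
        x0 = steady_state(params, work(t_span[0]))
    rhs_s = lambda t, x: np.asarray(_rhs(t, x, params, work)) / 60.0  # per second
    t_eval = np.arange(t_span[0], t_span[1] + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_span[1]]
    sol = integrate.solve_ivp(
        rhs_s,
        t_span,
        x0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=rtol * np.array([100.0, 40.0, 0.2, 0.5, 1.0]),
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    states = sol.y
    if np.any(states < -1e-9):
        bad = int(np.argmax(np.min(states, axis=0) < -1e-9))
        raise RuntimeError(f"negative state encountered at t={sol.t[bad]:.1f}s")

    cao2, caco2, mrco2, q, va = _algebraic(params, states)
    w_t = np.array([work(t) for t in sol.t])
    if deadspace is None:
        vd = np.zeros_like(va)
    else:
        vd = deadspace_rate(deadspace, w_t)
    ve = va + vd
    va = ve - vd  # re-derive so the reported identity VA = VE - VD is bitwise exact
    return pd.DataFrame(
        {
            "t_s": sol.t,
            "work_W": w_t,
            "va_Lmin": va,
            "vd_Lmin": vd,
            "ve_Lmin": ve,
            "pao2_mmHg": states[0],
            "paco2_mmHg": states[1],
            "cvo2_LL": states[2],
            "cvco2_LL": states[3],
            "mro2_Lmin": states[4],
            "mrco2_Lmin": mrco2,
            "q_Lmin": q,
            "vo2_pulm_Lmin": va * (params.p_insp_o2 - states[0]) / params.conversion,
            "vo2_tissue_Lmin": q * (cao2 - states[2]),
        }
    )


# ----------------------------------------------------- cohort-level summaries


def _phase_means(record: PatientRecord, window_s: float = 30.0):
    """(rest, peak) means of BF, VE and work over warm-up / pre-exhaustion windows."""
    t = record.trace
    rest = (t.time >= t.warmup_start_s) & (t.time < t.ramp_start_s)
    peak = (t.time >= t.exhaustion_s - window_s) & (t.time <= t.exhaustion_s)
    if not rest.any() or not peak.any():
        raise ValueError(f"{record.patient_id}: empty rest or peak window")
    return (
        (float(t.bf[rest].mean()), float(t.ve[rest].mean()), float(t.work_rate[rest].mean())),
        (float(t.bf[peak].mean()), float(t.ve[peak].mean()), float(t.work_rate[peak].mean())),
    )


def cohort_ventilatory_split(
    records: list[PatientRecord],
    vd_rest: Optional[dict] = None,
    vd_exercise: Optional[dict] = None,
) -> pd.DataFrame:
    """Rest vs peak (VE, VD, VA) per patient, with the linear dead-space model.

    Per-patient dead volumes V_D at rest and exercise are measured inputs; for
    synthetic records they default to the generator's ground-truth values.
    Returns one row per patient plus a ``group_mean`` row (the red-star
    summary of the rest/peak ventilatory comparison).
    """
    rows = []
    for rec in records:
        vdr = (vd_rest or {}).get(rec.patient_id)
        vde = (vd_exercise or {}).get(rec.patient_id)
        if vdr is None or vde is None:
            if rec.truth is None or "vd_rest" not in rec.truth.params:
                raise ValueError(
                    f"{rec.patient_id}: dead volumes not supplied and no ground truth available"
                )
            vdr = rec.truth.params["vd_rest"]
            vde = rec.truth.params["vd_exercise"]
        (bf_r, ve_r, _), (bf_e, ve_e, w_e) = _phase_means(rec)
        ds = deadspace_params(bf_r, vdr, bf_e, vde, w_e)
        vd_r, vd_e = ds.vdb, float(deadspace_rate(ds, np.array([w_e]))[0])
        rows.append(
            {
                "patient_id": rec.patient_id,
                "vdb_Lmin": ds.vdb,
                "a_Lmin_per_W": ds.a,
                "ve_rest_Lmin": ve_r,
                "vd_rest_Lmin": vd_r,
                "va_rest_Lmin": ve_r - vd_r,
                "ve_peak_Lmin": ve_e,
                "vd_peak_Lmin": vd_e,
                "va_peak_Lmin": ve_e - vd_e,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns="patient_id").mean().to_dict()
    mean_row["patient_id"] = "group_mean"
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
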