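"""Synthetic cohort of paediatric cystic-fibrosis patients undergoing ramp CPET.

Emulates the ramp-incremental protocol (3-min warm-up at a low fixed power, a
ramp chosen to elicit volitional exhaustion in roughly ten minutes, then 5 min
of active recovery at 20 W) and the statistical structure the downstream
analysis assumes:

* VO2 rises linearly with work rate (aerobic efficiency slope), optionally
  through a first-order lag;
* VCO2 follows VO2 with a respiratory quotient below the gas exchange
  threshold and an extra excess-CO2 slope above it (the V-slope breakpoint);
* minute ventilation is log-linear in VO2, with a hyperventilation surge in
  the final 60 s before exhaustion (past the respiratory compensation point);
* tidal volume saturates towards a fraction of FVC, and BF = VE / VT exactly;
* per-channel breath-to-breath noise.

Every record carries a :class:`~cpetcf.trace.GroundTruth` with the generator's
true threshold, so detection and emulation can be scored against known labels.
Generation is deterministic given ``(seed, index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import pandas as pd

from .trace import CPETTrace, GroundTruth, PatientRecord

__all__ = ["CohortConfig", "generate_patient", "generate_cohort", "truth_table"]


@dataclass
class CohortConfig:
    """Distributional parameters of the virtual cohort.

    Two-tuples are (mean, SD) of a clipped normal draw; scalars are shared by
    every patient.  Defaults describe children and adolescents with CF on the
    ramp protocol: low-ish FVC and FEV1/FVC, peak VO2 around 1.4-2.8 L/min,
    and a threshold at 40-75% of VO2max.
    """

    n_patients: int = 15
    seed: int = 0

    # demographics and spirometry
    age_y: Tuple[float, float] = (13.0, 2.5)
    age_bounds: Tuple[float, float] = (8.0, 18.0)
    fvc_L: Tuple[float, float] = (3.0, 0.7)
    fvc_bounds: Tuple[float, float] = (1.6, 5.0)
    fev1_fvc_ratio: Tuple[float, float] = (0.78, 0.08)
    fev1_fvc_bounds: Tuple[float, float] = (0.45, 0.95)

    # protocol
    warmup_power_W: float = 15.0  # within the 10-20 W warm-up band
    warmup_duration_s: float = 180.0
    target_ramp_duration_s: float = 600.0  # exhaustion in ~10 min
    ramp_rate_bounds: Tuple[float, float] = (10.0, 25.0)  # W/min protocol range
    recovery_power_W: float = 20.0
    recovery_duration_s: float = 300.0
    dt_s: float = 1.0  # uniform breath-table grid

    # metabolic structure
    vo2_rest_Lmin: Tuple[float, float] = (0.30, 0.03)
    vo2_rest_bounds: Tuple[float, float] = (0.20, 0.45)
    efficiency_Lmin_per_W: Tuple[float, float] = (0.010, 0.0008)
    efficiency_bounds: Tuple[float, float] = (0.008, 0.012)
    vo2max_Lmin: Tuple[float, float] = (1.9, 0.35)
    vo2max_bounds: Tuple[float, float] = (1.4, 2.8)
    get_fraction: Tuple[float, float] = (0.55, 0.06)
    get_fraction_bounds: Tuple[float, float] = (0.40, 0.75)
    rq_below_get: Tuple[float, float] = (0.85, 0.04)
    rq_bounds: Tuple[float, float] = (0.75, 0.95)
    excess_co2_slope: Tuple[float, float] = (0.45, 0.10)
    excess_co2_bounds: Tuple[float, float] = (0.20, 0.80)
    tau_vo2_s: float = 30.0  # first-order VO2 lag; 0 disables

    # ventilatory structure
    ve_slope_per_Lmin: Tuple[float, float] = (1.0, 0.12)  # beta of log VE vs VO2
    ve_slope_bounds: Tuple[float, float] = (0.70, 1.40)
    baseline_bf_permin: Tuple[float, float] = (22.0, 3.0)
    baseline_bf_bounds: Tuple[float, float] = (14.0, 32.0)
    baseline_vt_L: Tuple[float, float] = (0.65, 0.10)
    baseline_vt_bounds: Tuple[float, float] = (0.40, 1.00)
    vtmax_fvc_fraction: Tuple[float, float] = (0.45, 0.07)
    vtmax_fvc_bounds: Tuple[float, float] = (0.30, 0.60)
    rc_surge_fraction: float = 0.30  # VE inflation reached at exhaustion

    # dead-space fractions used by the mechanistic stage (of VT at rest/peak)
    vd_rest_fraction: float = 0.35
    vd_exercise_fraction: float = 0.30

    # breath-to-breath noise
    noise_vo2_Lmin: float = 0.035
    noise_vco2_Lmin: float = 0.040
    noise_ve_rel: float = 0.040  # multiplicative log-normal sigma
    noise_vt_L: float = 0.020

    def validate(self) -> "CohortConfig":
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("noise_vo2_Lmin", "noise_vco2_Lmin", "noise_ve_rel", "noise_vt_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.get_fraction_bounds
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("GET fraction bounds must lie inside (0, 1)")
        lo, hi = self.vtmax_fvc_bounds
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("max-VT fraction bounds must lie inside (0, 1]")
        if not (10.0 <= self.warmup_power_W <= 20.0):
            raise ValueError("warm-up power must lie in the protocol band [10, 20] W")
        return self

    def zero_noise(self) -> "CohortConfig":
        """Copy of the config with every noise SD set to zero (analytic checks)."""
        from dataclasses import replace

        return replace(
            self, noise_vo2_Lmin=0.0, noise_vco2_Lmin=0.0, noise_ve_rel=0.0, noise_vt_L=0.0
        )


def _draw(rng: np.random.Generator, dist: Tuple[float, float], bounds: Tuple[float, float]) -> float:
    mean, sd = dist
    return float(np.clip(rng.normal(mean, sd), *bounds))


def _first_order_lag(signal: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exact exponential filter for piecewise-constant input, seeded at signal[0]."""
    if tau <= 0:
        return signal.copy()
    out = np.empty_like(signal)
    out[0] = signal[0]
    decay = np.exp(-dt / tau)
    for i in range(1, signal.size):
        out[i] = signal[i] + (out[i - 1] - signal[i]) * decay
    return out


def generate_patient(config: CohortConfig, index: int) -> PatientRecord:
    """Generate one virtual patient; deterministic given ``(config.seed, index)``."""
    config.validate()
    if index >= config.n_patients:
        raise ValueError(f"index {index} out of range for n_patients={config.n_patients}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(index)]))

    age = _draw(rng, config.age_y, config.age_bounds)
    fvc = _draw(rng, config.fvc_L, config.fvc_bounds)
    fev1 = _draw(rng, config.fev1_fvc_ratio, config.fev1_fvc_bounds) * fvc

    vo2_rest = _draw(rng, config.vo2_rest_Lmin, config.vo2_rest_bounds)
    eff = _draw(rng, config.efficiency_Lmin_per_W, config.efficiency_bounds)
    vo2max_target = _draw(rng, config.vo2max_Lmin, config.vo2max_bounds)
    get_frac = _draw(rng, config.get_fraction, config.get_fraction_bounds)
    rq = _draw(rng, config.rq_below_get, config.rq_bounds)
    excess = _draw(rng, config.excess_co2_slope, config.excess_co2_bounds)

    beta = _draw(rng, config.ve_slope_per_Lmin, config.ve_slope_bounds)
    bf_base = _draw(rng, config.baseline_bf_permin, config.baseline_bf_bounds)
    vt_base = _draw(rng, config.baseline_vt_L, config.baseline_vt_bounds)
    vtmax = _draw(rng, config.vtmax_fvc_fraction, config.vtmax_fvc_bounds) * fvc
    vt_base = min(vt_base, 0.8 * vtmax)

    # Ramp rate chosen (as in the protocol) to elicit exhaustion in roughly the
    # target duration for this patient's predicted peak power, then clipped to
    # the 10-25 W/min protocol range.
    w_peak = (vo2max_target - vo2_rest) / eff
    wu = config.warmup_power_W
    t_wu = config.warmup_duration_s
    ramp_rate = float(
        np.clip(60.0 * (w_peak - wu) / config.target_ramp_duration_s, *config.ramp_rate_bounds)
    )
    t_exh = t_wu + 60.0 * (w_peak - wu) / ramp_rate
    recovery_end = t_exh + config.recovery_duration_s

    dt = config.dt_s
    time = np.arange(0.0, recovery_end + 1e-9, dt)
    recovery_end = float(time[-1])

    work = np.where(
        time < t_wu,
        wu,
        np.where(time <= t_exh, wu + ramp_rate * (time - t_wu) / 60.0, config.recovery_power_W),
    )
    work_lag = _first_order_lag(work, dt, config.tau_vo2_s)

    vo2_clean = vo2_rest + eff * work_lag
    true_vo2max = float(vo2_clean[time <= t_exh].max())
    true_get = get_frac * true_vo2max
    ramp_mask = (time >= t_wu) & (time <= t_exh)
    crossing = np.flatnonzero(ramp_mask & (vo2_clean >= true_get))
    true_get_time = float(time[crossing[0]]) if crossing.size else float(t_exh)

    vco2_clean = rq * vo2_clean + excess * np.maximum(vo2_clean - true_get, 0.0)

    vo2_wu = vo2_rest + eff * wu  # warm-up steady state (lag seeded there)
    alpha = np.log(bf_base * vt_base) - beta * vo2_wu
    ve_clean = np.exp(alpha + beta * vo2_clean)
    # hyperventilation past the respiratory compensation point: linear surge
    # over the final 60 s before exhaustion (excluded from downstream fits)
    surge = 1.0 + config.rc_surge_fraction * np.clip((time - (t_exh - 60.0)) / 60.0, 0.0, 1.0)
    surge[time > t_exh] = 1.0
    ve_clean = ve_clean * surge

    ve_wu = bf_base * vt_base
    ve_peak = float(np.exp(alpha + beta * true_vo2max)) * (1.0 + config.rc_surge_fraction)
    sat_rate = 3.0 / max(ve_peak - ve_wu, 1e-6)
    vt_clean = vtmax - (vtmax - vt_base) * np.exp(-sat_rate * np.maximum(ve_clean - ve_wu, 0.0))

    vo2 = np.clip(vo2_clean + config.noise_vo2_Lmin * rng.standard_normal(time.size), 1e-6, None)
    vco2 = np.clip(vco2_clean + config.noise_vco2_Lmin * rng.standard_normal(time.size), 1e-6, None)
    ve = ve_clean * np.exp(config.noise_ve_rel * rng.standard_normal(time.size))
    vt = np.clip(vt_clean + config.noise_vt_L * rng.standard_normal(time.size), 0.05, None)
    bf = ve / vt  # identity VE = BF*VT exact by construction

    trace = CPETTrace(
        time=time,
        work_rate=work,
        vo2=vo2,
        vco2=vco2,
        ve=ve,
        bf=bf,
        vt=vt,
        warmup_start_s=0.0,
        ramp_start_s=t_wu,
        exhaustion_s=float(t_exh),
        recovery_end_s=recovery_end,
    )
    truth = GroundTruth(
        true_get_vo2=float(true_get),
        true_get_time_s=true_get_time,
        true_vo2max=true_vo2max,
        params={
            "seed": int(config.seed),
            "index": int(index),
            "vo2_rest": vo2_rest,
            "efficiency": eff,
            "rq_below_get": rq,
            "excess_co2_slope": excess,
            "alpha": float(alpha),
            "beta": beta,
            "baseline_bf": bf_base,
            "baseline_vt": vt_base,
            "vtmax": vtmax,
            "ramp_rate": ramp_rate,
            "noise_vo2": config.noise_vo2_Lmin,
            "noise_vco2": config.noise_vco2_Lmin,
            "noise_ve_rel": config.noise_ve_rel,
            "noise_vt": config.noise_vt_L,
            "vd_rest": config.vd_rest_fraction * vt_base,
            "vd_exercise": config.vd_exercise_fraction * vtmax,
        },
    )
    record = PatientRecord(
        patient_id=f"synthetic-{config.seed:04d}-{index:02d}",
        age=age,
        fvc=fvc,
        fev1=fev1,
        ramp_rate=ramp_rate,
        trace=trace,
        truth=truth,
    )
    return record.validate()


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` independent records."""
    config.validate()
    return [generate_patient(config, i) for i in range(config.n_patients)]


def truth_table(records: list[PatientRecord]) -> pd.DataFrame:
    """Ground-truth labels of a synthetic cohort as a tidy table."""
    rows = []
    for rec in records:
        if rec.truth is None:
            continue
        row = {
            "patient_id": rec.patient_id,
            "true_get_vo2_Lmin": rec.truth.true_get_vo2,
            "true_get_time_s": rec.truth.true_get_time_s,
            "true_vo2max_Lmin": rec.truth.true_vo2max,
        }
        row.update({f"param_{k}": v for k, v in rec.truth.params.items()})
        rows.append(row)
    return pd.DataFrame(rows)
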