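"""End-to-end analysis pipeline: cohort -> features -> GET -> GP -> PCA -> mechanistic.

``run_all`` reproduces the study's analysis chain on a synthetic cohort (or on
traces already on disk): it extracts the seven emulator inputs and the
performance metric, detects the gas exchange threshold, fits and
cross-validates the GP emulator (per-patient prediction +/- 1.96 s table and
MSE_LOO), runs the breathing-pattern PCA, and produces the rest/peak
ventilatory-split summaries of the dead-space model.  Every stage writes
machine-readable tables into the output directory, and a manifest records the
seed, configuration hash and package versions so a run can be repeated
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort, truth_table
from .features import build_feature_vector, feature_table, VE_REF_LMIN
from .gp import GPEmulator
from .mechanistic import (
    CardioRespParams,
    DeadSpaceParams,
    cohort_ventilatory_split,
    simulate_cardioresp,
)
from .pca import pca_performance
from .threshold import detect_get_vslope
from .trace import read_trace, write_trace

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs are kept."""


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: Optional[str] = None  # read traces from here instead of generating
    ve_ref: float = VE_REF_LMIN
    slope_against: str = "vo2"
    knot_grid_frac: float = 0.01
    get_alpha: float = 0.05
    gp_restarts: int = 5
    gp_objective: str = "reml"  # restricted ML: unbiased signal variance with the
    # d+1-parameter mean profiled out (see docs/methods.md)
    loo_mode: str = "refit"
    deadspace_mode: str = "linear"  # or "zero"
    n_ode_patients: int = 3  # per-patient ODE simulations (0 disables)
    ode_params: CardioRespParams = field(default_factory=CardioRespParams)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = _time.perf_counter()
            try:
                value = fn()
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            timings[name] = _time.perf_counter() - t0
            return value

        return wrap

    # ------------------------------------------------------------- cohort
    def _cohort():
        cohort_dir = out / "cohort"
        cohort_dir.mkdir(exist_ok=True)
        if config.cohort_dir is not None:
            index = json.loads((Path(config.cohort_dir) / "index.json").read_text())
            return [(pid, Path(config.cohort_dir) / fname) for pid, fname in index]
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        records = generate_cohort(cohort_cfg)
        index = []
        for rec in records:
            fname = f"{rec.patient_id}.csv"
            write_trace(rec, cohort_dir / fname)
            index.append((rec.patient_id, fname))
        truth_table(records).to_csv(cohort_dir / "truth.csv", index=False)
        (cohort_dir / "index.json").write_text(json.dumps(index))
        # keep in-memory records (with ground truth) for downstream stages
        results["records"] = records
        return [(pid, cohort_dir / fname) for pid, fname in index]

    index = stage("cohort")(_cohort)

    # ----------------------------------------------------------- features
    def _features():
        records = results.get("records")
        if records is None:
            records = []
            for pid, path in index:
                if not Path(path).exists():
                    raise FileNotFoundError(f"missing trace file for patient {pid}: {path}")
                records.append(read_trace(path))
            results["records"] = records
        feats, gets = [], []
        for rec in records:
            det = detect_get_vslope(
                rec.trace, knot_grid_frac=config.knot_grid_frac, alpha=config.get_alpha
            )
            gets.append(
                {
                    "patient_id": rec.patient_id,
                    "get_vo2_Lmin": det.get_vo2,
                    "get_time_s": det.get_time_s,
                    "slope_below": det.slope_below,
                    "slope_above": det.slope_above,
                    "valid": det.valid,
                    "reason": det.reason,
                }
            )
            feats.append(
                build_feature_vector(
                    rec, det, ve_ref=config.ve_ref, slope_against=config.slope_against
                )
            )
        ftab = feature_table(feats)
        ftab.to_csv(out / "features.csv", index=False)
        pd.DataFrame(gets).to_csv(out / "get.csv", index=False)
        return ftab

    ftab = stage("features")(_features)

    # ------------------------------------------------------------ emulator
    def _gp():
        from .features import PREDICTOR_FIELDS

        valid = ftab["get_vo2"].notna()
        X = ftab.loc[valid, list(PREDICTOR_FIELDS)].to_numpy(dtype=float)
        y = ftab.loc[valid, "get_vo2"].to_numpy(dtype=float)
        # detected thresholds carry measurement error, so the noise variance
        # (nugget) is estimated alongside the kernel hyperparameters
        em = GPEmulator(
            n_restarts=config.gp_restarts,
            random_state=config.seed,
            estimate_nugget=True,
            objective=config.gp_objective,
        )
        em.fit(X, y)
        report = em.loo(X, y, mode=config.loo_mode)
        std = np.sqrt(report.variance)
        loo_df = pd.DataFrame(
            {
                "patient_id": ftab.loc[valid, "patient_id"].to_numpy(),
                "get_true_Lmin": report.y_true,
                "get_pred_Lmin": report.mean,
                "pred_sd_Lmin": std,
                "ci95_lo": report.mean - 1.96 * std,
                "ci95_hi": report.mean + 1.96 * std,
                "covered": (report.y_true >= report.mean - 1.96 * std)
                & (report.y_true <= report.mean + 1.96 * std),
            }
        )
        loo_df.to_csv(out / "loo_report.csv", index=False)
        model = em.to_dict()
        model["predictors"] = list(PREDICTOR_FIELDS)
        (out / "gp_model.json").write_text(json.dumps(model, indent=1))
        return {"emulator": em, "loo": report, "loo_table": loo_df}

    results["gp"] = stage("gp")(_gp)

    # ---------------------------------------------------------------- pca
    def _pca():
        res = pca_performance(ftab)
        payload = {
            "explained_variance_ratio": res.explained_variance_ratio.tolist(),
            "loadings": res.loadings.tolist(),
            "theta_rad": res.theta,
            "performance_r2_pc1": res.performance_r2_pc1,
        }
        (out / "pca.json").write_text(json.dumps(payload, indent=1))
        return res

    results["pca"] = stage("pca")(_pca)

    # --------------------------------------------------------- mechanistic
    def _mechanistic():
        records = results["records"]
        split = cohort_ventilatory_split(records)
        split.to_csv(out / "ventilatory_split.csv", index=False)
        sims = []
        for rec in records[: config.n_ode_patients]:
            tr = rec.trace
            knots_t = np.array([tr.warmup_start_s, tr.ramp_start_s, tr.exhaustion_s, tr.recovery_end_s])
            knots_w = np.interp(knots_t, tr.time, tr.work_rate)
            ds = None
            if config.deadspace_mode == "linear" and rec.truth is not None:
                row = split.loc[split["patient_id"] == rec.patient_id].iloc[0]
                ds = DeadSpaceParams(vdb=row["vdb_Lmin"], a=row["a_Lmin_per_W"])
            sim = simulate_cardioresp(
                config.ode_params,
                (knots_t, knots_w),
                deadspace=ds,
                t_span=(tr.warmup_start_s, tr.exhaustion_s),
                rtol=1e-8,
            )
            peak = sim.iloc[-30:]
            sims.append(
                {
                    "patient_id": rec.patient_id,
                    "ve_peak_pred_Lmin": float(peak["ve_Lmin"].mean()),
                    "ve_peak_data_Lmin": float(
                        tr.ve[(tr.time >= tr.exhaustion_s - 30)
                              & (tr.time <= tr.exhaustion_s)].mean()
                    ),
                    "va_peak_pred_Lmin": float(peak["va_Lmin"].mean()),
                    "deadspace_mode": config.deadspace_mode,
                }
            )
        if sims:
            pd.DataFrame(sims).to_csv(out / "mechanistic_sim.csv", index=False)
        return split

    results["ventilatory_split"] = stage("mechanistic")(_mechanistic)

    # ------------------------------------------------------------ manifest
    loo = results["gp"]["loo"]
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": _jsonable(dataclasses.asdict(config)),
        "versions": {
            "cpetcf": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": timings,
        "summary": {
            "n_patients": int(len(ftab)),
            "mse_loo": loo.mse_loo,
            "mse_loo_pct_of_mean_get": 100.0 * loo.mse_loo_relative,
            "ci95_coverage_count": loo.coverage_count,
            "pca_pc1_explained_pct": 100.0
            * float(results["pca"].explained_variance_ratio[0]),
            "performance_r2_pc1": results["pca"].performance_r2_pc1,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
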