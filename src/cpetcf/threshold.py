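"""Automated gas exchange threshold (GET) detection via the V-slope method.

Below the anaerobic threshold, VCO2 tracks VO2 through the cellular respiratory
quotient; above it, bicarbonate buffering of lactate adds excess CO2 and the
VCO2-vs-VO2 relation steepens.  The detector fits a continuous two-segment
piecewise-linear model of VCO2 on VO2 over the ramp window (same exclusions as
the ventilatory fits: first 180 s and final 60 s dropped), searching candidate
breakpoints on a grid over the central 10-90% of the VO2 range and keeping the
knot with minimal residual sum of squares.  An F-test against a single straight
line guards against spurious breakpoints on linear data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .trace import CPETTrace
from .features import ramp_fit_window

__all__ = ["GETResult", "detect_get_vslope", "two_segment_fit"]


@dataclass
class GETResult:
    """Outcome of V-slope detection on one trace."""

    get_vo2: float  # L/min at the breakpoint
    get_time_s: Optional[float]  # first ramp-phase crossing of get_vo2
    slope_below: float  # dVCO2/dVO2 below the knot
    slope_above: float  # dVCO2/dVO2 above the knot
    rss: float  # residual sum of squares of the two-segment fit
    valid: bool
    reason: str = ""


def two_segment_fit(x: np.ndarray, y: np.ndarray, knot: float) -> tuple[np.ndarray, float]:
    """Continuous two-segment least squares with a fixed knot.

    Basis: [1, x, (x - knot)_+], so the segments share the knot point.
    Returns (coefficients, rss).
    """
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - knot, 0.0)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def detect_get_vslope(
    trace: CPETTrace,
    knot_grid_frac: float = 0.01,
    alpha: float = 0.05,
    smooth_window_s: float = 15.0,
    min_samples: int = 20,
    interior_frac: tuple[float, float] = (0.10, 0.90),
) -> GETResult:
    """Locate the V-slope breakpoint of VCO2 vs VO2 on the ramp window.

    Parameters
    ----------
    knot_grid_frac : candidate-knot grid step as a fraction of the VO2 range.
    alpha : significance level of the two-segment-vs-line F-test.
    smooth_window_s : moving-average window applied to VO2 before locating the
        threshold crossing time (avoids noise-triggered early crossings).
    interior_frac : fraction band of the VO2 range searched for the knot.
    """
    window = ramp_fit_window(trace)
    mask = (trace.time >= window[0]) & (trace.time <= window[1])
    n = int(mask.sum())
    if n < min_samples:
        raise ValueError(f"ramp window holds {n} samples; need >= {min_samples}")
    x = trace.vo2[mask]
    y = trace.vco2[mask]
    x_range = float(x.max() - x.min())
    if x_range <= 0:
        raise ValueError("VO2 constant over the ramp window; V-slope undefined")

    lo = x.min() + interior_frac[0] * x_range
    hi = x.min() + interior_frac[1] * x_range
    step = knot_grid_frac * x_range
    knots = np.arange(lo, hi + 0.5 * step, step)

    best_knot, best_coef, best_rss = None, None, np.inf
    for c in knots:
        coef, rss = two_segment_fit(x, y, c)
        if rss < best_rss:
            best_knot, best_coef, best_rss = float(c), coef, rss

    # single-line null model
    X1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss_line = float(np.sum((y - X1 @ coef1) ** 2))

    slope_below = float(best_coef[1])
    slope_above = float(best_coef[1] + best_coef[2])

    valid = True
    reason = ""
    scale = float(np.sum(y**2)) + 1e-300
    if rss_line <= 1e-12 * scale:
        # the data are a perfect straight line: no breakpoint exists
        valid, reason = False, "single line already fits to numerical precision"
    else:
        # two-segment model spends 2 extra effective parameters (delta-slope + knot)
        df2 = n - 4
        if df2 <= 0:
            valid, reason = False, "too few samples for the F-test"
        else:
            f_stat = ((rss_line - best_rss) / 2.0) / (best_rss / df2) if best_rss > 0 else np.inf
            p = float(stats.f.sf(f_stat, 2, df2))
            if p >= alpha:
                valid, reason = False, f"two-segment fit not better than a line (p={p:.3g})"
    if valid and slope_above < slope_below:
        valid, reason = False, "slope above knot below slope below knot (no excess CO2)"

    get_time = _crossing_time(trace, best_knot, smooth_window_s) if valid else None
    return GETResult(
        get_vo2=best_knot,
        get_time_s=get_time,
        slope_below=slope_below,
        slope_above=slope_above,
        rss=best_rss,
        valid=valid,
        reason=reason,
    )


def _crossing_time(trace: CPETTrace, get_vo2: float, smooth_window_s: float) -> Optional[float]:
    """First ramp-phase time at which (smoothed) VO2 reaches the threshold."""
    mask = (trace.time >= trace.ramp_start_s) & (trace.time <= trace.exhaustion_s)
    t = trace.time[mask]
    v = trace.vo2[mask]
    if smooth_window_s > 0 and t.size > 2:
        dt = float(np.median(np.diff(t)))
        width = max(1, int(round(smooth_window_s / dt)))
        kernel = np.ones(width) / width
        pad = width // 2
        v = np.convolve(np.pad(v, pad, mode="edge"), kernel, mode="same")[pad : pad + t.size]
    hits = np.flatnonzero(v >= get_vo2)
    return float(t[hits[0]]) if hits.size else None
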