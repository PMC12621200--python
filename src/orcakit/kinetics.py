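"""Initial-rate extraction and control normalization for the incision assay.

Raw plate-reader traces are turned into initial slopes ("the linear part" of
each progress curve, anchored at t=0), then normalized against the DMSO
(basal) and APE1 (full-turnover) controls to give % activation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .types import KineticTrace, RateEstimate

__all__ = [
    "LinearWindow",
    "detect_linear_window",
    "initial_rate",
    "percent_activation",
    "relative_rate",
    "saturation_profile",
    "SaturationFit",
    "plate_rates",
]


@dataclass(frozen=True)
class LinearWindow:
    start: int
    stop: int          # exclusive
    low_quality: bool  # no prefix met the r2 requirement

    def as_slice(self) -> slice:
        return slice(self.start, self.stop)


def _ols(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form simple OLS: slope, intercept, r2, slope SE.

    r2 is defined as 1 when the response has zero variance (a constant trace
    is a perfect fit of a flat line), avoiding 0/0.
    """
    n = t.size
    if np.ptp(t) == 0:
        raise ValueError("degenerate window: all times equal")
    tbar, fbar = t.mean(), f.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (f - fbar)))
    slope = sxy / sxx
    intercept = fbar - slope * tbar
    resid = f - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((f - fbar) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    se = math.sqrt(ss_res / (n - 2) / sxx) if n > 2 else float("nan")
    return slope, intercept, r2, se


def detect_linear_window(
    trace: KineticTrace, min_frac: float = 0.3, r2_min: float = 0.99
) -> LinearWindow:
    """Longest prefix of the trace that still fits a line with r2 >= r2_min.

    The window is anchored at the first point (initial rates are defined at
    t=0) and must span at least ``max(3, ceil(min_frac * n))`` points.  If no
    such prefix qualifies, the minimal window is returned flagged
    ``low_quality``.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    n = len(trace)
    min_len = max(3, math.ceil(min_frac * n))
    best = None
    for stop in range(min_len, n + 1):
        _, _, r2, _ = _ols(trace.times[:stop], trace.fluorescence[:stop])
        if r2 >= r2_min:
            best = stop
    if best is not None:
        return LinearWindow(0, best, low_quality=False)
    return LinearWindow(0, min_len, low_quality=True)


def initial_rate(trace: KineticTrace, window: LinearWindow | None = None) -> RateEstimate:
    """OLS slope over the (detected or supplied) linear window."""
    if window is None:
        window = detect_linear_window(trace)
    if window.start < 0 or window.stop > len(trace) or window.stop - window.start < 3:
        raise ValueError("window out of bounds or shorter than 3 points")
    sl = window.as_slice()
    slope, intercept, r2, se = _ols(trace.times[sl], trace.fluorescence[sl])
    return RateEstimate(
        slope=slope, intercept=intercept, window=(window.start, window.stop),
        r2=r2, se=se, low_quality=window.low_quality,
    )


def percent_activation(v_c: float, v_dmso: float, v_ape1: float) -> float:
    """% activation of the APE1 full-turnover control, DMSO-baselined:
    100 * (v_c - v_dmso) / (v_ape1 - v_dmso).

    0% = basal (DMSO) rate, 100% = APE1-coupled full turnover.  May be
    negative (inhibition below basal) or exceed 100.
    """
    if v_ape1 <= v_dmso:
        raise ValueError("invalid control pair: APE1 rate must exceed DMSO rate")
    return 100.0 * (v_c - v_dmso) / (v_ape1 - v_dmso)


def relative_rate(v_c: float, v_ref: float) -> float:
    """Rate relative to a reference well (e.g. wt enzyme + DMSO)."""
    if v_ref <= 0:
        raise ValueError("reference rate must be positive")
    return v_c / v_ref


@dataclass(frozen=True)
class SaturationFit:
    vmax: float
    km: float
    non_saturating: bool   # fitted Km exceeds the largest tested substrate level
    rss: float


def saturation_profile(points: Sequence[tuple[float, float]]) -> SaturationFit:
    """Michaelis-Menten fit v = Vmax*S/(Km+S) to (substrate, rate) data.

    If the fitted Km exceeds the maximum tested substrate concentration the
    data do not establish a plateau and the fit is flagged non-saturating.
    """
    s = np.asarray([p[0] for p in points], float)
    v = np.asarray([p[1] for p in points], float)
    if np.unique(s).size < 4:
        raise ValueError("need >= 4 distinct substrate levels")
    if np.all(v == 0):
        return SaturationFit(vmax=0.0, km=float(np.median(s)), non_saturating=False, rss=0.0)
    smax = float(s.max())
    vmax0 = float(v.max())
    km0 = float(np.median(s))
    popt, _ = curve_fit(
        lambda S, vmax, km: vmax * S / (km + S), s, v,
        p0=(vmax0, km0), bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20000,
    )
    vmax, km = float(popt[0]), float(popt[1])
    rss = float(np.sum((v - vmax * s / (km + s)) ** 2))
    return SaturationFit(vmax=vmax, km=km, non_saturating=km > smax, rss=rss)


def plate_rates(
    traces: Iterable[KineticTrace],
    min_frac: float = 1.0,
    r2_min: float = 0.0,
) -> pd.DataFrame:
    """Tidy per-well rates table with % activation.

    Control rates are averaged at the rate level (mean of replicate slopes,
    SE = SD/sqrt(n)); every compound well is then normalized against the
    mean DMSO and APE1 rates.  Columns: well index, role, compound_id,
    conc_uM, slope, se, r2, low_quality, pct_activation.
    """
    rows = []
    for i, tr in enumerate(traces):
        est = initial_rate(tr, detect_linear_window(tr, min_frac, r2_min))
        rows.append({
            "well": i, "role": tr.role, "compound_id": tr.compound_id,
            "conc_uM": tr.concentration, "replicate": tr.replicate,
            "slope": est.slope, "se": est.se, "r2": est.r2,
            "low_quality": est.low_quality,
        })
    df = pd.DataFrame(rows)
    v_dmso = df.loc[df.role == "dmso", "slope"].mean()
    v_ape1 = df.loc[df.role == "ape1", "slope"].mean()
    if pd.notna(v_dmso) and pd.notna(v_ape1):
        df["pct_activation"] = [
            percent_activation(s, v_dmso, v_ape1) if role == "compound" else np.nan
            for s, role in zip(df.slope, df.role)
        ]
    else:
        df["pct_activation"] = np.nan
    return df
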