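"""Bell-shaped activation dose-response fitting and AC50/IC50 extraction.

An activator that binds the active site accelerates turnover at low
concentration but competes with substrate at high concentration, so
% activation rises and then falls.  The model is the product of two
first-order (Hill slope 1) terms,

    A(c) = a_max * c/(c + k_a) * k_i/(k_i + c)

with ``k_a`` the rising-limb midpoint and ``k_i`` the falling-limb midpoint.
AC50 is read off the fitted curve's rising limb: the smallest concentration
at which the curve crosses 50% of the full-turnover control from below.
Compounds whose curve never reaches 50% within the tested range are
reported censored ("AC50 > c_max").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from . import kinetics
from .types import KineticTrace

__all__ = [
    "DoseResponsePoint",
    "BellFitResult",
    "PotencyResult",
    "bell_model",
    "fit_bell",
    "ac50_from_fit",
    "classify_compound",
    "ac50_pipeline",
    "HIT_AC50_UM",
]

HIT_AC50_UM = 100.0  # primary-hit rule: AC50 below 100 uM


@dataclass(frozen=True)
class DoseResponsePoint:
    concentration: float   # uM, > 0
    pct_activation: float
    se: float = float("nan")

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


@dataclass(frozen=True)
class BellFitResult:
    a_max: float   # percent
    k_a: float     # uM, rising-limb midpoint
    k_i: float     # uM, falling-limb midpoint
    rss: float
    converged: bool

    def curve(self, c: np.ndarray | float) -> np.ndarray | float:
        return bell_model(c, self.a_max, self.k_a, self.k_i)


@dataclass(frozen=True)
class PotencyResult:
    ac50: float                  # uM; censoring bound when censored
    censored: str                # none | above_max | below_min
    classification: str          # activator | inhibitor | inactive
    ic50: Optional[float] = None
    hit: bool = False
    fit: Optional[BellFitResult] = None


def bell_model(c, a_max, k_a, k_i):
    c = np.asarray(c, dtype=float)
    return a_max * (c / (c + k_a)) * (k_i / (k_i + c))


def fit_bell(points: Sequence[DoseResponsePoint], weighted: bool = False) -> BellFitResult:
    """Least-squares fit of the bell model.

    With ``weighted=True`` residuals are scaled by 1/se (i.e. 1/se^2
    weighting) where SEs are available.  The default is unweighted: SEs
    estimated from a handful of replicates are so noisy that inverse-variance
    weighting degrades the fit more than it helps.  The optimizer is
    deterministically multi-started over a fixed log-spaced grid of
    (k_a, k_i) initial values spanning the tested range; k_a and k_i are
    fitted on a log scale to keep them positive.
    """
    conc = np.array([p.concentration for p in points], float)
    y = np.array([p.pct_activation for p in points], float)
    se = np.array([p.se for p in points], float)
    if np.unique(conc).size < 5:
        raise ValueError("need >= 5 distinct concentrations")
    use_w = weighted and np.all(np.isfinite(se)) and np.all(se > 0)
    w = 1.0 / se if use_w else np.ones_like(y)

    if np.allclose(y, 0.0):
        return BellFitResult(a_max=0.0, k_a=float(np.median(conc)),
                             k_i=float(conc.max()), rss=0.0, converged=False)

    cmin, cmax = conc.min(), conc.max()
    a0 = max(float(y.max()), 1.0)

    def resid(theta):
        a, lka, lki = theta
        # clamp log-params so the optimizer cannot overflow exp()
        ka = math.exp(min(max(lka, -40.0), 40.0))
        ki = math.exp(min(max(lki, -40.0), 40.0))
        return w * (bell_model(conc, a, ka, ki) - y)

    best = None
    for ka0 in np.geomspace(cmin, cmax, 4):
        for ki0 in np.geomspace(cmin, cmax * 100.0, 4):
            sol = least_squares(resid, x0=(a0, math.log(ka0), math.log(ki0)),
                                method="lm", max_nfev=5000)
            if best is None or sol.cost < best.cost:
                best = sol
    a, lka, lki = best.x
    k_a = math.exp(min(max(lka, -40.0), 40.0))
    k_i = math.exp(min(max(lki, -40.0), 40.0))
    rss = float(np.sum((bell_model(conc, a, k_a, k_i) - y) ** 2))
    # a_max is clamped at 0: a negative fitted amplitude means "no activation"
    return BellFitResult(a_max=float(max(a, 0.0)), k_a=float(k_a), k_i=float(k_i),
                         rss=rss, converged=bool(best.success))


def ac50_from_fit(
    fit: BellFitResult,
    conc_range: tuple[float, float],
    target: float = 50.0,
    rel_tol: float = 1e-4,
) -> PotencyResult:
    """AC50 from the fitted curve's rising limb.

    The smallest c in ``conc_range`` where A(c) crosses ``target`` from
    below, located by bisection to ``rel_tol`` relative tolerance.  If the
    curve never reaches the target inside the range: censored above_max
    (classification left as inactive; see classify_compound for the
    inhibitor branch).
    """
    if not fit.converged:
        raise ValueError("cannot extract AC50 from a non-converged fit")
    c_lo, c_hi = conc_range
    if not 0 < c_lo < c_hi:
        raise ValueError("invalid concentration range")
    c_peak = math.sqrt(fit.k_a * fit.k_i)  # argmax of the bell model
    c_top = min(c_hi, max(c_peak, c_lo))
    if fit.curve(c_lo) >= target:
        return PotencyResult(ac50=c_lo, censored="below_min", classification="activator", fit=fit)
    if fit.curve(c_top) < target:
        return PotencyResult(ac50=c_hi, censored="above_max", classification="inactive", fit=fit)
    lo, hi = c_lo, c_top
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        if fit.curve(mid) >= target:
            hi = mid
        else:
            lo = mid
    ac50 = math.sqrt(lo * hi)
    return PotencyResult(ac50=float(ac50), censored="none",
                         classification="activator",
                         hit=ac50 < HIT_AC50_UM, fit=fit)


def classify_compound(
    result: PotencyResult,
    points: Sequence[DoseResponsePoint],
    relative_rates: Optional[Sequence[tuple[float, float]]] = None,
    inhibition_threshold: float = 10.0,
) -> PotencyResult:
    """Final activator / inhibitor / inactive call.

    Activator: an uncensored AC50 exists.  Inhibitor: the best-fit (or
    observed) response drops below -inhibition_threshold % activation at
    some tested concentration; the IC50 is then the midpoint of a monotone
    decreasing hyperbolic fit r(c) = 1/(1 + c/IC50) to the relative rates
    (v/v_dmso), when supplied.  Inactive otherwise.
    """
    if result.censored == "none" or result.censored == "below_min":
        return result
    responses = np.array([p.pct_activation for p in points], float)
    fitted = np.asarray(result.fit.curve(np.array([p.concentration for p in points])))
    if np.min(np.minimum(responses, fitted)) <= -inhibition_threshold:
        ic50 = None
        if relative_rates:
            c = np.array([p[0] for p in relative_rates], float)
            r = np.array([p[1] for p in relative_rates], float)
            popt, _ = curve_fit(lambda cc, ic: 1.0 / (1.0 + cc / ic), c, r,
                                p0=(float(np.median(c)),), bounds=(1e-9, np.inf),
                                maxfev=10000)
            ic50 = float(popt[0])
        return PotencyResult(ac50=result.ac50, censored=result.censored,
                             classification="inhibitor", ic50=ic50,
                             hit=False, fit=result.fit)
    return result


def aggregate_points(rates: pd.DataFrame) -> list[DoseResponsePoint]:
    """Collapse a per-well rates table (from kinetics.plate_rates) to one
    dose-response point per concentration (mean % activation, SE = SD/sqrt(n))."""
    comp = rates[rates.role == "compound"]
    pts = []
    for c, grp in comp.groupby("conc_uM"):
        vals = grp.pct_activation.to_numpy()
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        pts.append(DoseResponsePoint(float(c), float(vals.mean()), se))
    return sorted(pts, key=lambda p: p.concentration)


def ac50_pipeline(
    traces: Iterable[KineticTrace],
    min_frac: float = 1.0,
    r2_min: float = 0.0,
    inhibition_threshold: float = 10.0,
) -> pd.DataFrame:
    """End-to-end: traces -> rates -> % activation -> bell fit -> potency.

    Returns one row per compound with AC50 (uM), censoring, classification,
    the primary-hit flag (uncensored AC50 < 100 uM) and fit parameters.
    """
    rates = kinetics.plate_rates(traces, min_frac=min_frac, r2_min=r2_min)
    v_dmso = rates.loc[rates.role == "dmso", "slope"].mean()
    rows = []
    for cid, grp in rates[rates.role == "compound"].groupby("compound_id"):
        sub = pd.concat([grp, rates[rates.role != "compound"]])
        pts = aggregate_points(sub)
        conc = [p.concentration for p in pts]
        fit = fit_bell(pts)
        if not fit.converged:
            rows.append({"compound_id": cid, "ac50_uM": np.nan, "censored": "above_max",
                         "classification": "inactive", "ic50_uM": np.nan, "hit": False,
                         "a_max": fit.a_max, "k_a": fit.k_a, "k_i": fit.k_i, "rss": fit.rss})
            continue
        res = ac50_from_fit(fit, (min(conc), max(conc)))
        rel = None
        if np.isfinite(v_dmso) and v_dmso > 0:
            rel = [(float(c), float(s) / float(v_dmso))
                   for c, s in zip(grp.conc_uM, grp.slope)]
        res = classify_compound(res, pts, relative_rates=rel,
                                inhibition_threshold=inhibition_threshold)
        rows.append({
            "compound_id": cid,
            "ac50_uM": res.ac50 if res.censored == "none" else np.nan,
            "censored": res.censored,
            "classification": res.classification,
            "ic50_uM": res.ic50 if res.ic50 is not None else np.nan,
            "hit": res.hit,
            "a_max": fit.a_max, "k_a": fit.k_a, "k_i": fit.k_i, "rss": fit.rss,
        })
    return pd.DataFrame(rows)
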