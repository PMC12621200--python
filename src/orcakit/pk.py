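"""In-vitro pharmacokinetic calculations: microsomal stability, Caco-2
apparent permeability with efflux/P-gp logic, and kinetic solubility.

Microsomal stability assumes first-order loss of parent compound; the
elimination rate constant k_el is the negative slope of ln(remaining signal)
vs time, t1/2 = ln2/k_el, and intrinsic clearance scales k_el by the
incubation volume per mg of microsomal protein (1000 uL/mL at 0.42 mg/mL,
i.e. Clint = k_el * 1000 / 0.42 uL/min/mg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import TransportMeasurement

__all__ = [
    "MicrosomalResult",
    "TransportResult",
    "SolubilityResult",
    "fit_microsomal",
    "calc_papp",
    "efflux_ratio",
    "classify_efflux",
    "transport_summary",
    "kinetic_solubility",
    "PROTEIN_MG_PER_ML",
    "EFFLUX_THRESHOLD",
]

PROTEIN_MG_PER_ML = 0.42   # microsomal protein concentration in the incubation
EFFLUX_THRESHOLD = 2.0     # efflux ratio above which active efflux is called
SOLUBILITY_RANGE_UM = (2.0, 350.0)


@dataclass(frozen=True)
class MicrosomalResult:
    kel: float        # 1/min; 0 when censored
    t_half: float     # min; inf when censored
    clint: float      # uL/min/mg; 0 when censored
    r2: float
    censored: bool    # no measurable decay over the assay span
    assay_span: float  # min


def fit_microsomal(
    times_min: Sequence[float],
    remaining: Sequence[float],
    protein_mg_per_ml: float = PROTEIN_MG_PER_ML,
) -> MicrosomalResult:
    """Log-linear regression of the remaining-parent time course.

    OLS of ln(remaining) vs time; kel = -slope.  A non-positive kel means no
    measurable decay: the compound is reported stable (censored), with
    t1/2 > assay span.  For uncensored fits t_half * kel == ln 2 exactly.
    """
    t = np.asarray(times_min, float)
    r = np.asarray(remaining, float)
    if t.size < 3:
        raise ValueError("need >= 3 time points")
    if np.any(r <= 0):
        raise ValueError("remaining fractions must be positive to take logs")
    slope, intercept = np.polyfit(t, np.log(r), 1)
    pred = intercept + slope * t
    ss_tot = float(np.sum((np.log(r) - np.log(r).mean()) ** 2))
    ss_res = float(np.sum((np.log(r) - pred) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    kel = -float(slope)
    span = float(t.max() - t.min())
    if kel <= 0:
        return MicrosomalResult(kel=0.0, t_half=float("inf"), clint=0.0,
                                r2=r2, censored=True, assay_span=span)
    return MicrosomalResult(
        kel=kel,
        t_half=math.log(2) / kel,
        clint=kel * 1000.0 / protein_mg_per_ml,
        r2=r2, censored=False, assay_span=span,
    )


def calc_papp(m: TransportMeasurement) -> float:
    """Apparent permeability in nm/s from one transwell measurement.

    Papp = V_A / (Area * Time) * amount_acceptor / amount_donor_initial,
    with the acceptor volume in cm^3; the cm/s result is reported in nm/s
    (x 1e7).
    """
    if m.amount_donor_initial_nmol <= 0:
        raise ValueError("initial donor amount must be positive")
    v_a_cm3 = m.v_acceptor_uL / 1000.0
    papp_cm_s = (v_a_cm3 / (m.area_cm2 * m.time_s)) \
        * (m.amount_acceptor_nmol / m.amount_donor_initial_nmol)
    return papp_cm_s * 1e7


def efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """Papp(B->A) divided by Papp(A->B)."""
    if papp_ab <= 0:
        raise ValueError("Papp(A->B) must be positive")
    return papp_ba / papp_ab


@dataclass(frozen=True)
class TransportResult:
    papp_ab: float
    papp_ba: float
    efflux_ratio: float
    efflux_ratio_inhibited: Optional[float]
    active_efflux: bool
    pgp_substrate: bool


def classify_efflux(
    ratio: float,
    ratio_inhibited: Optional[float] = None,
    rel_decrease_min: float = 0.10,
) -> tuple[bool, bool]:
    """Active-efflux and P-gp-substrate calls from efflux ratios.

    Active efflux when the ratio exceeds 2.  P-gp substrate when, in
    addition, the verapamil-inhibited ratio shows a strict decrease of at
    least ``rel_decrease_min`` (relative), guarding against noise-level
    changes.
    """
    active = ratio > EFFLUX_THRESHOLD
    pgp = (
        active
        and ratio_inhibited is not None
        and ratio_inhibited < ratio * (1.0 - rel_decrease_min)
    )
    return active, bool(pgp)


def transport_summary(
    measurements: Sequence[TransportMeasurement],
    rel_decrease_min: float = 0.10,
) -> TransportResult:
    """Full bidirectional transport analysis.

    Expects one AB and one BA measurement without inhibitor; an optional
    verapamil pair yields the inhibited ratio for the P-gp call.
    """
    def _papp(direction: str, inhibitor: str) -> Optional[float]:
        sel = [m for m in measurements
               if m.direction == direction and m.inhibitor == inhibitor]
        if not sel:
            return None
        return float(np.mean([calc_papp(m) for m in sel]))

    papp_ab = _papp("AB", "none")
    papp_ba = _papp("BA", "none")
    if papp_ab is None or papp_ba is None:
        raise ValueError("need AB and BA measurements without inhibitor")
    ratio = efflux_ratio(papp_ba, papp_ab)
    ab_i, ba_i = _papp("AB", "verapamil"), _papp("BA", "verapamil")
    ratio_i = efflux_ratio(ba_i, ab_i) if ab_i is not None and ba_i is not None else None
    active, pgp = classify_efflux(ratio, ratio_i, rel_decrease_min)
    return TransportResult(
        papp_ab=papp_ab, papp_ba=papp_ba, efflux_ratio=ratio,
        efflux_ratio_inhibited=ratio_i, active_efflux=active, pgp_substrate=pgp,
    )


@dataclass(frozen=True)
class SolubilityResult:
    concentration_uM: float
    calibration_r2: float
    out_of_range: bool       # outside the ~2-350 uM effective assay range
    poor_calibration: bool   # calibration R^2 < 0.99


def kinetic_solubility(
    calibration: Sequence[tuple[float, float]],
    sample_abs: float,
    dilution_factor: float = 2.0,
) -> SolubilityResult:
    """Quantify solubility against an absorbance calibration line.

    OLS through the calibration points (conc uM, absorbance); the sample
    concentration is dilution_factor * (abs - intercept) / slope.  Results
    outside the assay's effective range (~2-350 uM) or from a calibration
    with R^2 < 0.99 are flagged.
    """
    pts = np.asarray(calibration, float)
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 calibration points (including blank)")
    conc, ab = pts[:, 0], pts[:, 1]
    if np.ptp(ab) == 0:
        raise ValueError("degenerate calibration: zero slope (flat absorbance)")
    slope, intercept = np.polyfit(conc, ab, 1)
    if slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    pred = intercept + slope * conc
    ss_tot = float(np.sum((ab - ab.mean()) ** 2))
    ss_res = float(np.sum((ab - pred) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    c = dilution_factor * (sample_abs - intercept) / slope
    lo, hi = SOLUBILITY_RANGE_UM
    return SolubilityResult(
        concentration_uM=float(c),
        calibration_r2=r2,
        out_of_range=not (lo <= c <= hi),
        poor_calibration=r2 < 0.99,
    )
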