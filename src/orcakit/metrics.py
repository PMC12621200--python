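"""Compound-efficiency metrics and virtual-screening triage arithmetic.

Potency-normalized efficiency metrics for activators mirror the standard
ligand-efficiency family, with pAC50 in place of pIC50:

    pAC50 = -log10(AC50 [mol/L])
    AcLE  = (1.37 / #heavy atoms) * pAC50
    AcLLE = pAC50 - clogP
    LE    = -(docking score [kcal/mol]) / #heavy atoms

Heavy atoms are counted on the free base; metrics are kept at full precision
internally and rounded only at the reporting layer.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "CompoundRecord",
    "EfficiencyMetrics",
    "heavy_atom_count",
    "strip_adduct_proton",
    "pac50",
    "acle",
    "aclle",
    "ligand_efficiency",
    "le_triage",
    "TriageReport",
    "selectivity_fold",
    "SelectivityResult",
    "efficiency_metrics",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U".split()
)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into element counts.

    Only free-base, single-component formulas are accepted: a salt or
    solvate written with dot components (``.`` or ``·``) is an error, as is
    any unrecognized token.
    """
    if not formula or not formula.strip():
        raise ValueError("empty molecular formula")
    if "." in formula or "·" in formula:
        raise ValueError(
            f"multi-component formula {formula!r}: desalt to the free base first"
        )
    counts: dict[str, int] = {}
    pos = 0
    s = formula.strip()
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or m.group(1) not in _ELEMENTS:
            raise ValueError(f"unparseable formula token at {s[pos:]!r} in {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    return counts


def heavy_atom_count(formula: str) -> int:
    """Number of non-hydrogen atoms in a free-base molecular formula."""
    counts = parse_formula(formula)
    return sum(n for el, n in counts.items() if el != "H")


def strip_adduct_proton(formula: str) -> str:
    """Convert an [M+H]+ HRMS formula to the free base by removing one H."""
    counts = parse_formula(formula)
    if counts.get("H", 0) < 1:
        raise ValueError(f"no hydrogen to strip in {formula!r}")
    counts["H"] -= 1
    parts = []
    for el in sorted(counts, key=lambda e: (e != "C", e != "H", e)):
        n = counts[el]
        if n > 0:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


@dataclass
class CompoundRecord:
    """Identity and measured/calculated properties of one screening compound."""

    id: str
    formula: str = ""
    heavy_atoms: Optional[int] = None
    clogp: Optional[float] = None
    docking_score: Optional[float] = None   # kcal/mol, more negative = better
    ac50: Optional[float] = None            # uM
    panel_ic50s: Sequence[float] = field(default_factory=tuple)
    panel_censored: Sequence[bool] = field(default_factory=tuple)
    pains_flag: bool = False
    reos_flag: bool = False

    def __post_init__(self) -> None:
        if self.heavy_atoms is None and self.formula:
            self.heavy_atoms = heavy_atom_count(self.formula)
        if self.heavy_atoms is not None and self.heavy_atoms < 1:
            raise ValueError("heavy_atoms must be >= 1")


@dataclass(frozen=True)
class EfficiencyMetrics:
    pac50: float
    acle: Optional[float]
    aclle: Optional[float]
    le: Optional[float]
    selectivity_fold: Optional["SelectivityResult"]


def pac50(ac50_uM: float) -> float:
    """pAC50 = -log10 of the AC50 expressed in mol/L (molar convention)."""
    if ac50_uM <= 0:
        raise ValueError("AC50 must be positive")
    return -math.log10(ac50_uM * 1e-6)


def acle(pac50_value: float, heavy_atoms: int) -> float:
    """Activator ligand efficiency: (1.37 / #heavy atoms) * pAC50."""
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return (1.37 / heavy_atoms) * pac50_value


def aclle(pac50_value: float, clogp: float) -> float:
    """Activator lipophilic ligand efficiency: pAC50 - clogP."""
    return pac50_value - clogp


def ligand_efficiency(docking_score: float, heavy_atoms: int) -> float:
    """Docking-based ligand efficiency: -(docking score) / #heavy atoms."""
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return -docking_score / heavy_atoms


@dataclass(frozen=True)
class TriageReport:
    n_input: int
    n_skipped_no_score: int
    n_fail_le: int
    n_fail_pains: int
    n_fail_reos: int
    n_kept: int


def le_triage(
    records: Sequence[CompoundRecord], le_min: float = 0.40
) -> tuple[list[CompoundRecord], TriageReport]:
    """Virtual-screening triage: keep records with LE >= le_min (boundary
    inclusive) and neither PAINS nor REOS flags set.

    Records without a docking score are counted as skipped, never silently
    dropped.  Filter stages are counted in application order (LE, PAINS,
    REOS) for the funnel report.
    """
    kept: list[CompoundRecord] = []
    skipped = fail_le = fail_pains = fail_reos = 0
    for rec in records:
        if rec.docking_score is None:
            skipped += 1
            continue
        if rec.heavy_atoms is None:
            raise ValueError(f"record {rec.id}: heavy atom count unavailable")
        if ligand_efficiency(rec.docking_score, rec.heavy_atoms) < le_min:
            fail_le += 1
        elif rec.pains_flag:
            fail_pains += 1
        elif rec.reos_flag:
            fail_reos += 1
        else:
            kept.append(rec)
    report = TriageReport(
        n_input=len(records), n_skipped_no_score=skipped, n_fail_le=fail_le,
        n_fail_pains=fail_pains, n_fail_reos=fail_reos, n_kept=len(kept),
    )
    return kept, report


@dataclass(frozen=True)
class SelectivityResult:
    fold: float
    lower_bound: bool  # True when every panel IC50 is itself a ">x" bound

    def __str__(self) -> str:
        return f">{self.fold:g}" if self.lower_bound else f"{self.fold:g}"


def selectivity_fold(
    panel_ic50s: Sequence[float],
    ac50_uM: float,
    censored: Sequence[bool] | bool = False,
) -> SelectivityResult:
    """Fold selectivity: lowest off-target panel IC50 divided by the OGG1 AC50.

    ``censored`` marks panel entries that are lower bounds (">x"); when all
    entries are censored the result is itself a lower bound.
    """
    if ac50_uM <= 0:
        raise ValueError("AC50 must be positive")
    vals = list(panel_ic50s)
    if not vals:
        raise ValueError("panel must be non-empty")
    cens = [censored] * len(vals) if isinstance(censored, bool) else list(censored)
    if len(cens) != len(vals):
        raise ValueError("censored flags must match panel length")
    uncensored = [v for v, c in zip(vals, cens) if not c]
    if uncensored:
        return SelectivityResult(fold=min(uncensored) / ac50_uM, lower_bound=False)
    return SelectivityResult(fold=min(vals) / ac50_uM, lower_bound=True)


def efficiency_metrics(rec: CompoundRecord) -> EfficiencyMetrics:
    """All efficiency metrics computable from one compound record."""
    if rec.ac50 is None:
        raise ValueError(f"record {rec.id}: AC50 required for efficiency metrics")
    p = pac50(rec.ac50)
    sel = None
    if rec.panel_ic50s:
        cens = rec.panel_censored if len(rec.panel_censored) else False
        sel = selectivity_fold(rec.panel_ic50s, rec.ac50, cens)
    return EfficiencyMetrics(
        pac50=p,
        acle=acle(p, rec.heavy_atoms) if rec.heavy_atoms else None,
        aclle=aclle(p, rec.clogp) if rec.clogp is not None else None,
        le=ligand_efficiency(rec.docking_score, rec.heavy_atoms)
        if rec.docking_score is not None and rec.heavy_atoms else None,
        selectivity_fold=sel,
    )
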