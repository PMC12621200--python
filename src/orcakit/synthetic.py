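"""Synthetic data generators for every pipeline stage.

The generators emulate the mechanistic and statistical structure the
downstream analyses assume:

* incision kinetics whose observed rate rises with activator occupancy and
  falls again at high concentration (competitive occlusion of the active
  site), giving a bell-shaped dose-response;
* first-order microsomal decay with multiplicative (LC-MS-like) noise;
* bidirectional transwell transport that inverts the apparent-permeability
  equation exactly in noiseless mode;
* Cartesian trajectories with Gaussian atomic fluctuation, random rigid
  frame motions, and waters drawn from a known radial density around the
  ligand.

All generators are deterministic for a fixed seed; plate wells use
independent child streams derived from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .types import KineticTrace, Trajectory, TransportMeasurement

__all__ = [
    "MechanisticParams",
    "PlateDesign",
    "TransportGeometry",
    "effective_rate",
    "simulate_trace",
    "simulate_plate",
    "simulate_microsomal",
    "simulate_transport",
    "simulate_trajectory",
    "true_percent_activation",
    "true_ac50",
]

WELL_ROLES = ("compound", "dmso", "ape1", "no_enzyme")


@dataclass(frozen=True)
class MechanisticParams:
    """Rate-law and detection parameters of the fluorescence incision assay.

    The observed incision rate constant is modelled as an activator-occupancy
    term times a competitive-inhibition term,

        k_obs(c) = (k0 + k_acc * c/(c + K_A)) * K_I/(K_I + c)

    so the rate equals the basal ``k0`` without compound, accelerates as the
    activator occupies its site (half-occupancy at ``K_A``) and declines
    again once the compound competes with substrate binding (``K_I``).

    Defaults are chosen so that the ground-truth AC50 (concentration at which
    the rate reaches 50% of the APE1 full-turnover control, above basal) is
    0.50 uM.
    """

    k0: float = 3.125e-6        # basal incision rate, 1/s
    k_acc: float = 6.003125e-5  # maximal activator-driven rate increment, 1/s
    K_A: float = 0.5            # activation half-occupancy, uM
    K_I: float = 50.0           # competitive-inhibition constant, uM
    k_ape1: float = 6.25e-5     # APE1-coupled full-turnover rate, 1/s
    S0: float = 10.0            # substrate concentration, nM
    gain: float = 100.0         # fluorescence per incised substrate, RFU/nM
    F0: float = 50.0            # baseline fluorescence, RFU
    sigma: float = 0.0          # additive Gaussian noise SD, RFU
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k0, self.k_acc, self.k_ape1) < 0:
            raise ValueError("rate constants must be >= 0")
        if self.K_A <= 0 or self.K_I <= 0:
            raise ValueError("K_A and K_I must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.k_ape1 < self.k0:
            raise ValueError("k_ape1 must be >= k0 (full turnover >= basal)")


@dataclass(frozen=True)
class PlateDesign:
    """Layout of a dose-response plate: concentration series, replication,
    read schedule and which control well types to include."""

    concentrations: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)
    replicates: int = 3
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 1610, 10))
    include_dmso: bool = True
    include_ape1: bool = True
    include_no_enzyme: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, float)
        if c.size == 0 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly positive and sorted")
        if len(self.timepoints) < 3:
            raise ValueError("need >= 3 timepoints")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def effective_rate(params: MechanisticParams, c: float | np.ndarray) -> float | np.ndarray:
    """Observed incision rate constant k_obs(c) in 1/s at concentration c (uM).

    k_obs(0) = k0; k_obs -> 0 as c -> infinity; unimodal in c for k_acc > 0.
    """
    carr = np.asarray(c, dtype=float)
    if np.any(carr < 0):
        raise ValueError("concentration must be >= 0")
    occupancy = carr / (carr + params.K_A)
    inhibition = params.K_I / (params.K_I + carr)
    k = (params.k0 + params.k_acc * occupancy) * inhibition
    return float(k) if np.isscalar(c) else k


def true_percent_activation(params: MechanisticParams, c: float | np.ndarray) -> float | np.ndarray:
    """Noise-free % activation implied by the rate law:
    100 * (k_obs(c) - k0) / (k_ape1 - k0)."""
    k = effective_rate(params, c)
    return 100.0 * (np.asarray(k) - params.k0) / (params.k_ape1 - params.k0) if not np.isscalar(c) \
        else 100.0 * (k - params.k0) / (params.k_ape1 - params.k0)


def true_ac50(params: MechanisticParams, c_max: float = 1e4) -> float:
    """Ground-truth AC50: smallest c where the noise-free activation curve
    crosses 50% from below; bisection on the rising limb."""
    c_peak = math.sqrt(params.K_A * params.K_I)
    grid = np.geomspace(1e-6, min(c_peak, c_max), 4000)
    pct = np.asarray(true_percent_activation(params, grid))
    above = np.nonzero(pct >= 50.0)[0]
    if above.size == 0:
        raise ValueError("activation never reaches 50% on the rising limb")
    hi = grid[above[0]]
    lo = grid[above[0] - 1] if above[0] > 0 else 1e-9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if true_percent_activation(params, mid) >= 50.0:
            hi = mid
        else:
            lo = mid
        if hi / lo < 1 + 1e-12:
            break
    return hi


def _role_rate(params: MechanisticParams, role: str, c: float) -> float:
    if role == "compound":
        return float(effective_rate(params, c))
    if role == "dmso":
        return params.k0
    if role == "ape1":
        return params.k_ape1
    if role == "no_enzyme":
        return 0.0
    raise ValueError(f"unknown well role: {role!r}")


def simulate_trace(
    params: MechanisticParams,
    c: float,
    role: str = "compound",
    timepoints: Sequence[float] = tuple(float(t) for t in range(0, 1610, 10)),
    rng: np.random.Generator | None = None,
    compound_id: str = "",
    replicate: int = 0,
) -> KineticTrace:
    """One well's fluorescence time course.

    F(t) = F0 + gain * S0 * (1 - exp(-k t)) + eps,  eps ~ N(0, sigma^2),
    with k set by the well role (compound -> k_obs(c), dmso -> k0,
    ape1 -> k_ape1, no_enzyme -> 0).
    """
    if role not in WELL_ROLES:
        raise ValueError(f"unknown well role: {role!r}")
    t = np.asarray(timepoints, dtype=float)
    k = _role_rate(params, role, c)
    f = params.F0 + params.gain * params.S0 * (1.0 - np.exp(-k * t))
    if params.sigma > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        f = f + rng.normal(0.0, params.sigma, size=t.shape)
    return KineticTrace(
        times=t,
        fluorescence=f,
        role=role,
        compound_id=compound_id,
        concentration=float(c) if role == "compound" else 0.0,
        replicate=replicate,
    )


def simulate_plate(
    params: MechanisticParams,
    design: PlateDesign = PlateDesign(),
    compound_id: str = "CPD-1",
) -> pd.DataFrame:
    """Simulate a full dose-response plate as a long-format table.

    One well per (concentration x replicate), plus ``replicates`` wells for
    each requested control type.  Per-well random streams are spawned from
    the master seed (SeedSequence children), so wells are independent and
    the whole plate is bit-reproducible.

    Returns a DataFrame with the plate CSV schema:
    well, role, compound_id, conc_uM, time_s, rfu.
    """
    wells: list[tuple[str, str, str, float, int]] = []
    for i, c in enumerate(design.concentrations):
        for r in range(design.replicates):
            wells.append((f"C{i:02d}R{r}", "compound", compound_id, float(c), r))
    controls = []
    if design.include_dmso:
        controls.append("dmso")
    if design.include_ape1:
        controls.append("ape1")
    if design.include_no_enzyme:
        controls.append("no_enzyme")
    for role in controls:
        for r in range(design.replicates):
            wells.append((f"{role[:4].upper()}R{r}", role, "", 0.0, r))
    if not wells:
        raise ValueError("empty plate design")

    children = np.random.SeedSequence(params.seed).spawn(len(wells))
    rows = []
    for (well, role, cid, c, rep), ss in zip(wells, children):
        trace = simulate_trace(
            params, c, role, design.timepoints,
            rng=np.random.default_rng(ss), compound_id=cid, replicate=rep,
        )
        for t, f in zip(trace.times, trace.fluorescence):
            rows.append((well, role, cid, c, t, f))
    return pd.DataFrame(rows, columns=["well", "role", "compound_id", "conc_uM", "time_s", "rfu"])


def simulate_microsomal(
    kel_true: float,
    timepoints: Sequence[float] = (0.0, 10.0, 20.0, 30.0, 40.0),
    cv: float = 0.0,
    duplicates: int = 2,
    seed: int = 0,
    include_control: bool = True,
) -> pd.DataFrame:
    """Microsomal stability time course: remaining parent fraction
    R(t) = exp(-kel_true * t) * (1 + eta), eta ~ N(0, cv^2).

    The no-cofactor control series stays at 1 (same noise model).
    Returns columns: time_min, replicate, series ('nadph'|'control'), remaining.
    """
    if kel_true < 0:
        raise ValueError("kel_true must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for series, kel in (("nadph", kel_true),) + ((("control", 0.0),) if include_control else ()):
        for rep in range(duplicates):
            r = np.exp(-kel * t)
            if cv > 0:
                r = r * (1.0 + rng.normal(0.0, cv, size=t.shape))
            for ti, ri in zip(t, r):
                rows.append((ti, rep, series, ri))
    return pd.DataFrame(rows, columns=["time_min", "replicate", "series", "remaining"])


@dataclass(frozen=True)
class TransportGeometry:
    """Transwell geometry; defaults mirror a 24-well HTS insert run
    (0.7 cm^2 insert, 90 min, 300 uL apical / 1000 uL basolateral)."""

    area_cm2: float = 0.7
    time_s: float = 90.0 * 60.0
    v_apical_uL: float = 300.0
    v_basolateral_uL: float = 1000.0
    amount_donor_nmol: float = 3.0


def simulate_transport(
    papp_ab_true: float,
    papp_ba_true: float,
    geometry: TransportGeometry = TransportGeometry(),
    cv: float = 0.0,
    seed: int = 0,
    inhibitor: str = "none",
) -> list[TransportMeasurement]:
    """Bidirectional transwell measurements consistent with the Papp equation.

    The acceptor amount is the Papp equation inverted:
    amount_acc = Papp(cm/s) * Area * Time / V_A(cm^3) * amount_donor.
    In noiseless mode (cv=0) this round-trips exactly through calc_papp.
    Papp inputs are in nm/s.
    """
    rng = np.random.default_rng(seed)
    out = []
    for direction, papp in (("AB", papp_ab_true), ("BA", papp_ba_true)):
        if papp < 0:
            raise ValueError("Papp must be >= 0")
        v_acceptor = geometry.v_basolateral_uL if direction == "AB" else geometry.v_apical_uL
        v_acc_cm3 = v_acceptor / 1000.0
        amount_acc = (papp * 1e-7) * geometry.area_cm2 * geometry.time_s \
            / v_acc_cm3 * geometry.amount_donor_nmol
        if cv > 0:
            amount_acc *= 1.0 + rng.normal(0.0, cv)
        out.append(TransportMeasurement(
            direction=direction,
            v_acceptor_uL=v_acceptor,
            area_cm2=geometry.area_cm2,
            time_s=geometry.time_s,
            amount_acceptor_nmol=amount_acc,
            amount_donor_initial_nmol=geometry.amount_donor_nmol,
            inhibitor=inhibitor,
        ))
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via unit quaternion sampling."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _sample_water_radii(
    profile: str | tuple, n: int, box_radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Radial distances for water oxygens around the ligand centroid.

    ``"uniform"`` draws uniformly inside the sphere of ``box_radius``
    (r ~ R * U^(1/3)); ``("gaussian_shell", mu, sd)`` draws shell radii from
    N(mu, sd^2) truncated to (0, box_radius]; ``("shell_uniform_mix", mu, sd,
    frac)`` puts a fraction ``frac`` of waters in such a shell and the rest
    in the uniform bulk."""
    if profile == "uniform":
        return box_radius * rng.uniform(size=n) ** (1.0 / 3.0)
    if isinstance(profile, tuple) and profile[0] == "gaussian_shell":
        _, mu, sd = profile
        r = rng.normal(mu, sd, size=n)
        bad = (r <= 0) | (r > box_radius)
        while np.any(bad):
            r[bad] = rng.normal(mu, sd, size=int(bad.sum()))
            bad = (r <= 0) | (r > box_radius)
        return r
    if isinstance(profile, tuple) and profile[0] == "shell_uniform_mix":
        _, mu, sd, frac = profile
        if not 0.0 <= frac <= 1.0:
            raise ValueError("shell fraction must be in [0, 1]")
        n_shell = int(round(frac * n))
        shell = _sample_water_radii(("gaussian_shell", mu, sd), n_shell, box_radius, rng)
        bulk = _sample_water_radii("uniform", n - n_shell, box_radius, rng)
        return np.concatenate([shell, bulk])
    raise ValueError(f"unknown water density profile: {profile!r}")


def simulate_trajectory(
    n_frames: int,
    n_ca: int = 20,
    n_waters: int = 100,
    fluct_sigma: float = 0.3,
    water_density_profile: str | tuple = "uniform",
    box_radius: float = 10.0,
    seed: int = 0,
    n_ligand: int = 5,
    rigid_motion: bool = True,
) -> Trajectory:
    """Synthetic MD-like trajectory in Angstrom.

    Calpha atoms fluctuate isotropically (per-atom Gaussian, SD
    ``fluct_sigma``) about fixed reference sites; the ligand is a small
    rigid cluster at the origin; water oxygens are resampled per frame from
    ``water_density_profile`` around the ligand centroid.  Each frame is
    additionally subjected to a random rigid rotation + translation (within
    +-box_radius) unless ``rigid_motion`` is False, so downstream analyses
    must superpose.
    """
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    rng = np.random.default_rng(seed)
    ref_ca = rng.uniform(-box_radius, box_radius, size=(n_ca, 3))
    lig = rng.uniform(-1.5, 1.5, size=(n_ligand, 3))
    lig -= lig.mean(axis=0)  # ligand centroid at origin in the body frame

    n_atoms = n_ca + n_ligand + n_waters
    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        ca = ref_ca + (rng.normal(0.0, fluct_sigma, size=(n_ca, 3)) if fluct_sigma > 0 else 0.0)
        r = _sample_water_radii(water_density_profile, n_waters, box_radius, rng)
        u = rng.normal(size=(n_waters, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        waters = u * r[:, None]
        frame = np.vstack([ca, lig, waters])
        if rigid_motion:
            rot = _random_rotation(rng)
            trans = rng.uniform(-box_radius, box_radius, size=3)
            frame = frame @ rot.T + trans
        coords[f] = frame
    roles = np.array(["ca"] * n_ca + ["ligand"] * n_ligand + ["water_o"] * n_waters)
    return Trajectory(coords=coords, roles=roles)
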