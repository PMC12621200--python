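"""Shared domain containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

WELL_ROLES = ("compound", "dmso", "ape1", "no_enzyme")
ATOM_ROLES = ("ca", "ligand", "water_o", "other")


@dataclass
class KineticTrace:
    """One well's time-resolved fluorescence with its role metadata."""

    times: np.ndarray          # s, strictly increasing
    fluorescence: np.ndarray   # RFU
    role: str                  # compound | dmso | ape1 | no_enzyme
    compound_id: str = ""
    concentration: float = 0.0  # uM; 0 for controls
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size < 3:
            raise ValueError("a kinetic trace needs >= 3 points")
        if self.times.size != self.fluorescence.size:
            raise ValueError("times and fluorescence must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")
        if self.role not in WELL_ROLES:
            raise ValueError(f"unknown well role: {self.role!r}")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RateEstimate:
    """Initial-rate OLS fit over a chosen window of a kinetic trace."""

    slope: float       # RFU/s
    intercept: float   # RFU
    window: tuple[int, int]  # [start, stop) indices used
    r2: float
    se: float          # slope standard error
    low_quality: bool = False


@dataclass(frozen=True)
class TransportMeasurement:
    """One direction of a transwell Caco-2 transport experiment."""

    direction: str                    # AB | BA
    v_acceptor_uL: float
    area_cm2: float
    time_s: float
    amount_acceptor_nmol: float
    amount_donor_initial_nmol: float
    inhibitor: str = "none"           # none | verapamil

    def __post_init__(self) -> None:
        if self.direction not in ("AB", "BA"):
            raise ValueError("direction must be AB or BA")
        if min(self.v_acceptor_uL, self.area_cm2, self.time_s) <= 0:
            raise ValueError("volume, area and time must be positive")
        if self.inhibitor not in ("none", "verapamil"):
            raise ValueError("inhibitor must be 'none' or 'verapamil'")


@dataclass
class Trajectory:
    """Frames x atoms x 3 Cartesian coordinates (Angstrom) with atom roles."""

    coords: np.ndarray
    roles: np.ndarray              # per-atom tag: ca | ligand | water_o | other
    frame_times_ns: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.roles = np.asarray(self.roles)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("a trajectory needs >= 2 frames")
        if self.roles.shape != (self.coords.shape[1],):
            raise ValueError("roles must have one entry per atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        unknown = set(np.unique(self.roles)) - set(ATOM_ROLES)
        if unknown:
            raise ValueError(f"unknown atom roles: {sorted(unknown)}")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def select(self, role: str) -> np.ndarray:
        """Coordinate sub-array (frames, n_role, 3) for one atom role."""
        mask = self.roles == role
        if not mask.any():
            raise ValueError(f"no atoms with role {role!r}")
        return self.coords[:, mask, :]
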