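"""File formats and run configuration.

Plate data travel as long-format CSV (one row per read:
well, role, compound_id, conc_uM, time_s, rfu).  Trajectories are exchanged
as multi-model PDB (ATOM/CA for protein, HETATM for ligand and water
oxygens) or as extended XYZ with a role column.  Readers validate strictly
and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .types import ATOM_ROLES, WELL_ROLES, KineticTrace, Trajectory

__all__ = [
    "PLATE_COLUMNS",
    "RunConfig",
    "read_plate",
    "write_plate",
    "traces_from_frame",
    "write_results",
    "read_trajectory",
    "write_trajectory",
]

PLATE_COLUMNS = ["well", "role", "compound_id", "conc_uM", "time_s", "rfu"]


@dataclass
class RunConfig:
    """Pipeline thresholds and geometry defaults.

    The defaults are the constants the analyses are defined with: r2 >= 0.99
    for the linear window, primary-hit AC50 below 100 uM, virtual-screening
    LE threshold 0.40, active efflux above ratio 2, 0.7 cm^2 transwell
    inserts, 0.42 mg microsomal protein per mL.
    """

    seed: int = 0
    r2_min: float = 0.99
    min_frac: float = 0.3
    hit_ac50_uM: float = 100.0
    le_min: float = 0.40
    efflux_threshold: float = 2.0
    area_cm2: float = 0.7
    protein_mg_per_ml: float = 0.42
    report_decimals: Mapping[str, int] = field(
        default_factory=lambda: {"acle": 3, "aclle": 2, "efflux_ratio": 1})

    def __post_init__(self) -> None:
        for name in ("r2_min", "min_frac", "hit_ac50_uM", "le_min",
                     "efflux_threshold", "area_cm2", "protein_mg_per_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items() if k != "report_decimals"}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _fail(msg: str, rows=None) -> None:
    if rows is not None:
        rows = list(np.atleast_1d(rows))[:10]
        msg += f" (rows {rows})"
    raise ValueError(msg)


def validate_plate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        _fail(f"plate table missing columns: {missing}")
    bad_role = ~df["role"].isin(WELL_ROLES)
    if bad_role.any():
        _fail(f"invalid well roles {sorted(df.loc[bad_role, 'role'].unique())}",
              df.index[bad_role])
    for col in ("conc_uM", "time_s", "rfu"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()]
            wells = sorted(df.loc[bad, "well"].unique())
            _fail(f"non-numeric or missing {col} in wells {wells}", bad)
    dup = df.duplicated(subset=["well", "time_s"])
    if dup.any():
        _fail("duplicate (well, time_s) rows", df.index[dup])
    return df


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format plate CSV; rows are sorted by well
    and time so shuffled files parse to identical traces."""
    df = pd.read_csv(path, dtype={"well": str, "role": str},
                     keep_default_na=False, na_values=[""])
    df["compound_id"] = df["compound_id"].fillna("").astype(str) \
        if "compound_id" in df.columns else ""
    validate_plate(df)
    df = df.sort_values(["well", "time_s"], kind="mergesort").reset_index(drop=True)
    for well, grp in df.groupby("well"):
        if np.any(np.diff(grp["time_s"].to_numpy(float)) <= 0):
            _fail(f"non-monotone times in well {well}")
    return df


def write_plate(df: pd.DataFrame, path: str | Path) -> None:
    validate_plate(df)
    out = df[PLATE_COLUMNS].sort_values(["well", "time_s"], kind="mergesort")
    out.to_csv(path, index=False, float_format="%.6g")


def traces_from_frame(df: pd.DataFrame) -> list[KineticTrace]:
    """Plate table -> one KineticTrace per well."""
    traces = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_s")
        traces.append(KineticTrace(
            times=grp["time_s"].to_numpy(float),
            fluorescence=grp["rfu"].to_numpy(float),
            role=str(grp["role"].iloc[0]),
            compound_id=str(grp["compound_id"].iloc[0]),
            concentration=float(grp["conc_uM"].iloc[0]),
            replicate=0,
        ))
    return traces


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named results table as <name>.csv under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


# --- trajectory formats ----------------------------------------------------

_ROLE_TO_PDB = {
    "ca": ("ATOM", "CA", "ALA", "C"),
    "ligand": ("HETATM", "C1", "LIG", "C"),
    "water_o": ("HETATM", "O", "HOH", "O"),
    "other": ("ATOM", "X", "UNK", "X"),
}


def write_trajectory(traj: Trajectory, path: str | Path, dialect: str = "pdb_multimodel") -> None:
    """Export a trajectory as multi-model PDB or extended XYZ."""
    path = Path(path)
    if dialect == "pdb_multimodel":
        lines = []
        for f in range(traj.n_frames):
            lines.append(f"MODEL     {f + 1:4d}")
            for i in range(traj.n_atoms):
                record, name, res, elem = _ROLE_TO_PDB[str(traj.roles[i])]
                x, y, z = traj.coords[f, i]
                lines.append(
                    f"{record:<6}{i + 1:>5} {name:^4} {res:<3} A{i + 1:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2}"
                )
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "xyz":
        lines = []
        for f in range(traj.n_frames):
            lines.append(str(traj.n_atoms))
            lines.append(f"frame={f} columns=role:x:y:z")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                lines.append(f"{traj.roles[i]} {x:.6f} {y:.6f} {z:.6f}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown trajectory dialect: {dialect!r}")


def _infer_role(record: str, atom_name: str, res_name: str, ligand_resname: str) -> str:
    if res_name in ("HOH", "WAT") and atom_name.startswith("O"):
        return "water_o"
    if res_name == ligand_resname:
        return "ligand"
    if atom_name == "CA":
        return "ca"
    return "other"


def _read_pdb_multimodel(path: Path, ligand_resname: str) -> Trajectory:
    text = path.read_text()
    n_model = sum(1 for ln in text.splitlines() if ln.startswith("MODEL"))
    n_endmdl = sum(1 for ln in text.splitlines() if ln.startswith("ENDMDL"))
    if n_model != n_endmdl:
        raise ValueError("malformed multi-model PDB: MODEL/ENDMDL blocks unbalanced "
                         "(missing ENDMDL?)")
    import biotite.structure.io.pdb as bpdb

    pdb = bpdb.PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()  # AtomArrayStack, all models
    except Exception as exc:  # biotite raises on inconsistent atom counts
        raise ValueError(f"inconsistent frames in multi-model PDB: {exc}") from exc
    coords = np.asarray(stack.coord, float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    roles = np.array([
        _infer_role("", an, rn, ligand_resname)
        for an, rn in zip(stack.atom_name, stack.res_name)
    ])
    return Trajectory(coords=coords, roles=roles)


def _read_xyz(path: Path) -> Trajectory:
    lines = path.read_text().splitlines()
    frames, roles = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"bad XYZ atom count at line {i + 1}") from exc
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ValueError("truncated XYZ frame")
        frame_roles, xyz = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) != 4:
                raise ValueError(f"bad XYZ atom line: {ln!r}")
            frame_roles.append(parts[0])
            xyz.append([float(v) for v in parts[1:]])
        if roles is None:
            roles = frame_roles
        elif roles != frame_roles:
            raise ValueError("inconsistent atom roles across XYZ frames")
        frames.append(xyz)
        i += 2 + n
    return Trajectory(coords=np.asarray(frames, float), roles=np.asarray(roles))


def read_trajectory(
    path: str | Path, dialect: str = "pdb_multimodel", ligand_resname: str = "LIG"
) -> Trajectory:
    """Read a trajectory; atom roles are inferred from atom/residue names
    (CA -> ca, HOH/WAT oxygen -> water_o, configurable ligand residue)."""
    path = Path(path)
    if dialect == "pdb_multimodel":
        return _read_pdb_multimodel(path, ligand_resname)
    if dialect == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown trajectory dialect: {dialect!r}")
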