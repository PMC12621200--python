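"""Trajectory analyses: Kabsch superposition RMSD, per-atom RMSF,
ligand-water radial distribution functions, hydration-shell counts, and
average-linkage RMSD clustering of frames.

Coordinates are Angstrom throughout.  There is no periodic-boundary
minimum imaging: the RDF normalizes against a user-supplied enclosing
volume, which suits the non-periodic synthetic trajectories this package
generates (a documented difference from PME/periodic production MD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import Trajectory

__all__ = [
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "rdf",
    "RDFProfile",
    "waters_within",
    "cluster_frames",
    "ClusterResult",
    "average_linkage_merges",
]


def kabsch_superpose(
    mobile: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition (Kabsch, SVD form).

    Returns (rotation R, translation t, rmsd) such that ``mobile @ R.T + t``
    best fits ``ref`` in the least-squares sense; the determinant correction
    restricts R to SO(3) so reflections are never used.
    """
    mob = np.asarray(mobile, float)
    r = np.asarray(ref, float)
    if mob.shape != r.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and ref must both be (n_atoms, 3)")
    if mob.shape[0] < 3:
        raise ValueError("need >= 3 atoms for superposition")
    cm, cr = mob.mean(axis=0), r.mean(axis=0)
    p, q = mob - cm, r - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cr - rot @ cm
    fitted = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return rot, t, rmsd


def _frame_coords(traj: Trajectory, selection: str) -> np.ndarray:
    return traj.select(selection)


def rmsd_series(
    traj: Trajectory, selection: str = "ca", ref_frame: int = 0
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) to a reference frame after superposing each
    frame onto the reference on the given selection."""
    x = _frame_coords(traj, selection)
    ref = x[ref_frame]
    return np.array([kabsch_superpose(x[f], ref)[2] for f in range(traj.n_frames)])


def rmsf(traj: Trajectory, selection: str = "ca", n_iter: int = 2) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    All frames are superposed onto the running mean structure (iterated
    ``n_iter`` times so the mean and the alignment are self-consistent);
    RMSF_i = sqrt(<|x_i - <x_i>|^2>).
    """
    x = _frame_coords(traj, selection).copy()
    mean = x[0].copy()
    for _ in range(n_iter):
        aligned = np.empty_like(x)
        for f in range(x.shape[0]):
            rot, t, _ = kabsch_superpose(x[f], mean)
            aligned[f] = x[f] @ rot.T + t
        mean = aligned.mean(axis=0)
        x = aligned
    dev = x - mean[None, :, :]
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


@dataclass(frozen=True)
class RDFProfile:
    r_centers: np.ndarray       # Angstrom, uniform bins
    g: np.ndarray               # unitless
    n_pairs: np.ndarray         # raw pair counts per bin
    cumulative_count: np.ndarray  # mean number of B atoms within r (per A atom)


def rdf(
    traj: Trajectory,
    group_a: str = "ligand",
    group_b: str = "water_o",
    r_max: float = 10.0,
    dr: float = 0.1,
    volume: Optional[float] = None,
) -> RDFProfile:
    """Radial distribution function g(r) between two atom groups.

    A-B distances from every frame are histogrammed in uniform bins of
    width ``dr``; g(r) normalizes each bin count by the ideal-gas
    expectation  n_A * n_frames * rho_B * 4 pi r^2 dr  with
    rho_B = n_B / volume.  ``cumulative_count`` is the running mean count of
    B atoms within r of an A atom (unnormalized).
    """
    a = traj.select(group_a)
    b = traj.select(group_b)
    if volume is None or volume <= 0:
        raise ValueError("a positive enclosing volume is required for g(r) normalization")
    n_frames, n_a, n_b = a.shape[0], a.shape[1], b.shape[1]
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(edges.size - 1)
    for f in range(n_frames):
        d = np.linalg.norm(a[f][:, None, :] - b[f][None, :, :], axis=2).ravel()
        counts += np.histogram(d, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho_b = n_b / volume
    shell = 4.0 * math.pi * centers**2 * dr
    g = counts / (n_a * n_frames * rho_b * shell)
    cumulative = np.cumsum(counts) / (n_a * n_frames)
    return RDFProfile(r_centers=centers, g=g, n_pairs=counts, cumulative_count=cumulative)


def waters_within(
    traj: Trajectory, cutoff: float = 5.0, ligand_role: str = "ligand",
    water_role: str = "water_o",
) -> tuple[float, float, np.ndarray]:
    """Hydration-shell size: waters within ``cutoff`` of the ligand.

    A water oxygen is counted in a frame when its minimum distance to any
    ligand atom is <= cutoff.  Returns (mean, SD, per-frame counts).
    """
    lig = traj.select(ligand_role)
    try:
        wat = traj.select(water_role)
    except ValueError:
        counts = np.zeros(traj.n_frames)
        return 0.0, 0.0, counts
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = np.linalg.norm(wat[f][:, None, :] - lig[f][None, :, :], axis=2)
        counts[f] = int(np.sum(d.min(axis=1) <= cutoff))
    return float(counts.mean()), float(counts.std(ddof=0)), counts


def pairwise_rmsd_matrix(traj: Trajectory, selection: str = "ca") -> np.ndarray:
    """Symmetric matrix of pairwise superposition RMSDs between frames."""
    x = _frame_coords(traj, selection)
    n = x.shape[0]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch_superpose(x[i], x[j])[2]
    return m


def average_linkage_merges(dist: np.ndarray) -> list[tuple[frozenset, frozenset]]:
    """Agglomerative average-linkage merge sequence on a distance matrix.

    At each step the pair of clusters with the smallest mean pairwise
    inter-cluster distance is merged; ties are broken by the lowest member
    frame index (then of the second cluster), making the sequence fully
    deterministic.  Returns the merged (cluster, cluster) pairs in order.
    """
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                a, b = clusters[ai], clusters[bi]
                d = float(dist[np.ix_(sorted(a), sorted(b))].mean())
                key = (d, min(min(a), min(b)), max(min(a), min(b)))
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        _, ai, bi = best
        a, b = clusters[ai], clusters[bi]
        merges.append((a, b) if min(a) < min(b) else (b, a))
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)] + [a | b]
    return merges


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray            # per-frame cluster label, 0..k-1
    representatives: np.ndarray   # one frame index per cluster
    rmsd_matrix: np.ndarray


def cluster_frames(
    traj: Trajectory, k: int = 10, selection: str = "ca"
) -> ClusterResult:
    """Average-linkage clustering of frames on the pairwise superposition
    RMSD matrix, cut at ``k`` clusters.

    The representative of each cluster is the frame minimizing the mean RMSD
    to the other members (lowest frame index on ties).  Clusters are labeled
    0..k-1 in order of their lowest member frame index, so the result is
    deterministic and permutation-equivariant.
    """
    if k < 1 or k > traj.n_frames:
        raise ValueError("k must be between 1 and the number of frames")
    dist = pairwise_rmsd_matrix(traj, selection)
    n = traj.n_frames
    merges = average_linkage_merges(dist)[: n - k]
    clusters: dict[int, set] = {i: {i} for i in range(n)}
    # replay merges on a member->cluster map
    owner = list(range(n))
    for a, b in merges:
        ia, ib = owner[min(a)], owner[min(b)]
        clusters[ia] |= clusters.pop(ib)
        for m in clusters[ia]:
            owner[m] = ia
    final = sorted(clusters.values(), key=min)
    labels = np.empty(n, dtype=int)
    reps = np.empty(len(final), dtype=int)
    for lab, members in enumerate(final):
        ms = sorted(members)
        for m in ms:
            labels[m] = lab
        if len(ms) == 1:
            reps[lab] = ms[0]
        else:
            mean_d = [np.mean([dist[i, j] for j in ms if j != i]) for i in ms]
            reps[lab] = ms[int(np.argmin(mean_d))]
    return ClusterResult(labels=labels, representatives=reps, rmsd_matrix=dist)
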