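"""Superposition, RMSD/RMSF machinery, GROMOS clustering and frame selection.

The clustering is the iterative neighbor-count algorithm of Daura et al.:
the unassigned frame with the most neighbors within the RMSD cutoff
becomes a cluster center, it and its neighbors are removed, and the
procedure repeats.  Ties on neighbor count are broken by the lowest frame
index so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BACKBONE_ATOMS, MolecularTopology, Trajectory


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # Å; maps mobile -> reference as R @ x + t
    rmsd: float               # Å over the fit selection
    selection: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdMatrix:
    n: int
    values: np.ndarray        # symmetric n x n, Å
    selection: str = "calpha"


@dataclass
class Cluster:
    members: np.ndarray
    center: int
    size: int


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    cutoff: float

    def __len__(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def to_table(self) -> str:
        lines = ["cluster\tsize\tcenter\tmembers"]
        for k, c in enumerate(self.clusters):
            lines.append(
                f"{k}\t{c.size}\t{c.center}\t{','.join(map(str, c.members))}"
            )
        return "\n".join(lines) + "\n"


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The returned transform minimizes the RMSD over the selection;
    reflections are suppressed (det = +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if selection is None:
        selection = np.arange(len(mobile))
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty fit selection")
    if selection.size < 3:
        raise ValueError("need at least 3 points for a unique rotation")
    a = mobile[selection]
    b = reference[selection]
    if a.shape != b.shape:
        raise ValueError(f"selection length mismatch: {a.shape} vs {b.shape}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    diff = (a @ rot.T + trans) - b
    rmsd = float(np.sqrt((diff ** 2).sum() / len(a)))
    return SuperpositionResult(rot, trans, rmsd, selection)


def _resolve_selection(topology: MolecularTopology, selection) -> np.ndarray:
    if isinstance(selection, str):
        if selection == "calpha":
            idx = topology.select(["CA"])
        elif selection == "backbone":
            idx = topology.select(list(BACKBONE_ATOMS))
        else:
            raise ValueError(f"unknown selection {selection!r}")
    else:
        idx = np.asarray(selection, int)
    if idx.size < 3:
        raise ValueError(f"selection resolves to {idx.size} atoms; need >= 3")
    return idx


def rmsd_matrix(trajectory: Trajectory, selection="calpha") -> RmsdMatrix:
    """All-pairs minimized RMSD after pairwise superposition.

    Uses a batched Kabsch evaluation: with every frame's selection centered,
    the optimal-fit RMSD between frames i and j follows from the SVD of the
    3x3 cross-covariance, computed for all pairs at once.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 frames")
    idx = _resolve_selection(trajectory.topology, selection)
    xyz = trajectory.coordinate_array()[:, idx, :]
    xyz = xyz - xyz.mean(axis=1, keepdims=True)
    n = len(trajectory)
    norms = (xyz ** 2).sum(axis=(1, 2))
    iu, ju = np.triu_indices(n, k=1)
    h = np.einsum("pki,pkj->pij", xyz[iu], xyz[ju])
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    s[:, 2] = np.where(det < 0, -s[:, 2], s[:, 2])
    msd = (norms[iu] + norms[ju] - 2.0 * s.sum(axis=1)) / idx.size
    vals = np.zeros((n, n))
    vals[iu, ju] = vals[ju, iu] = np.sqrt(np.maximum(msd, 0.0))
    sel_name = selection if isinstance(selection, str) else "custom"
    return RmsdMatrix(n=n, values=vals, selection=sel_name)


def gromos_cluster(matrix: RmsdMatrix, cutoff: float) -> ClusterSet:
    """Daura-style iterative neighbor-count clustering of an RMSD matrix."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    vals = np.asarray(matrix.values, float)
    if vals.shape != (matrix.n, matrix.n):
        raise ValueError("matrix shape disagrees with n")
    if np.max(np.abs(vals - vals.T)) > 1e-6:
        raise ValueError("RMSD matrix is not symmetric")
    neighbor = vals <= cutoff
    np.fill_diagonal(neighbor, False)
    remaining = np.ones(matrix.n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (neighbor & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(remaining & (neighbor[center] | (np.arange(matrix.n) == center)))[0]
        clusters.append(Cluster(members=members, center=center, size=len(members)))
        remaining[members] = False
    # stable sort: sizes non-increasing, formation order preserved on ties
    clusters.sort(key=lambda c: -c.size)
    return ClusterSet(clusters=clusters, cutoff=cutoff)


def select_representative(clusters: ClusterSet) -> int:
    """Center frame of the most populated cluster."""
    if not clusters.clusters:
        raise ValueError("empty cluster set")
    return clusters.clusters[0].center


@dataclass
class RmsfResult:
    residue_indices: np.ndarray
    rmsf: np.ndarray                     # Å, per residue
    calpha_fallback: np.ndarray          # True where no side-chain heavy atoms

    def to_table(self) -> str:
        lines = ["residue\trmsf_A\tcalpha_only"]
        for r, v, g in zip(self.residue_indices, self.rmsf, self.calpha_fallback):
            lines.append(f"{r}\t{v:.4f}\t{int(g)}")
        return "\n".join(lines) + "\n"


def sidechain_rmsf(trajectory: Trajectory, residues=None,
                   reference: str = "mean-structure",
                   align_selection="calpha") -> RmsfResult:
    """Per-residue RMSF of side-chain heavy atoms about their time averages.

    Frames are first superposed onto the first frame over ``align_selection``,
    then mass-unweighted fluctuations are taken about the time-mean structure
    (or about frame 0 with ``reference='frame0'``) and averaged over each
    residue's side-chain heavy atoms.  Residues without side-chain heavy
    atoms (glycine-like) fall back to their CA atom and are flagged.
    """
    top = trajectory.topology
    fit_idx = _resolve_selection(top, align_selection)
    ref = trajectory[0].coordinates
    aligned = np.empty((len(trajectory), top.n_atoms, 3))
    for k, fr in enumerate(trajectory.frames):
        sup = kabsch_superpose(fr.coordinates, ref, fit_idx)
        aligned[k] = sup.apply(fr.coordinates)
    if reference == "mean-structure":
        ref_coords = aligned.mean(axis=0)
    elif reference == "frame0":
        ref_coords = aligned[0]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    msd_atom = ((aligned - ref_coords) ** 2).sum(axis=2).mean(axis=0)

    backbone = set(BACKBONE_ATOMS)
    if residues is None:
        residues = [r.index for r in top.residues
                    if not top.is_water_residue(r.name)]
    out_r, out_v, out_g = [], [], []
    for ridx in residues:
        res = top.residue(ridx)
        side = [i for i in res.atom_indices
                if top.atoms[i].name not in backbone
                and top.atoms[i].element.upper() != "H"]
        fallback = not side
        if fallback:
            side = [i for i in res.atom_indices if top.atoms[i].name == "CA"]
            if not side:
                side = list(res.atom_indices)
        out_r.append(ridx)
        out_v.append(float(np.sqrt(msd_atom[side].mean())))
        out_g.append(fallback)
    return RmsfResult(np.array(out_r), np.array(out_v), np.array(out_g))


def select_evenly_spaced_frames(trajectory: Trajectory,
                                window_ps: tuple[float, float],
                                n: int) -> np.ndarray:
    """Indices of ``n`` frames at uniform stride across a time window.

    The window is half-open on time, ``[t_start, t_end)``; the first and
    last frames inside it are always included.
    """
    t = trajectory.times_ps
    inside = np.where((t >= window_ps[0]) & (t < window_ps[1]))[0]
    if inside.size < n:
        raise ValueError(
            f"window {window_ps} contains {inside.size} frames, need {n}"
        )
    if n == 1:
        return inside[:1]
    pos = np.round(np.linspace(0, inside.size - 1, n)).astype(int)
    return inside[pos]
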