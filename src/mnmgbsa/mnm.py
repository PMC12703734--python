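"""Mix-and-Match complex reconstruction.

A Mix-and-Match (MnM) complex is assembled by rigid-body superposition of
the most representative unbound conformer of each chain onto the
corresponding chain of the crystal complex, using a backbone (N, CA, C, O)
Kabsch fit of sequence-matched residues.  No minimization or repacking is
attempted here; the clash report flags contacts that downstream relaxation
should resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ensemble import kabsch_superpose
from .model import BACKBONE_ATOMS, Frame, MolecularTopology


@dataclass
class MnmComplex:
    frame: Frame
    provenance: dict
    placement_rmsd: dict[str, float]   # chain label -> backbone fit RMSD, Å


@dataclass
class ClashReport:
    pairs: list[tuple[int, int, float]]   # (atom i, atom j, distance Å), ascending
    min_distance: float
    threshold: float

    def to_table(self) -> str:
        lines = ["atom_i\tatom_j\tdistance_A"]
        for i, j, d in self.pairs:
            lines.append(f"{i}\t{j}\t{d:.3f}")
        return "\n".join(lines) + "\n"


def _backbone_map(topology: MolecularTopology, chain_label: str) -> dict:
    """(residue position in chain, atom name) -> atom index for backbone atoms."""
    atoms = topology.molecule_atoms(chain_label)
    out = {}
    res_seen: list[int] = []
    for i in atoms:
        a = topology.atoms[i]
        if a.name in BACKBONE_ATOMS:
            if a.residue_index not in res_seen:
                res_seen.append(a.residue_index)
            out[(res_seen.index(a.residue_index), a.name)] = i
    return out


def build_mnm_complex(crystal_topology: MolecularTopology, crystal_frame: Frame,
                      rep_a: tuple[MolecularTopology, Frame],
                      rep_b: tuple[MolecularTopology, Frame],
                      *, max_unmatched_fraction: float = 0.0,
                      provenance: dict | None = None) -> MnmComplex:
    """Superpose representative chain conformers onto the crystal chains.

    ``rep_a``/``rep_b`` are single-chain topologies + frames whose residues
    correspond positionally to the crystal's chainA/chainB (identical
    sequences after renumbering).  The output frame preserves the crystal
    atom order so a single topology serves downstream energetics.
    """
    out = np.array(crystal_frame.coordinates, copy=True)
    placement: dict[str, float] = {}
    prov = dict(provenance or {})
    for chain_label, (rep_top, rep_frame) in (("chainA", rep_a), ("chainB", rep_b)):
        crystal_atoms = crystal_topology.molecule_atoms(chain_label)
        if crystal_atoms.size == 0:
            raise ValueError(f"crystal has no {chain_label}")
        rep_label = "chainA"  # a single-chain ensemble is its own first chain
        cry_bb = _backbone_map(crystal_topology, chain_label)
        rep_bb = _backbone_map(rep_top, rep_label)
        common = sorted(set(cry_bb) & set(rep_bb))
        n_res_cry = len({k[0] for k in cry_bb})
        n_res_common = len({k[0] for k in common})
        if n_res_cry == 0:
            raise ValueError(f"{chain_label}: no backbone atoms found")
        unmatched = 1.0 - n_res_common / n_res_cry
        if unmatched > max_unmatched_fraction:
            missing = sorted({k[0] for k in cry_bb} - {k[0] for k in common})
            raise ValueError(
                f"{chain_label}: {n_res_cry - n_res_common}/{n_res_cry} residues "
                f"unmatched (positions {missing[:10]}...)"
            )
        mob_sel = np.array([rep_bb[k] for k in common])
        ref_sel = np.array([cry_bb[k] for k in common])
        sup = kabsch_superpose(rep_frame.coordinates[mob_sel],
                               crystal_frame.coordinates[ref_sel],
                               np.arange(len(common)))
        placement[chain_label] = sup.rmsd
        # map every rep-chain atom onto the crystal slot with the same
        # (residue position, atom name)
        rep_atoms = rep_top.molecule_atoms(rep_label)
        rep_key = {}
        res_seen: list[int] = []
        for i in rep_atoms:
            a = rep_top.atoms[i]
            if a.residue_index not in res_seen:
                res_seen.append(a.residue_index)
            rep_key[(res_seen.index(a.residue_index), a.name)] = i
        res_seen = []
        transformed = sup.apply(rep_frame.coordinates)
        for i in crystal_atoms:
            a = crystal_topology.atoms[i]
            if a.residue_index not in res_seen:
                res_seen.append(a.residue_index)
            key = (res_seen.index(a.residue_index), a.name)
            if key in rep_key:
                out[i] = transformed[rep_key[key]]
    return MnmComplex(frame=Frame(out, time_ps=crystal_frame.time_ps),
                      provenance=prov, placement_rmsd=placement)


def clash_report(frame: Frame, topology: MolecularTopology,
                 threshold: float = 2.0) -> ClashReport:
    """Interchain heavy-atom pairs closer than ``threshold`` (KD-tree search)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ia = topology.heavy_atoms(topology.molecule_atoms("chainA"))
    ib = topology.heavy_atoms(topology.molecule_atoms("chainB"))
    xa = frame.coordinates[ia]
    xb = frame.coordinates[ib]
    tree = cKDTree(xb)
    pairs = []
    for k, hits in enumerate(tree.query_ball_point(xa, threshold)):
        for h in hits:
            d = float(np.linalg.norm(xa[k] - xb[h]))
            if d < threshold:
                pairs.append((int(ia[k]), int(ib[h]), d))
    pairs.sort(key=lambda p: p[2])
    dmin = pairs[0][2] if pairs else float(
        cKDTree(xb).query(xa, k=1)[0].min()) if len(xa) and len(xb) else np.inf
    return ClashReport(pairs=pairs, min_distance=float(dmin), threshold=threshold)
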