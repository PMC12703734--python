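"""SASA, interfacial residues, interface center of mass, water selection
and complex/receptor/ligand partitioning.

A residue counts as interfacial when its solvent-accessible surface area
drops by more than a threshold (default 0.50 Å²) on complexation:
ΔSASA = SASA(residue | isolated chain) − SASA(residue | complex), both
evaluated on the same coordinates.  Retained interfacial waters join the
*receptor* side of the partition; including them in the ligand is known to
inflate the frame-to-frame spread without improving ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import Frame, MolecularTopology, Trajectory

#: per-element SASA radii (Å); element-based like common SASA tools
DEFAULT_SASA_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}


@dataclass
class SasaResult:
    atom_sasa: np.ndarray       # Å², full topology length (0 outside the set)
    residue_sasa: dict[int, float]
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.atom_sasa.sum())


@dataclass
class InterfaceSpec:
    residues_by_chain: dict[str, list[int]]
    delta_sasa: dict[int, float]   # Å² per interfacial residue
    threshold: float

    @property
    def residues(self) -> list[int]:
        return sorted(r for rs in self.residues_by_chain.values() for r in rs)

    def to_table(self, topology: MolecularTopology) -> str:
        lines = ["chain\tresidue\tdelta_sasa_A2"]
        for ch, rs in sorted(self.residues_by_chain.items()):
            for r in rs:
                lines.append(f"{ch}\t{r}\t{self.delta_sasa[r]:.3f}")
        return "\n".join(lines) + "\n"


@dataclass
class SolvationSelection:
    water_ids: list[np.ndarray]   # per frame: indices into topology.water_molecules()
    n_requested: int
    interface_com: list[np.ndarray]


@dataclass
class SystemPartition:
    complex_atoms: np.ndarray
    receptor_atoms: np.ndarray
    ligand_atoms: np.ndarray
    ligand_chain: str
    retained_water_atoms: np.ndarray

    def __post_init__(self) -> None:
        rec, lig = set(self.receptor_atoms.tolist()), set(self.ligand_atoms.tolist())
        if rec & lig:
            raise ValueError("receptor and ligand atom sets overlap")
        if rec | lig != set(self.complex_atoms.tolist()):
            raise ValueError("receptor ∪ ligand must equal complex")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def compute_sasa(frame: Frame, topology: MolecularTopology, *,
                 probe: float = 1.4, n_points: int = 960,
                 atom_subset: np.ndarray | None = None,
                 radii: dict[str, float] | None = None,
                 include_hydrogens: bool = False) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    For each atom, the fraction of test points on its probe-inflated sphere
    not buried inside any neighbor's inflated sphere, times the sphere area.
    Heavy atoms only by default.
    """
    radii = radii or DEFAULT_SASA_RADII
    if atom_subset is None:
        atom_subset = np.arange(topology.n_atoms)
    atom_subset = np.asarray(atom_subset, int)
    if not include_hydrogens:
        atom_subset = topology.heavy_atoms(atom_subset)
    r = np.empty(atom_subset.size)
    for k, i in enumerate(atom_subset):
        el = topology.atoms[i].element.upper()
        if el not in radii:
            raise ValueError(
                f"no SASA radius for element {el!r} (atom {topology.atoms[i].serial}"
                f" {topology.atoms[i].name})"
            )
        r[k] = radii[el]
    xyz = frame.coordinates[atom_subset]
    inflated = r + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(xyz)
    max_r = inflated.max()
    atom_sasa = np.zeros(topology.n_atoms)
    for k in range(atom_subset.size):
        surface = xyz[k] + inflated[k] * pts
        neighbors = [j for j in tree.query_ball_point(xyz[k], inflated[k] + max_r)
                     if j != k]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((surface - xyz[j]) ** 2).sum(axis=1)
            exposed &= d2 > inflated[j] ** 2
            if not exposed.any():
                break
        atom_sasa[atom_subset[k]] = (
            exposed.sum() / n_points * 4.0 * np.pi * inflated[k] ** 2
        )
    residue_sasa: dict[int, float] = {}
    for i in atom_subset:
        ridx = topology.atoms[i].residue_index
        residue_sasa[ridx] = residue_sasa.get(ridx, 0.0) + atom_sasa[i]
    return SasaResult(atom_sasa=atom_sasa, residue_sasa=residue_sasa,
                      probe=probe, n_points=n_points)


def find_interface_residues(frame: Frame, topology: MolecularTopology, *,
                            threshold: float = 0.50,
                            probe: float = 1.4, n_points: int = 960,
                            ) -> InterfaceSpec:
    """Residues whose SASA drops by more than ``threshold`` on complexation."""
    chains = [lab for lab in ("chainA", "chainB")
              if topology.molecule_atoms(lab).size]
    if len(chains) < 2:
        raise ValueError("interface detection needs two protein chains")
    protein_atoms = np.concatenate([topology.molecule_atoms(c) for c in chains])
    complex_sasa = compute_sasa(frame, topology, probe=probe, n_points=n_points,
                                atom_subset=protein_atoms)
    residues_by_chain: dict[str, list[int]] = {c: [] for c in chains}
    delta: dict[int, float] = {}
    for c in chains:
        atoms_c = topology.molecule_atoms(c)
        isolated = compute_sasa(frame, topology, probe=probe, n_points=n_points,
                                atom_subset=atoms_c)
        for ridx, iso_val in isolated.residue_sasa.items():
            d = iso_val - complex_sasa.residue_sasa.get(ridx, 0.0)
            if d > threshold:
                residues_by_chain[c].append(ridx)
                delta[ridx] = d
    for c in residues_by_chain:
        residues_by_chain[c].sort()
    return InterfaceSpec(residues_by_chain=residues_by_chain,
                         delta_sasa=delta, threshold=threshold)


def interface_com(frame: Frame, topology: MolecularTopology,
                  interface: InterfaceSpec) -> np.ndarray:
    """Mass-weighted centroid over all atoms of the interfacial residues."""
    residues = interface.residues
    if not residues:
        raise ValueError("empty interface")
    idx = np.concatenate([topology.residue(r).atom_indices for r in residues])
    m = topology.array("mass")[idx]
    if m.sum() <= 0:
        raise ValueError("interface atoms have zero total mass")
    return (frame.coordinates[idx] * m[:, None]).sum(axis=0) / m.sum()


def select_closest_waters(frame: Frame, topology: MolecularTopology,
                          com: np.ndarray, n: int = 30, *,
                          measure: str = "oxygen") -> np.ndarray:
    """Ids (indices into ``topology.water_molecules()``) of the ``n`` waters
    nearest to ``com``.

    Distances are taken from the water oxygen by default (≈ the 3-site water
    COM) or from the true water COM with ``measure='water-com'``; ties break
    on the lower molecule index.
    """
    waters = topology.water_molecules()
    if not waters:
        raise ValueError("topology contains no waters")
    masses = topology.array("mass")
    d = np.empty(len(waters))
    for k, w in enumerate(waters):
        if measure == "oxygen":
            ox = [i for i in w if topology.atoms[i].element.upper() == "O"]
            ref = frame.coordinates[ox[0] if ox else w[0]]
        elif measure == "water-com":
            m = masses[w]
            ref = (frame.coordinates[w] * m[:, None]).sum(axis=0) / m.sum()
        else:
            raise ValueError(f"unknown measure {measure!r}")
        d[k] = np.linalg.norm(ref - com)
    if len(waters) < n:
        import warnings
        warnings.warn(f"only {len(waters)} waters present; retaining all")
        n = len(waters)
    order = np.lexsort((np.arange(len(waters)), d))  # stable tie-break on index
    return np.sort(order[:n])


def solvation_selection(trajectory: Trajectory, interface: InterfaceSpec,
                        n: int = 30, frames=None,
                        measure: str = "oxygen") -> SolvationSelection:
    """Per-frame closest-water selection around the interface center of mass."""
    if frames is None:
        frames = range(len(trajectory))
    ids, coms = [], []
    for k in frames:
        fr = trajectory[k]
        com = interface_com(fr, trajectory.topology, interface)
        ids.append(select_closest_waters(fr, trajectory.topology, com, n,
                                         measure=measure))
        coms.append(com)
    return SolvationSelection(water_ids=ids, n_requested=n, interface_com=coms)


def partition_system(topology: MolecularTopology, ligand_chain: str = "auto",
                     retained_water_ids: np.ndarray | None = None,
                     ) -> SystemPartition:
    """Complex/receptor/ligand atom index sets with waters on the receptor.

    ``ligand_chain='auto'`` picks the chain with fewer residues — the usual
    convention that the smaller, later-numbered chain is the ligand.
    """
    labels = [lab for lab in ("chainA", "chainB")
              if topology.molecule_atoms(lab).size]
    if len(labels) < 2:
        raise ValueError("partition needs two protein chains")
    if ligand_chain == "auto":
        n_res = {lab: len({topology.atoms[i].residue_index
                           for i in topology.molecule_atoms(lab)})
                 for lab in labels}
        ligand_chain = min(labels, key=lambda c: (n_res[c], c != "chainB"))
    if ligand_chain not in labels:
        raise ValueError(f"ligand chain {ligand_chain!r} not present")
    receptor_chain = next(c for c in labels if c != ligand_chain)
    lig = topology.molecule_atoms(ligand_chain)
    rec = topology.molecule_atoms(receptor_chain)
    water_atoms = np.empty(0, dtype=int)
    if retained_water_ids is not None and len(retained_water_ids):
        waters = topology.water_molecules()
        water_atoms = np.concatenate([waters[int(w)] for w in retained_water_ids])
        rec = np.sort(np.concatenate([rec, water_atoms]))
    return SystemPartition(
        complex_atoms=np.sort(np.concatenate([rec, lig])),
        receptor_atoms=np.sort(rec), ligand_atoms=np.sort(lig),
        ligand_chain=ligand_chain, retained_water_atoms=water_atoms,
    )
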