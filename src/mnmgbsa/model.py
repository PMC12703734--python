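"""Shared coordinate/topology data model.

Conventions used throughout the package:

* lengths in Å, times in ps, energies in kcal/mol, charges in elementary
  charge units (the Amber ``18.2223`` scaling is applied only at
  parameter-topology I/O, see :mod:`mnmgbsa.structure_io`);
* atom and residue indices are 0-based everywhere in memory and 1-based
  only inside files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

#: residue names recognised as water (configurable at call sites)
WATER_RESNAMES = frozenset({"WAT", "HOH", "TIP3", "SOL"})
#: residue names recognised as monoatomic counterions
ION_RESNAMES = frozenset({"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "MG2"})

#: names of the protein backbone heavy atoms used for fitting
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class TopologyError(ValueError):
    """Raised when a topology or file violates a structural contract."""


@dataclass
class AtomRecord:
    """One atom with the per-atom force-field parameters used downstream.

    ``lj_rmin_half``/``lj_epsilon`` follow the Amber convention
    (rmin/2 in Å, well depth in kcal/mol); ``gb_radius``/``gb_screen``
    are the intrinsic Born radius (mbondi3 convention) and the HCT
    screening factor.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    charge: float = 0.0
    mass: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0
    gb_radius: float = 0.0
    gb_screen: float = 0.0


@dataclass
class Residue:
    index: int
    name: str
    chain_id: str
    first_atom: int
    n_atoms: int

    @property
    def atom_indices(self) -> np.ndarray:
        return np.arange(self.first_atom, self.first_atom + self.n_atoms)


@dataclass
class MolecularTopology:
    """Atoms plus bonded terms, exclusions and molecule segmentation.

    ``bonds``: (i, j, k, r0) with E = k (r - r0)^2;
    ``angles``: (i, j, k, k_theta, theta0) with E = k (theta - theta0)^2,
    theta0 in radians;
    ``dihedrals``: (i, j, k, l, height, periodicity, phase) with
    E = height (1 + cos(n phi - phase)), height already divided by any
    Amber divider, phase in radians.

    ``molecules``: ordered (label, start, stop) half-open atom ranges with
    label in {"chainA", "chainB", "water", "ion"}; the ranges partition
    the atom list.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = field(default_factory=list)
    molecules: list[tuple[str, int, int]] = field(default_factory=list)
    water_resnames: frozenset[str] = WATER_RESNAMES

    def __post_init__(self) -> None:
        self._validate()
        self._build_residues()
        self._arrays: dict[str, np.ndarray] = {}
        self._exclusions: tuple[set, set] | None = None

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if not self.atoms:
            raise TopologyError("topology has zero atoms")
        n = len(self.atoms)
        prev = -np.inf
        for a in self.atoms:
            if a.serial <= prev:
                raise TopologyError(
                    f"atom serials must be strictly increasing (atom {a.name})"
                )
            prev = a.serial
        for term in self.bonds:
            self._check_indices(term[:2], n, "bond")
        for term in self.angles:
            self._check_indices(term[:3], n, "angle")
        for term in self.dihedrals:
            self._check_indices(term[:4], n, "dihedral")
        if self.molecules:
            spans = sorted((s, e) for _, s, e in self.molecules)
            pos = 0
            for s, e in spans:
                if s != pos:
                    raise TopologyError("molecule ranges do not partition the atom list")
                pos = e
            if pos != n:
                raise TopologyError("molecule ranges do not cover all atoms")

    @staticmethod
    def _check_indices(idx: Sequence[int], n: int, kind: str) -> None:
        for i in idx:
            if not 0 <= i < n:
                raise TopologyError(f"{kind} term references invalid atom index {i}")

    def _build_residues(self) -> None:
        residues: list[Residue] = []
        for i, a in enumerate(self.atoms):
            if residues and a.residue_index == residues[-1].index:
                residues[-1].n_atoms += 1
            else:
                if residues and a.residue_index < residues[-1].index:
                    raise TopologyError("residue indices must be non-decreasing")
                residues.append(Residue(a.residue_index, a.residue_name, a.chain_id, i, 1))
        self.residues = residues
        self._residue_by_index = {r.index: r for r in residues}

    # -- basic queries ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue(self, index: int) -> Residue:
        return self._residue_by_index[index]

    def array(self, attr: str) -> np.ndarray:
        """Per-atom attribute as a numpy array (cached)."""
        if attr not in self._arrays:
            vals = [getattr(a, attr) for a in self.atoms]
            if isinstance(vals[0], str):
                self._arrays[attr] = np.array(vals, dtype=object)
            else:
                self._arrays[attr] = np.asarray(vals, dtype=float)
        return self._arrays[attr]

    def molecule_atoms(self, label: str) -> np.ndarray:
        """All atom indices of molecules carrying ``label``, in atom order."""
        idx = [np.arange(s, e) for lab, s, e in self.molecules if lab == label]
        if not idx:
            return np.empty(0, dtype=int)
        return np.concatenate(idx)

    def water_molecules(self) -> list[np.ndarray]:
        """Atom-index triples of each water molecule, in order."""
        out = []
        for lab, s, e in self.molecules:
            if lab != "water":
                continue
            if (e - s) % 3:
                raise TopologyError("water molecule range is not a multiple of 3 atoms")
            for w in range(s, e, 3):
                out.append(np.arange(w, w + 3))
        return out

    def is_water_residue(self, resname: str) -> bool:
        return resname.strip().upper() in self.water_resnames

    def select(self, names: Iterable[str], atom_subset: np.ndarray | None = None) -> np.ndarray:
        """Indices of atoms whose name is in ``names`` (optionally within a subset)."""
        wanted = set(names)
        pool: Iterator[int] = (
            range(self.n_atoms) if atom_subset is None else atom_subset
        )
        return np.array([i for i in pool if self.atoms[i].name in wanted], dtype=int)

    def heavy_atoms(self, atom_subset: np.ndarray | None = None) -> np.ndarray:
        pool = range(self.n_atoms) if atom_subset is None else atom_subset
        return np.array(
            [i for i in pool if self.atoms[i].element.upper() != "H"], dtype=int
        )

    # -- exclusions ------------------------------------------------------------

    def exclusions(self) -> tuple[set, set]:
        """(excluded 1-2/1-3 pairs, scaled 1-4 pairs) as sets of sorted tuples.

        Derived from bond connectivity: pairs one or two bonds apart are fully
        excluded; pairs exactly three bonds apart are the scaled 1-4 set.
        """
        if self._exclusions is None:
            adj: dict[int, set[int]] = {}
            for i, j, *_ in self.bonds:
                adj.setdefault(i, set()).add(j)
                adj.setdefault(j, set()).add(i)
            ex: set[tuple[int, int]] = set()
            s14: set[tuple[int, int]] = set()
            for i in adj:
                for j in adj[i]:
                    if i < j:
                        ex.add((i, j))
                    for k in adj[j]:
                        if k != i:
                            ex.add((min(i, k), max(i, k)))
                            for l in adj[k]:
                                if l not in (i, j):
                                    s14.add((min(i, l), max(i, l)))
            s14 -= ex
            s14 = {p for p in s14 if p[0] != p[1]}
            self._exclusions = (ex, s14)
        return self._exclusions

    def with_molecules(self, molecules: list[tuple[str, int, int]]) -> "MolecularTopology":
        top = MolecularTopology(
            atoms=[replace(a) for a in self.atoms],
            bonds=list(self.bonds),
            angles=list(self.angles),
            dihedrals=list(self.dihedrals),
            molecules=molecules,
            water_resnames=self.water_resnames,
        )
        return top


@dataclass
class Frame:
    """One coordinate set (Å) with an optional time stamp and box."""

    coordinates: np.ndarray
    time_ps: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TopologyError("frame coordinates must be an N x 3 array")
        if not np.all(np.isfinite(self.coordinates)):
            raise TopologyError("frame contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames bound to one topology; time stamps non-decreasing."""

    topology: MolecularTopology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        last = -np.inf
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise TopologyError(
                    f"frame {k} has {f.n_atoms} atoms, topology has {n}"
                )
            if f.time_ps < last:
                raise TopologyError("frame times must be non-decreasing")
            last = f.time_ps

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])

    def coordinate_array(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])
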