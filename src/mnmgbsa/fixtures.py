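"""Synthetic toy systems with known ground truth.

These generators stand in for MD output so every pipeline stage is
testable at desk scale: a fully parameterized two-chain pseudo-peptide
dimer with a designed contact, weighted conformer ensembles with Gaussian
jitter, and hydrated frames with waters at prescribed distances from a
stated point.  Pseudo-residues carry 3–4 atoms so brute-force oracles
(all-pairs energies, quadrature GB) stay fast and exact.  Everything is
deterministic under the seed; ground truth (conformer labels, water
distance ranking, designed contact) is returned alongside the data so
tests never re-derive it from the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gbneck2 import element_screen, mbondi3_radius
from .model import AtomRecord, Frame, MolecularTopology, Trajectory

_ELEMENT_FF = {
    # element -> (mass, lj_rmin_half Å, lj_epsilon kcal/mol)
    "N": (14.007, 1.824, 0.170),
    "C": (12.011, 1.908, 0.086),
    "O": (15.999, 1.661, 0.210),
    "H": (1.008, 0.0, 0.0),
}

#: TIP3P-style 3-site water geometry and charges
WATER_OH = 0.9572
WATER_HOH_DEG = 104.52
WATER_CHARGES = (-0.834, 0.417, 0.417)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study system."""

    seed: int = 2024
    n_res_a: int = 5
    n_res_b: int = 4
    contact_distance: float = 4.0     # Å between the designed contact CB atoms
    residue_spacing: float = 3.3      # Å along the chain axis
    bond_k: float = 300.0             # kcal/mol/Å²
    angle_k: float = 50.0             # kcal/mol/rad²
    dihedral_height: float = 0.5      # kcal/mol
    conformer_weights: tuple[float, ...] = (0.7, 0.3)
    noise_sigma: float = 0.2          # Å
    n_frames: int = 200
    n_waters: int = 40

    def __post_init__(self) -> None:
        if abs(sum(self.conformer_weights) - 1.0) > 1e-9:
            raise ValueError("conformer weights must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def _residue_atoms(resname: str, with_cb: bool) -> list[tuple[str, str, float]]:
    """(name, element, charge); charges sum to zero per residue."""
    atoms = [("N", "N", -0.3), ("CA", "C", 0.1), ("C", "C", 0.2)]
    if with_cb:
        atoms.append(("CB", "C", 0.0))
    return atoms


def make_toy_dimer(spec: FixtureSpec | None = None,
                   ) -> tuple[MolecularTopology, Frame, tuple[int, int]]:
    """Two short pseudo-peptide chains with one designed contact.

    Chain A runs along x, chain B along y, meeting near the middle of
    chain A; the CB atoms of the contact residues sit
    ``spec.contact_distance`` apart while every other residue pair stays
    well separated.  Returns (topology, frame, (contact residue A,
    contact residue B)).
    """
    spec = spec or FixtureSpec()
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int, float, float]] = []
    angles: list[tuple[int, int, int, float, float]] = []
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = []

    contact_a = spec.n_res_a // 2
    contact_b = 0

    def add_chain(chain_id: str, n_res: int, origin: np.ndarray,
                  axis: np.ndarray, perp: np.ndarray, res_offset: int) -> None:
        up = np.cross(axis, perp)
        for r in range(n_res):
            # the last residue of each chain is glycine-like (no CB)
            with_cb = r != n_res - 1
            resname = "ALA" if with_cb else "GLY"
            base = origin + axis * (r * spec.residue_spacing)
            local = {
                "N": base,
                "CA": base + axis * 1.1 + up * 0.8,
                "C": base + axis * 2.2,
                "CB": base + axis * 1.1 + up * 0.8 + perp * 1.5,
            }
            first = len(atoms)
            for name, element, charge in _residue_atoms(resname, with_cb):
                mass, rmh, eps = _ELEMENT_FF[element]
                atoms.append(AtomRecord(
                    serial=len(atoms) + 1, name=name, element=element,
                    residue_index=res_offset + r, residue_name=resname,
                    chain_id=chain_id, charge=charge, mass=mass,
                    lj_rmin_half=rmh, lj_epsilon=eps,
                    gb_radius=mbondi3_radius(element),
                    gb_screen=element_screen(element),
                ))
                coords.append(local[name])
            iN, iCA, iC = first, first + 1, first + 2
            bonds.append((iN, iCA, spec.bond_k,
                          float(np.linalg.norm(local["CA"] - local["N"]))))
            bonds.append((iCA, iC, spec.bond_k,
                          float(np.linalg.norm(local["C"] - local["CA"]))))
            if with_cb:
                bonds.append((iCA, first + 3, spec.bond_k, 1.5))
            if r > 0:
                prevC = first - 1 if not prev_cb else first - 2
                bonds.append((prevC, iN, spec.bond_k,
                              float(np.linalg.norm(local["N"] - coords[prevC]))))

            def angle_val(i, j, k):
                v1 = coords[i] - coords[j]
                v2 = coords[k] - coords[j]
                return float(np.arccos(np.clip(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))

            angles.append((iN, iCA, iC, spec.angle_k, angle_val(iN, iCA, iC)))
            if with_cb:
                angles.append((iN, iCA, first + 3, spec.angle_k,
                               angle_val(iN, iCA, first + 3)))
            if r > 0:
                dihedrals.append((prev_iCA, prevC, iN, iCA,
                                  spec.dihedral_height, 3, 0.0))
            prev_iCA = iCA
            prevC = iC
            prev_cb = with_cb

    ex, ey, ez = np.eye(3)
    add_chain("A", spec.n_res_a, np.zeros(3), ex, ez, 0)
    # chain B runs along +y with its CB atoms pointing -z toward chain A;
    # origin chosen so CB(B res 0) sits contact_distance above CB(A contact)
    xc = contact_a * spec.residue_spacing
    origin_b = np.array([xc + 1.9, -1.9, 3.0 + spec.contact_distance])
    add_chain("B", spec.n_res_b, origin_b, ey, -ez, spec.n_res_a)

    na = sum(4 if r != spec.n_res_a - 1 else 3 for r in range(spec.n_res_a))
    top = MolecularTopology(
        atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals,
        molecules=[("chainA", 0, na), ("chainB", na, len(atoms))],
    )
    return top, Frame(np.array(coords)), (contact_a, spec.n_res_a + contact_b)


def bend_conformer(frame: Frame, pivot_atom: int, angle_deg: float,
                   axis: np.ndarray = (0.0, 1.0, 0.0)) -> Frame:
    """A genuinely distinct conformer: atoms after ``pivot_atom`` rotated
    about an axis through the pivot (internal deformation, so the
    conformers stay distinguishable under superposition-minimized RMSD)."""
    xyz = np.array(frame.coordinates, copy=True)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    k = axis
    def rot(v):
        return (v * np.cos(t) + np.cross(k, v) * np.sin(t)
                + k * (k @ v) * (1.0 - np.cos(t)))
    pivot = xyz[pivot_atom]
    for i in range(pivot_atom + 1, len(xyz)):
        xyz[i] = pivot + rot(xyz[i] - pivot)
    return Frame(xyz, time_ps=frame.time_ps)


def make_conformer_trajectory(topology: MolecularTopology,
                              conformers: list[Frame],
                              weights: tuple[float, ...],
                              n_frames: int, sigma: float, seed: int,
                              time_stride_ps: float = 10.0,
                              ) -> tuple[Trajectory, np.ndarray]:
    """Frames drawn from weighted conformers plus isotropic Gaussian jitter.

    Returns the trajectory and the ground-truth conformer label per frame.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if len(conformers) != len(weights):
        raise ValueError("one weight per conformer required")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(conformers), size=n_frames, p=np.asarray(weights))
    frames = []
    for k, lab in enumerate(labels):
        xyz = conformers[lab].coordinates + rng.normal(
            0.0, sigma, size=conformers[lab].coordinates.shape) if sigma > 0 \
            else conformers[lab].coordinates.copy()
        frames.append(Frame(np.asarray(xyz), time_ps=k * time_stride_ps))
    return Trajectory(topology, frames), labels


def hydration_shell_placements(frame: Frame, origin: np.ndarray, n: int,
                               r_min: float = 4.0, r_step: float = 0.5,
                               clearance: float = 2.8, seed: int = 0,
                               ) -> list[tuple[float, np.ndarray]]:
    """Non-overlapping water placements around ``origin`` with known radii.

    Oxygen positions go at increasing distances ``r_min + k * r_step`` in
    quasi-uniform directions, skipping directions that would put a water
    within ``clearance`` of an existing solute atom, so the ground-truth
    distance ranking equals the placement order.
    """
    rng = np.random.default_rng(seed)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    placements: list[tuple[float, np.ndarray]] = []
    k = 0
    attempt = 0
    while len(placements) < n:
        z = 1.0 - 2.0 * ((attempt % 97) + 0.5) / 97.0
        r = np.sqrt(max(1.0 - z * z, 0.0))
        u = np.array([r * np.cos(golden * attempt), r * np.sin(golden * attempt), z])
        dist = r_min + k * r_step
        pos = np.asarray(origin) + dist * u
        attempt += 1
        if attempt > 100 * n:
            raise RuntimeError("could not place waters without clashes")
        if np.min(np.linalg.norm(frame.coordinates - pos, axis=1)) < clearance:
            continue
        if placements:
            prev = np.array([np.asarray(o) + d * np.asarray(v) / np.linalg.norm(v)
                             for d, v in placements for o in [origin]])
            if np.min(np.linalg.norm(prev - pos, axis=1)) < 2.5:
                continue
        placements.append((float(dist), u))
        k += 1
    return placements


def _water_records(serial0: int, res0: int, n: int) -> list[AtomRecord]:
    out = []
    for w in range(n):
        for name, element, charge in (("O", "O", WATER_CHARGES[0]),
                                      ("H1", "H", WATER_CHARGES[1]),
                                      ("H2", "H", WATER_CHARGES[2])):
            mass, rmh, eps = _ELEMENT_FF[element]
            if element == "O":
                rmh, eps = 1.7683, 0.1520
            out.append(AtomRecord(
                serial=serial0 + len(out) + 1, name=name, element=element,
                residue_index=res0 + w, residue_name="WAT", chain_id="W",
                charge=charge, mass=mass, lj_rmin_half=rmh, lj_epsilon=eps,
                gb_radius=mbondi3_radius(element),
                gb_screen=element_screen(element),
            ))
    return out


def make_hydrated_frames(topology: MolecularTopology, frame: Frame,
                         placements: list[tuple[float, np.ndarray]],
                         seed: int = 0, origin: np.ndarray | None = None,
                         ) -> tuple[MolecularTopology, Frame, np.ndarray]:
    """Append 3-site waters at stated (distance, direction) placements.

    Water oxygens land at ``origin + distance * direction/|direction|``;
    hydrogens use the rigid 3-site geometry (O–H 0.9572 Å, H–O–H 104.52°)
    with a seed-deterministic orientation.  Returns the augmented topology
    and frame plus the ground-truth ranking of water ids by distance.
    """
    if origin is None:
        origin = np.zeros(3)
    if not placements:
        return topology, frame, np.empty(0, dtype=int)
    rng = np.random.default_rng(seed)
    o_pos = []
    for dist, direction in placements:
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        o_pos.append(np.asarray(origin) + dist * u)
    o_pos = np.array(o_pos)
    d2 = ((o_pos[:, None, :] - o_pos[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < 2.4 ** 2:
        i, j = np.unravel_index(int(d2.argmin()), d2.shape)
        raise ValueError(
            f"water placements {i} and {j} overlap (O–O {np.sqrt(d2.min()):.2f} Å)"
        )
    half = np.deg2rad(WATER_HOH_DEG) / 2.0
    xyz = [frame.coordinates]
    for o in o_pos:
        # random orthonormal pair defining the molecular plane
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        b = np.cross(a, rng.normal(size=3))
        b /= np.linalg.norm(b)
        h1 = o + WATER_OH * (np.cos(half) * a + np.sin(half) * b)
        h2 = o + WATER_OH * (np.cos(half) * a - np.sin(half) * b)
        xyz.append(np.stack([o, h1, h2]))
    n0 = topology.n_atoms
    res0 = topology.residues[-1].index + 1
    new_atoms = [a for a in topology.atoms] + _water_records(n0, res0, len(o_pos))
    bonds = list(topology.bonds)
    angles = list(topology.angles)
    for w in range(len(o_pos)):
        io = n0 + 3 * w
        bonds.append((io, io + 1, 450.0, WATER_OH))
        bonds.append((io, io + 2, 450.0, WATER_OH))
        angles.append((io + 1, io, io + 2, 55.0, np.deg2rad(WATER_HOH_DEG)))
    new_top = MolecularTopology(
        atoms=new_atoms, bonds=bonds, angles=angles,
        dihedrals=list(topology.dihedrals),
        molecules=list(topology.molecules) + [("water", n0, n0 + 3 * len(o_pos))],
        water_resnames=topology.water_resnames,
    )
    dists = np.array([p[0] for p in placements])
    ranking = np.argsort(dists, kind="stable")
    return new_top, Frame(np.concatenate(xyz, axis=0), time_ps=frame.time_ps), ranking
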