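"""Single-trajectory end-point MM-GBSA energetics.

The binding free energy is estimated per frame as

    dG_bind = G_complex - G_receptor - G_ligand,
    G = E_bond + E_angle + E_dihedral + E_vdW + E_elec + G_polar + G_nonpolar,

with all three subsystems evaluated on the *same* complex-trajectory
coordinates (single-trajectory convention), so the internal bonded terms
cancel exactly.  G_polar is the GB-Neck2 generalized-Born energy with
effective radii recomputed per subsystem; G_nonpolar = gamma * SASA + b
with gamma = 0.0072 kcal/(mol·Å²) and b = 0.  The solute entropy term is
deliberately not computed; it is reported as "not computed" rather than
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gbneck2 import GbParameters, hct_integral_array, neck_value
from .interface import SolvationSelection, SystemPartition, compute_sasa, partition_system
from .model import Frame, MolecularTopology, Trajectory

#: Eq-6 nonpolar surface coefficient, kcal/(mol Å²), and offset, kcal/mol
SA_GAMMA = 0.0072
SA_OFFSET = 0.0
#: Amber 1-4 scaling divisors (ff14SB convention)
SCEE = 1.2
SCNB = 2.0


@dataclass
class EnergyComponents:
    e_bond: float = 0.0
    e_angle: float = 0.0
    e_dihedral: float = 0.0
    e_vdw: float = 0.0
    e_elec: float = 0.0
    g_polar: float = 0.0
    g_nonpolar: float = 0.0

    @property
    def total(self) -> float:
        return (self.e_bond + self.e_angle + self.e_dihedral + self.e_vdw
                + self.e_elec + self.g_polar + self.g_nonpolar)

    def __sub__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(*(getattr(self, f) - getattr(other, f)
                                  for f in ("e_bond", "e_angle", "e_dihedral",
                                            "e_vdw", "e_elec", "g_polar",
                                            "g_nonpolar")))


@dataclass
class BindingEnergySeries:
    frames: np.ndarray
    complex_energies: list[EnergyComponents]
    receptor_energies: list[EnergyComponents]
    ligand_energies: list[EnergyComponents]
    entropy_term: None = None   # -T dS is not computed by this protocol

    @property
    def delta_components(self) -> list[EnergyComponents]:
        return [c - r - l for c, r, l in zip(
            self.complex_energies, self.receptor_energies, self.ligand_energies)]

    @property
    def delta_g(self) -> np.ndarray:
        return np.array([d.total for d in self.delta_components])

    @property
    def mean(self) -> float:
        return float(self.delta_g.mean())

    @property
    def std(self) -> float:
        return float(self.delta_g.std(ddof=1)) if len(self.frames) > 1 else 0.0

    def summary_table(self) -> str:
        comps = self.delta_components
        lines = ["frame\tdE_vdW\tdE_elec\tdG_polar\tdG_nonpolar\tdG_bind"]
        for k, d in zip(self.frames, comps):
            lines.append(f"{k}\t{d.e_vdw:.4f}\t{d.e_elec:.4f}\t{d.g_polar:.4f}"
                         f"\t{d.g_nonpolar:.4f}\t{d.total:.4f}")
        lines.append(f"# mean dG_bind = {self.mean:.4f} +/- {self.std:.4f} kcal/mol"
                     f" (entropy term not computed)")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# molecular-mechanics terms
# ---------------------------------------------------------------------------

def bonded_energy(topology: MolecularTopology, frame: Frame,
                  atom_set: np.ndarray) -> tuple[float, float, float]:
    """Harmonic bonds/angles and periodic dihedrals over terms fully inside
    ``atom_set`` (Amber convention E_bond = k (r − r0)²)."""
    inset = np.zeros(topology.n_atoms, dtype=bool)
    inset[np.asarray(atom_set, int)] = True
    x = frame.coordinates
    e_bond = 0.0
    for i, j, k, r0 in topology.bonds:
        if inset[i] and inset[j]:
            r = np.linalg.norm(x[i] - x[j])
            e_bond += k * (r - r0) ** 2
    e_angle = 0.0
    for i, j, l, k, t0 in topology.angles:
        if inset[i] and inset[j] and inset[l]:
            v1 = x[i] - x[j]
            v2 = x[l] - x[j]
            ct = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = np.arccos(np.clip(ct, -1.0, 1.0))
            e_angle += k * (theta - t0) ** 2
    e_dih = 0.0
    for i, j, l, m, height, n, phase in topology.dihedrals:
        if inset[i] and inset[j] and inset[l] and inset[m]:
            b1, b2, b3 = x[j] - x[i], x[l] - x[j], x[m] - x[l]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            mvec = np.cross(n1, b2 / np.linalg.norm(b2))
            phi = np.arctan2(np.dot(mvec, n2), np.dot(n1, n2))
            e_dih += height * (1.0 + np.cos(n * phi - phase))
    return float(e_bond), float(e_angle), float(e_dih)


def _pair_masks(topology: MolecularTopology, atom_set: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(iu, ju, excluded mask, 1-4 mask) over local pair indices."""
    atom_set = np.asarray(atom_set, int)
    n = atom_set.size
    local = {int(g): k for k, g in enumerate(atom_set)}
    iu, ju = np.triu_indices(n, k=1)
    excl, s14 = topology.exclusions()
    ex_mask = np.zeros(iu.size, dtype=bool)
    s14_mask = np.zeros(iu.size, dtype=bool)
    pair_pos = {}
    for p, (a, b) in enumerate(zip(iu, ju)):
        pair_pos[(int(a), int(b))] = p
    for (gi, gj) in excl:
        if gi in local and gj in local:
            a, b = sorted((local[gi], local[gj]))
            ex_mask[pair_pos[(a, b)]] = True
    for (gi, gj) in s14:
        if gi in local and gj in local:
            a, b = sorted((local[gi], local[gj]))
            s14_mask[pair_pos[(a, b)]] = True
    return iu, ju, ex_mask, s14_mask


def nonbonded_gas_energy(topology: MolecularTopology, frame: Frame,
                         atom_set: np.ndarray, *, eps_in: float = 1.0,
                         coulomb: float = 332.0636,
                         ) -> tuple[float, float]:
    """Gas-phase vdW + Coulomb over all pairs inside ``atom_set``.

    No distance cutoff; 1-2/1-3 pairs excluded, 1-4 pairs divided by 1.2
    (electrostatics) and 2.0 (vdW) per the Amber convention.
    """
    atom_set = np.asarray(atom_set, int)
    x = frame.coordinates[atom_set]
    q = topology.array("charge")[atom_set]
    rmh = topology.array("lj_rmin_half")[atom_set]
    eps = topology.array("lj_epsilon")[atom_set]
    iu, ju, ex_mask, s14_mask = _pair_masks(topology, atom_set)
    d = np.linalg.norm(x[iu] - x[ju], axis=1)
    keep = ~ex_mask
    scale_e = np.where(s14_mask, 1.0 / SCEE, 1.0)
    scale_v = np.where(s14_mask, 1.0 / SCNB, 1.0)
    e_elec = coulomb / eps_in * np.sum(
        np.where(keep, scale_e * q[iu] * q[ju] / d, 0.0))
    rmin = rmh[iu] + rmh[ju]
    epsij = np.sqrt(eps[iu] * eps[ju])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (rmin / d) ** 6
    lj = epsij * (sr6 * sr6 - 2.0 * sr6)
    e_vdw = np.sum(np.where(keep & (epsij > 0), scale_v * lj, 0.0))
    return float(e_vdw), float(e_elec)


# ---------------------------------------------------------------------------
# GB-Neck2 polar solvation
# ---------------------------------------------------------------------------

def effective_born_radii(topology: MolecularTopology, frame: Frame,
                         params: GbParameters,
                         atom_set: np.ndarray | None = None) -> np.ndarray:
    """Per-atom GB-Neck2 effective radii for the atoms of ``atom_set``."""
    if atom_set is None:
        atom_set = np.arange(topology.n_atoms)
    atom_set = np.asarray(atom_set, int)
    rho = topology.array("gb_radius")[atom_set]
    if np.any(rho <= 0):
        bad = atom_set[np.where(rho <= 0)[0][0]]
        raise ValueError(f"non-positive intrinsic Born radius on atom "
                         f"{topology.atoms[bad].serial} ({topology.atoms[bad].name})")
    screen = topology.array("gb_screen")[atom_set]
    x = frame.coordinates[atom_set]
    n = atom_set.size
    rho_t = rho - params.offset
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    sj = (screen * rho_t)[None, :] * np.ones((n, 1))
    ri = rho_t[:, None] * np.ones((1, n))
    integral = hct_integral_array(np.where(d > 0, d, 1.0), ri, sj)
    np.fill_diagonal(integral, 0.0)
    # neck correction per pair (uses intrinsic, un-offset radii)
    neck = np.zeros_like(d)
    uniq = sorted(set(np.round(rho, 4)))
    for ra in uniq:
        for rb in uniq:
            mask = (np.abs(rho[:, None] - ra) < 5e-5) & (np.abs(rho[None, :] - rb) < 5e-5)
            np.fill_diagonal(mask, False)
            if mask.any():
                neck[mask] = neck_value(d[mask], float(ra), float(rb),
                                        params.probe_radius)
    total = integral.sum(axis=1) + params.neck_scale * neck.sum(axis=1)
    psi = total * rho_t
    abg = np.array([params.abg(topology.atoms[g].element) for g in atom_set])
    alpha, beta, gamma = abg[:, 0], abg[:, 1], abg[:, 2]
    inv = 1.0 / rho_t - np.tanh(alpha * psi - beta * psi ** 2 + gamma * psi ** 3) / rho
    radii = np.where(inv > 1.0 / params.max_effective_radius,
                     1.0 / inv, params.max_effective_radius)
    return radii


def _gb_pair_energy_matrix(q: np.ndarray, d: np.ndarray, radii: np.ndarray,
                           params: GbParameters) -> np.ndarray:
    """Full matrix of GB pair energies; diagonal holds the self terms.

    e_ij = -1/2 C q_i q_j (1/eps_in - exp(-kappa f_ij)/eps_out) / f_ij,
    f_ij = sqrt(d² + R_i R_j exp(-d²/(4 R_i R_j))), f_ii = R_i.
    """
    rr = radii[:, None] * radii[None, :]
    f = np.sqrt(d * d + rr * np.exp(-d * d / (4.0 * rr)))
    np.fill_diagonal(f, radii)
    kappa = params.kappa_gb
    tau = 1.0 / params.eps_in - np.exp(-kappa * f) / params.eps_out
    return -0.5 * params.coulomb * (q[:, None] * q[None, :]) * tau / f


def gb_polar_energy(topology: MolecularTopology, frame: Frame,
                    radii: np.ndarray, params: GbParameters,
                    atom_set: np.ndarray | None = None) -> float:
    """GB polar solvation free energy of the atom set (self + pair terms)."""
    if atom_set is None:
        atom_set = np.arange(topology.n_atoms)
    atom_set = np.asarray(atom_set, int)
    q = topology.array("charge")[atom_set]
    x = frame.coordinates[atom_set]
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    e = _gb_pair_energy_matrix(q, d, radii, params)
    # off-diagonal pairs appear twice in the full matrix (weight 2 in the
    # i<=j convention), so the plain matrix sum is the desired energy
    return float(e.sum())


def sa_nonpolar_energy(sasa_total: float, gamma: float = SA_GAMMA,
                       b: float = SA_OFFSET) -> float:
    """Linear surface-area nonpolar solvation term."""
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * sasa_total + b


# ---------------------------------------------------------------------------
# end-point binding free energy
# ---------------------------------------------------------------------------

def _subsystem_energy(topology: MolecularTopology, frame: Frame,
                      atom_set: np.ndarray, params: GbParameters,
                      sasa_points: int) -> EnergyComponents:
    eb, ea, ed = bonded_energy(topology, frame, atom_set)
    ev, ee = nonbonded_gas_energy(topology, frame, atom_set,
                                  eps_in=params.eps_in, coulomb=params.coulomb)
    radii = effective_born_radii(topology, frame, params, atom_set)
    gp = gb_polar_energy(topology, frame, radii, params, atom_set)
    sasa = compute_sasa(frame, topology, atom_subset=atom_set,
                        n_points=sasa_points)
    gn = sa_nonpolar_energy(sasa.total)
    return EnergyComponents(eb, ea, ed, ev, ee, gp, gn)


def endpoint_binding_free_energy(trajectory: Trajectory,
                                 partition: SystemPartition,
                                 frames: np.ndarray | list[int] | None = None,
                                 params: GbParameters | None = None, *,
                                 solvation: SolvationSelection | None = None,
                                 sasa_points: int = 960,
                                 ) -> BindingEnergySeries:
    """Frame-ensemble single-trajectory MM-GBSA binding free energy.

    With ``solvation`` given, the retained waters (and hence the
    receptor/complex atom sets) are rebuilt per frame from the per-frame
    closest-water selection; the ligand set never contains waters.
    """
    params = params or GbParameters()
    if frames is None:
        frames = np.arange(len(trajectory))
    frames = np.asarray(frames, int)
    if frames.size and (frames.min() < 0 or frames.max() >= len(trajectory)):
        raise IndexError(f"frame index out of range 0..{len(trajectory) - 1}")
    if solvation is not None and len(solvation.water_ids) != frames.size:
        raise ValueError("solvation selection length does not match frames")
    comp, rec, lig = [], [], []
    top = trajectory.topology
    for pos, k in enumerate(frames):
        fr = trajectory[int(k)]
        if solvation is not None:
            part = partition_system(top, partition.ligand_chain,
                                    solvation.water_ids[pos])
        else:
            part = partition
        comp.append(_subsystem_energy(top, fr, part.complex_atoms, params, sasa_points))
        rec.append(_subsystem_energy(top, fr, part.receptor_atoms, params, sasa_points))
        lig.append(_subsystem_energy(top, fr, part.ligand_atoms, params, sasa_points))
    return BindingEnergySeries(frames=frames, complex_energies=comp,
                               receptor_energies=rec, ligand_energies=lig)


# ---------------------------------------------------------------------------
# pairwise per-residue decomposition
# ---------------------------------------------------------------------------

@dataclass
class PairDecomposition:
    pairs: dict[tuple[int, int], dict[str, float]]  # (res rec, res lig) -> terms
    residue_sa: dict[int, float]
    frames: np.ndarray

    def totals(self) -> dict[tuple[int, int], float]:
        return {p: v["vdw"] + v["elec"] + v["gb"] for p, v in self.pairs.items()}

    def top_pairs(self, n: int = 10) -> list[tuple[tuple[int, int], float]]:
        t = self.totals()
        return sorted(t.items(), key=lambda kv: kv[1])[:n]

    def to_table(self, topology: MolecularTopology) -> str:
        lines = ["res_rec\tres_lig\tvdW\telec\tGB\ttotal"]
        for (ra, rb), v in sorted(self.pairs.items()):
            na = topology.residue(ra).name
            nb = topology.residue(rb).name
            lines.append(f"{na}{ra}\t{nb}{rb}\t{v['vdw']:.4f}\t{v['elec']:.4f}"
                         f"\t{v['gb']:.4f}\t{v['vdw'] + v['elec'] + v['gb']:.4f}")
        return "\n".join(lines) + "\n"


def pairwise_decomposition(trajectory: Trajectory, partition: SystemPartition,
                           frames: np.ndarray | list[int] | None = None,
                           params: GbParameters | None = None, *,
                           sasa_points: int = 960,
                           ) -> PairDecomposition:
    """Cross-partition residue-pair attribution of the interaction energy.

    vdW and electrostatics are direct atom-pair sums between receptor and
    ligand residues; the GB term attributes every cross-partition pair term
    of the polar double sum (complex effective radii).  Self terms stay
    with their own residue and do not enter the pairwise table.  Values are
    averaged over the selected frames.
    """
    params = params or GbParameters()
    if frames is None:
        frames = np.arange(len(trajectory))
    frames = np.asarray(frames, int)
    top = trajectory.topology
    res_of = np.array([a.residue_index for a in top.atoms])
    comp = partition.complex_atoms
    in_rec = np.isin(comp, partition.receptor_atoms)
    in_lig = np.isin(comp, partition.ligand_atoms)
    q = top.array("charge")[comp]
    rmh = top.array("lj_rmin_half")[comp]
    eps = top.array("lj_epsilon")[comp]
    pairs_acc: dict[tuple[int, int], dict[str, float]] = {}
    sa_acc: dict[int, float] = {}
    excl, s14 = top.exclusions()
    for k in frames:
        fr = trajectory[int(k)]
        x = fr.coordinates[comp]
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
        radii = effective_born_radii(top, fr, params, comp)
        gb = _gb_pair_energy_matrix(q, d, radii, params)
        cross = in_rec[:, None] & in_lig[None, :]
        ii, jj = np.where(cross)
        for a, b in zip(ii, jj):
            gi, gj = int(comp[a]), int(comp[b])
            key = (int(res_of[gi]), int(res_of[gj]))
            rec_pair = tuple(sorted((gi, gj)))
            if rec_pair in excl:
                e_el = e_vdw = 0.0
            else:
                se, sv = (1.0 / SCEE, 1.0 / SCNB) if rec_pair in s14 else (1.0, 1.0)
                e_el = se * params.coulomb / params.eps_in * q[a] * q[b] / d[a, b]
                epsij = np.sqrt(eps[a] * eps[b])
                if epsij > 0:
                    sr6 = ((rmh[a] + rmh[b]) / d[a, b]) ** 6
                    e_vdw = sv * epsij * (sr6 * sr6 - 2.0 * sr6)
                else:
                    e_vdw = 0.0
            e_gb = 2.0 * gb[a, b]   # unordered pair appears twice in the sum
            acc = pairs_acc.setdefault(key, {"vdw": 0.0, "elec": 0.0, "gb": 0.0})
            acc["vdw"] += e_vdw
            acc["elec"] += e_el
            acc["gb"] += e_gb
        # per-residue surface term: burial on complexation, per residue
        sas_c = compute_sasa(fr, top, atom_subset=comp, n_points=sasa_points)
        sas_r = compute_sasa(fr, top, atom_subset=partition.receptor_atoms,
                             n_points=sasa_points)
        sas_l = compute_sasa(fr, top, atom_subset=partition.ligand_atoms,
                             n_points=sasa_points)
        iso = {**sas_r.residue_sasa, **sas_l.residue_sasa}
        for ridx, val in sas_c.residue_sasa.items():
            sa_acc[ridx] = sa_acc.get(ridx, 0.0) + SA_GAMMA * (val - iso.get(ridx, 0.0))
    nf = float(frames.size)
    for acc in pairs_acc.values():
        for kk in acc:
            acc[kk] /= nf
    return PairDecomposition(pairs=pairs_acc,
                             residue_sa={r: v / nf for r, v in sa_acc.items()},
                             frames=frames)


def atom_pair_distance_series(trajectory: Trajectory,
                              spec_a: tuple[str, int, str],
                              spec_b: tuple[str, int, str],
                              frames: np.ndarray | list[int] | None = None,
                              ) -> np.ndarray:
    """Per-frame distance between two atoms given as (chain id, residue
    index, atom name)."""
    top = trajectory.topology

    def resolve(spec):
        chain, ridx, name = spec
        hits = [i for i, a in enumerate(top.atoms)
                if a.chain_id == chain and a.residue_index == ridx and a.name == name]
        if len(hits) != 1:
            raise ValueError(f"atom spec {spec} resolves to {len(hits)} atoms")
        return hits[0]

    ia, ib = resolve(spec_a), resolve(spec_b)
    if frames is None:
        frames = np.arange(len(trajectory))
    return np.array([
        float(np.linalg.norm(trajectory[int(k)].coordinates[ia]
                             - trajectory[int(k)].coordinates[ib]))
        for k in np.asarray(frames, int)])
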