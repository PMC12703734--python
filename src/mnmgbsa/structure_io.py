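"""Readers/writers for PDB, Amber parameter-topology and ASCII trajectories.

Only the parameter-topology sections feeding the energy model are parsed
(pointers, names, charges, masses, LJ, bonded terms, radii, screening);
anything else is skipped with a debug log line.  Charges are converted to
elementary-charge units at the file boundary (Amber stores q * 18.2223).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np

from .model import (
    ION_RESNAMES,
    WATER_RESNAMES,
    AtomRecord,
    Frame,
    MolecularTopology,
    TopologyError,
    Trajectory,
)

log = logging.getLogger(__name__)

#: Amber internal charge unit: sqrt(332.0522...) — divide on read, multiply on write
AMBER_CHARGE_SCALE = 18.2223

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.453, "K": 39.098, "MG": 24.305,
    "F": 18.998, "BR": 79.904, "FE": 55.845, "ZN": 65.38,
}
_ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "FE": 26, "ZN": 30, "BR": 35,
}
_NUM_TO_ELEMENT = {v: k.capitalize() for k, v in _ATOMIC_NUMBERS.items()}


class FileFormatError(ValueError):
    """Raised on malformed input files; message carries file context."""


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in ("CL", "NA", "MG", "BR", "FE", "ZN") and len(atom_name.strip()) > 1:
        return two.capitalize()
    return stripped[0].upper()


def _segment_molecules(atoms: list[AtomRecord],
                       water_resnames: frozenset[str] = WATER_RESNAMES,
                       ) -> list[tuple[str, int, int]]:
    """Label contiguous atom ranges as chainA/chainB/water/ion.

    Protein chains are assigned in order of first appearance of their
    chain id; the first becomes chainA, every later one chainB-style
    labels in sequence (chainB, chainC...).
    """
    ranges: list[tuple[str, int, int]] = []
    chain_labels: dict[str, str] = {}
    label_cycle = ["chainA", "chainB", "chainC", "chainD"]
    for i, a in enumerate(atoms):
        rn = a.residue_name.strip().upper()
        if rn in water_resnames:
            lab = "water"
        elif rn in ION_RESNAMES:
            lab = "ion"
        else:
            if a.chain_id not in chain_labels:
                chain_labels[a.chain_id] = label_cycle[min(len(chain_labels), 3)]
            lab = chain_labels[a.chain_id]
        if ranges and ranges[-1][0] == lab:
            ranges[-1] = (lab, ranges[-1][1], i + 1)
        else:
            ranges.append((lab, i, i + 1))
    return ranges


def read_pdb(path: str | Path, water_resnames: frozenset[str] = WATER_RESNAMES,
             ) -> tuple[MolecularTopology, list[Frame]]:
    """Read a (possibly multi-MODEL) PDB file.

    Returns a topology skeleton (no force-field fields populated) and one
    frame per MODEL record, or a single frame if the file has none.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    frames_xyz: list[list[tuple[float, float, float]]] = [[]]
    in_first_model = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain = line[21].strip() or "A"
                    resseq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise FileFormatError(
                        f"{path.name}: malformed ATOM/HETATM record at line {lineno}: {exc}"
                    ) from exc
                element = line[76:78].strip() if len(line) >= 78 else ""
                frames_xyz[-1].append((x, y, z))
                if in_first_model:
                    atoms.append(AtomRecord(
                        serial=serial, name=name,
                        element=element.capitalize() or _infer_element(name),
                        residue_index=0,  # assigned below
                        residue_name=resname, chain_id=chain,
                    ))
                    # stash the file residue number for renumbering below
                    atoms[-1]._file_resseq = resseq  # type: ignore[attr-defined]
            elif rec.startswith("ENDMDL"):
                in_first_model = False
                frames_xyz.append([])
    if frames_xyz and not frames_xyz[-1]:
        frames_xyz.pop()
    if not atoms:
        raise FileFormatError(f"{path.name}: no ATOM/HETATM records found")
    for k, fx in enumerate(frames_xyz):
        if len(fx) != len(atoms):
            raise FileFormatError(
                f"{path.name}: MODEL {k + 1} has {len(fx)} atoms, expected {len(atoms)}"
            )
    # 0-based residue indices in order of appearance of (chain, resseq)
    res_index = -1
    last_key = None
    for a in atoms:
        key = (a.chain_id, a._file_resseq)  # type: ignore[attr-defined]
        if key != last_key:
            res_index += 1
            last_key = key
        a.residue_index = res_index
        del a._file_resseq  # type: ignore[attr-defined]
    top = MolecularTopology(
        atoms=atoms,
        molecules=_segment_molecules(atoms, water_resnames),
        water_resnames=water_resnames,
    )
    frames = [Frame(np.array(fx)) for fx in frames_xyz]
    return top, frames


def write_pdb(topology: MolecularTopology, frames: Frame | list[Frame],
              path: str | Path, *, water_resname: str = "WAT",
              renumber_chain_b: bool = False,
              partition_labels: dict[int, str] | None = None) -> None:
    """Write fixed-column PDB; multi-frame input becomes MODEL/ENDMDL blocks.

    With ``renumber_chain_b`` the second chain's residues continue
    sequentially after the last residue of the first chain (the
    renumbering convention used when pairing unbound-chain ensembles with
    their crystal complex).  ``partition_labels`` (atom index -> short
    label) lands in the segment-id columns.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    path = Path(path)
    # residue numbers: 1-based per chain, or sequential across chains
    resnum: dict[int, int] = {}
    if renumber_chain_b:
        for r in topology.residues:
            resnum[r.index] = r.index + 1
    else:
        per_chain: dict[str, int] = {}
        for r in topology.residues:
            per_chain[r.chain_id] = per_chain.get(r.chain_id, 0) + 1
            resnum[r.index] = per_chain[r.chain_id]
    with open(path, "w") as fh:
        multi = len(frames) > 1
        for m, fr in enumerate(frames, start=1):
            if fr.n_atoms != topology.n_atoms:
                raise TopologyError("frame atom count does not match topology")
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i, a in enumerate(topology.atoms):
                x, y, z = fr.coordinates[i]
                if max(abs(x), abs(y), abs(z)) >= 10000:
                    raise FileFormatError(
                        f"coordinate overflow for atom {a.serial} ({a.name}): "
                        f"|{max(abs(x), abs(y), abs(z)):.1f}| does not fit %8.3f"
                    )
                rn = a.residue_name
                if topology.is_water_residue(rn):
                    rn = water_resname
                name = a.name if len(a.name) >= 4 else f" {a.name}"
                seg = (partition_labels or {}).get(i, "")
                fh.write(
                    f"ATOM  {a.serial % 100000:5d} {name:<4.4s} {rn:<3.3s} "
                    f"{a.chain_id:1.1s}{resnum[a.residue_index] % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}      "
                    f"{seg:<4.4s}{a.element:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Amber parameter-topology (prmtop)
# ---------------------------------------------------------------------------

_MANDATORY_FLAGS = (
    "POINTERS", "ATOM_NAME", "CHARGE", "MASS", "RESIDUE_LABEL",
    "RESIDUE_POINTER", "RADII", "SCREEN",
)


def _parse_prmtop_sections(path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("%VERSION"):
                continue
            if line.startswith("%FLAG"):
                current = line.split()[1]
                sections[current] = []
            elif line.startswith("%FORMAT"):
                continue
            elif line.startswith("%COMMENT"):
                continue
            elif current is not None:
                sections[current].append(line.rstrip("\n"))
    return sections


def _floats(lines: list[str]) -> np.ndarray:
    return np.array([float(t) for ln in lines for t in ln.split()])


def _ints(lines: list[str]) -> np.ndarray:
    toks = [t for ln in lines for t in ln.split()]
    return np.array([int(t) for t in toks], dtype=int) if toks else np.empty(0, int)


def _names(lines: list[str], width: int = 4) -> list[str]:
    out = []
    for ln in lines:
        for k in range(0, len(ln), width):
            tok = ln[k:k + width].strip()
            if tok:
                out.append(tok)
    return out


def read_prmtop(path: str | Path,
                water_resnames: frozenset[str] = WATER_RESNAMES,
                ) -> MolecularTopology:
    """Read an Amber %FLAG/%FORMAT parameter-topology file."""
    path = Path(path)
    sec = _parse_prmtop_sections(path)
    for flag in _MANDATORY_FLAGS:
        if flag not in sec:
            raise FileFormatError(f"{path.name}: missing mandatory section {flag}")
    known = set(_MANDATORY_FLAGS) | {
        "TITLE", "ATOMIC_NUMBER", "ATOM_TYPE_INDEX", "NONBONDED_PARM_INDEX",
        "BOND_FORCE_CONSTANT", "BOND_EQUIL_VALUE", "ANGLE_FORCE_CONSTANT",
        "ANGLE_EQUIL_VALUE", "DIHEDRAL_FORCE_CONSTANT", "DIHEDRAL_PERIODICITY",
        "DIHEDRAL_PHASE", "LENNARD_JONES_ACOEF", "LENNARD_JONES_BCOEF",
        "BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN", "ANGLES_INC_HYDROGEN",
        "ANGLES_WITHOUT_HYDROGEN", "DIHEDRALS_INC_HYDROGEN",
        "DIHEDRALS_WITHOUT_HYDROGEN", "AMBER_ATOM_TYPE",
    }
    for flag in sec:
        if flag not in known:
            log.debug("prmtop section %s ignored", flag)

    ptr = _ints(sec["POINTERS"])
    natom, ntypes = int(ptr[0]), int(ptr[1])
    nres = int(ptr[11])
    charges = _floats(sec["CHARGE"]) / AMBER_CHARGE_SCALE
    masses = _floats(sec["MASS"])
    names = _names(sec["ATOM_NAME"])
    radii = _floats(sec["RADII"])
    screen = _floats(sec["SCREEN"])
    for label, arr in (("CHARGE", charges), ("MASS", masses),
                       ("ATOM_NAME", names), ("RADII", radii), ("SCREEN", screen)):
        if len(arr) != natom:
            raise FileFormatError(
                f"{path.name}: section {label} has {len(arr)} entries, POINTERS says {natom} atoms"
            )
    res_labels = _names(sec["RESIDUE_LABEL"])
    res_ptr = _ints(sec["RESIDUE_POINTER"]) - 1  # 1-based in file
    if len(res_labels) != nres or len(res_ptr) != nres:
        raise FileFormatError(f"{path.name}: residue sections disagree with POINTERS NRES={nres}")

    # elements
    if "ATOMIC_NUMBER" in sec:
        elements = [_NUM_TO_ELEMENT.get(int(z), "X") for z in _ints(sec["ATOMIC_NUMBER"])]
    else:
        elements = [min(_ELEMENT_MASSES, key=lambda e: abs(_ELEMENT_MASSES[e] - m)).capitalize()
                    for m in masses]

    # per-atom LJ from the diagonal of the type-pair tables
    rmin_half = np.zeros(natom)
    epsilon = np.zeros(natom)
    if "ATOM_TYPE_INDEX" in sec and "LENNARD_JONES_ACOEF" in sec:
        tidx = _ints(sec["ATOM_TYPE_INDEX"]) - 1
        nbidx = _ints(sec["NONBONDED_PARM_INDEX"])
        acoef = _floats(sec["LENNARD_JONES_ACOEF"])
        bcoef = _floats(sec["LENNARD_JONES_BCOEF"])
        for i in range(natom):
            t = tidx[i]
            k = nbidx[ntypes * t + t] - 1
            a, b = acoef[k], bcoef[k]
            if a > 0 and b > 0:
                rmin = (2.0 * a / b) ** (1.0 / 6.0)
                epsilon[i] = b * b / (4.0 * a)
                rmin_half[i] = rmin / 2.0

    # residue assignment per atom
    res_of_atom = np.zeros(natom, dtype=int)
    for r in range(nres):
        start = res_ptr[r]
        stop = res_ptr[r + 1] if r + 1 < nres else natom
        res_of_atom[start:stop] = r

    atoms = [AtomRecord(
        serial=i + 1, name=names[i], element=elements[i],
        residue_index=int(res_of_atom[i]), residue_name=res_labels[res_of_atom[i]],
        chain_id="?", charge=float(charges[i]), mass=float(masses[i]),
        lj_rmin_half=float(rmin_half[i]), lj_epsilon=float(epsilon[i]),
        gb_radius=float(radii[i]), gb_screen=float(screen[i]),
    ) for i in range(natom)]

    bonds: list[tuple[int, int, float, float]] = []
    if "BOND_FORCE_CONSTANT" in sec:
        bk = _floats(sec["BOND_FORCE_CONSTANT"])
        br = _floats(sec["BOND_EQUIL_VALUE"])
        for flag in ("BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN"):
            raw = _ints(sec.get(flag, []))
            for k in range(0, len(raw), 3):
                i, j, t = raw[k] // 3, raw[k + 1] // 3, raw[k + 2] - 1
                bonds.append((int(i), int(j), float(bk[t]), float(br[t])))
    angles: list[tuple[int, int, int, float, float]] = []
    if "ANGLE_FORCE_CONSTANT" in sec:
        ak = _floats(sec["ANGLE_FORCE_CONSTANT"])
        a0 = _floats(sec["ANGLE_EQUIL_VALUE"])  # radians in file
        for flag in ("ANGLES_INC_HYDROGEN", "ANGLES_WITHOUT_HYDROGEN"):
            raw = _ints(sec.get(flag, []))
            for k in range(0, len(raw), 4):
                i, j, l, t = raw[k] // 3, raw[k + 1] // 3, raw[k + 2] // 3, raw[k + 3] - 1
                angles.append((int(i), int(j), int(l), float(ak[t]), float(a0[t])))
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = []
    if "DIHEDRAL_FORCE_CONSTANT" in sec:
        dk = _floats(sec["DIHEDRAL_FORCE_CONSTANT"])
        dn = _floats(sec["DIHEDRAL_PERIODICITY"])
        dp = _floats(sec["DIHEDRAL_PHASE"])
        for flag in ("DIHEDRALS_INC_HYDROGEN", "DIHEDRALS_WITHOUT_HYDROGEN"):
            raw = _ints(sec.get(flag, []))
            for k in range(0, len(raw), 5):
                i, j = raw[k] // 3, raw[k + 1] // 3
                kk, ll, t = abs(raw[k + 2]) // 3, abs(raw[k + 3]) // 3, raw[k + 4] - 1
                dihedrals.append((int(i), int(j), int(kk), int(ll),
                                  float(dk[t]), int(round(dn[t])), float(dp[t])))

    # chain segmentation: waters/ions by residue name; protein split into
    # bonded runs (prmtop carries no chain ids)
    chain_of_res: dict[int, str] = {}
    bonded_res = {(min(res_of_atom[i], res_of_atom[j]), max(res_of_atom[i], res_of_atom[j]))
                  for i, j, *_ in bonds if res_of_atom[i] != res_of_atom[j]}
    chain_letter = 0
    for r in range(nres):
        label = res_labels[r].strip().upper()
        if label in water_resnames or label in ION_RESNAMES:
            continue
        if r - 1 not in chain_of_res or (r - 1, r) not in bonded_res \
                or res_labels[r - 1].strip().upper() in water_resnames | ION_RESNAMES:
            chain_letter += 1
        chain_of_res[r] = chr(ord("A") + min(chain_letter - 1, 25))
    for a in atoms:
        a.chain_id = chain_of_res.get(a.residue_index, "W")

    return MolecularTopology(
        atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals,
        molecules=_segment_molecules(atoms, water_resnames),
        water_resnames=water_resnames,
    )


def _fmt_block(fh, flag: str, fmt: str, tokens: list[str], per_line: int) -> None:
    fh.write(f"%FLAG {flag}\n%FORMAT({fmt})\n")
    if not tokens:
        fh.write("\n")
        return
    for k in range(0, len(tokens), per_line):
        fh.write("".join(tokens[k:k + per_line]) + "\n")


def write_prmtop(topology: MolecularTopology, path: str | Path,
                 title: str = "generated by mnmgbsa") -> None:
    """Write a minimal Amber parameter-topology for ``topology``.

    One LJ type per distinct (rmin/2, epsilon) pair and one bonded type per
    distinct parameter tuple; all bonded terms are emitted in the
    *_WITHOUT_HYDROGEN sections.
    """
    path = Path(path)
    atoms = topology.atoms
    natom = len(atoms)
    lj_types: list[tuple[float, float]] = []
    tidx = []
    for a in atoms:
        key = (round(a.lj_rmin_half, 8), round(a.lj_epsilon, 8))
        if key not in lj_types:
            lj_types.append(key)
        tidx.append(lj_types.index(key) + 1)
    ntypes = len(lj_types)
    nbindex = np.zeros((ntypes, ntypes), dtype=int)
    acoef, bcoef = [], []
    k = 0
    for i in range(ntypes):
        for j in range(i + 1):
            rmin = lj_types[i][0] + lj_types[j][0]
            eps = np.sqrt(lj_types[i][1] * lj_types[j][1])
            acoef.append(eps * rmin ** 12)
            bcoef.append(2.0 * eps * rmin ** 6)
            k += 1
            nbindex[i, j] = nbindex[j, i] = k

    def unique_types(terms, params_slice):
        types, index = [], []
        for t in terms:
            key = tuple(round(v, 10) for v in params_slice(t))
            if key not in types:
                types.append(key)
            index.append(types.index(key) + 1)
        return types, index

    bond_types, bond_tidx = unique_types(topology.bonds, lambda t: t[2:4])
    angle_types, angle_tidx = unique_types(topology.angles, lambda t: t[3:5])
    dih_types, dih_tidx = unique_types(topology.dihedrals, lambda t: t[4:7])

    nres = len(topology.residues)
    ptr = [0] * 31
    ptr[0], ptr[1] = natom, ntypes
    ptr[3] = ptr[12] = len(topology.bonds)
    ptr[5] = ptr[13] = len(topology.angles)
    ptr[7] = ptr[14] = len(topology.dihedrals)
    ptr[11] = nres
    ptr[15], ptr[16], ptr[17] = len(bond_types), len(angle_types), len(dih_types)
    ptr[18] = ntypes

    def f_e(vals):
        return [f"{v:16.8E}" for v in vals]

    def f_i(vals):
        return [f"{int(v):8d}" for v in vals]

    def f_a(vals):
        return [f"{v:<4.4s}" for v in vals]

    with open(path, "w") as fh:
        fh.write("%VERSION  VERSION_STAMP = V0001.000\n")
        _fmt_block(fh, "TITLE", "20a4", f_a([title[:80]]), 20)
        _fmt_block(fh, "POINTERS", "10I8", f_i(ptr), 10)
        _fmt_block(fh, "ATOM_NAME", "20a4", f_a([a.name for a in atoms]), 20)
        _fmt_block(fh, "CHARGE", "5E16.8",
                   f_e([a.charge * AMBER_CHARGE_SCALE for a in atoms]), 5)
        _fmt_block(fh, "ATOMIC_NUMBER", "10I8",
                   f_i([_ATOMIC_NUMBERS.get(a.element.upper(), 0) for a in atoms]), 10)
        _fmt_block(fh, "MASS", "5E16.8", f_e([a.mass for a in atoms]), 5)
        _fmt_block(fh, "ATOM_TYPE_INDEX", "10I8", f_i(tidx), 10)
        _fmt_block(fh, "NONBONDED_PARM_INDEX", "10I8",
                   f_i(list(nbindex.flatten())), 10)
        _fmt_block(fh, "RESIDUE_LABEL", "20a4",
                   f_a([r.name for r in topology.residues]), 20)
        _fmt_block(fh, "RESIDUE_POINTER", "10I8",
                   f_i([r.first_atom + 1 for r in topology.residues]), 10)
        _fmt_block(fh, "BOND_FORCE_CONSTANT", "5E16.8", f_e([t[0] for t in bond_types]), 5)
        _fmt_block(fh, "BOND_EQUIL_VALUE", "5E16.8", f_e([t[1] for t in bond_types]), 5)
        _fmt_block(fh, "ANGLE_FORCE_CONSTANT", "5E16.8", f_e([t[0] for t in angle_types]), 5)
        _fmt_block(fh, "ANGLE_EQUIL_VALUE", "5E16.8", f_e([t[1] for t in angle_types]), 5)
        _fmt_block(fh, "DIHEDRAL_FORCE_CONSTANT", "5E16.8", f_e([t[0] for t in dih_types]), 5)
        _fmt_block(fh, "DIHEDRAL_PERIODICITY", "5E16.8", f_e([t[1] for t in dih_types]), 5)
        _fmt_block(fh, "DIHEDRAL_PHASE", "5E16.8", f_e([t[2] for t in dih_types]), 5)
        _fmt_block(fh, "LENNARD_JONES_ACOEF", "5E16.8", f_e(acoef), 5)
        _fmt_block(fh, "LENNARD_JONES_BCOEF", "5E16.8", f_e(bcoef), 5)
        _fmt_block(fh, "BONDS_INC_HYDROGEN", "10I8", [], 10)
        _fmt_block(fh, "BONDS_WITHOUT_HYDROGEN", "10I8",
                   f_i([v for t, ti in zip(topology.bonds, bond_tidx)
                        for v in (t[0] * 3, t[1] * 3, ti)]), 10)
        _fmt_block(fh, "ANGLES_INC_HYDROGEN", "10I8", [], 10)
        _fmt_block(fh, "ANGLES_WITHOUT_HYDROGEN", "10I8",
                   f_i([v for t, ti in zip(topology.angles, angle_tidx)
                        for v in (t[0] * 3, t[1] * 3, t[2] * 3, ti)]), 10)
        _fmt_block(fh, "DIHEDRALS_INC_HYDROGEN", "10I8", [], 10)
        _fmt_block(fh, "DIHEDRALS_WITHOUT_HYDROGEN", "10I8",
                   f_i([v for t, ti in zip(topology.dihedrals, dih_tidx)
                        for v in (t[0] * 3, t[1] * 3, t[2] * 3, t[3] * 3, ti)]), 10)
        _fmt_block(fh, "RADII", "5E16.8", f_e([a.gb_radius for a in atoms]), 5)
        _fmt_block(fh, "SCREEN", "5E16.8", f_e([a.gb_screen for a in atoms]), 5)


# ---------------------------------------------------------------------------
# Amber ASCII coordinate trajectory (mdcrd, 10F8.3)
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, topology: MolecularTopology,
                    fmt: str = "amber-ascii", *, has_box: bool = False,
                    time_start_ps: float = 0.0, time_stride_ps: float = 10.0,
                    ) -> Trajectory:
    """Read a coordinate trajectory bound to ``topology``.

    ``fmt`` is ``amber-ascii`` (10F8.3, optional per-frame box line) or
    ``multi-model-pdb``.  Formats carrying no time stamps get times
    ``time_start_ps + k * time_stride_ps``.
    """
    path = Path(path)
    if fmt == "multi-model-pdb":
        _, frames = read_pdb(path, water_resnames=topology.water_resnames)
        for f in frames:
            if f.n_atoms != topology.n_atoms:
                raise FileFormatError(
                    f"{path.name}: frame has {f.n_atoms} atoms, topology has {topology.n_atoms}"
                )
        for k, f in enumerate(frames):
            f.time_ps = time_start_ps + k * time_stride_ps
        return Trajectory(topology, frames)
    if fmt != "amber-ascii":
        raise ValueError(f"unknown trajectory format {fmt!r}")

    n = topology.n_atoms
    per_frame = 3 * n
    values: list[float] = []
    with open(path) as fh:
        fh.readline()  # title
        for line in fh:
            for k in range(0, len(line.rstrip("\n")), 8):
                tok = line[k:k + 8].strip()
                if tok:
                    values.append(float(tok))
    block = per_frame + (3 if has_box else 0)
    if len(values) % block:
        nfull = len(values) // block
        raise FileFormatError(
            f"{path.name}: truncated final frame — expected {per_frame} coordinates "
            f"per frame, found {len(values) - nfull * block} after frame {nfull}"
        )
    frames = []
    for k in range(len(values) // block):
        chunk = values[k * block:(k + 1) * block]
        xyz = np.array(chunk[:per_frame]).reshape(n, 3)
        box = np.array(chunk[per_frame:]) if has_box else None
        frames.append(Frame(xyz, time_ps=time_start_ps + k * time_stride_ps,
                            box=box))
    return Trajectory(topology, frames)


def write_trajectory(trajectory: Trajectory, path: str | Path,
                     title: str = "mnmgbsa trajectory") -> None:
    """Write an Amber ASCII (10F8.3) coordinate trajectory."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(title[:80] + "\n")
        for fr in trajectory.frames:
            flat = fr.coordinates.reshape(-1)
            if np.max(np.abs(flat)) >= 10000:
                raise FileFormatError("coordinate overflow of the 8.3 fixed-width field")
            for k in range(0, len(flat), 10):
                fh.write("".join(f"{v:8.3f}" for v in flat[k:k + 10]) + "\n")
            if fr.box is not None:
                fh.write("".join(f"{v:8.3f}" for v in fr.box[:3]) + "\n")
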