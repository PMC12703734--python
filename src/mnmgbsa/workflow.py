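"""End-to-end orchestration of the post-MD analysis schemes.

Three schemes are supported: ``scheme0`` analyses a complex trajectory
started from the crystal structure; ``mnm1``/``mnm2`` first cluster
unbound-chain ensembles (over the first 12 ns or the last 20 ns of a
100 ns chain run, respectively), rebuild a Mix-and-Match complex from the
most populated conformers, and then analyse the complex trajectory the
user simulated from that reconstruction.  The MD step between assembly
and analysis is an explicit external hand-off: if a scheme needs a
complex trajectory that was not supplied, the run stops with an error
naming the missing input — it is never silently skipped.

Every stage writes its artifact plus a manifest line with parameters and
a content checksum, so reruns are bit-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ensemble, gbsa, interface, mnm
from .gbneck2 import GbParameters
from .model import Frame, MolecularTopology, Trajectory
from .structure_io import write_pdb

#: protocol-default stage windows (ps) per scheme
SCHEME_DEFAULTS = {
    "scheme0": {"clustering_window_ps": None, "analysis_window_ps": (3000.0, 4000.0)},
    "mnm1": {"clustering_window_ps": (0.0, 12000.0),
             "analysis_window_ps": (40000.0, 50000.0)},
    "mnm2": {"clustering_window_ps": (80000.0, 100000.0),
             "analysis_window_ps": (40000.0, 50000.0)},
}


@dataclass
class RunConfig:
    scheme: str = "mnm1"
    clustering_window_ps: tuple[float, float] | None = None
    analysis_window_ps: tuple[float, float] | None = None
    n_frames: int = 100
    rmsd_cutoff: float = 1.0          # Å, GROMOS Cα clustering
    n_waters: int = 30                # 0 disables water retention
    interface_threshold: float = 0.50  # Å²
    salt_molar: float = 0.15
    sasa_points: int = 960
    ligand_chain: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_DEFAULTS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        d = SCHEME_DEFAULTS[self.scheme]
        if self.clustering_window_ps is None:
            self.clustering_window_ps = d["clustering_window_ps"]
        if self.analysis_window_ps is None:
            self.analysis_window_ps = d["analysis_window_ps"]
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for w in (self.clustering_window_ps, self.analysis_window_ps):
            if w is not None and not w[0] < w[1]:
                raise ValueError(f"window {w} is not well-ordered")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("clustering_window_ps", "analysis_window_ps"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def gb_parameters(self) -> GbParameters:
        return GbParameters(salt_molar=self.salt_molar)


@dataclass
class SchemeInputs:
    """In-memory inputs of one complex's run.

    ``chain_a``/``chain_b`` are unbound-chain ensembles (MnM schemes only);
    ``complex_trajectory`` is the trajectory of the (crystal- or
    MnM-started) complex simulation.
    """

    crystal_topology: MolecularTopology
    crystal_frame: Frame
    complex_trajectory: Trajectory | None = None
    chain_a: Trajectory | None = None
    chain_b: Trajectory | None = None


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_scheme(config: RunConfig, inputs: SchemeInputs, outdir: str | Path) -> dict:
    """Execute one scheme end-to-end; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: list(v) if isinstance(v, tuple) else v
                                 for k, v in asdict(config).items()},
                      "stages": {}}

    def record(stage: str, path: Path, **params) -> None:
        manifest["stages"][stage] = {"file": path.name, "sha256": _checksum(path),
                                     **params}

    mnm_complex = None
    if config.scheme in ("mnm1", "mnm2"):
        reps = {}
        for label, chain_traj in (("chainA", inputs.chain_a), ("chainB", inputs.chain_b)):
            if chain_traj is None:
                raise FileNotFoundError(
                    f"scheme {config.scheme} needs the unbound {label} ensemble "
                    f"trajectory; supply it as SchemeInputs.{label.replace('chain', 'chain_').lower()}"
                )
            lo, hi = config.clustering_window_ps
            t = chain_traj.times_ps
            keep = [k for k in range(len(chain_traj)) if lo <= t[k] < hi]
            sub = Trajectory(chain_traj.topology,
                             [chain_traj[k] for k in keep])
            mat = ensemble.rmsd_matrix(sub, "calpha")
            clusters = ensemble.gromos_cluster(mat, config.rmsd_cutoff)
            rep_local = ensemble.select_representative(clusters)
            reps[label] = (chain_traj.topology, sub[rep_local],
                           keep[rep_local])
            p = outdir / f"clusters_{label}.tsv"
            p.write_text(clusters.to_table())
            record(f"cluster_{label}", p, cutoff=config.rmsd_cutoff,
                   representative_frame=keep[rep_local],
                   representative_time_ps=sub[rep_local].time_ps)
        mnm_complex = mnm.build_mnm_complex(
            inputs.crystal_topology, inputs.crystal_frame,
            (reps["chainA"][0], reps["chainA"][1]),
            (reps["chainB"][0], reps["chainB"][1]),
            provenance={"scheme": config.scheme,
                        "chainA_time_ps": reps["chainA"][1].time_ps,
                        "chainB_time_ps": reps["chainB"][1].time_ps},
        )
        p = outdir / "mnm_complex.pdb"
        write_pdb(inputs.crystal_topology, mnm_complex.frame, p)
        clash = mnm.clash_report(mnm_complex.frame, inputs.crystal_topology)
        pc = outdir / "clash_report.tsv"
        pc.write_text(clash.to_table())
        record("build_mnm", p, placement_rmsd=mnm_complex.placement_rmsd)
        record("clash_report", pc, min_distance=clash.min_distance)

    traj = inputs.complex_trajectory
    if traj is None:
        raise FileNotFoundError(
            "complex trajectory missing: run MD on "
            + ("the reconstructed complex (mnm_complex.pdb)" if mnm_complex is not None
               else "the crystal complex")
            + " externally and supply it as SchemeInputs.complex_trajectory"
        )
    frames = ensemble.select_evenly_spaced_frames(
        traj, config.analysis_window_ps, config.n_frames)
    p = outdir / "frames.txt"
    p.write_text("\n".join(map(str, frames.tolist())) + "\n")
    record("frames", p, window_ps=list(config.analysis_window_ps),
           n=config.n_frames)

    spec = interface.find_interface_residues(
        traj[int(frames[0])], traj.topology,
        threshold=config.interface_threshold, n_points=config.sasa_points)
    p = outdir / "interface.tsv"
    p.write_text(spec.to_table(traj.topology))
    record("interface", p, threshold=config.interface_threshold,
           n_residues=len(spec.residues))

    params = config.gb_parameters()
    solvation = None
    if config.n_waters > 0:
        solvation = interface.solvation_selection(
            traj, spec, n=config.n_waters, frames=frames.tolist())
        p = outdir / "waters.tsv"
        p.write_text("\n".join(
            ",".join(map(str, ids.tolist())) for ids in solvation.water_ids) + "\n")
        record("select_waters", p, n=config.n_waters)

    part = interface.partition_system(traj.topology, config.ligand_chain)
    series = gbsa.endpoint_binding_free_energy(
        traj, part, frames, params, solvation=solvation,
        sasa_points=config.sasa_points)
    p = outdir / "gbsa.tsv"
    p.write_text(series.summary_table())
    record("gbsa", p, mean=series.mean, std=series.std,
           n_waters=config.n_waters)

    decomp = gbsa.pairwise_decomposition(traj, part, frames, params,
                                         sasa_points=config.sasa_points)
    p = outdir / "decomposition.tsv"
    p.write_text(decomp.to_table(traj.topology))
    record("decomposition", p, n_pairs=len(decomp.pairs))

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
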