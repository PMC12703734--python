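# Methods

## Scope and model

The package implements the post-MD half of a Mix-and-Match MM-GBSA
workflow for protein–protein complexes.  It deliberately does **not** run
molecular dynamics, add hydrogens, assign protonation states, or relax
reconstructed complexes: the MnM assembly stage writes a starting
structure and a clash report, and the user's MD engine is an explicit
hand-off between assembly and analysis.  The workflow driver refuses to
continue without the post-assembly complex trajectory rather than
silently skipping the simulation step.

The binding free energy is a single-trajectory end-point estimate: for
each selected frame of the complex trajectory, the complex, receptor and
ligand energies are all evaluated on the same coordinates, so every
internal bonded term (and, with retained waters placed in the receptor,
every water-internal and water–receptor gas-phase pair) cancels exactly
in the difference.  The per-frame total is

    G = E_bond + E_angle + E_dihedral + E_vdW + E_elec + G_polar + G_nonpolar

and ΔG_bind = G_complex − G_receptor − G_ligand, reported as mean ± sample
standard deviation over frames.  The solute entropy (−TΔS) is not
computed; the results object carries an explicit `entropy_term = None` so
the omission is visible rather than a silent zero.

## Energy terms and their parameters

**Gas phase.**  Amber conventions throughout: E = k(r−r0)² bonds,
k(θ−θ0)² angles, Σ(V/divider)(1+cos(nφ−γ)) dihedrals; 12-6 LJ from
per-atom rmin/2 and ε with Lorentz–Berthelot-style combination; Coulomb
constant 332.0636 kcal·Å·mol⁻¹·e⁻² with ε_in = 1.  No distance cutoff —
cutoffs belong to trajectory generation, not to end-point re-evaluation.
1-2/1-3 pairs are excluded and 1-4 pairs divided by 1.2 (electrostatics)
and 2.0 (vdW), the ff14SB defaults.  Exclusion and 1-4 sets are derived
from bond connectivity (1, 2 or 3 bonds apart); for acyclic topologies
this is identical to the dihedral-derived list in the Amber file format,
and the file reader round-trips against it in the tests.

**Polar solvation (GB-Neck2).**  Effective Born radii come from the
pairwise HCT descreening integral over offset-reduced intrinsic radii
(ρ̃ = ρ − 0.195141 Å, mbondi3 radii, per-element screening factors), a
neck correction for the solvent-inaccessible region between nearby atom
pairs (scaled by 0.826836), and the per-element tanh rescaling
1/R = 1/ρ̃ − tanh(αΨ − βΨ² + γΨ³)/ρ with Ψ = I·ρ̃.  The per-element α/β/γ
and screening factors ship as a versioned data table
(`mnmgbsa/data/gbneck2_params.json`).  The pair energy is

    e_ij = −½·332.0636·q_i q_j (1/ε_in − exp(−κ f_ij)/ε_out) / f_ij,
    f_ij = sqrt(r_ij² + R_i R_j exp(−r_ij²/(4 R_i R_j))),  f_ii = R_i,

with off-diagonal pairs counted twice.  Defaults: ε_out = 78.5,
0.15 M 1:1 salt at 298.15 K.  κ is computed from the Debye–Hückel
expression (Bjerrum length from the same Coulomb constant) and rescaled
by the conventional 0.73 inside the GB exponential; both the physical κ
and the rescaled value are exposed on `GbParameters`.

*Neck lookup.*  The neck function needs, per radius pair, the separation
d0 at which the neck integral peaks and its height m0.  No installed
package provides the published lookup table, so the package computes
d0/m0 at run time by direct numerical integration of the defining
geometry — the region outside both van der Waals spheres that a 1.4 Å
probe cannot reach, integrated as (1/4π)∫|x−x_i|⁻⁴ dV on a cylindrical
grid — and caches the result per rounded radius pair.  The analytic form
m0/(1+(r−d0)²+0.3(r−d0)⁶) is used between atoms, zeroed once the probe
fits through (r > ρ_i+ρ_j+2·1.4 Å).  Tests pin the HCT term to an
independent quadrature oracle (≤ 5·10⁻⁷ absolute) and verify the neck fit
reproduces the direct integral at its peak; absolute agreement with any
external implementation's table is not asserted anywhere.  Effective
radii are clamped to 30 Å when the tanh argument would drive the inverse
radius nonpositive (deeply buried atoms in pathological geometries).

**Nonpolar solvation.**  γ·SASA + b with γ = 0.0072 kcal·mol⁻¹·Å⁻² and
b = 0.  SASA is Shrake–Rupley on a deterministic golden-spiral point set,
960 points by default, heavy atoms only, with per-element radii
(C 1.7, N 1.55, O 1.52, S 1.8, H 1.2, P 1.8 Å) — an element-based set like
the common SASA tools rather than LJ-derived radii, so absolute areas are
implementation-dependent and are treated as such.  Closed-form checks
(isolated sphere ≤ 0.5 %, two-sphere overlap ≤ 1 % at 960 points) hold;
on many-atom systems the point-counting noise at 960 points is ~0.5 % of
the total, falling below 0.2 % per doubling from 1920 points on.

## Pipeline conventions

* **Clustering** is the iterative Daura neighbor-count algorithm on a
  pairwise superposition-minimized Cα RMSD matrix (1 Å default cutoff).
  Ties on neighbor count break to the lowest frame index; cluster lists
  are size-sorted with formation order preserved on equal sizes, making
  representative selection fully deterministic.  The original algorithm
  statement leaves the tie unspecified.
* **Representative frame** = center of the most populated cluster.
* **RMSF** is computed about the time-mean structure after Cα alignment
  to frame 0 (frame-0 reference available), mass-unweighted, averaged over
  side-chain heavy atoms; glycine-like residues fall back to Cα and are
  flagged.
* **Frame selection** takes n indices at uniform stride across a time
  window, half-open on time [t0, t1), endpoints of the in-window index
  range always included.
* **Interface** residues are those whose per-residue SASA drops by more
  than 0.50 Å² between the isolated-chain and complex evaluations of the
  same coordinates.  The scan runs once on the starting complex frame
  (matching the one-shot interface definition used to drive water
  selection); per-frame recomputation is a flag away.
* **Water selection** ranks waters by oxygen distance to the interface
  center of mass (oxygen ≈ 3-site water COM; a true-COM mode exists), ties
  to the lower molecule index, independently per frame — membership may
  legitimately change frame to frame.  Retained waters join the
  *receptor*: placing them in the ligand is known to inflate the
  frame-to-frame spread without improving ranking.
* **MnM assembly** fits each representative chain's backbone (N, CA, C, O
  of positionally matched residues — matching is by residue position
  after the sequential renumbering convention, not by alignment) onto the
  crystal chain with a Kabsch fit, preserving crystal atom order so one
  topology serves all downstream energetics.  No minimization follows;
  the clash report (KD-tree, interchain heavy-atom pairs under a
  threshold) documents what the downstream MD must relax.
* **Decomposition** attributes receptor↔ligand residue-pair terms: direct
  atom-pair sums for vdW/electrostatics, the cross-partition pair terms of
  the GB double sum at complex radii for the polar part; self terms stay
  with their own residue.  The pair total is conserved against the
  cross-partition interaction energy to 10⁻⁶ kcal/mol by construction and
  by test.
* **Affinity statistics**: ΔG = RT ln K at 298.15 K by default (the
  conversion temperature is configurable; across the benchmark's range the
  choice of 298.15 vs 300 K moves ΔG by < 0.1 kcal/mol); r² is the square
  of Pearson's r, equal to the unadjusted R² of the univariate fit.  ΔΔG
  reports default to all unordered pairs, with a reference-complex mode
  because the pairing convention is genuinely open.

## The synthetic study system

`mnmgbsa.fixtures` generates everything the tests and the acceptance
script consume:

* a two-chain pseudo-peptide dimer (5 + 4 residues, 3–4 atoms each, full
  charges/LJ/bonded/GB parameters, net charge zero, one designed contact
  at 4 Å) — small enough that all-pairs brute-force oracles are exact and
  fast;
* weighted conformer ensembles (default 0.7/0.3 populations, σ = 0.2 Å
  isotropic jitter, 200 frames) with ground-truth labels emitted alongside
  the data, so recovery tests never re-derive truth from the code under
  test;
* hydrated frames with 3-site waters (O–H 0.9572 Å, H–O–H 104.52°) at
  prescribed distances from a stated point, clash-free by construction,
  with the ground-truth distance ranking returned.

What passing these tests shows: the algorithms are implemented correctly
(closed-form limits, oracle equivalence, conservation and cancellation
identities, deterministic recovery of designed populations).  What it does
not show: predictive accuracy on real proteins — the fixtures have no
realistic geometry, no hydrogens on the solute, no force-field realism,
and interfaces of a dozen atoms.  The packaged experimental benchmark
table enables the correlation machinery, but the matching per-complex
predictions require ~50 ns explicit-solvent MD per complex and are out of
desk-scale reach.

## Numerical choices and degenerate inputs

* Charges live in elementary-charge units internally; the 18.2223 Amber
  factor is applied only at parameter-topology I/O.
* 0-based atom/residue indexing internally, 1-based only inside files.
* Kabsch fits suppress reflections (determinant forced to +1) and refuse
  < 3 points; the all-pairs RMSD matrix uses a batched 3×3 SVD.
* Zero-variance series make correlations undefined and raise; fewer than
  3 paired complexes raise.
* Fewer waters than requested: all are retained with a warning; no
  waters at all is an error.
* PDB coordinates that overflow the fixed-width field raise rather than
  truncate; malformed records report their line number.
* Workflow stage outputs are pure functions of (inputs, config); the
  manifest records parameters and content checksums and contains no
  timestamps, so reruns are bit-identical.

## Known limitations

* No Poisson–Boltzmann route, no normal-mode entropy, no alchemical
  methods — out of scope by design.
* The GB neck lookup is derived from the defining geometry rather than
  the published table; small numerical differences from other GB-Neck2
  implementations are expected, and no test asserts cross-implementation
  equality.
* The prmtop reader covers the sections the energy model needs;
  exotic sections (CMAP, polarizabilities, chamber topologies) are
  ignored with a debug log line.
* Chain segmentation of a prmtop (which has no chain ids) infers chains
  from bonded runs of protein residues; systems with more than two
  protein segments are not supported.
* SASA radii are element-based; absolute areas differ between SASA
  implementations and only differences (ΔSASA) are used quantitatively.
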