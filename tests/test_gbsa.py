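"""MM-GBSA energetics: bonded/nonbonded terms, GB-Neck2 radii and polar
energy, surface term, end-point binding free energy and decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mnmgbsa.gbneck2 import (GbParameters, hct_integral, neck_d0_m0,
                             neck_integral, neck_value)
from mnmgbsa.gbsa import (SA_GAMMA, atom_pair_distance_series, bonded_energy,
                          effective_born_radii, endpoint_binding_free_energy,
                          gb_polar_energy, nonbonded_gas_energy,
                          pairwise_decomposition, sa_nonpolar_energy)
from mnmgbsa.interface import partition_system, select_closest_waters
from mnmgbsa.model import AtomRecord, Frame, MolecularTopology, Trajectory

from oracles import (born_self_energy, brute_nonbonded, quadrature_hct)


def ion_topology(charges, radii, screens=None):
    screens = screens or [0.8] * len(charges)
    atoms = [AtomRecord(k + 1, "I", "Na", k, "ION", "A", charge=q, mass=23.0,
                        gb_radius=r, gb_screen=s)
             for k, (q, r, s) in enumerate(zip(charges, radii, screens))]
    return MolecularTopology(atoms=atoms, molecules=[("ion", 0, len(atoms))])


class TestBonded:
    def test_single_stretched_bond(self):
        atoms = [AtomRecord(1, "A", "C", 0, "X", "A"),
                 AtomRecord(2, "B", "C", 0, "X", "A")]
        top = MolecularTopology(atoms=atoms, bonds=[(0, 1, 100.0, 1.0)],
                                molecules=[("chainA", 0, 2)])
        fr = Frame(np.array([[0.0, 0, 0], [1.1, 0, 0]]))
        eb, ea, ed = bonded_energy(top, fr, np.arange(2))
        assert eb == pytest.approx(1.0, abs=1e-12)
        assert ea == ed == 0.0

    def test_equilibrium_geometry_is_zero(self, toy_dimer):
        top, frame, _ = toy_dimer
        eb, ea, ed = bonded_energy(top, frame, np.arange(top.n_atoms))
        # the fixture's bonds and angles are built at their equilibrium values
        assert eb == pytest.approx(0.0, abs=1e-18)
        assert ea == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_summed_terms(self, toy_dimer, rng):
        top, frame, _ = toy_dimer
        x = frame.coordinates + rng.normal(0, 0.1, frame.coordinates.shape)
        eb, ea, ed = bonded_energy(top, Frame(x), np.arange(top.n_atoms))
        eb_ref = sum(k * (np.linalg.norm(x[i] - x[j]) - r0) ** 2
                     for i, j, k, r0 in top.bonds)
        assert eb == pytest.approx(eb_ref, rel=1e-12)
        ea_ref = 0.0
        for i, j, l, k, t0 in top.angles:
            v1, v2 = x[i] - x[j], x[l] - x[j]
            th = np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ea_ref += k * (th - t0) ** 2
        assert ea == pytest.approx(ea_ref, rel=1e-12)
        assert ed > 0.0   # periodic terms present


class TestNonbonded:
    def test_coulomb_reference_distance(self):
        top = ion_topology([1.0, 1.0], [1.5, 1.5])
        fr = Frame(np.array([[0.0, 0, 0], [3.320636, 0, 0]]))
        _, e_elec = nonbonded_gas_energy(top, fr, np.arange(2))
        assert e_elec == pytest.approx(100.0, abs=1e-6)

    def test_lj_minimum_depth(self):
        atoms = [AtomRecord(1, "A", "C", 0, "X", "A", lj_rmin_half=1.9,
                            lj_epsilon=0.1, gb_radius=1.7, gb_screen=0.8),
                 AtomRecord(2, "B", "C", 1, "X", "A", lj_rmin_half=1.7,
                            lj_epsilon=0.2, gb_radius=1.7, gb_screen=0.8)]
        top = MolecularTopology(atoms=atoms, molecules=[("chainA", 0, 2)])
        fr = Frame(np.array([[0.0, 0, 0], [3.6, 0, 0]]))
        e_vdw, _ = nonbonded_gas_energy(top, fr, np.arange(2))
        assert e_vdw == pytest.approx(-np.sqrt(0.1 * 0.2), rel=1e-12)

    def test_matches_double_loop_with_exclusions(self, toy_dimer, rng):
        top, frame, _ = toy_dimer
        idx = np.arange(top.n_atoms)
        e_vdw, e_elec = nonbonded_gas_energy(top, frame, idx)
        excl, s14 = top.exclusions()
        ref_vdw, ref_elec = brute_nonbonded(
            frame.coordinates, top.array("charge"), top.array("lj_rmin_half"),
            top.array("lj_epsilon"), excl, s14)
        assert e_vdw == pytest.approx(ref_vdw, rel=1e-10)
        assert e_elec == pytest.approx(ref_elec, rel=1e-10)

    def test_subsystem_restriction(self, toy_dimer):
        top, frame, _ = toy_dimer
        sub = top.molecule_atoms("chainB")
        e_vdw, e_elec = nonbonded_gas_energy(top, frame, sub)
        excl, s14 = top.exclusions()
        keep = set(sub.tolist())
        excl = {p for p in excl if set(p) <= keep}
        s14 = {p for p in s14 if set(p) <= keep}
        remap = {g: k for k, g in enumerate(sub)}
        ref_vdw, ref_elec = brute_nonbonded(
            frame.coordinates[sub], top.array("charge")[sub],
            top.array("lj_rmin_half")[sub], top.array("lj_epsilon")[sub],
            {(remap[a], remap[b]) for a, b in excl},
            {(remap[a], remap[b]) for a, b in s14})
        assert e_vdw == pytest.approx(ref_vdw, rel=1e-10)
        assert e_elec == pytest.approx(ref_elec, rel=1e-10)


class TestBornRadii:
    def test_isolated_atom_equals_reduced_radius(self):
        p = GbParameters()
        top = ion_topology([1.0], [2.0])
        r = effective_born_radii(top, Frame(np.zeros((1, 3))), p)
        assert r[0] == pytest.approx(2.0 - p.offset, abs=1e-12)

    def test_distant_pair_approaches_isolated_values(self):
        p = GbParameters()
        top = ion_topology([1.0, -1.0], [2.0, 1.5])
        fr = Frame(np.array([[0.0, 0, 0], [500.0, 0, 0]]))
        r = effective_born_radii(top, fr, p)
        np.testing.assert_allclose(r, [2.0 - p.offset, 1.5 - p.offset],
                                   atol=1e-6)

    def test_matches_quadrature_descreening(self):
        """Effective radii agree with direct numerical evaluation of the
        descreening integral (separations outside the neck regime)."""
        p = GbParameters()
        radii = [1.6, 1.7, 1.5, 1.8, 1.55]
        screens = [0.8, 1.0, 0.9, 0.7, 1.1]
        top = ion_topology([0.1] * 5, radii, screens)
        coords = np.array([[0.0, 0, 0], [7.0, 0, 0], [0, 7.5, 0],
                           [0, 0, 8.0], [7.0, 7.0, 7.0]])
        fr = Frame(coords)
        ours = effective_born_radii(top, fr, p)
        for i in range(5):
            rho_t_i = radii[i] - p.offset
            total = 0.0
            for j in range(5):
                if j == i:
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                sj = screens[j] * (radii[j] - p.offset)
                total += quadrature_hct(d, rho_t_i, sj)
                total += p.neck_scale * neck_value(d, radii[i], radii[j])
            psi = total * rho_t_i
            a, b, g = p.abg("Na")
            inv = 1.0 / rho_t_i - np.tanh(a * psi - b * psi ** 2 + g * psi ** 3) / radii[i]
            assert ours[i] == pytest.approx(1.0 / inv, abs=1e-3)

    def test_neck_fit_matches_direct_integral_at_peak(self):
        d0, m0 = neck_d0_m0(1.7, 1.55)
        assert neck_value(d0, 1.7, 1.55) == pytest.approx(m0, rel=1e-12)
        assert neck_integral(d0, 1.7, 1.55) == pytest.approx(m0, rel=1e-6)
        # decays away from the peak and vanishes once the probe fits through
        assert neck_value(d0 + 1.0, 1.7, 1.55) < m0
        assert neck_value(1.7 + 1.55 + 2 * 1.4 + 0.1, 1.7, 1.55) == 0.0

    def test_neck_descreening_grows_radii(self):
        p = GbParameters()
        top = ion_topology([0.0, 0.0], [1.7, 1.7])
        fr = Frame(np.array([[0.0, 0, 0], [3.8, 0, 0]]))
        with_neck = effective_born_radii(top, fr, p)
        p0 = GbParameters(neck_scale=1e-12)
        without = effective_born_radii(top, fr, p0)
        assert np.all(with_neck > without)

    def test_hct_closed_form_vs_quadrature(self):
        for d, ri, sj in [(3.0, 1.5, 1.2), (2.0, 1.3, 1.5), (1.0, 0.5, 1.8),
                          (5.0, 1.5, 1.3), (0.8, 0.3, 2.0)]:
            assert hct_integral(d, ri, sj) == pytest.approx(
                quadrature_hct(d, ri, sj), abs=5e-7)

    def test_non_positive_radius_rejected(self):
        top = ion_topology([1.0], [0.0])
        with pytest.raises(ValueError, match="Born radius"):
            effective_born_radii(top, Frame(np.zeros((1, 3))), GbParameters())


class TestGbPolar:
    def test_born_closed_form_single_ion(self):
        p = GbParameters(salt_molar=0.0)
        top = ion_topology([1.0], [2.0 + p.offset])
        fr = Frame(np.zeros((1, 3)))
        radii = effective_born_radii(top, fr, p)
        g = gb_polar_energy(top, fr, radii, p)
        assert g == pytest.approx(born_self_energy(1.0, 2.0), abs=1e-9)
        assert g == pytest.approx(-0.5 * 332.0636 * (1 - 1 / 78.5) / 2.0, abs=1e-6)

    def test_zero_charges_give_zero(self, toy_dimer):
        top, frame, _ = toy_dimer
        p = GbParameters()
        zeroed = ion_topology([0.0, 0.0], [1.7, 1.6])
        fr = Frame(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        radii = effective_born_radii(zeroed, fr, p)
        assert gb_polar_energy(zeroed, fr, radii, p) == 0.0

    def test_two_distant_ions_reduce_to_screened_coulomb(self):
        p = GbParameters(salt_molar=0.15)
        top = ion_topology([1.0, -1.0], [2.0 + p.offset, 1.5 + p.offset])
        fr = Frame(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        radii = effective_born_radii(top, fr, p)
        g = gb_polar_energy(top, fr, radii, p)
        # at 50 Å the pair function f -> r, radii -> isolated, so the result
        # is two Born self terms plus one screened cross term
        r1, r2 = radii
        kappa = p.kappa_gb
        f = np.sqrt(50.0 ** 2 + r1 * r2 * np.exp(-50.0 ** 2 / (4 * r1 * r2)))
        cross = -332.0636 * (1.0 * -1.0) * (1 - np.exp(-kappa * f) / 78.5) / f
        expect = (born_self_energy(1.0, r1, kappa=kappa * r1 / r1) if False else
                  -0.5 * 332.0636 * (1 - np.exp(-kappa * r1) / 78.5) / r1
                  - 0.5 * 332.0636 * (1 - np.exp(-kappa * r2) / 78.5) / r2
                  + cross)
        assert g == pytest.approx(expect, abs=1e-6)

    def test_matched_dielectrics_kill_polar_term(self, toy_dimer):
        top, frame, _ = toy_dimer
        p = GbParameters(eps_out=1.0 + 1e-9, salt_molar=0.0)
        radii = effective_born_radii(top, frame, p)
        g = gb_polar_energy(top, frame, radii, p)
        assert abs(g) < 1e-6


class TestSurfaceTerm:
    def test_linear_map(self):
        assert sa_nonpolar_energy(100.0) == pytest.approx(0.72, abs=1e-12)
        assert sa_nonpolar_energy(0.0) == 0.0
        assert sa_nonpolar_energy(100.0, gamma=0.01, b=1.0) == pytest.approx(2.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            sa_nonpolar_energy(-1.0)


class TestEndpoint:
    def test_internal_terms_cancel_exactly(self, hydrated_trajectory,
                                           hydrated_dimer):
        htop, hframe, ranking, com = hydrated_dimer
        ids = select_closest_waters(hframe, htop, com, 30)
        part = partition_system(htop, retained_water_ids=ids)
        series = endpoint_binding_free_energy(hydrated_trajectory, part, [0],
                                              GbParameters(), sasa_points=240)
        d = series.delta_components[0]
        assert d.e_bond == 0.0
        assert d.e_angle == 0.0
        assert d.e_dihedral == 0.0

    def test_gas_interaction_equals_cross_terms(self, hydrated_trajectory,
                                                hydrated_dimer):
        """Water-internal and water–receptor terms shared between complex and
        receptor cancel: the gas-phase ΔE is exactly the receptor↔ligand
        cross sum."""
        htop, hframe, ranking, com = hydrated_dimer
        ids = select_closest_waters(hframe, htop, com, 30)
        part = partition_system(htop, retained_water_ids=ids)
        series = endpoint_binding_free_energy(hydrated_trajectory, part, [0],
                                              GbParameters(), sasa_points=240)
        d = series.delta_components[0]
        q = htop.array("charge")
        x = hframe.coordinates
        cross_elec = cross_vdw = 0.0
        rmh = htop.array("lj_rmin_half")
        eps = htop.array("lj_epsilon")
        for i in part.receptor_atoms:
            for j in part.ligand_atoms:
                dist = float(np.linalg.norm(x[i] - x[j]))
                cross_elec += 332.0636 * q[i] * q[j] / dist
                e = np.sqrt(eps[i] * eps[j])
                if e > 0:
                    sr6 = ((rmh[i] + rmh[j]) / dist) ** 6
                    cross_vdw += e * (sr6 * sr6 - 2 * sr6)
        assert d.e_elec == pytest.approx(cross_elec, abs=1e-8)
        assert d.e_vdw == pytest.approx(cross_vdw, abs=1e-8)

    def test_separated_ligand_limit(self, toy_dimer):
        top, frame, _ = toy_dimer
        coords = np.array(frame.coordinates, copy=True)
        coords[top.molecule_atoms("chainB")] += 200.0
        traj = Trajectory(top, [Frame(coords)])
        part = partition_system(top)
        series = endpoint_binding_free_energy(traj, part, [0], GbParameters(),
                                              sasa_points=240)
        d = series.delta_components[0]
        assert abs(d.e_vdw) < 1e-6
        assert abs(d.e_elec) < 1e-3   # net-neutral chains at 200 Å
        # what remains is solvation-only
        assert d.total == pytest.approx(d.g_polar + d.g_nonpolar + d.e_elec
                                        + d.e_vdw, abs=1e-12)

    def test_mean_matches_per_frame_reevaluation(self, toy_dimer, rng):
        top, frame, _ = toy_dimer
        frames = [Frame(frame.coordinates + rng.normal(0, 0.05,
                                                       frame.coordinates.shape),
                        time_ps=10.0 * k) for k in range(5)]
        traj = Trajectory(top, frames)
        part = partition_system(top)
        p = GbParameters()
        series = endpoint_binding_free_energy(traj, part, None, p,
                                              sasa_points=240)
        from mnmgbsa.gbsa import _subsystem_energy
        per_frame = []
        for fr in frames:
            g = [_subsystem_energy(top, fr, s, p, 240).total
                 for s in (part.complex_atoms, part.receptor_atoms,
                           part.ligand_atoms)]
            per_frame.append(g[0] - g[1] - g[2])
        assert series.mean == pytest.approx(np.mean(per_frame), abs=1e-10)
        assert series.std == pytest.approx(np.std(per_frame, ddof=1), abs=1e-10)

    def test_rigid_motion_invariance(self, toy_dimer, rng):
        top, frame, _ = toy_dimer
        rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        moved = Frame(frame.coordinates @ rot.T + np.array([3.0, -8.0, 12.0]))
        part = partition_system(top)
        p = GbParameters()
        a = endpoint_binding_free_energy(Trajectory(top, [frame]), part, [0],
                                         p, sasa_points=960)
        b = endpoint_binding_free_energy(Trajectory(top, [Frame(moved.coordinates)]),
                                         part, [0], p, sasa_points=960)
        da, db = a.delta_components[0], b.delta_components[0]
        for f in ("e_vdw", "e_elec", "g_polar"):
            assert getattr(da, f) == pytest.approx(getattr(db, f), abs=1e-6)
        # the surface term moves only by quadrature noise of the rotated grid
        assert da.g_nonpolar == pytest.approx(db.g_nonpolar, abs=0.05)

    def test_out_of_range_frame_rejected(self, toy_dimer):
        top, frame, _ = toy_dimer
        traj = Trajectory(top, [frame])
        with pytest.raises(IndexError):
            endpoint_binding_free_energy(traj, partition_system(top), [3],
                                         GbParameters())

    def test_deterministic_reports(self, toy_dimer):
        top, frame, _ = toy_dimer
        traj = Trajectory(top, [frame])
        part = partition_system(top)
        a = endpoint_binding_free_energy(traj, part, [0], GbParameters(),
                                         sasa_points=240).summary_table()
        b = endpoint_binding_free_energy(traj, part, [0], GbParameters(),
                                         sasa_points=240).summary_table()
        assert a == b


class TestDecomposition:
    def test_two_residue_system_single_pair(self):
        p = GbParameters()
        atoms = [AtomRecord(1, "A", "C", 0, "X", "A", charge=0.5, mass=12.0,
                            lj_rmin_half=1.9, lj_epsilon=0.1,
                            gb_radius=1.7, gb_screen=0.8),
                 AtomRecord(2, "B", "C", 1, "Y", "B", charge=-0.5, mass=12.0,
                            lj_rmin_half=1.9, lj_epsilon=0.1,
                            gb_radius=1.7, gb_screen=0.8)]
        top = MolecularTopology(atoms=atoms,
                                molecules=[("chainA", 0, 1), ("chainB", 1, 2)])
        fr = Frame(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        traj = Trajectory(top, [fr])
        part = partition_system(top, ligand_chain="chainB")
        dec = pairwise_decomposition(traj, part, [0], p, sasa_points=240)
        assert set(dec.pairs) == {(0, 1)}
        v = dec.pairs[(0, 1)]
        ev, ee = nonbonded_gas_energy(top, fr, np.arange(2))
        assert v["vdw"] == pytest.approx(ev, abs=1e-10)
        assert v["elec"] == pytest.approx(ee, abs=1e-10)

    def test_conservation_against_components(self, toy_dimer):
        top, frame, _ = toy_dimer
        p = GbParameters()
        traj = Trajectory(top, [frame])
        part = partition_system(top)
        dec = pairwise_decomposition(traj, part, [0], p, sasa_points=240)
        total = sum(v["vdw"] + v["elec"] + v["gb"] for v in dec.pairs.values())
        ev_c, ee_c = nonbonded_gas_energy(top, frame, part.complex_atoms)
        ev_r, ee_r = nonbonded_gas_energy(top, frame, part.receptor_atoms)
        ev_l, ee_l = nonbonded_gas_energy(top, frame, part.ligand_atoms)
        from mnmgbsa.gbsa import _gb_pair_energy_matrix
        radii = effective_born_radii(top, frame, p, part.complex_atoms)
        q = top.array("charge")[part.complex_atoms]
        x = frame.coordinates[part.complex_atoms]
        dm = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
        gbm = _gb_pair_energy_matrix(q, dm, radii, p)
        in_rec = np.isin(part.complex_atoms, part.receptor_atoms)
        cross_gb = 2.0 * gbm[np.ix_(in_rec, ~in_rec)].sum()
        ref = (ev_c - ev_r - ev_l) + (ee_c - ee_r - ee_l) + cross_gb
        assert total == pytest.approx(ref, abs=1e-6)

    def test_matches_brute_force_per_pair(self, rng):
        """4-residue system: every pair's vdW/elec equals a direct
        re-evaluation over its atom pairs."""
        atoms = []
        for r in range(4):
            for k in range(2):
                atoms.append(AtomRecord(
                    len(atoms) + 1, f"A{k}", "C", r, "RES",
                    "A" if r < 2 else "B", charge=rng.uniform(-0.4, 0.4),
                    mass=12.0, lj_rmin_half=1.8, lj_epsilon=0.1,
                    gb_radius=1.7, gb_screen=0.8))
        top = MolecularTopology(atoms=atoms,
                                molecules=[("chainA", 0, 4), ("chainB", 4, 8)])
        coords = rng.uniform(0, 8, size=(8, 3))
        fr = Frame(coords)
        traj = Trajectory(top, [fr])
        part = partition_system(top, ligand_chain="chainB")
        p = GbParameters()
        dec = pairwise_decomposition(traj, part, [0], p, sasa_points=240)
        q = top.array("charge")
        for (ra, rb), v in dec.pairs.items():
            ee = 0.0
            for i in top.residue(ra).atom_indices:
                for j in top.residue(rb).atom_indices:
                    ee += 332.0636 * q[i] * q[j] / np.linalg.norm(coords[i] - coords[j])
            assert v["elec"] == pytest.approx(ee, abs=1e-9)


class TestAtomPairDistance:
    def test_three_four_five(self, toy_dimer):
        atoms = [AtomRecord(1, "P", "C", 0, "X", "A"),
                 AtomRecord(2, "Q", "C", 1, "X", "A")]
        top = MolecularTopology(atoms=atoms, molecules=[("chainA", 0, 2)])
        fr = Frame(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        traj = Trajectory(top, [fr])
        d = atom_pair_distance_series(traj, ("A", 0, "P"), ("A", 1, "Q"))
        assert d[0] == pytest.approx(5.0, abs=1e-12)

    def test_identical_atoms_zero_and_series_matches_norm(self, toy_dimer, rng):
        top, frame, _ = toy_dimer
        frames = [Frame(frame.coordinates + rng.normal(0, 0.3,
                                                       frame.coordinates.shape),
                        time_ps=10.0 * k) for k in range(4)]
        traj = Trajectory(top, frames)
        d = atom_pair_distance_series(traj, ("A", 0, "CA"), ("A", 0, "CA"))
        np.testing.assert_allclose(d, 0.0)
        ca0 = top.select(["CA"])[0]
        cb = [i for i, a in enumerate(top.atoms)
              if a.name == "CB" and a.residue_index == 5][0]
        d = atom_pair_distance_series(traj, ("A", 0, "CA"), ("B", 5, "CB"))
        expect = [np.linalg.norm(f.coordinates[ca0] - f.coordinates[cb])
                  for f in frames]
        np.testing.assert_allclose(d, expect, atol=1e-12)

    def test_ambiguous_spec_rejected(self, toy_dimer):
        top, frame, _ = toy_dimer
        traj = Trajectory(top, [frame])
        with pytest.raises(ValueError, match="resolves to"):
            atom_pair_distance_series(traj, ("A", 0, "NOPE"), ("A", 1, "CA"))
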