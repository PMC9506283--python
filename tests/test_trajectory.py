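"""Structural operators: Voronoi areas, order parameters, thicknesses,
density profiles, contacts, hydrogen bonds, RDF and hydration."""

import numpy as np
import pytest

from leafletlab import synth
from leafletlab.topology import LipidTopology, SpeciesTopology
from leafletlab.trajectory import (MonolayerTrajectory, area_per_lipid,
                                   contact_heatmap, electron_density_profile,
                                   hydration_histogram, hydration_map,
                                   hydrogen_bonds, order_parameter,
                                   periodic_voronoi_areas, rdf, thicknesses,
                                   vector_orientation)
from oracles import brute_force_contacts, brute_force_hbonds, mc_voronoi_areas


def make_traj(coords, box, species, names, elements, mol_ids, periodic_z=False):
    return MonolayerTrajectory(
        coords=np.asarray(coords, dtype=float), box=np.asarray(box, float),
        species=np.array(species), names=np.array(names),
        elements=np.array(elements), molecule_ids=np.array(mol_ids),
        periodic_z=periodic_z)


class TestVoronoi:
    def test_hexagonal_lattice_cells_are_equal(self, hex_sterol_monolayer):
        traj, top = hex_sterol_monolayer
        _, per_lipid = area_per_lipid(traj, top)
        areas = np.array(list(per_lipid.values()))
        expected = 30.0 * 30.0 / 16
        assert np.allclose(areas, expected, rtol=1e-9)

    def test_total_area_conservation(self):
        # random points: cell areas must tile the box exactly
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 50, size=(40, 2))
        areas = periodic_voronoi_areas(pts, np.array([50.0, 50.0]))
        assert areas.sum() == pytest.approx(2500.0, rel=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 30, size=(25, 2))
        box = np.array([30.0, 30.0])
        a1 = periodic_voronoi_areas(pts, box)
        a2 = periodic_voronoi_areas(pts + np.array([7.3, -4.1]), box)
        assert np.allclose(a1, a2, rtol=1e-9)

    def test_matches_monte_carlo_integration(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 40, size=(50, 2))
        box = np.array([40.0, 40.0])
        exact = periodic_voronoi_areas(pts, box)
        mc = mc_voronoi_areas(pts, box, n_samples=10_000_000, seed=8)
        rel = np.abs(mc - exact) / exact
        # binomial sampling noise: ~0.2% relative for a typical cell
        assert np.median(rel) < 0.005
        assert np.max(rel) < 0.02


class TestOrderParameter:
    def test_all_trans_vertical_chains_give_one_half(self, phospholipid_monolayer):
        traj, top = phospholipid_monolayer
        for tail in ("sn1", "sn2"):
            prof = order_parameter(traj, top, "PLA", tail)
            assert np.allclose(prof.s_cd, 0.5, atol=1e-12)
            assert not prof.flags

    def _bond_traj(self, directions):
        """n molecules, each one carbon with one hydrogen along the given
        unit vectors."""
        n = directions.shape[0]
        coords = np.zeros((1, 2 * n, 3))
        names, elements, species, mol_ids = [], [], [], []
        for i, d in enumerate(directions):
            coords[0, 2 * i] = [10 * i, 0, 50]
            coords[0, 2 * i + 1] = coords[0, 2 * i] + 1.09 * d
            names += ["C11", "H11A"]
            elements += ["C", "H"]
            species += ["X", "X"]
            mol_ids += [i, i]
        traj = make_traj(coords, [10.0 * n, 10.0, 100.0], species, names,
                         elements, mol_ids)
        st = SpeciesTopology(name="X",
                             electrons={"C11": 6, "H11A": 1},
                             ref_atoms=[], tails={"sn1": [("C11", ["H11A"])]})
        return traj, LipidTopology(species={"X": st})

    def test_isotropic_bonds_average_to_zero(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=(100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        traj, top = self._bond_traj(v)
        prof = order_parameter(traj, top, "X", "sn1")
        assert abs(prof.s_cd[0]) <= 0.01

    def test_bonds_parallel_to_normal_are_flagged(self):
        v = np.tile([0.0, 0.0, 1.0], (20, 1))
        traj, top = self._bond_traj(v)
        with pytest.warns(UserWarning, match="impossible"):
            prof = order_parameter(traj, top, "X", "sn1")
        assert prof.s_cd[0] == pytest.approx(-1.0)
        assert prof.flags == ["C11"]

    def test_invariant_under_rotation_about_z(self, phospholipid_monolayer):
        traj, top = phospholipid_monolayer
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        rotated = MonolayerTrajectory(
            coords=traj.coords @ R.T, box=traj.box, species=traj.species,
            names=traj.names, elements=traj.elements,
            molecule_ids=traj.molecule_ids)
        p1 = order_parameter(traj, top, "PLA", "sn1")
        p2 = order_parameter(rotated, top, "PLA", "sn1")
        assert np.allclose(p1.s_cd, p2.s_cd, atol=1e-12)


class TestThickness:
    def _rigid_lipid_traj(self, tilt_deg=0.0):
        """One lipid with terminal C at origin-like layout: tail 16.1 Å,
        head 7.6 Å along z before tilting about x."""
        pts = np.array([[0.0, 0.0, 0.0],     # terminal carbon
                        [0.0, 0.0, 16.1],    # carbonyl
                        [0.0, 0.0, 23.7]])   # phosphorus
        t = np.deg2rad(tilt_deg)
        R = np.array([[1, 0, 0],
                      [0, np.cos(t), -np.sin(t)],
                      [0, np.sin(t), np.cos(t)]])
        pts = pts @ R.T + np.array([20.0, 20.0, 30.0])
        water = np.array([[5.0, 5.0, 70.0]])
        coords = np.vstack([pts, water])[None]
        traj = make_traj(coords, [40.0, 40.0, 100.0],
                         ["L", "L", "L", "SOL"],
                         ["CT", "CC", "P", "O"],
                         ["C", "C", "P", "O"], [0, 0, 0, 1])
        st = SpeciesTopology(name="L",
                             electrons={"CT": 6, "CC": 6, "P": 15},
                             ref_atoms=[], tails={},
                             carbonyl="CC", terminal="CT", phosphorus="P")
        water = SpeciesTopology(name="SOL", electrons={"O": 8}, is_water=True)
        return traj, LipidTopology(species={"L": st, "SOL": water})

    def test_constructed_decomposition(self):
        traj, top = self._rigid_lipid_traj()
        th = thicknesses(traj, top)["L"]
        assert th["tail"] == pytest.approx(16.1)
        assert th["head"] == pytest.approx(7.6)
        assert th["total"] == pytest.approx(23.7)

    def test_total_is_sum_identity(self, phospholipid_monolayer):
        traj, top = phospholipid_monolayer
        for vals in thicknesses(traj, top).values():
            assert vals["total"] == pytest.approx(vals["tail"] + vals["head"])

    def test_tilt_scales_z_projections(self):
        traj0, top = self._rigid_lipid_traj(0.0)
        traj60, _ = self._rigid_lipid_traj(60.0)
        th0 = thicknesses(traj0, top)["L"]
        th60 = thicknesses(traj60, top)["L"]
        assert th60["total"] == pytest.approx(0.5 * th0["total"], rel=1e-9)

    def test_sterols_are_excluded(self, hex_sterol_monolayer):
        traj, top = hex_sterol_monolayer
        with pytest.raises(ValueError):
            thicknesses(traj, top)


class TestElectronDensityProfile:
    def test_single_atom_occupies_one_bin(self):
        coords = np.array([[[5.0, 5.0, 25.0]]])
        traj = make_traj(coords, [10.0, 10.0, 100.0], ["X"], ["C1"], ["C"], [0])
        st = SpeciesTopology(name="X", electrons={"C1": 6})
        top = LipidTopology(species={"X": st})
        z, rho = electron_density_profile(traj, top, bins=50,
                                          average_leaflets=False)
        bin_vol = 2.0 * 10.0 * 10.0
        i = np.argmin(np.abs(z - 25.0))
        assert rho[i] == pytest.approx(6 / bin_vol)
        assert np.count_nonzero(rho) == 1

    def test_electron_count_conservation(self, phospholipid_monolayer):
        traj, top = phospholipid_monolayer
        from leafletlab.constants import ELECTRONS
        z, rho = electron_density_profile(traj, top, bins=73)
        total = rho.sum() * (z[1] - z[0]) * traj.box[0] * traj.box[1]
        expected = sum(ELECTRONS[str(e)] for e in traj.elements)
        assert total == pytest.approx(expected, rel=1e-9)

    def test_uniform_atoms_give_flat_profile(self):
        rng = np.random.default_rng(12)
        n = 20000
        coords = rng.uniform(0, [20, 20, 80], size=(1, n, 3))
        traj = make_traj(coords, [20.0, 20.0, 80.0], ["X"] * n,
                         ["C1"] * n, ["C"] * n, list(range(n)))
        top = LipidTopology(species={"X": SpeciesTopology(
            name="X", electrons={"C1": 6})})
        z, rho = electron_density_profile(traj, top, bins=20,
                                          average_leaflets=False)
        per_bin = n / 20
        sigma = np.sqrt(per_bin)
        counts = rho * (z[1] - z[0]) * 400.0 / 6.0
        assert np.all(np.abs(counts - per_bin) < 3.5 * sigma)


class TestVectorOrientation:
    def _axis_traj(self, vecs):
        n = vecs.shape[0]
        coords = np.zeros((1, 2 * n + 1, 3))
        names, elements, species, mol_ids = [], [], [], []
        for i, v in enumerate(vecs):
            coords[0, 2 * i] = [5.0 * i, 0, 40]
            coords[0, 2 * i + 1] = coords[0, 2 * i] + v
            names += ["C3", "C17"]
            elements += ["C", "C"]
            species += ["STE", "STE"]
            mol_ids += [i, i]
        coords[0, -1] = [1.0, 1.0, 90.0]
        names.append("O")
        elements.append("O")
        species.append("SOL")
        mol_ids.append(n)
        traj = make_traj(coords, [5.0 * max(n, 2), 10.0, 100.0], species,
                         names, elements, mol_ids)
        ste = SpeciesTopology(name="STE", electrons={"C3": 6, "C17": 6},
                              ref_atoms=["O3"] if False else [],
                              sterol_axis=("C3", "C17"), is_sterol=True)
        sol = SpeciesTopology(name="SOL", electrons={"O": 8}, is_water=True)
        return traj, LipidTopology(species={"STE": ste, "SOL": sol})

    def test_vertical_vector_is_zero_degrees(self):
        traj, top = self._axis_traj(np.array([[0.0, 0.0, 9.0]]))
        angles, _, _, mean = vector_orientation(traj, top, "STE")
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_vector_is_ninety_degrees(self):
        traj, top = self._axis_traj(np.array([[9.0, 0.0, 0.0]]))
        _, _, _, mean = vector_orientation(traj, top, "STE")
        assert mean == pytest.approx(90.0, abs=1e-9)

    def test_isotropic_hemisphere_vectors_mean_one_radian(self):
        # sin θ-weighted angles over the upper hemisphere average to 1 rad
        rng = np.random.default_rng(13)
        v = rng.normal(size=(100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[:, 2] = np.abs(v[:, 2])
        traj, top = self._axis_traj(9.0 * v)
        _, _, _, mean = vector_orientation(traj, top, "STE")
        assert mean == pytest.approx(np.degrees(1.0), abs=1.0)

    def test_zero_length_vector_raises(self):
        traj, top = self._axis_traj(np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError):
            vector_orientation(traj, top, "STE")


class TestContacts:
    def test_matrix_normalisation_and_single_pair(self):
        coords = np.array([[[5.0, 5.0, 50.0],    # sterol atom A
                            [15.0, 5.0, 50.0],   # sterol atom B (far)
                            [5.0, 7.0, 50.0],    # partner atom P1 (2 Å from A)
                            [20.0, 20.0, 50.0]]])  # partner atom P2 (far)
        traj = make_traj(coords, [40.0, 40.0, 100.0],
                         ["STE", "STE", "PLX", "PLX"],
                         ["SA", "SB", "P1", "P2"],
                         ["C", "C", "C", "C"], [0, 0, 1, 1])
        ste = SpeciesTopology(name="STE", electrons={"SA": 6, "SB": 6})
        plx = SpeciesTopology(name="PLX", electrons={"P1": 6, "P2": 6})
        top = LipidTopology(species={"STE": ste, "PLX": plx})
        hm = contact_heatmap(traj, top, "STE", "PLX", cutoff=4.0)
        assert hm.matrix.sum() == pytest.approx(1.0)
        i = hm.sterol_atoms.index("SA")
        j = hm.partner_atoms.index("P1")
        assert hm.matrix[i, j] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(14)
        box = np.array([20.0, 20.0, 20.0])
        n_s, n_p = 3, 4
        atoms_per = 6
        coords, species, names, elements, mol_ids = [], [], [], [], []
        for m in range(n_s + n_p):
            sp = "STE" if m < n_s else "PLX"
            centre = rng.uniform(0, 20, 3)
            for a in range(atoms_per):
                coords.append(centre + rng.normal(scale=1.5, size=3))
                species.append(sp)
                names.append(f"A{a}")
                elements.append("C")
                mol_ids.append(m)
        frames = np.repeat(np.asarray(coords)[None], 5, axis=0)
        frames += rng.normal(scale=0.3, size=frames.shape)
        traj = make_traj(frames, box, species, names, elements, mol_ids,
                         periodic_z=True)
        electrons = {f"A{a}": 6 for a in range(atoms_per)}
        top = LipidTopology(species={
            "STE": SpeciesTopology(name="STE", electrons=dict(electrons)),
            "PLX": SpeciesTopology(name="PLX", electrons=dict(electrons))})
        hm = contact_heatmap(traj, top, "STE", "PLX", cutoff=4.0)
        # oracle: exhaustive pair enumeration over frames and molecule pairs
        expected = {}
        sm = [np.nonzero((traj.species == "STE")
                         & (traj.molecule_ids == m))[0] for m in range(n_s)]
        pm = [np.nonzero((traj.species == "PLX")
                         & (traj.molecule_ids == m))[0]
              for m in range(n_s, n_s + n_p)]
        for f in range(5):
            for s_idx in sm:
                for p_idx in pm:
                    c = brute_force_contacts(
                        frames[f, s_idx], [names[i] for i in s_idx],
                        frames[f, p_idx], [names[i] for i in p_idx],
                        box, (True, True, True), 4.0)
                    for k, v in c.items():
                        expected[k] = expected.get(k, 0) + v
        total = sum(expected.values())
        for (na, nb), v in expected.items():
            i = hm.sterol_atoms.index(na)
            j = hm.partner_atoms.index(nb)
            assert hm.matrix[i, j] == pytest.approx(v / total)
        assert hm.matrix.sum() == pytest.approx(1.0)


class TestHydrogenBonds:
    def _three_atom_traj(self, angle_deg, d_oo=2.8):
        """O–H donor and acceptor O with a prescribed D–H–A angle."""
        d_oh = 1.0
        donor_o = np.array([10.0, 10.0, 10.0])
        h = donor_o + np.array([d_oh, 0.0, 0.0])
        # place the acceptor so the angle between H→D and H→A equals the
        # requested D–H–A angle
        theta = np.deg2rad(angle_deg)
        hd = donor_o - h
        hd /= np.linalg.norm(hd)
        perp = np.array([0.0, 1.0, 0.0])
        ha_dir = np.cos(theta) * hd + np.sin(theta) * perp
        # choose |HA| so that |DA| = d_oo
        # |DA|² = |DH|² + |HA|² - 2 DH·HA... solve quadratic
        b = 2 * d_oh * np.dot(-hd, ha_dir)
        disc = b**2 - 4 * (d_oh**2 - d_oo**2)
        r = (-b + np.sqrt(disc)) / 2
        acceptor = h + r * ha_dir
        coords = np.array([[donor_o, h, acceptor]])
        traj = make_traj(coords, [40.0, 40.0, 40.0],
                         ["W", "W", "W"], ["OD", "HD", "OA"],
                         ["O", "H", "O"], [0, 0, 1], periodic_z=True)
        w = SpeciesTopology(name="W",
                            electrons={"OD": 8, "HD": 1, "OA": 8},
                            donors={"OD": ["HD"]}, acceptors=["OA"])
        return traj, LipidTopology(species={"W": w}, water_species="NONE")

    def test_linear_geometry_detected(self):
        traj, top = self._three_atom_traj(180.0)
        bonds = hydrogen_bonds(traj, top)
        assert bonds[("W:OD", "W:OA")][0] == 1

    def test_bent_geometry_rejected(self):
        traj, top = self._three_atom_traj(140.0)
        assert hydrogen_bonds(traj, top) == {}

    def test_angle_threshold_boundary(self):
        traj, top = self._three_atom_traj(151.0)
        assert hydrogen_bonds(traj, top)
        traj, top = self._three_atom_traj(149.0)
        assert hydrogen_bonds(traj, top) == {}

    def test_matches_brute_force_on_random_frame(self):
        rng = np.random.default_rng(15)
        box = np.array([15.0, 15.0, 15.0])
        n_mol = 50
        coords, species, names, elements, mol_ids = [], [], [], [], []
        for m in range(n_mol):
            o = rng.uniform(0, 15, 3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords += [o, o + u]
            species += ["W", "W"]
            names += ["OW", "HW"]
            elements += ["O", "H"]
            mol_ids += [m, m]
        traj = make_traj(np.asarray(coords)[None], box, species, names,
                         elements, mol_ids, periodic_z=True)
        w = SpeciesTopology(name="W", electrons={"OW": 8, "HW": 1},
                            donors={"OW": ["HW"]}, acceptors=["OW"])
        top = LipidTopology(species={"W": w}, water_species="NONE")
        ours = hydrogen_bonds(traj, top)
        n_ours = sum(v[0] for v in ours.values())
        donors = [(m, 2 * m, [2 * m + 1]) for m in range(n_mol)]
        acceptors = [(m, 2 * m) for m in range(n_mol)]
        oracle = brute_force_hbonds(np.asarray(coords), donors, acceptors,
                                    box, (True, True, True))
        assert n_ours == len(oracle)


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(16)
        n = 10_000
        L = 21.5
        coords = rng.uniform(0, L, size=(1, n, 3))
        traj = make_traj(coords, [L, L, L], ["X"] * n, ["A"] * n, ["C"] * n,
                         list(range(n)), periodic_z=True)
        sel = np.arange(n)
        res = rdf(traj, sel, sel, r_max=5.0, bins=25)
        assert np.all(np.abs(res.g[2:] - 1.0) < 0.05)

    def test_two_atoms_single_bin(self):
        coords = np.array([[[5.0, 5.0, 5.0], [8.0, 5.0, 5.0]]])
        traj = make_traj(coords, [20.0, 20.0, 20.0], ["X", "X"], ["A", "B"],
                         ["C", "C"], [0, 1], periodic_z=True)
        res = rdf(traj, np.array([0]), np.array([1]), r_max=8.0, bins=16)
        nonzero = np.nonzero(res.g)[0]
        assert len(nonzero) == 1
        assert res.r[nonzero[0]] == pytest.approx(3.0, abs=0.25)
        assert np.all(res.g >= 0)

    def test_r_max_validation(self):
        coords = np.zeros((1, 2, 3))
        traj = make_traj(coords, [10.0, 10.0, 10.0], ["X", "X"], ["A", "B"],
                         ["C", "C"], [0, 1])
        with pytest.raises(ValueError):
            rdf(traj, np.array([0]), np.array([1]), r_max=8.0)


class TestHydration:
    def test_hydration_map_normalisation(self, phospholipid_monolayer):
        traj, top = phospholipid_monolayer
        hm = hydration_map(traj, top, "PLA")
        assert hm.probability.sum() == pytest.approx(1.0)
        assert np.all(hm.probability >= 0)

    def test_single_hydrated_atom_gets_probability_one(self):
        coords = np.array([[[5.0, 5.0, 20.0],    # atom A (near water)
                            [5.0, 5.0, 40.0],    # atom B (far)
                            [5.0, 8.0, 20.0]]])  # water O, 3 Å from A
        traj = make_traj(coords, [20.0, 20.0, 60.0],
                         ["X", "X", "SOL"], ["A", "B", "O"],
                         ["C", "C", "O"], [0, 0, 1])
        st = SpeciesTopology(name="X", electrons={"A": 6, "B": 6})
        sol = SpeciesTopology(name="SOL", electrons={"O": 8}, is_water=True)
        top = LipidTopology(species={"X": st, "SOL": sol})
        hm = hydration_map(traj, top, "X")
        assert dict(zip(hm.atoms, hm.probability)) == {"A": 1.0, "B": 0.0}

    def test_three_to_one_event_counting(self):
        # atom A hydrated in 3 frames, atom B in 1 → map (0.75, 0.25)
        base = np.array([[5.0, 5.0, 20.0], [5.0, 5.0, 30.0],
                         [5.0, 8.0, 20.0]])
        frames = np.repeat(base[None], 4, axis=0)
        frames[3, 2] = [5.0, 8.0, 30.0]      # water next to B in last frame
        frames[3, 2, 1] = 5.0
        frames[3, 2] = [5.0, 5.0, 33.0]
        traj = make_traj(frames, [20.0, 20.0, 60.0],
                         ["X", "X", "SOL"], ["A", "B", "O"],
                         ["C", "C", "O"], [0, 0, 1])
        st = SpeciesTopology(name="X", electrons={"A": 6, "B": 6})
        sol = SpeciesTopology(name="SOL", electrons={"O": 8}, is_water=True)
        top = LipidTopology(species={"X": st, "SOL": sol})
        hm = hydration_map(traj, top, "X")
        probs = dict(zip(hm.atoms, hm.probability))
        assert probs["A"] == pytest.approx(0.75)
        assert probs["B"] == pytest.approx(0.25)

    def test_histogram_bulk_plateau(self):
        # dense planar surface at z=0 under a uniform water slab: the
        # minimum-distance histogram must plateau at 1 in density units
        rng = np.random.default_rng(17)
        L = 30.0
        n_frames = 10
        xs = np.arange(0.5, L, 1.0)
        surface = np.array([[x, y, 0.0] for x in xs for y in xs])
        n_w = int(0.0334 * L * L * 40.0)
        species, names, elements, mol_ids = [], [], [], []
        for i in range(len(surface)):
            species.append("X")
            names.append("S")
            elements.append("C")
            mol_ids.append(i)
        for j in range(n_w):
            species.append("SOL")
            names.append("O")
            elements.append("O")
            mol_ids.append(len(surface) + j)
        frames = np.empty((n_frames, len(surface) + n_w, 3))
        for f in range(n_frames):
            frames[f, :len(surface)] = surface
            frames[f, len(surface):] = rng.uniform([0, 0, 2.0], [L, L, 42.0],
                                                   size=(n_w, 3))
        traj = make_traj(frames, [L, L, 60.0], species,
                         names, elements, mol_ids)
        st = SpeciesTopology(name="X", electrons={"S": 6}, head_atoms=["S"])
        sol = SpeciesTopology(name="SOL", electrons={"O": 8}, is_water=True)
        top = LipidTopology(species={"X": st, "SOL": sol})
        r, h = hydration_histogram(traj, top, bins=20, r_max=40.0)
        bulk = h[(r > 10) & (r < 35)]
        assert np.all(np.abs(bulk - 1.0) < 0.15)

    def test_translation_shifts_support(self):
        coords = np.array([[[5.0, 5.0, 10.0], [5.0, 5.0, 16.0]]])
        shifted = coords.copy()
        shifted[0, 1, 2] += 5.0
        args = ([20.0, 20.0, 60.0], ["X", "SOL"], ["S", "O"], ["C", "O"],
                [0, 1])
        st = SpeciesTopology(name="X", electrons={"S": 6}, head_atoms=["S"])
        sol = SpeciesTopology(name="SOL", electrons={"O": 8}, is_water=True)
        top = LipidTopology(species={"X": st, "SOL": sol})
        r1, h1 = hydration_histogram(make_traj(coords, *args), top,
                                     bins=30, r_max=30.0)
        r2, h2 = hydration_histogram(make_traj(shifted, *args), top,
                                     bins=30, r_max=30.0)
        assert r1[np.nonzero(h1)[0][0]] + 5.0 == pytest.approx(
            r2[np.nonzero(h2)[0][0]], abs=1.0)
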