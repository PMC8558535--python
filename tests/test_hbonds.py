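"""Hydrogen-bond geometry, detection, per-water statistics and ring motifs."""

import math

import networkx as nx
import numpy as np
import pytest

from hydracryst.core import (
    Atom,
    Box,
    Structure,
    Trajectory,
    class_array,
    classify_atoms,
    min_image_displacement,
    min_image_distance,
)
from hydracryst.hbonds import (
    DegenerateGeometryError,
    HBondCriterion,
    NoHydrogensError,
    build_donor_acceptor_table,
    find_hbonds,
    find_rings,
    hb_geometry,
    per_water_counts,
    rings_near_class,
    water_network,
    water_network_from_frame,
)
from hydracryst.synth import make_ice_lattice, make_ring_fixture

from conftest import random_water_box, single_frame, water


class TestHbGeometry:
    def test_collinear(self):
        r, theta = hb_geometry([0, 0, 0], [0.96, 0, 0], [2.80, 0, 0])
        assert r == pytest.approx(1.84)
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_120_degree_angle_gives_theta_60(self):
        # acceptor at 120 deg from the donor direction, 2.0 A from H
        h = np.array([0.96, 0, 0])
        direction = np.array([math.cos(math.radians(60)),
                              math.sin(math.radians(60)), 0.0])
        r, theta = hb_geometry([0, 0, 0], h, h + 2.0 * direction)
        assert r == pytest.approx(2.0)
        assert theta == pytest.approx(60.0)

    def test_matches_independent_dot_product_oracle(self, rng):
        def oracle(d, h, a):
            v1 = np.asarray(d) - h
            v2 = np.asarray(a) - h
            ang = math.degrees(math.acos(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
            return np.linalg.norm(v2), 180.0 - ang

        for _ in range(50):
            d, h, a = rng.random((3, 3)) * 5
            r1, t1 = hb_geometry(d, h, a)
            r2, t2 = oracle(d, h, a)
            assert r1 == pytest.approx(r2, abs=1e-9)
            assert t1 == pytest.approx(t2, abs=1e-9)

    def test_minimum_image_used(self):
        box = Box((10.0, 10.0, 10.0))
        r, theta = hb_geometry([0.5, 0, 0], [9.9, 0, 0], [8.0, 0, 0], box)
        assert r == pytest.approx(1.9)
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            hb_geometry([1, 1, 1], [1, 1, 1], [2, 2, 2])


def brute_force_hbonds(frame, classes, crit):
    """Independent all-pairs evaluation of the geometric criterion."""
    classes_arr = class_array(frame, classes)
    table = build_donor_acceptor_table(frame, classes_arr)
    atoms, pos, box = frame.atoms, frame.positions, frame.box
    found = set()
    for d_i, h_i in table.donors:
        for a_i in table.acceptors:
            if a_i == d_i:
                continue
            if (atoms[a_i].chain_id, atoms[a_i].residue_id) == \
               (atoms[d_i].chain_id, atoms[d_i].residue_id):
                continue
            if not min_image_distance(pos[d_i], pos[a_i], box) < crit.d_oo_max:
                continue
            v1 = min_image_displacement(pos[h_i], pos[d_i], box)
            v2 = min_image_displacement(pos[h_i], pos[a_i], box)
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = 180.0 - math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if theta <= crit.theta_max:
                found.add((atoms[d_i].serial, atoms[h_i].serial, atoms[a_i].serial))
    return found


class TestFindHbonds:
    def test_distance_gate_excludes_3p6(self):
        atoms = water(1, [0, 0, 0]) + water(2, [3.6, 0, 0], start_serial=4)
        s = Structure(atoms)
        assert find_hbonds(s, classify_atoms(s)) == []

    def test_collinear_dimer_single_bond(self, collinear_dimer):
        bonds = find_hbonds(collinear_dimer, classify_atoms(collinear_dimer))
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor_atom, b.hydrogen, b.acceptor_atom) == (1, 2, 4)
        assert b.theta == pytest.approx(0.0, abs=1e-9)
        assert b.r == pytest.approx(2.8 - 0.9572, abs=1e-6)
        assert not b.n_mediated

    def test_boundary_exactly_3p5_excluded(self):
        atoms = water(1, [0, 0, 0]) + water(2, [3.5, 0, 0], start_serial=4)
        s = Structure(atoms)
        assert find_hbonds(s, classify_atoms(s)) == []

    def test_boundary_angle_120_included(self):
        # place acceptor so the O-H...O angle is exactly 120 deg (theta = 60)
        h = np.array([0.9572, 0.0, 0.0])
        direction = np.array([math.cos(math.radians(60)),
                              math.sin(math.radians(60)), 0.0])
        acc = h + 1.8 * direction
        assert np.linalg.norm(acc) < 3.5
        atoms = water(1, [0, 0, 0]) + water(2, acc, start_serial=4)
        s = Structure(atoms)
        bonds = find_hbonds(s, classify_atoms(s))
        assert len(bonds) == 1
        assert bonds[0].theta == pytest.approx(60.0, abs=1e-9)

    def test_relabelling_dimer_waters_is_symmetric(self, collinear_dimer):
        atoms = list(reversed(collinear_dimer.atoms))
        s = Structure(atoms)
        bonds = find_hbonds(s, classify_atoms(s))
        assert len(bonds) == 1
        assert bonds[0].donor_atom == 1

    def test_no_hydrogens_raises(self):
        s = Structure([Atom(1, "O", "O", "HOH", 1, "W", [0, 0, 0]),
                       Atom(2, "O", "O", "HOH", 2, "W", [2.8, 0, 0])])
        with pytest.raises(NoHydrogensError):
            find_hbonds(s, classify_atoms(s))

    @pytest.mark.parametrize("seed", range(20))
    def test_neighbor_search_equals_brute_force(self, seed):
        s = random_water_box(64, 12.0, seed=seed)
        classes = classify_atoms(s)
        crit = HBondCriterion()
        fast = {(b.donor_atom, b.hydrogen, b.acceptor_atom)
                for b in find_hbonds(s, classes, crit)}
        assert fast == brute_force_hbonds(s, classes, crit)

    def test_water_protein_donating_and_accepting(self):
        # serine hydroxyl donates to a water; the same water donates back to
        # the carbonyl O of the residue -> one water-protein bond each way
        atoms = [
            Atom(1, "OG", "O", "SER", 1, "A", [0.0, 0.0, 0.0]),
            Atom(2, "HG", "H", "SER", 1, "A", [0.96, 0.0, 0.0]),
        ]
        atoms += water(2, [2.8, 0.0, 0.0], h1=[3.76, 0.0, 0.0],
                       h2=[2.56, 0.93, 0.0], start_serial=3)
        atoms += [Atom(6, "O", "O", "GLY", 3, "A", [5.6, 0.0, 0.0])]
        s = Structure(atoms)
        bonds = find_hbonds(s, classify_atoms(s))
        kinds = sorted((b.donor_class, b.acceptor_class) for b in bonds)
        assert kinds == [("side_chain_hydrophilic", "water"),
                         ("water", "main_chain")]


class TestPerWaterCounts:
    def test_ice_lattice_reaches_bulk_limit_of_four(self):
        ice = make_ice_lattice(3, jitter_sigma=0.0, seed=0)
        summary = per_water_counts(single_frame(ice), classify_atoms(ice))
        assert summary.total == pytest.approx(4.0)
        assert summary.water_water == pytest.approx(4.0)
        assert summary.water_protein == 0.0

    def test_dilute_gas_has_no_bonds(self):
        atoms = []
        for i in range(8):
            atoms += water(i + 1, [6.0 * i, 0.0, 0.0], start_serial=3 * i + 1)
        s = Structure(atoms)
        summary = per_water_counts(single_frame(s), classify_atoms(s))
        assert summary.total == 0.0

    def test_constructed_surface_decomposition(self):
        # each water donates once to a protein carbonyl and once to a water
        atoms = [Atom(1, "O", "O", "GLY", 1, "A", [0.0, 0.0, 0.0])]
        atoms += water(1, [2.8, 0.0, 0.0], h1=[1.84, 0.0, 0.0],
                       h2=[3.08, 0.92, 0.0], start_serial=2)
        atoms += water(2, [2.8, -2.8, 0.0], h1=[2.8, -1.84, 0.0],
                       h2=[3.7, -3.1, 0.0], start_serial=5)
        # second water donates h1 to first water; first donates h2 to nothing
        s = Structure(atoms)
        summary = per_water_counts(single_frame(s), classify_atoms(s))
        assert summary.n_waters == 2
        # bonds: water1->carbonyl (water-protein), water2->water1 (water-water
        # counted once for each molecule)
        assert summary.water_protein == pytest.approx(0.5)
        assert summary.water_water == pytest.approx(1.0)
        assert summary.total == pytest.approx(1.5)
        assert summary.water_main_chain + summary.water_side_chain == \
            pytest.approx(summary.water_protein)

    def test_jittered_ice_degrades_gracefully(self):
        ice = make_ice_lattice(3, jitter_sigma=0.1, seed=4)
        summary = per_water_counts(single_frame(ice), classify_atoms(ice))
        assert summary.total >= 3.9

    def test_no_waters_is_an_error(self):
        s = Structure([Atom(1, "CA", "C", "ALA", 1, "A", [0, 0, 0]),
                       Atom(2, "HA", "H", "ALA", 1, "A", [1, 0, 0])])
        with pytest.raises(ValueError, match="no water"):
            per_water_counts(single_frame(s), classify_atoms(s))


class TestWaterNetworkAndRings:
    def test_empty_bonds_empty_graph(self):
        g = water_network([], {})
        assert g.number_of_nodes() == 0

    def test_dimer_graph(self, collinear_dimer):
        g = water_network_from_frame(collinear_dimer,
                                     classify_atoms(collinear_dimer))
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1

    def test_edge_count_bounded_by_bond_count(self):
        s = random_water_box(64, 12.0, seed=99)
        classes = classify_atoms(s)
        bonds = find_hbonds(s, classes)
        ww = [b for b in bonds if b.donor_class == "water"
              and b.acceptor_class == "water"]
        g = water_network_from_frame(s, classes)
        assert g.number_of_edges() <= len(ww)

    def test_pentagon_fixture_one_ring_of_five(self):
        ring = make_ring_fixture(5)
        g = water_network_from_frame(ring, classify_atoms(ring))
        rings = find_rings(g, 6)
        assert len(rings) == 1
        assert len(rings[0]) == 5

    def test_hexagon_fixture(self):
        ring = make_ring_fixture(6)
        g = water_network_from_frame(ring, classify_atoms(ring))
        assert [len(r) for r in find_rings(g, 6)] == [6]

    def test_tree_has_no_rings(self):
        g = nx.balanced_tree(2, 3)
        assert find_rings(g, 6) == []

    def test_cube_rings_match_exhaustive_enumeration(self):
        g = nx.hypercube_graph(3)
        rings = find_rings(g, 6)
        assert all(len(r) == 4 for r in rings)
        exhaustive = [c for c in nx.simple_cycles(g, length_bound=4)
                      if len(c) == 4]
        assert len(rings) == len(exhaustive)

    def test_rings_reported_once_up_to_rotation(self):
        g = nx.cycle_graph(5)
        assert len(find_rings(g, 5)) == 1

    def test_max_size_validates(self):
        with pytest.raises(ValueError):
            find_rings(nx.cycle_graph(4), 2)


class TestRingsNearClass:
    def _pentagon_above_slab(self, z_offset):
        ring = make_ring_fixture(5)
        atoms = [Atom(1000 + i, "CD1", "C", "LEU", 100 + i, "P",
                      [4.0 * i - 4.0, 0.0, -z_offset]) for i in range(3)]
        all_atoms = ring.atoms + atoms
        return Structure(all_atoms)

    def test_pentagon_near_hydrophobic_slab_included(self):
        s = self._pentagon_above_slab(3.0)
        classes = classify_atoms(s)
        g = water_network_from_frame(s, classes)
        rings = find_rings(g, 6)
        near = rings_near_class(rings, s, classes, "side_chain_hydrophobic", 4.0)
        assert len(near) == 1

    def test_distant_ring_excluded(self):
        s = self._pentagon_above_slab(30.0)
        classes = classify_atoms(s)
        g = water_network_from_frame(s, classes)
        rings = find_rings(g, 6)
        near = rings_near_class(rings, s, classes, "side_chain_hydrophobic", 4.0)
        assert near == []

    def test_output_subset_of_input(self):
        s = self._pentagon_above_slab(3.0)
        classes = classify_atoms(s)
        g = water_network_from_frame(s, classes)
        rings = find_rings(g, 6)
        near = rings_near_class(rings, s, classes, "side_chain_hydrophobic", 4.0)
        assert all(r in rings for r in near)

    def test_unknown_class_raises(self):
        s = self._pentagon_above_slab(3.0)
        classes = classify_atoms(s)
        with pytest.raises(ValueError, match="no atoms of class"):
            rings_near_class([], s, classes, "bogus_class", 4.0)
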