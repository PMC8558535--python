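"""Surface-distance profiles, geometry maps, trends and contact maps."""

import numpy as np
import pytest

from hydracryst.core import (
    Atom,
    Box,
    Structure,
    Trajectory,
    classify_atoms,
    min_image_distance,
)
from hydracryst.hydration import (
    GeometryMap,
    HydrationProfile,
    ProfilePeaks,
    contact_map,
    default_bins,
    geometry_map,
    map_peak,
    peak_trends,
    surface_distance_profile,
)
from hydracryst.synth import make_toy_surface

from conftest import single_frame, water


def amide_site(x=0.0):
    """N-H group with H at (x+1, 0, 0)."""
    return [Atom(1, "N", "N", "GLY", 1, "A", [x, 0.0, 0.0]),
            Atom(2, "H", "H", "GLY", 1, "A", [x + 1.0, 0.0, 0.0])]


class TestSurfaceDistanceProfile:
    def test_single_water_lands_in_1p8_bin(self):
        atoms = amide_site() + water(1, [2.8, 0.0, 0.0], start_serial=3)
        s = Structure(atoms)
        prof = surface_distance_profile(single_frame(s), classify_atoms(s))
        # the measured distance is 1.8 A up to floating error, so the count
        # must sit in a bin whose edges touch 1.8
        for cls in ("main_chain", "whole_surface"):
            nz = np.nonzero(prof.counts[cls])[0]
            assert len(nz) == 1
            assert prof.bin_edges[nz[0]] <= 1.8 <= prof.bin_edges[nz[0] + 2]
            assert prof.counts[cls].sum() == 1.0

    def test_no_waters_all_zero(self):
        s = Structure(amide_site())
        prof = surface_distance_profile(single_frame(s), classify_atoms(s))
        for counts in prof.counts.values():
            assert counts.sum() == 0.0

    def test_matches_brute_force_minimum_distances(self, rng):
        surf = make_toy_surface(4, 4, seed=1)
        extra = []
        serial = max(a.serial for a in surf.atoms) + 1
        for i in range(12):
            extra += water(100 + i, rng.random(3) * 20, start_serial=serial)
            serial += 3
        s = Structure(surf.atoms + extra)
        classes = classify_atoms(s)
        prof = surface_distance_profile(single_frame(s), classes, r_max=40.0)
        # independent brute force for the whole-surface histogram
        protein = np.array([a.position for a in s.atoms
                            if classes[a.serial] not in ("water", "ion")])
        waters = np.array([a.position for a in s.atoms
                           if classes[a.serial] == "water" and a.name == "O"])
        dmin = np.array([np.linalg.norm(protein - w, axis=1).min() for w in waters])
        expected = np.histogram(dmin, bins=prof.bin_edges)[0]
        np.testing.assert_allclose(prof.counts["whole_surface"], expected)

    def test_profile_conservation(self):
        surf = make_toy_surface(5, 7, seed=2)
        classes = classify_atoms(surf)
        r_max = 6.0
        prof = surface_distance_profile(single_frame(surf), classes, r_max=r_max)
        n_within = 12  # all placed waters sit within 2.5 A of the surface
        assert prof.counts["whole_surface"].sum() == pytest.approx(n_within)

    def test_per_protein_normalisation(self):
        atoms = amide_site()
        atoms += [Atom(3, "N", "N", "GLY", 1, "B", [40.0, 0.0, 0.0]),
                  Atom(4, "H", "H", "GLY", 1, "B", [41.0, 0.0, 0.0])]
        atoms += water(1, [2.8, 0.0, 0.0], start_serial=5)
        s = Structure(atoms)
        prof = surface_distance_profile(single_frame(s), classify_atoms(s))
        assert prof.n_proteins == 2
        assert prof.counts["main_chain"].sum() == pytest.approx(0.5)

    def test_invalid_r_max(self):
        s = Structure(amide_site())
        with pytest.raises(ValueError):
            surface_distance_profile(single_frame(s), classify_atoms(s), r_max=-1)


class TestGeometryMap:
    def test_single_collinear_dimer_bin(self, collinear_dimer):
        traj = single_frame(collinear_dimer)
        m = geometry_map(traj, classify_atoms(collinear_dimer))
        # only the bond-forming hydrogen lands in the map; the three other
        # hydrogens of the proximal pair point away (theta > 90) and spill
        assert m.counts.sum() == 1
        assert m.spill == 3
        ri = int(np.digitize(2.8 - 0.9572, m.r_edges)) - 1
        assert m.r_centers[ri] == pytest.approx(1.85)
        assert m.counts[ri, 0] == 1

    def test_empty_trajectory_all_zero(self, collinear_dimer):
        traj = Trajectory(topology=collinear_dimer, frames=[])
        m = geometry_map(traj, classify_atoms(collinear_dimer))
        assert m.counts.sum() == 0

    def test_count_conservation_on_random_sample(self):
        from conftest import random_water_box
        s = random_water_box(64, 12.0, seed=5)
        classes = classify_atoms(s)
        m = geometry_map(single_frame(s), classes)
        # every scored geometry lands in a bin or in the spill register
        from hydracryst.core import class_array
        from hydracryst.hbonds import build_donor_acceptor_table, hb_geometry
        table = build_donor_acceptor_table(s, class_array(s, classes))
        pos, box = s.positions, s.box
        from hydracryst.core import min_image_distance
        n_scored = 0
        for d_i, h_i in table.donors:
            for a_i in table.acceptors:
                if a_i == d_i:
                    continue
                if s.atoms[a_i].residue_id == s.atoms[d_i].residue_id:
                    continue
                if min_image_distance(pos[d_i], pos[a_i], box) < 3.5:
                    n_scored += 1
        assert m.counts.sum() + m.spill == n_scored

    def test_invariant_to_rigid_motion_and_frame_order(self, collinear_dimer):
        from scipy.spatial.transform import Rotation
        s = collinear_dimer
        rot = Rotation.from_euler("xyz", [20, 40, 60], degrees=True).as_matrix()
        moved = s.with_positions(s.positions @ rot.T + np.array([3.0, -2.0, 5.0]))
        traj_a = Trajectory(topology=s, frames=[(s.positions, None),
                                                (moved.positions, None)])
        traj_b = Trajectory(topology=s, frames=[(moved.positions, None),
                                                (s.positions, None)])
        classes = classify_atoms(s)
        np.testing.assert_allclose(geometry_map(traj_a, classes).counts,
                                   geometry_map(traj_b, classes).counts)

    def test_unknown_pair_class(self, collinear_dimer):
        with pytest.raises(ValueError, match="pair class"):
            geometry_map(single_frame(collinear_dimer),
                         classify_atoms(collinear_dimer), pair_class="water-ion")


class TestMapPeak:
    def _map_with(self, hot_bins):
        r_edges, t_edges = default_bins()
        counts = np.zeros((len(r_edges) - 1, len(t_edges) - 1))
        for (ri, ti), v in hot_bins.items():
            counts[ri, ti] = v
        return GeometryMap(r_edges=r_edges, theta_edges=t_edges,
                           counts=counts, pair_class="water-water")

    def test_single_bin_peak(self):
        # bin centred at (2.05, 17.5)
        m = self._map_with({(8, 3): 5.0})
        assert map_peak(m) == (pytest.approx(2.05), pytest.approx(17.5))

    def test_tie_breaks_toward_smaller_r_then_theta(self):
        m = self._map_with({(8, 3): 5.0, (4, 1): 5.0, (4, 6): 5.0})
        r_star, t_star = map_peak(m)
        assert r_star == pytest.approx(1.65)
        assert t_star == pytest.approx(7.5)

    def test_empty_map_raises(self):
        with pytest.raises(ValueError, match="empty"):
            map_peak(self._map_with({}))


class TestPeakTrends:
    def _profile(self, h, scale):
        edges = np.arange(0.0, 6.0 + 0.05, 0.1)
        counts = {}
        base = np.zeros(len(edges) - 1)
        base[18] = 2.0   # bin containing 1.8 A
        base[25] = 3.0   # bin containing 2.5 A
        for cls in ("main_chain", "hydrophilic", "hydrophobic", "whole_surface"):
            counts[cls] = base * scale
        return HydrationProfile(bin_edges=edges, counts=counts, h=h)

    def test_doubling_counts_doubles_trends(self):
        table = peak_trends([self._profile(0.1, 1.0), self._profile(0.2, 2.0)])
        lo = table[(table.h == 0.1) & (table["class"] == "hydrophilic")]
        hi = table[(table.h == 0.2) & (table["class"] == "hydrophilic")]
        assert hi[hi.distance == "hb"].value.item() == \
            2 * lo[lo.distance == "hb"].value.item()
        assert hi[hi.distance == "vdw"].value.item() == \
            2 * lo[lo.distance == "vdw"].value.item()

    def test_single_profile_single_h(self):
        table = peak_trends([self._profile(0.3, 1.0)], classes=("hydrophobic",))
        assert len(table) == 2  # hb and vdw rows
        assert set(table.h) == {0.3}

    def test_duplicate_h_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            peak_trends([self._profile(0.1, 1.0), self._profile(0.1, 2.0)])

    def test_monotone_fixture_gives_monotone_trends(self):
        profiles = [self._profile(h, s) for h, s in
                    [(0.1, 1.0), (0.2, 1.5), (0.4, 2.5)]]
        table = peak_trends(profiles)
        for cls in ("hydrophilic", "hydrophobic"):
            for dist in ("hb", "vdw"):
                vals = table[(table["class"] == cls)
                             & (table.distance == dist)].value.to_numpy()
                assert np.all(np.diff(vals) >= 0)


class TestContactMap:
    def _two_chain_frame(self, separation):
        atoms = []
        serial = 1
        for cid, offset in (("A", 0.0), ("B", separation)):
            for rid in range(1, 4):
                atoms.append(Atom(serial, "CA", "C", "ALA", rid, cid,
                                  [offset + 0.0, rid * 3.0, 0.0]))
                serial += 1
        return Structure(atoms, box=Box((200.0, 200.0, 200.0)))

    def test_close_residues_contact(self):
        cm = contact_map(self._two_chain_frame(3.9), "A", "B")
        assert cm.matrix.any()
        assert cm.matrix[0, 0]

    def test_distant_chains_all_false(self):
        cm = contact_map(self._two_chain_frame(50.0), "A", "B")
        assert not cm.matrix.any()

    def test_swap_transposes(self):
        f = self._two_chain_frame(4.0)
        ab = contact_map(f, "A", "B")
        ba = contact_map(f, "B", "A")
        np.testing.assert_array_equal(ab.matrix, ba.matrix.T)

    def test_identical_chains_rejected(self):
        with pytest.raises(ValueError):
            contact_map(self._two_chain_frame(4.0), "A", "A")
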