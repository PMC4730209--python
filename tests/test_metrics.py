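"""Geometric and energetic metrics: Rg, buried waters, H-bonds, rings, energies."""

import numpy as np
import pytest

from pepagg.metrics import (
    HBondCriteria,
    assign_lj_params,
    buried_waters,
    detect_hbonds,
    hbond_per_residue_table,
    interpeptide_energies,
    radius_of_gyration,
    ring_geometry,
    stacking_census,
    water_mediated_bridges,
)
from pepagg.model import Atom, AtomRole, Frame, Topology, Trajectory
from pepagg.synthetic import make_cluster_with_waters, make_ring_pair

from conftest import point_topology


def _frame(coords, box=1000.0):
    return Frame(time=0.0, coordinates=np.asarray(coords, float), box=[box] * 3)


class TestRadiusOfGyration:
    def test_two_equal_points(self):
        f = _frame([[0, 0, 0], [10, 0, 0]])
        rg, center = radius_of_gyration(f, [0, 1])
        assert rg == pytest.approx(5.0)
        np.testing.assert_allclose(center, [5, 0, 0])

    def test_single_atom_is_zero(self):
        rg, _ = radius_of_gyration(_frame([[3, 4, 5]]), [0])
        assert rg == 0.0

    def test_weighted_center(self):
        f = _frame([[0, 0, 0], [10, 0, 0]])
        _, center = radius_of_gyration(f, [0, 1], weights=np.array([3.0, 1.0]))
        np.testing.assert_allclose(center, [2.5, 0, 0])

    def test_group_split_across_periodic_boundary(self):
        f = Frame(time=0.0, coordinates=[[1.0, 5, 5], [19.0, 5, 5]], box=[20.0] * 3)
        rg, _ = radius_of_gyration(f, [0, 1])
        assert rg == pytest.approx(1.0)  # true separation 2 Å through the wall

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            radius_of_gyration(_frame([[0, 0, 0]]), [])


class TestBuriedWaters:
    def test_water_at_center_is_always_buried(self):
        frame, top = make_cluster_with_waters(8.0, 50, 0, 3, seed=4)
        idx = np.arange(50)
        _, center = radius_of_gyration(frame, idx)
        coords = frame.coordinates.copy()
        coords[50] = center  # drop one "outside" water onto the centre
        moved = Frame(time=0.0, coordinates=coords, box=frame.box)
        count, found = buried_waters(moved, top, ["A"])
        assert count == 1

    def test_no_waters_returns_zero(self):
        frame, top = make_cluster_with_waters(8.0, 50, 0, 0, seed=5)
        assert buried_waters(frame, top, ["A"]) == (0, [])

    def test_empty_cluster_rejected(self):
        frame, top = make_cluster_with_waters(8.0, 50, 1, 1, seed=6)
        with pytest.raises(ValueError, match="at least one"):
            buried_waters(frame, top, [])


def _hbond_atoms():
    """Donor hydroxyl + H on chain A, acceptor carbonyl O on chain B, water W."""
    return [
        Atom(0, "A", 1, "SER", "OG", AtomRole.SIDECHAIN, "O", 1.52, is_donor=True, is_acceptor=True),
        Atom(1, "A", 1, "SER", "HG", AtomRole.SIDECHAIN, "H", 1.20),
        Atom(2, "B", 1, "ALA", "O", AtomRole.MAINCHAIN, "O", 1.52, is_acceptor=True),
        Atom(3, "W", 1, "HOH", "OW", AtomRole.WATER, "O", 1.52, is_donor=True, is_acceptor=True),
    ]


class TestDetectHbonds:
    def test_linear_bond_inside_thresholds(self):
        top = Topology(_hbond_atoms())
        f = _frame([[0, 0, 0], [0.96, 0, 0], [2.9, 0, 0], [100, 100, 100]])
        bonds = detect_hbonds(f, top)
        pp = [b for b in bonds if b.partner_class == "P-P"]
        assert len(pp) == 1
        assert pp[0].donor == 0 and pp[0].acceptor == 2 and pp[0].hydrogen == 1
        assert pp[0].role_class == "SC-MC"

    def test_distance_beyond_cutoff_not_detected(self):
        top = Topology(_hbond_atoms())
        f = _frame([[0, 0, 0], [0.96, 0, 0], [5.0, 0, 0], [100, 100, 100]])
        assert [b for b in detect_hbonds(f, top) if b.partner_class == "P-P"] == []

    def test_bad_angle_rejected_when_hydrogen_present(self):
        top = Topology(_hbond_atoms())
        # H points away from the acceptor: angle D-H-A ~ 0 degrees
        f = _frame([[0, 0, 0], [-0.96, 0, 0], [2.9, 0, 0], [100, 100, 100]])
        assert [b for b in detect_hbonds(f, top) if b.partner_class == "P-P"] == []

    def test_water_bridge_gives_two_pw_bonds_and_one_bridge(self):
        atoms = [
            Atom(0, "A", 1, "ASN", "OD1", AtomRole.SIDECHAIN, "O", 1.52, is_acceptor=True),
            Atom(1, "B", 1, "ASN", "OD1", AtomRole.SIDECHAIN, "O", 1.52, is_acceptor=True),
            Atom(2, "W", 1, "HOH", "OW", AtomRole.WATER, "O", 1.52, is_donor=True, is_acceptor=True),
        ]
        top = Topology(atoms)
        f = _frame([[0, 0, 0], [5.6, 0, 0], [2.8, 0, 0]])
        bonds = detect_hbonds(f, top)
        pw = [b for b in bonds if b.partner_class == "P-W"]
        assert len(pw) == 2
        bridges = water_mediated_bridges(bonds, top)
        assert len(bridges) == 1
        assert bridges[0][3] == "SC-SC"

    def test_same_chain_partners_make_no_bridge(self):
        atoms = [
            Atom(0, "A", 1, "ASN", "OD1", AtomRole.SIDECHAIN, "O", 1.52, is_acceptor=True),
            Atom(1, "A", 2, "ASN", "OD1", AtomRole.SIDECHAIN, "O", 1.52, is_acceptor=True),
            Atom(2, "W", 1, "HOH", "OW", AtomRole.WATER, "O", 1.52, is_donor=True, is_acceptor=True),
        ]
        top = Topology(atoms)
        f = _frame([[0, 0, 0], [5.6, 0, 0], [2.8, 0, 0]])
        bonds = detect_hbonds(f, top)
        assert len([b for b in bonds if b.partner_class == "P-W"]) == 2
        assert water_mediated_bridges(bonds, top) == []

    def test_two_independent_bridges_are_additive(self):
        atoms = []
        coords = []
        for k in range(2):
            base = k * 50.0
            atoms += [
                Atom(3 * k + 0, "A", k + 1, "ASN", "OD1", AtomRole.SIDECHAIN, "O", 1.52, is_acceptor=True),
                Atom(3 * k + 1, "B", k + 1, "ASN", "OD1", AtomRole.SIDECHAIN, "O", 1.52, is_acceptor=True),
                Atom(3 * k + 2, "W", k + 1, "HOH", "OW", AtomRole.WATER, "O", 1.52, is_donor=True, is_acceptor=True),
            ]
            coords += [[base, 0, 0], [base + 5.6, 0, 0], [base + 2.8, 0, 0]]
        bonds = detect_hbonds(_frame(coords), Topology(atoms))
        assert len(water_mediated_bridges(bonds, Topology(atoms))) == 2


def _frozen_mc_fixture(n_chains=27, n_res=4, n_bonds=11):
    """27 4-residue chains; exactly n_bonds cross-chain MC-MC contacts."""
    atoms = []
    coords = []
    aid = 0
    for c in range(n_chains):
        for r in range(n_res):
            x, y = 40.0 * c, 12.0 * r
            atoms.append(Atom(aid, f"c{c}", r + 1, "GLN", "N", AtomRole.MAINCHAIN, "N", 1.55, is_donor=True))
            coords.append([x, y, 0.0])
            aid += 1
            atoms.append(Atom(aid, f"c{c}", r + 1, "GLN", "O", AtomRole.MAINCHAIN, "O", 1.52, is_acceptor=True))
            coords.append([x, y, 6.0])
            aid += 1
    coords = np.array(coords)
    # pair donor of chain 2k, residue 1 with acceptor of chain 2k+1
    for k in range(n_bonds):
        donor_idx = (2 * k) * n_res * 2
        acceptor_idx = (2 * k + 1) * n_res * 2 + 1
        coords[acceptor_idx] = coords[donor_idx] + [2.9, 0.0, 0.0]
    top = Topology(atoms)
    frame = Frame(time=0.0, coordinates=coords, box=[2000.0] * 3)
    return top, frame


class TestHbondTable:
    def test_frozen_fixture_gives_11_over_108_per_residue(self):
        top, frame = _frozen_mc_fixture()
        traj = Trajectory(top, [frame, Frame(time=10.0, coordinates=frame.coordinates, box=frame.box)])
        table = hbond_per_residue_table(traj)
        assert table.loc["MC-MC", "P-P"] == pytest.approx(11 / 108)
        assert table.loc["SC-SC", "P-P"] == 0.0
        assert (table["P-W"] == 0).all()

    def test_no_bonds_gives_all_zeros(self):
        top, frame = _frozen_mc_fixture(n_bonds=0)
        traj = Trajectory(top, [frame])
        assert (hbond_per_residue_table(traj).to_numpy() == 0).all()

    def test_doubling_bond_count_doubles_entry(self):
        top1, frame1 = _frozen_mc_fixture(n_bonds=5)
        top2, frame2 = _frozen_mc_fixture(n_bonds=10)
        t1 = hbond_per_residue_table(Trajectory(top1, [frame1]))
        t2 = hbond_per_residue_table(Trajectory(top2, [frame2]))
        assert t2.loc["MC-MC", "P-P"] == pytest.approx(2 * t1.loc["MC-MC", "P-P"])


class TestRingGeometry:
    def test_collinear_atoms_rejected(self):
        f = _frame([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 5, 0], [1, 5, 0], [0, 5, 1]])
        with pytest.raises(ValueError, match="collinear"):
            ring_geometry(f, [0, 1, 2], [3, 4, 5])

    def test_census_all_parallel_is_face_to_face(self):
        frame, top = make_ring_pair(3.5, 0.0, 0.0)
        census = stacking_census(Trajectory(top, [frame]))
        row = census.iloc[0]
        assert (row["face_to_face"], row["t_stack"], row["other"]) == (1, 0, 0)

    def test_census_perpendicular_is_t_stack(self):
        frame, top = make_ring_pair(5.0, 90.0, 90.0)
        census = stacking_census(Trajectory(top, [frame]))
        row = census.iloc[0]
        assert (row["face_to_face"], row["t_stack"], row["other"]) == (0, 1, 0)

    def test_census_excludes_pairs_beyond_cutoff(self):
        frame, top = make_ring_pair(6.0, 0.0, 0.0)
        census = stacking_census(Trajectory(top, [frame]), r_cen_max=5.5)
        assert census.iloc[0][["face_to_face", "t_stack", "other"]].sum() == 0


class TestEnergies:
    def test_coulomb_closed_form_100_kcal(self):
        top = point_topology(2, charge=1.0)
        f = _frame([[0, 0, 0], [3.320636, 0, 0]])
        res = interpeptide_energies(f, top, dielectric=1.0, include_vdw=False)
        assert res.coulomb_total == pytest.approx(100.0, rel=1e-9)

    def test_dielectric_80_scales_to_1_25(self):
        top = point_topology(2, charge=1.0)
        f = _frame([[0, 0, 0], [3.320636, 0, 0]])
        res = interpeptide_energies(f, top, dielectric=80.0, include_vdw=False)
        assert res.coulomb_total == pytest.approx(1.25, rel=1e-9)

    def test_lj_minimum_is_minus_epsilon(self):
        top = assign_lj_params(point_topology(2), epsilon=0.5, sigma=3.4)
        r_min = 2 ** (1 / 6) * 3.4
        f = _frame([[0, 0, 0], [r_min, 0, 0]])
        res = interpeptide_energies(f, top)
        assert res.vdw_total == pytest.approx(-0.5, rel=1e-12)

    def test_pair_order_symmetry_and_inverse_dielectric(self):
        rng = np.random.default_rng(8)
        top = assign_lj_params(point_topology(4, charge=0.5), epsilon=0.2, sigma=3.0)
        f = _frame(rng.uniform(0, 20, (4, 3)))
        e1 = interpeptide_energies(f, top, dielectric=1.0)
        e4 = interpeptide_energies(f, top, dielectric=4.0)
        assert e1.coulomb_total == pytest.approx(4.0 * e4.coulomb_total, rel=1e-12)
        assert e1.vdw_total == pytest.approx(e4.vdw_total)  # vdW independent of epsilon_r
        pairs = e1.pairs.set_index(["peptide_i", "peptide_j"])
        assert len(pairs) == 6  # all unordered pairs reported once

    def test_missing_lj_parameters_is_hard_error(self):
        top = point_topology(2)
        f = _frame([[0, 0, 0], [4, 0, 0]])
        with pytest.raises(ValueError, match="LJ parameters"):
            interpeptide_energies(f, top)

    def test_sign_pattern_charged_vs_sticky_clusters(self):
        rng = np.random.default_rng(9)
        # compact blob of 6 single-bead peptides
        coords = rng.uniform(0, 6, (6, 3))
        charged = point_topology(6, charge=1.0)
        res_c = interpeptide_energies(_frame(coords), charged, include_vdw=False)
        assert res_c.coulomb_total > 0  # like charges destabilise the cluster
        neutral = assign_lj_params(point_topology(6), epsilon=0.3, sigma=3.5)
        # place beads near the LJ minimum of their neighbours
        ring = 3.93 * np.array(
            [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
        )
        res_n = interpeptide_energies(_frame(ring + 50.0), neutral)
        assert res_n.vdw_total < 0  # attraction stabilises the sticky cluster
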