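"""Contact graph, cluster sizes, MCS statistics and robustness sweeps."""

import numpy as np
import pytest

from pepagg.clusters import (
    ClusterLabeling,
    ContactSpec,
    analyze_trajectory,
    cluster_sizes,
    contact_graph,
    parameter_sweep,
    window_average,
)
from pepagg.model import Frame, Trajectory
from pepagg.synthetic import SimulationParams, make_grid_configuration, simulate_sticky_spheres

from conftest import brute_force_components, brute_force_contacts, point_topology


def _frame(coords, box=100.0):
    return Frame(time=0.0, coordinates=np.asarray(coords, float), box=[box] * 3)


class TestContactGraph:
    def test_threshold_arithmetic_carbon_pair(self):
        top = point_topology(2, radius=1.70)
        close = _frame([[10, 10, 10], [13.3, 10, 10]])
        far = _frame([[10, 10, 10], [13.5, 10, 10]])
        assert contact_graph(close, top)[0, 1]          # 3.3 < 3.40
        assert not contact_graph(far, top)[0, 1]        # 3.5 > 3.40

    def test_padding_turns_noncontact_into_contact(self):
        top = point_topology(2, radius=1.70)
        f = _frame([[10, 10, 10], [13.5, 10, 10]])
        assert not contact_graph(f, top, ContactSpec(padding=0.0))[0, 1]
        assert contact_graph(f, top, ContactSpec(padding=0.7))[0, 1]

    def test_min_pairs_requires_enough_atom_pairs(self):
        # two 2-bead chains sharing exactly one qualifying atom pair
        frame, top = make_grid_configuration(2, spacing=30.0, box_edge=100.0, beads_per_peptide=2)
        c = frame.coordinates.copy()
        c[2] = c[1] + [3.5, 0.0, 0.0]   # one cross-chain pair inside 4.0 Å
        c[3] = c[2] + [3.8, 0.0, 0.0]
        f = _frame(c)
        assert contact_graph(f, top, ContactSpec(min_pairs=1))[0, 1]
        assert not contact_graph(f, top, ContactSpec(min_pairs=2))[0, 1]

    def test_contact_across_periodic_boundary(self):
        top = point_topology(2, radius=1.70)
        f = _frame([[0.5, 10, 10], [99.0, 10, 10]])  # 1.5 Å through the wall
        assert contact_graph(f, top)[0, 1]

    def test_strict_inequality_at_threshold(self):
        top = point_topology(2, radius=1.70)
        f = _frame([[10, 10, 10], [13.4, 10, 10]])  # exactly the radius sum
        assert not contact_graph(f, top)[0, 1]


class TestClusterSizes:
    def test_chain_plus_isolated(self):
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        labels, cs = cluster_sizes(adj)
        assert list(cs) == [3, 3, 3, 1]
        assert labels[0] == labels[1] == labels[2] != labels[3]

    def test_no_edges_all_monomers(self):
        _, cs = cluster_sizes(np.zeros((27, 27), bool))
        assert (cs == 1).all()
        assert cs.mean() == 1.0

    def test_complete_graph_single_cluster(self):
        adj = ~np.eye(27, dtype=bool)
        _, cs = cluster_sizes(adj)
        assert (cs == 27).all()
        assert cs.mean() == 27.0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_closure_on_random_graphs(self, trial):
        rng = np.random.default_rng(trial)
        n = rng.integers(2, 9)
        adj = rng.random((n, n)) < 0.3
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        labels, cs = cluster_sizes(adj)
        ref = brute_force_components(adj)
        # same partition up to label names
        for i in range(n):
            for j in range(n):
                assert (labels[i] == labels[j]) == (ref[i] == ref[j])
        ref_sizes = np.bincount(ref)[ref]
        assert (cs == ref_sizes).all()


class TestAnalyzeTrajectory:
    def test_two_frame_toy_mcs_formula(self):
        top = point_topology(3, radius=1.70)
        f1 = Frame(time=0.0, coordinates=[[10, 10, 10], [20, 10, 10], [30, 10, 10]], box=[100] * 3)
        f2 = Frame(time=10.0, coordinates=[[10, 10, 10], [13, 10, 10], [30, 10, 10]], box=[100] * 3)
        lab = analyze_trajectory(Trajectory(top, [f1, f2]))
        np.testing.assert_allclose(lab.mcs_series, [1.0, 5 / 3])
        assert list(lab.monomer_series) == [3, 1]
        assert list(lab.monomer_dimer_series) == [3, 3]

    def test_mcs_identity_sum_cs_equals_sum_s_squared(self):
        rng = np.random.default_rng(5)
        top = point_topology(10, radius=2.0)
        frames = [
            Frame(time=10.0 * k, coordinates=rng.uniform(0, 30, (10, 3)), box=[30] * 3)
            for k in range(5)
        ]
        lab = analyze_trajectory(Trajectory(top, frames))
        for k in range(5):
            sizes = np.bincount(lab.labels[k])
            sizes = sizes[sizes > 0]
            assert lab.cs[k].sum() / 10 == pytest.approx((sizes ** 2).sum() / 10)

    def test_mcs_bounds_and_monomer_equivalence(self):
        rng = np.random.default_rng(6)
        top = point_topology(8, radius=2.0)
        frames = [
            Frame(time=10.0 * k, coordinates=rng.uniform(0, 25, (8, 3)), box=[25] * 3)
            for k in range(10)
        ]
        lab = analyze_trajectory(Trajectory(top, frames))
        assert ((lab.mcs_series >= 1.0) & (lab.mcs_series <= 8.0)).all()
        for k in range(10):
            assert (lab.mcs_series[k] == 1.0) == (lab.monomer_series[k] == 8)


class TestWindowAverage:
    def _lab(self, mcs_values):
        n = 4
        cs = np.array([[int(v)] * n for v in mcs_values])
        return ClusterLabeling(
            times=np.arange(len(mcs_values)) * 10.0,
            labels=np.zeros_like(cs),
            cs=cs,
            n_peptides=n,
        )

    def test_constant_series(self):
        lab = self._lab([27, 27, 27])
        mcs, _ = window_average(lab, 0.0, 20.0)
        assert mcs == 27.0

    def test_simple_mean(self):
        lab = self._lab([1, 2, 3])
        mcs, _ = window_average(lab, 0.0, 20.0)
        assert mcs == 2.0

    def test_empty_window_is_hard_error(self):
        lab = self._lab([1, 2, 3])
        with pytest.raises(ValueError, match="window"):
            window_average(lab, 100.0, 200.0)


@pytest.fixture(scope="module")
def short_traj():
    frame, top = make_grid_configuration(8, spacing=12.0, box_edge=40.0)
    params = SimulationParams(
        n_peptides=8, box_edge=40.0, epsilon_attract=5.0,
        n_steps=20_000, save_interval=1_000, seed=7,
    )
    return simulate_sticky_spheres((frame, top), params)


class TestParameterSweep:
    def test_mcs_monotone_in_padding_and_min_pairs(self, short_traj):
        sweep = parameter_sweep(short_traj, [0.0, 0.7, 1.4, 2.1, 2.8], [1, 2, 3])
        for mp in (1, 2, 3):
            series = [
                row["labeling"].mcs_series
                for _, row in sweep[sweep["min_pairs"] == mp].sort_values("padding").iterrows()
            ]
            for a, b in zip(series, series[1:]):
                assert (b >= a - 1e-12).all()
        for pad in (0.0, 0.7, 1.4, 2.1, 2.8):
            series = [
                row["labeling"].mcs_series
                for _, row in sweep[sweep["padding"] == pad].sort_values("min_pairs").iterrows()
            ]
            for a, b in zip(series, series[1:]):
                assert (b <= a + 1e-12).all()

    def test_default_setting_matches_analyze_trajectory(self, short_traj):
        sweep = parameter_sweep(short_traj, [0.0], [1])
        direct = analyze_trajectory(short_traj)
        np.testing.assert_array_equal(
            sweep.iloc[0]["labeling"].mcs_series, direct.mcs_series
        )

    def test_empty_grid_rejected(self, short_traj):
        with pytest.raises(ValueError, match="non-empty"):
            parameter_sweep(short_traj, [], [1])


class TestContactOracle:
    @pytest.mark.parametrize("trial", range(10))
    def test_kdtree_contacts_match_double_loop(self, trial):
        rng = np.random.default_rng(100 + trial)
        frame, top = make_grid_configuration(
            n_peptides=6, spacing=8.0, box_edge=30.0, beads_per_peptide=3
        )
        coords = np.mod(
            frame.coordinates + rng.normal(0, 3.0, frame.coordinates.shape), 30.0
        )
        f = Frame(time=0.0, coordinates=coords, box=[30.0] * 3)
        for pad, mp in [(0.0, 1), (1.4, 1), (0.7, 2)]:
            fast = contact_graph(f, top, ContactSpec(pad, mp))
            slow = brute_force_contacts(f, top, pad, mp)
            np.testing.assert_array_equal(fast, slow)
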