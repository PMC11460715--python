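"""Graph thresholding and subnetwork measures against brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from densefc import graphs, synth
from densefc.connectivity import Adjacency


def _random_symmetric(rng, n, loc=0.0):
    w = rng.standard_normal((n, n)) + loc
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


class TestMstThreshold:
    def test_exact_edge_count_small_case(self):
        # 4 nodes, density 0.5 -> 3 of 6 pairs; MST edges are the 3 strongest
        w = np.array(
            [
                [0, 0.9, 0.1, 0.2],
                [0.9, 0, 0.8, 0.3],
                [0.1, 0.8, 0, 0.7],
                [0.2, 0.3, 0.7, 0],
            ]
        )
        g = graphs.mst_threshold(w, 0.5)
        assert sorted(g.edges) == [(0, 1), (1, 2), (2, 3)]

    def test_tie_break_deterministic(self):
        w = np.ones((5, 5)) - np.eye(5)
        g1 = graphs.mst_threshold(w, 0.5)
        g2 = graphs.mst_threshold(w, 0.5)
        assert g1.edges == g2.edges
        assert len(g1.edges) == 5  # ceil(0.5 * 10)

    def test_connected_at_all_densities(self, rng):
        w = _random_symmetric(rng, 15)
        for density in (0.10, 0.20, 0.30):
            g = graphs.mst_threshold(w, density)
            G = nx.Graph(g.edges)
            G.add_nodes_from(range(15))
            assert nx.is_connected(G)

    def test_contains_every_mst_edge(self, rng):
        w = _random_symmetric(rng, 12)
        g = graphs.mst_threshold(w, 0.3)
        G = nx.from_numpy_array(w)
        mst = nx.maximum_spanning_tree(G)
        for i, j in mst.edges:
            assert tuple(sorted((i, j))) in g.edges

    def test_matches_brute_force_oracle(self, rng):
        # oracle: networkx maximum spanning tree + exhaustive ranking of the
        # remaining positive links (weights are continuous, so tie-free)
        for trial in range(5):
            w = _random_symmetric(rng, 20, loc=0.2)
            density = 0.2
            g = graphs.mst_threshold(w, density)

            G = nx.from_numpy_array(w)
            mst_edges = {tuple(sorted(e)) for e in nx.maximum_spanning_tree(G).edges}
            rest = sorted(
                (e for e in itertools.combinations(range(20), 2) if e not in mst_edges),
                key=lambda e: -w[e],
            )
            target = int(np.ceil(density * 190))
            expected = set(mst_edges)
            for e in rest:
                if len(expected) >= target or w[e] <= 0:
                    break
                expected.add(e)
            assert set(g.edges) == expected

    def test_low_density_returns_mst(self, rng):
        w = _random_symmetric(rng, 10)
        g = graphs.mst_threshold(w, 0.01)
        assert len(g.edges) == 9
        assert g.density > 0.01

    def test_no_negative_links_beyond_tree(self):
        w = -np.abs(_random_symmetric(np.random.default_rng(3), 8)) - 0.1
        np.fill_diagonal(w, 0)
        g = graphs.mst_threshold(w, 0.9)
        assert len(g.edges) == 7  # only the tree; no positive links exist


class TestParticipation:
    def test_all_edges_inside_community_is_zero(self):
        g = graphs.BinaryGraph(4, [(0, 1), (0, 2)])
        pc = graphs.participation(g, np.array(["a", "a", "a", "b"]))
        assert pc[0] == 0.0

    def test_even_split_between_two_communities(self):
        g = graphs.BinaryGraph(3, [(0, 1), (0, 2)])
        pc = graphs.participation(g, np.array(["a", "a", "b"]))
        assert pc[0] == pytest.approx(0.5)

    def test_isolated_node_convention(self):
        g = graphs.BinaryGraph(3, [(0, 1)])
        pc = graphs.participation(g, np.array(["a", "b", "b"]))
        assert pc[2] == 0.0

    def test_matches_direct_count_oracle(self, rng):
        w = _random_symmetric(rng, 15)
        g = graphs.mst_threshold(w, 0.3)
        comm = rng.choice(["a", "b", "c"], 15)
        pc = graphs.participation(g, comm)
        adj = g.adjacency()
        for i in range(15):
            k = adj[i].sum()
            if k == 0:
                assert pc[i] == 0
                continue
            expected = 1.0
            for c in np.unique(comm):
                k_is = adj[i][comm == c].sum()
                expected -= (k_is / k) ** 2
            assert pc[i] == pytest.approx(expected)

    def test_random_graph_mean_pc_near_one_minus_inverse_m(self, rng):
        # edges uniform over nodes of m=4 equal communities -> mean PC ~ 1 - 1/4
        n, m = 80, 4
        comm = np.repeat(np.arange(m), n // m)
        pairs = list(itertools.combinations(range(n), 2))
        chosen = rng.choice(len(pairs), 1200, replace=False)
        g = graphs.BinaryGraph(n, [pairs[i] for i in chosen])
        pc = graphs.participation(g, comm)
        assert abs(pc.mean() - (1 - 1 / m)) < 0.02


class TestEfficiency:
    def test_complete_subgraph_is_one(self):
        g = graphs.BinaryGraph(4, [(0, 1), (0, 2), (1, 2), (2, 3)])
        comm = np.array(["a", "a", "a", "b"])
        assert graphs.efficiency_within(g, "a", comm) == pytest.approx(1.0)

    def test_path_graph_closed_form(self):
        g = graphs.BinaryGraph(3, [(0, 1), (1, 2)])
        comm = np.array(["a", "a", "a"])
        assert graphs.efficiency_within(g, "a", comm) == pytest.approx(5 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        g = graphs.BinaryGraph(4, [(0, 1), (2, 3)])
        comm = np.array(["a", "a", "a", "a"])
        # pairs: (01)=1, (23)=1, four disconnected pairs -> (1+1)/6
        assert graphs.efficiency_within(g, "a", comm) == pytest.approx(2 / 6)

    def test_singleton_network_undefined(self):
        g = graphs.BinaryGraph(2, [(0, 1)])
        assert np.isnan(graphs.efficiency_within(g, "b", np.array(["a", "b"])))

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(3):
            w = _random_symmetric(rng, 18)
            g = graphs.mst_threshold(w, 0.25)
            comm = np.array(["x"] * 18)
            adj = g.adjacency().astype(float)
            dist = np.where(adj > 0, 1.0, np.inf)
            np.fill_diagonal(dist, 0.0)
            for k in range(18):
                dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
            iu = np.triu_indices(18, 1)
            expected = np.mean(np.where(np.isinf(dist[iu]), 0, 1 / dist[iu]))
            assert graphs.efficiency_within(g, "x", comm) == pytest.approx(expected)


class TestMetricSeries:
    def _adjs(self, rng, n_sessions=4, n=12):
        out = []
        for d in range(n_sessions):
            w = _random_symmetric(rng, n, loc=0.3)
            np.fill_diagonal(w, 1.0)
            out.append(Adjacency(np.clip(w, -0.99, 0.99), "r", session_day=d))
        return out

    def test_identical_sessions_constant_series(self, rng, small_atlas):
        adj = self._adjs(rng, 1, 20)[0]
        adjs = [Adjacency(adj.weights.copy(), "r", d) for d in range(5)]
        table = graphs.metric_series(adjs, small_atlas, ["default_mode"])
        for _, sub in table.groupby(["metric", "threshold"]):
            assert sub["value"].nunique() == 1

    def test_efficiency_monotone_in_density(self, rng, small_atlas):
        adjs = self._adjs(rng, 3, 20)
        table = graphs.metric_series(adjs, small_atlas, ["default_mode"])
        eff = table[table["metric"] == "efficiency"]
        for day, sub in eff.groupby("session_day"):
            vals = sub.sort_values("threshold")["value"].to_numpy()
            assert np.all(np.diff(vals) >= -1e-12)

    def test_rows_complete(self, rng, small_atlas):
        adjs = self._adjs(rng, 3, 20)
        table = graphs.metric_series(adjs, small_atlas, ["default_mode", "somatomotor"])
        assert len(table) == 3 * 2 * 2 * 3  # sessions x networks x metrics x thresholds

    def test_unknown_network_rejected(self, rng, small_atlas):
        with pytest.raises(ValueError, match="not present"):
            graphs.metric_series(self._adjs(rng, 1, 20), small_atlas, ["nope"])

    def test_injected_densification_tracks_covariate(self):
        # sessions whose target within-network links strengthen with a factor
        # show an efficiency series that correlates positively with it
        rng = np.random.default_rng(31)
        cfg = synth.SynthConfig(
            n_sessions=16, n_days=90, n_rois=16, n_networks=4,
            session_days=synth.default_session_days(16), n_time=500,
            base_within=0.15, seed=31,
        )
        atlas = synth.gen_atlas(16, 4, seed=31)
        behav = synth.gen_behavior(cfg)
        # default_mode nodes are 0,4,8,12 (round-robin): densify two disjoint links
        eff_spec = synth.EffectSpec(
            target_links=[(0, 4), (8, 12)], factor_name="steps",
            lag_days=0, slope=1.2, base_corr=0.1,
        )
        sessions, _ = synth.gen_sessions(cfg, atlas, behav, [eff_spec])
        from densefc import connectivity as conn

        adjs = [
            conn.pearson_adjacency(s.data, session_day=s.session_day) for s in sessions
        ]
        table = graphs.metric_series(adjs, atlas, ["default_mode"], densities=(0.10,))
        eff = table[table["metric"] == "efficiency"].sort_values("session_day")
        f = behav.truth["steps"].loc[cfg.session_days].to_numpy()
        assert np.corrcoef(eff["value"], f)[0, 1] > 0
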