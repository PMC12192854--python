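from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from allonet import network, synth
from allonet.io import DomainMap, Ensemble
from allonet.network import (CorrelationMatrix, build_graph, betweenness,
                             dccm, dccm_similarity, detect_communities,
                             integration_module, threshold_consistency,
                             top_connectors)


def _matrix(values, res_ids=None):
    values = np.asarray(values, dtype=float)
    if res_ids is None:
        res_ids = np.arange(1, len(values) + 1)
    return CorrelationMatrix(values, np.asarray(res_ids))


class TestDCCM:
    def test_hand_toy_matches_manual_computation(self):
        coords = np.array([
            [[0.0, 0, 0], [10, 0, 0], [20, 3, 1]],
            [[1.0, 1, 0], [10, 2, 0], [21, 3, 0]],
            [[0.5, 0, 1], [11, 0, 1], [20, 4, 1]],
            [[0.0, 2, 0], [10, 1, 2], [22, 3, 2]],
        ])
        ens = Ensemble(coords, np.arange(3))
        got = dccm(ens, align=False).values
        dev = coords - coords.mean(axis=0, keepdims=True)
        manual = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                num = np.mean([dev[f, i] @ dev[f, j] for f in range(4)])
                den = np.sqrt(np.mean([dev[f, i] @ dev[f, i] for f in range(4)])
                              * np.mean([dev[f, j] @ dev[f, j] for f in range(4)]))
                manual[i, j] = num / den
        np.testing.assert_allclose(got, manual, atol=1e-10)

    def test_identical_motion_fully_correlated(self, rng):
        disp = rng.standard_normal((30, 1, 3))
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        coords = base[None] + np.concatenate([disp, disp], axis=1)
        c = dccm(Ensemble(coords, np.arange(2)), align=False).values
        np.testing.assert_allclose(c[0, 1], 1.0, atol=1e-12)

    def test_mirrored_motion_anticorrelated(self, rng):
        disp = rng.standard_normal((30, 1, 3))
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        coords = base[None] + np.concatenate([disp, -disp], axis=1)
        c = dccm(Ensemble(coords, np.arange(2)), align=False).values
        np.testing.assert_allclose(c[0, 1], -1.0, atol=1e-12)

    def test_invariants_on_random_ensembles(self, rng):
        for _ in range(5):
            coords = rng.standard_normal((40, 8, 3)) * 2.0
            coords[:, :, 0] += np.linspace(0, 30, 8)
            c = dccm(Ensemble(coords, np.arange(8))).values
            np.testing.assert_allclose(c, c.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
            assert np.abs(c).max() <= 1.0 + 1e-12

    def test_zero_variance_residue_warns_and_zeroes(self):
        coords = np.zeros((10, 3, 3))
        coords[:, 0, 0] = np.arange(10.0)
        coords[:, 1, 1] = np.arange(10.0) * -1
        coords[:, 2] = 5.0   # static residue
        with pytest.warns(UserWarning, match="zero-variance"):
            c = dccm(Ensemble(coords, np.arange(3)), align=False).values
        assert c[2, 0] == 0.0 and c[2, 2] == 1.0


class TestSimilarity:
    def test_self_similarity_is_one(self, rng):
        m = _matrix(np.corrcoef(rng.standard_normal((5, 30))))
        r, p = dccm_similarity(m, m)
        np.testing.assert_allclose(r, 1.0)

    def test_negated_off_diagonal_gives_minus_one(self, rng):
        a = np.corrcoef(rng.standard_normal((5, 30)))
        b = -a.copy()
        np.fill_diagonal(b, 1.0)
        r, _ = dccm_similarity(_matrix(a), _matrix(b))
        np.testing.assert_allclose(r, -1.0)

    def test_matches_flattened_pearson(self, rng):
        a = np.corrcoef(rng.standard_normal((6, 40)))
        b = np.corrcoef(rng.standard_normal((6, 40)))
        r, p = dccm_similarity(_matrix(a), _matrix(b))
        iu = np.triu_indices(6, k=1)
        want_r, want_p = stats.pearsonr(a[iu], b[iu])
        np.testing.assert_allclose([r, p], [want_r, want_p])

    def test_constant_matrix_rejected(self):
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        with pytest.raises(ValueError, match="constant"):
            dccm_similarity(_matrix(c), _matrix(c))


class TestGraph:
    def test_identity_matrix_gives_empty_edge_set(self):
        g = build_graph(_matrix(np.eye(5)))
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 5

    def test_boundary_value_excluded_by_strict_threshold(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = 0.8
        assert build_graph(_matrix(c), 0.8).number_of_edges() == 0
        c[0, 1] = c[1, 0] = 0.8000001
        assert build_graph(_matrix(c), 0.8).number_of_edges() == 1

    def test_planted_block_edge_count_matches_enumeration(self):
        dm = DomainMap.from_ranges({"SH3": [[1, 6]], "SH2": [[7, 12]]})
        spec = synth.CouplingSpec(intra_block_corr=0.85, baseline_corr=0.1)
        c = synth.build_planted_covariance(dm, spec)
        g = build_graph(_matrix(c, dm.res_ids), 0.8)
        expected = sum(1 for i, j in combinations(range(12), 2)
                       if abs(c[i, j]) > 0.8)
        assert g.number_of_edges() == expected

    def test_negative_correlations_enter_by_magnitude(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = -0.9
        g = build_graph(_matrix(c), 0.8)
        assert g.number_of_edges() == 1
        assert g.edges[0, 1]["corr"] == -0.9 and g.edges[0, 1]["weight"] == 0.9

    def test_edge_set_monotone_in_threshold(self, rng):
        c = np.corrcoef(rng.standard_normal((10, 12)))
        prev = None
        for t in (0.3, 0.5, 0.7, 0.9):
            edges = set(build_graph(_matrix(c), t).edges())
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_graph(_matrix(np.eye(3)), 1.5)

    def test_graphml_roundtrip(self, tmp_path, rng):
        c = np.corrcoef(rng.standard_normal((6, 15)))
        g = network.build_graph(_matrix(c), 0.3)
        p = tmp_path / "net.graphml"
        network.export_graphml(g, p)
        back = nx.read_graphml(p, node_type=int)
        assert set(back.nodes) == set(g.nodes)
        assert back.number_of_edges() == g.number_of_edges()


def _clique_matrix(groups, rho=0.9, n=None):
    if n is None:
        n = sum(len(g) for g in groups)
    c = np.eye(n)
    for g in groups:
        for i, j in combinations(g, 2):
            c[i, j] = c[j, i] = rho
    return c


class TestCommunities:
    def test_two_disconnected_cliques_found_exactly(self):
        dm = DomainMap.from_ranges({"SH3": [[1, 5]], "SH2": [[6, 10]]})
        c = _clique_matrix([range(5), range(5, 10)])
        g = build_graph(_matrix(c, dm.res_ids), 0.8)
        part = detect_communities(g, dm, seed=0)
        assert len(part.sizes) == 2
        mods = {part.module_of[0], part.module_of[5]}
        assert len(mods) == 2
        assert all(part.module_of[i] == part.module_of[0] for i in range(5))

    def test_single_region_clique_purity_one(self):
        dm = DomainMap.from_ranges({"SH3": [[1, 5]], "SH2": [[6, 10]]})
        c = _clique_matrix([range(5), range(5, 10)])
        g = build_graph(_matrix(c, dm.res_ids), 0.8)
        part = detect_communities(g, dm, seed=0)
        assert all(p == 1.0 for p in part.purity.values())

    def test_forced_mixed_module_purity(self):
        # 2 SH3 + 1 SH2 + 1 SH1N residues in one clique -> purity 0.5
        dm = DomainMap.from_ranges({"SH3": [[1, 2]], "SH2": [[3, 3]],
                                    "SH1N": [[4, 4]], "L": [[5, 8]]})
        c = _clique_matrix([range(4), range(4, 8)])
        g = build_graph(_matrix(c, dm.res_ids), 0.8)
        part = detect_communities(g, dm, seed=0)
        mid = part.module_of[0]
        assert part.purity[mid] == 0.5
        assert part.dominant_region[mid] == "SH3"

    def test_isolated_nodes_unassigned(self):
        dm = DomainMap.from_ranges({"SH3": [[1, 5]], "SH2": [[6, 10]]})
        c = _clique_matrix([range(4)], n=10)   # residues 5..10 isolated
        g = build_graph(_matrix(c, dm.res_ids), 0.8)
        part = detect_communities(g, dm, seed=0)
        assert part.unassigned == [4, 5, 6, 7, 8, 9]

    def test_empty_graph_rejected(self):
        dm = DomainMap.from_ranges({"SH3": [[1, 3]]})
        g = build_graph(_matrix(np.eye(3), dm.res_ids), 0.8)
        with pytest.raises(ValueError):
            detect_communities(g, dm, seed=0)


class TestIntegrationModule:
    def _partition(self, purities, sizes):
        from allonet.network import CommunityPartition
        return CommunityPartition(
            module_of={}, purity=dict(enumerate(purities)),
            dominant_region={i: "SH3" for i in range(len(purities))},
            sizes=dict(enumerate(sizes)), unassigned=[], modularity=0.5)

    def test_lowest_purity_selected(self):
        p = self._partition([1.0, 0.9, 0.4], [10, 10, 10])
        assert integration_module(p) == 2

    def test_tie_broken_by_size_then_id(self):
        p = self._partition([0.5, 0.5], [6, 10])
        assert integration_module(p) == 1
        q = self._partition([0.5, 0.5], [10, 10])
        assert integration_module(q) == 0

    def test_minimum_size_enforced(self):
        p = self._partition([0.2, 0.9], [3, 10])
        assert integration_module(p, min_size=4) == 1
        q = self._partition([0.2], [3])
        with pytest.raises(ValueError):
            integration_module(q, min_size=4)


def brute_force_betweenness(g: nx.Graph, weight="length"):
    """Exhaustive all-simple-paths shortest-path counting oracle."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        lengths = [sum(g.edges[u, v][weight] for u, v in zip(p, p[1:]))
                   for p in paths]
        best = min(lengths)
        shortest = [p for p, ell in zip(paths, lengths)
                    if ell <= best + 1e-12]
        for p in shortest:
            for v in p[1:-1]:
                score[v] += 1.0 / len(shortest)
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: s * norm for v, s in score.items()}


class TestBetweenness:
    def _graph_from_edges(self, n, edges):
        g = nx.Graph()
        for v in range(n):
            g.add_node(v, res_id=v + 1)
        for u, v, c in edges:
            g.add_edge(u, v, corr=c, weight=abs(c), length=-np.log(abs(c)))
        g.graph["length"] = "neglog"
        return g

    def test_three_node_path(self):
        g = self._graph_from_edges(3, [(0, 1, 0.9), (1, 2, 0.9)])
        prof = betweenness(g)
        np.testing.assert_allclose(prof.values, [0.0, 1.0, 0.0])

    def test_star_center_maximal(self):
        g = self._graph_from_edges(5, [(0, i, 0.9) for i in range(1, 5)])
        prof = betweenness(g)
        assert prof.values[0] == prof.values.max() > 0
        np.testing.assert_allclose(prof.values[1:], 0.0)

    def test_matches_exhaustive_oracle_on_random_graphs(self, rng):
        for trial in range(10):
            n = int(rng.integers(5, 11))
            g = nx.Graph()
            for v in range(n):
                g.add_node(v, res_id=v + 1)
            for i, j in combinations(range(n), 2):
                if rng.random() < 0.35:
                    c = float(rng.uniform(0.2, 0.99))
                    g.add_edge(i, j, corr=c, weight=c, length=-np.log(c))
            g.graph["length"] = "neglog"
            got = betweenness(g).values
            want = brute_force_betweenness(g)
            np.testing.assert_allclose(got, [want[v] for v in range(n)],
                                       atol=1e-10)

    def test_top_connectors_tie_break_by_residue_id(self):
        g = self._graph_from_edges(4, [(0, 1, 0.9), (1, 2, 0.9),
                                       (2, 3, 0.9)])
        prof = betweenness(g)
        top = top_connectors(prof, n=3)
        assert list(top[:2]) == [2, 3]     # equal scores -> lower id first


class TestThresholdConsistency:
    def test_always_and_never_top(self):
        dm = DomainMap.from_ranges({"SH3": [[1, 5]], "SH2": [[6, 10]]})
        # residue 5 bridges the two cliques at very high correlation
        c = _clique_matrix([range(5), range(5, 10)], rho=0.95)
        c[4, 5:] = c[5:, 4] = 0.93
        cons = threshold_consistency(_matrix(c, dm.res_ids), dm,
                                     thresholds=(0.7, 0.8, 0.9), n=1)
        assert cons[5] == 1.0
        assert cons[1] == 0.0

    def test_all_empty_thresholds_error(self):
        dm = DomainMap.from_ranges({"SH3": [[1, 3]]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                threshold_consistency(_matrix(np.eye(3), dm.res_ids), dm,
                                      thresholds=(0.9,))

    def test_values_are_threshold_fractions(self, compact_dm):
        spec = synth.CouplingSpec(intra_block_corr=0.9, baseline_corr=0.72,
                                  hub_residues=tuple(
                                      int(r) for r in compact_dm.residues_in("L")),
                                  hub_cross_corr=0.9)
        c = synth.build_planted_covariance(compact_dm, spec)
        cons = threshold_consistency(_matrix(c, compact_dm.res_ids),
                                     compact_dm, thresholds=(0.75, 0.8, 0.85))
        assert all(v in (0.0, 1 / 3, 2 / 3, 1.0) for v in cons.values())
        hub_mean = np.mean([cons[int(r)] for r in compact_dm.residues_in("L")])
        rest_mean = np.mean([cons[int(r)] for r in compact_dm.res_ids
                             if compact_dm.region_of[int(r)] != "L"])
        assert hub_mean > rest_mean
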