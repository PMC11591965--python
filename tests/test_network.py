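import itertools

import numpy as np
import pytest

from divnet.network import (
    DCCM,
    build_graph,
    betweenness,
    centrality_table,
    closeness,
    compute_dccm,
    degree,
    rank_top,
)
from divnet.traj import ResidueId, SuperpositionResult, Trajectory, superpose

from conftest import random_trajectory


def ids(n):
    return [ResidueId("A", i + 1, "ALA") for i in range(n)]


def graph_from_matrix(c, cutoff=0.5):
    return build_graph(DCCM(np.asarray(c, dtype=float), ids(len(c))), cutoff)


# ---------------------------------------------------------------------------
# Exhaustive shortest-path oracle (independent of networkx)


def oracle_centralities(n, weights):
    """Brute-force closeness/betweenness/degree via simple-path enumeration.

    ``weights``: dict {(i, j): w} with i < j. Returns three arrays using the
    conventions: closeness per connected component with component-local n;
    betweenness normalized by total n(n-1)/2, endpoints excluded.
    """
    adj = {i: set() for i in range(n)}
    for i, j in weights:
        adj[i].add(j)
        adj[j].add(i)

    def w(i, j):
        return weights[(i, j) if i < j else (j, i)]

    def all_paths(s, t):
        out = []

        def extend(path, cost):
            last = path[-1]
            if last == t:
                out.append((cost, path))
                return
            for nxt in adj[last]:
                if nxt not in path:
                    extend(path + [nxt], cost + w(last, nxt))

        extend([s], 0.0)
        return out

    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    passes = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        best = min(c for c, _ in paths)
        dist[s, t] = dist[t, s] = best
        shortest = [p for c, p in paths if c <= best + 1e-12]
        for node in range(n):
            if node in (s, t):
                continue
            frac = sum(node in p for p in shortest) / len(shortest)
            passes[node] += frac

    close = np.zeros(n)
    for i in range(n):
        reach = [j for j in range(n) if j != i and np.isfinite(dist[i, j])]
        if reach:
            close[i] = len(reach) / sum(dist[i, j] for j in reach)
    betw = passes / (n * (n - 1) / 2.0)
    deg = np.array([len(adj[i]) for i in range(n)])
    return close, betw, deg


def random_graph_weights(n, rng):
    weights = {}
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.45:
            weights[(i, j)] = float(rng.uniform(0.05, 2.0))
    return weights


def residue_graph_from_weights(n, weights):
    """Inject arbitrary positive weights by inverting w = -ln|C|."""
    c = np.eye(n)
    for (i, j), w in weights.items():
        c[i, j] = c[j, i] = np.exp(-w)
    # cutoff below the smallest kept correlation
    cutoff = min((np.exp(-w) for w in weights.values()), default=0.5) * 0.99
    cutoff = min(max(cutoff, 1e-6), 0.999999)
    return graph_from_matrix(c, cutoff)


# ---------------------------------------------------------------------------


class TestDCCM:
    def test_unit_diagonal_and_symmetry(self):
        sup = superpose(random_trajectory(20, 6, seed=0))
        d = compute_dccm(sup)
        np.testing.assert_array_equal(np.diag(d.matrix), 1.0)
        np.testing.assert_allclose(d.matrix, d.matrix.T, atol=1e-14)
        assert np.abs(d.matrix).max() <= 1.0

    def test_negated_motion_gives_minus_one(self):
        rng = np.random.default_rng(5)
        series = rng.standard_normal((10, 3))
        coords = np.zeros((10, 3, 3))
        coords[:, 0] = series
        coords[:, 1] = -series
        coords[:, 2] = rng.standard_normal((10, 3))
        sup = SuperpositionResult(
            aligned=Trajectory(coords, ids(3)),
            reference=coords.mean(axis=0),
        )
        d = compute_dccm(sup)
        assert abs(d.matrix[0, 1] + 1.0) < 1e-12

    def test_matches_direct_formula(self):
        """DCCM equals an independent elementwise evaluation of the
        normalized displacement covariance on a 4-residue toy trajectory."""
        t = random_trajectory(6, 4, seed=13)
        sup = superpose(t, reference="none")
        d = compute_dccm(sup)
        x = sup.aligned.coordinates
        mean = x.mean(axis=0)
        expected = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                di = x[:, i] - mean[i]
                dj = x[:, j] - mean[j]
                num = np.mean(np.sum(di * dj, axis=1))
                den = np.sqrt(
                    np.mean(np.sum(di * di, axis=1))
                    * np.mean(np.sum(dj * dj, axis=1))
                )
                expected[i, j] = num / den
        np.testing.assert_allclose(d.matrix, expected, atol=1e-12)

    def test_zero_fluctuation_residue_is_named(self):
        coords = np.zeros((5, 3, 3))
        coords[:, :2] = np.random.default_rng(0).standard_normal((5, 2, 3))
        sup = SuperpositionResult(
            aligned=Trajectory(coords, ids(3)), reference=coords.mean(axis=0)
        )
        with pytest.raises(ValueError, match="A:3:ALA"):
            compute_dccm(sup)

    def test_permutation_consistency(self):
        sup = superpose(random_trajectory(15, 5, seed=2))
        d = compute_dccm(sup)
        perm = np.array([3, 0, 4, 1, 2])
        coords = sup.aligned.coordinates[:, perm]
        sup_p = SuperpositionResult(
            aligned=Trajectory(coords, [sup.aligned.residue_ids[p] for p in perm]),
            reference=sup.reference[perm],
        )
        d_p = compute_dccm(sup_p)
        np.testing.assert_allclose(
            d_p.matrix, d.matrix[np.ix_(perm, perm)], atol=1e-12
        )


class TestGraph:
    def test_weight_convention(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 1.0
        c[1, 2] = c[2, 1] = np.exp(-1.0)
        g = graph_from_matrix(c, 0.3)
        assert g.graph[0][1]["weight"] == 0.0
        assert abs(g.graph[1][2]["weight"] - 1.0) < 1e-12

    def test_zero_correlation_never_an_edge(self):
        c = np.eye(3)
        g = graph_from_matrix(c, 1e-6)
        assert g.graph.number_of_edges() == 0

    def test_anticorrelation_uses_magnitude(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = -0.8
        g = graph_from_matrix(c, 0.5)
        assert g.graph.has_edge(0, 1)
        assert abs(g.graph[0][1]["weight"] + np.log(0.8)) < 1e-12

    def test_cutoff_validation(self):
        with pytest.raises(ValueError, match="cutoff"):
            graph_from_matrix(np.eye(3), 0.0)
        with pytest.raises(ValueError, match="cutoff"):
            graph_from_matrix(np.eye(3), 1.0)

    def test_raising_cutoff_never_raises_degree(self):
        sup = superpose(random_trajectory(30, 8, seed=4))
        d = compute_dccm(sup)
        prev = None
        for cutoff in (0.1, 0.3, 0.5, 0.7, 0.9):
            deg = degree(build_graph(d, cutoff))
            if prev is not None:
                assert np.all(deg <= prev)
            prev = deg


class TestCentralities:
    def path3(self):
        c = np.eye(3)
        w = np.exp(-1.0)  # unit edge weights
        c[0, 1] = c[1, 0] = w
        c[1, 2] = c[2, 1] = w
        return graph_from_matrix(c, 0.3)

    def test_path_closeness(self):
        cc = closeness(self.path3())
        assert abs(cc[1] - 1.0) < 1e-12
        assert abs(cc[0] - 2 / 3) < 1e-12
        assert abs(cc[2] - 2 / 3) < 1e-12

    def test_path_betweenness(self):
        b = betweenness(self.path3())
        assert abs(b[1] - 1 / 3) < 1e-12
        assert b[0] == 0 and b[2] == 0

    def test_complete_graph(self):
        n = 4
        c = np.full((n, n), np.exp(-1.0))
        np.fill_diagonal(c, 1.0)
        g = graph_from_matrix(c, 0.3)
        np.testing.assert_allclose(closeness(g), 1.0, atol=1e-12)
        np.testing.assert_array_equal(betweenness(g), 0.0)
        np.testing.assert_array_equal(degree(g), 3)

    def test_star_betweenness(self):
        c = np.eye(4)
        for leaf in (1, 2, 3):
            c[0, leaf] = c[leaf, 0] = np.exp(-1.0)
        g = graph_from_matrix(c, 0.3)
        assert abs(betweenness(g)[0] - 0.5) < 1e-12

    def test_isolated_node_closeness_zero(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.8
        g = graph_from_matrix(c, 0.5)
        assert closeness(g)[2] == 0.0

    def test_degree_matches_hand_count(self):
        rng = np.random.default_rng(8)
        c = rng.uniform(-1, 1, (6, 6))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        g = graph_from_matrix(c, 0.5)
        expected = ((np.abs(c) >= 0.5).sum(axis=1) - 1)  # minus diagonal
        np.testing.assert_array_equal(degree(g), expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        weights = random_graph_weights(n, rng)
        g = residue_graph_from_weights(n, weights)
        assert g.graph.number_of_edges() == len(weights)
        close_o, betw_o, deg_o = oracle_centralities(n, weights)
        np.testing.assert_allclose(closeness(g), close_o, atol=1e-10)
        np.testing.assert_allclose(betweenness(g), betw_o, atol=1e-10)
        np.testing.assert_array_equal(degree(g), deg_o)


class TestRanking:
    def table(self, c, cutoff=0.5):
        return centrality_table(graph_from_matrix(c, cutoff))

    def test_k_larger_than_n_returns_all(self):
        c = np.full((3, 3), 0.8)
        np.fill_diagonal(c, 1.0)
        top = rank_top(self.table(c), k=10)
        assert len(top["degree"]) == 3

    def test_tie_broken_by_residue_number(self):
        c = np.full((4, 4), 0.8)
        np.fill_diagonal(c, 1.0)
        top = rank_top(self.table(c), k=2)
        assert top["degree"] == ["A:1:ALA", "A:2:ALA"]

    def test_planted_hub_ranks_first_everywhere(self):
        from divnet.synthetic import hub_correlation_matrix

        c = hub_correlation_matrix(12, [5])
        top = rank_top(self.table(c), k=3)
        for measure in ("betweenness", "closeness", "degree"):
            assert top[measure][0] == "A:6:ALA"
        assert "A:6:ALA" in top["overlap"]
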