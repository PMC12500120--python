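"""Communication models against brute-force path and series oracles."""

import numpy as np
import pytest

from tusnet.comm import (
    build_comm_models,
    communicability,
    cost_matrix,
    model_vector,
    representative_distance,
    representative_weights,
    search_information,
    shortest_paths,
    spe,
)
from tusnet.exceptions import IsolatedNodeError
from tusnet.synthetic import Connectome


def brute_force_best_paths(L):
    """Enumerate all simple paths: minimal cost, lexicographically smallest."""
    n = L.shape[0]
    best_cost = np.full((n, n), np.inf)
    best_path = [[None] * n for _ in range(n)]

    def dfs(src, node, cost, path, visited):
        for nxt in range(n):
            if visited[nxt] or not np.isfinite(L[node, nxt]):
                continue
            c = cost + L[node, nxt]
            if c > best_cost[src, nxt] + 1e-12:
                continue
            p = path + (nxt,)
            if c < best_cost[src, nxt] - 1e-12 or (
                best_path[src][nxt] is None or p < best_path[src][nxt]
            ):
                if abs(c - best_cost[src, nxt]) > 1e-12 or (
                    best_path[src][nxt] is None or p < best_path[src][nxt]
                ):
                    best_cost[src, nxt] = min(best_cost[src, nxt], c)
                    best_path[src][nxt] = p
            visited[nxt] = True
            dfs(src, nxt, c, p, visited)
            visited[nxt] = False

    for src in range(n):
        best_cost[src, src] = 0.0
        best_path[src][src] = (src,)
        visited = np.zeros(n, dtype=bool)
        visited[src] = True
        dfs(src, src, 0.0, (src,), visited)
    return best_cost, best_path


def random_graph_weights(rng, n, density=0.5):
    w = rng.uniform(0.1, 1.0, (n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return w


class TestRepresentative:
    def _cohort(self, mats_w, mats_d):
        return [
            Connectome(f"s{i}", w, d)
            for i, (w, d) in enumerate(zip(mats_w, mats_d))
        ]

    def test_single_subject_max_maps_to_one(self, rng):
        d = np.array([[0, 100.0], [100.0, 0]])
        w = np.array([[0, 3.0], [3.0, 0]])
        cohort = self._cohort([w], [d])
        assert representative_distance(cohort)[0, 1] == 1.0
        assert representative_weights(cohort).max() == 1.0

    def test_two_identical_subjects(self, small_cohort):
        twice = [small_cohort[0], small_cohort[0]]
        once = [small_cohort[0]]
        assert np.allclose(
            representative_distance(twice), representative_distance(once)
        )

    def test_range_symmetry_diagonal(self, small_cohort):
        for rep in (representative_distance, representative_weights):
            m = rep(small_cohort)
            assert m.max() == 1.0
            assert np.all((m >= 0) & (m <= 1))
            assert np.allclose(m, m.T)
            assert np.all(np.diag(m) == 0)

    def test_all_zero_rejected(self):
        z = np.zeros((3, 3))
        with pytest.raises(ValueError):
            representative_weights([Connectome("s", z, z)])


class TestCostAndShortestPaths:
    def test_cost_entries(self):
        w = np.array([[0, 0.5, 0], [0.5, 0, 1.0], [0, 1.0, 0]])
        L = cost_matrix(w)
        assert L[0, 1] == 2.0
        assert L[1, 2] == 1.0
        assert np.isinf(L[0, 2])
        assert np.all(np.diag(L) == 0)

    def test_three_node_chain(self):
        L = np.array([[0, 1.0, np.inf], [1.0, 0, 1.0], [np.inf, 1.0, 0]])
        spl, routes = shortest_paths(L)
        assert spl[0, 2] == 2.0
        assert routes[0][2] == (0, 1, 2)
        assert np.all(np.diag(spl) == 0)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            w = random_graph_weights(rng, 7)
            L = cost_matrix(w / max(w.max(), 1e-12))
            spl, routes = shortest_paths(L)
            bc, bp = brute_force_best_paths(L)
            assert np.allclose(spl, bc, equal_nan=True)
            for i in range(7):
                for j in range(7):
                    if np.isfinite(bc[i, j]) and i != j:
                        assert routes[i][j] == bp[i][j]

    def test_lexicographic_tie_break(self):
        # two equal-cost routes 0-1-3 and 0-2-3; the smaller sequence wins
        L = np.full((4, 4), np.inf)
        np.fill_diagonal(L, 0.0)
        for a, b in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            L[a, b] = L[b, a] = 1.0
        _, routes = shortest_paths(L)
        assert routes[0][3] == (0, 1, 3)

    def test_triangle_inequality(self, small_cohort):
        models = build_comm_models(small_cohort)
        spl = models.spl
        n = spl.shape[0]
        for j in range(n):
            lhs = spl
            rhs = spl[:, [j]] + spl[[j], :]
            assert np.all(lhs <= rhs + 1e-9)


class TestEfficiencyAndSearchInformation:
    def test_spe_values(self):
        spl = np.array([[0, 2.0, np.inf], [2.0, 0, 4.0], [np.inf, 4.0, 0]])
        e = spe(spl)
        assert e[0, 1] == 0.5
        assert e[0, 2] == 0.0
        assert np.all(np.isnan(np.diag(e)))

    def test_chain_one_bit(self):
        # uniform chain 0-1-2: walker at 0 must go to 1 (T=1), then has two
        # options at 1 (T=1/2): SI(0->2) = -log2(1 * 1/2) = 1 bit
        w = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
        L = cost_matrix(w)
        _, routes = shortest_paths(L)
        si = search_information(w, routes)
        assert si[0, 2] == pytest.approx(1.0)
        assert si[0, 1] == pytest.approx(0.0)  # single neighbor, one hop

    def test_asymmetry(self, rng):
        w = random_graph_weights(rng, 6, density=0.8)
        L = cost_matrix(w / w.max())
        _, routes = shortest_paths(L)
        si = search_information(w, routes)
        off = ~np.eye(6, dtype=bool)
        assert not np.allclose(si[off], si.T[off])

    def test_matches_hand_enumeration(self, rng):
        for _ in range(10):
            w = random_graph_weights(rng, 6, density=0.7)
            if np.any(w.sum(axis=1) == 0):
                continue
            L = cost_matrix(w / w.max())
            _, routes = shortest_paths(L)
            si = search_information(w, routes)
            T = w / w.sum(axis=1, keepdims=True)
            for i in range(6):
                for j in range(6):
                    if i == j or routes[i][j] is None:
                        continue
                    prob = 1.0
                    for a, b in zip(routes[i][j][:-1], routes[i][j][1:]):
                        prob *= T[a, b]
                    assert si[i, j] == pytest.approx(-np.log2(prob), rel=1e-10)

    def test_isolated_node_error(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(IsolatedNodeError):
            search_information(w, [[None] * 3] * 3)


class TestCommunicability:
    def test_zero_weights_need_strength(self):
        with pytest.raises(IsolatedNodeError):
            communicability(np.zeros((3, 3)))

    def test_matches_truncated_series(self, rng):
        for _ in range(10):
            w = random_graph_weights(rng, 6, density=0.8)
            if np.any(w.sum(axis=1) == 0):
                continue
            for norm in ("as_printed", "symmetric_sqrt"):
                cmy = communicability(w, normalization=norm)
                s = w.sum(axis=1)
                wp = w / np.outer(s, s) if norm == "as_printed" else w / np.sqrt(
                    np.outer(s, s)
                )
                series = np.eye(6)
                term = np.eye(6)
                for k in range(1, 41):
                    term = term @ wp / k
                    series = series + term
                assert np.allclose(cmy, series, atol=1e-10)
                assert np.allclose(cmy, cmy.T, atol=1e-12)

    def test_entries_dominate_identity(self, rng):
        w = random_graph_weights(rng, 6, density=0.9)
        cmy = communicability(w)
        assert np.all(cmy - np.eye(6) >= -1e-12)


class TestModelVector:
    def test_seed_row_of_symmetric_is_column(self, small_cohort):
        m = build_comm_models(small_cohort).cmy
        assert np.allclose(model_vector(m, "seed_row", target=3), m[:, 3])

    def test_node_summary_in_unit_interval(self, small_cohort):
        v = model_vector(build_comm_models(small_cohort).distance, "node_summary")
        assert v.min() == 0.0 and v.max() == 1.0

    def test_constant_matrix_warns_all_zero(self):
        m = np.ones((4, 4))
        with pytest.warns(RuntimeWarning, match="constant"):
            v = model_vector(m, "node_summary")
        assert np.all(v == 0)

    def test_bad_target(self):
        with pytest.raises(ValueError):
            model_vector(np.eye(3), "seed_row", target=5)
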