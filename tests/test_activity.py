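"""Activity measures, including a brute-force betweenness oracle."""

import itertools

import numpy as np
import pytest

from metacci.activity import (
    activity_score,
    betweenness,
    hubness,
    regulatory_effect,
)
from metacci.grn import GeneNetwork


def net_from_edges(p, edges, weights=None):
    coef = np.zeros((p, p))
    for k, (i, j) in enumerate(edges):
        coef[i, j] = 1.0 if weights is None else weights[k]
    return GeneNetwork([f"g{i}" for i in range(p)], coef, np.zeros(p))


def brute_force_betweenness(p, edges):
    """Enumerate all shortest directed paths with BFS; normalize by
    (|V|-1)(|V|-2) ordered pairs."""
    adj = {i: [] for i in range(p)}
    for i, j in edges:
        adj[i].append(j)

    def all_shortest_paths(s, t):
        # BFS layering, then DFS back through parents
        from collections import deque

        dist = {s: 0}
        parents = {s: []}
        dq = deque([s])
        while dq:
            u = dq.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parents[v] = [u]
                    dq.append(v)
                elif dist[v] == dist[u] + 1:
                    parents[v].append(u)
        if t not in dist:
            return []
        paths = []

        def back(v, acc):
            if v == s:
                paths.append([s] + acc)
                return
            for u in parents[v]:
                back(u, [v] + acc)

        back(t, [])
        return paths

    B = np.zeros(p)
    for s, t in itertools.permutations(range(p), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for j in range(p):
            if j == s or j == t:
                continue
            through = sum(1 for path in paths if j in path[1:-1])
            B[j] += through / len(paths)
    return B / ((p - 1) * (p - 2))


class TestRegulatoryEffect:
    def test_no_outgoing_edges_is_zero(self):
        net = net_from_edges(3, [(0, 1)])
        R = regulatory_effect(net, np.array([1.0, 5.0, 2.0]))
        assert R[1] == 0.0 and R[2] == 0.0

    def test_hand_computed_value(self):
        # mean 2, outgoing coefficients +1 and -3 -> R = 2 * (1 + 3) = 8
        net = net_from_edges(3, [(0, 1), (0, 2)], weights=[1.0, -3.0])
        R = regulatory_effect(net, np.array([2.0, 1.0, 1.0]))
        assert R[0] == pytest.approx(8.0)

    def test_linearity_in_mean_expression(self, rng):
        coef = rng.normal(size=(4, 4))
        np.fill_diagonal(coef, 0.0)
        net = GeneNetwork(list("abcd"), coef, np.zeros(4))
        m = rng.uniform(0, 3, 4)
        np.testing.assert_allclose(
            regulatory_effect(net, 2 * m), 2 * regulatory_effect(net, m)
        )


class TestHubness:
    def test_identical_neighborhoods(self):
        net = net_from_edges(3, [(0, 1)])
        hq, hc = hubness(net, net)
        assert hq[0] == hc[0] == 1.0

    def test_partial_overlap(self):
        # N_Q(g0) = {1, 2}, N_C(g0) = {2, 3}: union 3 -> H = 2/3 each
        nq = net_from_edges(4, [(0, 1), (0, 2)])
        nc = net_from_edges(4, [(0, 2), (3, 0)])
        hq, hc = hubness(nq, nc)
        assert hq[0] == pytest.approx(2 / 3)
        assert hc[0] == pytest.approx(2 / 3)

    def test_isolated_gene_zero(self):
        nq = net_from_edges(3, [(0, 1)])
        hq, hc = hubness(nq, nq)
        assert hq[2] == hc[2] == 0.0

    def test_sum_bounded_between_one_and_two(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            nq = net_from_edges(
                6, [(i, j) for i in range(6) for j in range(6)
                    if i != j and r.random() < 0.3]
            )
            nc = net_from_edges(
                6, [(i, j) for i in range(6) for j in range(6)
                    if i != j and r.random() < 0.3]
            )
            hq, hc = hubness(nq, nc)
            NQ, NC = nq.neighbor_sets(), nc.neighbor_sets()
            for j in range(6):
                if NQ[j] | NC[j]:
                    assert 1.0 - 1e-12 <= hq[j] + hc[j] <= 2.0 + 1e-12


class TestBetweenness:
    def test_directed_path_center(self):
        # g0 -> g1 -> g2: only ordered pair (0,2) routes through g1
        net = net_from_edges(3, [(0, 1), (1, 2)])
        B = betweenness(net)
        assert B[1] == pytest.approx(0.5)
        assert B[0] == B[2] == 0.0

    def test_complete_digraph_all_zero(self):
        edges = [(i, j) for i in range(4) for j in range(4) if i != j]
        B = betweenness(net_from_edges(4, edges))
        np.testing.assert_array_equal(B, 0.0)

    def test_star_center_zero_without_return_edges(self):
        # center -> leaves only: no leaf can reach another leaf
        B = betweenness(net_from_edges(4, [(0, 1), (0, 2), (0, 3)]))
        np.testing.assert_array_equal(B, 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_digraphs(self, seed):
        r = np.random.default_rng(seed)
        p = int(r.integers(3, 9))
        edges = [
            (i, j) for i in range(p) for j in range(p)
            if i != j and r.random() < 0.35
        ]
        net = net_from_edges(p, edges)
        np.testing.assert_allclose(
            betweenness(net), brute_force_betweenness(p, edges), atol=1e-12
        )

    def test_small_network_warns_zero(self):
        with pytest.warns(UserWarning):
            B = betweenness(net_from_edges(2, [(0, 1)]))
        np.testing.assert_array_equal(B, 0.0)


class TestActivityScore:
    def test_full_modulation_returns_r(self):
        R = np.array([3.0, 7.0])
        np.testing.assert_allclose(
            activity_score(R, np.ones(2), np.ones(2)), R
        )

    def test_zero_regulatory_effect(self):
        assert activity_score(
            np.zeros(1), np.array([0.9]), np.array([0.9])
        )[0] == 0.0

    def test_hand_computed(self):
        A = activity_score(np.array([4.0]), np.array([0.5]), np.array([0.25]))
        assert A[0] == pytest.approx(1.5)


def test_permutation_equivariance(rng):
    p = 5
    coef = (rng.random((p, p)) < 0.4) * rng.normal(size=(p, p))
    np.fill_diagonal(coef, 0.0)
    net = GeneNetwork([f"g{i}" for i in range(p)], coef, np.zeros(p))
    perm = rng.permutation(p)
    net_p = GeneNetwork(
        [f"g{i}" for i in range(p)], coef[np.ix_(perm, perm)], np.zeros(p)
    )
    np.testing.assert_allclose(betweenness(net_p), betweenness(net)[perm])
    m = rng.uniform(0, 2, p)
    np.testing.assert_allclose(
        regulatory_effect(net_p, m[perm]), regulatory_effect(net, m)[perm]
    )
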