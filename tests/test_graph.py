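import numpy as np
import pytest

from clustex import (
    ConfigurationError,
    enumerate_paths_bruteforce,
    k_shortest_paths,
    shortest_path_lengths,
    weight_network,
)
from clustex.graph import dijkstra_path_lex

from helpers import matrix_from_rows, random_weighted_network, weighted_network


def square_with_chord():
    # A-B(1), B-C(1), A-D(1), D-C(1), chord A-C(3)
    return weighted_network(
        [("A", "B", 1.0), ("B", "C", 1.0), ("A", "D", 1.0), ("D", "C", 1.0), ("A", "C", 3.0)]
    )


# -- weighting ----------------------------------------------------------------

def test_weight_network_distance_is_one_minus_correlation():
    rng = np.random.default_rng(0)
    rows = {g: list(rng.uniform(10, 300, size=5)) for g in "ABC"}
    m = matrix_from_rows(rows)
    skeleton = weighted_network([("A", "B", 1.0), ("B", "C", 1.0)])
    net = weight_network(skeleton, m)
    from clustex import ExpressionStats

    stats = ExpressionStats(m)
    for u, v in [("A", "B"), ("B", "C")]:
        w = net.graph[u][v]["weight"]
        assert w == pytest.approx(stats.abs_corr(u, v))
        assert net.graph[u][v]["distance"] == pytest.approx(1.0 - w)


def test_weight_network_limit_cases_via_injected_weights():
    m = matrix_from_rows({"A": [1, 2, 3], "B": [2, 4, 6], "C": [9, 9, 8]})
    skeleton = weighted_network([("A", "B", 0.5), ("B", "C", 0.5)])
    fixed = {("A", "B"): 1.0, ("B", "C"): 0.3}
    net = weight_network(
        skeleton, m, weight_fn=lambda s, x, y: fixed[tuple(sorted((x, y)))]
    )
    assert net.graph["A"]["B"]["distance"] == pytest.approx(0.0)
    assert net.graph["B"]["C"]["distance"] == pytest.approx(0.7)


def test_weight_network_intersection_vs_retention():
    m = matrix_from_rows({"A": [1, 2, 3], "B": [2, 4, 7]})
    skeleton = weighted_network([("A", "B", 0.5), ("B", "X", 0.5)])
    assert not weight_network(skeleton, m).has_node("X")
    retained = weight_network(skeleton, m, retain_unmeasured=True)
    assert retained.has_node("X")
    assert retained.graph["B"]["X"]["weight"] == 0.0
    assert retained.graph["B"]["X"]["distance"] == 1.0
    with pytest.raises(ConfigurationError):
        weight_network(weighted_network([("Y", "Z", 0.5)]), m)


# -- shortest paths -----------------------------------------------------------

def test_shortest_path_lengths_examples():
    net = weighted_network([("A", "B", 0.2), ("B", "C", 0.3), ("A", "C", 0.9), ("X", "Y", 0.1)])
    dm = shortest_path_lengths(net, ["A", "C", "X"])
    assert dm.get("A", "C") == pytest.approx(0.5)  # via B, beats direct 0.9
    assert dm.get("A", "A") == 0.0
    assert np.isinf(dm.get("A", "X"))
    assert np.allclose(dm.d, dm.d.T)


def test_shortest_path_matches_k1_path_length():
    rng = np.random.default_rng(7)
    for _ in range(10):
        net = random_weighted_network(rng)
        nodes = net.node_list()
        s, t = nodes[0], nodes[-1]
        dm = shortest_path_lengths(net, [s, t])
        paths = k_shortest_paths(net, s, t, 1)
        if paths:
            assert dm.get(s, t) == pytest.approx(paths[0].length)
        else:
            assert np.isinf(dm.get(s, t))


def test_distance_matrix_triangle_inequality():
    rng = np.random.default_rng(11)
    for _ in range(10):
        net = random_weighted_network(rng, n_min=5, n_max=9)
        dm = shortest_path_lengths(net, net.node_list())
        d = dm.d
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if np.isfinite(d[i, k]) and np.isfinite(d[k, j]):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


# -- deterministic Dijkstra and Yen -------------------------------------------

def test_dijkstra_lex_tie_break():
    path, length = dijkstra_path_lex(square_with_chord().graph, "A", "C")
    assert path == ("A", "B", "C")  # [A,B,C] < [A,D,C] at equal length 2
    assert length == pytest.approx(2.0)


def test_k_shortest_square_with_chord():
    paths = k_shortest_paths(square_with_chord(), "A", "C", 2)
    assert [p.nodes for p in paths] == [("A", "B", "C"), ("A", "D", "C")]
    assert [p.length for p in paths] == [pytest.approx(2.0), pytest.approx(2.0)]


def test_k_shortest_exhaustion_returns_all():
    triangle = weighted_network([("A", "B", 0.3), ("B", "C", 0.4), ("A", "C", 0.9)])
    paths = k_shortest_paths(triangle, "A", "C", 10)
    assert len(paths) == 2


def test_k_shortest_errors():
    net = square_with_chord()
    with pytest.raises(ConfigurationError):
        k_shortest_paths(net, "A", "A", 2)
    with pytest.raises(ConfigurationError):
        k_shortest_paths(net, "A", "Z", 2)
    with pytest.raises(ConfigurationError):
        k_shortest_paths(net, "A", "C", 0)


def test_bruteforce_enumeration():
    triangle = weighted_network([("A", "B", 0.3), ("B", "C", 0.4), ("A", "C", 0.9)])
    paths = enumerate_paths_bruteforce(triangle, "A", "C")
    assert [p.nodes for p in paths] == [("A", "B", "C"), ("A", "C")]
    chain = weighted_network([("A", "B", 1), ("B", "C", 1), ("C", "D", 1)])
    assert len(enumerate_paths_bruteforce(chain, "A", "D")) == 1
    disconnected = weighted_network([("A", "B", 1), ("C", "D", 1)])
    assert enumerate_paths_bruteforce(disconnected, "A", "C") == []
    rng = np.random.default_rng(0)
    big = random_weighted_network(rng, n_min=13, n_max=13, p=0.3)
    with pytest.raises(ConfigurationError):
        enumerate_paths_bruteforce(big, "N0", "N1")


def test_yen_matches_bruteforce_quick():
    """Spot-check of the oracle equivalence (the full 200-graph sweep runs in
    the acceptance suite)."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        net = random_weighted_network(rng)
        nodes = net.node_list()
        s, t = rng.choice(nodes, size=2, replace=False)
        expected = enumerate_paths_bruteforce(net, s, t)[:5]
        got = k_shortest_paths(net, s, t, 5)
        assert [p.nodes for p in got] == [p.nodes for p in expected]
        np.testing.assert_allclose(
            [p.length for p in got], [p.length for p in expected]
        )


def test_yen_path_nestedness():
    """Node coverage of top-k paths is contained in that of top-(k+1)."""
    rng = np.random.default_rng(5)
    for _ in range(15):
        net = random_weighted_network(rng, n_min=5, n_max=9)
        nodes = net.node_list()
        s, t = rng.choice(nodes, size=2, replace=False)
        prev: set = set()
        for k in range(1, 5):
            cover = {n for p in k_shortest_paths(net, s, t, k) for n in p.nodes}
            assert prev <= cover
            prev = cover
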