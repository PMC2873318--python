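import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clustex import (
    ConfigurationError,
    DegreePreservingSampler,
    ExpressionStats,
    GeneSetCollection,
    ResponsiveModule,
    enrich,
    filter_gene_sets,
    gscore,
    gscore_table,
    meet_min,
    tscore,
)

from helpers import matrix_from_rows


# -- Meet/Min -----------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, value",
    [
        ({"a", "b", "c"}, {"b", "c", "d", "e"}, 2 / 3),
        ({"a", "b"}, {"a", "b", "c"}, 1.0),
        ({"a"}, {"b"}, 0.0),
    ],
)
def test_meet_min_examples(a, b, value):
    assert meet_min(a, b) == pytest.approx(value)


def test_meet_min_empty_set_error():
    with pytest.raises(ConfigurationError):
        meet_min(set(), {"a"})


@given(
    a=st.sets(st.integers(0, 30), min_size=1, max_size=15),
    b=st.sets(st.integers(0, 30), min_size=1, max_size=15),
)
@settings(max_examples=80, deadline=None, derandomize=True)
def test_meet_min_properties(a, b):
    a = {str(x) for x in a}
    b = {str(x) for x in b}
    v = meet_min(a, b)
    assert 0.0 <= v <= 1.0
    assert v == meet_min(b, a)
    assert (v == 1.0) == (a <= b or b <= a)


# -- size filter --------------------------------------------------------------

def test_filter_gene_sets_boundaries_and_restriction():
    universe = frozenset(f"u{i}" for i in range(600))
    sets = {
        "tiny": frozenset(f"u{i}" for i in range(49)),
        "atmin": frozenset(f"u{i}" for i in range(50)),
        "atmax": frozenset(f"u{i}" for i in range(500)),
        "mixed": frozenset([f"u{i}" for i in range(60)] + [f"x{i}" for i in range(60)]),
    }
    filtered = filter_gene_sets(GeneSetCollection(sets), universe=universe)
    assert set(filtered.sets) == {"atmin", "atmax", "mixed"}
    assert len(filtered.sets["mixed"]) == 60  # restricted to the universe first


# -- gscore / tscore ----------------------------------------------------------

def gscore_fixture():
    """Gene A: fold 4 (log2 = 2), neighbors B (|cor|=1) and C (|cor|=0.5)."""
    a = np.array([1.0, 4.0, 2.0])
    ac = a - a.mean()
    ua = ac / np.linalg.norm(ac)
    # direction orthogonal to both ua and the constant vector, so centering
    # gene C leaves the intended correlation intact
    e = np.cross(ua, np.ones(3) / np.sqrt(3.0))
    e /= np.linalg.norm(e)
    c = 10.0 + 0.5 * ua + np.sqrt(0.75) * e
    rows = {"A": list(a), "B": list(2.0 * a), "C": list(c), "Z": [3.0, 3.0, 3.0]}
    stats = ExpressionStats(matrix_from_rows(rows), scale="raw", eps=1e-9)
    module = ResponsiveModule(
        "M",
        genes=frozenset("ABCZ"),
        de_genes=frozenset("A"),
        provenance={g: ("de" if g == "A" else "k_shortest") for g in "ABCZ"},
        edges=(("A", "B"), ("A", "C"), ("C", "Z")),
    )
    return stats, module


def test_gscore_adopted_form():
    stats, module = gscore_fixture()
    assert stats.abs_corr("A", "B") == pytest.approx(1.0)
    assert stats.abs_corr("A", "C") == pytest.approx(0.5)
    assert gscore("A", module, stats) == pytest.approx(2.0 * 1.5)
    # constant gene: fold 1 -> log2 1 = 0
    assert gscore("Z", module, stats) == pytest.approx(0.0)
    with pytest.raises(ConfigurationError):
        gscore("Q", module, stats)


def test_gscore_no_edges_is_zero():
    stats, _ = gscore_fixture()
    lonely = ResponsiveModule(
        "M", frozenset("AB"), frozenset(), {"A": "k_shortest", "B": "k_shortest"}, edges=()
    )
    assert gscore("A", lonely, stats) == 0.0


def test_tscore_sums_overlap_gscores():
    stats, module = gscore_fixture()
    table = gscore_table(module, stats)
    assert tscore(module, frozenset(), table) == 0.0
    assert tscore(module, frozenset("ABCZQ"), table) == pytest.approx(sum(table.values()))
    assert tscore(module, frozenset("AB"), table) == pytest.approx(table["A"] + table["B"])


# -- degree-preserving permutations -------------------------------------------

def ba_network(n=200, seed=0):
    from clustex import generate_network

    return generate_network(n, m=3, seed=seed)


def test_sampler_preserves_cardinality_and_degree():
    net = ba_network()
    universe = frozenset(net.graph.nodes())
    sampler = DegreePreservingSampler(net, universe)
    rng = np.random.default_rng(0)
    nodes = net.node_list()
    observed = frozenset(nodes[::7][:25])
    draws = sampler.sample_sets(observed, 400, rng)
    assert all(len(d) == len(observed) for d in draws)
    obs_mean = np.mean([net.degree(g) for g in observed])
    perm_mean = np.mean([net.degree(g) for d in draws for g in d])
    assert abs(perm_mean - obs_mean) / obs_mean < 0.10


def test_sampler_single_bin_reduces_to_uniform():
    import networkx as nx

    from clustex import GeneNetwork

    ring = nx.cycle_graph(30)
    ring = nx.relabel_nodes(ring, {i: f"n{i:02d}" for i in ring.nodes()})
    net = GeneNetwork(ring)  # all degrees equal: one bin
    sampler = DegreePreservingSampler(net, frozenset(ring.nodes()))
    rng = np.random.default_rng(1)
    draws = sampler.sample_sets(frozenset(["n00", "n01", "n02"]), 2000, rng)
    counts = {}
    for d in draws:
        for g in d:
            counts[g] = counts.get(g, 0) + 1
    freqs = np.array([counts.get(f"n{i:02d}", 0) for i in range(30)]) / (3 * 2000)
    assert abs(freqs.mean() - 1 / 30) < 1e-12
    assert freqs.std() < 0.01


def test_sampler_singleton_bin_maps_to_itself():
    import networkx as nx

    from clustex import GeneNetwork

    g = nx.star_graph(16)  # hub degree 16, leaves degree 1
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
    net = GeneNetwork(g)
    sampler = DegreePreservingSampler(net, frozenset(g.nodes()))
    rng = np.random.default_rng(2)
    with pytest.warns(UserWarning, match="single gene"):
        draws = sampler.sample_sets(frozenset(["n00"]), 5, rng)  # n00 is the hub
    assert all(d == {"n00"} for d in draws)


# -- enrich -------------------------------------------------------------------

def scenario_module(seed=0):
    import clustex as cx

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc = cx.default_scenario(seed=seed, n_genes=300, module_size=20)
        stats = cx.ExpressionStats(sc.expression)
        net = cx.weight_network(sc.network, sc.expression, stats=stats)
    planted = sc.truth.planted_modules[0]
    sub = net.graph.subgraph(planted)
    module = ResponsiveModule(
        "M1",
        genes=frozenset(planted),
        de_genes=sc.truth.de_genes[0],
        provenance={g: ("de" if g in sc.truth.de_genes[0] else "k_shortest") for g in planted},
        edges=tuple(sorted(tuple(sorted(e)) for e in sub.edges())),
    )
    return sc, net, stats, module


def test_enrich_deterministic_and_sorted():
    sc, net, stats, module = scenario_module()
    results1 = enrich(module, sc.gene_sets, net, kind="meet_min", n_perm=200, seed=5)
    results2 = enrich(module, sc.gene_sets, net, kind="meet_min", n_perm=200, seed=5)
    assert [(r.set_name, r.z_score) for r in results1] == [
        (r.set_name, r.z_score) for r in results2
    ]
    zs = [r.z_score for r in results1 if r.evaluable]
    assert zs == sorted(zs, reverse=True)


def test_enrich_true_sets_beat_decoys():
    sc, net, stats, module = scenario_module(seed=3)
    results = enrich(module, sc.gene_sets, net, kind="meet_min", n_perm=500, seed=0)
    by_name = {r.set_name: r for r in results}
    assert by_name["TRUE_SET_1"].z_score > 3.0
    assert by_name["TRUE_SET_1"].enriched
    decoy_z = [r.z_score for r in results if r.set_name.startswith("DECOY") and r.evaluable]
    assert np.mean([z > 3.0 for z in decoy_z]) < 0.3


def test_enrich_tscore_kind():
    sc, net, stats, module = scenario_module(seed=4)
    results = enrich(module, sc.gene_sets, net, kind="tscore", stats=stats, n_perm=300, seed=1)
    by_name = {r.set_name: r for r in results}
    assert by_name["TRUE_SET_1"].statistic_kind == "tscore"
    assert by_name["TRUE_SET_1"].z_score > 2.0  # the looser target-set cutoff
    with pytest.raises(ConfigurationError):
        enrich(module, sc.gene_sets, net, kind="tscore", stats=None, n_perm=50, seed=1)


def test_enrich_disjoint_set_negative_z():
    sc, net, stats, module = scenario_module(seed=6)
    outside = frozenset(set(net.graph.nodes()) - module.genes)
    disjoint = GeneSetCollection({"AWAY": frozenset(sorted(outside)[:40])})
    result = enrich(module, disjoint, net, kind="meet_min", n_perm=400, seed=2)[0]
    assert result.z_score < 0 and not result.enriched


def test_enrich_power_on_planted_sets():
    """The planted DE core (plus padding) must light up at z > 3 for nearly
    every generator seed."""
    hits = 0
    n_seeds = 25
    for seed in range(n_seeds):
        sc, net, stats, module = scenario_module(seed=seed)
        results = enrich(module, sc.gene_sets, net, kind="meet_min", n_perm=300, seed=seed)
        z = {r.set_name: r.z_score for r in results}["TRUE_SET_1"]
        hits += z > 3.0
    assert hits >= int(0.9 * n_seeds)
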