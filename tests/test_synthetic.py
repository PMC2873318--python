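import json
import warnings

import networkx as nx
import numpy as np
import pytest

from clustex import (
    ConfigurationError,
    ExpressionStats,
    generate_expression,
    generate_gene_sets,
    generate_network,
    plant_modules,
    read_expression,
    read_network,
    select_de_genes,
)
from clustex.synthetic import default_scenario, write_scenario


def test_preferential_attachment_counts_and_determinism():
    net = generate_network(500, m=2, seed=0)
    assert net.n_nodes == 500
    assert net.n_edges == 996  # m(n - m) for the star-seeded construction
    assert nx.is_connected(net.graph)
    again = generate_network(500, m=2, seed=0)
    assert nx.utils.graphs_equal(net.graph, again.graph)
    assert not nx.utils.graphs_equal(net.graph, generate_network(500, m=2, seed=1).graph)


def test_preferential_attachment_heavy_tail():
    for seed in range(5):
        net = generate_network(500, m=2, seed=seed)
        degrees = np.array([d for _, d in net.graph.degree()])
        assert degrees.max() >= 10 * np.median(degrees)


def test_erdos_renyi_largest_component_fallback():
    with pytest.warns(UserWarning, match="largest component"):
        net = generate_network(60, model="erdos_renyi", p=0.03, seed=2)
    assert nx.is_connected(net.graph)
    with pytest.raises(ConfigurationError):
        generate_network(5)
    with pytest.raises(ConfigurationError):
        generate_network(50, model="small_world")


def test_plant_modules_disjoint_connected():
    net = generate_network(400, m=3, seed=1)
    modules = plant_modules(net, 2, 30, seed=4)
    assert len(modules[0] & modules[1]) == 0
    for mod in modules:
        assert len(mod) == 30
        assert nx.is_connected(net.graph.subgraph(mod))
    assert plant_modules(net, 1, 1, seed=0)[0].__len__() == 1
    with pytest.raises(ConfigurationError):
        plant_modules(net, 20, 30, seed=0)


def test_noiseless_expression_is_perfectly_correlated():
    net = generate_network(60, m=2, seed=3)
    planted = plant_modules(net, 1, 10, seed=3)
    with pytest.warns(UserWarning, match="cor"):
        matrix, truth = generate_expression(
            net, planted, n_timepoints=12, noise_sd=0.0, seed=0, curve="rise"
        )
    stats = ExpressionStats(matrix)
    members = sorted(planted[0])
    for a, b in zip(members, members[1:]):
        assert stats.abs_corr(a, b) == pytest.approx(1.0, abs=1e-9)


def test_de_fraction_construction():
    net = generate_network(300, m=3, seed=5)
    planted = plant_modules(net, 1, 30, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, truth = generate_expression(
            net, planted, n_timepoints=25, de_fraction=0.5, seed=7
        )
    de = select_de_genes(matrix, 2.0)
    passing = len(de & planted[0])
    assert abs(passing - 15) <= 3
    assert truth.de_genes[0] <= de


def test_intra_module_correlation_hits_target():
    net = generate_network(300, m=3, seed=6)
    planted = plant_modules(net, 2, 25, seed=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, _ = generate_expression(net, planted, n_timepoints=25, rho_in=0.8, seed=8)
    stats = ExpressionStats(matrix)
    for module in planted:
        members = sorted(module)
        cors = [
            stats.abs_corr(a, b)
            for i, a in enumerate(members)
            for b in members[i + 1:]
        ]
        assert abs(np.mean(cors) - 0.8) < 0.1


def test_background_correlations_low():
    net = generate_network(200, m=3, seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, _ = generate_expression(net, [], n_timepoints=25, seed=10)
    stats = ExpressionStats(matrix)
    rng = np.random.default_rng(0)
    genes = matrix.gene_ids
    cors = [
        stats.abs_corr(*rng.choice(genes, size=2, replace=False)) for _ in range(300)
    ]
    assert np.mean(cors) < 0.2


def test_rho_incompatible_with_noise_warns():
    net = generate_network(80, m=2, seed=11)
    planted = plant_modules(net, 1, 10, seed=11)
    with pytest.warns(UserWarning, match="attainable"):
        generate_expression(net, planted, n_timepoints=15, rho_in=0.95, noise_sd=0.5, seed=1)
    with pytest.raises(ConfigurationError):
        generate_expression(net, planted, rho_in=1.5, seed=0)


def test_generated_gene_sets_structure():
    net = generate_network(250, m=3, seed=12)
    planted = plant_modules(net, 2, 25, seed=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, truth = generate_expression(net, planted, seed=12)
    universe = frozenset(net.graph.nodes())
    sets = generate_gene_sets(planted, truth.de_genes, universe, net, n_decoys=10, seed=13)
    true1 = sets.sets["TRUE_SET_1"]
    core = truth.de_genes[0]
    assert len(true1 & planted[0]) >= 0.8 * len(true1) - 1
    assert core <= true1
    sizes = [len(true1), len(sets.sets["TRUE_SET_2"])]
    for j in range(1, 11):
        decoy = sets.sets[f"DECOY_{j:02d}"]
        assert any(abs(len(decoy) - s) <= 0.25 * s + 1 for s in sizes)
    again = generate_gene_sets(planted, truth.de_genes, universe, net, n_decoys=10, seed=13)
    assert again.sets == sets.sets


def test_write_scenario_round_trip(tmp_path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc = default_scenario(seed=2, n_genes=120, module_size=12, n_decoys=4)
        paths = write_scenario(sc, tmp_path)
    matrix = read_expression(paths["expression"], "t00")
    assert matrix.gene_ids == sc.expression.gene_ids
    np.testing.assert_allclose(matrix.signals, sc.expression.signals, rtol=1e-5)
    net = read_network(paths["network"])
    assert nx.utils.graphs_equal(
        nx.Graph(net.graph.edges()), nx.Graph(sc.network.graph.edges())
    )
    manifest = json.loads(paths["manifest"].read_text())
    for key in ("seed", "planted_modules", "de_genes", "amplitudes", "params", "response_curves"):
        assert key in manifest
    assert (tmp_path / "reference_module_1.txt").exists()


def test_default_scenario_determinism():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = default_scenario(seed=5, n_genes=120, module_size=10, n_decoys=3)
        b = default_scenario(seed=5, n_genes=120, module_size=10, n_decoys=3)
    assert a.truth.planted_modules == b.truth.planted_modules
    np.testing.assert_array_equal(a.expression.signals, b.expression.signals)
    assert a.gene_sets.sets == b.gene_sets.sets
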