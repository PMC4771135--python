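"""Network generators, structural metrics, and edge-list round trips."""

import math

import networkx as nx
import numpy as np
import pytest

from netdilemma.netgen import (
    CalibrationError,
    assortative_rewire,
    barabasi_albert,
    clustered_scale_free,
    degree_assortativity,
    growing_exponential,
    network_metrics,
    random_regular,
    read_edge_list,
    validate_network,
    write_edge_list,
)


def brute_clustering(g: nx.Graph) -> float:
    """Triple-enumeration oracle: mean over vertices of the fraction of
    neighbor pairs that are adjacent (0 for degree < 2)."""
    total = 0.0
    for v in g:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(
            g.has_edge(a, b)
            for idx, a in enumerate(nbrs)
            for b in nbrs[idx + 1:]
        )
        total += closed / (k * (k - 1) / 2)
    return total / g.number_of_nodes()


def brute_assortativity(g: nx.Graph) -> float:
    """Edge-end correlation oracle: Pearson correlation of the degrees at
    the two ends of each edge, over both orientations."""
    xs, ys = [], []
    for u, v in g.edges():
        xs += [g.degree(u), g.degree(v)]
        ys += [g.degree(v), g.degree(u)]
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0:
        return math.nan
    return float(np.corrcoef(xs, ys)[0, 1])


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize(
    "factory",
    [
        lambda s: random_regular(60, 4, seed=s),
        lambda s: growing_exponential(80, 2, seed=s),
        lambda s: barabasi_albert(80, 2, seed=s),
        lambda s: clustered_scale_free(300, 2, 0.2, seed=s),
    ],
    ids=["regular", "exponential", "ba", "holme-kim"],
)
def test_generators_produce_valid_simple_graphs(factory, seed):
    g = factory(seed)
    validate_network(g)  # simple, undirected, no isolated vertices
    m = network_metrics(g)
    assert m.mean_degree == pytest.approx(2 * g.number_of_edges() / g.number_of_nodes())


def test_random_regular_degrees_exact():
    g = random_regular(100, 4, seed=0)
    assert all(d == 4 for _, d in g.degree())
    assert network_metrics(g).mean_degree == 4.0
    assert network_metrics(g).degree_variance == 0.0


def test_random_regular_parameter_errors():
    with pytest.raises(ValueError):
        random_regular(5, 3)  # odd degree sum
    with pytest.raises(ValueError):
        random_regular(10, 10)  # k >= n


def test_growing_exponential_mean_degree():
    g = growing_exponential(1000, 2, seed=1)
    # edge count = C(3,2) + 2*(n-3) exactly
    assert g.number_of_edges() == 3 + 2 * (1000 - 3)
    assert 3.9 <= network_metrics(g).mean_degree <= 4.0


def test_growing_exponential_size_error():
    with pytest.raises(ValueError):
        growing_exponential(4, 3)


def test_growing_exponential_tail_is_light():
    """Fraction of vertices of degree > 10*m is below 1% (exponential tail)."""
    heavy = 0
    total = 0
    for seed in range(10):
        g = growing_exponential(2000, 2, seed=seed)
        degs = np.array([d for _, d in g.degree()])
        heavy += int((degs > 20).sum())
        total += len(degs)
    assert heavy / total < 0.01


def test_ba_mean_degree_and_errors():
    g = barabasi_albert(1000, 2, seed=0)
    assert network_metrics(g).mean_degree == pytest.approx(4.0, rel=0.02)
    with pytest.raises(ValueError):
        barabasi_albert(10, 10)


def test_degree_heterogeneity_ordering():
    """Degree variance: BA > exponential > regular (=0) at matched kbar."""
    var_ba, var_exp = [], []
    for seed in range(10):
        var_ba.append(network_metrics(barabasi_albert(1000, 2, seed=seed)).degree_variance)
        var_exp.append(
            network_metrics(growing_exponential(1000, 2, seed=seed)).degree_variance
        )
    assert np.mean(var_ba) > np.mean(var_exp) > 0.0
    assert network_metrics(random_regular(1000, 4, seed=0)).degree_variance == 0.0


def test_clustered_scale_free_zero_target_is_ba():
    """C_target=0 goes through the identical BA growth code path."""
    g0 = clustered_scale_free(200, 2, 0.0, seed=5)
    gb = barabasi_albert(200, 2, seed=5)
    assert set(g0.edges()) == set(gb.edges())


def test_clustered_scale_free_hits_target():
    g = clustered_scale_free(2000, 2, 0.3, seed=1)
    assert abs(nx.average_clustering(g) - 0.3) <= 0.02


def test_clustered_scale_free_target_range():
    with pytest.raises(ValueError):
        clustered_scale_free(500, 2, 0.9)


# ---------------------------------------------------------------------------
# Rewiring
# ---------------------------------------------------------------------------

def test_rewire_preserves_degree_sequence():
    base = barabasi_albert(500, 2, seed=3)
    before = sorted(d for _, d in base.degree())
    g = assortative_rewire(base, 0.15, seed=4)
    assert sorted(d for _, d in g.degree()) == before
    assert abs(degree_assortativity(g) - 0.15) <= 0.02
    validate_network(g)


def test_rewire_noop_when_already_at_target():
    base = barabasi_albert(300, 2, seed=6)
    r0 = degree_assortativity(base)
    g = assortative_rewire(base, r0, seed=7)
    assert set(g.edges()) == set(base.edges())


def test_rewire_unreachable_target_errors():
    # a double star forces strong disassortativity; r=+0.3 is unreachable
    g = nx.Graph()
    g.add_edges_from((0, i) for i in range(2, 12))
    g.add_edges_from((1, i) for i in range(12, 22))
    g.add_edge(0, 1)
    with pytest.raises(CalibrationError):
        assortative_rewire(g, 0.3, seed=0, max_attempts=2000)


def test_rewire_rejects_regular_graph():
    with pytest.raises(CalibrationError, match="regular"):
        assortative_rewire(nx.cycle_graph(10), 0.1, seed=0)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_metrics_on_small_canonical_graphs():
    tri = network_metrics(nx.complete_graph(3))
    assert tri.mean_degree == 2.0 and tri.clustering == 1.0
    assert tri.degree_variance == 0.0
    path = network_metrics(nx.path_graph(3))
    assert path.clustering == 0.0
    star = network_metrics(nx.star_graph(4))  # K_{1,4}
    assert star.assortativity == pytest.approx(-1.0)


def test_assortativity_undefined_for_regular_graphs():
    assert math.isnan(degree_assortativity(nx.cycle_graph(12)))
    assert math.isnan(network_metrics(random_regular(30, 4, seed=0)).assortativity)


def test_metrics_match_brute_force_on_random_graphs():
    """C and r agree with independent triple-enumeration / edge-end
    correlation oracles on 100 random graphs with n <= 50."""
    rng = np.random.default_rng(12345)
    checked = 0
    while checked < 100:
        n = int(rng.integers(5, 51))
        p = float(rng.uniform(0.08, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g.remove_nodes_from([v for v, d in g.degree() if d == 0])
        if g.number_of_nodes() < 3 or g.number_of_edges() < 2:
            continue
        g = nx.convert_node_labels_to_integers(g)
        m = network_metrics(g)
        assert m.clustering == pytest.approx(brute_clustering(g), abs=1e-12)
        r_brute = brute_assortativity(g)
        if math.isnan(r_brute):
            assert math.isnan(m.assortativity)
        else:
            assert m.assortativity == pytest.approx(r_brute, abs=1e-9)
        checked += 1


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def test_read_simple_edge_list(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("# a comment\n0 1\n1 2\n")
    g = read_edge_list(p)
    assert sorted(g.edges()) == [(0, 1), (1, 2)]


def test_read_collapses_duplicates_and_reversals(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("0 1\n1 0\n0 1\n1 2\n")
    g = read_edge_list(p)
    assert g.number_of_edges() == 2


def test_read_warns_on_self_loops(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("0 0\n0 1\n1 2\n")
    with pytest.warns(UserWarning, match="self-loop"):
        g = read_edge_list(p)
    assert not any(g.has_edge(v, v) for v in g)


def test_read_rejects_isolated_after_self_loop_drop(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("5 5\n0 1\n")
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError, match="isolated"):
            read_edge_list(p)


def test_read_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("0 1\nnot numbers here\n")
    with pytest.raises(ValueError, match=":2:"):
        read_edge_list(p)


def test_read_normalizes_sparse_labels(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("10 20\n20 30\n")
    g = read_edge_list(p)
    assert sorted(g.nodes()) == [0, 1, 2]
    assert g.graph["original_labels"] == [10, 20, 30]


def test_write_read_round_trip(tmp_path):
    g = barabasi_albert(100, 2, seed=9)
    p = tmp_path / "ba.txt"
    write_edge_list(g, p)
    g2 = read_edge_list(p)
    assert set(map(frozenset, g2.edges())) == set(map(frozenset, g.edges()))
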