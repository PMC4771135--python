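"""Model-network generators, structural metrics, and edge-list I/O.

Populations are undirected simple graphs with no isolated vertices, vertex
ids 0..n-1.  Four model classes are provided, spanning increasing degree
heterogeneity at matched mean degree:

* random regular networks (zero degree variance),
* growing random networks with uniform attachment (exponential degree tail),
* Barabási–Albert preferential attachment (power-law tail),
* Holme–Kim growth with a triad-formation step, calibrated by bisection so
  the realized mean local clustering coefficient hits a target C, and
* degree-preserving biased edge swaps calibrated to a target assortativity r.

Metrics follow the standard definitions: mean degree kbar = 2m/n; clustering
C = mean over vertices of the fraction of neighbor pairs that are adjacent
(0 for vertices of degree < 2); assortativity r = Pearson correlation of
degrees across edge ends (undefined for regular graphs, reported as NaN).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "NetworkMetrics",
    "CalibrationError",
    "random_regular",
    "growing_exponential",
    "barabasi_albert",
    "clustered_scale_free",
    "assortative_rewire",
    "network_metrics",
    "degree_assortativity",
    "validate_network",
    "read_edge_list",
    "write_edge_list",
]


class CalibrationError(RuntimeError):
    """A structural target (clustering or assortativity) could not be reached."""


@dataclass(frozen=True)
class NetworkMetrics:
    """Structural summary of a network: kbar, C, r, and degree variance."""

    mean_degree: float
    clustering: float
    assortativity: float  # NaN when undefined (regular graphs)
    degree_variance: float


def validate_network(g: nx.Graph) -> None:
    """Raise if g is not a simple undirected graph without isolated vertices."""
    if g.is_directed() or g.is_multigraph():
        raise ValueError("network must be an undirected simple graph")
    if any(g.has_edge(v, v) for v in g):
        raise ValueError("network must not contain self-loops")
    isolated = [v for v, d in g.degree() if d == 0]
    if isolated:
        raise ValueError(f"network has isolated vertices: {isolated[:5]}")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def random_regular(n: int, k: int, seed: int | None = None) -> nx.Graph:
    """Uniformly random k-regular graph on n vertices (configuration pairing)."""
    if k < 2:
        raise ValueError(f"degree k must be >= 2, got {k}")
    if k >= n:
        raise ValueError(f"degree k={k} must be smaller than n={n}")
    if (n * k) % 2 != 0:
        raise ValueError(f"n*k must be even (handshake lemma); got n={n}, k={k}")
    return nx.random_regular_graph(k, n, seed=seed)


def growing_exponential(n: int, m_attach: int, seed: int | None = None) -> nx.Graph:
    """Growing random network with uniform attachment.

    Starts from a clique on m_attach+1 vertices; each subsequent vertex
    attaches m_attach edges to distinct, uniformly chosen existing vertices.
    The resulting degree distribution has an exponential tail and the mean
    degree approaches 2*m_attach.
    """
    if m_attach < 1:
        raise ValueError(f"m_attach must be >= 1, got {m_attach}")
    if n <= m_attach + 1:
        raise ValueError(
            f"n must exceed m_attach+1={m_attach + 1} so growth can start; got n={n}"
        )
    rng = np.random.default_rng(seed)
    g = nx.complete_graph(m_attach + 1)
    for v in range(m_attach + 1, n):
        targets = rng.choice(v, size=m_attach, replace=False)
        g.add_edges_from((v, int(t)) for t in targets)
    return g


def barabasi_albert(n: int, m_attach: int, seed: int | None = None) -> nx.Graph:
    """Scale-free network via Barabási–Albert preferential attachment."""
    if m_attach < 1:
        raise ValueError(f"m_attach must be >= 1, got {m_attach}")
    if n <= m_attach:
        raise ValueError(f"n={n} must exceed m_attach={m_attach}")
    return nx.barabasi_albert_graph(n, m_attach, seed=seed)


def _holme_kim(n: int, m_attach: int, p_triad: float, seed) -> nx.Graph:
    """One Holme–Kim growth realization: preferential attachment where each
    extra edge follows a triad-formation step with probability p_triad."""
    if p_triad == 0.0:
        # identical growth process; keeps C_target=0 on the BA code path
        return barabasi_albert(n, m_attach, seed=seed)
    return nx.powerlaw_cluster_graph(n, m_attach, p_triad, seed=seed)


def clustered_scale_free(
    n: int,
    m_attach: int,
    C_target: float,
    seed: int | None = None,
    tol: float = 0.02,
    max_iter: int = 30,
) -> nx.Graph:
    """Scale-free network with tunable clustering via the Holme–Kim model.

    The triad-formation probability is not a meaningful user-facing knob, so
    it is calibrated here by bisection until the realized mean local
    clustering coefficient is within ``tol`` of ``C_target``.  Raises
    :class:`CalibrationError` when the target exceeds what the model can
    reach at the given n and m_attach (reporting the achievable range).
    """
    if not 0.0 <= C_target <= 0.6:
        raise ValueError(f"C_target must lie in [0, 0.6], got {C_target}")
    seed = 0 if seed is None else int(seed)
    if C_target == 0.0:
        return _holme_kim(n, m_attach, 0.0, seed)

    def realized(p: float, s: int) -> tuple[float, nx.Graph]:
        g = _holme_kim(n, m_attach, p, s)
        return nx.average_clustering(g), g

    c_max, g_hi = realized(1.0, seed)
    if C_target > c_max + tol:
        raise CalibrationError(
            f"C_target={C_target} unreachable at n={n}, m_attach={m_attach}: "
            f"achievable clustering range is about [0, {c_max:.3f}]"
        )
    if abs(c_max - C_target) <= tol:
        return g_hi
    lo, hi = 0.0, 1.0
    for it in range(max_iter):
        mid = 0.5 * (lo + hi)
        c, g = realized(mid, seed + it + 1)
        if abs(c - C_target) <= tol:
            return g
        if c < C_target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"clustering calibration failed to reach C={C_target} within "
        f"tol={tol} after {max_iter} bisection steps"
    )


def _edge_degree_product_sum(g: nx.Graph) -> float:
    return float(sum(g.degree(u) * g.degree(v) for u, v in g.edges()))


def degree_assortativity(g: nx.Graph) -> float:
    """Degree assortativity coefficient r; NaN when undefined (regular graphs).

    r is the Pearson correlation of the degrees at the two ends of an edge,
    computed over both orientations of every edge; equivalently the
    normalized adjacency-matrix form sum_ij (A_ij - k_i k_j / 2m) k_i k_j
    over sum_ij (k_i d_ij - k_i k_j / 2m) k_i k_j.
    """
    degs = np.array([d for _, d in g.degree()], dtype=float)
    m = g.number_of_edges()
    s1 = degs.sum()  # = 2m
    s2 = (degs**2).sum()
    s3 = (degs**3).sum()
    denominator = s1 * s3 - s2**2
    if denominator == 0:
        return math.nan
    numerator = 2.0 * s1 * _edge_degree_product_sum(g) - s2**2
    return numerator / denominator


def network_metrics(g: nx.Graph) -> NetworkMetrics:
    """Mean degree, clustering, assortativity and degree variance of g."""
    n = g.number_of_nodes()
    degs = np.array([d for _, d in g.degree()], dtype=float)
    mean_degree = 2.0 * g.number_of_edges() / n
    clustering = nx.average_clustering(g, count_zeros=True)
    return NetworkMetrics(
        mean_degree=mean_degree,
        clustering=float(clustering),
        assortativity=degree_assortativity(g),
        degree_variance=float(degs.var()),
    )


def assortative_rewire(
    g: nx.Graph,
    r_target: float,
    seed: int | None = None,
    tol: float = 0.02,
    max_attempts: int | None = None,
) -> nx.Graph:
    """Degree-preserving edge swaps driving the assortativity toward r_target.

    Pairs of edges are repeatedly sampled; the four endpoints are re-paired
    by degree — highest with highest (assortative direction) or highest with
    lowest (disassortative) — whenever that moves r toward the target, and
    swaps never create self-loops or multi-edges, so the degree sequence is
    exactly preserved.  Since degrees never change, r is an affine function
    of the sum of degree products over edges, which is tracked incrementally.
    """
    if not -0.3 <= r_target <= 0.3:
        raise ValueError(f"r_target must lie in [-0.3, 0.3], got {r_target}")
    rng = np.random.default_rng(seed)
    g = g.copy()
    degs = dict(g.degree())
    deg_arr = np.array(list(degs.values()), dtype=float)
    s1, s2, s3 = deg_arr.sum(), (deg_arr**2).sum(), (deg_arr**3).sum()
    denom = s1 * s3 - s2**2
    if denom == 0:
        raise CalibrationError("assortativity undefined for regular graphs")
    # invert r = (2*s1*S_e - s2^2) / denom for the target edge-product sum
    target_se = (r_target * denom + s2**2) / (2.0 * s1)
    se = _edge_degree_product_sum(g)

    def current_r() -> float:
        return (2.0 * s1 * se - s2**2) / denom

    if abs(current_r() - r_target) <= tol:
        return g
    edges = [tuple(e) for e in g.edges()]
    n_edges = len(edges)
    if max_attempts is None:
        max_attempts = 400 * n_edges
    for _ in range(max_attempts):
        i1, i2 = rng.integers(0, n_edges, size=2)
        if i1 == i2:
            continue
        a, b = edges[i1]
        c, d = edges[i2]
        if len({a, b, c, d}) < 4:
            continue
        # candidate re-pairings of the four endpoints
        best = None
        for (u1, v1), (u2, v2) in (((a, c), (b, d)), ((a, d), (b, c))):
            if g.has_edge(u1, v1) or g.has_edge(u2, v2):
                continue
            new_se = (
                se
                - degs[a] * degs[b]
                - degs[c] * degs[d]
                + degs[u1] * degs[v1]
                + degs[u2] * degs[v2]
            )
            if abs(new_se - target_se) < abs(se - target_se):
                if best is None or abs(new_se - target_se) < abs(best[0] - target_se):
                    best = (new_se, (u1, v1), (u2, v2))
        if best is None:
            continue
        new_se, e1, e2 = best
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(*e1)
        g.add_edge(*e2)
        edges[i1] = e1
        edges[i2] = e2
        se = new_se
        if abs(current_r() - r_target) <= tol:
            return g
    raise CalibrationError(
        f"rewiring failed to reach r={r_target} (got {current_r():.4f}) "
        f"within {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path) -> nx.Graph:
    """Read an undirected edge list: two whitespace-separated integer columns.

    Lines starting with '#' (and blank lines) are ignored; duplicate and
    reversed pairs collapse to a single edge; self-loops are dropped with a
    single summary warning.  Vertex labels are normalized to dense ids
    0..n-1 (original labels kept in ``g.graph["original_labels"]``).  A
    vertex whose only incident lines were self-loops would be isolated and
    raises a validation error instead.
    """
    edges: set[tuple[int, int]] = set()
    mentioned: set[int] = set()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}: {line!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer vertex label in {line!r}"
                ) from exc
            mentioned.update((u, v))
            if u == v:
                n_self_loops += 1
                continue
            edges.add((min(u, v), max(u, v)))
    if n_self_loops:
        warnings.warn(
            f"{path}: dropped {n_self_loops} self-loop line(s)", stacklevel=2
        )
    connected = {u for e in edges for u in e}
    isolated = mentioned - connected
    if isolated:
        raise ValueError(
            f"{path}: vertices {sorted(isolated)[:5]} have no valid edges "
            "(isolated after dropping self-loops)"
        )
    labels = sorted(connected)
    index = {lab: i for i, lab in enumerate(labels)}
    g = nx.Graph()
    g.add_nodes_from(range(len(labels)))
    g.add_edges_from((index[u], index[v]) for u, v in edges)
    g.graph["original_labels"] = labels
    validate_network(g)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write g as a two-column edge list using original labels if present."""
    labels = g.graph.get("original_labels")
    with open(path, "w") as fh:
        fh.write(f"# n={g.number_of_nodes()} m={g.number_of_edges()}\n")
        for u, v in sorted((min(u, v), max(u, v)) for u, v in g.edges()):
            if labels is not None:
                fh.write(f"{labels[u]} {labels[v]}\n")
            else:
                fh.write(f"{u} {v}\n")
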