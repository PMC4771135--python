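"""Shared fixtures and independent oracles for the test suite."""

import math

import networkx as nx
import numpy as np
import pytest

from netdilemma.games import GameSpec, payoff_matrix


def all_small_graphs(max_n: int = 5):
    """All non-isomorphic graphs with 2 <= n <= max_n vertices and no
    isolated vertices, from the networkx graph atlas."""
    from networkx.generators.atlas import graph_atlas_g

    out = []
    for g in graph_atlas_g():
        n = g.number_of_nodes()
        if n < 2 or n > max_n:
            continue
        if any(d == 0 for _, d in g.degree()):
            continue
        out.append(g)
    return out


def enumerate_flip_probability(g, state, i, m, beta=1.0, rule="fermi"):
    """Brute-force oracle: exact one-step flip probability of focal i by
    enumerating every (j, k, l) draw with its sampling weight.

    j is uniform on N(i); k uniform on N(i) minus j (or j itself when i has
    a single neighbor); l uniform on N(j) minus i (or i itself when j has a
    single neighbor).  Adoption probabilities are computed from first
    principles here, independent of the package's update-rule code.
    """
    arr = m.as_array()
    pmax, pmin = float(arr.max()), float(arr.min())
    ni = list(g.neighbors(i))
    total = 0.0
    for j in ni:
        pool_k = [v for v in ni if v != j] or [j]
        pool_l = [v for v in g.neighbors(j) if v != i] or [i]
        for k in pool_k:
            for l in pool_l:
                P_i = arr[state[i], state[k]]
                P_j = arr[state[j], state[l]]
                if rule == "fermi":
                    x = beta * (P_j - P_i)
                    padopt = 1.0 / (1.0 + math.exp(-x))
                else:
                    padopt = (
                        0.0 if P_i >= P_j else (P_j - P_i) / (pmax - pmin)
                    )
                if state[j] != state[i]:
                    total += padopt / (len(ni) * len(pool_k) * len(pool_l))
    return total


@pytest.fixture(scope="session")
def small_graphs():
    return all_small_graphs(5)


@pytest.fixture
def donation_half():
    return payoff_matrix(GameSpec("donation", 0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
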