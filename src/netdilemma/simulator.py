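"""Asynchronous individual-based evolutionary dynamics on a network.

Each elementary interaction/update step samples a focal individual i
uniformly, a strategy-model neighbor j of i, an interaction partner k
uniform on N(i) minus j, and an interaction partner l uniform on N(j) minus i
(when i or j has a single neighbor the exclusion is vacuous and that
neighbor is used).  Excluding the model j from i's interaction draw, and
the focal i from j's, keeps the payoff comparison between i and j based on
interactions with third parties; without the exclusions a defector
compared against a neighboring cooperator is disproportionately scored on
exploiting that very cooperator, and the cooperative network effects the
model is built to exhibit (cooperation for 1/rho > kbar - 1 in the
donation game, and its sculling analogue) vanish.  The focal payoff is the
single-interaction payoff P_i = pi(s_i, s_k) and the comparison payoff
P_j = pi(s_j, s_l); i then adopts j's strategy with probability given by
the Fermi rule

    p(i adopts j) = 1 / (1 + exp(-beta (P_j - P_i))),

or by the replicator imitation rule (P_j - P_i)_+ / (P_max - P_min).  One
generation is n such steps (sampling the population n times with
replacement).  Homogeneous populations are absorbing: without mutation a
strategy that has vanished can never reappear, so simulation short-circuits
on absorption and pads the trajectory with the absorbing value.

The generation loop is compiled with numba when available; a pure-Python
kernel implementing the identical algorithm is used otherwise (the two
paths are equal in distribution, not bit-identical).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np
from scipy.special import expit

from .games import GameSpec, PayoffMatrix, payoff_matrix

try:  # pragma: no cover - exercised implicitly by which kernel runs
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "SimConfig",
    "Trajectory",
    "NetworkArrays",
    "fermi_probability",
    "replicator_probability",
    "interaction_update_step",
    "flip_probability",
    "simulate",
    "run_ensemble",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation experiment.

    generations: number of n-step interaction/update rounds.
    p0: initial cooperator fraction; exactly round(p0*n) cooperators are
        placed uniformly at random (no Bernoulli initial-condition noise).
    beta: selection strength of the Fermi rule (> 0); beta -> 0 is neutral.
    update_rule: "fermi" or "replicator".
    runs: number of independent replicate runs.
    seed: master seed; run r uses the derived stream seed (seed + r) mod 2^31-1.
    regenerate_network_per_run: draw a fresh network instance per run when a
        generator is supplied (vs. reusing one instance for all runs).
    """

    generations: int = 2000
    p0: float = 0.5
    beta: float = 1.0
    update_rule: str = "fermi"
    runs: int = 10
    seed: int = 0
    regenerate_network_per_run: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must lie in [0, 1], got {self.p0}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.update_rule not in ("fermi", "replicator"):
            raise ValueError(f"unknown update rule {self.update_rule!r}")
        if self.update_rule == "fermi" and not self.beta > 0:
            raise ValueError(f"fermi rule requires beta > 0, got {self.beta}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """Cooperator fraction per generation for one run.

    p_t has length generations+1 with p_t[0] the initial fraction;
    absorbed_at is the first generation index at which the population was
    homogeneous (None if never absorbed), and p_t is constant from there on.
    """

    p_t: np.ndarray
    absorbed_at: int | None
    seed: int

    @property
    def final(self) -> float:
        return float(self.p_t[-1])


class NetworkArrays:
    """CSR adjacency view of a graph for the simulation kernels."""

    def __init__(self, g: nx.Graph):
        n = g.number_of_nodes()
        if set(g.nodes()) != set(range(n)):
            raise ValueError("graph vertices must be labelled 0..n-1")
        degs = np.array([g.degree(v) for v in range(n)], dtype=np.int64)
        if (degs == 0).any():
            raise ValueError("graph must have no isolated vertices")
        self.n = n
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(degs, out=self.indptr[1:])
        self.indices = np.empty(self.indptr[-1], dtype=np.int64)
        for v in range(n):
            self.indices[self.indptr[v]: self.indptr[v + 1]] = sorted(g.neighbors(v))

    def neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v]: self.indptr[v + 1]]


def fermi_probability(P_i: float, P_j: float, beta: float) -> float:
    """Probability that i adopts j's strategy under the Fermi rule.

    Overflow-safe for arbitrarily large |beta * (P_j - P_i)|; always in (0, 1),
    equal to 1/2 at equal payoffs, and satisfies p(i<-j) + p(j<-i) = 1.
    """
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    return float(expit(beta * (P_j - P_i)))


def replicator_probability(
    P_i: float, P_j: float, P_max: float, P_min: float
) -> float:
    """Probability that i adopts j's strategy under the replicator rule:
    0 when P_i >= P_j, else (P_j - P_i) / (P_max - P_min)."""
    if not (P_min <= P_i <= P_max and P_min <= P_j <= P_max):
        raise ValueError(
            f"payoffs ({P_i}, {P_j}) must lie within [{P_min}, {P_max}]"
        )
    if P_i >= P_j:
        return 0.0
    return (P_j - P_i) / (P_max - P_min)


def _adopt_probability(
    P_i: float, P_j: float, m: PayoffMatrix, cfg: SimConfig
) -> float:
    if cfg.update_rule == "fermi":
        return fermi_probability(P_i, P_j, cfg.beta)
    arr = m.as_array()
    return replicator_probability(P_i, P_j, float(arr.max()), float(arr.min()))


def interaction_update_step(
    net: NetworkArrays | nx.Graph,
    state: np.ndarray,
    m: PayoffMatrix,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One elementary interaction/update step, mutating ``state`` in place.

    Draw order: focal i, model j uniform on N(i), partner k uniform on
    N(i) \\ {j}, partner l uniform on N(j) \\ {i} (exclusions vacuous at
    degree 1), then the adoption coin.  Returns the (mutated) state array.
    """
    if isinstance(net, nx.Graph):
        net = NetworkArrays(net)
    pay = m.as_array()
    i = int(rng.integers(net.n))
    ni = net.neighbors(i)
    j = int(ni[rng.integers(len(ni))])
    k = int(ni[rng.integers(len(ni))])
    if len(ni) > 1:
        while k == j:
            k = int(ni[rng.integers(len(ni))])
    nj = net.neighbors(j)
    l = int(nj[rng.integers(len(nj))])
    if len(nj) > 1:
        while l == i:
            l = int(nj[rng.integers(len(nj))])
    P_i = pay[state[i], state[k]]
    P_j = pay[state[j], state[l]]
    if rng.random() < _adopt_probability(P_i, P_j, m, cfg):
        state[i] = state[j]
    return state


def flip_probability(
    net: NetworkArrays | nx.Graph,
    state: np.ndarray,
    i: int,
    m: PayoffMatrix,
    cfg: SimConfig,
) -> float:
    """Exact probability that focal vertex i changes strategy in one step.

    Marginalizes the neighbor draws analytically: given the model j, the
    focal payoff depends only on whether the sampled partner k in
    N(i) \\ {j} cooperates, so P_i takes one of two values with weights
    given by the cooperator fraction of that restricted neighborhood, and
    likewise P_j over N(j) \\ {i}.  Only neighbors j with a strategy
    different from i's can change it.
    """
    if isinstance(net, nx.Graph):
        net = NetworkArrays(net)
    pay = m.as_array()
    s_i = int(state[i])
    ni = net.neighbors(i)
    total = 0.0
    for j in ni:
        j = int(j)
        s_j = int(state[j])
        if s_j == s_i:
            continue
        # partner pool for i excludes j (unless j is i's only neighbor)
        if len(ni) > 1:
            pool_i = ni[ni != j]
        else:
            pool_i = ni
        frac_c_i = float(state[pool_i].mean())
        nj = net.neighbors(j)
        if len(nj) > 1:
            pool_j = nj[nj != i]
        else:
            pool_j = nj
        frac_c_j = float(state[pool_j].mean())
        w_i = {1: frac_c_i, 0: 1.0 - frac_c_i}
        w_j = {1: frac_c_j, 0: 1.0 - frac_c_j}
        p = 0.0
        for sk, wk in w_i.items():
            for sl, wl in w_j.items():
                if wk == 0.0 or wl == 0.0:
                    continue
                p += wk * wl * _adopt_probability(
                    pay[s_i, sk], pay[s_j, sl], m, cfg
                )
        total += p / len(ni)
    return total


# ---------------------------------------------------------------------------
# Generation-loop kernels
# ---------------------------------------------------------------------------

def _kernel_python(indptr, indices, state, pay, beta, use_fermi, pmax, pmin,
                   generations, seed):
    rng = np.random.RandomState(seed)
    n = state.shape[0]
    ncoop = int(state.sum())
    p_t = np.empty(generations + 1)
    p_t[0] = ncoop / n
    absorbed_at = -1
    for t in range(1, generations + 1):
        if ncoop == 0 or ncoop == n:
            if absorbed_at < 0:
                absorbed_at = t - 1
            p_t[t:] = ncoop / n
            break
        for _ in range(n):
            i = rng.randint(n)
            di = indptr[i + 1] - indptr[i]
            j = indices[indptr[i] + rng.randint(di)]
            k = indices[indptr[i] + rng.randint(di)]
            if di > 1:
                while k == j:
                    k = indices[indptr[i] + rng.randint(di)]
            dj = indptr[j + 1] - indptr[j]
            l = indices[indptr[j] + rng.randint(dj)]
            if dj > 1:
                while l == i:
                    l = indices[indptr[j] + rng.randint(dj)]
            P_i = pay[state[i], state[k]]
            P_j = pay[state[j], state[l]]
            if use_fermi:
                x = beta * (P_j - P_i)
                if x >= 0:
                    prob = 1.0 / (1.0 + np.exp(-x))
                else:
                    e = np.exp(x)
                    prob = e / (1.0 + e)
            else:
                prob = 0.0 if P_i >= P_j else (P_j - P_i) / (pmax - pmin)
            if rng.random_sample() < prob and state[i] != state[j]:
                ncoop += 1 if state[j] == 1 else -1
                state[i] = state[j]
        p_t[t] = ncoop / n
    else:
        if ncoop in (0, n) and absorbed_at < 0:
            absorbed_at = generations
    return p_t, absorbed_at


if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _kernel_numba(indptr, indices, state, pay, beta, use_fermi, pmax, pmin,
                      generations, seed):  # pragma: no cover - compiled
        np.random.seed(seed)
        n = state.shape[0]
        ncoop = 0
        for v in range(n):
            ncoop += state[v]
        p_t = np.empty(generations + 1)
        p_t[0] = ncoop / n
        absorbed_at = -1
        for t in range(1, generations + 1):
            if ncoop == 0 or ncoop == n:
                if absorbed_at < 0:
                    absorbed_at = t - 1
                for tt in range(t, generations + 1):
                    p_t[tt] = ncoop / n
                return p_t, absorbed_at
            for _ in range(n):
                i = np.random.randint(0, n)
                di = indptr[i + 1] - indptr[i]
                j = indices[indptr[i] + np.random.randint(0, di)]
                k = indices[indptr[i] + np.random.randint(0, di)]
                if di > 1:
                    while k == j:
                        k = indices[indptr[i] + np.random.randint(0, di)]
                dj = indptr[j + 1] - indptr[j]
                l = indices[indptr[j] + np.random.randint(0, dj)]
                if dj > 1:
                    while l == i:
                        l = indices[indptr[j] + np.random.randint(0, dj)]
                P_i = pay[state[i], state[k]]
                P_j = pay[state[j], state[l]]
                if use_fermi:
                    x = beta * (P_j - P_i)
                    if x >= 0:
                        prob = 1.0 / (1.0 + np.exp(-x))
                    else:
                        e = np.exp(x)
                        prob = e / (1.0 + e)
                else:
                    if P_i >= P_j:
                        prob = 0.0
                    else:
                        prob = (P_j - P_i) / (pmax - pmin)
                if np.random.random() < prob and state[i] != state[j]:
                    ncoop += 1 if state[j] == 1 else -1
                    state[i] = state[j]
            p_t[t] = ncoop / n
        if ncoop == 0 or ncoop == n:
            if absorbed_at < 0:
                absorbed_at = generations
        return p_t, absorbed_at


def _initial_state(n: int, p0: float, rng: np.random.Generator) -> np.ndarray:
    """Exactly round(p0*n) cooperators placed uniformly at random."""
    n_coop = int(round(p0 * n))
    state = np.zeros(n, dtype=np.int8)
    state[rng.choice(n, size=n_coop, replace=False)] = 1
    return state


def simulate(
    g: nx.Graph | NetworkArrays,
    spec: GameSpec,
    cfg: SimConfig,
    run_index: int = 0,
) -> Trajectory:
    """Run one replicate of the individual-based dynamics and record p_t.

    The run seed is derived from the master seed as (seed + run_index)
    mod 2^31-1; the initial strategy placement and the generation loop use
    that same seed in separate streams.
    """
    net = g if isinstance(g, NetworkArrays) else NetworkArrays(g)
    m = payoff_matrix(spec)
    pay = m.as_array()
    run_seed = int((cfg.seed + run_index) % _SEED_MOD)
    state = _initial_state(net.n, cfg.p0, np.random.default_rng(run_seed))
    use_fermi = cfg.update_rule == "fermi"
    kernel = _kernel_numba if _HAVE_NUMBA else _kernel_python
    p_t, absorbed_at = kernel(
        net.indptr,
        net.indices,
        state,
        pay,
        float(cfg.beta),
        use_fermi,
        float(pay.max()),
        float(pay.min()),
        int(cfg.generations),
        run_seed,
    )
    return Trajectory(
        p_t=np.asarray(p_t),
        absorbed_at=None if absorbed_at < 0 else int(absorbed_at),
        seed=run_seed,
    )


def run_ensemble(
    g: nx.Graph | Callable[[int], nx.Graph],
    spec: GameSpec,
    cfg: SimConfig,
) -> list[Trajectory]:
    """Run cfg.runs replicates; ``g`` may be a fixed graph or a seed->graph
    factory (used per run when cfg.regenerate_network_per_run is set)."""
    trajectories = []
    if callable(g):
        base = None if cfg.regenerate_network_per_run else g(cfg.seed)
    else:
        base = g
    for r in range(cfg.runs):
        if base is None:
            graph = g(int((cfg.seed + 1000003 * (r + 1)) % _SEED_MOD))
        else:
            graph = base
        trajectories.append(simulate(graph, spec, cfg, run_index=r))
    return trajectories
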