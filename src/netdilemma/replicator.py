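"""Well-mixed replicator dynamics for symmetric 2x2 games.

For cooperator frequency p the replicator equation reads

    dp/dt = p (1 - p) [ p (alpha - gamma) + (1 - p) (beta - delta) ],

i.e. p grows when the fitness of C exceeds the population mean.  The
boundary points p = 0 and p = 1 are always equilibria; an interior
equilibrium exists when the bracket changes sign on (0, 1).

The module also provides the long-term cooperator fraction reached from an
initial frequency p0, and the cooperation index: the normalized integral of
that long-term fraction over the game's admissible cost-to-benefit interval
(A, B),

    Lambda = 1/(B - A) * integral_A^B pbar_inf(rho) d rho,

a parameter-free number in [0, 1] that summarises how cooperative a game is
over its whole parameter range.  Well-mixed closed forms: Lambda = 0 for
donation, 2 - ln 4 for snowdrift, and p0 for sculling started from p0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .games import GameSpec, PayoffMatrix, RHO_RANGES, payoff_matrix

__all__ = [
    "Equilibrium",
    "replicator_rhs",
    "equilibria",
    "integrate_replicator",
    "wellmixed_longterm",
    "wellmixed_lambda",
]

#: |p0 - separatrix| below which the sculling basin is considered undecidable.
SEPARATRIX_TOL = 1e-12


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the replicator dynamics with its local stability."""

    p_star: float
    stable: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_star <= 1.0:
            raise ValueError(f"p_star must lie in [0, 1], got {self.p_star}")

    @property
    def stability(self) -> str:
        return "asymptotically-stable" if self.stable else "unstable"


def replicator_rhs(p: float, m: PayoffMatrix) -> float:
    """Right-hand side of the replicator equation at cooperator frequency p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency p must lie in [0, 1], got {p}")
    return p * (1.0 - p) * (p * (m.alpha - m.gamma) + (1.0 - p) * (m.beta - m.delta))


def _interior_root(m: PayoffMatrix) -> float | None:
    """Root of p(alpha-gamma) + (1-p)(beta-delta) = 0 inside (0, 1), if any."""
    a = m.alpha - m.gamma
    b = m.beta - m.delta
    if a == b:  # bracket is constant in p
        return None
    p = b / (b - a)
    return p if 0.0 < p < 1.0 else None


def equilibria(m: PayoffMatrix, eps: float = 1e-6) -> list[Equilibrium]:
    """All equilibria of the replicator dynamics with stability flags.

    Stability is judged by the sign of the flow on either side of each
    fixed point (robust at non-hyperbolic points where the derivative
    vanishes): a point is asymptotically stable when the flow approaches
    it from both admissible sides.
    """
    points = [0.0, 1.0]
    interior = _interior_root(m)
    if interior is not None:
        points.insert(1, interior)

    def flow(p: float) -> float:
        return replicator_rhs(p, m)

    result = []
    for p in points:
        left = flow(max(p - eps, 0.0 + eps / 2)) if p > 0.0 else None
        right = flow(min(p + eps, 1.0 - eps / 2)) if p < 1.0 else None
        stable = True
        if left is not None and left < 0:
            stable = False  # flow moves away below p
        if right is not None and right > 0:
            stable = False  # flow moves away above p
        result.append(Equilibrium(p, stable))
    return result


def integrate_replicator(
    m: PayoffMatrix,
    p0: float,
    t_max: float = 1e6,
    rhs_tol: float = 1e-10,
) -> float:
    """Integrate the replicator ODE from p0 until the flow effectively stops.

    Integration runs until |dp/dt| < ``rhs_tol`` or t = ``t_max``, whichever
    comes first; all attractors of the three exemplar games are hyperbolic
    away from interval endpoints, so convergence is exponential.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")

    def rhs(_t, y):
        p = min(max(y[0], 0.0), 1.0)
        return [replicator_rhs(p, m)]

    def settled(_t, y):
        p = min(max(y[0], 0.0), 1.0)
        return abs(replicator_rhs(p, m)) - rhs_tol

    settled.terminal = True
    settled.direction = -1
    sol = solve_ivp(
        rhs, (0.0, t_max), [p0], events=settled, rtol=1e-10, atol=1e-12,
        method="LSODA",
    )
    return float(min(max(sol.y[0, -1], 0.0), 1.0))


def _attractor_from(m: PayoffMatrix, p0: float) -> float:
    """Attractor of the replicator flow reached from interior p0 (analytic).

    The equilibria partition [0, 1] into intervals on which the flow has a
    single sign; from p0 the trajectory moves monotonically to the endpoint
    of its interval in the direction of the flow.
    """
    eqs = sorted(e.p_star for e in equilibria(m))
    for lo, hi in zip(eqs[:-1], eqs[1:]):
        if lo <= p0 <= hi:
            if p0 == lo or p0 == hi:
                return p0  # started exactly on a fixed point
            v = replicator_rhs(p0, m)
            if v > 0:
                return hi
            if v < 0:
                return lo
            return p0
    raise RuntimeError("p0 outside [0, 1] partition")  # pragma: no cover


def wellmixed_longterm(
    spec: GameSpec, p0: float, method: str = "analytic"
) -> float:
    """Long-term cooperator fraction reached from p0 in a well-mixed population.

    donation -> 0; snowdrift -> (1 - rho)/(1 - rho/2); sculling -> 1 when
    p0 exceeds the separatrix rho - 1/2 and 0 when below it.  Starting the
    sculling game exactly on its separatrix is rejected, since the basin is
    then undefined.

    ``method="ode"`` computes the same limit by long-time numerical
    integration of the replicator equation (used as an internal cross-check).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in the open interval (0, 1), got {p0}")
    if spec.family == "sculling":
        separatrix = spec.rho - 0.5
        if abs(p0 - separatrix) < SEPARATRIX_TOL:
            raise ValueError(
                f"p0={p0} lies on the sculling separatrix p* = rho - 1/2 = "
                f"{separatrix}; the long-term state is undefined there"
            )
    m = payoff_matrix(spec)
    if method == "analytic":
        return _attractor_from(m, p0)
    if method == "ode":
        return integrate_replicator(m, p0)
    raise ValueError(f"unknown method {method!r}; expected 'analytic' or 'ode'")


def _longterm_curve(family: str, rho: float, p0: float) -> float:
    """pbar_inf(rho) for the Lambda quadrature; separatrix points (a set of
    measure zero) contribute the mean of the two basin attractors."""
    spec = GameSpec(family, rho)
    try:
        return wellmixed_longterm(spec, p0)
    except ValueError:
        m = payoff_matrix(spec)
        below = _attractor_from(m, max(p0 - 1e-9, 1e-12))
        above = _attractor_from(m, min(p0 + 1e-9, 1 - 1e-12))
        return 0.5 * (below + above)


def wellmixed_lambda(
    family: str,
    p0: float = 0.5,
    method: str = "closed_form",
    n_grid: int = 101,
) -> float:
    """Cooperation index of a game under well-mixed replicator dynamics.

    Closed forms: donation 0 (defection always wins); snowdrift
    2 - ln 4 ~ 0.614 (integral of the interior equilibrium
    (1-rho)/(1-rho/2) over (0,1)); sculling p0 (cooperation fixes exactly
    when rho < p0 + 1/2, a fraction p0 of the interval (1/2, 3/2)).

    ``method="quadrature"`` evaluates the defining integral by the midpoint
    rule on ``n_grid`` uniformly spaced interior points, avoiding the
    excluded endpoints of the open interval; closed form and quadrature
    agree to well below 1e-4 at the default grid.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if family not in RHO_RANGES:
        raise ValueError(f"unknown game family {family!r}")
    a, b = RHO_RANGES[family]
    if method == "closed_form":
        if family == "donation":
            return 0.0
        if family == "snowdrift":
            return 2.0 - math.log(4.0)
        # sculling: pbar_inf(rho) = 1 iff rho < p0 + 1/2 on (1/2, 3/2)
        return float(p0)
    if method == "quadrature":
        h = (b - a) / n_grid
        grid = a + (np.arange(n_grid) + 0.5) * h
        vals = [_longterm_curve(family, float(r), p0) for r in grid]
        return float(np.sum(vals) * h / (b - a))
    raise ValueError(f"unknown method {method!r}")
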