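"""Normalized payoff matrices for three exemplar social dilemmas.

The donation, snowdrift and sculling games are canonical representatives of
the prisoner's dilemma, hawk-dove and coordination classes of symmetric 2x2
games.  Each game is indexed by a single cost-to-benefit ratio ``rho = c/b``;
after dividing all payoffs by the benefit ``b`` (an affine transformation
that leaves the evolutionary dynamics unchanged) the matrix

    pi = [[alpha, beta],
          [gamma, delta]]

(rows/columns ordered cooperate, defect) takes the normalized forms

    donation:  alpha = 1 - rho,   beta = -rho,       gamma = 1,   delta = 0
    snowdrift: alpha = 1 - rho/2, beta = 1 - rho,    gamma = 1,   delta = 0
    sculling:  alpha = 2 - rho,   beta = 1/2 - rho,  gamma = 1/2, delta = 0

with rho restricted to (0, 1) for donation and snowdrift and to (1/2, 3/2)
for sculling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GameFamily",
    "PayoffMatrix",
    "GameSpec",
    "DominanceReport",
    "RHO_RANGES",
    "payoff_matrix",
    "classify_game",
    "sculling_dominance",
]

# Strategy encoding used across the package: D = 0, C = 1.
DEFECT = 0
COOPERATE = 1

GameFamily = str  # one of "donation", "snowdrift", "sculling"

#: Open admissible interval (A, B) of the cost-to-benefit ratio per game.
RHO_RANGES: dict[str, tuple[float, float]] = {
    "donation": (0.0, 1.0),
    "snowdrift": (0.0, 1.0),
    "sculling": (0.5, 1.5),
}


@dataclass(frozen=True)
class PayoffMatrix:
    """Payoffs of a symmetric 2x2 game with strategies C (cooperate), D (defect).

    alpha : payoff to C against C
    beta  : payoff to C against D
    gamma : payoff to D against C
    delta : payoff to D against D
    """

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"payoff entry {name} must be finite, got {v!r}")

    def payoff(self, own: int, opponent: int) -> float:
        """Payoff to a player using ``own`` against ``opponent`` (0=D, 1=C)."""
        return self.as_array()[own, opponent]

    def as_array(self) -> np.ndarray:
        """2x2 array indexed by the package's strategy encoding [own, opponent]."""
        return np.array(
            [[self.delta, self.gamma], [self.beta, self.alpha]], dtype=float
        )


@dataclass(frozen=True)
class GameSpec:
    """A game family together with its cost-to-benefit ratio.

    The admissible open interval (A, B) for ``rho`` is attached so that
    downstream code (the cooperation index in particular) can integrate
    over it without consulting a table.
    """

    family: str
    rho: float
    rho_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.family not in RHO_RANGES:
            raise ValueError(
                f"unknown game family {self.family!r}; "
                f"expected one of {sorted(RHO_RANGES)}"
            )
        if self.rho_range is None:
            object.__setattr__(self, "rho_range", RHO_RANGES[self.family])
        a, b = self.rho_range
        if not a < b:
            raise ValueError(f"rho_range must satisfy A < B, got ({a}, {b})")
        if not (a < self.rho < b):
            raise ValueError(
                f"{self.family} game requires rho in the open interval "
                f"({a}, {b}); got rho={self.rho}"
            )

    def payoff_matrix(self) -> PayoffMatrix:
        return payoff_matrix(self)


def payoff_matrix(spec: GameSpec) -> PayoffMatrix:
    """Normalized payoff matrix of the given game at its cost-to-benefit ratio."""
    rho = spec.rho
    if spec.family == "donation":
        return PayoffMatrix(1.0 - rho, -rho, 1.0, 0.0)
    if spec.family == "snowdrift":
        return PayoffMatrix(1.0 - rho / 2.0, 1.0 - rho, 1.0, 0.0)
    if spec.family == "sculling":
        return PayoffMatrix(2.0 - rho, 0.5 - rho, 0.5, 0.0)
    raise ValueError(f"unknown game family {spec.family!r}")


def classify_game(m: PayoffMatrix, atol: float = 0.0) -> str:
    """Classify a symmetric 2x2 game by the rank ordering of its payoffs.

    Returns one of ``"prisoners-dilemma"`` (defection dominates a socially
    superior outcome: gamma > alpha and delta > beta), ``"hawk-dove"``
    (each strategy invades the other: gamma > alpha and beta > delta),
    ``"coordination"`` (both monomorphic states uninvadable: alpha > gamma
    and delta > beta), or ``"harmony"`` (cooperation dominates).  Ties in
    the rank-relevant comparisons yield ``"degenerate"`` rather than an
    exception so that parameter sweeps crossing a boundary do not abort.

    The classification is invariant under affine transformations of the
    payoff matrix (adding a constant, scaling by a positive constant),
    since it depends only on the signs of gamma - alpha and delta - beta.
    """
    dc = m.gamma - m.alpha  # advantage of defecting against a cooperator
    dd = m.delta - m.beta  # advantage of defecting against a defector
    if abs(dc) <= atol or abs(dd) <= atol:
        return "degenerate"
    if dc > 0 and dd > 0:
        return "prisoners-dilemma"
    if dc > 0 and dd < 0:
        return "hawk-dove"
    if dc < 0 and dd > 0:
        return "coordination"
    return "harmony"


@dataclass(frozen=True)
class DominanceReport:
    """Equilibrium-selection report for the sculling (coordination) game."""

    payoff_dominant: str  # always "CC" for the sculling game
    risk_dominant: str  # "CC", "DD", or "tie"
    stag_hunt: bool  # payoff- and risk-dominance disagree


def sculling_dominance(rho: float) -> DominanceReport:
    """Payoff- and risk-dominance of the sculling game's pure equilibria.

    (C,C) is payoff-dominant for every admissible rho.  Risk dominance
    compares alpha + beta against gamma + delta: (C,C) is risk-dominant for
    rho < 1, (D,D) for rho > 1, with a tie exactly at rho = 1.  In the
    regime rho in (1, 3/2), where payoff dominance and risk dominance
    disagree, the game is a stag hunt.
    """
    a, b = RHO_RANGES["sculling"]
    if not (a < rho < b):
        raise ValueError(f"sculling game requires rho in ({a}, {b}); got {rho}")
    m = payoff_matrix(GameSpec("sculling", rho))
    margin = (m.alpha + m.beta) - (m.gamma + m.delta)  # = 2(1 - rho)
    if margin > 0:
        risk = "CC"
    elif margin < 0:
        risk = "DD"
    else:
        risk = "tie"
    return DominanceReport(
        payoff_dominant="CC", risk_dominant=risk, stag_hunt=(risk == "DD")
    )
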