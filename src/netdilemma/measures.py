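"""Long-term cooperator fractions and the cooperation index Lambda.

The long-term mean pbar_inf(rho) is the time average of the cooperator
fraction p_t at quasi-stationarity, estimated from a finite trajectory by
averaging over its final portion (after a burn-in).  The cooperation index

    Lambda = 1/(B - A) * integral_A^B pbar_inf(rho) d rho

integrates that long-term fraction over the game's admissible
cost-to-benefit interval (A, B), giving a single parameter-free number in
[0, 1] with which cooperation levels can be compared across games and
networks (Lambda = 1: complete cooperation; Lambda = 0: none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import Trajectory

__all__ = [
    "LambdaResult",
    "long_term_mean",
    "cooperation_index",
    "aggregate_runs",
    "midpoint_grid",
]

#: Default fraction of the trajectory discarded before time-averaging.
DEFAULT_BURN_IN = 0.5


@dataclass(frozen=True)
class LambdaResult:
    """Per-rho long-term means plus the integrated cooperation index.

    pbar/pbar_var are across-run mean and (population) variance per grid
    point; lambda_mean/lambda_var are the mean and variance of the per-run
    index values, matching error bars reported as across-run variance.
    """

    rho_grid: np.ndarray
    pbar: np.ndarray
    pbar_var: np.ndarray
    lambda_mean: float
    lambda_var: float


def midpoint_grid(A: float, B: float, n_points: int) -> np.ndarray:
    """Uniform midpoint grid of n_points strictly inside the open (A, B)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    h = (B - A) / n_points
    return A + (np.arange(n_points) + 0.5) * h


def long_term_mean(
    tr: Trajectory | np.ndarray, burn_in_fraction: float = DEFAULT_BURN_IN
) -> float:
    """Time-averaged cooperator fraction over the post-burn-in window.

    Averages p_t over generations t with t > burn_in_fraction * T, where
    T is the number of generations (the initial point p_0 never enters).
    For a trajectory absorbed before the cutoff this simply returns the
    absorbing value.
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError(
            f"burn_in_fraction must lie in [0, 1), got {burn_in_fraction}"
        )
    p_t = tr.p_t if isinstance(tr, Trajectory) else np.asarray(tr, dtype=float)
    T = len(p_t) - 1
    if T < 1:
        raise ValueError("trajectory must contain at least one generation")
    t_start = int(np.floor(burn_in_fraction * T)) + 1
    window = p_t[t_start:]
    if window.size == 0:
        raise ValueError("empty post-burn-in window")
    return float(window.mean())


def cooperation_index(
    rho_grid: np.ndarray,
    pbar_values: np.ndarray,
    A: float,
    B: float,
) -> float:
    """Midpoint-rule estimate of Lambda from pbar_inf sampled on a grid.

    The grid must be strictly increasing and strictly inside (A, B); each
    grid point is weighted by the cell it is the midpoint of (cell
    boundaries: midpoints between consecutive grid points, closed off by A
    and B), so for a uniform midpoint grid this is the classical composite
    midpoint rule.
    """
    rho = np.asarray(rho_grid, dtype=float)
    vals = np.asarray(pbar_values, dtype=float)
    if rho.ndim != 1 or rho.shape != vals.shape:
        raise ValueError("rho_grid and pbar_values must be equal-length 1-D")
    if rho.size == 0:
        raise ValueError("empty rho grid")
    if np.any(np.diff(rho) <= 0):
        raise ValueError("rho_grid must be strictly increasing")
    if rho[0] <= A or rho[-1] >= B:
        raise ValueError(f"rho_grid must lie strictly inside ({A}, {B})")
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("pbar values must lie in [0, 1]")
    bounds = np.concatenate(([A], 0.5 * (rho[1:] + rho[:-1]), [B]))
    widths = np.diff(bounds)
    return float(np.sum(widths * vals) / (B - A))


def aggregate_runs(
    rho_grid: np.ndarray,
    per_run_pbar: np.ndarray,
    A: float,
    B: float,
) -> LambdaResult:
    """Aggregate per-run pbar_inf estimates into a LambdaResult.

    ``per_run_pbar`` has shape (runs, len(rho_grid)).  The index is computed
    per run and then averaged, with across-run population variance reported
    (so identical runs give variance exactly 0).
    """
    rho = np.asarray(rho_grid, dtype=float)
    arr = np.asarray(per_run_pbar, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != rho.size:
        raise ValueError(
            f"per_run_pbar must have shape (runs, {rho.size}), got {arr.shape}"
        )
    lambdas = np.array(
        [cooperation_index(rho, row, A, B) for row in arr]
    )
    return LambdaResult(
        rho_grid=rho,
        pbar=arr.mean(axis=0),
        pbar_var=arr.var(axis=0),
        lambda_mean=float(lambdas.mean()),
        lambda_var=float(lambdas.var()),
    )
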