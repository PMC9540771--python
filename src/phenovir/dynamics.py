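"""Between-season dynamics: annual map, persistence, resident equilibrium.

Progeny left in the environment at the end of season ``n`` are the free
parasites at the start of season ``n+1``, so the year-to-year dynamics are
iterations of the seasonal map ``v_hat -> v2(T; v_init=v_hat)``.  The
parasite persists when a single parasite introduced at the season start
more than replaces itself (``season_map(1) >= 1``); host depletion makes
the per-capita growth decrease with density, so a persistent strain has a
unique positive fixed point ``v_star``, the resident equilibrium density
used as the environment in invasion analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .core import ModelParams, v2_end_of_season

logger = logging.getLogger("phenovir")

#: relative tolerance on the equilibrium fixed point
EQUILIBRIUM_RTOL = 1e-10
#: residual bound below which an equilibrium counts as converged
EQUILIBRIUM_RESIDUAL_TOL = 1e-8

__all__ = [
    "EquilibriumResult",
    "PersistenceResult",
    "season_map",
    "persistence_check",
    "resident_equilibrium",
    "detect_period_two",
]


@dataclass(frozen=True)
class EquilibriumResult:
    """Resident start-of-season equilibrium density with diagnostics.

    ``residual`` is ``|season_map(v_star) - v_star| / max(v_star, 1)``.
    ``v_star = 0`` (extinction) is a valid converged outcome.
    """

    v_star: float
    iterations: int
    converged: bool
    residual: float
    note: str = ""


@dataclass(frozen=True)
class PersistenceResult:
    """Outcome of the single-parasite invasion-of-the-void criterion."""

    growth_factor: float
    persists: bool


def season_map(v_hat: float, params: ModelParams) -> float:
    """End-of-season progeny density from start-of-season density ``v_hat``."""
    if v_hat < 0:
        raise ValueError(f"v_hat must be >= 0, got {v_hat}")
    if v_hat == 0.0:
        return 0.0
    p = params.replace(v_init=v_hat)
    return v2_end_of_season(p.host, p.season, p.traits)


def persistence_check(params: ModelParams) -> PersistenceResult:
    """Can a single parasite introduced at the season start persist?

    Returns the growth factor ``season_map(1)`` and whether it is at least
    one (the parasite-free state is unstable when the annual multiplication
    of a lone parasite has modulus greater than unity).
    """
    if params.tau >= params.T:
        return PersistenceResult(growth_factor=0.0, persists=False)
    growth = season_map(1.0, params)
    return PersistenceResult(growth_factor=growth, persists=bool(growth >= 1.0))


def detect_period_two(
    map_fn: Callable[[float], float],
    v0: float,
    n_burn: int = 200,
    n_check: int = 12,
    rtol: float = 1e-6,
) -> Optional[tuple[float, float]]:
    """Detect a period-2 orbit of a one-dimensional map by iteration.

    Returns the alternating pair ``(v_a, v_b)`` if the trajectory settles
    onto a 2-cycle with distinct points, otherwise ``None``.  Used as a
    diagnostic when fixed-point solving fails: oscillatory annual dynamics
    are reported rather than silently averaged.
    """
    v = v0
    for _ in range(n_burn):
        v = map_fn(v)
        if not np.isfinite(v) or v < 0:
            return None
    tail = []
    for _ in range(n_check):
        v = map_fn(v)
        tail.append(v)
    evens, odds = tail[0::2], tail[1::2]
    scale = max(abs(np.mean(evens)), abs(np.mean(odds)), 1.0)
    if (
        np.ptp(evens) < rtol * scale
        and np.ptp(odds) < rtol * scale
        and abs(np.mean(evens) - np.mean(odds)) > 10 * rtol * scale
    ):
        return (float(np.mean(evens)), float(np.mean(odds)))
    return None


def resident_equilibrium(
    params: ModelParams,
    v_guess: float = 1.0,
    rtol: float = EQUILIBRIUM_RTOL,
    max_expand: int = 120,
) -> EquilibriumResult:
    """Solve ``season_map(v_star) = v_star`` for the resident density.

    Host depletion makes the per-capita growth ``season_map(v)/v`` strictly
    decreasing in ``v``, so the nontrivial fixed point is bracketed by
    expanding upward from the persistence threshold and located by
    root-finding on the log growth (robust where plain fixed-point
    iteration may oscillate).  Non-persistent parasites get the extinction
    equilibrium ``v_star = 0``.
    """
    n_evals = 0

    def growth(v: float) -> float:
        nonlocal n_evals
        n_evals += 1
        return season_map(v, params) / v

    check = persistence_check(params)
    if not check.persists:
        return EquilibriumResult(
            v_star=0.0, iterations=0, converged=True, residual=0.0, note="extinct"
        )

    lo = max(v_guess, 1.0)
    g_lo = growth(lo)
    while g_lo < 1.0 and lo > 1.0:  # guess overshot the fixed point
        lo = max(lo / 8.0, 1.0)
        g_lo = growth(lo)
    if g_lo == 1.0:
        return EquilibriumResult(lo, n_evals, True, 0.0)

    hi = lo
    g_hi = g_lo
    for _ in range(max_expand):
        hi *= 8.0
        g_hi = growth(hi)
        if not np.isfinite(g_hi):
            break
        if g_hi < 1.0:
            break
    if not np.isfinite(g_hi) or g_hi >= 1.0:
        cycle = detect_period_two(lambda v: season_map(v, params), lo)
        note = f"period-2 orbit detected: {cycle}" if cycle else "bracketing failed"
        logger.warning("resident_equilibrium: %s", note)
        return EquilibriumResult(hi, n_evals, False, np.inf, note=note)

    x_star = brentq(
        lambda x: np.log(growth(np.exp(x))),
        np.log(lo),
        np.log(hi),
        xtol=1e-13,
        rtol=8.9e-16,
    )
    v_star = float(np.exp(x_star))
    residual = float(abs(season_map(v_star, params) - v_star) / max(v_star, 1.0))
    converged = residual < EQUILIBRIUM_RESIDUAL_TOL
    if not converged:
        cycle = detect_period_two(lambda v: season_map(v, params), v_star)
        note = f"period-2 orbit detected: {cycle}" if cycle else "large residual"
        logger.warning("resident_equilibrium: %s (residual %.3g)", note, residual)
        return EquilibriumResult(v_star, n_evals, False, residual, note=note)
    return EquilibriumResult(v_star, n_evals, True, residual)
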