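"""Evolutionary invasion analysis of the incubation delay (virulence).

A rare mutant strain is introduced at density ``v1m(0) = 1`` into the
environment set by the resident at its between-season equilibrium
``v_star``.  Its invasion fitness is the end-of-season progeny density
``v2m(T)``, computed from the same integrating-factor solution as the
resident but with susceptible hosts depleted by both the resident's
infection pressure (``alpha * v_star * exp(-delta t)``) and the mutant's
own, vanishingly small, self-shading pressure
(``alpha_m * v1m(0) * exp(-delta_m t)``).  This measure conditions on the
resident-set host environment, so it is a valid invasion-fitness maximand
(it is not a basic reproduction number).

The singular strategy ``tau_star`` is the delay at which the selection
gradient ``d v2m(T) / d tau_m`` (evaluated at ``tau_m = tau_r``, with the
resident equilibrium recomputed for every candidate resident) vanishes;
it is evolutionarily stable when the second derivative is negative and
convergence stable when the gradient changes sign from positive to
negative across it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq

from .core import ModelParams, SusceptibleField, progeny_end_density
from .dynamics import resident_equilibrium
from .tradeoffs import TradeoffFunction

logger = logging.getLogger("phenovir")

#: finite-difference step scale for the selection gradient
GRADIENT_STEP_SCALE = 1e-4
#: absolute tolerance on tau for the singular-strategy root
TAU_ROOT_TOL = 1e-6

__all__ = [
    "MutantTraits",
    "SingularStrategy",
    "BoundaryDiagnosis",
    "SelectionGradient",
    "InvasionProblem",
    "mutant_end_of_season",
    "selection_gradient",
    "find_singular_strategy",
    "pip_grid",
]


@dataclass(frozen=True)
class MutantTraits:
    """Traits of the invading mutant strain (subscript-m parameters)."""

    tau: float
    alpha: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("tau", "alpha", "delta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    @classmethod
    def from_resident(cls, params: ModelParams, **overrides) -> "MutantTraits":
        """Mutant identical to the resident apart from ``overrides``."""
        base = dict(
            tau=params.tau, alpha=params.alpha, beta=params.beta, delta=params.delta
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class SelectionGradient:
    """Finite-difference selection gradient at a resident trait value."""

    value: float
    tau_r: float
    v_star: float
    one_sided: bool = False


@dataclass(frozen=True)
class SingularStrategy:
    """A located singular virulence strategy and its classification."""

    tau_star: float
    gradient_at_star: float
    second_derivative: float
    is_ess: bool
    is_convergence_stable: bool
    v_star: float
    environment: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BoundaryDiagnosis:
    """No interior singular point: selection is monotone or nothing persists."""

    reason: str
    bracket: tuple[float, float]
    gradient_signs: tuple = ()


def mutant_end_of_season(
    params: ModelParams,
    v_star: float,
    mutant: MutantTraits,
    v1m0: float = 1.0,
    tradeoff: Optional[TradeoffFunction] = None,
) -> float:
    """End-of-season progeny density ``v2m(T)`` of a rare mutant.

    ``v_star`` is the resident's start-of-season equilibrium density; the
    mutant enters at density ``v1m0``.  With ``tradeoff`` given, the
    mutant's progeny number is ``tradeoff(tau_m)`` instead of
    ``mutant.beta``.  Reduces exactly to the resident's end-of-season
    density when the mutant equals the resident and ``v_star = 0``.
    """
    if v_star < 0 or v1m0 < 0:
        raise ValueError("densities must be >= 0")
    beta_m = tradeoff(mutant.tau) if tradeoff is not None else mutant.beta
    return progeny_end_density(
        s_hat=params.s_hat,
        t_l=params.t_l,
        T=params.T,
        mu=params.mu,
        tau=mutant.tau,
        alpha=mutant.alpha,
        beta=beta_m,
        delta=mutant.delta,
        v0=v1m0,
        hazards=[
            (params.alpha * v_star, params.delta),
            (mutant.alpha * v1m0, mutant.delta),
        ],
    )


class InvasionProblem:
    """Mutant fitness as a function of ``tau_m`` in a fixed environment.

    The susceptible-host field depends on the infection pressures but not
    on the mutant's incubation delay, so it is built once and reused for
    every ``tau_m`` — finite-difference stencils and profile scans cost
    one cheap integral each.
    """

    def __init__(
        self,
        params: ModelParams,
        v_star: float,
        v1m0: float = 1.0,
        tradeoff: Optional[TradeoffFunction] = None,
    ):
        self.params = params
        self.v_star = float(v_star)
        self.v1m0 = float(v1m0)
        self.tradeoff = tradeoff
        self._field = SusceptibleField(
            params.s_hat,
            params.t_l,
            params.mu,
            hazards=[
                (params.alpha * self.v_star, params.delta),
                (params.alpha * self.v1m0, params.delta),
            ],
        )

    def beta_m(self, tau_m: float) -> float:
        if self.tradeoff is not None:
            return self.tradeoff(tau_m)
        return self.params.beta

    def fitness(self, tau_m: float) -> float:
        """Mutant end-of-season progeny density ``v2m(T)``."""
        p = self.params
        if tau_m >= p.T:
            return 0.0
        U = p.T - tau_m
        return (
            p.alpha
            * self.beta_m(tau_m)
            * np.exp(-p.mu * tau_m)
            * self.v1m0
            * np.exp(-p.delta * U)
            * self._field.integral(U)
        )

    def per_capita_growth(self, tau_m: float) -> float:
        return self.fitness(tau_m) / self.v1m0


def _equilibrium_density(params: ModelParams, tau_r: float) -> float:
    eq = resident_equilibrium(params.replace(tau=tau_r))
    if not eq.converged:
        raise RuntimeError(
            f"resident equilibrium did not converge at tau_r={tau_r:g}: {eq.note}"
        )
    return eq.v_star


def selection_gradient(
    params: ModelParams,
    tau_r: Optional[float] = None,
    *,
    v_star: Optional[float] = None,
    tradeoff: Optional[TradeoffFunction] = None,
    v1m0: float = 1.0,
    step_scale: float = GRADIENT_STEP_SCALE,
) -> SelectionGradient:
    """Derivative of mutant fitness w.r.t. ``tau_m`` at ``tau_m = tau_r``.

    Central finite difference with step ``step_scale * max(1, tau_r)``;
    when ``tau_r`` sits within one step of the phenological regime
    boundary ``T - t_l``, a second-order one-sided stencil confined to a
    single regime branch is used instead and flagged.
    """
    if tau_r is None:
        tau_r = params.tau
    pr = params.replace(tau=tau_r)
    if v_star is None:
        v_star = _equilibrium_density(params, tau_r)
        if v_star == 0.0:
            raise ValueError(f"resident does not persist at tau_r={tau_r:g}")
    problem = InvasionProblem(pr, v_star, v1m0=v1m0, tradeoff=tradeoff)
    h = step_scale * max(1.0, tau_r)
    boundary = params.T - params.t_l
    one_sided = abs(tau_r - boundary) < h
    W = problem.fitness
    if not one_sided:
        value = (W(tau_r + h) - W(tau_r - h)) / (2.0 * h)
    elif tau_r <= boundary:
        value = (3.0 * W(tau_r) - 4.0 * W(tau_r - h) + W(tau_r - 2.0 * h)) / (2.0 * h)
    else:
        value = (-3.0 * W(tau_r) + 4.0 * W(tau_r + h) - W(tau_r + 2.0 * h)) / (2.0 * h)
    return SelectionGradient(
        value=float(value), tau_r=tau_r, v_star=v_star, one_sided=one_sided
    )


def find_singular_strategy(
    params: ModelParams,
    bracket: Optional[tuple[float, float]] = None,
    *,
    tradeoff: Optional[TradeoffFunction] = None,
    v1m0: float = 1.0,
    scan_points: int = 17,
    tau_tol: float = TAU_ROOT_TOL,
) -> Union[SingularStrategy, BoundaryDiagnosis]:
    """Locate and classify the singular incubation delay ``tau_star``.

    The resident equilibrium is recomputed for every candidate resident
    trait (the selection environment depends on ``tau_r``).  A coarse scan
    of the bracket finds a sign change of the selection gradient among
    persistent residents; the root is then polished by bracketed
    root-finding to ``tau_tol``.  Monotone selection or universal
    extinction yields a :class:`BoundaryDiagnosis`, never a fabricated
    root.
    """
    T = params.T
    lo, hi = bracket if bracket is not None else (0.05 * T, 0.98 * T)
    if tradeoff is not None:
        alo, ahi = tradeoff.admissible_interval()
        eps = 1e-9 * max(1.0, T)
        lo, hi = max(lo, alo + eps), min(hi, ahi - eps)
    if not (0 < lo < hi < T):
        raise ValueError(f"invalid bracket ({lo:g}, {hi:g}) for T={T:g}")

    eq_cache: dict[float, float] = {}

    def grad(tau_r: float) -> Optional[SelectionGradient]:
        if tau_r not in eq_cache:
            eq_cache[tau_r] = _equilibrium_density(params, tau_r)
        v = eq_cache[tau_r]
        if v == 0.0:
            return None
        return selection_gradient(
            params, tau_r, v_star=v, tradeoff=tradeoff, v1m0=v1m0
        )

    taus = np.linspace(lo, hi, scan_points)
    scan = [(t, grad(float(t))) for t in taus]
    alive = [(t, g) for t, g in scan if g is not None]
    if not alive:
        return BoundaryDiagnosis(
            reason="no persistent resident in bracket", bracket=(lo, hi)
        )
    signs = tuple((t, float(np.sign(g.value))) for t, g in alive)

    pair = None
    descending = True
    for (t0, g0), (t1, g1) in zip(alive[:-1], alive[1:]):
        if g0.value > 0 and g1.value < 0:
            pair = (t0, t1)
            break
    if pair is None:
        for (t0, g0), (t1, g1) in zip(alive[:-1], alive[1:]):
            if g0.value < 0 and g1.value > 0:
                pair = (t0, t1)
                descending = False
                break
    if pair is None:
        direction = "increasing" if alive[0][1].value > 0 else "decreasing"
        return BoundaryDiagnosis(
            reason=f"selection monotone ({direction}); no interior singular point",
            bracket=(lo, hi),
            gradient_signs=signs,
        )

    tau_star = brentq(
        lambda t: grad(t).value, pair[0], pair[1], xtol=tau_tol, rtol=8.9e-16
    )
    tau_star = float(tau_star)
    g_star = grad(tau_star)
    v_star = g_star.v_star

    # second-order (ESS) condition in the environment fixed at tau_star
    problem = InvasionProblem(
        params.replace(tau=tau_star), v_star, v1m0=v1m0, tradeoff=tradeoff
    )
    h2 = 1e-3 * max(1.0, tau_star)
    W = problem.fitness
    second = (W(tau_star + h2) - 2.0 * W(tau_star) + W(tau_star - h2)) / h2**2

    return SingularStrategy(
        tau_star=tau_star,
        gradient_at_star=g_star.value,
        second_derivative=float(second),
        is_ess=bool(second < 0),
        is_convergence_stable=descending,
        v_star=v_star,
        environment={
            "T": params.T,
            "t_l": params.t_l,
            "tradeoff": tradeoff.kind if tradeoff is not None else "none",
        },
    )


def pip_grid(
    params: ModelParams,
    tau_res_grid,
    tau_mut_grid,
    *,
    v1m0: float = 1.0,
    tradeoff: Optional[TradeoffFunction] = None,
) -> np.ndarray:
    """Pairwise-invasibility surface: per-capita mutant growth minus one.

    Entry ``[i, j]`` is the seasonal per-capita growth of mutant
    ``tau_mut_grid[j]`` in the environment of resident ``tau_res_grid[i]``
    minus one; positive entries mark invading mutants, the diagonal is
    neutral up to the mutant's own self-shading, and rows of ``NaN`` mark
    non-persistent residents.
    """
    tau_res_grid = np.asarray(tau_res_grid, dtype=float)
    tau_mut_grid = np.asarray(tau_mut_grid, dtype=float)
    if np.any(tau_res_grid <= 0) or np.any(tau_res_grid >= params.T):
        raise ValueError("resident grid must lie within (0, T)")
    if np.any(tau_mut_grid <= 0) or np.any(tau_mut_grid >= params.T):
        raise ValueError("mutant grid must lie within (0, T)")
    out = np.full((tau_res_grid.size, tau_mut_grid.size), np.nan)
    for i, tau_r in enumerate(tau_res_grid):
        v_star = _equilibrium_density(params, float(tau_r))
        if v_star == 0.0:
            continue
        problem = InvasionProblem(
            params.replace(tau=float(tau_r)), v_star, v1m0=v1m0, tradeoff=tradeoff
        )
        for j, tau_m in enumerate(tau_mut_grid):
            out[i, j] = problem.per_capita_growth(float(tau_m)) - 1.0
    return out
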