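"""Within-season dynamics of a seasonal obligate-killer parasite.

The model tracks a host cohort of size ``s_hat`` that emerges uniformly
over ``[0, t_l]`` at the start of each season of length ``T``.  Free
parasites ``v1`` (density ``v_init`` at the season start) decay in the
environment at rate ``delta`` and infect susceptible hosts at rate
``alpha``.  An infected host is killed by the parasite ``tau`` time units
after infection, releasing ``beta`` new parasites (``v2``), unless
background mortality (rate ``mu``) or the end of the season intervenes;
progeny released before ``T`` decay at rate ``delta`` until the season
ends.  ``tau`` is the inverse of virulence: short incubation means the
host is killed quickly.

The season dynamics are

    ds/dt  = s_hat * g(t, t_l) - mu * s - alpha * s * v1,
    dv1/dt = -delta * v1,
    dv2/dt = alpha * beta * exp(-mu*tau) * s(t-tau) * v1(t-tau) - delta * v2,

with ``g`` the uniform emergence density and ``s(0) = 0``, ``v2 = 0``
before the first kills at ``t = tau``.  Because ``v1`` decays purely
exponentially (parasite losses to transmission are negligible), the
susceptible equation is linear with hazard ``mu + alpha*v1(t)`` and has an
integrating-factor solution; the end-of-season progeny density collapses
to the single expression

    v2(T) = alpha * beta * exp(-mu*tau) * v_init * exp(-delta*(T-tau))
            * integral_0^{T-tau} s(u) du,

valid in both phenological regimes (``tau`` below or above ``T - t_l``),
which differ only through the piecewise structure of ``s``.

This module holds the parameter containers, the exact (quadrature-based)
solution, and an independent numerical oracle that integrates the delay
system directly on a grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, quad, solve_ivp
from scipy.interpolate import CubicSpline
from scipy.special import logsumexp

logger = logging.getLogger("phenovir")

#: number of nodes of the product-integration grid on the emergence phase
EMERGENCE_NODES = 1025
#: relative tolerance of the adaptive quadrature on the post-emergence phase
QUAD_RTOL = 1e-10

__all__ = [
    "HostParams",
    "ParasiteTraits",
    "SeasonConfig",
    "ModelParams",
    "SeasonTrajectory",
    "SusceptibleField",
    "emergence_rate",
    "v1_of_t",
    "s_of_t",
    "progeny_end_density",
    "v2_end_of_season",
    "numeric_season_oracle",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HostParams:
    """Host cohort parameters.

    Parameters
    ----------
    s_hat : float
        Emerging host cohort size (hosts, > 0).
    t_l : float
        Length of the host emergence period (time, > 0).
    mu : float
        Per-capita background host death rate (1/time, >= 0).
    """

    s_hat: float
    t_l: float
    mu: float = 0.5

    def __post_init__(self) -> None:
        if not self.s_hat > 0:
            raise ValueError(f"s_hat must be > 0, got {self.s_hat}")
        if not self.t_l > 0:
            raise ValueError(f"t_l must be > 0, got {self.t_l}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")


@dataclass(frozen=True)
class ParasiteTraits:
    """Parasite strain traits.

    Parameters
    ----------
    tau : float
        Incubation delay between infection and parasite-induced host death
        (time, > 0).  Inverse of virulence.
    alpha : float
        Transmission rate (1/(parasite * time), > 0).
    beta : float
        Progeny released at parasite-induced host death (parasites, > 0).
    delta : float
        Free-living parasite decay rate (1/time, > 0).
    """

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


@dataclass(frozen=True)
class SeasonConfig:
    """One season: its length and the start-of-season free parasite density."""

    T: float
    v_init: float = 1.0

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if self.v_init < 0:
            raise ValueError(f"v_init must be >= 0, got {self.v_init}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector for one parasite strain in one environment.

    Defaults are the baseline parameter set: cohort size 1e8 hosts,
    transmission rate 1e-8, decay rate 2, background death rate 0.5,
    progeny number 200, emergence period 1, season length 3, incubation
    delay 1.5, and one free parasite at the season start.
    """

    s_hat: float = 1e8
    t_l: float = 1.0
    T: float = 3.0
    alpha: float = 1e-8
    beta: float = 200.0
    delta: float = 2.0
    mu: float = 0.5
    tau: float = 1.5
    v_init: float = 1.0

    def __post_init__(self) -> None:
        # delegate range checks to the component types
        _ = self.host, self.traits, self.season
        if not self.t_l <= self.T:
            raise ValueError(f"t_l ({self.t_l}) must not exceed T ({self.T})")

    @property
    def host(self) -> HostParams:
        return HostParams(s_hat=self.s_hat, t_l=self.t_l, mu=self.mu)

    @property
    def traits(self) -> ParasiteTraits:
        return ParasiteTraits(
            tau=self.tau, alpha=self.alpha, beta=self.beta, delta=self.delta
        )

    @property
    def season(self) -> SeasonConfig:
        return SeasonConfig(T=self.T, v_init=self.v_init)

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class SeasonTrajectory:
    """Time-resolved season solution on a grid, plus the scalar ``v2(T)``."""

    times: np.ndarray
    s_vals: np.ndarray
    v1_vals: np.ndarray
    v2_vals: np.ndarray
    v2_end: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "s": self.s_vals, "v1": self.v1_vals, "v2": self.v2_vals}
        )

    def to_csv(self, path) -> None:
        """Write the trajectory as tidy CSV with columns t, s, v1, v2."""
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------


def emergence_rate(t, t_l):
    """Per-capita host emergence rate: uniform density 1/t_l on [0, t_l].

    Integrates to 1 over any season that contains the emergence period.
    Accepts scalars or arrays for ``t``.
    """
    if not t_l > 0:
        raise ValueError(f"t_l must be > 0, got {t_l}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.where(t <= t_l, 1.0 / t_l, 0.0)
    return out if out.ndim else float(out)


def v1_of_t(t, v_init, delta):
    """First-generation free parasite density: pure exponential decay."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if v_init < 0:
        raise ValueError("v_init must be >= 0")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    out = v_init * np.exp(-delta * t)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Susceptible-host solution under exponentially decaying infection hazards
# ---------------------------------------------------------------------------

# 3-point Gauss-Legendre rule on [-1, 1]
_GL_X = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GL_W = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


class SusceptibleField:
    """Integrating-factor solution of the susceptible-host balance.

    The susceptible density obeys ``ds/dt = (s_hat/t_l)*[t <= t_l] - h(t) s``
    with total hazard ``h(t) = mu + sum_i a_i exp(-d_i t)``, where each
    ``(a_i, d_i)`` pair is one free-parasite population's infection pressure
    at the season start (``a_i = alpha_i * v_i(0)``) and decay rate.  The
    cumulative hazard is

        H(t) = mu*t + sum_i (a_i / d_i) * (1 - exp(-d_i t)),

    so ``s(u) = (s_hat/t_l) * integral_0^min(u,t_l) exp(H(x) - H(u)) dx``.

    The emergence-phase integral is accumulated in log space with a
    per-interval 3-point Gauss-Legendre rule, which stays finite for
    arbitrarily large infection pressure (relevant while bracketing the
    between-season equilibrium, where trial densities can be huge).
    """

    def __init__(
        self,
        s_hat: float,
        t_l: float,
        mu: float,
        hazards: Sequence[tuple[float, float]] = (),
        n_nodes: int = EMERGENCE_NODES,
    ):
        if n_nodes < 9:
            raise ValueError("n_nodes too small")
        self.s_hat = float(s_hat)
        self.t_l = float(t_l)
        self.mu = float(mu)
        self.hazards = [(float(a), float(d)) for a, d in hazards if a != 0.0]
        for a, d in self.hazards:
            if a < 0 or d <= 0:
                raise ValueError("hazard amplitudes must be >= 0, decay rates > 0")

        u = np.linspace(0.0, self.t_l, n_nodes)
        self._nodes = u
        H = self.cumulative_hazard(u)
        self._H_nodes = H

        # per-interval log integral of e^H via 3-pt Gauss-Legendre
        a, b = u[:-1], u[1:]
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        x = mid[:, None] + half[:, None] * _GL_X[None, :]
        logw = np.log(half)[:, None] + np.log(_GL_W)[None, :]
        log_int = logsumexp(self.cumulative_hazard(x) + logw, axis=1)

        # A[m] = log integral_0^{u_m} e^{H}
        A = np.empty(n_nodes)
        A[0] = -np.inf
        A[1:] = np.logaddexp.accumulate(log_int)
        self._A_nodes = A

        with np.errstate(invalid="ignore"):
            log_s = np.log(self.s_hat / self.t_l) + A - H
        s_nodes = np.exp(log_s)
        s_nodes[0] = 0.0
        self._s_nodes = s_nodes
        self._s_tl = float(s_nodes[-1])
        self._H_tl = float(H[-1])
        self._s_antideriv = CubicSpline(u, s_nodes).antiderivative()

    # -- hazard -------------------------------------------------------------

    def cumulative_hazard(self, t):
        """H(t) = integral of the total per-capita susceptible-loss rate."""
        t = np.asarray(t, dtype=float)
        H = self.mu * t
        for a, d in self.hazards:
            H = H + (a / d) * (1.0 - np.exp(-d * t))
        return H

    # -- susceptible density ------------------------------------------------

    def _log_emergence_integral(self, t):
        """log integral_0^t e^{H(x)} dx for t in [0, t_l] (array)."""
        idx = np.clip(np.searchsorted(self._nodes, t, side="right") - 1, 0, None)
        u_k = self._nodes[idx]
        half = 0.5 * (t - u_k)
        mid = 0.5 * (t + u_k)
        x = mid[:, None] + half[:, None] * _GL_X[None, :]
        with np.errstate(divide="ignore"):
            logw = np.log(half)[:, None] + np.log(_GL_W)[None, :]
        log_tail = logsumexp(self.cumulative_hazard(x) + logw, axis=1)
        return np.logaddexp(self._A_nodes[idx], log_tail)

    def s(self, t):
        """Susceptible host density at season time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t1 = np.atleast_1d(t)
        if np.any(t1 < 0):
            raise ValueError("t must be >= 0")
        H = self.cumulative_hazard(t1)
        out = np.empty_like(t1)

        before = t1 <= self.t_l
        if np.any(before):
            logI = self._log_emergence_integral(t1[before])
            with np.errstate(invalid="ignore"):
                out[before] = np.where(
                    t1[before] == 0.0,
                    0.0,
                    np.exp(np.log(self.s_hat / self.t_l) + logI - H[before]),
                )
        after = ~before
        if np.any(after):
            out[after] = self._s_tl * np.exp(self._H_tl - H[after])
        return float(out[0]) if scalar else out

    # -- integrals ----------------------------------------------------------

    def integral(self, U: float) -> float:
        """``integral_0^U s(u) du`` for 0 <= U within the season."""
        if U <= 0:
            return 0.0
        partA = float(self._s_antideriv(min(U, self.t_l)))
        if U <= self.t_l:
            return partA
        H_tl = self._H_tl

        def decay(u):
            return np.exp(H_tl - self.cumulative_hazard(u))

        val, err = quad(
            decay,
            self.t_l,
            U,
            epsabs=1e-14 * (U - self.t_l),
            epsrel=QUAD_RTOL,
            limit=200,
        )
        if not np.isfinite(val):
            raise RuntimeError(
                f"quadrature failed on [{self.t_l}, {U}]: value={val}, err={err}"
            )
        return partA + self._s_tl * val


def s_of_t(
    t: float, host: HostParams, season: SeasonConfig, traits: ParasiteTraits
) -> float:
    """Susceptible host density at time ``t`` of the resident season."""
    if not 0 <= t <= season.T:
        raise ValueError(f"t={t} outside the season [0, {season.T}]")
    field_ = SusceptibleField(
        host.s_hat,
        host.t_l,
        host.mu,
        hazards=[(traits.alpha * season.v_init, traits.delta)],
    )
    return field_.s(t)


# ---------------------------------------------------------------------------
# End-of-season progeny density
# ---------------------------------------------------------------------------


def progeny_end_density(
    *,
    s_hat: float,
    t_l: float,
    T: float,
    mu: float,
    tau: float,
    alpha: float,
    beta: float,
    delta: float,
    v0: float,
    hazards: Sequence[tuple[float, float]],
) -> float:
    """End-of-season progeny density of one focal parasite strain.

    ``v0`` is the focal strain's free-parasite density at the season start
    and ``hazards`` lists every infection pressure acting on susceptible
    hosts (resident and, in invasion analyses, the rare mutant itself).
    Strains whose incubation delay reaches past the season end release no
    progeny.
    """
    if tau >= T:
        warnings.warn(
            "incubation delay tau >= season length T: hosts are never killed "
            "before the season ends, no progeny are released",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    if v0 == 0.0 or beta == 0.0 or alpha == 0.0:
        return 0.0
    field_ = SusceptibleField(s_hat, t_l, mu, hazards=hazards)
    U = T - tau
    return alpha * beta * np.exp(-mu * tau) * v0 * np.exp(-delta * U) * field_.integral(U)


def v2_end_of_season(
    host: HostParams, season: SeasonConfig, traits: ParasiteTraits
) -> float:
    """Resident parasite progeny density at the end of the season, ``v2(T)``."""
    return progeny_end_density(
        s_hat=host.s_hat,
        t_l=host.t_l,
        T=season.T,
        mu=host.mu,
        tau=traits.tau,
        alpha=traits.alpha,
        beta=traits.beta,
        delta=traits.delta,
        v0=season.v_init,
        hazards=[(traits.alpha * season.v_init, traits.delta)],
    )


# ---------------------------------------------------------------------------
# Independent numerical oracle
# ---------------------------------------------------------------------------


def _season_grid(T: float, grid_size: int, breakpoints: Sequence[float]) -> np.ndarray:
    grid = np.linspace(0.0, T, grid_size + 1)
    extra = [b for b in breakpoints if 0.0 < b < T]
    return np.unique(np.concatenate([grid, np.asarray(extra)]))


def numeric_season_oracle(
    host: HostParams,
    season: SeasonConfig,
    traits: ParasiteTraits,
    grid_size: int = 200_000,
) -> SeasonTrajectory:
    """Direct numerical integration of the season delay system on a grid.

    ``s`` is integrated with an adaptive high-order Runge-Kutta scheme
    (piecewise over the emergence discontinuity), ``v1`` is evaluated
    exactly, and the delayed ``v2`` source uses the stored ``s(t - tau)``
    by lagged interpolation with cumulative Simpson quadrature.  Entirely
    independent of the quadrature formulas in :func:`v2_end_of_season`;
    converges to them as ``grid_size`` grows.
    """
    if grid_size < 1_000:
        raise ValueError(f"grid_size must be >= 1000, got {grid_size}")
    T, t_l, tau = season.T, host.t_l, traits.tau
    grid = _season_grid(T, grid_size, [t_l, tau, t_l + tau])

    v1 = v1_of_t(grid, season.v_init, traits.delta)

    # susceptible hosts: two smooth segments split at the end of emergence
    def hazard(t):
        return host.mu + traits.alpha * season.v_init * np.exp(-traits.delta * t)

    s_vals = np.zeros_like(grid)
    seg1 = grid <= t_l
    t1 = grid[seg1]
    if t1[-1] < t_l:  # ensure the segment ends exactly at t_l
        t1 = np.append(t1, t_l)
    sol1 = solve_ivp(
        lambda t, y: host.s_hat / host.t_l - hazard(t) * y,
        (0.0, t_l),
        [0.0],
        method="DOP853",
        t_eval=t1,
        rtol=1e-12,
        atol=host.s_hat * 1e-16,
    )
    if not sol1.success:
        raise RuntimeError(f"susceptible integration failed: {sol1.message}")
    s_vals[seg1] = sol1.y[0, : seg1.sum()]
    s_at_tl = sol1.y[0, -1]
    if t_l < T:
        t2 = grid[~seg1]
        sol2 = solve_ivp(
            lambda t, y: -hazard(t) * y,
            (t_l, T),
            [s_at_tl],
            method="DOP853",
            t_eval=t2,
            rtol=1e-12,
            atol=host.s_hat * 1e-16,
        )
        if not sol2.success:
            raise RuntimeError(f"susceptible integration failed: {sol2.message}")
        s_vals[~seg1] = sol2.y[0]

    if s_vals.min() < -1e-9 * host.s_hat:
        raise RuntimeError(f"negative susceptible density: min s = {s_vals.min():g}")
    np.clip(s_vals, 0.0, None, out=s_vals)

    # progeny: dv2/dt = alpha*beta*e^{-mu tau} s(t-tau) v1(t-tau) - delta v2
    v2_vals = np.zeros_like(grid)
    if tau < T and traits.beta > 0 and season.v_init > 0:
        mask = grid >= tau
        tg = grid[mask]
        lag = tg - tau
        s_lag = np.interp(lag, grid, s_vals)
        source = (
            traits.alpha
            * traits.beta
            * np.exp(-host.mu * tau)
            * s_lag
            * v1_of_t(lag, season.v_init, traits.delta)
        )
        if tg.size >= 2:
            weighted = np.exp(traits.delta * (tg - tg[0])) * source
            cum = cumulative_simpson(weighted, x=tg, initial=0.0)
            v2_vals[mask] = np.exp(-traits.delta * (tg - tg[0])) * cum

    return SeasonTrajectory(
        times=grid,
        s_vals=s_vals,
        v1_vals=v1,
        v2_vals=v2_vals,
        v2_end=float(v2_vals[-1]),
    )
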