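"""Stochastic individual-based validation of the deterministic season model.

Simulates one season at reduced population scale, event by event, under
the same assumptions as the deterministic system: hosts emerge uniformly
on ``[0, t_l]``, face background mortality at rate ``mu`` and a
time-varying infection hazard ``alpha * v1(t)`` with ``v1`` the
deterministically decaying free-parasite density (transmission losses of
free parasites are negligible, so no parasite bookkeeping is needed
within a season); infected hosts are killed ``tau`` after infection,
releasing ``beta`` progeny, unless background death or the season end
arrives first; each released progeny survives independently to the season
end with probability ``exp(-delta * (T - release time))``.  Hosts are
independent under these rules, so the deterministic model is the exact
large-population limit and the simulated mean progeny count converges to
``v2(T)``.

Scale reduction follows the model's scaling invariance: a system with
cohort ``s_hat`` and transmission rate ``alpha`` is simulated with
``n_hosts = s_hat / c`` hosts, rate ``c * alpha``, and parasite densities
divided by ``c``, which leaves every per-capita hazard unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HostParams, ModelParams, ParasiteTraits, SeasonConfig, v2_end_of_season

logger = logging.getLogger("phenovir")

__all__ = [
    "IBMConfig",
    "IBMRealization",
    "sample_emergence_times",
    "simulate_season_ibm",
    "run_replicates",
    "deterministic_prediction",
]


@dataclass(frozen=True)
class IBMConfig:
    """Configuration of the reduced-scale individual-based simulation.

    ``params`` holds the full-scale parameters; ``v_init`` there is the
    full-scale start-of-season parasite density (a density at which
    infections are common, e.g. near the resident equilibrium, gives the
    simulation signal).  ``n_hosts`` is the simulated cohort and the scale
    factor is ``c = s_hat / n_hosts``.
    """

    params: ModelParams
    n_hosts: int = 10_000
    seed: int = 0
    n_replicates: int = 50

    def __post_init__(self) -> None:
        if self.n_hosts < 100:
            raise ValueError(f"n_hosts must be >= 100, got {self.n_hosts}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def scale(self) -> float:
        """Scale factor c relating full-scale to simulated populations."""
        return self.params.s_hat / self.n_hosts

    @property
    def scaled_params(self) -> ModelParams:
        """Parameter vector of the reduced-scale system."""
        c = self.scale
        return self.params.replace(
            s_hat=float(self.n_hosts),
            alpha=self.params.alpha * c,
            v_init=self.params.v_init / c,
        )


@dataclass
class IBMRealization:
    """Event-level record of one simulated season.

    ``death_cause`` is ``"parasite"``, ``"background"`` or ``"none"``
    (alive at season end); background deaths never release progeny.
    """

    emergence_times: np.ndarray
    infection_times: np.ndarray  # NaN for never-infected hosts
    death_times: np.ndarray  # NaN for hosts alive at season end
    death_cause: np.ndarray
    release_times: np.ndarray
    release_counts: np.ndarray
    v2_end_count: int

    @property
    def n_infected(self) -> int:
        return int(np.sum(~np.isnan(self.infection_times)))

    @property
    def n_released(self) -> int:
        return int(self.release_times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "emergence_time": self.emergence_times,
                "infection_time": self.infection_times,
                "death_time": self.death_times,
                "death_cause": self.death_cause,
            }
        )


def sample_emergence_times(n: int, t_l: float, seed) -> np.ndarray:
    """``n`` i.i.d. Uniform(0, t_l) emergence times; reproducible by seed.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not t_l >= 0:
        raise ValueError(f"t_l must be >= 0, got {t_l}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(0.0, t_l, size=n)


def _sample_infection_times(
    rng: np.random.Generator,
    emergence: np.ndarray,
    t_cut: np.ndarray,
    envelope: float,
    delta: float,
) -> np.ndarray:
    """Infection times under hazard ``envelope * exp(-delta t)`` by thinning.

    Constant-envelope thinning: candidate events at rate ``envelope``
    (the hazard at the season start, an upper bound since ``v1`` decays),
    accepted with probability ``exp(-delta t)``.  Hosts are at risk from
    their emergence time until ``t_cut`` (their background death or the
    season end).  Returns ``inf`` where no infection occurs.
    """
    n = emergence.size
    ti = np.full(n, np.inf)
    if envelope <= 0.0:
        return ti
    t_cur = emergence.copy()
    active = np.flatnonzero(t_cur < t_cut)
    while active.size:
        t_cur[active] += rng.exponential(1.0 / envelope, size=active.size)
        alive = active[t_cur[active] < t_cut[active]]
        if alive.size:
            accept = rng.uniform(size=alive.size) < np.exp(-delta * t_cur[alive])
            hit = alive[accept]
            ti[hit] = t_cur[hit]
            active = alive[~accept]
        else:
            active = alive
    return ti


def simulate_season_ibm(cfg: IBMConfig, replicate: int = 0) -> IBMRealization:
    """Simulate one season; replicate ``r`` uses seed ``cfg.seed + r``."""
    p = cfg.scaled_params
    rng = np.random.default_rng(cfg.seed + replicate)
    n = cfg.n_hosts

    emergence = sample_emergence_times(n, p.t_l, rng)
    if p.mu > 0:
        t_background = emergence + rng.exponential(1.0 / p.mu, size=n)
    else:
        t_background = np.full(n, np.inf)

    t_cut = np.minimum(t_background, p.T)
    envelope = p.alpha * p.v_init
    ti = _sample_infection_times(rng, emergence, t_cut, envelope, p.delta)

    infected = ti < t_cut
    t_kill = ti + p.tau
    released = infected & (t_kill <= p.T) & (t_kill < t_background)

    infection_times = np.where(infected, ti, np.nan)
    death_times = np.full(n, np.nan)
    death_cause = np.full(n, "none", dtype=object)
    parasite_killed = released
    background_died = ~parasite_killed & (t_background <= p.T)
    death_times[parasite_killed] = t_kill[parasite_killed]
    death_cause[parasite_killed] = "parasite"
    death_times[background_died] = t_background[background_died]
    death_cause[background_died] = "background"

    release_times = t_kill[released]
    beta_int = int(round(p.beta))
    release_counts = np.full(release_times.size, beta_int)
    if release_times.size and beta_int > 0:
        survive_p = np.exp(-p.delta * (p.T - release_times))
        v2_end = int(rng.binomial(beta_int, survive_p).sum())
    else:
        v2_end = 0

    return IBMRealization(
        emergence_times=emergence,
        infection_times=infection_times,
        death_times=death_times,
        death_cause=death_cause,
        release_times=release_times,
        release_counts=release_counts,
        v2_end_count=v2_end,
    )


def deterministic_prediction(cfg: IBMConfig) -> float:
    """Deterministic ``v2(T)`` of the reduced-scale system (mean of the IBM)."""
    p = cfg.scaled_params
    return v2_end_of_season(p.host, p.season, p.traits)


def run_replicates(cfg: IBMConfig) -> pd.DataFrame:
    """Run all replicates; one row per replicate with summary counts."""
    rows = []
    for r in range(cfg.n_replicates):
        real = simulate_season_ibm(cfg, replicate=r)
        rows.append(
            {
                "replicate": r,
                "v2_end_count": real.v2_end_count,
                "n_infected": real.n_infected,
                "n_released": real.n_released,
            }
        )
    return pd.DataFrame(rows)
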