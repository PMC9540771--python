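"""Figure-level parameter sweeps with machine-readable outputs.

Three experiments summarise how host phenology shapes the optimal
virulence strategy:

* ``sweep_season_length`` — optimal delay ``tau_star`` across season
  lengths ``T`` (fixed emergence period), with the death offset
  ``T - tau_star`` and the resident equilibrium at the optimum;
* ``sweep_emergence_period`` — ``tau_star`` across emergence-period
  lengths ``t_l`` at fixed ``T``;
* ``run_tradeoff_experiment`` — optima with and without linear
  transmission-virulence trade-offs at identical phenology.

All sweeps are deterministic given their configuration (quadrature and
root-finding involve no randomness), so reruns yield identical CSVs.
``reproduce_all`` executes the full set, asserts the qualitative claims
(intermediate virulence, season-length ordering and fixed offset,
non-monotone emergence-variation response, decreasing equilibrium
density, trade-off shift directions), and writes tidy CSVs plus a JSON
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ModelParams
from .dynamics import resident_equilibrium
from .invasion import SingularStrategy, find_singular_strategy
from .tradeoffs import TradeoffFunction

logger = logging.getLogger("phenovir")

#: season-length grid anchored at the captioned values T=3.2 and T=4
DEFAULT_T_GRID = (2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0)
#: emergence-period grid for the T=3 environment
DEFAULT_TL_GRID = (0.01, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5)
#: linear trade-off used in the "more progeny with longer infection" arm
TRADEOFF_POSITIVE = TradeoffFunction(kind="linear_positive", a=99.0, b=0.5)
#: linear trade-off used in the "fewer progeny with longer infection" arm
TRADEOFF_NEGATIVE = TradeoffFunction(kind="linear_negative", a=99.0, b=4.0)

__all__ = [
    "SweepSpec",
    "latin_hypercube_parameter_sets",
    "DEFAULT_T_GRID",
    "DEFAULT_TL_GRID",
    "TRADEOFF_POSITIVE",
    "TRADEOFF_NEGATIVE",
    "sweep_season_length",
    "sweep_emergence_period",
    "run_tradeoff_experiment",
    "figure_level_checks",
    "reproduce_all",
]


def latin_hypercube_parameter_sets(n: int, seed: int) -> list[ModelParams]:
    """``n`` Latin-hypercube parameter sets spanning the baseline magnitudes.

    Cohort size, transmission rate and start-of-season density are sampled
    log-uniformly around their baseline orders of magnitude; rates and
    phenology linearly.  The incubation delay is drawn as a fraction of
    the season so both phenological regimes (``tau`` below and above
    ``T - t_l``) are exercised.  Used for cross-validating the analytic
    season solution against direct numerical integration.
    """
    from scipy.stats import qmc

    u = qmc.LatinHypercube(d=9, seed=seed).random(n)

    def loguni(col, lo, hi):
        return 10.0 ** (np.log10(lo) + col * (np.log10(hi) - np.log10(lo)))

    def uni(col, lo, hi):
        return lo + col * (hi - lo)

    s_hat = loguni(u[:, 0], 1e7, 1e9)
    alpha = loguni(u[:, 1], 1e-9, 3e-8)
    v_init = loguni(u[:, 2], 1.0, 1e8)
    delta = uni(u[:, 3], 1.0, 4.0)
    mu = uni(u[:, 4], 0.1, 1.0)
    t_l = uni(u[:, 5], 0.3, 1.5)
    T = t_l + uni(u[:, 6], 0.8, 3.0)
    tau = uni(u[:, 7], 0.1, 0.92) * T
    beta = uni(u[:, 8], 50.0, 500.0)
    return [
        ModelParams(
            s_hat=s_hat[i],
            t_l=t_l[i],
            T=T[i],
            alpha=alpha[i],
            beta=beta[i],
            delta=delta[i],
            mu=mu[i],
            tau=tau[i],
            v_init=v_init[i],
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep: the varied parameter, its grid, fixed params."""

    varied: str
    grid: Sequence[float]
    params: ModelParams
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if self.varied not in ("T", "t_l"):
            raise ValueError(f"varied must be 'T' or 't_l', got {self.varied!r}")
        for v in self.grid:
            if not v > 0:
                raise ValueError(f"grid values must be > 0, got {v}")


def _optimum_row(params: ModelParams) -> dict:
    """tau_star and the resident equilibrium at the optimum, or NAs."""
    result = find_singular_strategy(params)
    if not isinstance(result, SingularStrategy):
        logger.info("no singular strategy (%s): %s", params, result.reason)
        return {"tau_star": np.nan, "v_star": np.nan, "is_ess": False}
    eq = resident_equilibrium(params.replace(tau=result.tau_star))
    return {"tau_star": result.tau_star, "v_star": eq.v_star, "is_ess": result.is_ess}


def sweep_season_length(
    params: ModelParams, T_grid: Sequence[float] = DEFAULT_T_GRID
) -> pd.DataFrame:
    """Optimal delay per season length: (T, tau_star, offset, v_star)."""
    rows = []
    for T in T_grid:
        if not T > params.t_l:
            raise ValueError(f"T={T} must exceed t_l={params.t_l}")
        logger.info("sweep_season_length: T=%g", T)
        row = _optimum_row(params.replace(T=float(T)))
        rows.append({"T": T, **row, "offset": T - row["tau_star"]})
    return pd.DataFrame(rows)[["T", "tau_star", "offset", "v_star", "is_ess"]]


def sweep_emergence_period(
    params: ModelParams, tl_grid: Sequence[float] = DEFAULT_TL_GRID
) -> pd.DataFrame:
    """Optimal delay per emergence-period length: (t_l, tau_star, v_star)."""
    rows = []
    for tl in tl_grid:
        if not tl < params.T:
            raise ValueError(f"t_l={tl} must be below T={params.T}")
        logger.info("sweep_emergence_period: t_l=%g", tl)
        row = _optimum_row(params.replace(t_l=float(tl)))
        rows.append({"t_l": tl, **row})
    return pd.DataFrame(rows)[["t_l", "tau_star", "v_star", "is_ess"]]


def run_tradeoff_experiment(
    params: ModelParams,
    tradeoffs: Sequence[TradeoffFunction] = (TRADEOFF_POSITIVE, TRADEOFF_NEGATIVE),
) -> pd.DataFrame:
    """Optima without and with each trade-off at identical phenology."""
    baseline = TradeoffFunction(kind="none", beta0=params.beta)
    base = find_singular_strategy(params, tradeoff=baseline)
    if not isinstance(base, SingularStrategy):
        raise RuntimeError(f"no baseline optimum: {base}")
    rows = [
        {
            "tradeoff": "none",
            "tau_star": base.tau_star,
            "shift": 0.0,
            "direction": 0,
        }
    ]
    for f in tradeoffs:
        logger.info("run_tradeoff_experiment: %s", f.kind)
        res = find_singular_strategy(params, tradeoff=f)
        if not isinstance(res, SingularStrategy):
            raise RuntimeError(f"no optimum under trade-off {f.kind}: {res}")
        shift = res.tau_star - base.tau_star
        rows.append(
            {
                "tradeoff": f.kind,
                "tau_star": res.tau_star,
                "shift": shift,
                "direction": 0 if shift == 0 else (1 if shift > 0 else -1),
            }
        )
    return pd.DataFrame(rows)


def figure_level_checks(
    t_sweep: pd.DataFrame, tl_sweep: pd.DataFrame, tradeoff_table: pd.DataFrame
) -> dict[str, bool]:
    """Assertable qualitative claims of the three experiments."""
    tau = t_sweep["tau_star"].to_numpy()
    offs = t_sweep["offset"].to_numpy()
    checks = {
        "intermediate_virulence": bool(
            np.all((tau > 0) & (tau < t_sweep["T"].to_numpy()))
        ),
        "tau_star_increasing_in_T": bool(np.all(np.diff(tau) > 0)),
        "fixed_offset_cv_below_10pct": bool(
            np.std(offs, ddof=0) / np.mean(offs) < 0.10
        ),
    }
    tl_tau = tl_sweep["tau_star"].to_numpy()
    i_min = int(np.argmin(tl_tau))
    checks["tl_response_non_monotone"] = bool(
        0 < i_min < len(tl_tau) - 1
        and tl_tau[0] > tl_tau[i_min]
        and tl_tau[-1] > tl_tau[i_min]
    )
    checks["equilibrium_density_decreasing_in_tl"] = bool(
        np.all(np.diff(tl_sweep["v_star"].to_numpy()) < 0)
    )
    by_kind = tradeoff_table.set_index("tradeoff")["direction"]
    checks["tradeoff_positive_raises_tau_star"] = bool(
        by_kind.get("linear_positive", 0) == 1
    )
    checks["tradeoff_negative_lowers_tau_star"] = bool(
        by_kind.get("linear_negative", 0) == -1
    )
    return checks


def _manifest(params: ModelParams) -> dict:
    from . import __version__

    cfg = json.dumps(params.to_dict(), sort_keys=True)
    return {
        "package": "phenovir",
        "version": __version__,
        "config": params.to_dict(),
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "T_grid": list(DEFAULT_T_GRID),
        "tl_grid": list(DEFAULT_TL_GRID),
        "tau_root_tol": 1e-6,
        "equilibrium_rtol": 1e-10,
    }


def reproduce_all(params: ModelParams, out_dir) -> dict:
    """Run every experiment, assert the qualitative claims, write outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_sweep = sweep_season_length(params.replace(t_l=1.0))
    tl_sweep = sweep_emergence_period(params.replace(T=3.0))
    tradeoff_table = run_tradeoff_experiment(params)
    t_sweep.to_csv(out / "sweep_season_length.csv", index=False)
    tl_sweep.to_csv(out / "sweep_emergence_period.csv", index=False)
    tradeoff_table.to_csv(out / "tradeoff_comparison.csv", index=False)
    checks = figure_level_checks(t_sweep, tl_sweep, tradeoff_table)
    manifest = _manifest(params)
    manifest["checks"] = checks
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    failed = [k for k, ok in checks.items() if not ok]
    if failed:
        raise AssertionError(f"figure-level checks failed: {failed}")
    logger.info("reproduce_all: all %d checks passed", len(checks))
    return checks
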