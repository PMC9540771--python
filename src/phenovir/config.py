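"""Structured configuration files: one namespace per model component.

A config file is YAML with up to four namespaces; every key is optional
and falls back to the baseline parameter set::

    host:     {s_hat: 1.0e8, t_l: 1.0, mu: 0.5}
    parasite: {alpha: 1.0e-8, beta: 200.0, delta: 2.0, tau: 1.5}
    season:   {T: 3.0, v_init: 1.0}
    tradeoff: {kind: none, a: 99.0, b: 0.5, beta0: 200.0}
    ibm:      {n_hosts: 10000, n_replicates: 50, seed: 0, v_init: 1.0e8}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .core import ModelParams
from .ibm import IBMConfig
from .tradeoffs import TradeoffFunction

__all__ = ["RunConfig", "load_config", "default_params"]

_HOST_KEYS = {"s_hat", "t_l", "mu"}
_PARASITE_KEYS = {"alpha", "beta", "delta", "tau"}
_SEASON_KEYS = {"T", "v_init"}


def default_params() -> ModelParams:
    """The baseline parameter set (see :class:`~phenovir.core.ModelParams`)."""
    return ModelParams()


@dataclass(frozen=True)
class RunConfig:
    """Everything a command run needs: parameters, trade-off, IBM settings."""

    params: ModelParams
    tradeoff: Optional[TradeoffFunction] = None
    ibm: Optional[IBMConfig] = None


def _namespace(raw: dict, name: str, allowed: set[str]) -> dict:
    ns = raw.get(name) or {}
    if not isinstance(ns, dict):
        raise ValueError(f"config namespace {name!r} must be a mapping")
    unknown = set(ns) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {name!r}: {sorted(unknown)}")
    return {k: float(v) for k, v in ns.items()}


def load_config(path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping at top level")
    known = {"host", "parasite", "season", "tradeoff", "ibm"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config namespace(s): {sorted(unknown)}")

    values = {}
    values.update(_namespace(raw, "host", _HOST_KEYS))
    values.update(_namespace(raw, "parasite", _PARASITE_KEYS))
    values.update(_namespace(raw, "season", _SEASON_KEYS))
    params = ModelParams(**{**ModelParams().to_dict(), **values})

    tradeoff = None
    ns = raw.get("tradeoff") or {}
    if ns and ns.get("kind", "none") != "none":
        tradeoff = TradeoffFunction(
            kind=str(ns["kind"]),
            a=float(ns.get("a", 99.0)),
            b=float(ns.get("b", 0.5)),
            beta0=float(ns.get("beta0", params.beta)),
        )

    ibm = None
    ns = raw.get("ibm") or {}
    if ns:
        ibm_params = params.replace(v_init=float(ns.get("v_init", params.v_init)))
        ibm = IBMConfig(
            params=ibm_params,
            n_hosts=int(ns.get("n_hosts", 10_000)),
            seed=int(ns.get("seed", 0)),
            n_replicates=int(ns.get("n_replicates", 50)),
        )
    return RunConfig(params=params, tradeoff=tradeoff, ibm=ibm)
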