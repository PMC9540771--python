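"""Transmission-virulence trade-off functions ``beta(tau)``.

The classical trade-off hypothesis links the progeny number released at
host death to the incubation delay.  Two linear families are supported:
``linear_positive`` (longer infections yield more progeny,
``beta = a*(tau + b)``) and ``linear_negative`` (longer infections yield
fewer progeny, ``beta = a*(-tau + b)``), alongside a constant (``none``)
and an arbitrary ``custom`` callable.  The defaults of the two linear
families, ``99*(tau + 0.5)`` and ``99*(-tau + 4)``, are the forms used in
the trade-off comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "TradeoffFunction",
    "beta_of_tau",
    "compare_tradeoff_optima",
    "TradeoffComparison",
]

_KINDS = ("none", "linear_positive", "linear_negative", "custom")


@dataclass(frozen=True)
class TradeoffFunction:
    """A progeny-number-vs-incubation-delay trade-off.

    Parameters
    ----------
    kind : str
        One of ``none``, ``linear_positive``, ``linear_negative``,
        ``custom``.
    a, b : float
        Scale and offset of the linear forms ``a*(tau + b)`` /
        ``a*(-tau + b)``.
    beta0 : float
        Constant progeny number for ``kind='none'``.
    beta_min : float
        Lower clip defining the admissible ``tau`` interval: ``tau`` values
        where ``beta(tau) < beta_min`` are rejected, which keeps optima
        away from pathological zero-progeny boundaries.
    func : callable, optional
        ``tau -> beta`` for ``kind='custom'``.
    """

    kind: str = "none"
    a: float = 99.0
    b: float = 0.5
    beta0: float = 200.0
    beta_min: float = 1.0
    func: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "custom" and self.func is None:
            raise ValueError("kind='custom' requires func")
        if self.beta_min <= 0:
            raise ValueError("beta_min must be > 0")

    def admissible_interval(self) -> tuple[float, float]:
        """Open ``tau`` interval on which ``beta(tau) >= beta_min``."""
        if self.kind == "none":
            return (0.0, np.inf)
        if self.kind == "linear_positive":
            return (max(0.0, self.beta_min / self.a - self.b), np.inf)
        if self.kind == "linear_negative":
            return (0.0, self.b - self.beta_min / self.a)
        return (0.0, np.inf)  # custom: validated pointwise

    def __call__(self, tau: float) -> float:
        if tau <= 0:
            raise ValueError(f"tau must be > 0, got {tau}")
        if self.kind == "none":
            return self.beta0
        if self.kind == "linear_positive":
            beta = self.a * (tau + self.b)
        elif self.kind == "linear_negative":
            beta = self.a * (-tau + self.b)
        else:
            beta = float(self.func(tau))
        if beta < self.beta_min:
            lo, hi = self.admissible_interval()
            raise ValueError(
                f"beta(tau={tau:g}) = {beta:g} is below beta_min={self.beta_min:g}; "
                f"admissible tau interval is ({lo:g}, {hi:g})"
            )
        return beta


def beta_of_tau(f: TradeoffFunction, tau: float) -> float:
    """Progeny number released at host death under trade-off ``f``."""
    return f(tau)


@dataclass(frozen=True)
class TradeoffComparison:
    """Optimal incubation delays with and without a trade-off."""

    tau_star_with: float
    tau_star_without: float
    direction: int  # sign(tau_star_with - tau_star_without)


def compare_tradeoff_optima(params, f: TradeoffFunction, bracket=None) -> TradeoffComparison:
    """Locate the optimal delay with and without trade-off ``f``.

    The no-trade-off reference uses a constant progeny number equal to
    ``params.beta`` and runs through the identical code path, so a
    constant "trade-off" yields a bitwise-identical optimum (direction 0).
    """
    from .invasion import SingularStrategy, find_singular_strategy

    baseline = TradeoffFunction(kind="none", beta0=params.beta)
    without = find_singular_strategy(params, bracket=bracket, tradeoff=baseline)
    with_ = find_singular_strategy(params, bracket=bracket, tradeoff=f)
    for name, res in (("without trade-off", without), ("with trade-off", with_)):
        if not isinstance(res, SingularStrategy):
            raise RuntimeError(f"no singular strategy found {name}: {res}")
    diff = with_.tau_star - without.tau_star
    direction = 0 if diff == 0.0 else (1 if diff > 0 else -1)
    return TradeoffComparison(
        tau_star_with=with_.tau_star,
        tau_star_without=without.tau_star,
        direction=direction,
    )
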