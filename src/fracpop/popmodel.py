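"""The fractional population-growth model, independent of any solver.

The classical quadratic growth law dN/dt = a*N^2 - b*N (pair-formation
births, linear deaths) is extended with a partner-choice term: with
probability p an adult chooses a same-sex partner, and a selection rate v(t)
scales how strongly the remaining fraction reduces pair formation, giving

    D^alpha N = a*N^2 - b*N - (1-p)*v(t)*N^2 =: V(t, N)

where D^alpha is the ABC derivative of order alpha in (0, 1].  This module
holds the right-hand side V, the equilibria N = 0 and N = b/(a - (1-p)v),
the extinction/critical/survival classification by the sign of a - (1-p)v,
and the fixed-point contraction condition that guarantees uniqueness of the
solution of the Volterra form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gamma as _gamma

from .abcalc import FractionalOrder

__all__ = [
    "SelectionFunction",
    "ModelParams",
    "Equilibrium",
    "EquilibriaResult",
    "UniquenessReport",
    "rhs",
    "equilibria",
    "classify_fate",
    "uniqueness_condition",
    "CRITICAL_TOL",
]

CRITICAL_TOL = 1e-12

_KINDS = ("constant", "linear-ramp", "exponential-decay", "user-tabulated")


@dataclass(frozen=True)
class SelectionFunction:
    """Deterministic, non-negative selection rate v(t) (year^-1).

    The model fixes no functional form for v; the families provided are
    constant, a linear ramp (clipped at zero), an exponential decay, and a
    tabulated function with linear interpolation.
    """

    kind: str = "constant"
    value: float = 0.0          # constant level / ramp intercept / decay amplitude
    slope: float = 0.0          # linear-ramp slope (year^-2)
    rate: float = 0.0           # exponential decay rate (year^-1)
    times: tuple[float, ...] = ()    # user-tabulated support
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown selection kind {self.kind!r}; choose from {_KINDS}")
        if self.kind == "user-tabulated":
            if len(self.times) != len(self.values) or len(self.times) < 2:
                raise ValueError("tabulated selection needs matching times/values, >= 2 points")
            if any(v < 0 for v in self.values):
                raise ValueError("selection values must be non-negative")
        elif self.value < 0:
            raise ValueError("selection level must be non-negative")

    @classmethod
    def constant(cls, value: float) -> "SelectionFunction":
        return cls(kind="constant", value=value)

    @classmethod
    def linear_ramp(cls, value: float, slope: float) -> "SelectionFunction":
        return cls(kind="linear-ramp", value=value, slope=slope)

    @classmethod
    def exponential_decay(cls, value: float, rate: float) -> "SelectionFunction":
        return cls(kind="exponential-decay", value=value, rate=rate)

    @classmethod
    def tabulated(cls, times: Sequence[float], values: Sequence[float]) -> "SelectionFunction":
        return cls(kind="user-tabulated", times=tuple(times), values=tuple(values))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full_like(t, self.value)
        elif self.kind == "linear-ramp":
            out = np.clip(self.value + self.slope * t, 0.0, None)
        elif self.kind == "exponential-decay":
            out = self.value * np.exp(-self.rate * t)
        else:
            out = np.interp(t, self.times, self.values)
        return float(out) if out.ndim == 0 else out

    def sup(self, horizon: float) -> float:
        """sup of v over [0, horizon] (exact for each family)."""
        if self.kind == "constant":
            return self.value
        if self.kind == "linear-ramp":
            return max(float(self(0.0)), float(self(horizon)))
        if self.kind == "exponential-decay":
            return self.value if self.rate >= 0 else float(self(horizon))
        mask_vals = [v for t, v in zip(self.times, self.values) if 0.0 <= t <= horizon]
        return max(mask_vals + [float(self(0.0)), float(self(horizon))])


@dataclass(frozen=True)
class ModelParams:
    """Growth-law parameters: birth coefficient a (half the per-pair birth
    probability per year), death probability b per year, same-sex choice
    probability p, and the selection function v(t)."""

    a: float
    b: float
    p: float
    v: SelectionFunction = field(default_factory=lambda: SelectionFunction.constant(0.0))

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("rates a and b must be non-negative")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")

    def net_growth(self, t: float) -> float:
        """The decisive coefficient a - (1-p)*v(t) of the quadratic term."""
        return self.a - (1.0 - self.p) * float(self.v(t))


def rhs(t: float, n: float, params: ModelParams) -> float:
    """V(t, N) = a*N^2 - b*N - (1-p)*v(t)*N^2 (population / year)."""
    if not math.isfinite(n):
        raise ValueError(f"population must be finite, got {n}")
    return params.net_growth(t) * n * n - params.b * n


@dataclass(frozen=True)
class Equilibrium:
    value: float
    physical: bool


@dataclass(frozen=True)
class EquilibriaResult:
    points: tuple[Equilibrium, ...]
    degenerate: bool

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(e.value for e in self.points)


def equilibria(params: ModelParams, t: float = 0.0) -> EquilibriaResult:
    """Stationary points of V with v frozen at time t.

    N = 0 always; N = b/(a - (1-p)v) when the denominator is nonzero,
    flagged non-physical when negative.  The degenerate case a = (1-p)v
    leaves only the origin.
    """
    q = params.net_growth(t)
    if q == 0.0:
        return EquilibriaResult(points=(Equilibrium(0.0, True),), degenerate=True)
    nstar = params.b / q
    return EquilibriaResult(
        points=(Equilibrium(0.0, True), Equilibrium(nstar, nstar >= 0.0)),
        degenerate=False,
    )


def classify_fate(params: ModelParams, t: float = 0.0, *, tol: float = CRITICAL_TOL) -> str:
    """'extinction' if a - (1-p)v < 0, 'critical' if zero (within tol),
    'survival' otherwise."""
    q = params.net_growth(t)
    if abs(q) <= tol:
        return "critical"
    return "extinction" if q < 0 else "survival"


@dataclass(frozen=True)
class UniquenessReport:
    """Contraction check for the Volterra fixed-point map on [0, horizon_b].

    J bounds the Lipschitz constant of V in N on {0 <= N <= L}; the map is a
    contraction — hence the solution unique — when

        (1-alpha)/B(alpha) * J + alpha*horizon_b^alpha/(B(alpha)*Gamma(alpha+1)) * J < 1.
    """

    J: float
    bound_L: float
    horizon_b: float
    alpha: float
    contraction_value: float
    is_contraction: bool


def uniqueness_condition(
    params: ModelParams,
    bound_L: float,
    horizon_b: float,
    order: FractionalOrder,
    *,
    constant: str = "sup-v",
) -> UniquenessReport:
    """Evaluate the contraction condition.

    constant:
        "sup-v"        -> J = 2aL + b + 2L(1-p)*sup_{[0,horizon]} v  (default;
                          dimensionally consistent Lipschitz bound)
        "literature-strict" -> J = 2aL + b + 2L(1-p)  (the looser literature
                          constant with v's magnitude dropped)
    """
    if bound_L <= 0 or horizon_b <= 0:
        raise ValueError("bound_L and horizon_b must be positive")
    if constant not in ("sup-v", "literature-strict"):
        raise ValueError(f"unknown constant mode {constant!r}")
    vfac = params.v.sup(horizon_b) if constant == "sup-v" else 1.0
    J = 2.0 * params.a * bound_L + params.b + 2.0 * bound_L * (1.0 - params.p) * vfac
    a, B = order.alpha, order.b
    cval = (1.0 - a) / B * J + a * horizon_b**a / (B * _gamma(a + 1.0)) * J
    return UniquenessReport(
        J=J,
        bound_L=bound_L,
        horizon_b=horizon_b,
        alpha=a,
        contraction_value=cval,
        is_contraction=bool(cval < 1.0),
    )
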