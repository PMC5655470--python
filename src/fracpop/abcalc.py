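"""Atangana-Baleanu fractional operators on uniformly sampled functions.

The AB family replaces the power-law kernel of classical fractional calculus
with the nonsingular Mittag-Leffler kernel E_alpha(-alpha/(1-alpha)(t-y)^alpha):

* ABC derivative — kernel convolved with f' (Caputo sense),
* ABR derivative — time derivative outside the kernel convolution of f,
* AB integral — their inverse: a weighted average of f itself and its
  Riemann-Liouville fractional integral,

all normalised by a positive function B(alpha) with B(0) = B(1) = 1.  The
operators act on functions sampled on a uniform grid; derivatives use
second-order finite differences, the nonsingular kernel convolutions use the
composite trapezoidal rule, and the weakly singular Riemann-Liouville
convolution inside the AB integral uses the product-trapezoidal weights
shared with the solver module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

from .mlf import ml_vectorized
from .quadrature import corrector_weights

__all__ = [
    "FractionalOrder",
    "SampledFunction",
    "normalization_b",
    "ab_integral",
    "abc_derivative",
    "abr_derivative",
]

_NORMALIZATIONS = ("ab", "unit")


@dataclass(frozen=True)
class FractionalOrder:
    """Fractional order alpha in (0, 1] plus the normalization B(alpha) choice.

    normalization:
        "ab"   -> B(alpha) = 1 - alpha + alpha/Gamma(alpha)   (default; B(0)=B(1)=1)
        "unit" -> B(alpha) = 1
    """

    alpha: float
    normalization: str = "ab"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; choose from {_NORMALIZATIONS}"
            )

    @property
    def b(self) -> float:
        return normalization_b(self)

    @property
    def ml_rate(self) -> float:
        """The kernel rate alpha/(1-alpha); only defined for alpha < 1."""
        if self.alpha >= 1.0:
            raise ValueError("kernel rate alpha/(1-alpha) is undefined at alpha=1")
        return self.alpha / (1.0 - self.alpha)


def normalization_b(order: FractionalOrder) -> float:
    """B(alpha) > 0 used by every AB operator."""
    if order.normalization == "ab":
        return 1.0 - order.alpha + order.alpha / _gamma(order.alpha)
    return 1.0


@dataclass(frozen=True)
class SampledFunction:
    """A function sampled on the uniform grid t_j = t0 + j*h."""

    t0: float
    h: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.h <= 0:
            raise ValueError(f"step h must be positive, got {self.h}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("need a 1-d sample array with at least 2 points")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.values.size)

    @classmethod
    def from_callable(cls, fn, t0: float, h: float, n: int) -> "SampledFunction":
        t = t0 + h * np.arange(n + 1)
        return cls(t0=t0, h=h, values=np.asarray([fn(ti) for ti in t], dtype=float))


def _grad(values: np.ndarray, h: float) -> np.ndarray:
    """Second-order finite differences: central inside, one-sided at the ends."""
    return np.gradient(values, h, edge_order=2)


def ab_integral(f: SampledFunction, order: FractionalOrder) -> SampledFunction:
    """AB fractional integral of order alpha on f's grid.

    g(t) = (1-alpha)/B * f(t) + alpha/(B*Gamma(alpha)) *
           int_{t0}^t (t-y)^(alpha-1) f(y) dy,

    the Riemann-Liouville convolution evaluated with product-trapezoidal
    weights.  At the left endpoint only the local term survives.
    """
    a, b = order.alpha, order.b
    vals = f.values
    n = vals.size - 1
    out = (1.0 - a) / b * vals.copy()
    c = a / (b * _gamma(a))
    for m in range(1, n + 1):
        table = corrector_weights(m - 1, a)
        out[m] += c * table.prefactor(f.h) * float(table.weights @ vals[: m + 1])
    return SampledFunction(t0=f.t0, h=f.h, values=out)


def _kernel_values(f: SampledFunction, order: FractionalOrder) -> np.ndarray:
    """E_alpha(-lam * (j*h)^alpha) for every grid offset j."""
    n = f.values.size - 1
    lags = f.h * np.arange(n + 1)
    return ml_vectorized(-order.ml_rate * lags**order.alpha, order.alpha)


def _conv_trapz(g: np.ndarray, kernel: np.ndarray, h: float) -> np.ndarray:
    """c[m] = int_0^{t_m} g(y) K(t_m - y) dy by the composite trapezoidal rule."""
    n = g.size - 1
    out = np.zeros(n + 1)
    for m in range(1, n + 1):
        integrand = g[: m + 1] * kernel[m::-1]
        out[m] = h * (integrand.sum() - 0.5 * (integrand[0] + integrand[-1]))
    return out


def abc_derivative(f: SampledFunction, order: FractionalOrder) -> SampledFunction:
    """ABC (Caputo-sense) derivative: kernel convolution of f'.

    Requires alpha strictly inside (0, 1); at alpha = 1 the kernel collapses
    and the classical derivative should be used instead.
    """
    if order.alpha >= 1.0:
        raise ValueError("ABC derivative needs alpha < 1; use a classical derivative at alpha=1")
    if f.values.size < 3:
        raise ValueError("need at least 3 samples to form the interior derivative")
    kernel = _kernel_values(f, order)
    conv = _conv_trapz(_grad(f.values, f.h), kernel, f.h)
    scale = order.b / (1.0 - order.alpha)
    return SampledFunction(t0=f.t0, h=f.h, values=scale * conv)


def abr_derivative(f: SampledFunction, order: FractionalOrder) -> SampledFunction:
    """ABR (Riemann-sense) derivative: time derivative of the kernel convolution of f."""
    if order.alpha >= 1.0:
        raise ValueError("ABR derivative needs alpha < 1; use a classical derivative at alpha=1")
    if f.values.size < 3:
        raise ValueError("need at least 3 samples to differentiate the convolution")
    kernel = _kernel_values(f, order)
    conv = _conv_trapz(f.values, kernel, f.h)
    scale = order.b / (1.0 - order.alpha)
    return SampledFunction(t0=f.t0, h=f.h, values=scale * _grad(conv, f.h))
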