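"""Product-trapezoidal quadrature weights for the weakly singular kernel.

The Volterra form of the model contains convolution integrals

    int_0^{t_{n+1}} (t_{n+1} - y)^(alpha-1) f(y) dy

on a uniform grid t_j = j*h.  Interpolating f piecewise-linearly and
integrating exactly against the kernel gives

    int ... dy  ~=  h^alpha / (alpha*(alpha+1)) * sum_j b_{j,n+1} f(t_j)

with the weight pattern implemented here.  The same weight family serves the
fractional Adams-Moulton corrector and the Riemann-Liouville part of the AB
integral.  A literal "printed" sign variant of the interior weights (with
-(n-j)^(alpha+1) instead of +) is kept available because it is the
documented counter-example: it is not exact for linear integrands and does
not collapse to the composite trapezoidal pattern at alpha = 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["corrector_weights", "singular_quadrature", "WeightTable"]

from dataclasses import dataclass, field


@dataclass(frozen=True)
class WeightTable:
    """Corrector weights b_{j,n+1}, j = 0..n+1, for one grid level.

    ``prefactor(h)`` = h^alpha/(alpha*(alpha+1)) converts the dimensionless
    pattern into quadrature weights for the kernel (t_{n+1}-y)^(alpha-1).
    """

    alpha: float
    n: int
    weights: np.ndarray = field(repr=False)

    def prefactor(self, h: float) -> float:
        return h**self.alpha / (self.alpha * (self.alpha + 1.0))


def corrector_weights(n: int, alpha: float, *, corrected: bool = True) -> WeightTable:
    """Weights b_{j,n+1} for the endpoint t_{n+1} with nodes t_0..t_{n+1}.

    b_{0,n+1}   = n^(a+1) - (n - a)(n+1)^a
    b_{j,n+1}   = (n-j+2)^(a+1) + (n-j)^(a+1) - 2(n-j+1)^(a+1),  1 <= j <= n
    b_{n+1,n+1} = 1

    ``corrected=False`` flips the sign of the (n-j)^(a+1) interior term to
    the literal printed form (degree-1 exactness then fails; see module
    docstring).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    a1 = alpha + 1.0
    w = np.empty(n + 2)
    w[0] = n**a1 - (n - alpha) * (n + 1) ** alpha
    j = np.arange(1, n + 1)
    mid_sign = 1.0 if corrected else -1.0
    w[1 : n + 1] = (n - j + 2) ** a1 + mid_sign * (n - j) ** a1 - 2.0 * (n - j + 1) ** a1
    w[n + 1] = 1.0
    return WeightTable(alpha=alpha, n=n, weights=w)


def singular_quadrature(values: np.ndarray, m: int, h: float, alpha: float) -> float:
    """int_0^{t_m} (t_m - y)^(alpha-1) f(y) dy from samples f(t_0..t_m), m >= 1."""
    if m < 1:
        raise ValueError("quadrature endpoint must be at least one step in")
    table = corrector_weights(m - 1, alpha)
    return table.prefactor(h) * float(table.weights @ values[: m + 1])
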