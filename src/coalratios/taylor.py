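"""Delta-method (Taylor) approximations for ratios of tree summaries.

For random X, Y with nonzero means, the second-order approximation to the
expectation and the first-order approximation to the variance of X/Y are

    E[X/Y]   ~ E[X]/E[Y] - Cov[X,Y]/E[Y]^2 + E[X] Var[Y]/E[Y]^3
    Var[X/Y] ~ (E[X]/E[Y])^2 (Var[X]/E[X]^2 - 2 Cov[X,Y]/(E[X]E[Y])
                              + Var[Y]/E[Y]^2)

Composing these with the exact moments and covariances of {H, L, E, I, B,
T(k)} yields exact rational approximations at every finite n, for any of the
15 pairs in either orientation.  The n -> infinity limits are computed
symbolically from the same composition.  A well-known consequence: although
E[E_n] -> 2 and E[H_n] -> 2, the approximate expectation of E_n/H_n tends to
pi^2/3 - 2 ~ 1.28987, not 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import sympy

from .covariance import covariance, _lookup as _cov_lookup
from .moments import MEAN_FORMULAS, VAR_FORMULAS, mean, variance
from .scalars import ExactScalar
from .statistics import TreeStatistic

__all__ = ["RatioPair", "RatioApproximation", "taylor_mean_ratio",
           "taylor_var_ratio", "ratio_mean_approx", "ratio_var_approx",
           "ratio_mean_limit", "ratio_var_limit", "CANONICAL_PAIRS"]

#: Canonical (numerator, denominator) orientations, matching the tabulated
#: closed forms in :mod:`coalratios.closed_forms`.
CANONICAL_PAIRS = (
    ("H", "T"), ("H", "L"), ("E", "H"), ("H", "I"), ("B", "H"),
    ("L", "T"), ("E", "L"), ("L", "I"), ("B", "L"), ("E", "T"),
    ("E", "I"), ("B", "E"), ("I", "T"), ("B", "I"), ("B", "T"),
)


def taylor_mean_ratio(mean_x, mean_y, var_y, cov_xy):
    """Second-order approximation to E[X/Y]; exact in its input arithmetic."""
    if mean_y == 0:
        raise ZeroDivisionError("denominator mean is zero")
    return mean_x / mean_y - cov_xy / mean_y ** 2 + mean_x * var_y / mean_y ** 3


def taylor_var_ratio(mean_x, mean_y, var_x, var_y, cov_xy):
    """First-order approximation to Var[X/Y]; exact in its input arithmetic."""
    if mean_x == 0 or mean_y == 0:
        raise ZeroDivisionError("both means must be nonzero")
    return (mean_x / mean_y) ** 2 * (var_x / mean_x ** 2
                                     - 2 * cov_xy / (mean_x * mean_y)
                                     + var_y / mean_y ** 2)


@dataclass(frozen=True)
class RatioPair:
    """A ratio X_n / Y_n of two distinct tree summaries."""

    numerator: TreeStatistic
    denominator: TreeStatistic

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("ratio numerator and denominator must differ")
        if self.numerator.kind == "T" and self.denominator.kind == "T":
            raise ValueError("ratios of two coalescence times are not covered")

    @property
    def min_n(self) -> int:
        return max(self.numerator.min_n, self.denominator.min_n)

    @property
    def k(self) -> Optional[int]:
        t = self.numerator if self.numerator.kind == "T" else self.denominator
        return t.k if t.kind == "T" else None

    def is_canonical(self) -> bool:
        return (self.numerator.kind, self.denominator.kind) in CANONICAL_PAIRS

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator}"


@dataclass(frozen=True)
class RatioApproximation:
    """Approximate mean and/or variance of X_n/Y_n at sample size n."""

    pair: RatioPair
    n: int
    mean_approx: Optional[ExactScalar] = None
    var_approx: Optional[ExactScalar] = None
    approximate: bool = False  # True when Cov[E,B] or Cov[I,B] is involved


def _exact_inputs(pair: RatioPair, n: int):
    x, y = pair.numerator, pair.denominator
    cov = covariance(x, y, n)
    return (mean(x, n).as_fraction(), mean(y, n).as_fraction(),
            variance(x, n).as_fraction(), variance(y, n).as_fraction(),
            cov.value.as_fraction(), cov.approximate)


def ratio_mean_approx(pair: RatioPair, n: int) -> RatioApproximation:
    """Exact rational value of the delta-method approximation to E[X/Y]."""
    mx, my, vx, vy, c, approx = _exact_inputs(pair, n)
    value = taylor_mean_ratio(mx, my, vy, c)
    return RatioApproximation(pair, n, mean_approx=ExactScalar.from_rational(value),
                              approximate=approx)


def ratio_var_approx(pair: RatioPair, n: int) -> RatioApproximation:
    """Exact rational value of the delta-method approximation to Var[X/Y]."""
    mx, my, vx, vy, c, approx = _exact_inputs(pair, n)
    value = taylor_var_ratio(mx, my, vx, vy, c)
    return RatioApproximation(pair, n, var_approx=ExactScalar.from_rational(value),
                              approximate=approx)


# -- symbolic composition for limits ----------------------------------------

def _symbolic_inputs(pair: RatioPair):
    from ._symbolic import N, surrogate_S

    x, y = pair.numerator, pair.denominator

    def stat_args(s: TreeStatistic):
        if s.kind == "T":
            return (N, surrogate_S, sympy.Integer(s.k))
        return (N, surrogate_S)

    mx = MEAN_FORMULAS[x.kind](*stat_args(x))
    my = MEAN_FORMULAS[y.kind](*stat_args(y))
    vx = VAR_FORMULAS[x.kind](*stat_args(x))
    vy = VAR_FORMULAS[y.kind](*stat_args(y))
    formula, k, approx = _cov_lookup(x, y)
    if k is None:
        c = formula(N, surrogate_S)
    else:
        c = formula(N, surrogate_S, sympy.Integer(k))
    return mx, my, vx, vy, c, approx


@lru_cache(maxsize=None)
def ratio_mean_limit(pair: RatioPair):
    """lim_{n->inf} of the approximate E[X/Y], from the composition."""
    from ._symbolic import limit_of_expr

    mx, my, _vx, vy, c, _ = _symbolic_inputs(pair)
    return limit_of_expr(taylor_mean_ratio(mx, my, vy, c))


@lru_cache(maxsize=None)
def ratio_var_limit(pair: RatioPair):
    """lim_{n->inf} of the approximate Var[X/Y], from the composition."""
    from ._symbolic import limit_of_expr

    mx, my, vx, vy, c, _ = _symbolic_inputs(pair)
    return limit_of_expr(taylor_var_ratio(mx, my, vx, vy, c))


def ratio_mean_float(pair: RatioPair, n: int) -> float:
    """Float composition at very large n (limit-consistency checks)."""
    from .covariance import covariance_float
    from .moments import mean_float, variance_float

    x, y = pair.numerator, pair.denominator
    return float(taylor_mean_ratio(mean_float(x, n), mean_float(y, n),
                                   variance_float(y, n), covariance_float(x, y, n)))


def ratio_var_float(pair: RatioPair, n: int) -> float:
    from .covariance import covariance_float
    from .moments import mean_float, variance_float

    x, y = pair.numerator, pair.denominator
    return float(taylor_var_ratio(mean_float(x, n), mean_float(y, n),
                                  variance_float(x, n), variance_float(y, n),
                                  covariance_float(x, y, n)))
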