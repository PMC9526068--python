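"""Exact expectations and variances of coalescent tree summaries.

Under the standard (Kingman) coalescent for a constant-size haploid
population, with time in units of N generations, the coalescence times T_k
are independent exponentials with rate k(k-1)/2, so E[T_k] = 2/(k(k-1)) and
Var[T_k] = 4/(k^2 (k-1)^2).  The moments of the derived summaries H, L, E,
I, B follow as closed forms in the harmonic sums S_{p,n-1}; all finite-n
values here are exact rationals, and the n -> infinity limits are exact
combinations of {1, pi^2, pi^4, pi^6, zeta(3), pi^2 zeta(3)}.

Notable limit values: E[H_n] -> 2, Var[H_n] -> 4 pi^2/3 - 12; E[L_n] and
E[I_n] diverge while their variances converge to 2 pi^2/3; E[E_n] = 2 for
every n with Var[E_n] -> 0; E[B_n] -> pi^2/3 - 2.
"""

from __future__ import annotations

from functools import lru_cache

from ._context import exact_S, exact_n
from .scalars import ExactScalar
from .statistics import TreeStatistic

__all__ = ["mean", "variance", "mean_limit", "variance_limit", "mean_float", "variance_float"]


# -- formula bodies, generic over the arithmetic context ---------------------
# Each takes (n, S[, k]) where S(p, m) = S_{p,m}; n (and k) support exact
# Fraction or sympy values.  E_n's variance is piecewise and handled at the
# dispatch level; the body below is the n > 2 branch.

def _mean_H(n, S):
    return 2 * (n - 1) / n


def _mean_L(n, S):
    return 2 * S(1, n - 1)


def _mean_E(n, S):
    return 2 * (n / n)  # constant 2, kept context-typed


def _mean_I(n, S):
    return 2 * S(1, n - 1) - 2


def _mean_B(n, S):
    return 2 * S(2, n - 1) - 2 + 2 / n


def _mean_T(n, S, k):
    return 2 / (k * (k - 1))


def _var_H(n, S):
    return 8 * (S(2, n) - 1) - 4 * ((n - 1) / n) ** 2


def _var_L(n, S):
    return 4 * S(2, n - 1)


def _var_E_gt2(n, S):
    return 8 * (S(1, n - 1) * n - 2 * (n - 1)) / ((n - 1) * (n - 2))


def _var_I(n, S):
    return 4 * (2 * (S(1, n - 1) * n - 2 * (n - 1)) / ((n - 1) * (n - 2))
                - 2 * S(1, n - 1) / (n - 1) + S(2, n - 1))


def _var_B(n, S):
    s2 = S(2, n - 1)
    return 2 * (3 * s2 * n ** 2 - 2 * s2 ** 2 * n ** 2 + n ** 2
                - 4 * s2 * n + 3 * n - 4) / n ** 2


def _var_T(n, S, k):
    return 4 / (k ** 2 * (k - 1) ** 2)


MEAN_FORMULAS = {"H": _mean_H, "L": _mean_L, "E": _mean_E, "I": _mean_I,
                 "B": _mean_B, "T": _mean_T}
VAR_FORMULAS = {"H": _var_H, "L": _var_L, "E": _var_E_gt2, "I": _var_I,
                "B": _var_B, "T": _var_T}


def _evaluate(formula, stat: TreeStatistic, n: int) -> ExactScalar:
    stat.validate_n(n)
    nn = exact_n(n)
    if stat.kind == "T":
        value = formula(nn, exact_S, exact_n(stat.k))
    else:
        value = formula(nn, exact_S)
    return ExactScalar.from_rational(value)


def mean(stat: TreeStatistic, n: int) -> ExactScalar:
    """Exact E[X_n] for summary ``stat`` at sample size ``n``."""
    return _evaluate(MEAN_FORMULAS[stat.kind], stat, n)


def variance(stat: TreeStatistic, n: int) -> ExactScalar:
    """Exact Var[X_n]; E_n's variance is piecewise (4 at n = 2)."""
    if stat.kind == "E":
        stat.validate_n(n)
        if n == 2:
            return ExactScalar.from_rational(4)
    return _evaluate(VAR_FORMULAS[stat.kind], stat, n)


@lru_cache(maxsize=None)
def mean_limit(stat: TreeStatistic):
    """lim_{n->inf} E[X_n], computed symbolically from the finite-n formula."""
    from ._symbolic import limit_of_formula

    return limit_of_formula(MEAN_FORMULAS[stat.kind], k=stat.k)


@lru_cache(maxsize=None)
def variance_limit(stat: TreeStatistic):
    """lim_{n->inf} Var[X_n], computed symbolically from the finite-n formula."""
    from ._symbolic import limit_of_formula

    return limit_of_formula(VAR_FORMULAS[stat.kind], k=stat.k)


# -- float path for very large n --------------------------------------------
# Evaluated under mpmath extended precision: several formulas multiply
# harmonic sums by n^2 before subtracting near-equal terms, which would lose
# all significant digits in float64 by n ~ 1e7.

def _evaluate_float(formula, stat: TreeStatistic, n: int) -> float:
    import mpmath

    from .harmonic import harmonic_sum_mp

    stat.validate_n(n)
    with mpmath.workdps(40):
        S = lambda p, m: harmonic_sum_mp(p, int(m))  # noqa: E731
        if stat.kind == "T":
            return float(formula(mpmath.mpf(n), S, mpmath.mpf(stat.k)))
        return float(formula(mpmath.mpf(n), S))


def mean_float(stat: TreeStatistic, n: int) -> float:
    """Float E[X_n]; usable at n far beyond the exact-rational range."""
    return _evaluate_float(MEAN_FORMULAS[stat.kind], stat, n)


def variance_float(stat: TreeStatistic, n: int) -> float:
    if stat.kind == "E" and n == 2:
        return 4.0
    return _evaluate_float(VAR_FORMULAS[stat.kind], stat, n)
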