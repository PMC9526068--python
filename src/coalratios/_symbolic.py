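"""Symbolic n -> infinity limits of the finite-n moment formulas.

Limits are never transcribed from anywhere: each one is obtained by
substituting standard asymptotic expansions of the harmonic sums,

    S_{1,m} = log m + gamma + 1/(2m) + O(1/m^2)
    S_{2,m} = pi^2/6 - 1/m + 1/(2 m^2) + O(1/m^3)
    S_{3,m} = zeta(3) - 1/(2 m^2) + 1/(2 m^3) + O(1/m^4)

into the very same formula bodies used for exact evaluation, and letting
sympy take the limit.  The formulas are rational in (n, S_{p,.}), so the
neglected remainders contribute only vanishing relative corrections; every
computed limit is additionally cross-checked numerically at large n by the
test suite.  Results are mapped onto the exact constant basis
{1, pi^2, pi^4, pi^6, zeta(3), pi^2 zeta(3)}.
"""

from __future__ import annotations

import sympy

from .scalars import DIVERGES, ExactScalar

__all__ = ["N", "surrogate_S", "limit_of_formula", "limit_of_expr"]

#: The symbolic sample size.
N = sympy.Symbol("n", positive=True)


def surrogate_S(p: int, m):
    """Asymptotic surrogate for S_{p,m} with ``m`` a sympy expression."""
    if p == 1:
        return sympy.log(m) + sympy.EulerGamma + sympy.Rational(1, 2) / m
    if p == 2:
        return sympy.pi ** 2 / 6 - 1 / m + sympy.Rational(1, 2) / m ** 2
    if p == 3:
        return (sympy.zeta(3) - sympy.Rational(1, 2) / m ** 2
                + sympy.Rational(1, 2) / m ** 3)
    raise ValueError(f"no surrogate for harmonic order {p}")


def limit_of_expr(expr: sympy.Expr):
    """n -> oo limit of a surrogate expression, as ExactScalar or DIVERGES."""
    expr = sympy.together(expr)
    value = sympy.limit(expr, N, sympy.oo)
    if value in (sympy.oo, -sympy.oo, sympy.zoo):
        return DIVERGES
    return ExactScalar.from_sympy(value)


def limit_of_formula(formula, k: int | None = None):
    """Limit of a moment/covariance formula body ``f(n, S[, k])``."""
    if k is None:
        expr = formula(N, surrogate_S)
    else:
        expr = formula(N, surrogate_S, sympy.Integer(k))
    return limit_of_expr(expr)
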