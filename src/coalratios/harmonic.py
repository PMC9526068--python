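"""Generalized harmonic sums S_{p,n} = sum_{k=1}^n k^(-p).

These sums are the building blocks of every moment formula in the package:
S_{1,n-1} drives expectations of total branch length, S_{2,n-1} and S_{3,n-1}
drive variances and covariances.  As n -> infinity, S_{p,n} -> zeta(p); in
particular S_{2,inf} = pi^2/6 and S_{3,inf} = zeta(3) (Apery's constant),
while S_{1,n} diverges like log n.

Exact values are plain :class:`fractions.Fraction` objects wrapped in
:class:`~coalratios.scalars.ExactScalar`; a float path via mpmath serves the
very large n used in limit-consistency checks, where exact rationals would
have denominators with hundreds of thousands of digits.
"""

from __future__ import annotations

from fractions import Fraction

import mpmath

from .scalars import DIVERGES, ExactScalar

__all__ = ["harmonic_sum", "harmonic_limit", "harmonic_sum_float"]

# Incrementally extended caches: _CACHE[p] = list of partial sums, index n.
_CACHE: dict[int, list[Fraction]] = {}


def _check_order(p) -> int:
    if not isinstance(p, (int,)) or isinstance(p, bool) or p < 1:
        raise ValueError(f"order p must be an integer >= 1, got {p!r}")
    return int(p)


def harmonic_sum(p: int, n: int) -> ExactScalar:
    """Exact S_{p,n} as a rational.  The empty sum (n = 0) is 0."""
    p = _check_order(p)
    if not isinstance(n, int) or isinstance(n, bool) or n < 0:
        raise ValueError(f"n must be an integer >= 0, got {n!r}")
    sums = _CACHE.setdefault(p, [Fraction(0)])
    while len(sums) <= n:
        k = len(sums)
        sums.append(sums[-1] + Fraction(1, k ** p))
    return ExactScalar.from_rational(sums[n])


def harmonic_limit(p: int):
    """lim_{n->inf} S_{p,n}: DIVERGES for p = 1, zeta(p) otherwise.

    For p in {2, 3} the value is returned exactly over the constant basis;
    higher even orders reduce to powers of pi^2 while odd orders >= 5 have no
    representation in the basis and raise :class:`ValueError`.
    """
    p = _check_order(p)
    if p == 1:
        return DIVERGES
    if p == 2:
        return ExactScalar((0, Fraction(1, 6), 0, 0, 0, 0))
    if p == 3:
        return ExactScalar((0, 0, 0, 0, 1, 0))
    if p == 4:
        return ExactScalar((0, 0, Fraction(1, 90), 0, 0, 0))
    if p == 6:
        return ExactScalar((0, 0, 0, Fraction(1, 945), 0, 0))
    raise ValueError(f"zeta({p}) is outside the package's constant basis")


def harmonic_sum_mp(p: int, n: int) -> "mpmath.mpf":
    """S_{p,n} at mpmath's current working precision, via digamma / Hurwitz
    zeta identities (cost independent of n)."""
    p = _check_order(p)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return mpmath.mpf(0)
    if p == 1:
        return mpmath.harmonic(n)
    return mpmath.zeta(p) - mpmath.zeta(p, n + 1)


def harmonic_sum_float(p: int, n: int) -> float:
    """Float S_{p,n} for large n, where exact rationals are impractical."""
    with mpmath.workdps(30):
        return float(harmonic_sum_mp(p, n))
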