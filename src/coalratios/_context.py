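"""Arithmetic contexts for the moment formulas.

Every closed-form moment in the package is written exactly once, as a Python
function of ``(n, S)`` (and ``k`` for coalescence times), where ``S(p, m)``
is the harmonic sum S_{p,m}.  Calling such a function with Fraction-valued
arguments yields the exact rational value; calling it with sympy symbols and
asymptotic surrogates for S yields a symbolic expression whose n -> infinity
limit can be taken.  This guarantees the exact path and the limit path can
never drift apart.
"""

from __future__ import annotations

from fractions import Fraction

from .harmonic import harmonic_sum


def exact_S(p: int, m) -> Fraction:
    """Harmonic-sum callback for the exact rational context."""
    return harmonic_sum(p, int(m)).as_fraction()


def exact_n(n: int) -> Fraction:
    """Wrap n so integer division inside formulas stays exact."""
    return Fraction(n)
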