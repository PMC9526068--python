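"""Exact scalar values for coalescent moment formulas.

Finite-sample moments of coalescent tree summaries are rational numbers.
Their large-sample limits live in the six-dimensional rational vector space
spanned by ``{1, pi^2, pi^4, pi^6, zeta(3), pi^2*zeta(3)}`` (zeta(3) is
Apery's constant).  :class:`ExactScalar` represents both cases canonically so
that equality is decidable, and carries two sentinels:

* ``DIVERGES`` -- the quantity grows without bound (e.g. lim E[L_n]);
* ``UNDEFINED`` -- the quantity is outside its validity domain (e.g. B_3).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Union

import mpmath
import sympy

__all__ = ["ExactScalar", "DIVERGES", "UNDEFINED", "BASIS_NAMES"]

#: Names of the constant basis, in coefficient order.
BASIS_NAMES = ("1", "pi**2", "pi**4", "pi**6", "zeta(3)", "pi**2*zeta(3)")

_Z3 = sympy.zeta(3)
_BASIS_SYMPY = (
    sympy.Integer(1),
    sympy.pi ** 2,
    sympy.pi ** 4,
    sympy.pi ** 6,
    _Z3,
    sympy.pi ** 2 * _Z3,
)

with mpmath.workdps(60):
    _PI2 = mpmath.pi ** 2
    _BASIS_FLOATS = (
        mpmath.mpf(1),
        _PI2,
        _PI2 ** 2,
        _PI2 ** 3,
        mpmath.zeta(3),
        _PI2 * mpmath.zeta(3),
    )

RationalLike = Union[int, Fraction]


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __reduce__(self):  # keep singletons through pickling
        return (_sentinel_lookup, (self._name,))


DIVERGES = _Sentinel("DIVERGES")
UNDEFINED = _Sentinel("UNDEFINED")


def _sentinel_lookup(name: str) -> _Sentinel:
    return {"DIVERGES": DIVERGES, "UNDEFINED": UNDEFINED}[name]


class ExactScalar:
    """A rational number or rational combination over the constant basis.

    Internally every value is a tuple of six :class:`~fractions.Fraction`
    coefficients over ``BASIS_NAMES``; purely rational values have zeros in
    every coordinate but the first.  Instances are immutable and hashable,
    and equality is coefficient-wise (hence exact).
    """

    __slots__ = ("_coeffs",)

    def __init__(self, coeffs: Iterable[RationalLike]) -> None:
        coeffs = tuple(Fraction(c) for c in coeffs)
        if len(coeffs) != 6:
            raise ValueError("ExactScalar needs exactly 6 basis coefficients")
        object.__setattr__(self, "_coeffs", coeffs)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_rational(cls, value: RationalLike) -> "ExactScalar":
        return cls((Fraction(value), 0, 0, 0, 0, 0))

    @classmethod
    def from_sympy(cls, expr: sympy.Expr) -> "ExactScalar | _Sentinel":
        """Convert a sympy expression lying in the basis span.

        ``oo`` maps to ``DIVERGES``.  Raises :class:`ValueError` if the
        expression contains monomials outside the basis (this is how basis
        membership of computed limits is enforced).
        """
        expr = sympy.nsimplify(expr, rational=False)
        if expr in (sympy.oo, -sympy.oo):
            return DIVERGES
        expr = sympy.expand(expr)
        coeffs = [Fraction(0)] * 6
        for term in sympy.Add.make_args(expr):
            matched = False
            for i, mono in enumerate(_BASIS_SYMPY):
                ratio = sympy.simplify(term / mono)
                if ratio.is_Rational:
                    coeffs[i] += Fraction(int(ratio.p), int(ratio.q))
                    matched = True
                    break
            if not matched:
                raise ValueError(f"term {term} outside constant basis")
        return cls(coeffs)

    # -- accessors ---------------------------------------------------------
    @property
    def coefficients(self) -> tuple:
        return self._coeffs

    @property
    def is_rational(self) -> bool:
        return all(c == 0 for c in self._coeffs[1:])

    def as_fraction(self) -> Fraction:
        if not self.is_rational:
            raise ValueError(f"{self!r} is not a pure rational")
        return self._coeffs[0]

    def to_sympy(self) -> sympy.Expr:
        return sympy.Add(*(sympy.Rational(c.numerator, c.denominator) * b
                           for c, b in zip(self._coeffs, _BASIS_SYMPY)))

    def __float__(self) -> float:
        with mpmath.workdps(50):
            acc = mpmath.mpf(0)
            for c, b in zip(self._coeffs, _BASIS_FLOATS):
                acc += mpmath.mpf(c.numerator) / c.denominator * b
            return float(acc)

    def render(self, places: int = 5) -> str:
        """Decimal rendering, default five places (the printed precision)."""
        return f"{float(self):.{places}f}"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "ExactScalar":
        if isinstance(other, ExactScalar):
            return other
        if isinstance(other, (int, Fraction)):
            return ExactScalar.from_rational(other)
        return NotImplemented

    def __add__(self, other):
        other = self._coerce(other)
        if other is NotImplemented:
            return NotImplemented
        return ExactScalar(a + b for a, b in zip(self._coeffs, other._coeffs))

    __radd__ = __add__

    def __neg__(self):
        return ExactScalar(-c for c in self._coeffs)

    def __sub__(self, other):
        other = self._coerce(other)
        if other is NotImplemented:
            return NotImplemented
        return self + (-other)

    def __rsub__(self, other):
        return -(self - other)

    def __mul__(self, other):
        if isinstance(other, (int, Fraction)):
            return ExactScalar(c * other for c in self._coeffs)
        return NotImplemented

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, Fraction)):
            return ExactScalar(c / other for c in self._coeffs)
        return NotImplemented

    # -- comparisons -------------------------------------------------------
    def __eq__(self, other) -> bool:
        if isinstance(other, (int, Fraction)):
            other = ExactScalar.from_rational(other)
        if isinstance(other, ExactScalar):
            return self._coeffs == other._coeffs
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._coeffs)

    def __repr__(self) -> str:
        if self.is_rational:
            return f"ExactScalar({self._coeffs[0]})"
        parts = [f"{c}*{n}" for c, n in zip(self._coeffs, BASIS_NAMES) if c != 0]
        return "ExactScalar(" + (" + ".join(parts) or "0") + ")"
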