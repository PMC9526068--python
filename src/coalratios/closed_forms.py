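"""Pair-specific closed forms for the delta-method ratio approximations.

These are independent transcriptions of the published per-pair formulas for
the approximate expectation and variance of X_n/Y_n, in the canonical
orientations of :data:`coalratios.taylor.CANONICAL_PAIRS`.  The runtime path
of the package is the generic composition in :mod:`coalratios.taylor`; the
forms here exist as a cross-check, and the test suite asserts exact rational
equality of the two routes over a dense grid of n (and k).

Notation inside the bodies: ``S1 = S_{1,n-1}``, ``S2 = S_{2,n-1}``,
``S3 = S_{3,n-1}``, ``S2n = S_{2,n}``.
"""

from __future__ import annotations

from ._context import exact_S, exact_n
from .scalars import ExactScalar
from .taylor import RatioPair

__all__ = ["closed_form_mean", "closed_form_var"]


# -- Approximate expectations ------------------------------------------------

def _mean_H_T(n, S, k):
    return ((2 * k ** 2 - 2 * k - 1) * n - 2 * k * (k - 1)) / n


def _mean_H_L(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((n - 1) / (S1 * n) - (S2 * n - n + 1) / (S1 ** 2 * n)
            + S2 * (n - 1) / (S1 ** 3 * n))


def _mean_E_H(n, S):
    S2n = S(2, n)
    return n * (2 * S2n * n ** 2 - 2 * n ** 2 - n + 1) / (n - 1) ** 3


def _mean_H_I(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((n - 1) / ((S1 - 1) * n) - (S2 - 1) / (S1 - 1) ** 2
            + (S2 * (n - 1) * (n - 2) - 4 * n + 4 * S1 + 4)
            / ((S1 - 1) ** 3 * n * (n - 2)))


def _mean_B_H(n, S):
    S2, S3, S2n = S(2, n - 1), S(3, n - 1), S(2, n)
    return ((S2 * n - n + 1) / (n - 1)
            + (3 * S2 * n ** 2 - S3 * n ** 2 - 4 * n ** 2 + 3 * n + 1) / (n - 1) ** 2
            + (S2 * n - n + 1) * (2 * S2n * n ** 2 - 3 * n ** 2 + 2 * n - 1)
            / (n - 1) ** 3)


def _mean_L_T(n, S, k):
    S1 = S(1, n - 1)
    return 2 * S1 * k ** 2 - (2 * S1 + 1) * k


def _mean_E_L(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((S1 ** 2 + S2) * n - 2 * S1 ** 2 - S2) / (S1 ** 3 * (n - 1))


def _mean_L_I(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return (((S1 ** 3 + S2) * (n - 1) * (n - 2)
             - S1 ** 2 * (2 * n ** 2 - 7 * n + 2)
             + S1 * (n ** 2 - 8 * n + 8))
            / ((S1 - 1) ** 3 * (n - 1) * (n - 2)))


def _mean_B_L(n, S):
    S1, S2, S3 = S(1, n - 1), S(2, n - 1), S(3, n - 1)
    return ((S2 * n - n + 1) / (S1 * n)
            + (S2 * n - S3 * n - n + 1) / (S1 ** 2 * n)
            + S2 * (S2 * n - n + 1) / (S1 ** 3 * n))


def _mean_E_T(n, S, k):
    return k * (k - 1) * (2 * n - 3) / (n - 1)


def _mean_E_I(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((S1 ** 2 * (n ** 2 - 2 * n + 4) - S1 * (2 * n ** 2 - n - 2)
             + (S2 + 1) * (n - 1) * (n - 2))
            / ((S1 - 1) ** 3 * (n - 1) * (n - 2)))


def _mean_B_E(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((n ** 2 + 2 * S1 * n - 8 * n + 8) * (S2 * n - n + 1)
            / (n * (n - 1) * (n - 2)))


def _mean_I_T(n, S, k):
    S1 = S(1, n - 1)
    return 2 * k * (k - 1) * (S1 - 1) - k * (n - k) / (n - 1)


def _mean_B_I(n, S):
    S1, S2, S3 = S(1, n - 1), S(2, n - 1), S(3, n - 1)
    return ((S2 * n - n + 1) / ((S1 - 1) * n)
            + (S2 * n - n + 1) * (S2 * (n - 1) * (n - 2) - 4 * n + 4 * S1 + 4)
            / ((S1 - 1) ** 3 * n * (n - 1) * (n - 2))
            + (S2 * n - (S3 + 1) * (n - 1)) / ((S1 - 1) ** 2 * (n - 1)))


def _mean_B_T(n, S, k):
    S2 = S(2, n - 1)
    return 2 * k * (k - 1) * (S2 * n - n + 1) / n - 1 / (k - 1)


# -- Approximate variances ---------------------------------------------------

def _var_H_T(n, S, k):
    S2n = S(2, n)
    return 2 * k * (k - 1) * (k * (k - 1) * S2n * n - (k ** 2 - k + 1) * n + 1) / n


def _var_H_L(n, S):
    S1, S2, S2n = S(1, n - 1), S(2, n - 1), S(2, n)
    return (((n - 1) / (S1 * n)) ** 2
            * ((2 * (S2n - 1) * n ** 2 - (n - 1) ** 2) / (n - 1) ** 2
               - 2 * (S2 * n - (n - 1)) / (S1 * (n - 1))
               + S2 / S1 ** 2))


def _var_E_H(n, S):
    S1, S2n = S(1, n - 1), S(2, n)
    return ((2 * S1 * n * (n - 1) + 2 * S2n * n ** 2 * (n - 2)
             - (n ** 2 - 3) * (3 * n - 2))
            * n ** 2 / ((n - 1) ** 4 * (n - 2)))


def _var_H_I(n, S):
    S1, S2, S2n = S(1, n - 1), S(2, n - 1), S(2, n)
    return ((2 * S2n * n ** 2 - 3 * n ** 2 + 2 * n - 1) / ((S1 - 1) ** 2 * n ** 2)
            + (((S2 * (n - 2) - 4) * (n - 1) + 4 * S1) * (n - 1) / (n ** 2 * (n - 2))
               - 2 * (S1 - 1) * (S2 - 1) * (n - 1) / n) / (S1 - 1) ** 4)


def _var_B_H(n, S):
    S2, S3, S2n = S(2, n - 1), S(3, n - 1), S(2, n)
    return (((4 * S3 * n ** 2 + 4 * S2n * n ** 2 + 11 * n ** 2 - 5 * n - 10)
             * (n - 1) ** 2
             - S2 * (4 * S3 * n ** 2 + 8 * S2n * n ** 2 + 13 * n ** 2 - 9 * n - 12)
             * n * (n - 1)
             + 4 * S2 ** 2 * (S2n * n ** 2 + n ** 2 - n - 1) * n ** 2)
            / (2 * (n - 1) ** 4))


def _var_L_T(n, S, k):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return k ** 2 * (k - 1) ** 2 * (S2 - 2 * S1 / (k - 1) + S1 ** 2)


def _var_E_L(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((2 * S1 ** 3 * n - S1 ** 2 * (6 * n - 8) + S2 * (n - 1) * (n - 2))
            / (S1 ** 4 * (n - 1) * (n - 2)))


def _var_L_I(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((2 * S1 ** 3 * n - S1 ** 2 * (6 * n - 8) + S2 * (n - 1) * (n - 2))
            / ((S1 - 1) ** 4 * (n - 1) * (n - 2)))


def _var_B_L(n, S):
    S1, S2, S3 = S(1, n - 1), S(2, n - 1), S(3, n - 1)
    return ((S1 ** 2 * (-2 * S2 ** 2 * n ** 2 + S2 * (3 * n - 4) * n
                        + n ** 2 + 3 * n - 4)
             + 4 * S1 * (S2 * n - n + 1) * (S2 * n - S3 * n - n + 1)
             + 2 * S2 * (S2 * n - n + 1) ** 2)
            / (2 * S1 ** 4 * n ** 2))


def _var_E_T(n, S, k):
    S1 = S(1, n - 1)
    return (k ** 2 * (k - 1) ** 2 * (n ** 2 + 2 * S1 * n - 9 * n + 10)
            / ((n - 1) * (n - 2)))


def _var_E_I(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((2 * S1 ** 3 * n - S1 ** 2 * (6 * n - 8) + S2 * (n - 1) * (n - 2))
            / ((S1 - 1) ** 4 * (n - 1) * (n - 2)))


def _var_B_E(n, S):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return ((4 * S1 * n * (S2 * n - n + 1) ** 2
             - 2 * S2 ** 2 * (n ** 2 + 3 * n - 6) * n ** 2
             + S2 * (3 * n - 4) * (n + 6) * n * (n - 1)
             + (n ** 2 - 10 * n + 8) * (n - 1) ** 2)
            / (2 * n ** 2 * (n - 1) * (n - 2)))


def _var_I_T(n, S, k):
    S1, S2 = S(1, n - 1), S(2, n - 1)
    return (k ** 2 * (k - 1)
            * ((k - 1) * S1 ** 2 * (n - 1) * (n - 2)
               - 2 * S1 * (k * n ** 2 - 4 * k * n + n + 2 * k)
               + (k - 1) * S2 * (n - 1) * (n - 2)
               + k * n ** 2 + n ** 2 - 9 * k * n + 3 * n + 10 * k - 6)
            / ((n - 1) * (n - 2)))


def _var_B_I(n, S):
    S1, S2, S3 = S(1, n - 1), S(2, n - 1), S(3, n - 1)
    return ((S2 * (n - 1) * (n - 2) - 4 * n + 4 * S1 + 4) * (S2 * n - n + 1) ** 2
            / ((S1 - 1) ** 4 * n ** 2 * (n - 1) * (n - 2))
            + 2 * (S2 * n - (S3 + 1) * (n - 1)) * (S2 * n - n + 1)
            / ((S1 - 1) ** 3 * n * (n - 1))
            - (2 * S2 ** 2 * n ** 2 - S2 * (3 * n - 4) * n - (n + 4) * (n - 1))
            / (2 * (S1 - 1) ** 2 * n ** 2))


def _var_B_T(n, S, k):
    S2 = S(2, n - 1)
    return (k / 2 * ((k * (k - 1) ** 2 * (3 * n + 2) + 4 * n) * (n - 1)
                     / n ** 2
                     - (k + 1) * (k ** 2 - 3 * k + 4) * S2))


_MEAN_FORMS = {
    ("H", "T"): _mean_H_T, ("H", "L"): _mean_H_L, ("E", "H"): _mean_E_H,
    ("H", "I"): _mean_H_I, ("B", "H"): _mean_B_H, ("L", "T"): _mean_L_T,
    ("E", "L"): _mean_E_L, ("L", "I"): _mean_L_I, ("B", "L"): _mean_B_L,
    ("E", "T"): _mean_E_T, ("E", "I"): _mean_E_I, ("B", "E"): _mean_B_E,
    ("I", "T"): _mean_I_T, ("B", "I"): _mean_B_I, ("B", "T"): _mean_B_T,
}

_VAR_FORMS = {
    ("H", "T"): _var_H_T, ("H", "L"): _var_H_L, ("E", "H"): _var_E_H,
    ("H", "I"): _var_H_I, ("B", "H"): _var_B_H, ("L", "T"): _var_L_T,
    ("E", "L"): _var_E_L, ("L", "I"): _var_L_I, ("B", "L"): _var_B_L,
    ("E", "T"): _var_E_T, ("E", "I"): _var_E_I, ("B", "E"): _var_B_E,
    ("I", "T"): _var_I_T, ("B", "I"): _var_B_I, ("B", "T"): _var_B_T,
}


def form_min_n(pair: RatioPair) -> int:
    """Smallest n covered by the tabulated forms: the published tables state
    validity n >= 3 whenever E_n or I_n is involved (n >= 4 with B_n)."""
    kinds = {pair.numerator.kind, pair.denominator.kind}
    return max(pair.min_n, 3 if kinds & {"E", "I"} else 2)


def _evaluate(forms, pair: RatioPair, n: int) -> ExactScalar:
    key = (pair.numerator.kind, pair.denominator.kind)
    if key not in forms:
        raise ValueError(f"no tabulated closed form for orientation {pair}; "
                         "use the generic composition")
    if n < form_min_n(pair):
        raise ValueError(f"the tabulated form for {pair} is undefined at n = {n}")
    nn = exact_n(n)
    if pair.k is not None:
        value = forms[key](nn, exact_S, exact_n(pair.k))
    else:
        value = forms[key](nn, exact_S)
    return ExactScalar.from_rational(value)


def closed_form_mean(pair: RatioPair, n: int) -> ExactScalar:
    """Tabulated approximate E[X/Y] at finite n (canonical orientation)."""
    return _evaluate(_MEAN_FORMS, pair, n)


def closed_form_var(pair: RatioPair, n: int) -> ExactScalar:
    """Tabulated approximate Var[X/Y] at finite n (canonical orientation)."""
    return _evaluate(_VAR_FORMS, pair, n)
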