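"""Exact covariances of pairs of coalescent tree summaries.

All 15 unordered pairs among {H, L, E, I, B, T(k)} are covered.  Thirteen
covariances are exact; the two involving the basal-branch summary together
with external/internal length -- (E, B) and (I, B) -- are themselves
approximations, and results for them carry ``approximate=True`` so that any
downstream quantity built on them (notably the delta-method variance of
B_n/E_n) can propagate the caveat.

Derivable sanity identities used by the test-suite oracles: with independent
T_k, Cov[H, T_k] = Var[T_k], Cov[L, T_k] = k Var[T_k], and Cov[H, L] =
sum_k k Var[T_k]; additivity in I = L - E relates every I-covariance to
L- and E-covariances.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from ._context import exact_S, exact_n
from .moments import variance, variance_limit
from .scalars import ExactScalar
from .statistics import TreeStatistic

__all__ = ["CovarianceResult", "covariance", "covariance_limit", "covariance_float",
           "APPROXIMATE_PAIRS"]

#: Unordered pairs whose covariance is approximate rather than exact.
APPROXIMATE_PAIRS = (frozenset({"E", "B"}), frozenset({"I", "B"}))

_ORDER = {"H": 0, "L": 1, "E": 2, "I": 3, "B": 4, "T": 5}


@dataclass(frozen=True)
class CovarianceResult:
    """A covariance value with a flag marking the two approximate entries."""

    value: ExactScalar
    approximate: bool = False

    def __float__(self) -> float:
        return float(self.value)


# -- Cov[X_n, Y_n] formula bodies, canonical order (H, L, E, I, B, T) --------

def _cov_H_T(n, S, k):
    return 4 / (k ** 2 * (k - 1) ** 2)


def _cov_H_L(n, S):
    return 4 * S(2, n - 1) - 4 + 4 / n


def _cov_H_E(n, S):
    return 4 / n


def _cov_H_I(n, S):
    return 4 * S(2, n - 1) - 4


def _cov_H_B(n, S):
    return 4 * (S(3, n - 1) * n ** 2 - 3 * S(2, n - 1) * n ** 2
                + (4 * n + 1) * (n - 1)) / n ** 2


def _cov_L_T(n, S, k):
    return 4 / (k * (k - 1) ** 2)


def _cov_L_E(n, S):
    return 4 * S(1, n - 1) / (n - 1)


def _cov_L_I(n, S):
    return 4 * S(2, n - 1) - 4 * S(1, n - 1) / (n - 1)


def _cov_L_B(n, S):
    return 4 * (S(3, n - 1) * n - S(2, n - 1) * n + n - 1) / n


def _cov_E_T(n, S, k):
    return 4 / (k * (k - 1) * (n - 1))


def _cov_E_I(n, S):
    return (4 * S(1, n - 1) / (n - 1)
            - 8 * S(1, n - 1) * n / ((n - 1) * (n - 2))
            + 16 / (n - 2))


def _cov_E_B(n, S):  # approximate
    return 4 * (S(2, n - 1) * n - n + 1) / (n * (n - 1))


def _cov_I_T(n, S, k):
    return 4 * (n - k) / (k * (k - 1) ** 2 * (n - 1))


def _cov_I_B(n, S):  # approximate
    return 4 * (S(3, n - 1) * n - S(2, n - 1) * n + n - S(3, n - 1) - 1) / (n - 1)


def _cov_B_T(n, S, k):
    return 4 / (k ** 2 * (k - 1) ** 3)


COV_FORMULAS = {
    ("H", "L"): _cov_H_L, ("H", "E"): _cov_H_E, ("H", "I"): _cov_H_I,
    ("H", "B"): _cov_H_B, ("H", "T"): _cov_H_T, ("L", "E"): _cov_L_E,
    ("L", "I"): _cov_L_I, ("L", "B"): _cov_L_B, ("L", "T"): _cov_L_T,
    ("E", "I"): _cov_E_I, ("E", "B"): _cov_E_B, ("E", "T"): _cov_E_T,
    ("I", "B"): _cov_I_B, ("I", "T"): _cov_I_T, ("B", "T"): _cov_B_T,
}


def _canonical(x: TreeStatistic, y: TreeStatistic):
    """Order the pair canonically; reject (T(j), T(k)) with j != k."""
    if x.kind == "T" and y.kind == "T":
        raise ValueError("covariance of two distinct coalescence times is not "
                         "tabulated; use variance for identical T(k)")
    if _ORDER[x.kind] > _ORDER[y.kind]:
        x, y = y, x
    return x, y


def _lookup(x: TreeStatistic, y: TreeStatistic):
    x, y = _canonical(x, y)
    key = (x.kind, y.kind)
    approx = frozenset(key) in APPROXIMATE_PAIRS
    k = x.k if x.kind == "T" else y.k
    return COV_FORMULAS[key], k, approx


def _joint_min_n(x: TreeStatistic, y: TreeStatistic) -> int:
    return max(x.min_n, y.min_n)


def covariance(x: TreeStatistic, y: TreeStatistic, n: int) -> CovarianceResult:
    """Exact Cov[X_n, Y_n]; symmetric; delegates to the variance when x = y.

    Pairs with B_n require n >= 4 and pairs with I_n require n >= 3.  Pairs
    of E_n with H, L, or T(k) are valid from n = 2, where E_2 = 2 T_2 = L_2
    makes the tabulated forms exact.
    """
    if x == y:
        return CovarianceResult(variance(x, n), approximate=False)
    formula, k, approx = _lookup(x, y)
    m = _joint_min_n(x, y)
    if not isinstance(n, int) or isinstance(n, bool) or n < m:
        raise ValueError(f"Cov[{x}, {y}] is undefined for n = {n} (needs n >= {m})")
    nn = exact_n(n)
    args = (nn, exact_S) if k is None else (nn, exact_S, exact_n(k))
    return CovarianceResult(ExactScalar.from_rational(formula(*args)), approx)


@lru_cache(maxsize=None)
def _covariance_limit_cached(x: TreeStatistic, y: TreeStatistic) -> CovarianceResult:
    from ._symbolic import limit_of_formula

    formula, k, approx = _lookup(x, y)
    return CovarianceResult(limit_of_formula(formula, k=k), approx)


def covariance_limit(x: TreeStatistic, y: TreeStatistic) -> CovarianceResult:
    """lim_{n->inf} Cov[X_n, Y_n], symbolically from the finite-n formula."""
    if x == y:
        return CovarianceResult(variance_limit(x), approximate=False)
    x, y = _canonical(x, y)
    return _covariance_limit_cached(x, y)


def covariance_float(x: TreeStatistic, y: TreeStatistic, n: int) -> float:
    """Float evaluation for very large n (limit-consistency checks).

    Runs under mpmath extended precision: formulas such as Cov[H,B] subtract
    near-equal multiples of n^2, which float64 cannot survive at n ~ 1e7.
    """
    import mpmath

    from .harmonic import harmonic_sum_mp
    from .moments import variance_float

    if x == y:
        return variance_float(x, n)
    formula, k, _ = _lookup(x, y)
    if n < _joint_min_n(x, y):
        raise ValueError(f"Cov[{x}, {y}] is undefined for n = {n}")
    with mpmath.workdps(40):
        S = lambda p, m: harmonic_sum_mp(p, int(m))  # noqa: E731
        nn = mpmath.mpf(n)
        args = (nn, S) if k is None else (nn, S, mpmath.mpf(k))
        return float(formula(*args))
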