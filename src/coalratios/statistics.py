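"""Identifiers for the six coalescent tree summaries.

The summaries of a genealogy with n leaves are:

* ``H`` -- tree height (TMRCA), H_n = sum_{k=2}^n T_k, defined for n >= 2;
* ``L`` -- total branch length, L_n = sum_{k=2}^n k*T_k, n >= 2;
* ``E`` -- total external branch length, n >= 2;
* ``I`` -- total internal branch length, I_n = L_n - E_n, n >= 3;
* ``B`` -- mean length of the two basal (root-incident) branches, n >= 4;
* ``T(k)`` -- the coalescence time while k lineages exist, 2 <= k <= n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["TreeStatistic", "H", "L", "E", "I", "B", "T", "KINDS"]

KINDS = ("H", "L", "E", "I", "B", "T")

# smallest sample size for which each summary is defined
_MIN_N = {"H": 2, "L": 2, "E": 2, "I": 3, "B": 4, "T": 2}


@dataclass(frozen=True)
class TreeStatistic:
    """One of H, L, E, I, B, or T(k), with its validity domain in n."""

    kind: str
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.kind == "T":
            if not isinstance(self.k, int) or isinstance(self.k, bool) or self.k < 2:
                raise ValueError("T(k) requires an integer k >= 2")
        elif self.k is not None:
            raise ValueError(f"{self.kind} does not take a k index")

    @property
    def min_n(self) -> int:
        """Smallest n for which the statistic is defined (k for T(k))."""
        if self.kind == "T":
            return self.k
        return _MIN_N[self.kind]

    def validate_n(self, n: int) -> None:
        if not isinstance(n, int) or isinstance(n, bool):
            raise ValueError(f"sample size n must be an integer, got {n!r}")
        if n < self.min_n:
            raise ValueError(f"{self} is undefined for n = {n} (needs n >= {self.min_n})")

    def __str__(self) -> str:
        return f"T({self.k})" if self.kind == "T" else self.kind


H = TreeStatistic("H")
L = TreeStatistic("L")
E = TreeStatistic("E")
I = TreeStatistic("I")  # noqa: E741 - the field's standard symbol
B = TreeStatistic("B")


def T(k: int) -> TreeStatistic:
    """The coalescence time T_k from k to k-1 lineages."""
    return TreeStatistic("T", k)
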