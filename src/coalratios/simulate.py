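"""Kingman coalescent simulator and empirical moment estimation.

Genealogies of n leaves are generated under the standard coalescent: while k
lineages remain, the waiting time T_k is exponential with rate k(k-1)/2 (time
in units of N generations) and the merging pair is uniform over the k(k-1)/2
unordered pairs.  Per-tree summaries H, L, E, I, B and all T_k are measured
on the realized genealogy: E sums each leaf's branch up to its first
coalescence, I = L - E, and B is the mean length of the two branches incident
to the root (reported for n >= 4 by default, matching the validity domain of
its moment formulas).

Reproducibility contract: a single integer seed fully determines every
replicate.  Replicate r of a run at sample size n uses the dedicated
generator ``numpy.random.default_rng([seed, n, r])``, so runs can be chunked
or parallelized over r without changing results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .scalars import UNDEFINED
from .statistics import TreeStatistic

__all__ = ["CoalescentTree", "StatBundle", "StatSamples", "EmpiricalMoments",
           "simulate_tree", "tree_statistics", "sample_statistics",
           "empirical_ratio_moments", "ratio_moments_from_samples",
           "stat_moments_from_samples", "covariance_from_samples",
           "write_newick"]


@dataclass(frozen=True)
class CoalescentTree:
    """A realized coalescent genealogy.

    Leaves are labeled 1..n; the internal node created by the j-th coalescence
    (0-based) is n+1+j, so the root is 2n-1.  ``times[j]`` is the waiting time
    T_k for k = n-j; ``merges[j]`` names the two lineages that coalesce.
    """

    n: int
    times: np.ndarray
    merges: tuple
    node_ages: np.ndarray

    def __post_init__(self) -> None:
        if len(self.merges) != self.n - 1 or len(self.times) != self.n - 1:
            raise ValueError("tree must have exactly n-1 coalescence events")

    def time(self, k: int) -> float:
        """The realized T_k, 2 <= k <= n."""
        if not 2 <= k <= self.n:
            raise ValueError(f"T_{k} does not exist in a tree with n = {self.n}")
        return float(self.times[self.n - k])

    @property
    def root(self) -> int:
        return 2 * self.n - 1

    @property
    def root_age(self) -> float:
        return float(self.node_ages[self.root - 1])

    def children(self) -> dict:
        """Map from internal node id to its two child ids."""
        return {self.n + 1 + j: pair for j, pair in enumerate(self.merges)}

    def parent_ages(self) -> np.ndarray:
        """Age of each node's parent, indexed by node id - 1 (root: nan)."""
        out = np.full(2 * self.n - 1, np.nan)
        for j, (a, b) in enumerate(self.merges):
            parent_age = self.node_ages[self.n + j]
            out[a - 1] = parent_age
            out[b - 1] = parent_age
        return out


@dataclass(frozen=True)
class StatBundle:
    """Per-tree values of the six summaries (B may be UNDEFINED for n < 4)."""

    n: int
    H: float
    L: float
    E: float
    I: float  # noqa: E741
    B: Union[float, object]
    times: np.ndarray  # T_n .. T_2

    def value(self, stat: TreeStatistic) -> float:
        if stat.kind == "T":
            if not 2 <= stat.k <= self.n:
                raise ValueError(f"{stat} undefined at n = {self.n}")
            return float(self.times[self.n - stat.k])
        v = getattr(self, stat.kind)
        if v is UNDEFINED:
            raise ValueError(f"{stat} is UNDEFINED for n = {self.n}")
        return float(v)


def simulate_tree(n: int, rng: np.random.Generator) -> CoalescentTree:
    """Draw one standard-coalescent genealogy with n leaves.

    The waiting time while k lineages exist is exponential with rate
    k(k-1)/2; the coalescing pair is uniform over unordered pairs.  The same
    generator state always yields the same tree.
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 2:
        raise ValueError(f"need an integer n >= 2, got {n!r}")
    ks = np.arange(n, 1, -1)
    times = (2.0 / (ks * (ks - 1.0))) * rng.standard_exponential(n - 1)
    u = rng.random((n - 1, 2))
    active = list(range(1, n + 1))
    ages = np.zeros(2 * n - 1)
    merges = []
    t = 0.0
    for j in range(n - 1):
        k = n - j
        t += times[j]
        i1 = int(u[j, 0] * k)
        i2 = int(u[j, 1] * (k - 1))
        if i2 >= i1:
            i2 += 1
        a, b = active[i1], active[i2]
        new = n + 1 + j
        ages[new - 1] = t
        if i1 < i2:
            i1, i2 = i2, i1
        active.pop(i1)
        active.pop(i2)
        active.append(new)
        merges.append((a, b))
    return CoalescentTree(n=n, times=times, merges=tuple(merges), node_ages=ages)


def tree_statistics(tree: CoalescentTree, basal_small_n: bool = False) -> StatBundle:
    """Compute H, L, E, I, B and the T_k realized on ``tree``.

    ``basal_small_n=True`` opts in to reporting the root-children mean B even
    for n in {2, 3}, where the tabulated moments leave it undefined.
    """
    n = tree.n
    ks = np.arange(n, 1, -1)
    H = float(np.sum(tree.times))
    L = float(np.dot(ks, tree.times))
    parent_ages = tree.parent_ages()
    E = float(np.sum(parent_ages[:n]))
    I = L - E  # noqa: E741
    if n >= 4 or basal_small_n:
        a, b = tree.merges[-1]
        root_age = tree.root_age
        B = root_age - 0.5 * (tree.node_ages[a - 1] + tree.node_ages[b - 1])
    else:
        B = UNDEFINED
    return StatBundle(n=n, H=H, L=L, E=E, I=I, B=B, times=tree.times)


# -- batched sampling --------------------------------------------------------

@dataclass
class StatSamples:
    """Replicate-by-replicate summary values from a simulation run.

    ``T`` has one column per level, ordered k = 2..n; ``B`` is NaN-filled
    when n < 4.
    """

    n: int
    reps: int
    seed: int
    H: np.ndarray = field(repr=False)
    L: np.ndarray = field(repr=False)
    E: np.ndarray = field(repr=False)
    I: np.ndarray = field(repr=False)  # noqa: E741
    B: np.ndarray = field(repr=False)
    T: np.ndarray = field(repr=False)

    def column(self, stat: TreeStatistic) -> np.ndarray:
        if stat.kind == "T":
            if not 2 <= stat.k <= self.n:
                raise ValueError(f"{stat} undefined at n = {self.n}")
            return self.T[:, stat.k - 2]
        if stat.kind == "B" and self.n < 4:
            raise ValueError(f"B is UNDEFINED for n = {self.n}")
        return getattr(self, stat.kind)


def replicate_rng(seed: int, n: int, r: int) -> np.random.Generator:
    """The dedicated generator for replicate r of a run at sample size n."""
    return np.random.default_rng([seed, n, r])


def sample_statistics(n: int, reps: int, seed: int) -> StatSamples:
    """Simulate ``reps`` independent genealogies and collect their summaries."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    H = np.empty(reps)
    L = np.empty(reps)
    E = np.empty(reps)
    I = np.empty(reps)  # noqa: E741
    B = np.full(reps, np.nan)
    T = np.empty((reps, n - 1))
    for r in range(reps):
        bundle = tree_statistics(simulate_tree(n, replicate_rng(seed, n, r)))
        H[r], L[r], E[r], I[r] = bundle.H, bundle.L, bundle.E, bundle.I
        if bundle.B is not UNDEFINED:
            B[r] = bundle.B
        T[r] = bundle.times[::-1]  # reorder to k = 2..n
    return StatSamples(n=n, reps=reps, seed=seed, H=H, L=L, E=E, I=I, B=B, T=T)


@dataclass(frozen=True)
class EmpiricalMoments:
    """Monte-Carlo mean and variance of a per-tree quantity, with SEs."""

    label: str
    n: int
    reps: int
    seed: int
    mean: float
    variance: float
    se_mean: float
    se_variance: float


def _moments_of(values: np.ndarray, label: str, n: int, reps: int,
                seed: int) -> EmpiricalMoments:
    if len(values) < 2:
        raise ValueError("need at least 2 replicates for moment estimates")
    m = float(np.mean(values))
    v = float(np.var(values, ddof=1))
    centered = values - m
    m4 = float(np.mean(centered ** 4))
    se_mean = float(np.sqrt(v / reps))
    se_var = float(np.sqrt(max(m4 - v * v, 0.0) / reps))
    return EmpiricalMoments(label=label, n=n, reps=reps, seed=seed, mean=m,
                            variance=v, se_mean=se_mean, se_variance=se_var)


def stat_moments_from_samples(samples: StatSamples,
                              stat: TreeStatistic) -> EmpiricalMoments:
    """Empirical mean/variance of one summary from an existing run."""
    return _moments_of(samples.column(stat), str(stat), samples.n,
                       samples.reps, samples.seed)


def ratio_moments_from_samples(samples: StatSamples, x: TreeStatistic,
                               y: TreeStatistic) -> EmpiricalMoments:
    """Empirical mean/variance of the per-tree ratio x/y from a run."""
    values = samples.column(x) / samples.column(y)
    return _moments_of(values, f"{x}/{y}", samples.n, samples.reps, samples.seed)


def covariance_from_samples(samples: StatSamples, x: TreeStatistic,
                            y: TreeStatistic):
    """Empirical Cov[x, y] and its standard error from a run."""
    xs = samples.column(x)
    ys = samples.column(y)
    dx = xs - xs.mean()
    dy = ys - ys.mean()
    reps = samples.reps
    cov = float(np.dot(dx, dy) / (reps - 1))
    # SE of the sample covariance via its influence-function variance
    se = float(np.sqrt(max(np.mean((dx * dy) ** 2) - cov * cov, 0.0) / reps))
    return cov, se


def empirical_ratio_moments(x: TreeStatistic, y: TreeStatistic, n: int,
                            reps: int, seed: int) -> EmpiricalMoments:
    """Simulate ``reps`` trees and estimate moments of the ratio x/y.

    The ratio must be well defined at this n (both statistics within their
    validity domains); identical arguments always return identical output.
    """
    if x == y:
        raise ValueError("ratio numerator and denominator must differ")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    for s in (x, y):
        s.validate_n(n)
    samples = sample_statistics(n, reps, seed)
    return ratio_moments_from_samples(samples, x, y)


# -- Newick output -----------------------------------------------------------

def write_newick(tree: CoalescentTree, digits: int = 12) -> str:
    """Single-line Newick string with branch lengths in coalescent units.

    Leaves are labeled "1".."n"; internal nodes are unlabeled; the root
    carries no branch length.
    """
    children = tree.children()
    ages = tree.node_ages
    rendered: dict[int, str] = {}
    for node in range(1, 2 * tree.n):
        if node <= tree.n:
            rendered[node] = str(node)
        else:
            a, b = children[node]
            la = ages[node - 1] - ages[a - 1]
            lb = ages[node - 1] - ages[b - 1]
            rendered[node] = (f"({rendered[a]}:{la:.{digits}g},"
                              f"{rendered[b]}:{lb:.{digits}g})")
    return rendered[tree.root] + ";"
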