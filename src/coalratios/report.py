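"""Tabular reporting: numeric moment tables, ratio-approximation tables, and
simulation-vs-approximation comparisons, with delimited-text output.

Tables are returned as pandas DataFrames.  A limit row (``n = "inf"``) can be
appended to the n-sweeps; cells outside a statistic's validity domain are
left empty.  Output files carry ``# key=value`` comment headers (seed, reps,
package version) so any stochastic table can be regenerated bit-identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .moments import mean, mean_limit, variance, variance_limit
from .scalars import DIVERGES, UNDEFINED, ExactScalar
from .simulate import (ratio_moments_from_samples, sample_statistics)
from .statistics import B, E, H, I, L, T, TreeStatistic
from .taylor import (RatioPair, ratio_mean_approx, ratio_mean_limit,
                     ratio_var_approx, ratio_var_limit)

__all__ = ["ComparisonRecord", "build_moment_table", "build_ratio_table",
           "compare_simulation", "write_delimited", "render_markdown",
           "parse_pair", "DEFAULT_STATS"]

DEFAULT_STATS = (H, L, E, I, B)


def _render(value, exact: bool, places: int = 5):
    """Render an ExactScalar/sentinel cell: float, 'p/q', 'inf', or ''."""
    if value is None or value is UNDEFINED:
        return ""
    if value is DIVERGES:
        return "inf"
    if isinstance(value, ExactScalar):
        if exact and value.is_rational:
            return str(value.as_fraction())
        if exact:
            return repr(value)
        return round(float(value), places)
    return value


def parse_pair(text: str) -> RatioPair:
    """Parse 'X/Y' pair notation, e.g. 'E/H', 'L/T2', 'B/T(3)'."""
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise ValueError(f"pair must look like 'X/Y', got {text!r}")

    def stat(token: str) -> TreeStatistic:
        token = token.strip().upper().replace("(", "").replace(")", "")
        if token.startswith("T") and len(token) > 1:
            return T(int(token[1:]))
        if token in {"H", "L", "E", "I", "B"}:
            return TreeStatistic(token)
        raise ValueError(f"unknown statistic {token!r} in pair {text!r}")

    return RatioPair(stat(parts[0]), stat(parts[1]))


def build_moment_table(n_range: Sequence[int],
                       stats: Sequence[TreeStatistic] = DEFAULT_STATS,
                       include_limit: bool = True,
                       exact: bool = False) -> pd.DataFrame:
    """One row per n with mean/variance of each statistic, plus a limit row.

    Cells where a statistic is undefined (e.g. B at n < 4) are empty.
    """
    n_range = list(n_range)
    if not n_range:
        raise ValueError("empty n range")
    rows = []
    for n in n_range:
        row = {"n": n}
        for s in stats:
            try:
                row[f"mean_{s}"] = _render(mean(s, n), exact)
                row[f"var_{s}"] = _render(variance(s, n), exact)
            except ValueError:
                row[f"mean_{s}"] = ""
                row[f"var_{s}"] = ""
        rows.append(row)
    if include_limit:
        row = {"n": "inf"}
        for s in stats:
            row[f"mean_{s}"] = _render(mean_limit(s), exact)
            row[f"var_{s}"] = _render(variance_limit(s), exact)
        rows.append(row)
    return pd.DataFrame(rows)


def build_ratio_table(pairs: Sequence[RatioPair], n_range: Sequence[int],
                      include_limit: bool = True,
                      exact: bool = False) -> pd.DataFrame:
    """Delta-method mean/variance of each ratio over an n sweep."""
    n_range = list(n_range)
    if not n_range:
        raise ValueError("empty n range")
    rows = []
    any_valid = False
    for pair in pairs:
        for n in n_range:
            row = {"pair": str(pair), "n": n,
                   "k": pair.k if pair.k is not None else ""}
            try:
                ma = ratio_mean_approx(pair, n)
                va = ratio_var_approx(pair, n)
            except (ValueError, ZeroDivisionError):
                row.update(mean_approx="", var_approx="", approx_cov="")
            else:
                any_valid = True
                row.update(mean_approx=_render(ma.mean_approx, exact),
                           var_approx=_render(va.var_approx, exact),
                           approx_cov=ma.approximate)
            rows.append(row)
        if include_limit:
            rows.append({"pair": str(pair), "n": "inf",
                         "k": pair.k if pair.k is not None else "",
                         "mean_approx": _render(ratio_mean_limit(pair), exact),
                         "var_approx": _render(ratio_var_limit(pair), exact),
                         "approx_cov": ""})
    if not any_valid:
        raise ValueError("no pair in the requested range is within its "
                         "validity domain")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonRecord:
    """Approximation vs simulation for one (pair, n); regenerable from
    (seed, reps) thanks to the simulator's counter-based substreams."""

    pair: str
    n: int
    k: Optional[int]
    approx_mean: float
    approx_var: float
    empirical_mean: float
    empirical_var: float
    se_mean: float
    se_var: float
    reps: int
    seed: int
    approximate_cov: bool


def compare_simulation(pairs: Sequence[RatioPair], n_range: Sequence[int],
                       reps: int, seed: int) -> pd.DataFrame:
    """Empirical vs approximate ratio moments; one simulation run per n."""
    if reps < 2:
        raise ValueError("reps must be >= 2")
    records = []
    for n in n_range:
        valid = [p for p in pairs if n >= p.min_n]
        if not valid:
            continue
        samples = sample_statistics(n, reps, seed)
        for pair in valid:
            ma = ratio_mean_approx(pair, n)
            va = ratio_var_approx(pair, n)
            em = ratio_moments_from_samples(samples, pair.numerator,
                                            pair.denominator)
            records.append(ComparisonRecord(
                pair=str(pair), n=n, k=pair.k,
                approx_mean=float(ma.mean_approx),
                approx_var=float(va.var_approx),
                empirical_mean=em.mean, empirical_var=em.variance,
                se_mean=em.se_mean, se_var=em.se_variance,
                reps=reps, seed=seed, approximate_cov=ma.approximate))
    if not records:
        raise ValueError("no valid (pair, n) combinations to compare")
    return pd.DataFrame([r.__dict__ for r in records])


def write_delimited(records: pd.DataFrame, path, delimiter: str = ",",
                    places: int = 5, metadata: Optional[dict] = None) -> None:
    """Write records as UTF-8 delimited text with '# key=value' headers."""
    if records is None or len(records) == 0:
        raise ValueError("refusing to write an empty table")
    meta = {"version": __version__}
    meta.update(metadata or {})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(records.columns)
        for _, row in records.iterrows():
            writer.writerow([_format_cell(v, places) for v in row])


def read_delimited(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a file produced by :func:`write_delimited` (skips # headers)."""
    return pd.read_csv(path, comment="#", delimiter=delimiter)


def _format_cell(value, places: int):
    if isinstance(value, float):
        return f"{value:.{places}f}"
    return value


def render_markdown(records: pd.DataFrame, places: int = 5) -> str:
    """A minimal GitHub-style markdown table."""
    cols = list(records.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in records.iterrows():
        cells = [str(_format_cell(v, places)) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
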