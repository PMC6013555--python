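"""Per-term and per-disorder DEG statistics and the number-vs-percentage ranking.

For each (region, age) condition the screen reports, per GO term, the count
of pool genes called differentially expressed and that count as a percentage
of the term's snapshot pool size; per disorder, the deduplicated count over
the pool union, its percentage, and the disorder's share of all DEGs on the
array.  Disorders are ranked either by DEG number or by percentage — the two
keys can disagree, and the screen's headline uses the number.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import pandas as pd

from .annotation import DisorderPool

Condition = tuple[str, int]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (display convention for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TermStats:
    """DEG count and percentage for one GO term in one condition."""

    term: str
    condition: Condition
    n_deg: int
    pool_size: int
    percentage: float  # 100 * n_deg / pool_size, half-up to two decimals

    @property
    def cell(self) -> str:
        """Display cell in the ``pct (n/size)`` convention."""
        return f"{self.percentage:.2f} ({self.n_deg}/{self.pool_size})"


@dataclass(frozen=True)
class DisorderTotals:
    """Deduplicated DEG totals for one disorder pool in one condition."""

    disorder: str
    condition: Condition
    n_deg_unique: int
    pool_size: int
    percentage: float  # over the pool union, half-up to two decimals
    share_of_all_degs: float  # 100 * n_deg_unique / n_total_degs, one decimal
    share_of_all_degs_int: int  # integer-rounded convenience display

    @property
    def cell(self) -> str:
        return f"{self.percentage:.2f} ({self.n_deg_unique}/{self.pool_size})"


def count_degs_per_term(
    deg_genes: set[str],
    term_sets: Mapping[str, set[str]],
    condition: Condition,
) -> list[TermStats]:
    """Per-term DEG counts: ``n_deg = |deg_genes ∩ term set|``."""
    if not term_sets:
        raise ValueError("term_sets must be non-empty")
    out = []
    for term in term_sets:
        pool = term_sets[term]
        if not pool:
            raise ValueError(f"term {term} has an empty gene set (pool size must be positive)")
        n = len(deg_genes & pool)
        out.append(
            TermStats(
                term=term,
                condition=condition,
                n_deg=n,
                pool_size=len(pool),
                percentage=round_half_up(100.0 * n / len(pool), 2),
            )
        )
    return out


def disorder_totals(
    deg_genes: set[str],
    pool: DisorderPool,
    n_total_degs: int,
    condition: Condition,
) -> DisorderTotals:
    """Deduplicated pool totals; a gene in two of the pool's terms counts once."""
    if n_total_degs <= 0:
        raise ValueError("n_total_degs must be positive")
    n_unique = len(deg_genes & pool.union)
    if n_total_degs < n_unique:
        raise ValueError(
            f"n_total_degs={n_total_degs} is smaller than the pool's own DEG count {n_unique}"
        )
    share = 100.0 * n_unique / n_total_degs
    return DisorderTotals(
        disorder=pool.disorder,
        condition=condition,
        n_deg_unique=n_unique,
        pool_size=len(pool.union),
        percentage=round_half_up(100.0 * n_unique / len(pool.union), 2),
        share_of_all_degs=round_half_up(share, 1),
        share_of_all_degs_int=int(round_half_up(share, 0)),
    )


class RankResult(NamedTuple):
    order: list[str]  # disorders, best first
    winner: str


def rank_disorders(
    totals: Sequence[DisorderTotals], by: Literal["number", "percentage"]
) -> RankResult:
    """Rank disorders for one condition, descending by the chosen key.

    Ties break on the other key (descending), then alphabetically.
    """
    if by not in ("number", "percentage"):
        raise ValueError(f"unknown ranking key {by!r}")
    names = [t.disorder for t in totals]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate disorder entries: {sorted(names)}")

    def key(t: DisorderTotals):
        number, pct = t.n_deg_unique, t.percentage
        primary, secondary = (number, pct) if by == "number" else (pct, number)
        return (-primary, -secondary, t.disorder)

    ordered = [t.disorder for t in sorted(totals, key=key)]
    return RankResult(order=ordered, winner=ordered[0])


def tidy_term_stats(stats: Iterable[TermStats]) -> pd.DataFrame:
    """Long-format table: one row per (term, condition)."""
    rows = [
        {
            "term": s.term,
            "region": s.condition[0],
            "age_months": s.condition[1],
            "n_deg": s.n_deg,
            "pool_size": s.pool_size,
            "percentage": s.percentage,
        }
        for s in stats
    ]
    return pd.DataFrame(
        rows, columns=["term", "region", "age_months", "n_deg", "pool_size", "percentage"]
    )


def stats_grid(
    per_term: Mapping[str, Iterable[TermStats]],
    totals: Mapping[str, Iterable[DisorderTotals]],
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Wide display grid: disorder/term rows x condition columns of ``pct (n/size)`` cells.

    ``per_term`` and ``totals`` map disorder -> stats across all conditions.
    """
    term_names = term_names or {}
    rows: dict[tuple[str, str], dict[str, str]] = {}
    for disorder, stats in per_term.items():
        for s in stats:
            col = f"{s.condition[0]}_{s.condition[1]}m"
            label = term_names.get(s.term, s.term)
            rows.setdefault((disorder, label), {})[col] = s.cell
    for disorder, ts in totals.items():
        for t in ts:
            col = f"{t.condition[0]}_{t.condition[1]}m"
            rows.setdefault((disorder, "TOTAL"), {})[col] = t.cell
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index = pd.MultiIndex.from_tuples(df.index, names=["disorder", "term"])
    return df[sorted(df.columns)]
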