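"""Cross-age intersection of DEG sets: common genes, contra-regulation, region specificity.

A pool gene significant at both ages in one region is a "common gene".
Commonality ignores direction: a common gene whose fold change is above 1 at
one age and below 1 at the other is contra-regulated, while consistent-up /
consistent-down genes move the same way at both ages.  A common gene is
region-specific when it attains both-age significance in exactly one of the
two regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .annotation import DisorderPool
from .deg import DEGRecord


class VennPartition(NamedTuple):
    only_7m: set[str]
    only_18m: set[str]
    common: set[str]


def venn_partition(set_7m: set[str], set_18m: set[str]) -> VennPartition:
    """Disjoint split of two gene sets into exclusive and shared parts."""
    return VennPartition(
        only_7m=set_7m - set_18m,
        only_18m=set_18m - set_7m,
        common=set_7m & set_18m,
    )


def classify_direction(fc_7m: float, fc_18m: float) -> str:
    """Direction class from the two ages' fold changes.

    ``consistent_up`` when both exceed 1, ``consistent_down`` when both are
    below 1, ``contra`` when the signs of (FC - 1) differ, and ``flat`` when
    either equals 1 exactly (unreachable for genes passing the FC criterion,
    defined for totality).
    """
    if fc_7m <= 0 or fc_18m <= 0:
        raise ValueError(f"fold changes must be positive, got ({fc_7m}, {fc_18m})")
    if fc_7m == 1.0 or fc_18m == 1.0:
        return "flat"
    if fc_7m > 1 and fc_18m > 1:
        return "consistent_up"
    if fc_7m < 1 and fc_18m < 1:
        return "consistent_down"
    return "contra"


@dataclass
class CrossAgeResult:
    """Cross-age outcome for one pool gene in one region and disorder."""

    gene: str
    region: str
    disorder: str
    significant_7m: bool
    significant_18m: bool
    fc_7m: float
    fc_18m: float
    venn_class: str  # only_7m | only_18m | common
    direction_class: str | None  # defined only when venn_class == "common"
    region_specific: bool | None = None  # set by region_specificity()


def find_common_genes(
    deg_records_7m: Sequence[DEGRecord],
    deg_records_18m: Sequence[DEGRecord],
    pool: DisorderPool,
    region: str,
) -> list[CrossAgeResult]:
    """Cross-age results for every pool gene significant at >= 1 age.

    Inputs are gene-level records for the same region at 7 and 18 months;
    results are restricted to ``pool.union`` and sorted by gene symbol.
    """
    if not pool.union:
        raise ValueError(f"disorder pool {pool.disorder} is empty")
    for rec in (*deg_records_7m, *deg_records_18m):
        if rec.condition[0] != region:
            raise ValueError(
                f"record for {rec.gene} has region {rec.condition[0]!r}, expected {region!r}"
            )
    by_gene_7 = {r.gene: r for r in deg_records_7m if r.gene in pool.union}
    by_gene_18 = {r.gene: r for r in deg_records_18m if r.gene in pool.union}
    sig7 = {g for g, r in by_gene_7.items() if r.significant}
    sig18 = {g for g, r in by_gene_18.items() if r.significant}
    part = venn_partition(sig7, sig18)

    results = []
    for gene in sorted(sig7 | sig18):
        r7, r18 = by_gene_7.get(gene), by_gene_18.get(gene)
        fc7 = r7.fold_change if r7 is not None else math.nan
        fc18 = r18.fold_change if r18 is not None else math.nan
        if gene in part.common:
            venn_class = "common"
            direction = classify_direction(fc7, fc18)
        else:
            venn_class = "only_7m" if gene in part.only_7m else "only_18m"
            direction = None
        results.append(
            CrossAgeResult(
                gene=gene,
                region=region,
                disorder=pool.disorder,
                significant_7m=gene in sig7,
                significant_18m=gene in sig18,
                fc_7m=fc7,
                fc_18m=fc18,
                venn_class=venn_class,
                direction_class=direction,
            )
        )
    return results


def region_specificity(
    results_cortex: Iterable[CrossAgeResult],
    results_hippocampus: Iterable[CrossAgeResult],
) -> dict[str, bool]:
    """Flag common genes found in exactly one region.

    Returns gene -> region_specific for every gene common in at least one
    region, and sets the ``region_specific`` field on the input results.
    """
    results_cortex = list(results_cortex)
    results_hippocampus = list(results_hippocampus)
    common_cortex = {r.gene for r in results_cortex if r.venn_class == "common"}
    common_hipp = {r.gene for r in results_hippocampus if r.venn_class == "common"}
    flags = {
        gene: (gene in common_cortex) != (gene in common_hipp)
        for gene in common_cortex | common_hipp
    }
    for r in (*results_cortex, *results_hippocampus):
        if r.venn_class == "common":
            r.region_specific = flags[r.gene]
    return flags


def venn_direction_counts(results: Iterable[CrossAgeResult]) -> pd.DataFrame:
    """Tidy count table: (region, disorder, venn_class, direction) -> n genes.

    Exclusive (single-age) genes are classed up/down by their fold change at
    the age they were significant; common genes use their direction class
    (up / down / contra).  Within each Venn region the direction counts sum
    to that region's gene count.
    """
    counts: dict[tuple[str, str, str, str], int] = {}
    for r in results:
        if r.venn_class == "common":
            direction = {
                "consistent_up": "up",
                "consistent_down": "down",
                "contra": "contra",
                "flat": "flat",
            }[r.direction_class]
        elif r.venn_class == "only_7m":
            direction = "up" if r.fc_7m > 1 else "down"
        else:
            direction = "up" if r.fc_18m > 1 else "down"
        key = (r.region, r.disorder, r.venn_class, direction)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "region": k[0],
            "disorder": k[1],
            "venn_class": k[2],
            "direction": k[3],
            "n_genes": v,
        }
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["region", "disorder", "venn_class", "direction", "n_genes"]
    )


def cross_age_grid(
    results_by_region: dict[str, Sequence[CrossAgeResult]],
    fc_tables: dict[tuple[str, int], pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Fold-change display grid for common genes across all four conditions.

    One row per (disorder, gene) common in some region; columns are the four
    (region, age) cells, each formatted ``FC`` with a ``*`` marker when the
    gene was significant in that cell.  ``fc_tables`` optionally supplies
    gene-level tables per condition so that cells from the non-common region
    can display their fold change too.
    """
    fc_lookup: dict[tuple[str, int, str], tuple[float, bool]] = {}
    if fc_tables:
        for (region, age), table in fc_tables.items():
            for row in table.itertuples():
                fc_lookup[(region, age, row.gene)] = (row.fold_change, bool(row.significant))
    for region, results in results_by_region.items():
        for r in results:
            fc_lookup.setdefault((region, 7, r.gene), (r.fc_7m, r.significant_7m))
            fc_lookup.setdefault((region, 18, r.gene), (r.fc_18m, r.significant_18m))

    common = {
        (r.disorder, r.gene)
        for results in results_by_region.values()
        for r in results
        if r.venn_class == "common"
    }
    rows = {}
    for disorder, gene in sorted(common):
        cells = {}
        for region in ("cortex", "hippocampus"):
            for age in (7, 18):
                entry = fc_lookup.get((region, age, gene))
                if entry is None:
                    cells[f"{region}_{age}m"] = ""
                else:
                    fc, sig = entry
                    cells[f"{region}_{age}m"] = f"{fc:.3f}{'*' if sig else ''}"
        rows[(disorder, gene)] = cells
    df = pd.DataFrame.from_dict(rows, orient="index")
    if not df.empty:
        df.index = pd.MultiIndex.from_tuples(df.index, names=["disorder", "gene"])
        df = df[sorted(df.columns)]
    return df
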