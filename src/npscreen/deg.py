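"""Two-group differential expression at probe level and probe->gene collapse.

A gene is differentially expressed (DEG) in one (region, age) condition when
some probe of it passes the joint criterion: two-sided p-value below alpha
*and* symmetric linear fold change above the threshold, i.e.
``max(FC, 1/FC) > fc_threshold`` with FC the KO/WT ratio of group mean
intensities.  Both inequalities are strict, and sub-unity fold changes
(down-regulation) are eligible symmetrically.

The per-probe test defaults to Welch's unequal-variance t-test on log2
intensities; a pooled-variance Student option is available for sensitivity
analysis.  Bonferroni and Benjamini-Hochberg adjusted p-values are reported
alongside the raw p-values used by the primary criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

Condition = tuple[str, int]  # (region, age_months)

PROBE_TABLE_COLUMNS = ["probe", "p_value", "fold_change", "direction", "significant"]
GENE_TABLE_COLUMNS = [
    "gene",
    "probe",
    "p_value",
    "fold_change",
    "direction",
    "significant",
]


@dataclass(frozen=True)
class DEGCriteria:
    """Significance criterion: p < alpha and symmetric fold change > threshold."""

    alpha: float = 0.05
    fc_threshold: float = 1.3
    correction: Literal["none", "bonferroni", "bh"] = "none"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_threshold <= 1:
            raise ValueError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if self.correction not in ("none", "bonferroni", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class DEGRecord:
    """Gene-level differential-expression result for one condition."""

    gene: str
    condition: Condition
    p_value: float
    fold_change: float
    significant: bool
    representative_probe: str

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1 else "down"


def fold_change(ko_values: Sequence[float], wt_values: Sequence[float]) -> float:
    """KO/WT ratio of group mean intensities on the linear scale."""
    ko = np.asarray(ko_values, dtype=float)
    wt = np.asarray(wt_values, dtype=float)
    if ko.size == 0 or wt.size == 0:
        raise ValueError("fold_change requires non-empty groups")
    if (ko <= 0).any() or (wt <= 0).any():
        raise ValueError("fold_change requires strictly positive intensities")
    return float(ko.mean() / wt.mean())


def probe_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> float:
    """Two-sided two-sample t-test p-value on log2-scale values.

    Welch's unequal-variance form by default; ``equal_var=True`` switches to
    Student's pooled-variance test.  When both groups have zero variance the
    p-value is 1.0 for equal means and 0.0 otherwise, by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("probe_test requires >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p)


def passes_criteria(p_value: float, fc: float, criteria: DEGCriteria) -> bool:
    """The joint DEG criterion with strict inequalities, symmetric in FC."""
    return p_value < criteria.alpha and max(fc, 1.0 / fc) > criteria.fc_threshold


def call_degs(
    matrix: ExpressionMatrix,
    condition: Condition,
    criteria: DEGCriteria = DEGCriteria(),
    test: Literal["welch", "student"] = "welch",
) -> pd.DataFrame:
    """Probe-level DEG table for one (region, age) condition.

    Returns one row per probe with columns ``probe``, ``p_value``,
    ``fold_change`` (KO/WT linear), ``direction`` and ``significant``.
    The test runs on log2-transformed intensities; the fold change is the
    ratio of linear group means.
    """
    region, age = condition
    wt_label, ko_label = "WT", "KO"
    genotypes = sorted(matrix.samples["genotype"].unique())
    if set(genotypes) != {wt_label, ko_label}:
        # Generic two-genotype design: first label alphabetically is control.
        wt_label, ko_label = genotypes[0], genotypes[-1]
    ko_cols = matrix.arrays_for(ko_label, region, age)
    wt_cols = matrix.arrays_for(wt_label, region, age)
    if len(ko_cols) < 2 or len(wt_cols) < 2:
        raise ValueError(
            f"condition (region={region!r}, age={age}) needs >= 2 arrays per genotype; "
            f"found {len(ko_cols)} KO and {len(wt_cols)} WT"
        )
    ko = matrix.values[ko_cols].to_numpy(dtype=float)
    wt = matrix.values[wt_cols].to_numpy(dtype=float)
    if (ko <= 0).any() or (wt <= 0).any():
        raise ValueError("expression intensities must be strictly positive")

    fc = ko.mean(axis=1) / wt.mean(axis=1)
    res = stats.ttest_ind(
        np.log2(ko), np.log2(wt), axis=1, equal_var=(test == "student")
    )
    p = np.asarray(res.pvalue, dtype=float)
    # Zero variance in both groups: p=1 when the means agree, else p=0.
    nan = np.isnan(p)
    if nan.any():
        equal_means = np.isclose(np.log2(ko).mean(axis=1), np.log2(wt).mean(axis=1))
        p[nan & equal_means] = 1.0
        p[nan & ~equal_means] = 0.0

    sym_fc = np.maximum(fc, 1.0 / fc)
    significant = (p < criteria.alpha) & (sym_fc > criteria.fc_threshold)
    out = pd.DataFrame(
        {
            "probe": matrix.probes,
            "p_value": p,
            "fold_change": fc,
            "direction": np.where(fc > 1, "up", "down"),
            "significant": significant,
        }
    )
    out.attrs["condition"] = condition
    return out


def collapse_probes(
    probe_records: pd.DataFrame, probe_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probe-level DEG table to gene level.

    A gene is significant iff at least one of its probes is; its reported
    p-value and fold change come from the representative probe — the
    minimum-p probe, ties broken by the lexicographically smallest probe id.
    This any-probe rule is deliberately liberal; see the methods note.
    """
    unmapped = [p for p in probe_records["probe"] if p not in probe_map]
    if unmapped:
        raise ValueError(f"probes missing from probe map: {sorted(unmapped)[:10]}")
    df = probe_records.copy()
    df["gene"] = [probe_map[p] for p in df["probe"]]
    df = df.sort_values(["gene", "p_value", "probe"], kind="mergesort")
    rep = df.groupby("gene", sort=True).first().reset_index()
    any_sig = df.groupby("gene", sort=True)["significant"].any().reset_index()
    out = rep.drop(columns=["significant"]).merge(any_sig, on="gene")
    out["direction"] = np.where(out["fold_change"] > 1, "up", "down")
    extras = [c for c in ("p_bonferroni", "p_bh") if c in out.columns]
    out = out[GENE_TABLE_COLUMNS + extras]
    out.attrs["condition"] = probe_records.attrs.get("condition")
    return out


def adjust_pvalues(
    p_values: Sequence[float], method: Literal["bonferroni", "bh"]
) -> np.ndarray:
    """Bonferroni (``min(1, m*p)``) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=sm_method)[1]


def attach_adjusted(probe_records: pd.DataFrame) -> pd.DataFrame:
    """Add ``p_bonferroni`` and ``p_bh`` columns across the table's probes.

    The correction family is the set of probes in the given table — in the
    screening pipeline, the GO-filtered pool probes of one condition.
    """
    out = probe_records.copy()
    out["p_bonferroni"] = adjust_pvalues(out["p_value"], "bonferroni")
    out["p_bh"] = adjust_pvalues(out["p_value"], "bh")
    return out


def records_from_frame(gene_table: pd.DataFrame, condition: Condition) -> list[DEGRecord]:
    """Convert a gene-level table from :func:`collapse_probes` to records."""
    return [
        DEGRecord(
            gene=row.gene,
            condition=condition,
            p_value=float(row.p_value),
            fold_change=float(row.fold_change),
            significant=bool(row.significant),
            representative_probe=row.probe,
        )
        for row in gene_table.itertuples()
    ]
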