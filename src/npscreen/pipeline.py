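"""End-to-end orchestration: inputs -> pools -> DEG -> statistics -> cross-age reports.

One configuration drives the whole screen.  Inputs come either from a named
synthetic preset or from user-supplied files (expression TSV, sample sheet,
probe map, GAF, OBO, disorder config); every stage writes a plain-TSV report
and a JSON manifest records the row counts flowing between stages (the
machine-readable analogue of the screen's workflow diagram).  Identical
configuration and seed yield byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, NamedTuple

import pandas as pd

from . import __version__
from .annotation import (
    OntologyGraph,
    build_disorder_pool,
    build_term_gene_sets,
    filter_annotations,
    load_disorder_presets,
    parse_gaf,
    pool_report,
)
from .cross_age import (
    cross_age_grid,
    find_common_genes,
    region_specificity,
    venn_direction_counts,
)
from .deg import (
    DEGCriteria,
    attach_adjusted,
    call_degs,
    collapse_probes,
    records_from_frame,
)
from .io import FLOAT_FORMAT, ExpressionMatrix, read_probe_map
from .simulate import PRESETS, generate_scenario
from .stats import count_degs_per_term, disorder_totals, rank_disorders, stats_grid, tidy_term_stats

logger = logging.getLogger(__name__)

#: Fixed condition iteration order for stable outputs.
CONDITIONS: tuple[tuple[str, int], ...] = (
    ("cortex", 7),
    ("cortex", 18),
    ("hippocampus", 7),
    ("hippocampus", 18),
)

_INPUT_KEYS = ("expression", "samples", "probe_map", "gaf", "obo")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (preset or paths), criteria, seed, output."""

    out_dir: Path
    preset: str | None = None
    expression: Path | None = None
    samples: Path | None = None
    probe_map: Path | None = None
    gaf: Path | None = None
    obo: Path | None = None
    disorders: str | Path = "paper"  # packaged preset, or a YAML path
    criteria: DEGCriteria = field(default_factory=DEGCriteria)
    test: str = "welch"
    seed: int = 0
    overwrite: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        paths = [self.expression, self.samples, self.probe_map, self.gaf, self.obo]
        if self.preset is not None:
            if any(p is not None for p in paths):
                raise ValueError("give either a preset or input paths, not both")
            if self.preset not in PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}")
        else:
            missing = [k for k, p in zip(_INPUT_KEYS, paths) if p is None]
            if missing:
                raise ValueError(f"missing input paths (and no preset): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        crit = doc.pop("criteria", {})
        if isinstance(crit, dict):
            crit = DEGCriteria(**crit)
        for key in _INPUT_KEYS:
            if doc.get(key) is not None:
                doc[key] = Path(doc[key])
        return cls(criteria=crit, **doc)


@dataclass
class RunManifest:
    """Machine-readable account of one run: config echo and per-stage counts."""

    version: str
    seed: int
    config: dict[str, Any]
    counts: dict[str, Any]
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


class ValidationCheck(NamedTuple):
    name: str
    passed: bool
    detail: str


def validate_inputs(
    expression: Path,
    samples: Path,
    probe_map: Path,
    gaf: Path,
    obo: Path,
) -> list[ValidationCheck]:
    """Pre-flight checks on user inputs; reports problems, never mutates.

    Checks sample-sheet completeness (every array has genotype, region and
    age), probe-map coverage of the matrix rows, and GAF/OBO parseability.
    """
    checks: list[ValidationCheck] = []

    matrix = None
    try:
        matrix = ExpressionMatrix.read(expression, samples)
        checks.append(ValidationCheck("expression_parses", True, f"{len(matrix.values)} probes"))
    except Exception as exc:
        checks.append(ValidationCheck("expression_parses", False, str(exc)))

    if matrix is not None:
        incomplete = matrix.samples[
            matrix.samples[["genotype", "region", "age_months"]].isna().any(axis=1)
        ]
        checks.append(
            ValidationCheck(
                "sample_sheet_complete",
                incomplete.empty,
                "ok" if incomplete.empty else f"arrays with missing fields: {list(incomplete.index)}",
            )
        )
        try:
            pmap = read_probe_map(probe_map)
            unmapped = [p for p in matrix.probes if p not in pmap]
            checks.append(
                ValidationCheck(
                    "probe_map_covers_matrix",
                    not unmapped,
                    "ok" if not unmapped else f"unmapped probes: {unmapped[:10]}",
                )
            )
        except Exception as exc:
            checks.append(ValidationCheck("probe_map_covers_matrix", False, str(exc)))

    try:
        records = parse_gaf(Path(gaf))
        checks.append(ValidationCheck("gaf_parses", True, f"{len(records)} records"))
    except Exception as exc:
        checks.append(ValidationCheck("gaf_parses", False, str(exc)))

    try:
        graph = OntologyGraph.from_obo(Path(obo).read_text())
        checks.append(ValidationCheck("obo_parses", True, f"{len(graph.terms)} terms"))
    except Exception as exc:
        checks.append(ValidationCheck("obo_parses", False, str(exc)))

    return checks


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full screen and write all reports under ``config.out_dir``.

    Stages: input acquisition (simulate or load), annotation pools, per
    condition DEG calling, disorder statistics, cross-age classification.
    Any stage failure aborts with a stage-named :class:`PipelineError` and
    removes partial outputs.
    """
    out_dir = config.out_dir
    if out_dir.exists() and any(out_dir.iterdir()) and not config.overwrite:
        raise PipelineError(f"output directory {out_dir} is not empty; pass overwrite")
    tmp = out_dir.parent / (out_dir.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)

    started = datetime.now(timezone.utc).isoformat()
    counts: dict[str, Any] = {}
    try:
        stage = "inputs"
        if config.preset is not None:
            scenario = generate_scenario(config.preset, config.seed)
            scenario.write(tmp / "inputs")
            matrix = scenario.expression
            probe_map = scenario.probe_map
            gaf_source: Any = scenario.gaf_text
            obo_source: Any = scenario.obo_text
            configs = scenario.disorder_configs
            counts["planted_degs_in_truth"] = int(len(scenario.deg_truth))
        else:
            matrix = ExpressionMatrix.read(config.expression, config.samples)
            probe_map = read_probe_map(config.probe_map)
            gaf_source = Path(config.gaf)
            obo_source = Path(config.obo).read_text()
            configs = (
                load_disorder_presets()
                if config.disorders == "paper"
                else load_disorder_presets(config.disorders)
            )
        counts["probes_initial"] = int(len(matrix.values))
        counts["arrays"] = int(len(matrix.samples))

        stage = "pools"
        records = parse_gaf(gaf_source)
        filtered = filter_annotations(records)
        graph = OntologyGraph.from_obo(obo_source)
        term_ids = sorted({t for c in configs for t in c.term_ids})
        term_sets = build_term_gene_sets(filtered, graph, term_ids)
        pools = {c.disorder: build_disorder_pool(term_sets, c) for c in configs}
        report = pool_report(list(pools.values()), configs)
        _write_tsv(report, tmp / "pool_report.tsv")
        counts["annotation_records"] = len(records)
        counts["annotation_records_filtered"] = len(filtered)
        counts["term_slots"] = report.attrs["term_slots"]
        counts["distinct_terms"] = report.attrs["distinct_terms"]
        counts["pool_sizes"] = {d: len(p.union) for d, p in pools.items()}

        stage = "go_filter"
        union_all = set().union(*(p.union for p in pools.values()))
        pool_probes = {p for p, g in probe_map.items() if g in union_all}
        matrix_pool_probes = [p for p in matrix.probes if p in pool_probes]
        counts["probes_after_go_filter"] = len(matrix_pool_probes)
        counts["genes_after_go_filter"] = len(
            {probe_map[p] for p in matrix_pool_probes}
        )

        stage = "deg"
        names = {tid: name for c in configs for tid, name in c.terms}
        gene_tables: dict[tuple[str, int], pd.DataFrame] = {}
        n_total_degs: dict[tuple[str, int], int] = {}
        counts["conditions"] = {}
        for cond in CONDITIONS:
            region, age = cond
            probe_full = call_degs(matrix, cond, config.criteria, test=config.test)
            gene_full = collapse_probes(probe_full, probe_map)
            total = int(gene_full["significant"].sum())
            n_total_degs[cond] = total
            probe_pool = probe_full[probe_full["probe"].isin(pool_probes)].reset_index(drop=True)
            probe_pool = attach_adjusted(probe_pool)
            probe_pool.attrs["condition"] = cond
            gene_pool = collapse_probes(probe_pool, probe_map)
            gene_tables[cond] = gene_pool
            _write_tsv(gene_pool, tmp / f"deg_{region}_{age}m.tsv")
            counts["conditions"][f"{region}_{age}m"] = {
                "n_total_degs": total,
                "n_pool_degs": int(gene_pool["significant"].sum()),
            }

        stage = "stats"
        per_term: dict[str, list] = {c.disorder: [] for c in configs}
        totals: dict[str, list] = {c.disorder: [] for c in configs}
        ranking_rows = []
        for cond in CONDITIONS:
            gene_pool = gene_tables[cond]
            deg_genes = set(gene_pool.loc[gene_pool["significant"], "gene"])
            cond_totals = []
            for c in configs:
                pool = pools[c.disorder]
                sets_for_config = {t: pool.term_sets[t] for t in c.term_ids}
                per_term[c.disorder].extend(
                    count_degs_per_term(deg_genes, sets_for_config, cond)
                )
                tot = disorder_totals(
                    deg_genes, pool, max(n_total_degs[cond], 1), cond
                )
                totals[c.disorder].append(tot)
                cond_totals.append(tot)
            for by in ("number", "percentage"):
                rank = rank_disorders(cond_totals, by=by)
                ranking_rows.append(
                    {
                        "region": cond[0],
                        "age_months": cond[1],
                        "by": by,
                        "order": ",".join(rank.order),
                        "winner": rank.winner,
                    }
                )
        tidy = tidy_term_stats(s for stats in per_term.values() for s in stats)
        _write_tsv(tidy, tmp / "term_stats.tsv")
        grid = stats_grid(per_term, totals, names)
        _write_tsv(grid, tmp / "stats_grid.tsv", index=True)
        totals_rows = [
            {
                "disorder": t.disorder,
                "region": t.condition[0],
                "age_months": t.condition[1],
                "n_deg_unique": t.n_deg_unique,
                "pool_size": t.pool_size,
                "percentage": t.percentage,
                "share_of_all_degs": t.share_of_all_degs,
                "share_of_all_degs_int": t.share_of_all_degs_int,
            }
            for ts in totals.values()
            for t in ts
        ]
        _write_tsv(pd.DataFrame(totals_rows), tmp / "disorder_totals.tsv")
        _write_tsv(pd.DataFrame(ranking_rows), tmp / "rankings.tsv")

        stage = "crossage"
        all_results = []
        results_by_region_disorder: dict[str, dict[str, list]] = {}
        for disorder, pool in pools.items():
            per_region = {}
            for region in ("cortex", "hippocampus"):
                recs7 = records_from_frame(gene_tables[(region, 7)], (region, 7))
                recs18 = records_from_frame(gene_tables[(region, 18)], (region, 18))
                per_region[region] = find_common_genes(recs7, recs18, pool, region)
            region_specificity(per_region["cortex"], per_region["hippocampus"])
            results_by_region_disorder[disorder] = per_region
            for results in per_region.values():
                all_results.extend(results)
        tidy_rows = [
            {
                "gene": r.gene,
                "region": r.region,
                "disorder": r.disorder,
                "significant_7m": r.significant_7m,
                "significant_18m": r.significant_18m,
                "fc_7m": r.fc_7m,
                "fc_18m": r.fc_18m,
                "venn_class": r.venn_class,
                "direction_class": r.direction_class or "",
                "region_specific": "" if r.region_specific is None else r.region_specific,
            }
            for r in sorted(all_results, key=lambda r: (r.disorder, r.region, r.gene))
        ]
        _write_tsv(pd.DataFrame(tidy_rows), tmp / "cross_age.tsv")
        _write_tsv(venn_direction_counts(all_results), tmp / "venn_counts.tsv")
        grids = []
        for disorder, per_region in results_by_region_disorder.items():
            g = cross_age_grid(per_region, gene_tables)
            if not g.empty:
                grids.append(g)
        grid_df = pd.concat(grids) if grids else pd.DataFrame()
        _write_tsv(grid_df, tmp / "cross_age_grid.tsv", index=True)
        counts["common_genes"] = {
            d: {
                region: sorted(
                    r.gene for r in per_region[region] if r.venn_class == "common"
                )
                for region in per_region
            }
            for d, per_region in results_by_region_disorder.items()
        }

        stage = "manifest"
        manifest = RunManifest(
            version=__version__,
            seed=config.seed,
            config=_config_echo(config),
            counts=counts,
            started=started,
            finished=datetime.now(timezone.utc).isoformat(),
        )
        (tmp / "manifest.json").write_text(manifest.to_json())
    except Exception as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if out_dir.exists():
        shutil.rmtree(out_dir)
    tmp.rename(out_dir)
    logger.info("pipeline run complete: %s", out_dir)
    return manifest


def _config_echo(config: PipelineConfig) -> dict[str, Any]:
    echo = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, Path):
            value = str(value)
        elif isinstance(value, DEGCriteria):
            value = dataclasses.asdict(value)
        echo[f.name] = value
    return echo
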