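"""Synthetic microarray and GO-annotation fixtures with known ground truth.

The generators emulate the study design the screening pipeline targets: an
Affymetrix-style probe matrix (several probes per gene) over a 2 genotypes x
2 brain regions x 2 ages layout with a configurable number of arrays per
group, plus GAF/OBO annotation fixtures whose per-term gene-set sizes and
overlap counts are configurable exactly.  Intensities follow a log-normal
model: Gaussian noise and planted genotype effects on the log2 scale,
exponentiated to linear intensities.

Every generator is deterministic given its seed; scenario presets bundle
expression, probe map, annotations, disorder configuration and ground-truth
tables so downstream stages can be tested against planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from ._seeds import derive_seed
from .annotation import DisorderConfig, load_disorder_presets
from .io import ExpressionMatrix, write_probe_map

PRESETS = ("null", "paper_like", "contra_demo")


@dataclass(frozen=True)
class SimulationDesign:
    """Factorial array layout and intensity model of one simulated experiment.

    The default two arrays per group mirrors the pooled design of the study
    the pipeline reimplements (two pooled samples per group); recovery and
    calibration scenarios raise ``arrays_per_group`` because a two-versus-two
    test has very little power.
    """

    n_genes: int = 1200
    genotypes: tuple[str, str] = ("WT", "KO")
    regions: tuple[str, ...] = ("cortex", "hippocampus")
    ages: tuple[int, ...] = (7, 18)
    arrays_per_group: int = 2
    probes_per_gene: tuple[int, int] = (1, 4)
    baseline_log2_mean: float = 8.0
    noise_sd_log2: float = 0.15
    seed: int = 0
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.arrays_per_group < 2:
            raise ValueError("arrays_per_group must be >= 2 (two-group test needs >= 2 values)")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be non-negative")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid probes_per_gene range: ({lo}, {hi})")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValueError(
                f"gene_names has {len(self.gene_names)} entries but n_genes={self.n_genes}"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        if self.gene_names is not None:
            return self.gene_names
        return tuple(f"G{i:05d}" for i in range(self.n_genes))

    @property
    def n_arrays(self) -> int:
        return (
            len(self.genotypes) * len(self.regions) * len(self.ages) * self.arrays_per_group
        )


@dataclass(frozen=True)
class PlantedEffect:
    """A genotype effect planted for one gene in one (region, age) condition.

    ``log2_effect`` is KO minus WT on the log2 scale; a gene may carry
    opposite-signed effects at the two ages to emulate contra-regulation.
    """

    gene: str
    region: str
    age: int
    log2_effect: float


def generate_probe_map(
    genes: Sequence[str], probes_per_gene: tuple[int, int], seed: int
) -> dict[str, str]:
    """Assign each gene 1+ uniquely-identified probes (uniform count draw).

    Probe ids are Affymetrix-style ``<number>_at`` strings, numbered in gene
    order, so the map is total over the emitted probe set and every gene has
    at least one probe.
    """
    lo, hi = probes_per_gene
    if lo < 1:
        raise ValueError(f"minimum probes per gene must be >= 1, got {lo}")
    if hi < lo:
        raise ValueError(f"invalid probes_per_gene range: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    counts = rng.integers(lo, hi + 1, size=len(genes))
    probe_map: dict[str, str] = {}
    probe_no = 100000
    for gene, count in zip(genes, counts):
        for _ in range(int(count)):
            probe_map[f"{probe_no}_at"] = gene
            probe_no += 1
    return probe_map


def _sample_sheet(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for genotype in design.genotypes:
        for region in design.regions:
            for age in design.ages:
                for r in range(1, design.arrays_per_group + 1):
                    rows.append(
                        {
                            "array_id": f"{genotype}_{region}_{age}m_{r}",
                            "genotype": genotype,
                            "region": region,
                            "age_months": age,
                        }
                    )
    return pd.DataFrame(rows).set_index("array_id")


def generate_expression(
    design: SimulationDesign,
    effects: Sequence[PlantedEffect] = (),
    probe_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Simulate linear-scale intensities for every probe and array.

    Each probe's log2 intensity is ``baseline + planted effect + N(0, sd)``,
    where the planted effect applies only to KO arrays of the effect's
    (region, age) condition and to every probe of the effect's gene.  The
    same design, effects and seed reproduce the matrix bit-for-bit.
    """
    genes = design.genes
    gene_set = set(genes)
    for e in effects:
        if e.gene not in gene_set:
            raise ValueError(f"planted effect references unknown gene: {e.gene!r}")
        if e.region not in design.regions:
            raise ValueError(f"planted effect references unknown region: {e.region!r}")
        if e.age not in design.ages:
            raise ValueError(f"planted effect references unknown age: {e.age!r}")

    if probe_map is None:
        probe_map = generate_probe_map(
            genes, design.probes_per_gene, derive_seed(design.seed, "probe_map")
        )
    probes = list(probe_map.keys())
    samples = _sample_sheet(design)

    # Effects summed per (gene, region, age) in case a gene carries several.
    effect_lookup: dict[tuple[str, str, int], float] = {}
    for e in effects:
        key = (e.gene, e.region, e.age)
        effect_lookup[key] = effect_lookup.get(key, 0.0) + e.log2_effect

    gene_of_probe = [probe_map[p] for p in probes]
    ko_label = design.genotypes[1]
    effect_matrix = np.zeros((len(probes), len(samples)), dtype=float)
    if effect_lookup:
        col_meta = list(samples.itertuples())
        gene_index: dict[str, list[int]] = {}
        for i, g in enumerate(gene_of_probe):
            gene_index.setdefault(g, []).append(i)
        for (gene, region, age), value in effect_lookup.items():
            rows = gene_index.get(gene, [])
            cols = [
                j
                for j, s in enumerate(col_meta)
                if s.genotype == ko_label and s.region == region and s.age_months == age
            ]
            for i in rows:
                effect_matrix[i, cols] += value

    rng = np.random.default_rng(derive_seed(design.seed, "expression"))
    noise = rng.normal(0.0, design.noise_sd_log2, size=effect_matrix.shape)
    log2_values = design.baseline_log2_mean + effect_matrix + noise
    values = pd.DataFrame(
        np.exp2(log2_values), index=pd.Index(probes, name="probe_id"), columns=samples.index
    )
    return ExpressionMatrix(values=values, samples=samples)


@dataclass(frozen=True)
class GoFixtureSpec:
    """Exact size/overlap specification for a generated annotation fixture.

    ``redundant_memberships`` is the number of gene-in-term memberships beyond
    each gene's first: the sum of per-term sizes minus the unique-union size
    that the realized fixture must achieve exactly.
    """

    term_sizes: dict[str, int]
    redundant_memberships: int = 0
    taxon: str = "10090"
    qualifier: str = "involved_in"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.term_sizes.values()):
            raise ValueError("term sizes must be positive")
        total = sum(self.term_sizes.values())
        biggest = max(self.term_sizes.values(), default=0)
        bound = total - biggest
        if not 0 <= self.redundant_memberships <= bound:
            raise ValueError(
                f"redundant_memberships={self.redundant_memberships} violates the bound "
                f"0 <= R <= sum(term_sizes) - max(term_sizes) = {bound}"
            )


def _default_namer(prefix: str = "NG") -> Callable[[], str]:
    counter = iter(range(1, 10**7))

    def namer() -> str:
        return f"{prefix}{next(counter):05d}"

    return namer


def realize_term_sets(
    term_sizes: Mapping[str, int],
    redundant_memberships: int,
    rng: np.random.Generator,
    namer: Callable[[], str] | None = None,
    fixed: Mapping[str, set[str]] | None = None,
    seeded_members: Mapping[str, Sequence[str]] | None = None,
    no_reuse: Iterable[str] = (),
) -> dict[str, set[str]]:
    """Construct gene sets with the requested sizes and exact total overlap.

    Terms are placed largest-first; each subsequent term reuses as many
    already-placed genes as the remaining redundancy budget allows and fills
    the rest with fresh symbols from ``namer``.  ``fixed`` passes pre-existing
    term sets that count toward the redundancy target (used when a term is
    shared with an earlier pool); ``seeded_members`` pre-places specific genes
    into specific terms, and genes in ``no_reuse`` are never drawn into a
    second term.
    """
    if namer is None:
        namer = _default_namer()
    fixed = dict(fixed or {})
    seeded_members = dict(seeded_members or {})
    no_reuse = set(no_reuse)

    sets: dict[str, set[str]] = {t: set(s) for t, s in fixed.items()}
    union: set[str] = set().union(*sets.values()) if sets else set()
    placed_redundancy = sum(len(s) for s in sets.values()) - len(union)
    remaining = redundant_memberships - placed_redundancy
    if remaining < 0:
        raise ValueError(
            f"fixed sets already carry {placed_redundancy} redundant memberships, "
            f"more than the requested {redundant_memberships}"
        )

    new_terms = sorted(
        (t for t in term_sizes if t not in fixed),
        key=lambda t: (-term_sizes[t], t),
    )
    for term in new_terms:
        size = term_sizes[term]
        members = set(seeded_members.get(term, ()))
        if len(members) > size:
            raise ValueError(f"term {term} seeded with more genes than its size {size}")
        available = sorted((union - members) - no_reuse)
        n_reuse = min(size - len(members), len(available), remaining)
        if n_reuse > 0:
            reused = rng.choice(available, size=n_reuse, replace=False)
            members.update(reused.tolist())
            remaining -= n_reuse
        while len(members) < size:
            members.add(namer())
        sets[term] = members
        union |= members
    if remaining != 0:
        raise ValueError(
            f"could not place {remaining} redundant membership(s); "
            "spec unsatisfiable with the given fixed/seeded sets"
        )
    realized = sum(len(s) for s in sets.values()) - len(union)
    assert realized == redundant_memberships
    return sets


def _allocate_child_ids(n: int, taken: set[str]) -> list[str]:
    ids = []
    counter = 9000001
    while len(ids) < n:
        cand = f"GO:{counter:07d}"
        if cand not in taken:
            ids.append(cand)
        counter += 1
    return ids


def build_child_ontology(
    roots: Sequence[str], depth: int, rng: np.random.Generator
) -> tuple[str, dict[str, list[str]]]:
    """OBO text for root terms plus an is_a chain of ``depth`` children each.

    Returns the OBO text and, per root, the list of child ids ordered from
    direct child to deepest descendant.
    """
    taken = set(roots)
    chains: dict[str, list[str]] = {}
    stanzas = []
    for root in roots:
        stanzas.append(f"[Term]\nid: {root}\nname: synthetic term {root}\n")
        chain = _allocate_child_ids(depth, taken)
        taken.update(chain)
        chains[root] = chain
        parent = root
        for child in chain:
            stanzas.append(
                f"[Term]\nid: {child}\nname: synthetic child of {root}\nis_a: {parent} ! parent\n"
            )
            parent = child
    header = "format-version: 1.2\nontology: npscreen-synthetic\n\n"
    return header + "\n".join(stanzas), chains


def render_gaf(
    term_sets: Mapping[str, set[str]],
    taxon: str,
    qualifier: str,
    chains: Mapping[str, list[str]] | None = None,
    child_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """GAF 2.2 text annotating each term's genes, optionally via child terms.

    With a non-empty chain for a term, a ``child_fraction`` share of its
    memberships is attached to a random descendant instead of the term
    itself, so parsing requires is_a expansion to recover the configured set.
    """
    from .annotation import AnnotationRecord, write_gaf

    chains = chains or {}
    if rng is None:
        rng = np.random.default_rng(0)
    records = []
    for term in sorted(term_sets):
        chain = chains.get(term, [])
        for gene in sorted(term_sets[term]):
            attach = term
            if chain and child_fraction > 0 and rng.random() < child_fraction:
                attach = chain[int(rng.integers(0, len(chain)))]
            records.append(
                AnnotationRecord(
                    gene=gene,
                    term=attach,
                    qualifiers=(qualifier,),
                    taxon=taxon,
                    evidence="IDA",
                )
            )
    return write_gaf(records)


def generate_annotations(
    spec: GoFixtureSpec, ontology_depth: int = 0, child_fraction: float = 0.5
) -> tuple[str, str]:
    """Generate a (GAF text, OBO text) pair realizing ``spec`` exactly.

    After taxon/qualifier filtering and is_a expansion, the GAF parses back
    to precisely the configured per-term gene sets; when ``ontology_depth`` is
    positive, a share of memberships is attached to generated child terms so
    that expansion is required to recover them.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "annotations"))
    term_sets = realize_term_sets(spec.term_sizes, spec.redundant_memberships, rng)
    obo_text, chains = build_child_ontology(sorted(spec.term_sizes), ontology_depth, rng)
    gaf_text = render_gaf(
        term_sets, spec.taxon, spec.qualifier, chains, child_fraction if ontology_depth else 0.0, rng
    )
    return gaf_text, obo_text


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A complete simulated study: inputs plus ground-truth tables."""

    preset: str
    seed: int
    design: SimulationDesign
    expression: ExpressionMatrix
    probe_map: dict[str, str]
    gaf_text: str
    obo_text: str
    disorder_configs: list[DisorderConfig]
    term_sets: dict[str, set[str]]
    effects: list[PlantedEffect]
    deg_truth: pd.DataFrame
    cross_age_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all fixture and truth files as plain TSV/GAF/OBO/YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "samples": outdir / "samples.tsv",
            "probe_map": outdir / "probe_map.tsv",
            "gaf": outdir / "annotations.gaf",
            "obo": outdir / "ontology.obo",
            "disorders": outdir / "disorders.yaml",
            "term_sets": outdir / "truth_term_sets.tsv",
            "deg_truth": outdir / "truth_planted_degs.tsv",
            "cross_age_truth": outdir / "truth_cross_age.tsv",
        }
        self.expression.write(paths["expression"], paths["samples"])
        write_probe_map(self.probe_map, paths["probe_map"])
        paths["gaf"].write_text(self.gaf_text)
        paths["obo"].write_text(self.obo_text)
        doc = {
            "disorders": {
                c.disorder: [{"id": tid, "name": name} for tid, name in c.terms]
                for c in self.disorder_configs
            }
        }
        paths["disorders"].write_text(yaml.safe_dump(doc, sort_keys=False))
        rows = [
            {"term": t, "gene": g} for t in sorted(self.term_sets) for g in sorted(self.term_sets[t])
        ]
        pd.DataFrame(rows, columns=["term", "gene"]).to_csv(
            paths["term_sets"], sep="\t", index=False
        )
        self.deg_truth.to_csv(paths["deg_truth"], sep="\t", index=False)
        self.cross_age_truth.to_csv(paths["cross_age_truth"], sep="\t", index=False)
        return paths


_DEG_TRUTH_COLUMNS = ["gene", "region", "age_months", "log2_effect", "direction", "disorders"]
_CROSS_AGE_TRUTH_COLUMNS = ["gene", "region", "disorder", "direction_class"]

#: Extra per-condition planted DEG counts for the ``paper_like`` preset,
#: on top of the named cross-age genes; chosen so SCZ leads by number in
#: every condition, counts rise sharply at 18 months, and the hippocampus
#: changes more than the cortex — the study's qualitative pattern at a
#: desk-testable scale.
_PAPER_LIKE_EXTRA: dict[tuple[str, int], dict[str, int]] = {
    ("cortex", 7): {"BIP": 1, "SCZ": 4, "MDD": 0},
    ("cortex", 18): {"BIP": 5, "SCZ": 9, "MDD": 5},
    ("hippocampus", 7): {"BIP": 3, "SCZ": 5, "MDD": 3},
    ("hippocampus", 18): {"BIP": 7, "SCZ": 11, "MDD": 9},
}

_BACKGROUND_DEGS_PER_CONDITION = 40


def _pool_namer(start: int = 1) -> Callable[[], str]:
    counter = iter(range(start, 10**7))

    def namer() -> str:
        return f"NG{next(counter):05d}"

    return namer


def build_disorder_fixture(
    rng: np.random.Generator, with_named_genes: bool
) -> tuple[dict[str, set[str]], list[DisorderConfig]]:
    """Realize the 13 disorder GO-term gene sets at their snapshot sizes.

    Within-disorder overlaps match the published redundant-membership counts
    exactly; the shared histone-methylation term contributes the same gene
    set to both BIP and SCZ.  With ``with_named_genes`` the cross-age genes
    (Arc, Hist1h1c, ...) are embedded in their home terms and kept exclusive
    to them.
    """
    configs = load_disorder_presets()
    by_name = {c.disorder: c for c in configs}
    sizes = reference.TERM_SIZES
    namer = _pool_namer()
    named_by_term: dict[str, list[str]] = {}
    if with_named_genes:
        for gene, term in reference.NAMED_GENE_TERMS.items():
            named_by_term.setdefault(term, []).append(gene)
    no_reuse = set(reference.NAMED_GENE_TERMS) if with_named_genes else set()

    methylation = "GO:0051568"
    bip_sizes = {t: sizes[t] for t in by_name["BIP"].term_ids}
    bip_sets = realize_term_sets(
        bip_sizes,
        reference.POOL_OVERLAPS["BIP"],
        rng,
        namer,
        seeded_members={t: g for t, g in named_by_term.items() if t in bip_sizes},
        no_reuse=no_reuse,
    )
    scz_sizes = {t: sizes[t] for t in by_name["SCZ"].term_ids}
    scz_sets = realize_term_sets(
        scz_sizes,
        reference.POOL_OVERLAPS["SCZ"],
        rng,
        namer,
        fixed={methylation: bip_sets[methylation]},
        seeded_members={t: g for t, g in named_by_term.items() if t in scz_sizes},
        no_reuse=no_reuse,
    )
    mdd_sizes = {t: sizes[t] for t in by_name["MDD"].term_ids}
    mdd_sets = realize_term_sets(
        mdd_sizes,
        reference.POOL_OVERLAPS["MDD"],
        rng,
        namer,
        seeded_members={t: g for t, g in named_by_term.items() if t in mdd_sizes},
        no_reuse=no_reuse,
    )
    term_sets = {**bip_sets, **scz_sets, **mdd_sets}
    return term_sets, configs


def _truth_frames(
    effects: Sequence[PlantedEffect],
    pools: Mapping[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    deg_rows = []
    for e in effects:
        disorders = sorted(d for d, genes in pools.items() if e.gene in genes)
        deg_rows.append(
            {
                "gene": e.gene,
                "region": e.region,
                "age_months": e.age,
                "log2_effect": e.log2_effect,
                "direction": "up" if e.log2_effect > 0 else "down",
                "disorders": ",".join(disorders),
            }
        )
    deg_truth = pd.DataFrame(deg_rows, columns=_DEG_TRUTH_COLUMNS)

    cross_rows = []
    by_gene_region: dict[tuple[str, str], dict[int, float]] = {}
    for e in effects:
        by_gene_region.setdefault((e.gene, e.region), {})[e.age] = e.log2_effect
    for (gene, region), ages in sorted(by_gene_region.items()):
        if len(ages) < 2:
            continue
        e7, e18 = ages[min(ages)], ages[max(ages)]
        if e7 > 0 and e18 > 0:
            klass = "consistent_up"
        elif e7 < 0 and e18 < 0:
            klass = "consistent_down"
        else:
            klass = "contra"
        for disorder in sorted(d for d, genes in pools.items() if gene in genes):
            cross_rows.append(
                {"gene": gene, "region": region, "disorder": disorder, "direction_class": klass}
            )
    cross_truth = pd.DataFrame(cross_rows, columns=_CROSS_AGE_TRUTH_COLUMNS)
    return deg_truth, cross_truth


def _named_gene_effects() -> list[PlantedEffect]:
    ages = (7, 18)
    effects: dict[tuple[str, str, int], PlantedEffect] = {}
    for entry in reference.CROSS_AGE_TABLE:
        for age, fc, sig in zip(ages, entry.fc, entry.significant):
            if sig:
                key = (entry.gene, entry.region, age)
                effects[key] = PlantedEffect(entry.gene, entry.region, age, math.log2(fc))
    return [effects[k] for k in sorted(effects)]


def generate_scenario(preset: str, seed: int, **overrides) -> Scenario:
    """Build a named scenario bundle with ground truth.

    Presets:

    * ``null`` — no planted effects; 4200 genes at 1-4 probes each (over
      10,000 probes) and 8 arrays per group, sized for type-I-error
      calibration of the downstream DEG caller.
    * ``paper_like`` — the full disorder fixture at snapshot pool sizes, the
      named cross-age genes planted with their published fold changes, and
      extra one-condition effects (|log2| = 1) so that SCZ leads the DEG
      count in all four conditions; background DEGs outside the pools give a
      non-trivial array-wide DEG total.
    * ``contra_demo`` — a minimal bundle with one gene planted +0.7/-0.7 log2
      at the two ages in the hippocampus, labelled contra-regulated in the
      ground truth.

    Keyword overrides (``arrays_per_group``, ``noise_sd_log2``, ...) are
    forwarded to the :class:`SimulationDesign`.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    if preset == "null":
        return _null_scenario(seed, **overrides)
    if preset == "paper_like":
        return _paper_like_scenario(seed, **overrides)
    return _contra_demo_scenario(seed, **overrides)


def _scenario_common(
    preset: str,
    seed: int,
    design: SimulationDesign,
    effects: list[PlantedEffect],
    term_sets: dict[str, set[str]],
    configs: list[DisorderConfig],
    ontology_depth: int,
    taxon: str = "10090",
    qualifier: str = "involved_in",
) -> Scenario:
    rng = np.random.default_rng(derive_seed(seed, preset, "gaf"))
    obo_text, chains = build_child_ontology(sorted(term_sets), ontology_depth, rng)
    gaf_text = render_gaf(
        term_sets, taxon, qualifier, chains, 0.3 if ontology_depth else 0.0, rng
    )
    expression = generate_expression(design, effects)
    probe_map = generate_probe_map(
        design.genes, design.probes_per_gene, derive_seed(design.seed, "probe_map")
    )
    pools = {
        c.disorder: set().union(*(term_sets[t] for t in c.term_ids)) for c in configs
    }
    deg_truth, cross_truth = _truth_frames(effects, pools)
    return Scenario(
        preset=preset,
        seed=seed,
        design=design,
        expression=expression,
        probe_map=probe_map,
        gaf_text=gaf_text,
        obo_text=obo_text,
        disorder_configs=configs,
        term_sets=term_sets,
        effects=effects,
        deg_truth=deg_truth,
        cross_age_truth=cross_truth,
    )


def _null_scenario(seed: int, **overrides) -> Scenario:
    rng = np.random.default_rng(derive_seed(seed, "null", "fixture"))
    term_sets, configs = build_disorder_fixture(rng, with_named_genes=False)
    pool_genes = sorted(set().union(*term_sets.values()))
    n_genes = overrides.pop("n_genes", 4200)
    extra = [f"G{i:05d}" for i in range(n_genes - len(pool_genes))]
    genes = tuple(pool_genes + extra)
    design = SimulationDesign(
        n_genes=len(genes),
        gene_names=genes,
        arrays_per_group=overrides.pop("arrays_per_group", 8),
        seed=derive_seed(seed, "null", "design"),
        **overrides,
    )
    return _scenario_common("null", seed, design, [], term_sets, configs, ontology_depth=1)


def _paper_like_scenario(seed: int, **overrides) -> Scenario:
    rng = np.random.default_rng(derive_seed(seed, "paper_like", "fixture"))
    term_sets, configs = build_disorder_fixture(rng, with_named_genes=True)
    pools = {
        c.disorder: set().union(*(term_sets[t] for t in c.term_ids)) for c in configs
    }
    all_pool = sorted(set().union(*pools.values()))

    n_genes = overrides.pop("n_genes", max(1600, len(all_pool) + 200))
    background = [f"BG{i:05d}" for i in range(n_genes - len(all_pool))]
    genes = tuple(all_pool + background)

    effects = _named_gene_effects()
    named = set(reference.NAMED_GENE_TERMS)
    exclusive = {
        "BIP": sorted(pools["BIP"] - pools["SCZ"] - pools["MDD"] - named),
        "SCZ": sorted(pools["SCZ"] - pools["BIP"] - pools["MDD"] - named),
        "MDD": sorted(pools["MDD"] - pools["BIP"] - pools["SCZ"] - named),
    }
    effect_rng = np.random.default_rng(derive_seed(seed, "paper_like", "effects"))
    cursor = {d: 0 for d in exclusive}
    shuffled = {d: list(effect_rng.permutation(g)) for d, g in exclusive.items()}
    for (region, age), per_disorder in _PAPER_LIKE_EXTRA.items():
        for disorder, count in per_disorder.items():
            for _ in range(count):
                gene = shuffled[disorder][cursor[disorder]]
                cursor[disorder] += 1
                sign = 1.0 if effect_rng.random() < 0.5 else -1.0
                effects.append(PlantedEffect(gene, region, age, sign))
    bg_iter = iter(effect_rng.permutation(background))
    for region in ("cortex", "hippocampus"):
        for age in (7, 18):
            for _ in range(_BACKGROUND_DEGS_PER_CONDITION):
                gene = next(bg_iter)
                sign = 1.0 if effect_rng.random() < 0.5 else -1.0
                effects.append(PlantedEffect(gene, region, age, sign))

    design = SimulationDesign(
        n_genes=len(genes),
        gene_names=genes,
        arrays_per_group=overrides.pop("arrays_per_group", 2),
        seed=derive_seed(seed, "paper_like", "design"),
        **overrides,
    )
    return _scenario_common(
        "paper_like", seed, design, effects, term_sets, configs, ontology_depth=1
    )


def _contra_demo_scenario(seed: int, **overrides) -> Scenario:
    contra_gene = "Ctr1"
    rng = np.random.default_rng(derive_seed(seed, "contra_demo", "fixture"))
    configs = [
        DisorderConfig("BIP", (("GO:0007129", "(Chromosomal) synapsis"),)),
        DisorderConfig("SCZ", (("GO:0014069", "Postsynaptic density"),)),
        DisorderConfig("MDD", (("GO:0034330", "Cell junction organization"),)),
    ]
    namer = _pool_namer()
    term_sets = realize_term_sets(
        {"GO:0007129": 15, "GO:0014069": 20, "GO:0034330": 15},
        0,
        rng,
        namer,
        seeded_members={"GO:0014069": [contra_gene]},
        no_reuse={contra_gene},
    )
    pool_genes = sorted(set().union(*term_sets.values()))
    extra = [f"G{i:05d}" for i in range(10)]
    genes = tuple(pool_genes + extra)
    effects = [
        PlantedEffect(contra_gene, "hippocampus", 7, +0.7),
        PlantedEffect(contra_gene, "hippocampus", 18, -0.7),
    ]
    design = SimulationDesign(
        n_genes=len(genes),
        gene_names=genes,
        arrays_per_group=overrides.pop("arrays_per_group", 10),
        seed=derive_seed(seed, "contra_demo", "design"),
        **overrides,
    )
    return _scenario_common(
        "contra_demo", seed, design, effects, term_sets, configs, ontology_depth=0
    )
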