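"""GO annotation parsing, filtering, is_a expansion, and disorder gene pools.

The screening workflow restricts a whole-genome expression matrix to genes
annotated to a small list of GO terms associated with bipolar disorder (BIP),
schizophrenia (SCZ) and major depressive disorder (MDD).  This module parses
GAF 2.2 annotation files and OBO 1.2 ontologies, applies the taxon/qualifier
filters of that workflow, expands each configured term to its transitive
``is_a`` descendants, and assembles per-disorder gene pools with
overlap (redundant-membership) accounting.

Gene identity is the case-sensitive symbol string; callers working with real
annotation exports must pre-map aliases to a single symbol per gene.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import yaml

try:  # Python >= 3.9
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _resource_files

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: Annotation qualifiers admitted into the screen (negated "NOT" records are
#: always excluded regardless of this set).
DEFAULT_QUALIFIERS = frozenset(
    {"part_of", "involved_in", "enables", "contributes_to", "colocalizes_with"}
)

#: NCBI taxon id for Mus musculus, the screen's organism.
MOUSE_TAXON = "10090"

# GAF 2.2 column indices (0-based).
_COL_SYMBOL = 2
_COL_QUALIFIER = 3
_COL_GO_ID = 4
_COL_EVIDENCE = 6
_COL_TAXON = 12
_MIN_COLUMNS = 13


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-to-term annotation (one GAF data line)."""

    gene: str
    term: str
    qualifiers: tuple[str, ...]
    taxon: str
    evidence: str

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.term):
            raise ValueError(f"not a GO id: {self.term!r}")

    @property
    def negated(self) -> bool:
        return bool(self.qualifiers) and self.qualifiers[0] == "NOT"


def _as_line_iterable(source) -> Iterable[str]:
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            return source.splitlines()
        return Path(source).read_text().splitlines()
    return source


def _parse_taxon(cell: str) -> str:
    # Cell looks like "taxon:10090" or "taxon:10090|taxon:11049"; the first
    # entry is the annotated gene product's taxon.
    first = cell.split("|")[0].strip()
    return first.removeprefix("taxon:")


def parse_gaf(source) -> list[AnnotationRecord]:
    """Parse GAF 2.2 text into annotation records.

    ``source`` may be a path, raw GAF text, a file object or any iterable of
    lines.  Lines starting with ``!`` are comments.  Malformed data lines
    (fewer than 13 columns, or an invalid GO id) are logged with their line
    number and skipped; they are never fatal.
    """
    records: list[AnnotationRecord] = []
    for lineno, line in enumerate(_as_line_iterable(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < _MIN_COLUMNS:
            logger.warning(
                "skipping malformed GAF line %d: %d column(s), need >= %d",
                lineno,
                len(cols),
                _MIN_COLUMNS,
            )
            continue
        qualifier_cell = cols[_COL_QUALIFIER].strip()
        qualifiers = tuple(q for q in qualifier_cell.split("|") if q) if qualifier_cell else ()
        term = cols[_COL_GO_ID].strip()
        if not GO_ID_PATTERN.match(term):
            logger.warning("skipping GAF line %d: invalid GO id %r", lineno, term)
            continue
        records.append(
            AnnotationRecord(
                gene=cols[_COL_SYMBOL].strip(),
                term=term,
                qualifiers=qualifiers,
                taxon=_parse_taxon(cols[_COL_TAXON]),
                evidence=cols[_COL_EVIDENCE].strip(),
            )
        )
    return records


def write_gaf(records: Sequence[AnnotationRecord], db: str = "NPSCREEN") -> str:
    """Serialize records back to GAF 2.2 text (inverse of :func:`parse_gaf`)."""
    lines = ["!gaf-version: 2.2"]
    for r in records:
        cols = [""] * 17
        cols[0] = db
        cols[1] = r.gene
        cols[_COL_SYMBOL] = r.gene
        cols[_COL_QUALIFIER] = "|".join(r.qualifiers)
        cols[_COL_GO_ID] = r.term
        cols[5] = "NPSCREEN:ref"
        cols[_COL_EVIDENCE] = r.evidence
        cols[8] = "P"
        cols[11] = "gene"
        cols[_COL_TAXON] = f"taxon:{r.taxon}"
        cols[13] = "20170919"
        cols[14] = db
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def parse_quickgo_tsv(source) -> list[AnnotationRecord]:
    """Adapter for QuickGO-style TSV exports (header-named columns).

    Maps the SYMBOL / QUALIFIER / GO TERM / GO EVIDENCE CODE / TAXON ID
    columns onto the same :class:`AnnotationRecord` the GAF parser emits, so
    the rest of the pipeline is dialect-agnostic.
    """
    lines = list(_as_line_iterable(source))
    if not lines:
        return []
    header = [h.strip().upper() for h in lines[0].split("\t")]
    try:
        idx = {
            name: header.index(name)
            for name in ("SYMBOL", "QUALIFIER", "GO TERM", "GO EVIDENCE CODE", "TAXON ID")
        }
    except ValueError as exc:
        raise ValueError(f"missing QuickGO column: {exc}") from exc
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) <= max(idx.values()):
            logger.warning("skipping malformed QuickGO line %d", lineno)
            continue
        qualifiers = tuple(q for q in cols[idx["QUALIFIER"]].split("|") if q)
        records.append(
            AnnotationRecord(
                gene=cols[idx["SYMBOL"]].strip(),
                term=cols[idx["GO TERM"]].strip(),
                qualifiers=qualifiers,
                taxon=cols[idx["TAXON ID"]].strip(),
                evidence=cols[idx["GO EVIDENCE CODE"]].strip(),
            )
        )
    return records


def filter_annotations(
    records: Iterable[AnnotationRecord],
    taxon: str = MOUSE_TAXON,
    allowed_qualifiers: frozenset[str] = DEFAULT_QUALIFIERS,
) -> list[AnnotationRecord]:
    """Apply the screen's taxon and qualifier filters (order preserving).

    A record survives iff its taxon matches, it is not NOT-qualified, and at
    least one of its qualifiers is in ``allowed_qualifiers``.  Records with no
    qualifier at all are dropped.
    """
    if not allowed_qualifiers:
        raise ValueError("allowed_qualifiers must be non-empty")
    kept = []
    for r in records:
        if r.taxon != taxon or r.negated:
            continue
        if not any(q in allowed_qualifiers for q in r.qualifiers):
            continue
        kept.append(r)
    return kept


class OntologyGraph:
    """Directed acyclic graph of GO terms connected by ``is_a`` edges.

    Edges point child -> parent.  Only ``is_a`` relationships participate in
    term expansion; other relationship types found in an OBO file (``part_of``
    etc.) are parsed but ignored, with a log notice.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("is_a graph contains a cycle")
        self._g = graph

    @classmethod
    def from_edges(
        cls, is_a_edges: Iterable[tuple[str, str]], terms: Iterable[str] = ()
    ) -> "OntologyGraph":
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(is_a_edges)
        return cls(g)

    @classmethod
    def from_obo(cls, source) -> "OntologyGraph":
        """Load from an OBO 1.2 file path, text, or file object."""
        if isinstance(source, str) and "\n" in source:
            source = _io.StringIO(source)
        raw = obonet.read_obo(source, ignore_obsolete=True)
        g = nx.DiGraph()
        g.add_nodes_from(raw.nodes)
        ignored: dict[str, int] = {}
        for child, parent, key in raw.edges(keys=True):
            if key == "is_a":
                g.add_edge(child, parent)
            else:
                ignored[key] = ignored.get(key, 0) + 1
        for rel, n in sorted(ignored.items()):
            logger.info("ignoring %d %r edge(s); only is_a is traversed", n, rel)
        return cls(g)

    @property
    def terms(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def descendants(self, term: str) -> set[str]:
        """All terms whose transitive is_a closure contains ``term``."""
        # Edges point child -> parent, so ontology descendants are the graph
        # nodes with a directed path *to* the term.
        return nx.ancestors(self._g, term)

    @property
    def nx_graph(self) -> nx.DiGraph:
        return self._g


def expand_term(graph: OntologyGraph, term: str) -> set[str]:
    """Return ``{term}`` plus every transitive is_a descendant of ``term``."""
    if term not in graph:
        raise KeyError(f"term not in ontology: {term}")
    return {term} | graph.descendants(term)


def build_term_gene_sets(
    records: Iterable[AnnotationRecord],
    graph: OntologyGraph,
    terms: Sequence[str],
) -> dict[str, set[str]]:
    """Gene set per requested term, pulling in annotations to descendants.

    A gene belongs to term ``t`` iff some (already filtered) record annotates
    it to any member of ``expand_term(graph, t)``.  Duplicate annotations —
    e.g. the same gene with two evidence codes — collapse to one membership.
    """
    by_term: dict[str, set[str]] = {}
    for r in records:
        by_term.setdefault(r.term, set()).add(r.gene)
    out: dict[str, set[str]] = {}
    for t in terms:
        expanded = expand_term(graph, t)  # raises on unknown term
        genes: set[str] = set()
        for member in expanded:
            genes |= by_term.get(member, set())
        out[t] = genes
    return out


@dataclass(frozen=True)
class DisorderConfig:
    """Which GO terms define one disorder's gene pool."""

    disorder: str
    terms: tuple[tuple[str, str], ...]  # (GO id, display name)

    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.terms)


@dataclass
class DisorderPool:
    """Resolved per-term gene sets for one disorder plus their union.

    ``redundant_memberships`` counts gene-in-term memberships beyond the
    first: the sum of per-term set sizes minus the size of the deduplicated
    union (the parenthesized overlap count of the pool-size table).
    """

    disorder: str
    term_sets: dict[str, set[str]]
    union: set[str] = field(default_factory=set)
    redundant_memberships: int = 0

    def __post_init__(self) -> None:
        union: set[str] = set()
        for s in self.term_sets.values():
            union |= s
        self.union = union
        self.redundant_memberships = sum(len(s) for s in self.term_sets.values()) - len(union)


def build_disorder_pool(
    term_sets: Mapping[str, set[str]], config: DisorderConfig
) -> DisorderPool:
    """Assemble one disorder's pool from resolved term gene sets."""
    missing = [t for t in config.term_ids if t not in term_sets]
    if missing:
        raise KeyError(f"terms missing from term_sets for {config.disorder}: {missing}")
    return DisorderPool(
        disorder=config.disorder,
        term_sets={t: set(term_sets[t]) for t in config.term_ids},
    )


def load_disorder_presets(path: str | Path | None = None) -> list[DisorderConfig]:
    """Load disorder->GO-term configuration (packaged BIP/SCZ/MDD preset by default).

    The preset assigns 4 terms to BIP and 5 each to SCZ and MDD; the histone
    H3-K4 methylation term is shared between BIP and SCZ, so the 14 slots name
    13 distinct terms.
    """
    if path is None:
        text = (_resource_files("npscreen") / "data" / "disorders.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    configs = []
    for disorder, entries in doc["disorders"].items():
        terms = tuple((e["id"], e["name"]) for e in entries)
        for tid, _ in terms:
            if not GO_ID_PATTERN.match(tid):
                raise ValueError(f"invalid GO id in config for {disorder}: {tid}")
        configs.append(DisorderConfig(disorder=disorder, terms=terms))
    return configs


def pool_report(pools: Sequence[DisorderPool], configs: Sequence[DisorderConfig]):
    """Tidy pool-size table: one row per (disorder, term) plus a Total row.

    The report also surfaces the slot count vs. the distinct-term count
    (e.g. 14 slots / 13 distinct terms when one term is shared between
    disorders) in ``DataFrame.attrs``.
    """
    import pandas as pd

    names = {tid: name for c in configs for tid, name in c.terms}
    rows = []
    for pool in pools:
        for tid, genes in pool.term_sets.items():
            rows.append(
                {
                    "disorder": pool.disorder,
                    "term": tid,
                    "name": names.get(tid, ""),
                    "n_genes": len(genes),
                }
            )
        rows.append(
            {
                "disorder": pool.disorder,
                "term": "TOTAL",
                "name": f"union ({pool.redundant_memberships} redundant)",
                "n_genes": len(pool.union),
            }
        )
    df = pd.DataFrame(rows, columns=["disorder", "term", "name", "n_genes"])
    all_ids = [tid for c in configs for tid in c.term_ids]
    df.attrs["term_slots"] = len(all_ids)
    df.attrs["distinct_terms"] = len(set(all_ids))
    return df
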