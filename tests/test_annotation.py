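"""GAF/OBO parsing, qualifier/taxon filtering, is_a expansion, pool accounting."""

from __future__ import annotations

import io

import numpy as np
import pytest

from npscreen.annotation import (
    AnnotationRecord,
    DisorderConfig,
    OntologyGraph,
    build_disorder_pool,
    build_term_gene_sets,
    expand_term,
    filter_annotations,
    load_disorder_presets,
    parse_gaf,
    parse_quickgo_tsv,
    write_gaf,
)


def gaf_line(gene, term, qualifier="involved_in", taxon="10090", evidence="IDA"):
    cols = [""] * 17
    cols[1] = cols[2] = gene
    cols[3] = qualifier
    cols[4] = term
    cols[6] = evidence
    cols[12] = f"taxon:{taxon}"
    return "\t".join(cols)


class TestParseGaf:
    def test_comment_only_file_yields_no_records(self):
        assert parse_gaf("!gaf-version: 2.2\n") == []

    def test_hand_written_lines_parse_to_expected_fields(self):
        text = "\n".join(
            [
                "!gaf-version: 2.2",
                gaf_line("Arc", "GO:0014069"),
                gaf_line("Cnn3", "GO:0043197", qualifier="part_of", taxon="9606"),
                gaf_line("Stx3", "GO:0033267", evidence="IEA"),
            ]
        )
        records = parse_gaf(text)
        assert records == [
            AnnotationRecord("Arc", "GO:0014069", ("involved_in",), "10090", "IDA"),
            AnnotationRecord("Cnn3", "GO:0043197", ("part_of",), "9606", "IDA"),
            AnnotationRecord("Stx3", "GO:0033267", ("involved_in",), "10090", "IEA"),
        ]

    def test_not_qualifier_is_split_and_flagged(self):
        records = parse_gaf(gaf_line("Arc", "GO:0014069", qualifier="NOT|involved_in"))
        assert records[0].qualifiers == ("NOT", "involved_in")
        assert records[0].negated

    def test_short_line_is_skipped_with_warning(self, caplog):
        text = "\n".join([gaf_line("Arc", "GO:0014069"), "too\tfew\tcolumns"])
        with caplog.at_level("WARNING"):
            records = parse_gaf(text)
        assert len(records) == 1
        assert any("line 2" in m for m in caplog.messages)

    def test_serialize_reparse_round_trip_is_identity(self):
        records = parse_gaf(
            "\n".join([gaf_line("Arc", "GO:0014069"), gaf_line("Hist1h1c", "GO:0051568")])
        )
        assert parse_gaf(write_gaf(records)) == records

    def test_file_object_input(self):
        assert len(parse_gaf(io.StringIO(gaf_line("Arc", "GO:0014069")))) == 1

    def test_quickgo_export_adapter_maps_columns(self):
        text = (
            "GENE PRODUCT DB\tGENE PRODUCT ID\tSYMBOL\tQUALIFIER\tGO TERM\t"
            "GO EVIDENCE CODE\tTAXON ID\n"
            "UniProtKB\tQ9WV31\tArc\tinvolved_in\tGO:0014069\tIDA\t10090\n"
        )
        records = parse_quickgo_tsv(text)
        assert records == [
            AnnotationRecord("Arc", "GO:0014069", ("involved_in",), "10090", "IDA")
        ]


class TestFilterAnnotations:
    def make(self, taxon="10090", qualifiers=("involved_in",)):
        return AnnotationRecord("G", "GO:0000001", tuple(qualifiers), taxon, "IDA")

    def test_enumerated_fixture_keeps_only_valid_records(self):
        records = [
            self.make(taxon="9606"),
            self.make(taxon="9031"),
            self.make(qualifiers=("NOT", "involved_in")),
            self.make(),
            self.make(qualifiers=("enables",)),
            self.make(qualifiers=("colocalizes_with",)),
        ]
        kept = filter_annotations(records)
        assert kept == records[3:]

    def test_empty_input_and_empty_qualifier_record(self):
        assert filter_annotations([]) == []
        assert filter_annotations([self.make(qualifiers=())]) == []

    def test_filter_is_idempotent_and_never_grows(self):
        rng = np.random.default_rng(5)
        records = [
            self.make(
                taxon=rng.choice(["10090", "9606"]),
                qualifiers=tuple(
                    rng.choice(["involved_in", "NOT", "enables", "acts_upstream_of"], size=2)
                ),
            )
            for _ in range(50)
        ]
        once = filter_annotations(records)
        assert len(once) <= len(records)
        assert filter_annotations(once) == once


def brute_force_descendants(edges: list[tuple[str, str]], term: str) -> set[str]:
    """Independent reachability oracle: BFS over reversed is_a edges."""
    children: dict[str, set[str]] = {}
    for child, parent in edges:
        children.setdefault(parent, set()).add(child)
    seen, frontier = {term}, [term]
    while frontier:
        node = frontier.pop()
        for child in children.get(node, ()):
            if child not in seen:
                seen.add(child)
                frontier.append(child)
    return seen


class TestExpandTerm:
    def test_leaf_term_expands_to_singleton(self):
        graph = OntologyGraph.from_edges([("GO:0000001", "GO:0000002")])
        assert expand_term(graph, "GO:0000001") == {"GO:0000001"}

    def test_chain_expansion(self):
        graph = OntologyGraph.from_edges(
            [("GO:0000001", "GO:0000002"), ("GO:0000002", "GO:0000003")]
        )
        assert expand_term(graph, "GO:0000003") == {"GO:0000001", "GO:0000002", "GO:0000003"}

    def test_diamond_counts_each_node_once(self):
        a, b, c, d = "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"
        graph = OntologyGraph.from_edges([(a, b), (a, c), (b, d), (c, d)])
        assert expand_term(graph, d) == {a, b, c, d}

    def test_unknown_term_raises_naming_it(self):
        graph = OntologyGraph.from_edges([], terms=["GO:0000001"])
        with pytest.raises(KeyError, match="GO:9999999"):
            expand_term(graph, "GO:9999999")

    def test_cyclic_graph_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyGraph.from_edges([("GO:0000001", "GO:0000002"), ("GO:0000002", "GO:0000001")])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 201))
        nodes = [f"GO:{i:07d}" for i in range(1, n + 1)]
        # Random DAG: edges only from lower to higher topological index.
        edges = []
        for j in range(1, n):
            for parent in rng.choice(j, size=min(j, int(rng.integers(0, 4))), replace=False):
                edges.append((nodes[j], nodes[parent]))
        graph = OntologyGraph.from_edges(edges, terms=nodes)
        for term in rng.choice(nodes, size=10, replace=False):
            assert expand_term(graph, term) == brute_force_descendants(edges, term)


class TestBuildTermGeneSets:
    GRAPH = OntologyGraph.from_edges(
        [("GO:0000010", "GO:0000020")], terms=["GO:0000010", "GO:0000020", "GO:0000030"]
    )

    def test_no_records_gives_empty_sets(self):
        sets = build_term_gene_sets([], self.GRAPH, ["GO:0000020", "GO:0000030"])
        assert sets == {"GO:0000020": set(), "GO:0000030": set()}

    def test_child_annotation_propagates_to_requested_parent(self):
        records = [AnnotationRecord("Arc", "GO:0000010", ("involved_in",), "10090", "IDA")]
        sets = build_term_gene_sets(records, self.GRAPH, ["GO:0000020"])
        assert sets["GO:0000020"] == {"Arc"}

    def test_duplicate_annotations_collapse_to_one_membership(self):
        records = [
            AnnotationRecord("Arc", "GO:0000020", ("involved_in",), "10090", "IDA"),
            AnnotationRecord("Arc", "GO:0000020", ("involved_in",), "10090", "IEA"),
        ]
        sets = build_term_gene_sets(records, self.GRAPH, ["GO:0000020"])
        assert sets["GO:0000020"] == {"Arc"}

    def test_term_absent_from_graph_raises(self):
        with pytest.raises(KeyError, match="GO:0009999"):
            build_term_gene_sets([], self.GRAPH, ["GO:0009999"])


class TestDisorderPool:
    def test_overlap_accounting_matches_set_algebra(self):
        term_sets = {
            "GO:0000001": {"a", "b", "c"},
            "GO:0000002": {"c", "d"},
            "GO:0000003": {"d", "e", "a"},
        }
        config = DisorderConfig("BIP", tuple((t, t) for t in term_sets))
        pool = build_disorder_pool(term_sets, config)
        assert pool.union == {"a", "b", "c", "d", "e"}
        assert pool.redundant_memberships == 8 - 5

    def test_disjoint_sets_have_zero_redundancy(self):
        term_sets = {"GO:0000001": {"a"}, "GO:0000002": {"b", "c"}}
        config = DisorderConfig("MDD", tuple((t, t) for t in term_sets))
        pool = build_disorder_pool(term_sets, config)
        assert len(pool.union) == 3 and pool.redundant_memberships == 0

    def test_missing_term_raises_naming_it(self):
        config = DisorderConfig("SCZ", (("GO:0000009", "missing"),))
        with pytest.raises(KeyError, match="GO:0000009"):
            build_disorder_pool({}, config)

    @pytest.mark.parametrize("seed", range(5))
    def test_redundancy_invariant_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(50)]
        term_sets = {
            f"GO:{i:07d}": set(rng.choice(universe, size=rng.integers(1, 30), replace=False))
            for i in range(1, 5)
        }
        config = DisorderConfig("BIP", tuple((t, t) for t in term_sets))
        pool = build_disorder_pool(term_sets, config)
        assert pool.redundant_memberships == sum(map(len, term_sets.values())) - len(pool.union)


class TestDisorderPresets:
    def test_packaged_preset_shape(self):
        configs = {c.disorder: c for c in load_disorder_presets()}
        assert set(configs) == {"BIP", "SCZ", "MDD"}
        assert len(configs["BIP"].terms) == 4
        assert len(configs["SCZ"].terms) == 5
        assert len(configs["MDD"].terms) == 5
        all_ids = [t for c in configs.values() for t in c.term_ids]
        assert len(all_ids) == 14 and len(set(all_ids)) == 13

    def test_methylation_term_shared_between_bip_and_scz(self):
        configs = {c.disorder: c for c in load_disorder_presets()}
        assert "GO:0051568" in configs["BIP"].term_ids
        assert "GO:0051568" in configs["SCZ"].term_ids
        assert "GO:0051568" not in configs["MDD"].term_ids


class TestOboParsing:
    OBO = (
        "format-version: 1.2\n\n"
        "[Term]\nid: GO:0000001\nname: root\n\n"
        "[Term]\nid: GO:0000002\nname: child\nis_a: GO:0000001 ! root\n"
        "relationship: part_of GO:0000003 ! other\n\n"
        "[Term]\nid: GO:0000003\nname: other\n"
    )

    def test_part_of_edges_are_parsed_but_not_traversed(self):
        graph = OntologyGraph.from_obo(self.OBO)
        assert expand_term(graph, "GO:0000001") == {"GO:0000001", "GO:0000002"}
        assert expand_term(graph, "GO:0000003") == {"GO:0000003"}
        assert not graph.nx_graph.has_edge("GO:0000002", "GO:0000003")
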