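"""KGML parsing, network reconstruction and pair classification."""

import itertools

import pytest

from interflora import pathway_graph as pg

from conftest import (
    ECREL_ALT_COMPOUND_KGML,
    ECREL_KGML,
    MINIMAL_KGML,
    MULTI_KO_KGML,
    PRODUCER_KGML,
    TRANSPORTER_KGML,
)


class TestParseKgml:
    def test_minimal_document_has_no_relations(self):
        doc = pg.parse_kgml(MINIMAL_KGML)
        assert doc.map_id == "00900"
        assert doc.relations == []
        assert doc.entries[0].ko_ids == ("K00001",)

    def test_ecrel_compound_resolved(self):
        doc = pg.parse_kgml(ECREL_KGML)
        assert len(doc.relations) == 1
        rel = doc.relations[0]
        assert rel.relation_type == "ecrel"
        assert rel.compound_entry_id == "3"
        assert rel.compound_id == "C00022"

    def test_multi_ko_entry_keeps_both_ids(self):
        doc = pg.parse_kgml(MULTI_KO_KGML)
        entry = doc.entry("1")
        assert entry.ko_ids == ("K00001", "K00002")

    def test_malformed_xml_names_line(self):
        with pytest.raises(pg.KgmlError, match="line"):
            pg.parse_kgml("<pathway><entry></pathway>")

    def test_missing_pathway_root_is_format_error(self):
        with pytest.raises(pg.KgmlError, match="pathway"):
            pg.parse_kgml("<notapathway/>")

    def test_unknown_relation_type_retained_as_other(self):
        text = ECREL_KGML.replace('type="ECrel"', 'type="PPrel"')
        doc = pg.parse_kgml(text)
        assert doc.relations[0].relation_type == "other"


class TestBuildGraph:
    def test_single_ecrel_gives_two_nodes_one_edge(self):
        g = pg.build_graph([pg.parse_kgml(ECREL_KGML)])
        assert g.nodes == {"K00001", "K00002"}
        records = g.edge_records()
        assert len(records) == 1
        assert records[0][:3] == ("K00001", "K00002", frozenset({"C00022"}))

    def test_overview_map_contributes_nothing(self):
        g = pg.build_graph([pg.parse_kgml(ECREL_KGML)], overview_map_ids={"00010"})
        assert g.nodes == set()
        assert g.map_category["00010"] == "overview"

    def test_default_overview_prefixes_drop_global_maps(self):
        text = ECREL_KGML.replace('number="00010"', 'number="01100"')
        g = pg.build_graph([pg.parse_kgml(text)])
        assert g.nodes == set()

    def test_shared_edge_merges_compound_sets(self):
        docs = [pg.parse_kgml(ECREL_KGML), pg.parse_kgml(ECREL_ALT_COMPOUND_KGML)]
        g = pg.build_graph(docs)
        (a, b, compounds, maps) = g.edge_records()[0]
        assert compounds == frozenset({"C00022", "C00099"})
        assert maps == frozenset({"00010", "00030"})

    def test_document_order_invariance(self):
        docs = [
            pg.parse_kgml(t)
            for t in (ECREL_KGML, MULTI_KO_KGML, PRODUCER_KGML, TRANSPORTER_KGML)
        ]
        forward = pg.build_graph(docs)
        backward = pg.build_graph(list(reversed(docs)))
        assert forward == backward

    def test_multi_ko_expansion_has_no_self_loops(self):
        text = MULTI_KO_KGML.replace('name="ko:K00003"', 'name="ko:K00001 ko:K00003"')
        g = pg.build_graph([pg.parse_kgml(text)])
        assert all(a != b for a, b, _, _ in g.edge_records())
        # cross combinations minus the self-pair
        assert {r[:2] for r in g.edge_records()} == {
            ("K00001", "K00003"),
            ("K00002", "K00003"),
            ("K00001", "K00002"),
        }

    def test_maplink_joined_across_maps(self):
        g = pg.build_graph([pg.parse_kgml(PRODUCER_KGML), pg.parse_kgml(TRANSPORTER_KGML)])
        keys = {r[:2] for r in g.edge_records()}
        assert ("K00010", "K00099") in keys

    def test_duplicate_map_id_warns_but_merges(self):
        docs = [pg.parse_kgml(ECREL_KGML), pg.parse_kgml(ECREL_KGML)]
        with pytest.warns(UserWarning, match="duplicate"):
            g = pg.build_graph(docs)
        assert len(g.edge_records()) == 1


class TestEnumeratePairs:
    def test_empty_graph(self):
        assert pg.enumerate_pairs(pg.PathwayGraph()) == []

    def test_compound_mode_filters_bare_edges(self):
        text = ECREL_KGML.replace(
            '<relation entry1="1" entry2="2" type="ECrel">\n    <subtype name="compound" value="3"/>\n  </relation>',
            '<relation entry1="1" entry2="2" type="ECrel"></relation>',
        )
        docs = [pg.parse_kgml(text), pg.parse_kgml(MULTI_KO_KGML), pg.parse_kgml(PRODUCER_KGML)]
        g = pg.build_graph(docs)
        all_pairs = pg.enumerate_pairs(g)
        with_compounds = pg.enumerate_pairs(g, require_compounds=True)
        assert len(all_pairs) == len(with_compounds) + 1

    def test_canonical_ordering(self):
        g = pg.build_graph([pg.parse_kgml(ECREL_KGML)])
        pair = pg.enumerate_pairs(g)[0]
        assert (pair.ko_a, pair.ko_b) == ("K00001", "K00002")
        with pytest.raises(ValueError):
            pg.AdjacentPair("K00002", "K00001")


class TestClassifyBoundary:
    @pytest.fixture()
    def graph(self):
        return pg.build_graph(
            [pg.parse_kgml(PRODUCER_KGML), pg.parse_kgml(TRANSPORTER_KGML), pg.parse_kgml(ECREL_KGML)]
        )

    def test_producer_transporter_pair_is_boundary(self, graph):
        pairs = pg.classify_boundary(pg.enumerate_pairs(graph), graph)
        cls = {p.key: p.pair_class for p in pairs}
        assert cls[("K00010", "K00099")] == pg.PAIR_CLASS_BOUNDARY

    def test_metabolic_only_pair(self, graph):
        pairs = pg.classify_boundary(pg.enumerate_pairs(graph), graph)
        cls = {p.key: p.pair_class for p in pairs}
        assert cls[("K00001", "K00002")] == pg.PAIR_CLASS_METABOLIC
        assert cls[("K00010", "K00011")] == pg.PAIR_CLASS_METABOLIC

    def test_unknown_ko_is_unclassified(self, graph):
        orphan = pg.AdjacentPair("K99998", "K99999", compounds=frozenset({"C00001"}))
        out = pg.classify_boundary([orphan], graph)
        assert out[0].pair_class == pg.PAIR_CLASS_UNCLASSIFIED

    def test_partition_is_exhaustive_and_exclusive(self, graph):
        pairs = pg.classify_boundary(pg.enumerate_pairs(graph), graph)
        valid = {pg.PAIR_CLASS_BOUNDARY, pg.PAIR_CLASS_METABOLIC, pg.PAIR_CLASS_UNCLASSIFIED}
        assert all(p.pair_class in valid for p in pairs)
        assert len(pairs) == len({p.key for p in pairs})

    def test_explicit_transporter_relations_override(self, graph):
        pairs = pg.enumerate_pairs(graph)
        out = pg.classify_boundary(pairs, graph, transporter_relations=[])
        assert all(p.pair_class != pg.PAIR_CLASS_BOUNDARY for p in out)


class TestModuleEdgeLookup:
    def make_pair(self, *compounds):
        return pg.AdjacentPair("K00001", "K00002", compounds=frozenset(compounds))

    def test_basic_edge_non_edge_absent(self):
        modules = [pg.ModuleDefinition("M1", frozenset({"C1"}), frozenset({"C2"}))]
        assert pg.module_edge_lookup(self.make_pair("C1"), modules) == "edge"
        assert pg.module_edge_lookup(self.make_pair("C2"), modules) == "non_edge"
        assert pg.module_edge_lookup(self.make_pair("C3"), modules) == "absent"

    def test_tie_resolves_to_edge_exhaustively(self):
        # C3 is a terminus in module A and internal in module B; check the
        # resolver on every subset of a 3-compound universe against a
        # brute-force rule evaluation
        modules = [
            pg.ModuleDefinition("A", frozenset({"C3"}), frozenset({"C1"})),
            pg.ModuleDefinition("B", frozenset({"C2"}), frozenset({"C3"})),
        ]
        universe = ["C1", "C2", "C3"]
        for r in range(1, 4):
            for combo in itertools.combinations(universe, r):
                pair = self.make_pair(*combo)
                edge_hit = any(
                    c in m.edge_compounds for m in modules for c in pair.compounds
                )
                internal_hit = any(
                    c in m.internal_compounds for m in modules for c in pair.compounds
                )
                expected = "edge" if edge_hit else ("non_edge" if internal_hit else "absent")
                assert pg.module_edge_lookup(pair, modules) == expected

    def test_module_definition_rejects_overlap(self):
        with pytest.raises(ValueError, match="both edge and internal"):
            pg.ModuleDefinition("M1", frozenset({"C1"}), frozenset({"C1"}))


def test_edge_list_round_trip(tmp_path):
    docs = [pg.parse_kgml(t) for t in (ECREL_KGML, MULTI_KO_KGML, PRODUCER_KGML, TRANSPORTER_KGML)]
    graph = pg.build_graph(docs)
    path = tmp_path / "edges.tsv"
    pg.write_edge_list(graph, path)
    again = pg.read_edge_list(path, map_category=graph.map_category)
    assert again == graph


def test_modules_tsv_round_trip(tmp_path):
    modules = [
        pg.ModuleDefinition("M00001", frozenset({"C00001", "C00005"}), frozenset({"C00002"})),
        pg.ModuleDefinition("M00002", frozenset({"C00009"}), frozenset()),
    ]
    path = tmp_path / "modules.tsv"
    pg.write_modules_tsv(modules, path)
    assert pg.read_modules_tsv(path) == modules
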