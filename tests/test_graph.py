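import io
import json

import networkx as nx
import pytest

from ontosim.errors import FormatError, OntosimError, ParseError, VersionError
from ontosim.fixtures import FixtureSpec, random_dag, toy_T0
from ontosim.graph import (
    ConceptGraph,
    RRFConfig,
    build_taxonomy,
    load_taxonomy,
    read_edge_list,
    read_obo,
    read_rrf_relations,
    save_taxonomy,
)

from conftest import make_taxonomy


class TestReadEdgeList:
    def test_basic_parse(self):
        g = read_edge_list(io.StringIO("C\tA\nA\tR\n"))
        assert g.concepts == {"C", "A", "R"}
        assert g.taxonomic_edges == {("C", "A"), ("A", "R")}
        assert not g.other_edges

    def test_duplicate_lines_collapse(self):
        g = read_edge_list(io.StringIO("C\tA\nA\tR\nC\tA\n"))
        assert len(g.taxonomic_edges) == 2

    def test_short_line_is_parse_error(self):
        with pytest.raises(ParseError, match="line 2"):
            read_edge_list(io.StringIO("C\tA\nC\n"))

    def test_self_edge_rejected_not_fatal(self, caplog):
        with caplog.at_level("WARNING"):
            g = read_edge_list(io.StringIO("C\tC\nC\tA\n"))
        assert g.taxonomic_edges == {("C", "A")}

    def test_labelled_line_goes_to_other_edges(self):
        g = read_edge_list(io.StringIO("C\tA\nC\tB\tpart_of\n"))
        assert g.other_edges == {("B", "C", "part_of")}

    def test_comments_and_blanks_skipped(self):
        g = read_edge_list(io.StringIO("# header\n\nC\tA\n"))
        assert g.taxonomic_edges == {("C", "A")}


OBO_DOC = """\
format-version: 1.2

[Term]
id: X:001
name: root

[Term]
id: X:002
name: middle
is_a: X:001 ! root

[Term]
id: X:003
name: leaf
is_a: X:002
relationship: part_of X:001

[Term]
id: X:004
is_obsolete: true
"""


class TestReadObo:
    def test_is_a_chain(self):
        g = read_obo(io.StringIO(OBO_DOC))
        assert ("X:002", "X:001") in g.taxonomic_edges
        assert ("X:003", "X:002") in g.taxonomic_edges

    def test_obsolete_excluded(self):
        g = read_obo(io.StringIO(OBO_DOC))
        assert "X:004" not in g.concepts
        assert g.concepts == {"X:001", "X:002", "X:003"}

    def test_relationship_edge_labelled(self):
        g = read_obo(io.StringIO(OBO_DOC))
        assert ("X:001", "X:003", "part_of") in g.other_edges
        assert ("X:003", "X:001") not in g.taxonomic_edges

    def test_unparseable_document(self):
        with pytest.raises(FormatError):
            read_obo(io.StringIO("not an obo file\n"))


class TestReadRRF:
    CONFIG = RRFConfig(
        concept1_col=0, concept2_col=2, label_col=3,
        hierarchical_labels=frozenset({"PAR"}), child_first=True,
    )

    def test_hierarchical_rows(self):
        g = read_rrf_relations(
            io.StringIO("C1|x|C2|PAR|\nC2|x|C3|PAR|\n"), self.CONFIG
        )
        assert g.taxonomic_edges == {("C1", "C2"), ("C2", "C3")}

    def test_unlisted_label_other_only(self):
        g = read_rrf_relations(io.StringIO("C1|x|C2|RO|\n"), self.CONFIG)
        assert not g.taxonomic_edges
        assert ("C1", "C2", "RO") in g.other_edges

    def test_empty_file_warns(self, caplog):
        with caplog.at_level("WARNING"):
            g = read_rrf_relations(io.StringIO(""), self.CONFIG)
        assert not g.concepts
        assert any("no rows" in r.message for r in caplog.records)

    def test_missing_column_is_config_error(self):
        from ontosim.errors import ConfigError

        with pytest.raises(ConfigError):
            read_rrf_relations(io.StringIO("C1|C2\n"), self.CONFIG)

    def test_parent_first_orientation(self):
        cfg = RRFConfig(0, 1, 2, frozenset({"CHD"}), child_first=False)
        g = read_rrf_relations(io.StringIO("P|C|CHD|\n"), cfg)
        assert g.taxonomic_edges == {("C", "P")}


class TestBuildTaxonomy:
    def test_t0_structure(self, t0):
        assert t0.d == 3
        assert t0.max_leaves == 3
        assert t0.depth["R"] == 1
        assert t0.depth["A"] == 2
        assert t0.depth["C"] == 3
        assert t0.root == "R"

    def test_two_cycle_removes_one_edge(self):
        g = ConceptGraph()
        g.add_taxonomic_edge("A", "B")
        g.add_taxonomic_edge("B", "A")
        t = build_taxonomy(g)
        assert len(t.removed_edges) == 1
        # result must be acyclic
        dg = nx.DiGraph((c, p) for c, ps in t.parents.items() for p in ps)
        assert nx.is_directed_acyclic_graph(dg)

    def test_two_chains_get_vroot(self):
        g = ConceptGraph()
        g.add_taxonomic_edge("a1", "a0")
        g.add_taxonomic_edge("b1", "b0")
        t = build_taxonomy(g)
        assert t.root == "VROOT"
        assert t.depth["VROOT"] == 1
        assert t.depth["a0"] == 2 and t.depth["b0"] == 2

    def test_empty_graph_error(self):
        with pytest.raises(OntosimError):
            build_taxonomy(ConceptGraph())

    def test_edgeless_concepts_under_vroot(self, caplog):
        g = ConceptGraph(concepts={"x", "y", "z"})
        t = build_taxonomy(g)
        assert t.root == "VROOT"
        assert all(t.depth[c] == 2 for c in ("x", "y", "z"))

    def test_cycle_removal_deterministic(self):
        g = ConceptGraph()
        for c, p in [("A", "B"), ("B", "C"), ("C", "A"), ("D", "A"), ("B", "A")]:
            g.add_taxonomic_edge(c, p)
        r1 = build_taxonomy(g).removed_edges
        r2 = build_taxonomy(g).removed_edges
        assert r1 == r2 and len(r1) >= 1

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_depth_matches_bfs_oracle(self, seed):
        t = make_taxonomy(seed, n_concepts=5 + 2 * seed)
        dg = nx.DiGraph((c, p) for c, ps in t.parents.items() for p in ps)
        for c in t.parents:
            # node-count depth = edge distance to root + 1
            assert t.depth[c] == nx.shortest_path_length(dg, c, t.root) + 1

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_n_leaves_matches_bruteforce(self, seed):
        t = make_taxonomy(seed, n_concepts=5 + 2 * seed)
        dg = nx.DiGraph((c, p) for c, ps in t.parents.items() for p in ps)
        leaves = {c for c in t.parents if not t.children[c]}
        for c in t.parents:
            below = nx.ancestors(dg, c) | {c}
            assert t.n_leaves[c] == len(below & leaves)

    def test_acyclic_on_all_random_dags(self, random_taxonomies):
        for t in random_taxonomies:
            dg = nx.DiGraph((c, p) for c, ps in t.parents.items() for p in ps)
            assert nx.is_directed_acyclic_graph(dg)
            assert not t.removed_edges  # acyclic by construction

    def test_invariant_root_leaf_count(self, random_taxonomies):
        for t in random_taxonomies:
            assert t.n_leaves[t.root] == t.max_leaves
            assert t.d == max(t.depth.values())
            for c in t.parents:
                assert 1 <= t.n_subsumers[c] <= len(t.parents)
                assert 1 <= t.n_leaves[c] <= t.max_leaves


class TestPersistence:
    def test_round_trip_identity(self, t0, tmp_path):
        path = tmp_path / "t0.tax"
        save_taxonomy(t0, str(path))
        assert load_taxonomy(str(path)) == t0

    def test_round_trip_random(self, tmp_path):
        t = make_taxonomy(7, n_concepts=40)
        path = tmp_path / "r.tax"
        save_taxonomy(t, str(path))
        back = load_taxonomy(str(path))
        assert back == t
        assert back.metadata == t.metadata

    def test_corrupted_file(self, tmp_path):
        path = tmp_path / "junk.tax"
        path.write_text("\x00\x01 not json")
        with pytest.raises(FormatError):
            load_taxonomy(str(path))

    def test_wrong_format_tag(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text(json.dumps({"format": "something-else", "version": 1}))
        with pytest.raises(FormatError):
            load_taxonomy(str(path))

    def test_future_version(self, t0, tmp_path):
        path = tmp_path / "t0.tax"
        save_taxonomy(t0, str(path))
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(VersionError):
            load_taxonomy(str(path))
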