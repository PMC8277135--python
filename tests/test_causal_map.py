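import io
import itertools

import numpy as np
import pytest

from seabedrisk import fixtures
from seabedrisk.causal_map import (
    CombinedNetwork,
    ConceptMap,
    Link,
    MapFormatError,
    SynonymTable,
    degree_table,
    from_adjacency,
    harmonize,
    merge_maps,
    read_concept_maps,
    read_synonym_table,
    summarize,
    to_adjacency,
    to_dot,
    to_graphml,
    write_concept_maps,
)


def parse(text):
    return read_concept_maps(io.StringIO(text))


class TestReadConceptMaps:
    def test_direct_parse(self):
        maps = parse("E1,A,B,3\nE1,B,C\n")
        assert len(maps) == 1
        (m,) = maps
        assert m.expert_id == "E1"
        assert m.nodes == {"A", "B", "C"}
        assert m.links == {Link("A", "B", 3), Link("B", "C", None)}

    def test_self_loop_rejected_with_location(self):
        with pytest.raises(MapFormatError, match=r"2.*self-loop|self-loop"):
            parse("E1,A,B\nE1,A,A,2\n")

    def test_strength_out_of_range_rejected(self):
        with pytest.raises(MapFormatError, match="strength"):
            parse("E1,A,B,4\n")

    def test_non_integer_strength_rejected(self):
        with pytest.raises(MapFormatError, match="strength"):
            parse("E1,A,B,strong\n")

    def test_multiple_experts_in_order(self):
        maps = parse("E2,A,B\nE1,B,C\nE2,C,D\n")
        assert [m.expert_id for m in maps] == ["E2", "E1"]

    def test_packaged_fixture_map_sizes(self):
        maps = fixtures.load_expert_maps()
        assert len(maps) == 11
        assert all(8 <= m.n_nodes <= 24 for m in maps)

    def test_roundtrip_write_read(self, tmp_path):
        maps = parse("E1,A,B,3\nE1,B,C\nE2,A,C,1\n")
        path = tmp_path / "maps.csv"
        write_concept_maps(maps, path)
        again = read_concept_maps(path)
        assert {m.expert_id: (m.nodes, m.links) for m in maps} == {
            m.expert_id: (m.nodes, m.links) for m in again
        }


class TestHarmonize:
    def test_collapse_keeps_max_strength(self):
        m = ConceptMap(
            "E1",
            nodes={"worms", "polychaetes", "X"},
            links={Link("worms", "X", 2), Link("polychaetes", "X", 3)},
        )
        table = SynonymTable({"worms": "mobile infauna", "polychaetes": "mobile infauna"})
        h = harmonize(m, table)
        assert h.nodes == {"mobile infauna", "X"}
        assert h.links == {Link("mobile infauna", "X", 3)}

    def test_missing_strength_never_beats_numeric(self):
        m = ConceptMap(
            "E1",
            nodes={"worms", "polychaetes", "X"},
            links={Link("worms", "X", None), Link("polychaetes", "X", 1)},
        )
        table = SynonymTable({"worms": "w", "polychaetes": "w"})
        h = harmonize(m, table)
        assert h.links == {Link("w", "X", 1)}

    def test_empty_table_is_identity(self):
        m = ConceptMap("E1", nodes={"A", "B"}, links={Link("A", "B", 2)})
        h = harmonize(m, SynonymTable.empty())
        assert h == m

    def test_collapsed_self_loop_dropped(self, caplog):
        m = ConceptMap("E1", nodes={"worms", "annelids"}, links={Link("worms", "annelids")})
        table = SynonymTable({"worms": "w", "annelids": "w"})
        with caplog.at_level("WARNING"):
            h = harmonize(m, table)
        assert h.links == frozenset()
        assert "self-loop" in caplog.text

    def test_idempotent(self):
        m = ConceptMap(
            "E1",
            nodes={"worms", "X", "Y"},
            links={Link("worms", "X", 1), Link("X", "Y")},
        )
        table = SynonymTable({"worms": "mobile infauna"})
        once = harmonize(m, table)
        assert harmonize(once, table) == once

    def test_unclosed_table_rejected(self):
        with pytest.raises(MapFormatError, match="closed"):
            SynonymTable({"a": "b", "b": "c"})

    def test_node_count_never_increases(self):
        m = ConceptMap("E1", nodes={"a", "b", "c"}, links={Link("a", "b"), Link("b", "c")})
        table = SynonymTable({"a": "z", "b": "z2"})
        assert harmonize(m, table).n_nodes <= m.n_nodes


class TestMergeMaps:
    def test_union_with_support(self):
        m1 = ConceptMap("E1", nodes={"A", "B"}, links={Link("A", "B", 2)})
        m2 = ConceptMap("E2", nodes={"A", "B", "C"}, links={Link("A", "B", 3), Link("B", "C")})
        net = merge_maps([m1, m2])
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.support_count("A", "B") == 2
        assert net.max_strength("A", "B") == 3
        assert net.support_count("B", "C") == 1

    def test_merge_with_itself_doubles_support(self):
        m = ConceptMap("E1", nodes={"A", "B"}, links={Link("A", "B", 2)})
        net1 = merge_maps([m])
        net2 = merge_maps([m, m])
        assert net1.nodes == net2.nodes and set(net1.edges) == set(net2.edges)
        assert net2.support_count("A", "B") == 2 * net1.support_count("A", "B")

    def test_empty_input_rejected(self):
        with pytest.raises(MapFormatError):
            merge_maps([])

    def test_fixture_counts(self):
        net = fixtures.load_combined()
        assert net.n_nodes == 53
        assert net.n_edges == 96

    def test_order_independence(self, rng):
        maps = [harmonize(m, fixtures.load_synonyms()) for m in fixtures.load_expert_maps()]
        base = merge_maps(maps)
        perm = [maps[i] for i in rng.permutation(len(maps))]
        other = merge_maps(perm)
        assert base.nodes == other.nodes
        assert set(base.edges) == set(other.edges)
        for edge in base.edges:
            assert base.support_count(*edge) == other.support_count(*edge)
            assert sorted(base.edges[edge]) == sorted(other.edges[edge])

    def test_size_inequalities(self):
        maps = [harmonize(m, fixtures.load_synonyms()) for m in fixtures.load_expert_maps()]
        net = merge_maps(maps)
        assert net.n_edges <= sum(len(m.links) for m in maps)
        assert net.n_nodes <= sum(m.n_nodes for m in maps)

    def test_every_edge_has_provenance(self):
        net = fixtures.load_combined()
        assert all(len(records) >= 1 for records in net.edges.values())


class TestAdjacency:
    @pytest.fixture
    def small_net(self):
        m1 = ConceptMap("E1", nodes={"A", "B"}, links={Link("A", "B", 2)})
        m2 = ConceptMap("E2", nodes={"A", "B", "C"}, links={Link("A", "B", 3), Link("B", "C")})
        return merge_maps([m1, m2])

    def test_unit_entries(self, small_net):
        mat = to_adjacency(small_net, "none")
        assert mat.to_numpy().sum() == 2
        assert mat.loc["A", "B"] == 1 and mat.loc["B", "C"] == 1

    def test_max_strength_rule(self, small_net):
        mat = to_adjacency(small_net, "max_strength")
        assert mat.loc["A", "B"] == 3
        assert mat.loc["B", "C"] == 1  # unelicited strengths weigh 1

    def test_support_count_rule(self, small_net):
        mat = to_adjacency(small_net, "support_count")
        assert mat.loc["A", "B"] == 2

    def test_unknown_rule_rejected(self, small_net):
        with pytest.raises(MapFormatError, match="weight rule"):
            to_adjacency(small_net, "mean")

    def test_lexicographic_labels(self):
        net = fixtures.load_combined()
        mat = to_adjacency(net)
        assert list(mat.index) == sorted(net.nodes)
        assert list(mat.index) == list(mat.columns)

    def test_roundtrip_topology(self, small_net):
        rebuilt = from_adjacency(to_adjacency(small_net, "support_count"))
        assert rebuilt.nodes == small_net.nodes
        assert set(rebuilt.edges) == set(small_net.edges)

    def test_fixture_roundtrip_topology(self):
        net = fixtures.load_combined()
        rebuilt = from_adjacency(to_adjacency(net, "max_strength"))
        assert rebuilt.nodes == net.nodes
        assert set(rebuilt.edges) == set(net.edges)


class TestSummarize:
    def test_fixture_summary(self):
        s = summarize(fixtures.load_combined())
        assert s["n_nodes"] == 53 and s["n_edges"] == 96
        assert sum(s["per_category"].values()) == 53

    def test_single_edge(self):
        net = merge_maps([ConceptMap("E1", nodes={"A", "B"}, links={Link("A", "B")})])
        s = summarize(net)
        assert s["n_nodes"] == 2 and s["n_edges"] == 1

    def test_handshake_identity(self):
        table = degree_table(fixtures.load_combined())
        assert table["in_degree"].sum() == table["out_degree"].sum() == 96


class TestExports:
    def test_graphml_and_dot(self, tmp_path):
        net = fixtures.load_combined()
        to_graphml(net, tmp_path / "c.graphml")
        to_dot(net, tmp_path / "c.dot")
        import networkx as nx

        g = nx.read_graphml(tmp_path / "c.graphml")
        assert g.number_of_nodes() == 53 and g.number_of_edges() == 96
        dot = (tmp_path / "c.dot").read_text()
        assert dot.count("->") == 96 and "support=" in dot
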