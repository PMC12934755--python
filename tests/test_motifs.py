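"""Motif patterns, compressed matching, extraction and custom search."""

import pytest

from rnamotifs import (
    CapacityError,
    ContractError,
    RNAGraph,
    SearchConfig,
    compress,
    custom_search,
    extract_motifs,
    from_dot_bracket,
    make_patterns,
    match,
    without_nonwc,
)
from oracles import loop_decomposition_motifs, wc_pairs_of


def _inventory(matches):
    return sorted((m.motif_class, m.size, frozenset(m.member_ordinals)) for m in matches)


class TestPatterns:
    def test_default_pattern_count(self):
        patterns = make_patterns()
        assert len(patterns) == 9  # hairpin + internal + bulge + junctions 3..8
        assert [p.motif_class for p in patterns[:3]] == ["HAIRPIN", "INTERNAL", "BULGE"]
        assert [p.ways for p in patterns[3:]] == [3, 4, 5, 6, 7, 8]

    def test_degenerate_ranges(self):
        tetraloop_only = make_patterns(SearchConfig(hairpin_range=(4, 4)))
        matches = match(tetraloop_only[0], compress(from_dot_bracket("((....))")))
        assert len(matches) == 1 and matches[0].size == 4
        no_match = match(tetraloop_only[0], compress(from_dot_bracket("((...))")))
        assert no_match == []
        assert len(make_patterns(SearchConfig(junction_ways=(3, 3)))) == 4

    def test_invalid_ranges_raise(self):
        with pytest.raises(ContractError):
            make_patterns(SearchConfig(hairpin_range=(5, 2)))
        with pytest.raises(ContractError):
            make_patterns(SearchConfig(junction_ways=(3, 9)))


class TestMatch:
    def test_hairpin_single_embedding_after_dedup(self):
        pattern = make_patterns()[0]
        matches = match(pattern, compress(from_dot_bracket("(((....)))")))
        assert len(matches) == 1
        m = matches[0]
        assert m.size == 4
        assert m.member_ordinals == (2, 3, 4, 5, 6, 7)

    def test_internal_plus_hairpin(self):
        c = compress(from_dot_bracket("((.((....)).))"))
        internal = match(make_patterns()[1], c)
        hairpin = match(make_patterns()[0], c)
        assert len(internal) == 1 and internal[0].size == 2
        assert internal[0].member_ordinals == (1, 2, 3, 10, 11, 12)
        assert len(hairpin) == 1 and hairpin[0].size == 4

    def test_hairpin_bound_excludes_21_loop(self):
        c = compress(from_dot_bracket("((" + "." * 21 + "))"))
        assert match(make_patterns()[0], c) == []
        c20 = compress(from_dot_bracket("((" + "." * 20 + "))"))
        assert len(match(make_patterns()[0], c20)) == 1


class TestExtract:
    def test_three_way_junction_planted_size(self, suite200):
        from rnamotifs import StructureSpec, generate

        gs = generate(
            StructureSpec(
                motifs=[("JUNCTION", {"ways": 3, "strands": [2, 3, 3],
                                      "children": [{}, {}]})],
                seed=5,
            )
        )
        junctions = [m for m in extract_motifs(gs.graph, enrich=False) if m.motif_class == "JUNCTION"]
        assert len(junctions) == 1
        assert junctions[0].size == 8 and junctions[0].ways == 3

    def test_minimal_internal_loop_size_is_two(self):
        g = from_dot_bracket("((.((....)).))")
        sizes = [m.size for m in extract_motifs(g, enrich=False) if m.motif_class == "INTERNAL"]
        assert min(sizes) == 2

    def test_unstructured_strand_yields_nothing(self):
        assert extract_motifs(from_dot_bracket("......"), enrich=False) == []

    def test_planted_inventory_recovered_exactly(self, suite200):
        for gs in suite200:
            got = _inventory(extract_motifs(gs.graph, enrich=False))
            expected = sorted(gs.expected_motifs)
            assert got == expected, gs.dot_bracket

    def test_match_equals_loop_decomposition_oracle(self, small_structures, suite200):
        for gs in small_structures + suite200[:50]:
            g = without_nonwc(gs.graph)
            from rnamotifs import crossing_free

            nested = crossing_free(g)
            pairs = nested.wc_pairs()
            keys = nested.keys
            breaks = {i for i in range(nested.n - 1) if keys[i][0] != keys[i + 1][0]}
            expected = loop_decomposition_motifs(nested.n, pairs, breaks)
            got = set(_inventory(extract_motifs(gs.graph, enrich=False)))
            assert got == expected, gs.dot_bracket

    def test_no_member_overlaps_dangling_run(self, suite200):
        for gs in suite200:
            g = without_nonwc(gs.graph)
            paired = g.paired_nodes()
            dangling = set()
            for start, end in g.chain_ranges():
                i = start
                while i <= end and i not in paired:
                    dangling.add(i)
                    i += 1
                i = end
                while i >= start and i not in paired:
                    dangling.add(i)
                    i -= 1
            for m in extract_motifs(gs.graph, enrich=False):
                assert not (set(m.member_ordinals) & dangling)

    def test_views_attached_and_consistent(self):
        from rnamotifs import StructureSpec, generate

        gs = generate(StructureSpec(motifs=[("HAIRPIN", {"loop": 6})], nonwc_edges=2, seed=9))
        for m in extract_motifs(gs.graph, structure_id="synthetic"):
            assert m.structure_id == "synthetic"
            assert m.graph_with_nonwc.n == m.n_members
            assert m.graph_without_nonwc.n == m.n_members
            assert not any(
                attr[2] == 1 for _, _, attr in m.graph_without_nonwc.edges()
            )


class TestCustomSearch:
    def _edge_graph(self, n, edges):
        payload = {
            "nodes": [{"index": i, "chain": "Q", "number": i + 1, "icode": "", "base": "OTHER"}
                      for i in range(n)],
            "edges": [{"a": a, "b": b, "attr": list(attr)} for a, b, attr in edges],
        }
        return RNAGraph.from_json(payload)

    def test_single_wc_edge_query_finds_both_pairs(self):
        query = self._edge_graph(2, [(0, 1, (0, 1, 0))])
        target = from_dot_bracket("((....))")
        assert len(custom_search(query, target)) == 2

    def test_planted_nonwc_triangle_found_once(self):
        target = from_dot_bracket("........")
        target.graph.add_edge(2, 4, attr=(0, 0, 1))
        query = self._edge_graph(3, [(0, 1, (1, 0, 0)), (1, 2, (1, 0, 0)), (0, 2, (0, 0, 1))])
        results = custom_search(query, target)
        assert len(results) == 1
        assert [k[1] for k in results[0]] == [3, 4, 5]

    def test_identity_query_matches_itself(self):
        target = from_dot_bracket("((..))..((...))")
        assert len(custom_search(target, target)) >= 1

    def test_capacity_and_contract_guards(self):
        big = from_dot_bracket("." * 31)
        with pytest.raises(CapacityError):
            custom_search(big, big)
        disconnected = self._edge_graph(3, [(0, 1, (1, 0, 0))])
        with pytest.raises(ContractError):
            custom_search(disconnected, from_dot_bracket("...."))
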