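"""Motif store, conformation classification, distributions, export."""

import io
import json
import zipfile

import pytest

from rnamotifs import (
    IntegrityError_,
    MotifRow,
    MotifStore,
    RNAGraph,
    StructureSpec,
    canonical_key,
    classify_conformations,
    distributions,
    export_csv,
    export_zip,
    extract_motifs,
    from_dot_bracket,
    generate,
)


def _tetraloop_graph(nonwc_pairs=()):
    g = from_dot_bracket("(....)", sequence="GAAAAC")
    for a, b in nonwc_pairs:
        if g.graph.has_edge(a, b):
            attr = g.graph.edges[a, b]["attr"]
            g.graph.edges[a, b]["attr"] = (attr[0], attr[1], 1)
        else:
            g.graph.add_edge(a, b, attr=(0, 0, 1))
    return g


def _row(motif_id, graph, motif_class="HAIRPIN", size=4, pdb_id="1xyz"):
    return MotifRow(
        motif_id=motif_id,
        motif_class=motif_class,
        pdb_id=pdb_id,
        size=size,
        members=[["A", i + 1, ""] for i in range(graph.n)],
        graph_with_nonwc=graph.to_json(),
        graph_without_nonwc=graph.to_json(),
    )


class TestStore:
    def test_store_query_filter(self):
        store = MotifStore()
        rows = [
            _row(1, _tetraloop_graph()),
            _row(2, _tetraloop_graph()),
            _row(3, _tetraloop_graph(), motif_class="INTERNAL", size=2),
        ]
        assert store.store_motifs(rows) == 3
        hits = store.query_motifs(motif_class="HAIRPIN", size=4)
        assert [r.motif_id for r in hits] == [1, 2]
        csv = export_csv(hits)
        assert csv.splitlines()[0] == "ID,motif type,PDB ID,nucleotide number"
        assert len(csv.splitlines()) == 3

    def test_duplicate_motif_id_raises(self):
        store = MotifStore()
        store.store_motifs([_row(1, _tetraloop_graph())])
        with pytest.raises(IntegrityError_):
            store.store_motifs([_row(1, _tetraloop_graph())])

    def test_round_trip_graph_json_bit_identical(self):
        store = MotifStore()
        row = _row(7, _tetraloop_graph(nonwc_pairs=[(1, 4)]))
        store.store_motifs([row])
        (back,) = store.query_motifs()
        assert back.graph_with_nonwc == row.graph_with_nonwc
        assert RNAGraph.from_json(back.graph_with_nonwc) == RNAGraph.from_json(row.graph_with_nonwc)

    def test_export_zip_contains_one_pdb_per_row(self):
        gs = generate(StructureSpec(motifs=[("HAIRPIN", {"loop": 4})], seed=1))
        matches = extract_motifs(gs.graph, structure_id="synthetic")
        rows = [MotifRow.from_match(m, motif_id=i + 1) for i, m in enumerate(matches)]
        blob = export_zip(rows, {"synthetic": gs.structure})
        with zipfile.ZipFile(io.BytesIO(blob)) as zf:
            assert zf.namelist() == ["1.pdb"]
            assert b"ATOM" in zf.read("1.pdb")
        empty = export_zip([], {})
        with zipfile.ZipFile(io.BytesIO(empty)) as zf:
            assert zf.namelist() == []


class TestConformationClasses:
    def test_frequency_counting(self):
        store = MotifStore()
        plain = _tetraloop_graph()
        decorated = _tetraloop_graph(nonwc_pairs=[(1, 4)])
        rows = [_row(i + 1, plain) for i in range(5)]
        rows += [_row(i + 6, decorated) for i in range(2)]
        store.store_motifs(rows)
        classes = classify_conformations(store, "HAIRPIN", 4)
        assert [c.frequency for c in classes] == [5, 2]
        assert sum(c.frequency for c in classes) == 7

    def test_one_nonwc_edge_separates_classes(self):
        assert canonical_key(_tetraloop_graph()) != canonical_key(
            _tetraloop_graph(nonwc_pairs=[(1, 4)])
        )

    def test_single_motif_single_class(self):
        store = MotifStore()
        store.store_motifs([_row(1, _tetraloop_graph())])
        classes = classify_conformations(store)
        assert len(classes) == 1 and classes[0].frequency == 1

    def test_partition_independent_of_insertion_order(self):
        plain = _tetraloop_graph()
        decorated = _tetraloop_graph(nonwc_pairs=[(2, 5)])
        rows = [_row(1, plain), _row(2, decorated), _row(3, plain), _row(4, decorated), _row(5, plain)]
        forward, backward = MotifStore(), MotifStore()
        forward.store_motifs(rows)
        backward.store_motifs(
            [_row(i + 1, RNAGraph.from_json(r.graph_with_nonwc)) for i, r in enumerate(reversed(rows))]
        )
        c1 = classify_conformations(forward)
        c2 = classify_conformations(backward)
        assert [(c.canonical_key, c.frequency) for c in c1] == [
            (c.canonical_key, c.frequency) for c in c2
        ]

    def test_canonical_key_invariant_under_100_relabelings(self):
        import numpy as np

        base = _tetraloop_graph(nonwc_pairs=[(1, 4), (2, 5)])
        reference = canonical_key(base)
        rng = np.random.default_rng(0)
        for _ in range(100):
            perm = rng.permutation(base.n)
            g = base.graph.__class__()
            for i in range(base.n):
                g.add_node(int(perm[i]), **base.graph.nodes[i])
            for a, b, data in base.graph.edges(data=True):
                g.add_edge(int(perm[a]), int(perm[b]), **data)
            assert canonical_key(RNAGraph(g)) == reference

    def test_distinct_topologies_get_distinct_keys(self):
        assert canonical_key(from_dot_bracket("(....)")) != canonical_key(
            from_dot_bracket("(...)")
        )
        assert canonical_key(from_dot_bracket("((..))")) != canonical_key(
            from_dot_bracket("(....)")
        )


class TestDistributions:
    def test_even_split_shares(self):
        store = MotifStore()
        rows = [_row(i + 1, _tetraloop_graph()) for i in range(10)]
        rows += [
            _row(i + 11, _tetraloop_graph(), motif_class="INTERNAL", size=2) for i in range(10)
        ]
        store.store_motifs(rows)
        shares, hists = distributions(store)
        assert shares["HAIRPIN"] == pytest.approx(50.0)
        assert shares["INTERNAL"] == pytest.approx(50.0)
        assert shares.sum() == pytest.approx(100.0)
        assert hists["HAIRPIN"].idxmax() == 4

    def test_empty_store(self):
        shares, hists = distributions(MotifStore())
        assert shares.empty and hists == {}

    def test_planted_modal_size(self, suite200):
        store = MotifStore()
        next_id = 1
        for gs in suite200[:60]:
            for m in extract_motifs(gs.graph, structure_id="synthetic"):
                store.store_motifs([MotifRow.from_match(m, motif_id=next_id)])
                next_id += 1
        shares, hists = distributions(store)
        assert shares.sum() == pytest.approx(100.0)
        planted = {}
        for gs in suite200[:60]:
            for cls, size, _ in gs.expected_motifs:
                planted.setdefault(cls, []).append(size)
        for cls, sizes in planted.items():
            expected_mode = max(set(sizes), key=sizes.count)
            # histogram mode equals the planted modal size (ties allowed)
            top = hists[cls][hists[cls] == hists[cls].max()].index.tolist()
            assert expected_mode in top
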