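"""WL kernel, assignment, RNA-level similarity, clustering, family test."""

import numpy as np
import pytest

from rnamotifs import (
    ContractError,
    MotifFeature,
    RNAGraph,
    StructureSpec,
    best_match,
    cluster,
    extract_motifs,
    family_comparison,
    from_dot_bracket,
    generate,
    pairwise_matrix,
    rna_similarity,
    similarity_matrix,
    wl_similarity,
)
from oracles import brute_force_assignment_cost


def _motif_graph(dot_bracket, nonwc=()):
    g = from_dot_bracket(dot_bracket)
    for a, b in nonwc:
        g.graph.add_edge(a, b, attr=(0, 0, 1))
    return g


def _random_features(rng, n_motifs):
    shapes = ["(....)", "((...))", "((....))", "(..(...)..)", "(.(..).)"]
    feats = []
    for _ in range(n_motifs):
        shape = shapes[rng.integers(len(shapes))]
        nonwc = []
        if rng.random() < 0.5:
            n = len(shape)
            a, b = sorted(rng.choice(n, size=2, replace=False).tolist())
            if b - a >= 2:
                nonwc.append((a, b))
        feats.append(MotifFeature.from_graph(_motif_graph(shape, nonwc)))
    return feats


class TestWlSimilarity:
    def test_self_similarity_is_one(self):
        for shape in ["(....)", "((..))", "(.(..).)"]:
            g = _motif_graph(shape)
            assert wl_similarity(g, g) == pytest.approx(1.0)

    def test_nonwc_decoration_lowers_similarity_strictly_between_0_and_1(self):
        g1 = _motif_graph("(....)")
        g2 = _motif_graph("(....)", nonwc=[(1, 4)])
        s = wl_similarity(g1, g2)
        assert 0.0 < s < 1.0

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(1)
        feats = _random_features(rng, 30)
        for _ in range(100):
            i, j = rng.integers(len(feats), size=2)
            assert wl_similarity(feats[i].graph, feats[j].graph) == pytest.approx(
                wl_similarity(feats[j].graph, feats[i].graph)
            )

    def test_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(2)
        g = _motif_graph("((...))", nonwc=[(2, 5)])
        other = _motif_graph("((....))")
        reference = wl_similarity(g, other)
        for _ in range(20):
            perm = rng.permutation(g.n)
            shuffled = g.graph.__class__()
            for i in range(g.n):
                shuffled.add_node(int(perm[i]), **g.graph.nodes[i])
            for a, b, data in g.graph.edges(data=True):
                shuffled.add_edge(int(perm[a]), int(perm[b]), **data)
            assert wl_similarity(RNAGraph(shuffled), other) == pytest.approx(reference)

    def test_empty_graph_rejected(self):
        import networkx as nx

        with pytest.raises(ContractError):
            wl_similarity(RNAGraph(nx.Graph()), _motif_graph("(....)"))


class TestBestMatch:
    def test_identity_assignment_zero_cost(self):
        feats = [MotifFeature.from_graph(_motif_graph(s)) for s in ["(....)", "((...))", "(.(..).)"]]
        assignment, s = best_match(feats, feats)
        assert sorted(assignment) == [(0, 0), (1, 1), (2, 2)]
        assert sum(1 - s[i, j] for i, j in assignment) == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_picks_higher_similarity_permutation(self):
        # two dissimilar shapes: the identity permutation dominates the swap
        a = [MotifFeature.from_graph(_motif_graph("(....)")),
             MotifFeature.from_graph(_motif_graph("((.(..).))"))]
        b = [MotifFeature.from_graph(_motif_graph("(....)")),
             MotifFeature.from_graph(_motif_graph("((.(..).))"))]
        assignment, s = best_match(a, b)
        assert s[0, 0] > s[0, 1] and s[1, 1] > s[1, 0]
        assert sorted(assignment) == [(0, 0), (1, 1)]

    def test_rectangular_case_matches_min_cardinality(self):
        a = [MotifFeature.from_graph(_motif_graph(s)) for s in ["(....)", "((...))", "(..)"]]
        b = [MotifFeature.from_graph(_motif_graph("(....)"))]
        assignment, _ = best_match(a, b)
        assert len(assignment) == 1

    def test_optimal_against_permutation_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = _random_features(rng, int(rng.integers(1, 7)))
            b = _random_features(rng, int(rng.integers(1, 7)))
            assignment, s = best_match(a, b)
            cost = sum(1 - s[i, j] for i, j in assignment)
            assert cost == pytest.approx(brute_force_assignment_cost(s.tolist()), abs=1e-9)


class TestRnaSimilarity:
    def test_identical_inventories_score_one(self):
        rng = np.random.default_rng(4)
        feats = _random_features(rng, 5)
        assert rna_similarity(feats, feats).score == pytest.approx(1.0)

    def test_worked_example_three_quarters(self):
        shared = MotifFeature.from_graph(_motif_graph("(....)"))  # L=6, NC=0, W=6
        extra = MotifFeature.from_graph(_motif_graph("(..)"))  # L=4, NC=0, W=4
        assert shared.W == 6 and extra.W == 4
        result = rna_similarity([shared], [shared, extra])
        assert result.score == pytest.approx(2 * 6 * 1.0 / (6 + 10), abs=1e-9)
        assert result.score == pytest.approx(0.75, abs=1e-9)

    def test_both_empty_rejected(self):
        with pytest.raises(ContractError):
            rna_similarity([], [])

    def test_one_empty_scores_zero(self):
        feats = [MotifFeature.from_graph(_motif_graph("(....)"))]
        assert rna_similarity(feats, []).score == 0.0

    def test_bounds_symmetry_self_similarity_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        inventories = [_random_features(rng, int(rng.integers(1, 6))) for _ in range(1000)]
        for _ in range(1000):
            i, j = rng.integers(len(inventories), size=2)
            rs = rna_similarity(inventories[i], inventories[j]).score
            assert 0.0 <= rs <= 1.0 + 1e-12
            assert rs == pytest.approx(rna_similarity(inventories[j], inventories[i]).score)
        for inv in inventories[:50]:
            assert rna_similarity(inv, inv).score == pytest.approx(1.0)

    def test_adding_shared_motif_never_decreases_similarity(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            a = _random_features(rng, int(rng.integers(1, 5)))
            b = _random_features(rng, int(rng.integers(1, 5)))
            before = rna_similarity(a, b).score
            shared = MotifFeature.from_graph(_motif_graph("((....))", nonwc=[(3, 6)]))
            after = rna_similarity(a + [shared], b + [shared]).score
            assert after >= before - 1e-9

    def test_weights_from_extracted_motifs(self):
        gs = generate(StructureSpec(motifs=[("HAIRPIN", {"loop": 4})], nonwc_edges=0, seed=8))
        (m,) = extract_motifs(gs.graph)
        feat = MotifFeature.from_match(m)
        assert feat.L == m.n_members
        assert feat.W == feat.L * (1 + feat.NC)


class TestClusteringAndFamilies:
    def test_planted_two_block_partition_recovered(self):
        rng = np.random.default_rng(7)
        n = 30
        m = np.full((n, n), 0.1)
        m[:15, :15] = 0.9
        m[15:, 15:] = 0.9
        noise = rng.normal(0, 0.02, size=(n, n))
        m = np.clip(m + (noise + noise.T) / 2, 0.01, 1.0)
        np.fill_diagonal(m, 1.0)
        labels, _ = cluster(m, seed=0)
        assert len(set(labels.tolist())) == 2
        assert len(set(labels[:15].tolist())) == 1
        assert len(set(labels[15:].tolist())) == 1

    def test_all_identical_rnas_single_cluster(self):
        m = np.ones((12, 12))
        labels, meta = cluster(m, seed=0)
        assert len(set(labels.tolist())) == 1
        assert meta.number_of_nodes() == 1  # 12 > 10 members

    def test_meta_graph_keeps_only_clusters_above_ten(self):
        n = 32  # blocks of 12, 15, 5
        m = np.full((n, n), 0.05)
        blocks = [(0, 12), (12, 27), (27, 32)]
        for a, b in blocks:
            m[a:b, a:b] = 0.95
        np.fill_diagonal(m, 1.0)
        labels, meta = cluster(m, seed=0)
        assert len(set(labels.tolist())) == 3
        assert meta.number_of_nodes() == 2
        sizes = sorted(d["size"] for _, d in meta.nodes(data=True))
        assert sizes == [12, 15]

    def test_pairwise_matrix_properties(self):
        rng = np.random.default_rng(9)
        inventories = [_random_features(rng, int(rng.integers(1, 4))) for _ in range(6)]
        m = pairwise_matrix(inventories)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_family_comparison_detects_shift(self):
        rng = np.random.default_rng(10)
        inter = np.clip(rng.normal(0.3, 0.1, size=50), 0, 1)
        intra = np.clip(inter + 0.3, 0, 1)
        _, p = family_comparison(intra, inter)
        assert p < 0.05

    def test_family_comparison_identical_samples(self):
        x = np.linspace(0.1, 0.9, 40)
        _, p = family_comparison(x, x)
        assert p > 0.9

    def test_family_comparison_smallest_case(self):
        u, p = family_comparison([0.8], [0.2])
        assert np.isfinite(u) and 0 < p <= 1
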