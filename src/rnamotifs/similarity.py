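"""Motif-based RNA similarity (MBRS).

Two RNAs are compared through their motif inventories.  Motif-motif
similarity S is a Weisfeiler-Lehman subtree kernel with edge-attribute-aware
initial labels, cosine-normalized to [0, 1].  The inventories are matched
one-to-one by linear sum assignment on the cost matrix 1 - S, and the
matched similarities are aggregated into the RNA-RNA score

    RS(i, j) = 2 * sum_m W_{m,sigma(m)} * S_{m,sigma(m)} / (W_i + W_j)

where W_i is RNA i's total motif weight, each motif weighing
W_m = L_m * (1 + NC_m) (L_m nucleotides, NC_m non-WC pairs — non-WC-rich
motifs carry more structural signal), and the matched-pair weight
W_{m,sigma(m)} is the mean of the two motif weights so that RS(x, x) = 1.

Downstream, pairwise RS matrices are clustered with the Leiden community
detection algorithm, and intra- vs inter-family score samples are compared
with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import mannwhitneyu

from .errors import ContractError
from .graphs import RNAGraph
from .motifs import MotifMatch


@dataclass
class MotifFeature:
    """One motif as seen by MBRS: its with-non-WC graph and its weight."""

    graph: RNAGraph
    L: int  # nucleotide count, closing pairs included
    NC: int  # edges with the NONWC component set (each edge once)

    @property
    def W(self) -> float:
        return self.L * (1 + self.NC)

    @classmethod
    def from_graph(cls, graph: RNAGraph) -> "MotifFeature":
        if graph.n == 0:
            raise ContractError("empty motif graph")
        nc = sum(1 for _, _, attr in graph.edges() if attr[2] == 1)
        return cls(graph=graph, L=graph.n, NC=nc)

    @classmethod
    def from_match(cls, match: MotifMatch) -> "MotifFeature":
        if match.graph_with_nonwc is None:
            raise ContractError("match carries no graph view; extract with enrich=True")
        return cls.from_graph(match.graph_with_nonwc)


@dataclass
class SimilarityResult:
    score: float
    assignment: list[tuple[int, int]]
    per_pair: list[float]


# ---------------------------------------------------------------------------
# WL kernel


def _wl_features(g: nx.Graph, iterations: int) -> Counter:
    labels = {
        node: tuple(sorted(g.edges[node, nb]["attr"] for nb in g[node])) for node in g
    }
    features: Counter = Counter(labels.values())
    for _ in range(iterations):
        labels = {
            node: (
                labels[node],
                tuple(sorted((g.edges[node, nb]["attr"], labels[nb]) for nb in g[node])),
            )
            for node in g
        }
        features.update(labels.values())
    return features


def wl_similarity(g1: RNAGraph, g2: RNAGraph, iterations: int = 3) -> float:
    """Cosine-normalized WL subtree kernel similarity in [0, 1].

    Initial node labels are the sorted multisets of incident edge-attribute
    vectors, so covalent, WC and non-WC context all enter the refinement.
    Symmetric and invariant under node relabeling.
    """
    if g1.n == 0 or g2.n == 0:
        raise ContractError("wl_similarity requires nonempty graphs")
    f1 = _wl_features(g1.graph, iterations)
    f2 = _wl_features(g2.graph, iterations)
    dot = sum(count * f2.get(label, 0) for label, count in f1.items())
    n1 = sum(c * c for c in f1.values())
    n2 = sum(c * c for c in f2.values())
    return dot / float(np.sqrt(n1) * np.sqrt(n2))


# ---------------------------------------------------------------------------
# assignment and RNA-level similarity


def similarity_matrix(a: list[MotifFeature], b: list[MotifFeature], iterations: int = 3) -> np.ndarray:
    s = np.zeros((len(a), len(b)))
    for i, fa in enumerate(a):
        for j, fb in enumerate(b):
            s[i, j] = wl_similarity(fa.graph, fb.graph, iterations)
    return s


def best_match(a: list[MotifFeature], b: list[MotifFeature], iterations: int = 3):
    """Optimal one-to-one partial matching minimizing total cost 1 - S.

    Returns (assignment index pairs, similarity matrix); the assignment has
    min(|a|, |b|) pairs, unmatched motifs are left out.
    """
    if not a or not b:
        return [], np.zeros((len(a), len(b)))
    s = similarity_matrix(a, b, iterations)
    rows, cols = linear_sum_assignment(1.0 - s)
    return list(zip(rows.tolist(), cols.tolist())), s


def rna_similarity(a: list[MotifFeature], b: list[MotifFeature], iterations: int = 3) -> SimilarityResult:
    """Weighted aggregation of matched motif similarities (score in [0, 1])."""
    if not a and not b:
        raise ContractError("similarity of two motif-free RNAs is undefined")
    total_w = sum(f.W for f in a) + sum(f.W for f in b)
    assignment, s = best_match(a, b, iterations)
    per_pair = [float(s[i, j]) for i, j in assignment]
    numerator = sum(
        ((a[i].W + b[j].W) / 2.0) * s[i, j] for i, j in assignment
    )
    score = float(2.0 * numerator / total_w)
    return SimilarityResult(score=score, assignment=assignment, per_pair=per_pair)


def pairwise_matrix(rnas: list[list[MotifFeature]], iterations: int = 3) -> np.ndarray:
    """Symmetric RS matrix with unit diagonal over a list of RNA inventories."""
    n = len(rnas)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = rna_similarity(rnas[i], rnas[j], iterations).score
    return m


# ---------------------------------------------------------------------------
# clustering


def cluster(matrix: np.ndarray, resolution: float = 1.0, seed: int = 0, min_meta_size: int = 11):
    """Leiden community detection on the full weighted similarity graph.

    Returns (labels, meta_graph): integer cluster labels per RNA, and a
    meta-graph whose nodes are the clusters with more than ten members
    (node attribute ``size``), edges weighted by mean inter-cluster
    similarity.
    """
    import igraph as ig
    import leidenalg

    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1] or matrix.shape[0] < 2:
        raise ContractError("pairwise matrix must be square with >= 2 RNAs")
    n = matrix.shape[0]
    edges, weights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            w = float(matrix[i, j])
            if w > 0:
                edges.append((i, j))
                weights.append(w)
    graph = ig.Graph(n=n, edges=edges)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(partition.membership)
    meta = nx.Graph()
    big = [c for c in np.unique(labels) if np.sum(labels == c) >= min_meta_size]
    for c in big:
        meta.add_node(int(c), size=int(np.sum(labels == c)))
    for ia, c1 in enumerate(big):
        for c2 in big[ia + 1 :]:
            block = matrix[np.ix_(labels == c1, labels == c2)]
            meta.add_edge(int(c1), int(c2), weight=float(block.mean()))
    return labels, meta


def family_comparison(intra_scores, inter_scores):
    """Two-sided Mann-Whitney U test of intra- vs inter-family RS samples."""
    intra = np.asarray(intra_scores, dtype=float)
    inter = np.asarray(inter_scores, dtype=float)
    if intra.size == 0 or inter.size == 0:
        raise ContractError("both score samples must be nonempty")
    result = mannwhitneyu(intra, inter, alternative="two-sided")
    return float(result.statistic), float(result.pvalue)
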