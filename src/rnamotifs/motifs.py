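"""Compressed motif patterns and motif extraction.

A loop motif (hairpin, internal loop, bulge, n-way junction) is, on the
compressed graph, an alternating cycle of WC closing-pair edges and *strand*
edges, where each strand is either a super-edge whose weight is the strand's
unpaired-nucleotide count or — for empty strands, as in coaxially stacked
junctions — a plain covalent edge.  One ranged pattern per motif class
therefore replaces the per-size enumeration that makes nucleotide-level
pattern libraries combinatorially large; matches are decompressed back to
full member sets.

Motif *size* is the number of unpaired nucleotides; the closing WC pairs are
counted as members but not in the size.  Hairpin loops are bounded at 1-20
unpaired nucleotides (larger loops are thermodynamically unstable); junction
patterns cover 3- to 8-way junctions with strands of 0-20 nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import CapacityError, ContractError
from .graphs import (
    CompressedGraph,
    RNAGraph,
    compress,
    crossing_free,
    induced_subgraph,
    without_nonwc,
)
from .isomorphism import find_monomorphisms
from .rna_io import ResidueKey

HAIRPIN = "HAIRPIN"
INTERNAL = "INTERNAL"
BULGE = "BULGE"
JUNCTION = "JUNCTION"

WC_ATTR = (0, 1, 0)
COV_ATTR = (1, 0, 0)


@dataclass(frozen=True)
class SearchConfig:
    hairpin_range: tuple[int, int] = (1, 20)
    internal_range: tuple[int, int] = (1, 20)  # per strand
    bulge_range: tuple[int, int] = (1, 20)
    junction_ways: tuple[int, int] = (3, 8)
    junction_strand_range: tuple[int, int] = (0, 20)


@dataclass
class MotifPattern:
    """Template for one motif class: an alternating WC/strand cycle."""

    motif_class: str
    ways: int  # number of closing WC pairs in the cycle
    strand_ranges: list[tuple[int, int]]
    template: nx.MultiGraph = field(repr=False, default=None)

    def __post_init__(self):
        if self.template is None:
            self.template = _cycle_template(self.ways, self.strand_ranges)


def _cycle_template(ways: int, strand_ranges: list[tuple[int, int]]) -> nx.MultiGraph:
    g = nx.MultiGraph()
    n = 2 * ways
    g.add_nodes_from(range(n))
    for i in range(ways):
        g.add_edge(2 * i, 2 * i + 1, kind="wc")
    for i, rng in enumerate(strand_ranges):
        g.add_edge(2 * i + 1, (2 * i + 2) % n, kind="strand", range=tuple(rng))
    return g


def make_patterns(config: SearchConfig | None = None) -> list[MotifPattern]:
    """One hairpin, one internal-loop, one bulge pattern, and one junction
    pattern per ways value — 9 patterns under the defaults."""
    config = config or SearchConfig()
    for name in ("hairpin_range", "internal_range", "bulge_range", "junction_strand_range"):
        lo, hi = getattr(config, name)
        if lo < 0 or hi < lo:
            raise ContractError(f"invalid {name}: ({lo}, {hi})")
    if config.hairpin_range[0] < 1:
        raise ContractError("hairpin loops need at least one unpaired nucleotide")
    lo_w, hi_w = config.junction_ways
    if not (3 <= lo_w <= hi_w <= 8):
        raise ContractError(f"junction ways range {config.junction_ways} outside [3, 8]")
    patterns = [
        MotifPattern(HAIRPIN, 1, [config.hairpin_range]),
        MotifPattern(INTERNAL, 2, [config.internal_range, config.internal_range]),
        MotifPattern(BULGE, 2, [config.bulge_range, (0, 0)]),
    ]
    for ways in range(lo_w, hi_w + 1):
        patterns.append(
            MotifPattern(JUNCTION, ways, [config.junction_strand_range] * ways)
        )
    return patterns


@dataclass
class MotifMatch:
    motif_class: str
    ways: int
    size: int  # unpaired nucleotides
    member_ordinals: tuple[int, ...]
    members: tuple[ResidueKey, ...]
    closing_pairs: tuple[tuple[int, int], ...]
    structure_id: str | None = None
    graph_with_nonwc: RNAGraph | None = None
    graph_without_nonwc: RNAGraph | None = None

    @property
    def n_members(self) -> int:
        """Total nucleotide count, closing pairs included."""
        return len(self.member_ordinals)

    def inventory_entry(self) -> tuple[str, int, tuple[int, ...]]:
        return (self.motif_class, self.size, self.member_ordinals)


def _pattern_edge_ok(p_edge: dict, t_edge: dict) -> bool:
    if p_edge["kind"] == "wc":
        return t_edge["kind"] == "plain" and t_edge["attr"] == WC_ATTR
    lo, hi = p_edge["range"]
    if t_edge["kind"] == "super":
        return lo <= t_edge["weight"] <= hi
    return lo == 0 and t_edge["attr"] == COV_ATTR


def match(pattern: MotifPattern, c: CompressedGraph) -> list[MotifMatch]:
    """All embeddings of the pattern in the compressed graph, decompressed to
    full member sets and deduplicated by (class, member-set)."""
    results: dict[frozenset[int], MotifMatch] = {}
    for mapping in find_monomorphisms(pattern.template, c.graph, edge_ok=_pattern_edge_ok):
        members: set[int] = set(mapping.values())
        closing = []
        size = 0
        ok = True
        for pa, pb, data in pattern.template.edges(data=True):
            ta, tb = mapping[pa], mapping[pb]
            if data["kind"] == "wc":
                closing.append((min(ta, tb), max(ta, tb)))
                continue
            # strand: the matching target edge is unique (a super-edge and a
            # covalent edge never coexist between one node pair)
            t_edges = [d for d in c.graph[ta][tb].values() if _pattern_edge_ok(data, d)]
            if not t_edges:
                ok = False
                break
            t_edge = t_edges[0]
            if t_edge["kind"] == "super":
                members.update(t_edge["labels"])
                size += t_edge["weight"]
        if not ok:
            continue
        key = frozenset(members)
        if key in results:
            continue
        ordered = tuple(sorted(members))
        results[key] = MotifMatch(
            motif_class=pattern.motif_class,
            ways=pattern.ways,
            size=size,
            member_ordinals=ordered,
            members=tuple(c.source_nodes[i][0] for i in ordered),
            closing_pairs=tuple(sorted(set(closing))),
        )
    return sorted(results.values(), key=lambda m: m.member_ordinals)


def extract_motifs(
    g: RNAGraph,
    config: SearchConfig | None = None,
    structure_id: str | None = None,
    enrich: bool = True,
) -> list[MotifMatch]:
    """Full extraction pipeline on one RNA graph.

    Non-WC edges are excluded from the search, crossing (pseudoknot) pairs
    are projected out, the nested structure is compressed, and every pattern
    is matched.  Each match carries both graph views (with and without
    non-WC edges) induced over its members.
    """
    wc_view = without_nonwc(g)
    nested = crossing_free(wc_view)
    compressed = compress(nested)
    matches: list[MotifMatch] = []
    for pattern in make_patterns(config):
        matches.extend(match(pattern, compressed))
    if enrich:
        for m in matches:
            member_set = set(m.member_ordinals)
            m.structure_id = structure_id
            m.graph_with_nonwc = induced_subgraph(g, member_set)
            m.graph_without_nonwc = induced_subgraph(wc_view, member_set)
    matches.sort(key=lambda m: (m.member_ordinals, m.motif_class))
    return matches


def custom_search(query: RNAGraph, target: RNAGraph, max_query_nodes: int = 30):
    """User-defined substructure search at full node resolution.

    Unlike the motif patterns, the query may contain non-WC edges and is
    matched exactly (no compression), attribute vectors compared for
    equality.  Returns the distinct member sets, each a tuple of residue
    keys in ordinal order.
    """
    if query.n == 0:
        raise ContractError("empty query graph")
    if query.n > max_query_nodes:
        raise CapacityError(f"query has {query.n} nodes; limit is {max_query_nodes}")
    if not nx.is_connected(query.graph):
        raise ContractError("query graph must be connected")

    def edge_ok(p_edge, t_edge):
        return p_edge["attr"] == t_edge["attr"]

    seen: set[frozenset[int]] = set()
    out: list[tuple[ResidueKey, ...]] = []
    for mapping in find_monomorphisms(query.graph, target.graph, edge_ok=edge_ok):
        key = frozenset(mapping.values())
        if key in seen:
            continue
        seen.add(key)
        out.append(tuple(target.key_of(i) for i in sorted(mapping.values())))
    return out
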