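"""Attributed nucleotide-level RNA graphs and the compression algorithm.

Nodes are nucleotides, indexed 0..n-1 along the concatenated chains in file
order, each carrying its residue key and base.  Edges carry a 3-component
one-hot (possibly multi-hot) indicator attribute over the interaction types
``(COVALENT, WC, NONWC)``; a residue pair annotated with more than one
interaction type gets a single multi-hot edge.

The compression step replaces every maximal run of consecutive unpaired
nucleotides lying strictly between two retained nucleotides with a single
weighted *super-edge* that stores the collapsed labels, shrinking the search
space of the subgraph-isomorphism motif matcher while remaining losslessly
decompressible.  Dangling chain-terminal runs are kept as plain nodes: motif
loops are by definition flanked by structure on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import CapacityError, ContractError, FormatError, IntegrityError_, ReferenceError_
from .rna_io import COVALENT, NONWC, WC, InteractionSet, ResidueKey, Structure

ATTR_INDEX = {COVALENT: 0, WC: 1, NONWC: 2}
PAGE_CHARS = ["()", "[]", "{}", "<>"]
MAX_PAGES = len(PAGE_CHARS)


@dataclass
class RNAGraph:
    """Nucleotide-level graph: integer nodes with ``key``/``base`` attributes,
    edges with a 3-component ``attr`` indicator tuple."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def keys(self) -> list[ResidueKey]:
        return [self.graph.nodes[i]["key"] for i in range(self.n)]

    @property
    def bases(self) -> list[str]:
        return [self.graph.nodes[i]["base"] for i in range(self.n)]

    def key_of(self, i: int) -> ResidueKey:
        return self.graph.nodes[i]["key"]

    def attr(self, a: int, b: int) -> tuple[int, int, int]:
        return self.graph.edges[a, b]["attr"]

    def edges(self):
        for a, b, data in self.graph.edges(data=True):
            yield (min(a, b), max(a, b), data["attr"])

    def wc_pairs(self) -> list[tuple[int, int]]:
        """Sorted WC pairs (a < b).  Raises if WC edges are not a matching."""
        partner: dict[int, int] = {}
        pairs = []
        for a, b, attr in self.edges():
            if attr[1] != 1:
                continue
            for node in (a, b):
                if node in partner:
                    raise ContractError(
                        f"node {node} has more than one WC partner; WC edges must form a matching"
                    )
            partner[a] = b
            partner[b] = a
            pairs.append((a, b))
        return sorted(pairs)

    def paired_nodes(self) -> set[int]:
        out: set[int] = set()
        for a, b, attr in self.edges():
            if attr[1] == 1:
                out.update((a, b))
        return out

    def chain_ranges(self) -> list[tuple[int, int]]:
        """Inclusive ordinal ranges [(start, end), ...] of the chains."""
        ranges = []
        keys = self.keys
        start = 0
        for i in range(1, self.n):
            if keys[i][0] != keys[i - 1][0]:
                ranges.append((start, i - 1))
                start = i
        if self.n:
            ranges.append((start, self.n - 1))
        return ranges

    def copy(self) -> "RNAGraph":
        return RNAGraph(self.graph.copy())

    def __eq__(self, other) -> bool:  # label-preserving equality, not isomorphism
        if not isinstance(other, RNAGraph):
            return NotImplemented
        if self.n != other.n or self.keys != other.keys or self.bases != other.bases:
            return False
        return set(self.edges()) == set(other.edges())

    # -- serialization (matches the custom-search JSON payload contract) ----

    def to_json(self) -> dict:
        nodes = [
            {
                "index": i,
                "chain": k[0],
                "number": k[1],
                "icode": k[2],
                "base": self.graph.nodes[i]["base"],
            }
            for i, k in enumerate(self.keys)
        ]
        edges = [{"a": a, "b": b, "attr": list(attr)} for a, b, attr in sorted(self.edges())]
        return {"nodes": nodes, "edges": edges}

    @classmethod
    def from_json(cls, payload: dict) -> "RNAGraph":
        g = nx.Graph()
        for node in payload["nodes"]:
            g.add_node(
                node["index"],
                key=(node["chain"], node["number"], node.get("icode", "")),
                base=node.get("base", "OTHER"),
            )
        for edge in payload["edges"]:
            attr = tuple(int(v) for v in edge["attr"])
            _check_attr(attr)
            g.add_edge(edge["a"], edge["b"], attr=attr)
        return cls(g)


def _check_attr(attr: tuple[int, int, int]) -> None:
    if len(attr) != 3 or any(v not in (0, 1) for v in attr) or not any(attr):
        raise ContractError(f"edge attribute {attr!r} must be a nonzero 0/1 indicator triple")


# ---------------------------------------------------------------------------
# construction


def build_graph(s: Structure, ia: InteractionSet) -> RNAGraph:
    """One node per residue, one (possibly multi-hot) edge per interacting pair."""
    g = nx.Graph()
    index: dict[ResidueKey, int] = {}
    i = 0
    for chain in s.chains:
        for res in chain.residues:
            if res.key in index:
                raise IntegrityError_(f"duplicate residue key {res.key!r}")
            index[res.key] = i
            g.add_node(i, key=res.key, base=res.base)
            i += 1
    for ka, kb, types in ia.interactions:
        if ka not in index or kb not in index:
            missing = ka if ka not in index else kb
            raise ReferenceError_(f"interaction references unknown residue {missing!r}")
        attr = [0, 0, 0]
        for t in types:
            attr[ATTR_INDEX[t]] = 1
        a, b = index[ka], index[kb]
        g.add_edge(a, b, attr=tuple(attr))
    return RNAGraph(g)


def without_nonwc(g: RNAGraph) -> RNAGraph:
    """Zero the NONWC component everywhere; drop edges that become all-zero.

    The node set is unchanged; idempotent.
    """
    out = nx.Graph()
    out.add_nodes_from(g.graph.nodes(data=True))
    for a, b, attr in g.edges():
        new_attr = (attr[0], attr[1], 0)
        if any(new_attr):
            out.add_edge(a, b, attr=new_attr)
    return RNAGraph(out)


# ---------------------------------------------------------------------------
# dot-bracket


def _crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


def assign_pages(pairs: list[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """First-fit interval coloring of base pairs, ordered by left endpoint.

    Nested/disjoint pairs share a page; a pair crossing every open page gets
    the next one.  Raises :class:`CapacityError` beyond four pages.
    """
    pages: list[list[tuple[int, int]]] = []
    result: dict[tuple[int, int], int] = {}
    for pair in sorted(pairs):
        for p, placed in enumerate(pages):
            if not any(_crosses(pair, q) for q in placed):
                placed.append(pair)
                result[pair] = p
                break
        else:
            if len(pages) >= MAX_PAGES:
                raise CapacityError(
                    f"pair {pair} needs page {len(pages)}; only {MAX_PAGES} bracket pages available"
                )
            pages.append([pair])
            result[pair] = len(pages) - 1
    return result


def to_dot_bracket(g: RNAGraph) -> str:
    """Extended dot-bracket of the WC pairing, one character per node.

    Pages use ``()``, ``[]``, ``{}``, ``<>`` in first-fit order; unpaired
    nucleotides are dots.  Operates on the WC component only (use
    :func:`without_nonwc` first if the graph carries non-WC edges).
    """
    chars = ["."] * g.n
    pages = assign_pages(g.wc_pairs())
    for (a, b), p in pages.items():
        chars[a] = PAGE_CHARS[p][0]
        chars[b] = PAGE_CHARS[p][1]
    return "".join(chars)


def from_dot_bracket(t: str, sequence: str | None = None, chain_id: str = "A") -> RNAGraph:
    """Inverse of :func:`to_dot_bracket` (single chain, covalent backbone added).

    ``sequence`` optionally assigns bases; unknown letters become ``OTHER``.
    """
    if sequence is not None and len(sequence) != len(t):
        raise ContractError("sequence length does not match dot-bracket length")
    openers = {pc[0]: p for p, pc in enumerate(PAGE_CHARS)}
    closers = {pc[1]: p for p, pc in enumerate(PAGE_CHARS)}
    stacks: list[list[int]] = [[] for _ in PAGE_CHARS]
    pairs = []
    for pos, ch in enumerate(t):
        if ch == ".":
            continue
        if ch in openers:
            stacks[openers[ch]].append(pos)
        elif ch in closers:
            stack = stacks[closers[ch]]
            if not stack:
                raise FormatError(f"unbalanced {ch!r} at position {pos + 1}")
            pairs.append((stack.pop(), pos))
        else:
            raise FormatError(f"unknown dot-bracket character {ch!r} at position {pos + 1}")
    for p, stack in enumerate(stacks):
        if stack:
            raise FormatError(
                f"unbalanced {PAGE_CHARS[p][0]!r} at position {stack[-1] + 1}"
            )
    g = nx.Graph()
    for i in range(len(t)):
        base = "OTHER"
        if sequence is not None and sequence[i].upper() in "AUGC":
            base = sequence[i].upper()
        g.add_node(i, key=(chain_id, i + 1, ""), base=base)
    for i in range(len(t) - 1):
        g.add_edge(i, i + 1, attr=(1, 0, 0))
    for a, b in pairs:
        if g.has_edge(a, b):
            attr = g.edges[a, b]["attr"]
            g.edges[a, b]["attr"] = (attr[0], 1, attr[2])
        else:
            g.add_edge(a, b, attr=(0, 1, 0))
    return RNAGraph(g)


def crossing_free(g: RNAGraph) -> RNAGraph:
    """Project onto the non-crossing (page-0) pairing.

    Crossing WC pairs — the pseudoknot-forming ones, as picked out by the
    first-fit page assignment — are removed; everything else is unchanged.
    Classic loop motifs are defined relative to this nested secondary
    structure, while crossing pairs are analyzed by
    :mod:`rnamotifs.pseudoknots`.
    """
    pages = assign_pages(g.wc_pairs())
    out = nx.Graph()
    out.add_nodes_from(g.graph.nodes(data=True))
    for a, b, attr in g.edges():
        if attr[1] == 1 and pages.get((a, b), 0) != 0:
            new_attr = (attr[0], 0, attr[2])
            if any(new_attr):
                out.add_edge(a, b, attr=new_attr)
            continue
        out.add_edge(a, b, attr=attr)
    return RNAGraph(out)


def induced_subgraph(g: RNAGraph, members: set[int]) -> RNAGraph:
    """Subgraph over ``members``, re-indexed 0..m-1 in ordinal order."""
    ordered = sorted(members)
    rank = {node: i for i, node in enumerate(ordered)}
    out = nx.Graph()
    for node in ordered:
        out.add_node(rank[node], **g.graph.nodes[node])
    for a, b, attr in g.edges():
        if a in rank and b in rank:
            out.add_edge(rank[a], rank[b], attr=attr)
    return RNAGraph(out)


# ---------------------------------------------------------------------------
# compression


@dataclass
class CompressedGraph:
    """Graph whose interior unpaired runs are weighted super-edges.

    ``graph`` is a multigraph over the retained ordinals (a WC pair that
    closes a loop carries both its WC edge and the loop's super-edge).
    Plain edges keep their attribute vector (``kind="plain"``); super-edges
    carry the collapsed run (``kind="super"``, ``labels``/``label_keys``,
    ``weight = len(labels)``).  Enough source metadata is kept for
    :func:`decompress` to be exact.
    """

    graph: nx.MultiGraph
    source_nodes: list[tuple[ResidueKey, str]]  # (key, base) for every ordinal

    @property
    def n_retained(self) -> int:
        return self.graph.number_of_nodes()

    def super_edges(self):
        for a, b, data in self.graph.edges(data=True):
            if data["kind"] == "super":
                yield (min(a, b), max(a, b), data)

    def plain_edges(self):
        for a, b, data in self.graph.edges(data=True):
            if data["kind"] == "plain":
                yield (min(a, b), max(a, b), data["attr"])


def compress(g: RNAGraph) -> CompressedGraph:
    """Collapse interior runs of unpaired nucleotides into super-edges.

    Requires a without-non-WC view.  Retained nodes are the WC-paired ones
    plus chain-terminal dangling runs; every maximal unpaired run flanked by
    two retained nodes of the same chain becomes one super-edge whose weight
    is the run length.
    """
    if any(attr[2] == 1 for _, _, attr in g.edges()):
        raise ContractError("compress expects a without-non-WC view")
    paired = g.paired_nodes()
    retained: set[int] = set(paired)
    runs: list[tuple[int, int, list[int]]] = []  # (left flank, right flank, run)
    for start, end in g.chain_ranges():
        i = start
        while i <= end:
            if i in paired:
                i += 1
                continue
            j = i
            while j <= end and j not in paired:
                j += 1
            run = list(range(i, j))
            if i == start or j > end:  # dangling: no paired flank on one side
                retained.update(run)
            else:
                runs.append((i - 1, j, run))
            i = j
    mg = nx.MultiGraph()
    for node in sorted(retained):
        mg.add_node(node, **g.graph.nodes[node])
    for a, b, attr in g.edges():
        if a in retained and b in retained:
            mg.add_edge(a, b, kind="plain", attr=attr)
    for left, right, run in runs:
        mg.add_edge(
            left,
            right,
            kind="super",
            labels=tuple(run),
            label_keys=tuple(g.key_of(i) for i in run),
            weight=len(run),
        )
    source_nodes = [(g.key_of(i), g.graph.nodes[i]["base"]) for i in range(g.n)]
    return CompressedGraph(graph=mg, source_nodes=source_nodes)


def decompress(c: CompressedGraph) -> RNAGraph:
    """Exact inverse of :func:`compress`: reinsert collapsed runs."""
    g = nx.Graph()
    for i, (key, base) in enumerate(c.source_nodes):
        g.add_node(i, key=key, base=base)
    for a, b, attr in c.plain_edges():
        g.add_edge(a, b, attr=attr)
    for a, b, data in c.super_edges():
        left, right = (a, b) if data["labels"][0] - a == 1 else (b, a)
        path = [left, *data["labels"], right]
        for u, v in zip(path, path[1:]):
            g.add_edge(u, v, attr=(1, 0, 0))
    # drop nodes beyond the source count never happens: source_nodes is total
    return RNAGraph(g)
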