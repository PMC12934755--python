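"""Attribute-constrained subgraph monomorphism by backtracking.

A small VF2-style matcher over (multi)graphs with caller-supplied node and
edge predicates.  It enumerates injective node maps from a pattern into a
target such that every pattern edge between a mapped node pair can be
assigned injectively to a distinct compatible target edge between the images
(parallel edges in multigraph patterns are respected).  Pattern nodes are
visited in a connectivity-first order so candidates stay constrained to
neighbors of the partial embedding.
"""

from __future__ import annotations

from collections.abc import Callable, Iterator

import networkx as nx

NodePredicate = Callable[[dict, dict], bool]
EdgePredicate = Callable[[dict, dict], bool]


def _edges_between(g, a, b) -> list[dict]:
    if not g.has_edge(a, b):
        return []
    if g.is_multigraph():
        return list(g[a][b].values())
    return [g.edges[a, b]]


def _multiedge_feasible(p_edges: list[dict], t_edges: list[dict], edge_ok: EdgePredicate) -> bool:
    """Can the pattern edges be injectively assigned to compatible target edges?"""

    def assign(i: int, used: int) -> bool:
        if i == len(p_edges):
            return True
        for j, te in enumerate(t_edges):
            if used & (1 << j):
                continue
            if edge_ok(p_edges[i], te):
                if assign(i + 1, used | (1 << j)):
                    return True
        return False

    return len(p_edges) <= len(t_edges) and assign(0, 0)


def _pattern_order(pattern) -> list:
    """Connectivity-first visiting order, highest degree first per component."""
    order: list = []
    seen: set = set()
    nodes_by_degree = sorted(pattern.nodes, key=lambda n: -pattern.degree(n))
    for root in nodes_by_degree:
        if root in seen:
            continue
        frontier = [root]
        while frontier:
            frontier.sort(
                key=lambda n: (-sum(nb in seen for nb in pattern[n]), -pattern.degree(n))
            )
            node = frontier.pop(0)
            if node in seen:
                continue
            seen.add(node)
            order.append(node)
            frontier.extend(nb for nb in pattern[node] if nb not in seen)
    return order


def find_monomorphisms(
    pattern,
    target,
    node_ok: NodePredicate | None = None,
    edge_ok: EdgePredicate | None = None,
) -> Iterator[dict]:
    """Yield injective node maps (pattern node -> target node).

    ``node_ok(pattern_node_data, target_node_data)`` and
    ``edge_ok(pattern_edge_data, target_edge_data)`` default to accepting
    everything.  The target may carry extra edges between matched nodes
    (monomorphism, not induced-subgraph isomorphism).
    """
    if node_ok is None:
        node_ok = lambda p, t: True  # noqa: E731
    if edge_ok is None:
        edge_ok = lambda p, t: True  # noqa: E731
    if pattern.number_of_nodes() == 0:
        yield {}
        return
    if pattern.number_of_nodes() > target.number_of_nodes():
        return
    order = _pattern_order(pattern)
    target_nodes = list(target.nodes)
    mapping: dict = {}
    used: set = set()

    def candidates(p_node):
        mapped_neighbors = [nb for nb in pattern[p_node] if nb in mapping]
        if not mapped_neighbors:
            return (t for t in target_nodes if t not in used)
        # intersect target neighborhoods of the mapped pattern neighbors
        base = min(
            (set(target[mapping[nb]]) for nb in mapped_neighbors), key=len
        )
        return (t for t in base if t not in used)

    def feasible(p_node, t_node) -> bool:
        if not node_ok(pattern.nodes[p_node], target.nodes[t_node]):
            return False
        for nb in pattern[p_node]:
            if nb not in mapping:
                continue
            p_edges = _edges_between(pattern, p_node, nb)
            t_edges = _edges_between(target, t_node, mapping[nb])
            if not _multiedge_feasible(p_edges, t_edges, edge_ok):
                return False
        return True

    def extend(depth: int) -> Iterator[dict]:
        if depth == len(order):
            yield dict(mapping)
            return
        p_node = order[depth]
        for t_node in list(candidates(p_node)):
            if feasible(p_node, t_node):
                mapping[p_node] = t_node
                used.add(t_node)
                yield from extend(depth + 1)
                used.discard(t_node)
                del mapping[p_node]

    yield from extend(0)
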