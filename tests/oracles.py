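"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the production code paths: the loop enumerator
works directly on the pair list by secondary-structure loop decomposition
(no compression, no subgraph matching), the crossing check is a quadratic
scan over pair combinations, and the assignment oracle enumerates
permutations.
"""

from __future__ import annotations

from itertools import combinations, permutations


def loop_decomposition_motifs(n, pairs, chain_break_after=frozenset(), config=None):
    """Enumerate loop motifs of a nested pairing by tree decomposition.

    ``pairs`` are 0-based (i, j) WC pairs, assumed non-crossing.  For every
    pair, its loop is the region between i and j minus the subtrees of the
    directly nested child pairs; classification follows the strand counts:
    0 children = hairpin, 1 child = internal/bulge, k >= 2 children =
    (k+1)-way junction.  Returns {(class, size, frozenset(members)), ...}
    filtered by the same ranges as the production patterns.
    """
    from rnamotifs.motifs import SearchConfig

    config = config or SearchConfig()
    pairs = sorted(pairs)
    partner = {}
    for a, b in pairs:
        partner[a] = b
        partner[b] = a
    out = set()
    for i, j in pairs:
        pos = i + 1
        children = []
        strands = []  # unpaired runs between consecutive helix anchors
        run = []
        broken = False
        while pos < j:
            if pos - 1 in chain_break_after:
                broken = True  # loop interrupted by a chain break: not a motif
            if pos in partner:
                q = partner[pos]
                if not (i < pos < q < j):
                    broken = True
                    break
                children.append((pos, q))
                strands.append(run)
                run = []
                pos = q + 1
            else:
                run.append(pos)
                pos += 1
        if j - 1 in chain_break_after:
            broken = True
        strands.append(run)
        if broken:
            continue
        members = {i, j}
        for a, b in children:
            members.update((a, b))
        for run in strands:
            members.update(run)
        sizes = [len(run) for run in strands]
        size = sum(sizes)
        k = len(children)
        if k == 0:
            lo, hi = config.hairpin_range
            if lo <= size <= hi:
                out.add(("HAIRPIN", size, frozenset(members)))
        elif k == 1:
            a, b = sizes
            if a >= 1 and b >= 1:
                lo, hi = config.internal_range
                if lo <= a <= hi and lo <= b <= hi:
                    out.add(("INTERNAL", size, frozenset(members)))
            elif (a == 0) != (b == 0):
                lo, hi = config.bulge_range
                if lo <= max(a, b) <= hi:
                    out.add(("BULGE", size, frozenset(members)))
        else:
            ways = k + 1
            lo_w, hi_w = config.junction_ways
            lo, hi = config.junction_strand_range
            if lo_w <= ways <= hi_w and all(lo <= s <= hi for s in sizes):
                out.add(("JUNCTION", size, frozenset(members)))
    return out


def has_crossing_pair(pairs) -> bool:
    """True iff some (i, j), (k, l) satisfy i < k < j < l."""
    for (i, j), (k, l) in combinations(sorted(pairs), 2):
        if i < k < j < l:
            return True
    return False


def brute_force_assignment_cost(similarity_matrix):
    """Minimal total 1-S cost over all one-to-one partial matchings."""
    n_a, n_b = len(similarity_matrix), len(similarity_matrix[0]) if len(similarity_matrix) else 0
    if n_a == 0 or n_b == 0:
        return 0.0
    k = min(n_a, n_b)
    best = None
    rows = list(range(n_a))
    for chosen in combinations(rows, k):
        for perm in permutations(range(n_b), k):
            cost = sum(1.0 - similarity_matrix[r][c] for r, c in zip(chosen, perm))
            if best is None or cost < best:
                best = cost
    return best


def wc_pairs_of(graph):
    """0-based WC pairs of an RNAGraph (direct edge scan)."""
    return [(a, b) for a, b, attr in graph.edges() if attr[1] == 1]
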