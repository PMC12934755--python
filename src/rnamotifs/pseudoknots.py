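"""Pseudoknot detection and six-class topological typing.

A pseudoknot exists whenever two WC pairs (i, j) and (k, l) cross
(i < k < j < l).  Detection works on the extended dot-bracket string: the
first-fit page assignment places one family of crossing pairs in square
brackets; each family's bracketed region is extended outward while it
contains brackets whose partners lie outside, and overlapping regions are
merged.

Typing is purely topological (pairing pattern, no 3D geometry).  With the
crossing pairs' left endpoints L and right endpoints R located in the
page-0 (nested) structure, the cascade is, most specific first:

* ``HHH`` — kissing hairpins: L and R lie in the loops of two distinct
  page-0 hairpins;
* ``HLIN`` — one group lies in a page-0 loop that also holds an extra
  hairpin (a multibranch loop), the other in single-stranded region;
* ``HLOUT`` — classic H geometry plus an extra page-0 hairpin in the
  single-stranded segment between the two groups;
* ``LL`` — at least one group lies in a non-hairpin loop (internal, bulge
  or junction loop);
* ``H`` — one group in a hairpin loop, the other in single-stranded region;
* ``LR`` — strict fallback for everything else (long-range / complex).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError
from .graphs import RNAGraph, assign_pages, from_dot_bracket, to_dot_bracket, without_nonwc
from .rna_io import ResidueKey

PK_CLASSES = ("H", "HHH", "HLOUT", "HLIN", "LL", "LR")


@dataclass
class PseudoknotRecord:
    span: tuple[int, int]  # 1-based inclusive
    dot_bracket: str  # over the span
    pk_class: str
    members: tuple[ResidueKey, ...]


def _pairs_with_pages(t: str) -> dict[tuple[int, int], int]:
    g = from_dot_bracket(t)
    return assign_pages(g.wc_pairs())


def find_pseudoknots(t: str) -> list[tuple[int, int]]:
    """Maximal crossing regions of an extended dot-bracket string.

    Returns merged 1-based inclusive spans; empty if the structure is
    purely nested.
    """
    pages = _pairs_with_pages(t)
    partner: dict[int, int] = {}
    for a, b in pages:
        partner[a] = b
        partner[b] = a
    page1 = sorted(pair for pair, page in pages.items() if page == 1)
    if not page1:
        return []
    # group square-bracket pairs whose intervals intersect
    families: list[list[tuple[int, int]]] = []
    for pair in page1:
        merged: list[tuple[int, int]] = [pair]
        kept = []
        for fam in families:
            lo = min(p[0] for p in fam)
            hi = max(p[1] for p in fam)
            if pair[0] <= hi and lo <= pair[1]:
                merged.extend(fam)
            else:
                kept.append(fam)
        kept.append(merged)
        families = kept
    spans = []
    for fam in families:
        s = min(p[0] for p in fam)
        e = max(p[1] for p in fam)
        # extend while a bracket's partner lies outside the span
        changed = True
        while changed:
            changed = False
            for p in range(s, e + 1):
                q = partner.get(p)
                if q is None:
                    continue
                if q < s:
                    s, changed = q, True
                elif q > e:
                    e, changed = q, True
        spans.append((s, e))
    spans.sort()
    merged_spans: list[tuple[int, int]] = []
    for s, e in spans:
        if merged_spans and s <= merged_spans[-1][1]:
            merged_spans[-1] = (merged_spans[-1][0], max(merged_spans[-1][1], e))
        else:
            merged_spans.append((s, e))
    return [(s + 1, e + 1) for s, e in merged_spans]


def _page0_context(pos: int, page0: list[tuple[int, int]]):
    """Locate a position in the nested structure.

    Returns ``("ss", None)`` outside any page-0 pair, else ``("hairpin", P)``
    or ``("multiloop", P)`` for the nearest enclosing pair P depending on
    whether P's loop holds further page-0 pairs.
    """
    enclosing = [p for p in page0 if p[0] < pos < p[1]]
    if not enclosing:
        return ("ss", None)
    nearest = max(enclosing, key=lambda p: p[0])
    has_children = any(
        nearest[0] < p[0] and p[1] < nearest[1] for p in page0 if p != nearest
    )
    return ("multiloop" if has_children else "hairpin", nearest)


def _group_context(positions: list[int], page0: list[tuple[int, int]]):
    contexts = {_page0_context(p, page0) for p in positions}
    if len(contexts) == 1:
        return contexts.pop()
    return ("mixed", None)


def classify_pseudoknot(span: tuple[int, int], g: RNAGraph) -> str:
    """Assign one of the six topological classes to a detected span."""
    t = to_dot_bracket(without_nonwc(g))
    pages = assign_pages(from_dot_bracket(t).wc_pairs())
    s, e = span[0] - 1, span[1] - 1
    crossing = [p for p, page in pages.items() if page >= 1 and s <= p[0] and p[1] <= e]
    if not crossing:
        raise ContractError(f"span {span} contains no crossing pairs")
    page0 = [p for p, page in pages.items() if page == 0]
    left = sorted(p[0] for p in crossing)
    right = sorted(p[1] for p in crossing)
    kind_l, pair_l = _group_context(left, page0)
    kind_r, pair_r = _group_context(right, page0)
    kinds = {kind_l, kind_r}

    if kind_l == kind_r == "hairpin" and pair_l != pair_r:
        return "HHH"
    if kinds == {"multiloop", "ss"}:
        return "HLIN"
    gap_lo, gap_hi = max(left), min(right)
    extra_hairpin_between = any(
        gap_lo < p[0] and p[1] < gap_hi for p in page0
    )
    if kinds == {"hairpin", "ss"} and extra_hairpin_between:
        return "HLOUT"
    if "multiloop" in kinds:
        return "LL"
    if kinds == {"hairpin", "ss"}:
        return "H"
    return "LR"


def pseudoknot_inventory(g: RNAGraph) -> list[PseudoknotRecord]:
    """Detect and classify every pseudoknot region of one RNA graph."""
    wc_view = without_nonwc(g)
    t = to_dot_bracket(wc_view)
    records = []
    keys = g.keys
    for span in find_pseudoknots(t):
        pk_class = classify_pseudoknot(span, g)
        records.append(
            PseudoknotRecord(
                span=span,
                dot_bracket=t[span[0] - 1 : span[1]],
                pk_class=pk_class,
                members=tuple(keys[span[0] - 1 : span[1]]),
            )
        )
    return records
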