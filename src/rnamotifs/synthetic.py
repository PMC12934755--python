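"""Seeded synthetic RNA structures with known ground truth.

Structures are composed from parametric elements — hairpins, internal
loops, bulges, multiway junctions and six pseudoknot topologies — laid out
left to right with unpaired spacers.  For every generated structure the
module knows:

* the exact loop-motif inventory (class, size, member set) that extraction
  over the nested pairing must return;
* the pseudoknot classes that :func:`rnamotifs.pseudoknots.pseudoknot_inventory`
  must report;
* toy 3D coordinates (a schematic ladder, one rung per planted pair at the
  naive annotator's detection distance) so the structure round-trips
  through PDB text and distance-based annotation;
* a pairing annotation text in the package's dialect.

Sequences are complementary across planted pairs and random elsewhere.
The geometry is schematic, not physically realistic: it exercises format
handling and distance thresholds, not RNA stereochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ContractError
from .graphs import RNAGraph, to_dot_bracket, without_nonwc
from .rna_io import Chain, Residue, Structure

PAIR_CHOICES = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
PAIR_DISTANCE = 10.4  # C1'-C1' angstroms, middle of the naive annotator window


@dataclass
class StructureSpec:
    """Planted motif list, e.g. ``[("HAIRPIN", {"loop": 4})]``."""

    motifs: list[tuple[str, dict]]
    nonwc_edges: int = 0
    seed: int = 0
    dangle5: int = 0
    dangle3: int = 0
    spacer: int = 2


@dataclass
class GeneratedStructure:
    spec: StructureSpec
    dot_bracket: str
    sequence: str
    graph: RNAGraph
    structure: Structure
    annotation: str
    expected_motifs: list[tuple[str, int, frozenset]]  # (class, size, ordinals)
    expected_pseudoknots: list[str]  # pk classes, 5' to 3'

    @property
    def n(self) -> int:
        return len(self.dot_bracket)


class _Builder:
    def __init__(self):
        self.n = 0
        self.pairs: list[tuple[int, int]] = []
        self.inventory: list[tuple[str, int, frozenset]] = []
        self.pk_classes: list[str] = []

    def take(self, k: int) -> list[int]:
        out = list(range(self.n, self.n + k))
        self.n += k
        return out

    def pair_up(self, opens: list[int], closes: list[int]) -> None:
        for i, a in enumerate(opens):
            self.pairs.append((a, closes[len(closes) - 1 - i]))


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ContractError(f"unrealizable spec: {message}")


def _emit_hairpin(b: _Builder, stem: int = 3, loop: int = 4, record: bool = True) -> dict:
    _require(stem >= 1, "hairpin stem must be >= 1")
    _require(1 <= loop <= 20, "hairpin loop must be 1..20")
    opens = b.take(stem)
    loop_pos = b.take(loop)
    closes = b.take(stem)
    b.pair_up(opens, closes)
    if record:
        b.inventory.append(
            ("HAIRPIN", loop, frozenset({opens[-1], closes[0], *loop_pos}))
        )
    return {"first": opens[0], "last": closes[-1]}


def _emit_internal(b: _Builder, a: int = 1, bb: int = 1, stem: int = 2, inner: dict | None = None) -> dict:
    _require(a >= 1 and bb >= 1, "internal loop strands must both be >= 1")
    inner = inner or {}
    opens = b.take(stem)
    a_pos = b.take(a)
    child = _emit_hairpin(b, **inner)
    b_pos = b.take(bb)
    closes = b.take(stem)
    b.pair_up(opens, closes)
    b.inventory.append(
        (
            "INTERNAL",
            a + bb,
            frozenset({opens[-1], closes[0], child["first"], child["last"], *a_pos, *b_pos}),
        )
    )
    return {"first": opens[0], "last": closes[-1]}


def _emit_bulge(b: _Builder, a: int = 1, stem: int = 2, side: str = "5p", inner: dict | None = None) -> dict:
    _require(a >= 1, "bulge strand must be >= 1")
    inner = inner or {}
    opens = b.take(stem)
    a_pos = b.take(a) if side == "5p" else []
    child = _emit_hairpin(b, **inner)
    if side != "5p":
        a_pos = b.take(a)
    closes = b.take(stem)
    b.pair_up(opens, closes)
    b.inventory.append(
        (
            "BULGE",
            a,
            frozenset({opens[-1], closes[0], child["first"], child["last"], *a_pos}),
        )
    )
    return {"first": opens[0], "last": closes[-1]}


def _emit_junction(
    b: _Builder,
    ways: int = 3,
    strands: list[int] | None = None,
    stem: int = 2,
    children: list[dict] | None = None,
) -> dict:
    _require(3 <= ways <= 8, "junction ways must be 3..8")
    strands = list(strands) if strands is not None else [2] * ways
    _require(len(strands) == ways, "junction needs one strand length per way")
    _require(all(0 <= s <= 20 for s in strands), "junction strands must be 0..20")
    children = children or [{}] * (ways - 1)
    _require(len(children) == ways - 1, "junction needs ways-1 child helices")
    opens = b.take(stem)
    members = {opens[-1]}
    strand_pos: list[int] = []
    for strand_len, child_params in zip(strands[:-1], children):
        strand_pos.extend(b.take(strand_len))
        child = _emit_hairpin(b, **child_params)
        members.update((child["first"], child["last"]))
    strand_pos.extend(b.take(strands[-1]))
    closes = b.take(stem)
    b.pair_up(opens, closes)
    members.add(closes[0])
    members.update(strand_pos)
    b.inventory.append(("JUNCTION", sum(strands), frozenset(members)))
    return {"first": opens[0], "last": closes[-1]}


# -- pseudoknot skeletons ----------------------------------------------------
# Inventories below describe the nested (page-0) projection, which is what
# loop-motif extraction operates on; crossing pairs are reported separately
# through the pseudoknot inventory.


def _emit_pk_h(b: _Builder, stem: int = 4, loop: int = 4, pk: int = 3, connector: int = 4) -> dict:
    _require(min(stem, loop, pk) >= 1 and connector >= 1, "H skeleton sizes must be >= 1")
    opens = b.take(stem)
    loop_pos = b.take(loop)
    pk_open = b.take(pk)
    closes = b.take(stem)
    b.take(connector)
    pk_close = b.take(pk)
    b.pair_up(opens, closes)
    b.pair_up(pk_open, pk_close)
    b.inventory.append(
        ("HAIRPIN", loop + pk, frozenset({opens[-1], closes[0], *loop_pos, *pk_open}))
    )
    b.pk_classes.append("H")
    return {"first": opens[0], "last": pk_close[-1]}


def _emit_pk_hhh(
    b: _Builder, stem: int = 3, a: int = 2, pk: int = 3, bb: int = 2, connector: int = 4,
    stem2: int = 3, d: int = 2, e: int = 2,
) -> dict:
    _require(min(stem, stem2, a, pk, bb, d, e) >= 1 and connector >= 1, "HHH sizes must be >= 1")
    opens1 = b.take(stem)
    a_pos = b.take(a)
    pk_open = b.take(pk)
    b_pos = b.take(bb)
    closes1 = b.take(stem)
    b.take(connector)
    opens2 = b.take(stem2)
    d_pos = b.take(d)
    pk_close = b.take(pk)
    e_pos = b.take(e)
    closes2 = b.take(stem2)
    b.pair_up(opens1, closes1)
    b.pair_up(opens2, closes2)
    b.pair_up(pk_open, pk_close)
    b.inventory.append(
        ("HAIRPIN", a + pk + bb, frozenset({opens1[-1], closes1[0], *a_pos, *pk_open, *b_pos}))
    )
    b.inventory.append(
        ("HAIRPIN", d + pk + e, frozenset({opens2[-1], closes2[0], *d_pos, *pk_close, *e_pos}))
    )
    b.pk_classes.append("HHH")
    return {"first": opens1[0], "last": closes2[-1]}


def _emit_pk_hlout(
    b: _Builder, stem: int = 4, loop: int = 4, pk: int = 3, c1: int = 2,
    extra_stem: int = 2, extra_loop: int = 3, c2: int = 2,
) -> dict:
    _require(min(stem, loop, pk, extra_stem, extra_loop) >= 1, "HLOUT sizes must be >= 1")
    opens = b.take(stem)
    loop_pos = b.take(loop)
    pk_open = b.take(pk)
    closes = b.take(stem)
    b.take(c1)
    _emit_hairpin(b, stem=extra_stem, loop=extra_loop)
    b.take(c2)
    pk_close = b.take(pk)
    b.pair_up(opens, closes)
    b.pair_up(pk_open, pk_close)
    b.inventory.append(
        ("HAIRPIN", loop + pk, frozenset({opens[-1], closes[0], *loop_pos, *pk_open}))
    )
    b.pk_classes.append("HLOUT")
    return {"first": opens[0], "last": pk_close[-1]}


def _emit_pk_hlin(
    b: _Builder, stem: int = 4, a: int = 2, extra_stem: int = 2, extra_loop: int = 3,
    bb: int = 2, pk: int = 3, connector: int = 4,
) -> dict:
    _require(min(stem, a, extra_stem, extra_loop, bb, pk) >= 1 and connector >= 1, "HLIN sizes must be >= 1")
    opens = b.take(stem)
    a_pos = b.take(a)
    child = _emit_hairpin(b, stem=extra_stem, loop=extra_loop)
    b_pos = b.take(bb)
    pk_open = b.take(pk)
    closes = b.take(stem)
    b.take(connector)
    pk_close = b.take(pk)
    b.pair_up(opens, closes)
    b.pair_up(pk_open, pk_close)
    b.inventory.append(
        (
            "INTERNAL",
            a + bb + pk,
            frozenset({opens[-1], closes[0], child["first"], child["last"], *a_pos, *b_pos, *pk_open}),
        )
    )
    b.pk_classes.append("HLIN")
    return {"first": opens[0], "last": pk_close[-1]}


def _emit_pk_ll(
    b: _Builder, stem: int = 3, a: int = 2, pk: int = 2, bb: int = 2,
    child_stem: int = 2, child_loop: int = 3, c: int = 2, connector: int = 3,
    stem2: int = 3, e: int = 2, f: int = 2,
) -> dict:
    _require(min(stem, stem2, a, pk, bb, child_stem, child_loop, c, e, f) >= 1, "LL sizes must be >= 1")
    opens1 = b.take(stem)
    a_pos = b.take(a)
    pk_open = b.take(pk)
    b_pos = b.take(bb)
    child = _emit_hairpin(b, stem=child_stem, loop=child_loop)
    c_pos = b.take(c)
    closes1 = b.take(stem)
    b.take(connector)
    opens2 = b.take(stem2)
    e_pos = b.take(e)
    pk_close = b.take(pk)
    f_pos = b.take(f)
    closes2 = b.take(stem2)
    b.pair_up(opens1, closes1)
    b.pair_up(opens2, closes2)
    b.pair_up(pk_open, pk_close)
    b.inventory.append(
        (
            "INTERNAL",
            a + pk + bb + c,
            frozenset(
                {opens1[-1], closes1[0], child["first"], child["last"],
                 *a_pos, *pk_open, *b_pos, *c_pos}
            ),
        )
    )
    b.inventory.append(
        ("HAIRPIN", e + pk + f, frozenset({opens2[-1], closes2[0], *e_pos, *pk_close, *f_pos}))
    )
    b.pk_classes.append("LL")
    return {"first": opens1[0], "last": closes2[-1]}


def _emit_pk_lr(
    b: _Builder, stem: int = 3, pk: int = 2, loop_pad: int = 2, connector: int = 3,
) -> dict:
    """Chained kissing interaction across three hairpin loops (falls through
    the specific classes to the long-range fallback)."""
    _require(min(stem, pk, loop_pad) >= 1 and connector >= 1, "LR sizes must be >= 1")
    opens1 = b.take(stem)
    a_pos = b.take(loop_pad)
    pka_open = b.take(pk)
    b_pos = b.take(loop_pad)
    closes1 = b.take(stem)
    b.take(connector)
    opens2 = b.take(stem)
    c_pos = b.take(loop_pad)
    pka_close = b.take(pk)
    d_pos = b.take(loop_pad)
    pkb_open = b.take(pk)
    e_pos = b.take(loop_pad)
    closes2 = b.take(stem)
    b.take(connector)
    opens3 = b.take(stem)
    f_pos = b.take(loop_pad)
    pkb_close = b.take(pk)
    g_pos = b.take(loop_pad)
    closes3 = b.take(stem)
    b.pair_up(opens1, closes1)
    b.pair_up(opens2, closes2)
    b.pair_up(opens3, closes3)
    b.pair_up(pka_open, pka_close)
    b.pair_up(pkb_open, pkb_close)
    b.inventory.append(
        ("HAIRPIN", 2 * loop_pad + pk, frozenset({opens1[-1], closes1[0], *a_pos, *pka_open, *b_pos}))
    )
    b.inventory.append(
        (
            "HAIRPIN",
            3 * loop_pad + 2 * pk,
            frozenset({opens2[-1], closes2[0], *c_pos, *pka_close, *d_pos, *pkb_open, *e_pos}),
        )
    )
    b.inventory.append(
        ("HAIRPIN", 2 * loop_pad + pk, frozenset({opens3[-1], closes3[0], *f_pos, *pkb_close, *g_pos}))
    )
    b.pk_classes.append("LR")
    return {"first": opens1[0], "last": closes3[-1]}


_PK_EMITTERS = {
    "H": _emit_pk_h,
    "HHH": _emit_pk_hhh,
    "HLOUT": _emit_pk_hlout,
    "HLIN": _emit_pk_hlin,
    "LL": _emit_pk_ll,
    "LR": _emit_pk_lr,
}

_EMITTERS = {
    "HAIRPIN": _emit_hairpin,
    "INTERNAL": _emit_internal,
    "BULGE": _emit_bulge,
    "JUNCTION": _emit_junction,
}


def generate(spec: StructureSpec) -> GeneratedStructure:
    """Realize a spec as sequence, graph, toy coordinates and ground truth."""
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    b.take(spec.dangle5)
    for i, (motif_class, params) in enumerate(spec.motifs):
        if i > 0:
            b.take(spec.spacer)
        params = dict(params)
        if motif_class == "PSEUDOKNOT":
            pk_class = params.pop("pk_class")
            if pk_class not in _PK_EMITTERS:
                raise ContractError(f"unknown pseudoknot class {pk_class!r}")
            _PK_EMITTERS[pk_class](b, **params)
        elif motif_class in _EMITTERS:
            _EMITTERS[motif_class](b, **params)
        else:
            raise ContractError(f"unknown motif class {motif_class!r}")
    b.take(spec.dangle3)
    n = b.n
    _require(n > 0, "empty structure")

    # sequence: complementary across pairs, random elsewhere
    bases = [None] * n
    for a, c in b.pairs:
        ba, bc = PAIR_CHOICES[rng.integers(len(PAIR_CHOICES))]
        bases[a], bases[c] = ba, bc
    for i in range(n):
        if bases[i] is None:
            bases[i] = "AUGC"[rng.integers(4)]
    sequence = "".join(bases)

    # non-WC decorations: random non-adjacent, non-WC-paired position pairs
    wc_set = {frozenset(p) for p in b.pairs}
    nonwc: list[tuple[int, int]] = []
    attempts = 0
    while len(nonwc) < spec.nonwc_edges and attempts < 200 * (spec.nonwc_edges + 1):
        attempts += 1
        i, j = sorted(rng.integers(0, n, size=2).tolist())
        if j - i < 2 or frozenset((i, j)) in wc_set or (i, j) in nonwc:
            continue
        nonwc.append((i, j))
    _require(len(nonwc) == spec.nonwc_edges, "could not place the requested non-WC edges")

    g = nx.Graph()
    for i in range(n):
        g.add_node(i, key=("A", i + 1, ""), base=bases[i])
    for i in range(n - 1):
        g.add_edge(i, i + 1, attr=(1, 0, 0))
    for a, c in b.pairs:
        g.add_edge(a, c, attr=(0, 1, 0))
    for a, c in nonwc:
        if g.has_edge(a, c):
            attr = g.edges[a, c]["attr"]
            g.edges[a, c]["attr"] = (attr[0], attr[1], 1)
        else:
            g.add_edge(a, c, attr=(0, 0, 1))
    graph = RNAGraph(g)
    dot_bracket = to_dot_bracket(without_nonwc(graph))

    structure = _toy_structure(b, bases, n)
    annotation_lines = [f"A{a + 1}-A{c + 1} : WC" for a, c in sorted(b.pairs)]
    annotation_lines += [f"A{a + 1}-A{c + 1} : NONWC" for a, c in sorted(nonwc)]

    return GeneratedStructure(
        spec=spec,
        dot_bracket=dot_bracket,
        sequence=sequence,
        graph=graph,
        structure=structure,
        annotation="\n".join(annotation_lines) + ("\n" if annotation_lines else ""),
        expected_motifs=sorted(b.inventory, key=lambda m: sorted(m[2])),
        expected_pseudoknots=list(b.pk_classes),
    )


def _toy_structure(b: _Builder, bases: list[str], n: int) -> Structure:
    """Schematic ladder: one rung per planted pair at the detection distance,
    unpaired nucleotides far off to the side."""
    coords: dict[int, tuple[float, float, float]] = {}
    for k, (a, c) in enumerate(sorted(b.pairs)):
        coords[a] = (0.0, 30.0 * k, 0.0)
        coords[c] = (PAIR_DISTANCE, 30.0 * k, 0.0)
    for i in range(n):
        if i not in coords:
            coords[i] = (500.0 + 30.0 * i, 0.0, 0.0)
    chain = Chain(chain_id="A")
    for i in range(n):
        x, y, z = coords[i]
        chain.residues.append(
            Residue(
                key=("A", i + 1, ""),
                base=bases[i],
                atoms=[
                    ("P", x - 1.0, y + 0.5, z),
                    ("C1'", x, y, z),
                    ("N1", x + 0.8, y - 0.4, z + 0.3),
                ],
            )
        )
    return Structure(structure_id="synthetic", chains=[chain], source_format="PDB")


# ---------------------------------------------------------------------------
# suites


def random_spec(rng: np.random.Generator, allow_pseudoknots: bool = True) -> StructureSpec:
    motifs: list[tuple[str, dict]] = []
    for _ in range(int(rng.integers(1, 4))):
        choice = rng.integers(0, 5 if allow_pseudoknots else 4)
        if choice == 0:
            motifs.append(("HAIRPIN", {"loop": int(rng.integers(1, 21)), "stem": int(rng.integers(1, 4))}))
        elif choice == 1:
            motifs.append(
                ("INTERNAL", {"a": int(rng.integers(1, 7)), "bb": int(rng.integers(1, 7)),
                              "stem": int(rng.integers(1, 4)),
                              "inner": {"loop": int(rng.integers(1, 9)), "stem": int(rng.integers(1, 3))}})
            )
        elif choice == 2:
            motifs.append(
                ("BULGE", {"a": int(rng.integers(1, 7)), "stem": int(rng.integers(1, 4)),
                           "side": "5p" if rng.random() < 0.5 else "3p",
                           "inner": {"loop": int(rng.integers(1, 9)), "stem": int(rng.integers(1, 3))}})
            )
        elif choice == 3:
            ways = int(rng.integers(3, 7))
            motifs.append(
                ("JUNCTION", {"ways": ways,
                              "strands": [int(rng.integers(0, 7)) for _ in range(ways)],
                              "stem": int(rng.integers(1, 3)),
                              "children": [{"loop": int(rng.integers(1, 7)), "stem": int(rng.integers(1, 3))}
                                           for _ in range(ways - 1)]})
            )
        else:
            pk_class = list(_PK_EMITTERS)[rng.integers(len(_PK_EMITTERS))]
            motifs.append(("PSEUDOKNOT", {"pk_class": pk_class}))
    return StructureSpec(
        motifs=motifs,
        nonwc_edges=int(rng.integers(0, 4)),
        seed=int(rng.integers(0, 2**31 - 1)),
        dangle5=int(rng.integers(0, 4)),
        dangle3=int(rng.integers(0, 4)),
        spacer=int(rng.integers(1, 4)),
    )


def random_suite(n: int, seed: int) -> list[GeneratedStructure]:
    """Reproducible suite spanning all motif classes, hairpin sizes 1-20,
    junction ways 3-8, the six pseudoknot classes, and non-WC decorations."""
    if n < 1:
        raise ContractError("n must be >= 1")
    rng = np.random.default_rng(seed)
    quota_specs: list[StructureSpec] = []
    for loop in range(1, 21):
        quota_specs.append(StructureSpec(motifs=[("HAIRPIN", {"loop": loop})], seed=int(rng.integers(2**31))))
    for ways in range(3, 9):
        quota_specs.append(
            StructureSpec(
                motifs=[("JUNCTION", {"ways": ways, "strands": [2] * ways,
                                      "children": [{} for _ in range(ways - 1)]})],
                seed=int(rng.integers(2**31)),
            )
        )
    for pk_class in _PK_EMITTERS:
        quota_specs.append(
            StructureSpec(motifs=[("PSEUDOKNOT", {"pk_class": pk_class})], seed=int(rng.integers(2**31)))
        )
    for params in ({"a": 1, "bb": 1}, {"a": 2, "bb": 3}, {"a": 4, "bb": 1}, {"a": 1, "bb": 2}, {"a": 3, "bb": 3}):
        quota_specs.append(StructureSpec(motifs=[("INTERNAL", dict(params))], seed=int(rng.integers(2**31))))
    for a in (1, 2, 3, 4, 5):
        quota_specs.append(
            StructureSpec(motifs=[("BULGE", {"a": a})], nonwc_edges=a % 3, seed=int(rng.integers(2**31)))
        )
    specs = quota_specs[:n]
    while len(specs) < n:
        specs.append(random_spec(rng))
    return [generate(spec) for spec in specs]


def small_suite(seed: int = 0) -> list[GeneratedStructure]:
    """Compact structures (<= 25 nt) for exhaustive cross-checks."""
    specs = [
        StructureSpec(motifs=[("HAIRPIN", {"loop": loop, "stem": stem})], seed=seed + loop * 10 + stem)
        for loop in (1, 2, 4, 6)
        for stem in (1, 2, 3)
    ]
    specs += [
        StructureSpec(motifs=[("INTERNAL", {"a": 1, "bb": 1, "stem": 1, "inner": {"stem": 1, "loop": 3}})], seed=seed),
        StructureSpec(motifs=[("INTERNAL", {"a": 2, "bb": 1, "stem": 2, "inner": {"stem": 1, "loop": 4}})], seed=seed + 1),
        StructureSpec(motifs=[("BULGE", {"a": 1, "stem": 1, "inner": {"stem": 1, "loop": 3}})], seed=seed + 2),
        StructureSpec(motifs=[("BULGE", {"a": 3, "stem": 2, "side": "3p", "inner": {"stem": 1, "loop": 3}})], seed=seed + 3),
        StructureSpec(
            motifs=[("JUNCTION", {"ways": 3, "strands": [1, 2, 1], "stem": 1,
                                  "children": [{"stem": 1, "loop": 3}, {"stem": 1, "loop": 3}]})],
            seed=seed + 4,
        ),
        StructureSpec(
            motifs=[("JUNCTION", {"ways": 3, "strands": [0, 0, 0], "stem": 1,
                                  "children": [{"stem": 1, "loop": 3}, {"stem": 1, "loop": 3}]})],
            seed=seed + 5,
        ),
        StructureSpec(motifs=[("HAIRPIN", {"loop": 4})], dangle5=2, dangle3=3, seed=seed + 6),
        StructureSpec(motifs=[("HAIRPIN", {"loop": 3, "stem": 1}), ("HAIRPIN", {"loop": 3, "stem": 1})], spacer=2, seed=seed + 7),
        StructureSpec(motifs=[("PSEUDOKNOT", {"pk_class": "H", "stem": 2, "loop": 2, "pk": 2, "connector": 2})], seed=seed + 8),
    ]
    return [generate(spec) for spec in specs]
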