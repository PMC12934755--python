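# Methods

This note documents the models, algorithms and numerical choices behind
`rnamotifs`, and what the synthetic test conditions do and do not show
about real structures.

## Structure normalization

Coordinate files (PDB, mmCIF) are reduced to a `Structure`: ordered chains
of residues keyed by `(chain, author number, insertion code)`. Rules
applied on read:

* **First model only.** Multi-model (NMR) inputs keep model 1; ensembles
  add conformational redundancy without adding motif topology.
* **Single-character chains.** Multi-character chain identifiers (common
  in mmCIF assemblies) are remapped to the first unused symbol in
  `A–Z a–z 0–9`, in encounter order; more than 62 chains is a capacity
  error. The remap table is kept on the structure.
* **Serial overflow.** Atom serial fields that overflow the fixed PDB
  columns (≥100000) are tolerated by a whitespace-tokenized fallback;
  serials are ignored on input and re-sequenced from 1 on output.
* **Modified nucleotides.** Residues other than A/U/G/C are kept with
  base `OTHER`; a chain counts as RNA if it has at least one standard
  nucleotide. Hetero-residues inside RNA chains therefore become graph
  nodes — a deliberate choice where the alternative (dropping them) would
  break backbone runs.

Base-pair annotations are consumed from a one-pair-per-line dialect
(`A1-A8 : WC`, types `WC`/`NONWC`); production annotations from an
external tool can be adapted to this seam. Chain-adjacent residues always
contribute covalent interactions, independent of the pairing lines. The
built-in `naive_annotate` is *fixture-grade*: it pairs complementary bases
(A-U, G-C, G-U) whose C1'–C1' distance falls in 8.5–12.0 Å, greedily by
distance, one partner per residue. The window brackets the ~10.4 Å
C1'–C1' separation of paired nucleotides; the generator places rungs at
exactly that distance, so synthetic structures round-trip exactly. It is
not a substitute for geometric base-pair annotation of real structures
(no edge/face typing, no non-WC calls).

## Graphs and compression

`RNAGraph` nodes are nucleotides with ordinal indices along the
concatenated chains; edges carry a 3-component indicator
`(COVALENT, WC, NONWC)`, multi-hot when a pair interacts in more than one
way. Graph equality is label-preserving (same keys, same edges), not
isomorphism — round-trip guarantees are exact, not up to relabeling.

`compress` replaces every maximal run of unpaired nucleotides *between
two retained nucleotides of the same chain* with one super-edge holding
the run's labels (weight = run length). Chain-terminal dangling runs are
retained as plain nodes: loop motifs are flanked by structure on both
sides, so dangling ends can never be motif members, and excluding them
keeps decompression trivially exact. `decompress ∘ compress` is the
identity on every without-non-WC graph.

Dot-bracket conversion assigns crossing pair families to bracket pages by
first-fit interval coloring ordered by left endpoint: `()`, `[]`, `{}`,
`<>`. Four pages suffice for every structure the package generates;
beyond that the conversion fails loudly rather than silently mislabeling.
The inverse parser rejects unbalanced pages with the offending position.

## Motif search

On the compressed graph, each loop motif class is one alternating cycle
of WC closing-pair edges and strand edges:

| class | WC pairs | strand ranges |
|---|---|---|
| hairpin | 1 | 1–20 |
| internal loop | 2 | 1–20 each |
| bulge | 2 | 1–20 and exactly 0 |
| n-way junction | n = 3…8 | 0–20 each |

A strand edge of range [lo, hi] matches a super-edge of weight w iff
lo ≤ w ≤ hi, and a plain covalent edge iff lo = 0 (empty strands, as in
coaxially stacked junctions). The hairpin bound of 20 reflects the
thermodynamic instability of larger loops; junction strand bounds default
to 0–20 since no principled upper bound exists. Matching is a bespoke
backtracking monomorphism search with per-edge predicates (parallel
pattern edges — a closing pair plus its loop — are assigned injectively).
Embeddings are decompressed and deduplicated by (class, member set);
size is the unpaired-nucleotide count, members include the closing pairs.
The field counts a "1-1 internal loop" sometimes as 2 (unpaired) and
sometimes as 6 (with closing pairs); the package reports `size = 2` and
exposes `n_members = 6` separately.

**Crossing pairs are projected out before loop-motif search.** A
pseudoknot's crossing helices form alternating cycles that are
graph-indistinguishable from loop motifs (a depth-1 H-knot *is* a 4-cycle
of two WC pairs and two strands, i.e. an internal loop; deeper knots
produce junction-like cycles through helix interiors). Loop motifs are
therefore defined on the nested (page-0) pairing, and crossing pairs are
routed to the pseudoknot module — the two inventories partition the
structure's pairing information. Non-WC edges are likewise excluded from
search (they multiply pattern count without changing loop topology) but
are restored in each match's with-non-WC view.

`custom_search` is the user-defined variant: exact node-level
monomorphism with attribute-vector equality, non-WC edges allowed in the
query, no compression, queries capped at 30 nodes.

## Pseudoknot typing

Detection: square-bracket (page-1) families are grouped by interval
intersection; each family's span is extended while it contains a bracket
whose partner lies outside, and overlapping spans merge. A span exists
iff the pairing contains a crossing pair (i < k < j < l).

Typing is a deterministic cascade on where the crossing pairs' left (L)
and right (R) endpoint groups sit in the nested structure — inside a
hairpin loop (innermost page-0 pair), inside a multibranch loop (page-0
pair with children), in single-stranded region, or mixed across regions:

1. **HHH** — L and R in hairpin loops of two distinct stems.
2. **HLin** — one group in a loop that also holds an extra hairpin, the
   other single-stranded.
3. **HLout** — hairpin-loop/single-strand geometry with an extra page-0
   hairpin in the segment between the groups.
4. **LL** — any group in a non-hairpin loop (internal/bulge/junction).
5. **H** — hairpin-loop/single-strand geometry, no decoration.
6. **LR** — strict fallback (including mixed-context groups, e.g. chained
   kissing interactions).

Most-specific-first ordering prevents H from swallowing its decorated
variants. The six classes are defined in the literature pictorially; this
cascade is the package's operationalization, and LR is intentionally the
only unreachable-by-rule class. Classification uses pairing topology
only — no 3D geometry, no sequence — and is invariant to padding the
structure with external unpaired nucleotides.

## Catalog and conformation classes

The store is one SQLite file (schema versioned) with the occurrence-level
row: motif id, class, source structure id, size, member keys, both graph
JSON views, coordinate reference. Identical motifs recurring across
structures are kept as separate occurrences — the library counts
occurrences, not unique shapes.

Conformation classification partitions a (class, size) bin by *exact*
attribute-isomorphism of the with-non-WC graphs. The canonical key is
computed by iterative color refinement on (color, sorted incident
(edge-attribute, neighbor-color)) signatures, with
individualization-refinement branching on the first non-singleton color
class and the lexicographically minimal adjacency serialization taken
over branches. This is exponential in the worst case but motif graphs are
small (tens of nodes) and highly asymmetric; a heuristic hash would risk
merging distinct conformations, which defeats the purpose of the
classification. The partition is independent of insertion order, and
node relabelings never change the key.

## MBRS

Motif-motif similarity is a WL subtree kernel: initial node label = the
sorted multiset of incident edge-attribute vectors; 3 refinement rounds
(more rounds saturate on graphs this small); feature counts from all
rounds; cosine normalization. The kernel is symmetric, relabeling
invariant, 1 on identical graphs.

RNA-level aggregation uses the conventions: matched-pair weight
W<sub>m,σ(m)</sub> = (W<sub>m</sub> + W<sub>σ(m)</sub>)/2 and denominator
= total motif weight of both RNAs, which together force RS(x, x) = 1 and
RS ∈ [0, 1]; the motif weight is W = L·(1 + NC), i.e. non-WC-rich motifs
dominate the average. Unmatched motifs contribute only denominator
dilution — no extra penalty. The assignment stage minimizes Σ(1 − S) by
rectangular linear sum assignment (scipy); Leiden clustering runs on the
dense weighted similarity graph with no thresholding (resolution exposed,
default 1.0), and the cluster meta-graph keeps clusters with more than 10
members. The family contrast is a two-sided Mann-Whitney U test.

## Evolution model

Domain: s ∈ [s_min, 1], default s_min = 0.01, reflecting boundaries —
the s^(−1/2) density is integrable at 0 but its drift −D/(2s) diverges,
so a lower cutoff is required; similarity is bounded above by 1. D
defaults to 1 (time units arbitrary; only the steady state is fitted).

* `stationary_density`: trapezoid quadrature of ∫A/D on the grid,
  exponentiation (max-shifted), normalization to unit mass. Geometric
  grids resolve the small-s region: 2·10⁴ points give the s^(−1/2)
  solution to ~10⁻⁸ relative.
* `fit_power_law`: least-squares slope of log f vs log s; sample input is
  binned into 50 log-spaced bins first; the lowest/highest 5% of the
  s-range are excluded to avoid boundary-layer bias (both exposed as
  parameters).
* `drift_from_density`: A = D f′/f with central differences; exact to
  ~10⁻⁶ relative on smooth densities over a 4000-point geometric grid.
  The round trip drift → density → drift recovers smooth drifts bounded
  away from zero to well under 0.5% relative error (relative error is
  ill-defined where A crosses zero).
* `simulate`: Euler-Maruyama, s ← s + A(s)·dt + √(2·D·dt)·ξ, reflecting
  folds at both boundaries; a step-size guard rejects |A|·dt exceeding
  the domain width. With dt = 10⁻⁴, 10⁵ walkers and 10⁴ steps the
  long-run histogram reproduces the −1/2 exponent to a few times 10⁻²
  (these sizes keep the check well inside a few CPU-minutes while the
  statistical error, ~σ/√n, is far below the acceptance band).

## Synthetic data: what it shows and what it does not

The generator composes parametric elements left-to-right with unpaired
spacers, so every structure's loop-motif inventory and pseudoknot classes
are known by construction (for pseudoknot skeletons, the loop inventory
is derived on the nested projection, consistent with the extraction
pipeline). Defaults span the conditions the package targets: hairpin
loops 1–20, junctions 3–8 ways, strand lengths 0–20, all six pseudoknot
topologies, 0–3 non-WC decorations per structure. Sequences are
complementary across planted pairs and uniform elsewhere; coordinates are
a schematic ladder at the naive annotator's detection distance.

Passing the planted-recovery and oracle-equivalence suites therefore
demonstrates the *combinatorial* correctness of compression, matching,
decompression and typing over the realizable topology space. It does not
demonstrate geometric robustness on experimental coordinates: real
base-pair annotation (with its non-WC calls, modified residues and
borderline geometries) is delegated to external annotation tools via the
text dialect, and the distance annotator is explicitly fixture-grade.
Library-scale statistics (type shares, size distributions over an entire
structure archive) exercise the same code paths but are not reproduced at
desk scale.

## Degenerate inputs and tie-breaks

* Empty annotation → backbone-only graph; single-residue chains → one
  node, no edges; unstructured strands → no motifs, no spans.
* A residue pair with several annotation lines accumulates one multi-hot
  edge; exact attribute equality in matching means a WC+covalent edge is
  not a plain WC edge.
* Similarity of two motif-free RNAs is undefined (error); one-sided
  emptiness scores 0.
* Conformation-class ties (equal frequency) order by canonical key;
  motif matches order by member ordinals; page assignment ties resolve
  by left endpoint.
* `fit_power_law` refuses nonpositive densities inside the fit range;
  `stationary_density` refuses non-normalizable masses; `simulate`
  refuses divergent steps.
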