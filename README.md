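# rnamotifs

Graph-based extraction and analysis of RNA 3D structural motifs.

Recurrent structural elements — hairpin loops, internal loops, bulges,
multiway junctions and pseudoknots — are the building blocks of RNA
architecture and the raw material of motif-based 3D structure prediction
and design. `rnamotifs` is a toolkit for building and querying a motif
library from RNA coordinate files: it represents each RNA as an attributed
nucleotide-level graph, finds motifs by subgraph isomorphism over
compressed graphs, types pseudoknots topologically, scores motif-based RNA
similarity, and models how the distribution of pairwise similarity could
arise from evolution.

## What it does

**Graphs.** Nucleotides are nodes; edges carry a one-hot (or multi-hot)
indicator over three interaction types: covalent backbone, Watson-Crick
(WC) pairs and non-Watson-Crick (non-WC) base-base interactions. Every
motif is kept in two views, with and without non-WC edges.

**Compression-accelerated motif search.** Subgraph isomorphism is
NP-complete, and enumerating one pattern per loop size explodes
combinatorially. Instead, runs of consecutive unpaired nucleotides are
collapsed into single weighted *super-edges* carrying the collapsed
labels, so a single ranged pattern per motif class (hairpin loops of 1–20
unpaired nucleotides; internal loops; bulges; 3- to 8-way junctions)
matches all sizes at once. Matches are decompressed back to full member
sets; compression is exactly invertible.

**Pseudoknots.** Crossing pair families are located in extended
dot-bracket notation (square-bracket regions, extended while partners lie
outside, merged when overlapping) and typed into six topological classes —
H, HHH (kissing hairpins), HLout, HLin, LL, and LR as the fallback for
complex long-range knots.

**Catalog.** Motif occurrences live in a single-file SQLite store (id,
class, source structure, size, members, both graph views) with CSV/ZIP
export, and are partitioned into unique conformations by exact
attribute-isomorphism of their with-non-WC graphs — one non-WC pair is
enough to separate two otherwise identical tetraloops.

**Motif-based RNA similarity (MBRS).** Motif-motif similarity
S<sub>m,n</sub> is a Weisfeiler-Lehman subtree kernel with
edge-attribute-aware labels, cosine-normalized to [0, 1]. Inventories are
matched one-to-one by linear sum assignment on cost 1 − S, and aggregated
as

&nbsp;&nbsp;&nbsp;&nbsp;RS<sub>i,j</sub> = 2 Σ<sub>m</sub> W<sub>m,σ(m)</sub> S<sub>m,σ(m)</sub> / (W<sub>i</sub> + W<sub>j</sub>),&nbsp;&nbsp;&nbsp; W<sub>m</sub> = L<sub>m</sub> (1 + NC<sub>m</sub>)

with L<sub>m</sub> the motif's nucleotide count and NC<sub>m</sub> its
non-WC pair count, so RS ∈ [0, 1] and RS(x, x) = 1. Pairwise RS matrices
are clustered with the Leiden algorithm; intra- vs inter-family contrasts
use the Mann-Whitney U test.

**Similarity evolution.** The density f(s, t) of pairwise similarity s is
modeled by a drift-diffusion (Fokker-Planck) equation
∂f/∂t = −∂/∂s [A(s) f] + D ∂²f/∂s², where drift captures systematic change
(motif swapping) and diffusion random change (mutation). The stationary
solution is f(s) ∝ exp((1/D)∫A ds); the drift A(s) = −D/(2s) yields the
power law f(s) ∝ s<sup>−1/2</sup>, and the module computes stationary
densities, fits power-law exponents, inverts densities back to drifts and
runs Euler-Maruyama simulations.

**Synthetic structures.** A seeded generator plants arbitrary combinations
of motifs and pseudoknot topologies with exactly known inventories,
complementary sequences, schematic 3D coordinates and annotation text —
every other module is testable without downloading a single structure.

## Worked example

```python
from rnamotifs import StructureSpec, extract_motifs, generate

spec = StructureSpec(
    motifs=[("INTERNAL", {"a": 1, "bb": 1, "inner": {"loop": 4}}),
            ("JUNCTION", {"ways": 3, "strands": [2, 3, 3], "children": [{}, {}]})],
    seed=11,
)
gs = generate(spec)
print(gs.dot_bracket)
for m in extract_motifs(gs.graph, structure_id="example"):
    print(m.motif_class, m.size, m.n_members)
```

prints

```
((.(((....))).))..((..(((....)))...(((....)))...))
INTERNAL 2 6
HAIRPIN 4 6
JUNCTION 8 14
HAIRPIN 4 6
HAIRPIN 4 6
```

The 1-1 internal loop has size 2 — the smallest internal loop possible —
because size counts unpaired nucleotides only, while its 6 members include
the two closing WC pairs. The three-way junction's size 8 is the sum of
its strand lengths (2+3+3), and each branch helix ends in a tetraloop.

Longer narrative scripts live in `examples/` (one per capability:
extraction, pseudoknot typing, the catalog, MBRS similarity/clustering,
and the evolution model). A thin CLI mirrors the library:
`rnamotifs extract --in structure.pdb --annotation pairs.txt`,
`rnamotifs pseudoknots ...`, `rnamotifs db {load,query,classify}`,
`rnamotifs cluster`, `rnamotifs evolve {stationary,fit,simulate}`,
`rnamotifs fixtures`.

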