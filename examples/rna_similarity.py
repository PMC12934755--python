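"""Motif-based RNA similarity (MBRS), clustering and the family contrast.

Extracts motif inventories from three synthetic RNAs (two sharing their
architecture), scores all pairs with the weighted WL-kernel similarity,
then shows Leiden clustering of a planted two-block similarity matrix and a
Mann-Whitney comparison of intra- vs inter-family score samples.
"""

import numpy as np

from rnamotifs import (
    MotifFeature,
    StructureSpec,
    cluster,
    extract_motifs,
    family_comparison,
    generate,
    rna_similarity,
)

architectures = {
    "rna_a": [("HAIRPIN", {"loop": 4}), ("INTERNAL", {"a": 1, "bb": 1})],
    "rna_b": [("HAIRPIN", {"loop": 4}), ("INTERNAL", {"a": 1, "bb": 1})],
    "rna_c": [("JUNCTION", {"ways": 4, "strands": [2, 2, 2, 2], "children": [{}, {}, {}]})],
}
inventories = {
    name: [MotifFeature.from_match(m)
           for m in extract_motifs(generate(StructureSpec(motifs=arch, seed=i)).graph)]
    for i, (name, arch) in enumerate(architectures.items())
}
names = list(inventories)
for i, a in enumerate(names):
    for b in names[i + 1:]:
        rs = rna_similarity(inventories[a], inventories[b])
        print(f"RS({a}, {b}) = {rs.score:.3f}  ({len(rs.assignment)} matched motif pairs)")
print("shared architecture scores 1.0; the junction-only RNA scores lower.\n")

rng = np.random.default_rng(0)
m = np.full((30, 30), 0.1)
m[:15, :15] = m[15:, 15:] = 0.9
noise = rng.normal(0, 0.02, size=m.shape)
m = np.clip(m + (noise + noise.T) / 2, 0.01, 1.0)
np.fill_diagonal(m, 1.0)
labels, meta = cluster(m, seed=0)
print(f"Leiden on a planted 15+15 block matrix: {len(set(labels.tolist()))} clusters,"
      f" meta-graph nodes {sorted(d['size'] for _, d in meta.nodes(data=True))}")

intra = np.clip(rng.normal(0.6, 0.1, 50), 0, 1)
inter = np.clip(rng.normal(0.3, 0.1, 50), 0, 1)
u, p = family_comparison(intra, inter)
print(f"Mann-Whitney intra vs inter family: U = {u:.0f}, p = {p:.2e} (p < 0.05)")
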