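"""Store motifs in the relational catalog and classify conformations.

Non-WC decorations distinguish otherwise identical tetraloops: the catalog
partitions each (class, size) bin into exact attribute-isomorphism classes
and reports their frequencies, plus class shares and the CSV export.
"""

from rnamotifs import (
    MotifRow,
    MotifStore,
    classify_conformations,
    distributions,
    export_csv,
    extract_motifs,
    from_dot_bracket,
)


def tetraloop(nonwc_pairs=()):
    """GNRA-style tetraloop graph; non-WC pairs decorate the loop."""
    g = from_dot_bracket("((....))", sequence="GCGAAAGC")
    for a, b in nonwc_pairs:
        g.graph.add_edge(a, b, attr=(0, 0, 1))
    return g


# seven plain tetraloops, three with one loop-internal non-WC pair, two with two
variants = [tetraloop()] * 7 + [tetraloop([(2, 5)])] * 3 + [tetraloop([(2, 5), (3, 6)])] * 2
store = MotifStore()  # in-memory SQLite; pass a path for a persistent file
for i, g in enumerate(variants):
    (m,) = extract_motifs(g, structure_id=f"syn{i:02d}")
    store.store_motifs([MotifRow.from_match(m, motif_id=i + 1)])

print("tetraloop conformation classes (frequency-sorted):")
for c in classify_conformations(store, "HAIRPIN", 4):
    print(f"  frequency {c.frequency:>2}  key {c.canonical_key[:44]}...")

shares, hists = distributions(store)
print("\nclass shares (%):")
print(shares.to_string())
print("\nhairpin size histogram:")
print(hists["HAIRPIN"].to_string())
print("\nCSV export (first 4 rows):")
print("\n".join(export_csv(store.query_motifs(motif_class="HAIRPIN", size=4)).splitlines()[:5]))
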