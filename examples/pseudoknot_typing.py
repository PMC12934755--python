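"""Detect and type pseudoknots from extended dot-bracket topology.

Builds one canonical structure per pseudoknot class and shows the detected
span and assigned type; crossing pairs are rendered as square brackets.
"""

from rnamotifs import PK_CLASSES, StructureSpec, generate, pseudoknot_inventory

for pk_class in PK_CLASSES:
    gs = generate(StructureSpec(motifs=[("PSEUDOKNOT", {"pk_class": pk_class})], seed=1))
    (rec,) = pseudoknot_inventory(gs.graph)
    print(f"{rec.pk_class:<6} span={rec.span[0]:>3}..{rec.span[1]:<3}  {gs.dot_bracket}")
print()
print("H pairs a hairpin loop with downstream single strand; HHH is the")
print("kissing-hairpin interaction; HLOUT/HLIN add an extra hairpin outside/")
print("inside the knotted loop; LL involves a non-hairpin loop; LR is the")
print("fallback for complex long-range topologies.")
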