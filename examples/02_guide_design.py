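"""Scan an amplicon for protospacers and name guides around a target codon.

Finds every 20-nt protospacer followed by an NGG PAM on either strand,
names each by its distance from an anchor codon (L/R for left/right of
the anchor, a leading "t" for template-strand protospacers), and
annotates an example substitution for its codon change and nearest
feature.
"""

import numpy as np

from dbeprof import ReferenceAmplicon, annotate_mutations, find_protospacers, gc_content, name_guide

rng = np.random.default_rng(4)
seq = "".join(rng.choice(list("ACGT"), 180))
ref = ReferenceAmplicon(
    "orf", seq, orf_offset=0,
    anchors={"target_codon": 90},
    features={"loop1": (30, 54), "loop2": (96, 120)},
)

hits = find_protospacers(ref)
anchor = ref.anchors["target_codon"]
print(f"GC content: {gc_content(seq):.2f}")
print(f"{len(hits)} protospacer candidates; nearest five to the anchor:")
for g in sorted(hits, key=lambda g: abs(g.pam3_pos - anchor))[:5]:
    print(f"  {name_guide(g, anchor):>6}  strand={g.protospacer_strand:<8} "
          f"PAM 3' at {g.pam3_pos}")

pos = 100
ann = annotate_mutations([(pos, seq[pos], "A" if seq[pos] != "A" else "G")], ref)[0]
print(f"substitution at {ann.position}: {ann.ref}->{ann.alt}, codon {ann.codon_index} "
      f"{ann.ref_codon}->{ann.alt_codon} ({ann.aa_ref}->{ann.aa_alt}, "
      f"{'silent' if ann.silent else 'missense'}), "
      f"nearest feature {ann.nearest_feature} at {ann.feature_distance} bp")
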