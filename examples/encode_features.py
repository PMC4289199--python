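"""Encode DNA sequences into PseNAC feature vectors.

Builds two short sequences — one CG-rich, one CG-poor — and prints the
feature values that distinguish them: the CG dinucleotide frequency and
the first pseudo (sequence-order) component.
"""

import recspot as rs

seqs = [
    rs.DnaSequence("cg_rich", "ACGCGTCGCGACGCGTCGCGACGCGTCGCG"),
    rs.DnaSequence("cg_poor", "ACTTGATAGGACTTGATAGGACTTGATAGG"),
]

X, layout = rs.encode_dataset(seqs, k_max=3, params=rs.PseDncParams(omega=5, weight=0.05))
names = layout.names

print(f"feature dimension: {layout.dim} "
      f"(tiers 1-3: 4+16+64 k-mers, PseDNC: 16+5)")
for row, seq in zip(X, seqs):
    f_cg = row[names.index("kmer:CG")]
    g1 = row[names.index("pse:1")]
    print(f"{seq.id}: f(CG)={f_cg:.3f}  pseudo-component lag1={g1:.4f}")

# f(CG) is the fraction of overlapping dinucleotide windows that read CG;
# the lag-1 pseudo component summarizes how physicochemically dissimilar
# adjacent dinucleotides are along the sequence.
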