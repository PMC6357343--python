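"""Classify lncRNA-mRNA positional relationships from transcript geometry.

Builds a handful of two-transcript configurations and prints the category
the classifier assigns to each: which side of the mRNA the lncRNA sits
on, whether it overlaps an exon or is buried in an intron, and whether
the two transcripts share a bidirectional promoter.
"""

from lncolink import TranscriptModel, classify_pair

mrna = TranscriptModel("NM_demo", "GENE1", "chr1", "+",
                       exons=((500, 899), (2001, 2500)), biotype="mRNA")

cases = {
    "lncRNA exon over mRNA exon, same strand":
        TranscriptModel("L1", "gl1", "chr1", "+", ((700, 1100),), "lncRNA"),
    "lncRNA inside the intron, same strand":
        TranscriptModel("L2", "gl2", "chr1", "+", ((1000, 1500),), "lncRNA"),
    "lncRNA inside the intron, antisense":
        TranscriptModel("L3", "gl3", "chr1", "-", ((1000, 1500),), "lncRNA"),
    "lncRNA over the exon, antisense":
        TranscriptModel("L4", "gl4", "chr1", "-", ((700, 1100),), "lncRNA"),
    "head-to-head, 200 bp upstream":
        TranscriptModel("L5", "gl5", "chr1", "-", ((1, 300),), "lncRNA"),
    "3 kb downstream, no overlap":
        TranscriptModel("L6", "gl6", "chr1", "-", ((5500, 6000),), "lncRNA"),
}

for desc, lnc in cases.items():
    call = classify_pair(lnc, mrna)
    print(f"{desc:45s} -> {call.category:25s} "
          f"(overlap {call.overlap_bp} bp, TSS distance {call.tss_distance})")

print()
print("The category drives biomarker pairing: a significant mRNA is only kept")
print("if a non-intergenic lncRNA partner is significant too.")
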