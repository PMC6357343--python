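"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval arithmetic: positional
categories are decided from base-by-base occupancy masks, and q-values
are cross-checked against statsmodels' Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np

from lncolink.positional import TranscriptModel


def base_mask_classify(lnc: TranscriptModel, mrna: TranscriptModel) -> str:
    """Classify a pair from per-base occupancy masks (brute force)."""
    if lnc.chrom != mrna.chrom:
        return "intergenic"
    lo = min(lnc.start, mrna.start)
    hi = max(lnc.end, mrna.end)
    size = hi - lo + 1

    def mask(intervals):
        m = np.zeros(size, dtype=bool)
        for s, e in intervals:
            m[s - lo : e - lo + 1] = True
        return m

    lnc_exon = mask(lnc.exons)
    lnc_span = mask([lnc.span])
    mrna_exon = mask(mrna.exons)
    mrna_span = mask([mrna.span])
    mrna_intron = mrna_span & ~mrna_exon

    same = lnc.strand == mrna.strand
    span_overlap = bool((lnc_span & mrna_span).any())

    if same:
        if bool((lnc_exon & mrna_exon).any()):
            return "exon_sense_overlapping"
        if span_overlap and bool((lnc_span & mrna_intron).any()):
            return "intron_sense_overlapping"
        return "intergenic"

    if span_overlap:
        if not bool((lnc_span & ~mrna_intron).any()):
            return "intronic_antisense"
        return "natural_antisense"

    # disjoint, opposite strands: bidirectional iff head-to-head <= 1 kb
    left, right = (lnc, mrna) if lnc.end < mrna.start else (mrna, lnc)
    if left.strand == "-" and right.strand == "+":
        if abs(lnc.tss - mrna.tss) <= 1000:
            return "bidirectional"
    return "intergenic"
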