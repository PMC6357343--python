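"""Positional classification of lncRNA-mRNA pairs.

Long non-coding RNAs are annotated relative to nearby protein-coding
transcripts by where they sit on the genome: overlapping a coding exon on
the same strand, overlapping an intron (sense or antisense), overlapping
the coding transcript from the opposite strand, transcribed head-to-head
from a shared bidirectional promoter, or far from any coding gene
(intergenic).  These positional relationships are the basis for pairing
each lncRNA with the coding gene it most plausibly regulates in cis.

All coordinates are 1-based, fully closed intervals (GTF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "CATEGORIES",
    "TranscriptModel",
    "RelationshipCall",
    "classify_pair",
    "map_relationships",
]

#: Positional categories, most specific first.  This is also the priority
#: order used when one lncRNA qualifies against several mRNAs.
CATEGORIES = (
    "exon_sense_overlapping",
    "intron_sense_overlapping",
    "intronic_antisense",
    "natural_antisense",
    "bidirectional",
    "intergenic",
)

_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

#: Maximum TSS-to-TSS distance (bp, inclusive) for a bidirectional pair.
BIDIRECTIONAL_MAX_TSS_DISTANCE = 1000


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript on one chromosome.

    ``exons`` are 1-based closed ``(start, end)`` intervals; they are
    sorted and must not overlap.  The transcript span runs from the first
    exon start to the last exon end; gaps between consecutive exons are
    the introns.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end of the transcript."""
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 1-based closed."""
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 - e0 > 1:
                out.append((e0 + 1, s1 - 1))
        return tuple(out)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RelationshipCall:
    """One lncRNA paired (or not) with an mRNA, plus the assigned category."""

    lnc_id: str
    mrna_id: Optional[str]
    category: str
    overlap_bp: int = 0
    tss_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in _PRIORITY and self.category != "sense_overlap":
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "intergenic") != (self.mrna_id is None):
            raise ValueError("mrna_id must be None exactly for intergenic calls")
        if self.category == "bidirectional":
            if self.overlap_bp != 0:
                raise ValueError("bidirectional pairs cannot overlap")
            if self.tss_distance is None or self.tss_distance > BIDIRECTIONAL_MAX_TSS_DISTANCE:
                raise ValueError("bidirectional requires TSS distance <= 1000 bp")


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap in bases of two 1-based closed intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _exon_exon_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    return sum(_overlap_len(ea, eb) for ea in a.exons for eb in b.exons)


def classify_pair(lnc: TranscriptModel, mrna: TranscriptModel) -> RelationshipCall:
    """Assign the positional relationship of one lncRNA-mRNA pair.

    The decision procedure, in priority order:

    1. same strand, any lncRNA-exon / mRNA-exon overlap
       -> ``exon_sense_overlapping``;
    2. same strand, spans overlap with zero exon-exon overlap, and the
       lncRNA span reaches into an mRNA intron
       -> ``intron_sense_overlapping``;
    3. opposite strands, lncRNA span entirely inside one mRNA intron
       -> ``intronic_antisense``;
    4. opposite strands, any span overlap not entirely intronic
       -> ``natural_antisense``;
    5. disjoint spans, opposite strands, head-to-head (each TSS is the end
       facing the other transcript) with TSS-to-TSS distance <= 1000 bp
       -> ``bidirectional``;
    6. anything else -> ``intergenic``.

    ``overlap_bp`` counts exon-exon bases for category 1 and span-span
    bases for categories 2-4.  TSS distance is ``|tss_lnc - tss_mrna|``.
    """
    if lnc.chrom != mrna.chrom:
        return RelationshipCall(lnc.transcript_id, None, "intergenic")

    same_strand = lnc.strand == mrna.strand
    span_ov = _overlap_len(lnc.span, mrna.span)
    tss_dist = abs(lnc.tss - mrna.tss)

    if same_strand:
        ee = _exon_exon_overlap(lnc, mrna)
        if ee > 0:
            return RelationshipCall(
                lnc.transcript_id, mrna.transcript_id, "exon_sense_overlapping",
                overlap_bp=ee, tss_distance=tss_dist,
            )
        if span_ov > 0 and any(
            _overlap_len(lnc.span, intron) > 0 for intron in mrna.introns
        ):
            return RelationshipCall(
                lnc.transcript_id, mrna.transcript_id, "intron_sense_overlapping",
                overlap_bp=span_ov, tss_distance=tss_dist,
            )
        return RelationshipCall(lnc.transcript_id, None, "intergenic")

    # opposite strands
    if span_ov > 0:
        inside_intron = any(
            intron[0] <= lnc.start and lnc.end <= intron[1] for intron in mrna.introns
        )
        category = "intronic_antisense" if inside_intron else "natural_antisense"
        return RelationshipCall(
            lnc.transcript_id, mrna.transcript_id, category,
            overlap_bp=span_ov, tss_distance=tss_dist,
        )

    # disjoint, opposite strands: bidirectional iff head-to-head within 1 kb.
    # Head-to-head means each transcript's TSS is the end nearest the other,
    # i.e. they transcribe away from the shared gap.
    left, right = (lnc, mrna) if lnc.end < mrna.start else (mrna, lnc)
    head_to_head = left.strand == "-" and right.strand == "+"
    if head_to_head and tss_dist <= BIDIRECTIONAL_MAX_TSS_DISTANCE:
        return RelationshipCall(
            lnc.transcript_id, mrna.transcript_id, "bidirectional",
            overlap_bp=0, tss_distance=tss_dist,
        )
    return RelationshipCall(lnc.transcript_id, None, "intergenic")


def map_relationships(
    lncs: Sequence[TranscriptModel], mrnas: Sequence[TranscriptModel]
) -> list[RelationshipCall]:
    """One call per lncRNA against the best-matching mRNA.

    When several mRNAs qualify, the highest-priority category wins; ties
    break by larger ``overlap_bp``, then smaller ``tss_distance``, then
    lexicographic ``mrna_id``.  lncRNAs with no qualifying mRNA are
    ``intergenic``.
    """
    seen: set[str] = set()
    for t in list(lncs) + list(mrnas):
        if t.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        seen.add(t.transcript_id)

    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in mrnas:
        by_chrom.setdefault(m.chrom, []).append(m)

    calls = []
    for lnc in lncs:
        best: Optional[RelationshipCall] = None
        for m in by_chrom.get(lnc.chrom, ()):
            call = classify_pair(lnc, m)
            if call.category == "intergenic":
                continue
            if best is None or _call_sort_key(call) < _call_sort_key(best):
                best = call
        calls.append(best if best is not None else RelationshipCall(lnc.transcript_id, None, "intergenic"))
    return calls


def _call_sort_key(call: RelationshipCall):
    return (
        _PRIORITY[call.category],
        -call.overlap_bp,
        call.tss_distance if call.tss_distance is not None else 10**12,
        call.mrna_id or "",
    )
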