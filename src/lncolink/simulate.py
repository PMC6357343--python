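"""Synthetic genomes and expression studies with known ground truth.

The generator emulates the study design the pipeline targets: a paired
lncRNA/mRNA array panel in which every lncRNA has a known positional
relationship to a coding transcript, a 16-vs-16
tumor/normal microarray discovery cohort with planted, coexpressed
differential lncRNA-mRNA pairs, and a 21-vs-21 RPKM-scale RNA-seq
cohort for cross-platform validation.

Geometry is constructed per category, so every pair carries its true
positional label; expression carries a truth table of planted features
and their directions.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionStudy
from .positional import CATEGORIES, TranscriptModel

__all__ = [
    "GenomeSpec",
    "StudySpec",
    "generate_transcript_pairs",
    "generate_expression_study",
    "generate_validation_rnaseq",
]

#: Minimum distance between distinct pairs so they can never interact.
PAIR_SPACING = 10_000

_PAIRABLE = tuple(c for c in CATEGORIES if c != "intergenic")


@dataclass
class GenomeSpec:
    """Parameters for the synthetic transcript-pair genome.

    ``counts_per_category`` maps each positional category to the number
    of lncRNA-mRNA pairs to construct with that true label.
    """

    counts_per_category: dict[str, int] = field(
        default_factory=lambda: {c: 20 for c in CATEGORIES}
    )
    chrom_length: int = 60_000_000
    min_gene_len: int = 2_000
    max_gene_len: int = 20_000
    exons_per_gene: tuple[int, int] = (2, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts_per_category) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in self.counts_per_category.values()):
            raise ValueError("category counts must be non-negative")
        if not 0 < self.min_gene_len <= self.max_gene_len:
            raise ValueError("need 0 < min_gene_len <= max_gene_len")
        if self.max_gene_len > self.chrom_length:
            raise ValueError("gene longer than chromosome")


@dataclass
class StudySpec:
    """Parameters for the planted-signal discovery expression study.

    Defaults mirror the targeted discovery design: 16 tumor vs 16
    normal samples, log-normal microarray-style intensities, planted
    mean shifts of ``effect_size`` standard deviations on the log scale,
    and a lncRNA partner that moves in the same direction as its mRNA
    for a fraction ``concordant_fraction`` of planted pairs (0.83,
    the concordant share of the discovery biomarker table).
    """

    n_tumor: int = 16
    n_normal: int = 16
    n_de_pairs: int = 50
    effect_size: float = 2.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    concordant_fraction: float = 0.83
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need >= 2 samples per group")
        if not 0 <= self.concordant_fraction <= 1:
            raise ValueError("concordant_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")


# ---------------------------------------------------------------------------
# Geometry


def _segment_lengths(total: int, n_seg: int, mins: Sequence[int], rng) -> list[int]:
    """Random positive segment lengths with given minimums summing to total."""
    base = list(mins)
    slack = total - sum(base)
    if slack < 0:
        raise ValueError("gene too short for requested exon count")
    w = rng.dirichlet(np.ones(n_seg))
    extra = np.floor(w * slack).astype(int)
    extra[0] += slack - extra.sum()
    return [b + int(e) for b, e in zip(base, extra)]


def _transcript_from_segs(
    tid: str, gid: str, chrom: str, strand: str, start: int,
    segs: Sequence[int], biotype: str,
) -> TranscriptModel:
    """Assemble a transcript from alternating exon/intron segment lengths."""
    exons, pos = [], start
    for i, seg in enumerate(segs):
        if i % 2 == 0:
            exons.append((pos, pos + seg - 1))
        pos += seg
    return TranscriptModel(tid, gid, chrom, strand, tuple(exons), biotype)


def _make_transcript(
    tid: str, gid: str, chrom: str, strand: str, start: int, length: int,
    n_exons: int, biotype: str, rng, min_intron: Optional[tuple[int, int]] = None,
) -> TranscriptModel:
    """Build one transcript spanning [start, start+length-1] with n_exons exons.

    ``min_intron=(j, size)`` forces intron j to be at least ``size`` bp,
    used to guarantee room for an intron-hosted lncRNA.
    """
    n_seg = 2 * n_exons - 1
    mins = [30 if i % 2 == 0 else 60 for i in range(n_seg)]
    if min_intron is not None:
        j, size = min_intron
        mins[2 * j + 1] = max(mins[2 * j + 1], size)
    segs = _segment_lengths(length, n_seg, mins, rng)
    return _transcript_from_segs(tid, gid, chrom, strand, start, segs, biotype)


def generate_transcript_pairs(
    spec: GenomeSpec,
) -> list[tuple[TranscriptModel, TranscriptModel, str]]:
    """Construct lncRNA-mRNA pairs whose geometry realises each category.

    Pairs are laid left-to-right along one chromosome, at least 10 kb
    apart, so no lncRNA can qualify against a foreign mRNA.  Returns
    ``(lnc, mrna, true_category)`` triples; deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = "chrS"
    cursor = 1
    out: list[tuple[TranscriptModel, TranscriptModel, str]] = []
    k = 0
    lo_e, hi_e = spec.exons_per_gene

    for category in CATEGORIES:
        for _ in range(spec.counts_per_category.get(category, 0)):
            k += 1
            mlen = int(rng.integers(spec.min_gene_len, spec.max_gene_len + 1))
            n_ex = int(rng.integers(max(2, lo_e), max(2, hi_e) + 1))
            llen = int(rng.integers(200, max(201, mlen // 4)))
            mid, lid, gid = f"NM_{k:06d}", f"LNC_{k:06d}", f"G{k:06d}"
            strand = "+" if rng.random() < 0.5 else "-"
            anti = "-" if strand == "+" else "+"

            if category == "bidirectional":
                gap = int(rng.integers(1, 1001))
                # left transcript transcribes leftward, right one rightward
                lnc_left = rng.random() < 0.5
                left_len, right_len = (llen, mlen) if lnc_left else (mlen, llen)
                left_start = cursor
                left_end = left_start + left_len - 1
                right_start = left_end + gap
                if lnc_left:
                    lnc = _make_transcript(lid, gid + "L", chrom, "-", left_start, llen, 1, "lncRNA", rng)
                    mrna = _make_transcript(mid, gid, chrom, "+", right_start, mlen, n_ex, "mRNA", rng)
                else:
                    mrna = _make_transcript(mid, gid, chrom, "-", left_start, mlen, n_ex, "mRNA", rng)
                    lnc = _make_transcript(lid, gid + "L", chrom, "+", right_start, llen, 1, "lncRNA", rng)
            elif category == "intergenic":
                mrna = _make_transcript(mid, gid, chrom, strand, cursor, mlen, n_ex, "mRNA", rng)
                far = mrna.end + PAIR_SPACING + int(rng.integers(1, 5000))
                lnc = _make_transcript(lid, gid + "L", chrom, anti, far, llen, 1, "lncRNA", rng)
            else:
                # offset the mRNA so a lncRNA reaching upstream of it can
                # never enter the previous pair's 10 kb exclusion zone
                mrna = _make_transcript(
                    mid, gid, chrom, strand, cursor + llen, mlen, n_ex, "mRNA", rng
                )
                if category == "exon_sense_overlapping":
                    ex_s, ex_e = mrna.exons[int(rng.integers(0, len(mrna.exons)))]
                    start = int(rng.integers(max(1, ex_s - llen // 2), ex_e + 1))
                    lnc = _make_transcript(lid, gid + "L", chrom, strand, start, llen, 1, "lncRNA", rng)
                elif category == "natural_antisense":
                    ex_s, ex_e = mrna.exons[0]
                    start = int(rng.integers(max(1, ex_s - llen // 2), ex_e + 1))
                    lnc = _make_transcript(lid, gid + "L", chrom, anti, start, llen, 1, "lncRNA", rng)
                else:  # intron sense-overlapping / intronic antisense
                    # rebuild the mRNA reserving intron j for the lncRNA
                    j = int(rng.integers(0, n_ex - 1))
                    llen = min(llen, mlen // 4)
                    mrna = _make_transcript(
                        mid, gid, chrom, strand, cursor, mlen, n_ex, "mRNA", rng,
                        min_intron=(j, llen + 40),
                    )
                    iv = mrna.introns[j]
                    start = int(rng.integers(iv[0] + 10, iv[1] - llen - 8))
                    s = strand if category == "intron_sense_overlapping" else anti
                    lnc = _make_transcript(lid, gid + "L", chrom, s, start, llen, 1, "lncRNA", rng)
            pair_end = max(lnc.end, mrna.end)
            if pair_end > spec.chrom_length:
                raise ValueError(
                    f"chromosome length {spec.chrom_length} exhausted at pair {k}"
                )
            out.append((lnc, mrna, category))
            cursor = pair_end + PAIR_SPACING + 1
    return out


# ---------------------------------------------------------------------------
# Expression


def generate_expression_study(
    pairs: Sequence[tuple[TranscriptModel, TranscriptModel, str]],
    spec: StudySpec,
) -> tuple[ExpressionStudy, ExpressionStudy, pd.DataFrame]:
    """Microarray-style mRNA and lncRNA studies with planted DE pairs.

    Values are log-normal: normal on the log scale with the spec's
    baseline mean/sd, exponentiated, so a log (Box-Cox lambda = 0)
    transform recovers normality.  Planted pairs get a tumor-group mean
    shift of ``effect_size * baseline_sd`` on the log scale; the lncRNA
    partner shifts concordantly with probability ``concordant_fraction``,
    otherwise in the opposite direction.  The truth table lists every
    planted feature with its pair, role, direction and category.
    """
    rng = np.random.default_rng(spec.seed)
    eligible = [i for i, (_, _, c) in enumerate(pairs) if c != "intergenic"]
    if spec.n_de_pairs > len(eligible):
        raise ValueError(
            f"n_de_pairs={spec.n_de_pairs} exceeds {len(eligible)} non-intergenic pairs"
        )
    planted = sorted(rng.choice(eligible, size=spec.n_de_pairs, replace=False).tolist())

    n = spec.n_tumor + spec.n_normal
    groups = ["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal
    samples = [f"T{i+1:02d}" for i in range(spec.n_tumor)] + [
        f"N{i+1:02d}" for i in range(spec.n_normal)
    ]
    tumor = np.arange(n) < spec.n_tumor

    def _draw(n_feat: int) -> np.ndarray:
        return rng.normal(spec.baseline_mean, spec.baseline_sd, size=(n_feat, n))

    log_m = _draw(len(pairs))
    log_l = _draw(len(pairs))

    truth_rows = []
    shift = spec.effect_size * spec.baseline_sd
    for idx in planted:
        lnc, mrna, cat = pairs[idx]
        up = rng.random() < 0.5
        concordant = rng.random() < spec.concordant_fraction
        m_sign = 1.0 if up else -1.0
        l_sign = m_sign if concordant else -m_sign
        log_m[idx, tumor] += m_sign * shift
        log_l[idx, tumor] += l_sign * shift
        truth_rows.append(
            dict(pair_index=idx, feature_id=mrna.transcript_id, role="mrna",
                 partner_id=lnc.transcript_id, direction="up" if up else "down",
                 category=cat)
        )
        truth_rows.append(
            dict(pair_index=idx, feature_id=lnc.transcript_id, role="lnc",
                 partner_id=mrna.transcript_id,
                 direction="up" if l_sign > 0 else "down", category=cat)
        )

    mrna_study = ExpressionStudy(
        [m.transcript_id for _, m, _ in pairs], samples, np.exp(log_m), groups, "microarray"
    )
    lnc_study = ExpressionStudy(
        [l.transcript_id for l, _, _ in pairs], samples, np.exp(log_l), groups, "microarray"
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["pair_index", "feature_id", "role", "partner_id", "direction", "category"],
    )
    return mrna_study, lnc_study, truth


def generate_validation_rnaseq(
    genes: Sequence[str],
    n_per_group: int = 21,
    effect_size: float = 2.0,
    seed: int = 0,
    directions: Optional[Mapping[str, str]] = None,
) -> ExpressionStudy:
    """RPKM-scale RNA-seq validation study over a fixed gene panel.

    Per gene, values are gamma distributed (shape 4, so dispersion is
    RNA-seq-like) around a gene-specific baseline mean drawn log-uniform
    in [1, 100] RPKM.  Genes listed in ``directions`` get their tumor
    mean multiplied by ``exp(+-effect_size/2)`` matching the training
    direction; unlisted genes carry no signal.
    """
    if not len(genes):
        raise ValueError("gene panel is empty")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = ["tumor"] * n_per_group + ["normal"] * n_per_group
    samples = [f"RT{i+1:02d}" for i in range(n_per_group)] + [
        f"RN{i+1:02d}" for i in range(n_per_group)
    ]
    tumor = np.arange(n) < n_per_group
    shape = 4.0
    values = np.empty((len(genes), n))
    for i, g in enumerate(genes):
        base = float(np.exp(rng.uniform(0.0, np.log(100.0))))
        mean = np.full(n, base)
        d = (directions or {}).get(g)
        if d is not None and effect_size > 0:
            factor = float(np.exp(effect_size / 2.0))
            mean[tumor] *= factor if d == "up" else 1.0 / factor
        values[i] = rng.gamma(shape, mean / shape)
    return ExpressionStudy(list(genes), samples, values, groups, "rnaseq")
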