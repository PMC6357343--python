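import numpy as np
import pytest

from lncolink import (
    CATEGORIES,
    GenomeSpec,
    StudySpec,
    generate_expression_study,
    generate_transcript_pairs,
)


@pytest.fixture(scope="session")
def small_pairs():
    """Ten generator-constructed pairs per category (seed 1)."""
    spec = GenomeSpec(counts_per_category={c: 10 for c in CATEGORIES}, seed=1)
    return generate_transcript_pairs(spec)


@pytest.fixture(scope="session")
def planted_run():
    """The discovery-design planted study: d=2, 16 vs 16, 50 planted pairs.

    120 pairs (20 per category, 100 non-intergenic); returns
    (pairs, mrna_study, lnc_study, truth).
    """
    genome = GenomeSpec(counts_per_category={c: 20 for c in CATEGORIES}, seed=3)
    pairs = generate_transcript_pairs(genome)
    spec = StudySpec(n_tumor=16, n_normal=16, n_de_pairs=50, effect_size=2.0, seed=3)
    mrna_study, lnc_study, truth = generate_expression_study(pairs, spec)
    return pairs, mrna_study, lnc_study, truth


def make_transcript(tid, exons, strand="+", chrom="chr1", biotype="mRNA", gene=None):
    from lncolink import TranscriptModel

    return TranscriptModel(tid, gene or f"g_{tid}", chrom, strand, tuple(exons), biotype)
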