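"""Positional classifier: contract examples, oracle agreement, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_transcript
from oracles import base_mask_classify
from lncolink import (
    RelationshipCall,
    TranscriptModel,
    classify_pair,
    map_relationships,
)
from lncolink.io import read_transcripts, write_gtf


class TestClassifyPair:
    def test_exon_sense_overlap_count(self):
        lnc = make_transcript("l", [(100, 200)], "+", biotype="lncRNA")
        m = make_transcript("m", [(150, 400)], "+")
        call = classify_pair(lnc, m)
        assert call.category == "exon_sense_overlapping"
        assert call.overlap_bp == 51  # closed-interval arithmetic

    def test_intronic_antisense_containment(self):
        m = make_transcript("m", [(500, 899), (2001, 2500)], "+")
        lnc = make_transcript("l", [(1000, 1500)], "-", biotype="lncRNA")
        assert classify_pair(lnc, m).category == "intronic_antisense"

    def test_antisense_spanning_exon_and_intron_is_natural(self):
        # overlapping both exon and intron on the antisense strand is not
        # "intronic": containment in the intron is required
        m = make_transcript("m", [(500, 899), (2001, 2500)], "+")
        lnc = make_transcript("l", [(800, 1200)], "-", biotype="lncRNA")
        assert classify_pair(lnc, m).category == "natural_antisense"

    def test_intron_sense_overlapping(self):
        m = make_transcript("m", [(500, 899), (2001, 2500)], "+")
        lnc = make_transcript("l", [(1000, 1500)], "+", biotype="lncRNA")
        assert classify_pair(lnc, m).category == "intron_sense_overlapping"

    def test_bidirectional_head_to_head_within_1kb(self):
        lnc = make_transcript("l", [(1000, 1500)], "-", biotype="lncRNA")
        m = make_transcript("m", [(2000, 3000)], "+")
        call = classify_pair(lnc, m)
        assert call.category == "bidirectional"
        assert call.overlap_bp == 0
        assert call.tss_distance == 500

    def test_tail_to_tail_is_not_bidirectional(self):
        lnc = make_transcript("l", [(1000, 1500)], "+", biotype="lncRNA")
        m = make_transcript("m", [(2000, 3000)], "-")
        assert classify_pair(lnc, m).category == "intergenic"

    def test_tss_distance_beyond_1kb_is_intergenic(self):
        lnc = make_transcript("l", [(1000, 1500)], "-", biotype="lncRNA")
        m = make_transcript("m", [(2600, 3000)], "+")
        assert classify_pair(lnc, m).category == "intergenic"

    def test_different_chromosome_is_intergenic(self):
        lnc = make_transcript("l", [(100, 200)], "+", chrom="chr2", biotype="lncRNA")
        m = make_transcript("m", [(150, 400)], "+")
        assert classify_pair(lnc, m).category == "intergenic"


def _grid_cases():
    """All strand combos x offsets for two multi-exon shapes."""
    mrna_exons = [(0, 150), (400, 550), (900, 1100)]
    lnc_exons = [(0, 80), (260, 400)]
    for ls in "+-":
        for ms in "+-":
            for off in range(-2000, 2001, 7):
                yield ls, ms, off, lnc_exons, mrna_exons


def test_grid_agrees_with_base_mask_oracle():
    """Interval-arithmetic classifier == base-by-base oracle on a dense grid."""
    base = 5000
    disagreements = []
    for ls, ms, off, lnc_ex, mrna_ex in _grid_cases():
        lnc = make_transcript(
            "l", [(base + off + s, base + off + e) for s, e in lnc_ex], ls,
            biotype="lncRNA",
        )
        m = make_transcript("m", [(base + s, base + e) for s, e in mrna_ex], ms)
        got = classify_pair(lnc, m).category
        want = base_mask_classify(lnc, m)
        if got != want:
            disagreements.append((ls, ms, off, got, want))
    assert disagreements == []


def test_classifier_recovers_generator_labels(small_pairs):
    calls = map_relationships(
        [p[0] for p in small_pairs], [p[1] for p in small_pairs]
    )
    truth = {p[0].transcript_id: p[2] for p in small_pairs}
    wrong = [c for c in calls if c.category != truth[c.lnc_id]]
    assert wrong == []


def test_per_category_tallies_match_generator(small_pairs):
    from collections import Counter

    calls = map_relationships([p[0] for p in small_pairs], [p[1] for p in small_pairs])
    assert Counter(c.category for c in calls) == Counter(p[2] for p in small_pairs)


class TestMapRelationships:
    def test_lnc_with_no_nearby_mrna_is_intergenic(self):
        lnc = make_transcript("l", [(1000, 1500)], "+", biotype="lncRNA")
        m = make_transcript("m", [(50_000, 60_000)], "+")
        (call,) = map_relationships([lnc], [m])
        assert call.category == "intergenic" and call.mrna_id is None

    def test_priority_exon_sense_beats_bidirectional(self):
        lnc = make_transcript("l", [(2000, 2600)], "+", biotype="lncRNA")
        a = make_transcript("A", [(2500, 3500)], "+")  # exon-sense overlap
        b = make_transcript("B", [(1000, 1900)], "-")  # head-to-head... from lnc view
        # ensure B would be bidirectional on its own
        (call,) = map_relationships([lnc], [a, b])
        assert call.category == "exon_sense_overlapping" and call.mrna_id == "A"

    def test_tie_breaks_by_overlap_then_id(self):
        lnc = make_transcript("l", [(100, 300)], "+", biotype="lncRNA")
        small = make_transcript("B", [(250, 500)], "+")  # 51 bp overlap
        big = make_transcript("C", [(150, 500)], "+")  # 151 bp overlap
        (call,) = map_relationships([lnc], [small, big])
        assert call.mrna_id == "C"

    def test_duplicate_ids_rejected(self):
        lnc = make_transcript("x", [(100, 300)], "+", biotype="lncRNA")
        m = make_transcript("x", [(250, 500)], "+")
        with pytest.raises(ValueError, match="duplicate"):
            map_relationships([lnc], [m])


class TestInvariances:
    def test_exon_input_order_irrelevant(self):
        a = make_transcript("l", [(100, 200), (400, 500)], "+", biotype="lncRNA")
        b = TranscriptModel("l2", "g", "chr1", "+", ((400, 500), (100, 200)), "lncRNA")
        m = make_transcript("m", [(450, 900)], "+")
        assert classify_pair(a, m).category == classify_pair(b, m).category

    @given(off=st.integers(-2200, 2200), ls=st.sampled_from("+-"), ms=st.sampled_from("+-"))
    @settings(max_examples=60, deadline=None)
    def test_double_strand_flip_preserves_category(self, off, ls, ms):
        flip = {"+": "-", "-": "+"}
        lnc = make_transcript("l", [(3000 + off, 3400 + off)], ls, biotype="lncRNA")
        m = make_transcript("m", [(3000, 3200), (3600, 4000)], ms)
        lnc2 = make_transcript("l", [(3000 + off, 3400 + off)], flip[ls], biotype="lncRNA")
        m2 = make_transcript("m", [(3000, 3200), (3600, 4000)], flip[ms])
        c1, c2 = classify_pair(lnc, m).category, classify_pair(lnc2, m2).category
        if c1 in ("exon_sense_overlapping", "intron_sense_overlapping",
                  "intronic_antisense", "natural_antisense"):
            assert c1 == c2

    def test_shuffling_input_lists_preserves_calls(self, small_pairs):
        lncs = [p[0] for p in small_pairs]
        mrnas = [p[1] for p in small_pairs]
        ref = {c.lnc_id: c for c in map_relationships(lncs, mrnas)}
        rng = np.random.default_rng(0)
        got = map_relationships(
            [lncs[i] for i in rng.permutation(len(lncs))],
            [mrnas[i] for i in rng.permutation(len(mrnas))],
        )
        assert all(ref[c.lnc_id] == c for c in got)


class TestModelValidation:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_transcript("t", [(100, 200), (150, 300)])

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            TranscriptModel("t", "g", "chr1", ".", ((1, 10),))

    def test_bidirectional_call_invariants(self):
        with pytest.raises(ValueError):
            RelationshipCall("l", "m", "bidirectional", overlap_bp=5, tss_distance=10)
        with pytest.raises(ValueError):
            RelationshipCall("l", None, "natural_antisense")


class TestGtfRoundTrip:
    def test_round_trip_preserves_models(self, tmp_path, small_pairs):
        transcripts = [p[0] for p in small_pairs] + [p[1] for p in small_pairs]
        path = tmp_path / "t.gtf"
        write_gtf(transcripts, path)
        back = read_transcripts(path)
        assert sorted(back, key=lambda t: t.transcript_id) == sorted(
            transcripts, key=lambda t: t.transcript_id
        )

    def test_two_exon_transcript_sorted_span(self, tmp_path):
        t = make_transcript("t", [(400, 500), (100, 200)])
        write_gtf([t], tmp_path / "t.gtf")
        (back,) = read_transcripts(tmp_path / "t.gtf")
        assert back.exons == ((100, 200), (400, 500))
        assert back.span == (100, 500)

    def test_empty_file_returns_empty_list(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert read_transcripts(p) == []
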