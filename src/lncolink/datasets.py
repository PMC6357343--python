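"""Packaged reference fixtures: the published biomarker table and
validation confusion matrices for the HCC panel.

The biomarker table is the published discovery output: 41 mRNA probes
(38 genes) each paired with a significantly differential, positionally
related lncRNA.  One row carries the legacy display label
"sense overlap", which is not one of the six classifier categories; it
is preserved verbatim and mapped to the internal tag ``sense_overlap``
that the classifier itself never emits.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .selection import BiomarkerRecord
from .validation import ConfusionMatrix

__all__ = [
    "load_biomarker_table",
    "load_validation_confusions",
    "fixture_sha256",
    "DISPLAY_TO_CATEGORY",
]

#: Display labels used in the published table -> internal category tags.
DISPLAY_TO_CATEGORY = {
    "exon sense-overlapping": "exon_sense_overlapping",
    "intron sense-overlapping": "intron_sense_overlapping",
    "intronic antisense": "intronic_antisense",
    "natural antisense": "natural_antisense",
    "bidirectional": "bidirectional",
    "sense overlap": "sense_overlap",  # legacy label, classifier never emits it
    "intergenic": "intergenic",
}

def _read_bytes(name: str) -> bytes:
    return (resources.files("lncolink") / "data" / name).read_bytes()


def fixture_sha256(name: str) -> str:
    """SHA-256 of a packaged fixture file."""
    return hashlib.sha256(_read_bytes(name)).hexdigest()


def load_biomarker_table(as_records: bool = True):
    """The packaged 41-row biomarker table.

    Returns :class:`BiomarkerRecord` objects (relationships mapped to
    internal category tags) or, with ``as_records=False``, the raw
    DataFrame with the original display labels.
    """
    import io as _io

    df = pd.read_csv(_io.BytesIO(_read_bytes("reference_biomarker_panel.tsv")), sep="\t")
    if not as_records:
        return df
    return [
        BiomarkerRecord(
            mrna_id=r.mrna_id,
            gene_symbol=r.gene_symbol,
            mrna_direction=r.mrna_direction,
            mrna_q=float(r.mrna_q),
            lnc_id=r.lnc_id,
            relationship=DISPLAY_TO_CATEGORY[r.relationship],
            lnc_direction=r.lnc_direction,
            lnc_q=float(r.lnc_q),
        )
        for r in df.itertuples()
    ]


def load_validation_confusions() -> dict[str, dict]:
    """Published validation confusion matrices and printed metrics.

    Keys ``training``, ``testing``, ``rna_testing``; each value holds a
    :class:`ConfusionMatrix` under ``confusion`` and the printed metric
    percentages (plus AUC) under ``printed``.
    """
    raw = json.loads(_read_bytes("reference_validation_confusion.json"))
    out = {}
    for key in ("training", "testing", "rna_testing"):
        out[key] = {
            "confusion": ConfusionMatrix(**raw[key]["confusion"]),
            "printed": raw[key]["printed"],
        }
    return out
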