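"""GTF and expression-matrix I/O.

Transcript models round-trip through GTF (gene/transcript/exon features
with ``gene_id``, ``transcript_id`` and ``gene_biotype`` attributes).
Expression studies round-trip through a pair of TSVs: a feature-by-sample
matrix and a sample->group label table.
"""

from __future__ import annotations

import logging
import os
from typing import Sequence

import gffutils
import pandas as pd

from .diffexpr import ExpressionStudy
from .positional import TranscriptModel

log = logging.getLogger(__name__)

__all__ = ["read_transcripts", "write_gtf", "read_expression", "write_expression"]

_BIOTYPE_MAP = {"protein_coding": "mRNA", "lncRNA": "lncRNA"}
_BIOTYPE_INV = {"mRNA": "protein_coding", "lncRNA": "lncRNA"}


def read_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    One model per ``transcript_id``; exons are collected and sorted.
    Biotype comes from the ``gene_biotype`` attribute (``protein_coding``
    -> mRNA, ``lncRNA`` -> lncRNA).  Files without exon features raise;
    an empty file returns an empty list with a warning.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            log.warning("GTF file %s contains no features", path)
            return []

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    for i, feat in enumerate(db.features_of_type("exon"), start=1):
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"{path}: exon feature for {feat.attributes.get('transcript_id')}"
                f" has unknown strand {feat.strand!r}"
            )
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(f"{path}: exon feature missing {exc} attribute") from exc
        biotype = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
        rec = exons.setdefault(
            tid,
            {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand,
             "biotype": _BIOTYPE_MAP.get(biotype, "mRNA"), "exons": []},
        )
        rec["exons"].append((feat.start, feat.end))

    if not exons:
        raise ValueError(f"{path}: no exon features found")

    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
            biotype=rec["biotype"],
        )
        for tid, rec in exons.items()
    ]


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcripts as GTF gene/transcript/exon lines."""
    with open(path, "w") as fh:
        for t in transcripts:
            biotype = _BIOTYPE_INV[t.biotype]
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{biotype}";'
            )
            for ftype in ("gene", "transcript"):
                fh.write(
                    f"{t.chrom}\tlncolink\t{ftype}\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tlncolink\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_expression(study: ExpressionStudy, expr_path, groups_path) -> None:
    """Write a study as matrix TSV (feature rows) + sample->group TSV."""
    df = study.to_frame()
    df.to_csv(expr_path, sep="\t", index_label="feature_id")
    pd.DataFrame({"sample_id": df.columns, "group": study.groups}).to_csv(
        groups_path, sep="\t", index=False
    )


def read_expression(expr_path, groups_path, platform: str = "microarray") -> ExpressionStudy:
    """Read a matrix TSV + group TSV back into an :class:`ExpressionStudy`."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    labels = pd.read_csv(groups_path, sep="\t")
    groups = labels.set_index("sample_id").loc[df.columns, "group"].tolist()
    return ExpressionStudy.from_frame(df, groups, platform=platform)
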