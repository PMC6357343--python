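"""Paired-significance biomarker selection.

An mRNA probe becomes a biomarker when (1) it is differentially
expressed at q below threshold and (2) it is positionally related
(non-intergenic) to a lncRNA that is itself differentially expressed at
q below threshold.  "Coexpressed" is operationalised as this joint
significance, not as direction concordance — discordant pairs (mRNA up,
lncRNA down) are legitimate biomarkers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .diffexpr import DERecord
from .positional import RelationshipCall

__all__ = [
    "BiomarkerRecord",
    "select_biomarkers",
    "tally_relationships",
    "collapse_to_genes",
    "biomarker_table",
]


@dataclass(frozen=True)
class BiomarkerRecord:
    """One selected (mRNA probe, related lncRNA) pair."""

    mrna_id: str
    gene_symbol: str
    mrna_direction: str
    mrna_q: float
    lnc_id: str
    relationship: str
    lnc_direction: str
    lnc_q: float


def select_biomarkers(
    mrna_de: Sequence[DERecord],
    lnc_de: Sequence[DERecord],
    relationship_calls: Sequence[RelationshipCall],
    q_threshold: float = 0.05,
    gene_symbols: Optional[Mapping[str, str]] = None,
) -> list[BiomarkerRecord]:
    """Join the two DE tables through the positional map.

    Emits one record per (mRNA probe, lncRNA) pair where both members
    pass ``q < q_threshold`` and the pair's relationship is not
    intergenic, sorted by mRNA q ascending.  ``gene_symbols`` maps probe
    ids to gene symbols (defaults to the probe id itself).
    """
    mrna_by_id = {r.feature_id: r for r in mrna_de}
    lnc_by_id = {r.feature_id: r for r in lnc_de}
    records = []
    for call in relationship_calls:
        if call.category == "intergenic":
            continue
        if call.lnc_id not in lnc_by_id:
            raise KeyError(f"relationship call references unknown lncRNA {call.lnc_id!r}")
        if call.mrna_id not in mrna_by_id:
            raise KeyError(f"relationship call references unknown mRNA {call.mrna_id!r}")
        m, l = mrna_by_id[call.mrna_id], lnc_by_id[call.lnc_id]
        if m.q_value < q_threshold and l.q_value < q_threshold:
            records.append(
                BiomarkerRecord(
                    mrna_id=m.feature_id,
                    gene_symbol=(gene_symbols or {}).get(m.feature_id, m.feature_id),
                    mrna_direction=m.direction,
                    mrna_q=m.q_value,
                    lnc_id=l.feature_id,
                    relationship=call.category,
                    lnc_direction=l.direction,
                    lnc_q=l.q_value,
                )
            )
    records.sort(key=lambda r: r.mrna_q)
    return records


def tally_relationships(records: Sequence[BiomarkerRecord]) -> dict[str, int]:
    """Count selected pairs per positional category."""
    return dict(Counter(r.relationship for r in records))


def collapse_to_genes(records: Sequence[BiomarkerRecord]) -> list[str]:
    """Unique gene symbols in order of first appearance."""
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.gene_symbol)
    return list(seen)


def biomarker_table(records: Sequence[BiomarkerRecord]) -> pd.DataFrame:
    """Selected biomarkers as a tidy table mirroring the discovery output."""
    return pd.DataFrame(
        {
            "mrna_id": [r.mrna_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "mrna_direction": [r.mrna_direction for r in records],
            "mrna_q": [r.mrna_q for r in records],
            "lnc_id": [r.lnc_id for r in records],
            "relationship": [r.relationship for r in records],
            "lnc_direction": [r.lnc_direction for r in records],
            "lnc_q": [r.lnc_q for r in records],
        }
    )
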