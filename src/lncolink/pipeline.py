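"""End-to-end orchestration: simulate -> classify -> DE -> select -> validate.

A run is a pure function of its :class:`RunConfig`: every random stage
derives its seed from the config seed, all stage outputs are written to
the output directory with SHA-256 checksums, and the manifest records
seeds, thresholds and hyperparameters so a rerun is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import io as lio
from .datasets import load_biomarker_table, load_validation_confusions, fixture_sha256
from .diffexpr import de_table, run_de
from .positional import map_relationships
from .selection import (
    biomarker_table,
    collapse_to_genes,
    select_biomarkers,
    tally_relationships,
)
from .simulate import (
    GenomeSpec,
    StudySpec,
    generate_expression_study,
    generate_transcript_pairs,
    generate_validation_rnaseq,
)
from .validation import (
    SVM_PARAMS,
    average_by_gene,
    confusion_metrics,
    cross_platform_eval,
    crossvalidate_svm,
    minmax_normalize,
    train_test_split_eval,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "reproduce_reference_tables"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulation`` (GenomeSpec/StudySpec parameter dicts)
    or ``inputs`` (paths to GTF + expression/group TSVs) must be given.
    """

    outdir: str
    seed: int = 0
    q_threshold: float = 0.05
    simulation: Optional[dict] = None
    inputs: Optional[dict] = None
    validation_n_per_group: int = 21
    validation_effect_size: float = 2.0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'simulation' or 'inputs'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _report_dict(cm, rep) -> dict:
    return {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "sensitivity": rep.sensitivity,
        "specificity": rep.specificity,
        "precision": rep.precision,
        "accuracy": rep.accuracy,
        "auc": rep.auc,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest.

    Stage order mirrors the discovery workflow: build (or load) the
    transcript annotation and expression studies; classify every lncRNA
    against the mRNAs; run differential expression separately for the
    mRNA and lncRNA families; select paired-significant biomarkers;
    collapse to genes; and validate the panel with five-fold SVM CV, a
    held-out split, and a cross-platform RPKM blind test.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.simulation is not None:
            stage = "simulate"
            genome = GenomeSpec(**config.simulation.get("genome", {}), seed=config.seed)
            study_spec = StudySpec(**config.simulation.get("study", {}), seed=config.seed + 1)
            pairs = generate_transcript_pairs(genome)
            mrna_study, lnc_study, truth = generate_expression_study(pairs, study_spec)
            lncs = [p[0] for p in pairs]
            mrnas = [p[1] for p in pairs]
            lio.write_gtf(lncs + mrnas, out / "transcripts.gtf")
            lio.write_expression(mrna_study, out / "mrna_expr.tsv", out / "samples.tsv")
            lio.write_expression(lnc_study, out / "lnc_expr.tsv", out / "samples.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            gene_symbols = {m.transcript_id: m.gene_id for m in mrnas}
        else:
            stage = "load"
            transcripts = lio.read_transcripts(config.inputs["gtf"])
            lncs = [t for t in transcripts if t.biotype == "lncRNA"]
            mrnas = [t for t in transcripts if t.biotype == "mRNA"]
            mrna_study = lio.read_expression(
                config.inputs["mrna_expr"], config.inputs["groups"], "microarray"
            )
            lnc_study = lio.read_expression(
                config.inputs["lnc_expr"], config.inputs["groups"], "microarray"
            )
            truth = None
            gene_symbols = {m.transcript_id: m.gene_id for m in mrnas}

        stage = "classify"
        calls = map_relationships(lncs, mrnas)
        pd_calls = _calls_frame(calls)
        pd_calls.to_csv(out / "relationships.tsv", sep="\t", index=False)

        stage = "diffexpr"
        mrna_de = run_de(mrna_study)
        lnc_de = run_de(lnc_study)
        de_table(mrna_de).to_csv(out / "mrna_de.tsv", sep="\t", index=False)
        de_table(lnc_de).to_csv(out / "lnc_de.tsv", sep="\t", index=False)

        stage = "select"
        records = select_biomarkers(
            mrna_de, lnc_de, calls, q_threshold=config.q_threshold,
            gene_symbols=gene_symbols,
        )
        biomarker_table(records).to_csv(out / "biomarkers.tsv", sep="\t", index=False)
        tally = tally_relationships(records)
        genes = collapse_to_genes(records)

        stage = "validate"
        report: dict = {"tally": tally, "n_biomarkers": len(records), "genes": genes}
        if records:
            panel_probes = sorted({r.mrna_id for r in records})
            # min-max scale before the RBF kernel so distances are O(1)
            panel_study = minmax_normalize(mrna_study.subset(panel_probes))
            # five-fold CV on all discovery samples (probe level, as published)
            _, _, cv_cm, cv_rep = crossvalidate_svm(panel_study, k=5, seed=config.seed + 2)
            report["cv_all_samples"] = _report_dict(cv_cm, cv_rep)
            split = train_test_split_eval(panel_study, seed=config.seed + 3)
            for name, (cm, rep) in split.items():
                report[f"split_{name}"] = _report_dict(cm, rep)

            # cross-platform: gene-averaged training vs RPKM blind test
            gene_train = average_by_gene(
                mrna_study.subset(panel_probes),
                {p: gene_symbols.get(p, p) for p in panel_probes},
            )
            if config.simulation is not None:
                directions = (
                    truth[truth.role == "mrna"]
                    .assign(gene=lambda d: d.feature_id.map(gene_symbols))
                    .set_index("gene")["direction"]
                    .to_dict()
                )
                rnaseq = generate_validation_rnaseq(
                    genes,
                    n_per_group=config.validation_n_per_group,
                    effect_size=config.validation_effect_size,
                    seed=config.seed + 4,
                    directions=directions,
                )
                lio.write_expression(rnaseq, out / "rnaseq_expr.tsv", out / "rnaseq_samples.tsv")
            else:
                rnaseq = lio.read_expression(
                    config.inputs["rnaseq_expr"], config.inputs["rnaseq_groups"], "rnaseq"
                )
            xp = cross_platform_eval(gene_train, rnaseq, genes, seed=config.seed + 5)
            report["cross_platform_cv"] = _report_dict(*xp["train_cv"])
            report["cross_platform_blind"] = _report_dict(*xp["blind_test"])

        stage = "manifest"
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest = {
            "seed": config.seed,
            "q_threshold": config.q_threshold,
            "svm_params": dict(SVM_PARAMS),
            "n_pairs": len(lncs),
            "n_biomarkers": len(records),
            "n_genes": len(genes),
            "outputs": {
                p.name: _sha256(p)
                for p in sorted(out.iterdir())
                if p.suffix in {".tsv", ".gtf", ".json"} and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _calls_frame(calls):
    import pandas as pd

    return pd.DataFrame(
        {
            "lnc_id": [c.lnc_id for c in calls],
            "mrna_id": [c.mrna_id for c in calls],
            "category": [c.category for c in calls],
            "overlap_bp": [c.overlap_bp for c in calls],
            "tss_distance": [c.tss_distance for c in calls],
        }
    )


#: Expected values published for the reference biomarker panel.
EXPECTED_TALLY = {
    "natural_antisense": 16,
    "bidirectional": 9,
    "exon_sense_overlapping": 7,
    "intronic_antisense": 6,
    "intron_sense_overlapping": 2,
    "sense_overlap": 1,
}
EXPECTED_N_GENES = 38

_FIXTURE_CHECKSUMS = {
    "reference_biomarker_panel.tsv": "8ada7d86863d313853bbd3659494629db9bfd880672cb47dca0d1a0e2f5a0bb2",
    "reference_validation_confusion.json": "aac37d2447f2300cec97da73525fa15db96b37120e2730660534b599f668d075",
}


def reproduce_reference_tables() -> dict:
    """Recompute the published tallies and validation metrics from fixtures.

    Verifies fixture checksums, tallies the 41-row biomarker table by
    relationship, collapses to genes, and recomputes the four confusion
    metrics for each published validation matrix, comparing each to the
    printed value at its printed precision.  Returns a report with a
    pass flag per check.
    """
    for name, expected in _FIXTURE_CHECKSUMS.items():
        actual = fixture_sha256(name)
        if actual != expected:
            raise RuntimeError(f"fixture {name} checksum mismatch: {actual}")

    records = load_biomarker_table()
    tally = tally_relationships(records)
    genes = collapse_to_genes(records)
    checks = {}
    for cat, expected in EXPECTED_TALLY.items():
        checks[f"tally/{cat}"] = {"value": tally.get(cat, 0), "expected": expected,
                                  "pass": tally.get(cat, 0) == expected}
    checks["tally/total"] = {"value": sum(tally.values()), "expected": len(records),
                             "pass": sum(tally.values()) == len(records)}
    checks["n_genes"] = {"value": len(genes), "expected": EXPECTED_N_GENES,
                         "pass": len(genes) == EXPECTED_N_GENES}

    for key, entry in load_validation_confusions().items():
        rep = confusion_metrics(entry["confusion"])
        for metric in ("sensitivity", "specificity", "precision", "accuracy"):
            got = round(getattr(rep, metric) * 100, 1)
            want = entry["printed"][metric]
            checks[f"{key}/{metric}"] = {"value": got, "expected": want,
                                         "pass": got == want}
    checks["all_pass"] = all(
        v["pass"] for k, v in checks.items() if isinstance(v, dict)
    )
    return checks
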