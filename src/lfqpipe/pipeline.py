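"""End-to-end orchestration: filter -> transform -> impute -> test -> classify
-> enrich -> correlate, with a machine-readable run summary.

The in-memory entry point is :func:`analyze_tables` (used heavily by the
test-bench and simulation studies); :func:`run_pipeline` wraps it with file
I/O, GO enrichment of the differential sets and the transcript correlation
stage, writing one TSV per stage plus ``summary.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment as enr
from . import integration as integ
from .design import SampleDesign
from .differential import Thresholds, category_labels, run_differential
from .impute import ImputationParams, impute
from .io import (
    AnnotationMap,
    ProteinMeta,
    read_annotation_table,
    read_protein_groups,
    read_transcript_table,
    write_results,
)
from .preprocess import (
    apply_quality_filters,
    filter_for_quantification,
    log2_transform,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "analyze_tables", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """File paths and parameters for a full run."""

    protein_groups: str
    design: str
    outdir: str
    annotation: str | None = None
    transcripts: str | None = None
    thresholds: Thresholds = Thresholds()
    imputation: ImputationParams = ImputationParams()
    test: str = "student"
    fdr_method: str = "bh"
    enrichment_correction: str = "bh"
    pseudocount: float = 1.0
    min_razor_unique: int = 2
    min_unique: int = 1
    min_valid_total: int = 4
    seed: int = 0


@dataclass
class PipelineResult:
    """Everything the core quantification stages produce."""

    design: SampleDesign
    n_input: int
    quality_ids: list[str]
    quantset: object
    completed: pd.DataFrame
    audit: pd.DataFrame
    differential: pd.DataFrame
    counts: dict = field(default_factory=dict)


def analyze_tables(
    intensities: pd.DataFrame,
    meta: list[ProteinMeta],
    design: SampleDesign,
    thresholds: Thresholds = Thresholds(),
    imputation: ImputationParams = ImputationParams(),
    test: str = "student",
    fdr_method: str = "bh",
    min_razor_unique: int = 2,
    min_unique: int = 1,
    min_valid_total: int = 4,
) -> PipelineResult:
    """Run quality filter, log transform, valid-value filter, imputation and
    differential classification on in-memory tables."""
    quality_ids = apply_quality_filters(meta, min_razor_unique, min_unique)
    log_table = log2_transform(intensities.loc[quality_ids])
    quantset = filter_for_quantification(log_table, design, min_valid_total)
    completed, audit = impute(log_table, quantset, imputation)
    diff = run_differential(
        completed, quantset, design, thresholds, test=test, fdr_method=fdr_method
    )
    counts = {
        "proteins_read": len(meta),
        "after_quality_filters": len(quality_ids),
        "after_valid_value_filter": len(quantset.retained_ids),
        "categories": {
            c: int((diff["category"] == c).sum()) for c in category_labels(design)
        },
    }
    return PipelineResult(
        design=design,
        n_input=len(meta),
        quality_ids=quality_ids,
        quantset=quantset,
        completed=completed,
        audit=audit,
        differential=diff,
        counts=counts,
    )


def _differential_sets(diff: pd.DataFrame, design: SampleDesign) -> dict[str, set[str]]:
    ref, trt = design.conditions
    out = {}
    for cond in (ref, trt):
        mask = diff["category"].isin([f"{cond}-enriched", f"{cond}-specific"])
        out[cond] = set(diff.index[mask])
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Full file-based run; returns the summary dictionary.

    Writes ``differential.tsv``, ``imputation_audit.tsv``, per-condition
    ``enrichment_<cond>.tsv`` (when an annotation table is given),
    ``correlation.tsv`` (when transcripts are given too) and
    ``summary.json`` into the output directory.  Deterministic under a
    fixed seed.  Stage failures abort with the stage name; partial outputs
    are removed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read inputs"
        design = SampleDesign.from_tsv(config.design)
        intensities, meta = read_protein_groups(config.protein_groups, design)

        stage = "quantification"
        imputation = ImputationParams(
            width=config.imputation.width,
            downshift=config.imputation.downshift,
            seed=config.seed,
        )
        result = analyze_tables(
            intensities, meta, design,
            thresholds=config.thresholds,
            imputation=imputation,
            test=config.test,
            fdr_method=config.fdr_method,
            min_razor_unique=config.min_razor_unique,
            min_unique=config.min_unique,
            min_valid_total=config.min_valid_total,
        )
        diff_path = outdir / "differential.tsv"
        write_results(result.differential.reset_index(names="protein_id"), diff_path)
        written.append(diff_path)
        audit_path = outdir / "imputation_audit.tsv"
        write_results(result.audit.reset_index(), audit_path)
        written.append(audit_path)

        summary = {
            "parameters": {
                "logfc_cut": config.thresholds.logfc_cut,
                "fdr_cut": config.thresholds.fdr_cut,
                "imputation_width": config.imputation.width,
                "imputation_downshift": config.imputation.downshift,
                "test": config.test,
                "fdr_method": config.fdr_method,
                "pseudocount": config.pseudocount,
                "min_razor_unique": config.min_razor_unique,
                "min_unique": config.min_unique,
                "min_valid_total": config.min_valid_total,
                "seed": config.seed,
            },
            "counts": result.counts,
            "outputs": {},
        }

        annotation: AnnotationMap | None = None
        if config.annotation:
            stage = "enrichment"
            annotation = read_annotation_table(config.annotation)
            background = set(result.quantset.retained_ids)
            n_terms = {}
            for cond, query in _differential_sets(
                result.differential, design
            ).items():
                if not query:
                    logger.info("no %s differential proteins; enrichment skipped", cond)
                    continue
                table = enr.enrich(
                    query, background, annotation,
                    correction=config.enrichment_correction,
                )
                path = outdir / f"enrichment_{cond}.tsv"
                write_results(table, path)
                written.append(path)
                n_terms[cond] = int(table["significant"].sum())
            summary["counts"]["enriched_terms"] = n_terms

        if config.transcripts:
            stage = "correlation"
            if annotation is None:
                raise ValueError(
                    "correlation stage requires an annotation table for the "
                    "protein-to-gene mapping"
                )
            transcripts = read_transcript_table(config.transcripts)
            tfc = integ.transcript_log2fc(
                transcripts, design.conditions, pseudocount=config.pseudocount
            )
            corr = integ.correlate_by_class(
                result.differential["log2_ratio"], tfc, annotation
            )
            path = outdir / "correlation.tsv"
            write_results(corr, path)
            written.append(path)
            g = corr[corr["scope"] == integ.GLOBAL_SCOPE].iloc[0]
            summary["counts"]["correlation_global_r"] = float(g["r"])
            summary["counts"]["correlation_scopes"] = int(len(corr))

        summary["outputs"] = {p.name: str(p) for p in written}
        stage = "write summary"
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
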