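"""Simulation benchmarks: FDR calibration, recovery power, correlation
recovery.

These routines drive the synthetic generator through the full
quantification pipeline and measure how well the planted truth is
recovered.  They are used both by the test suite and by the acceptance
script; each takes an explicit seed and derives per-run seeds from a
:class:`numpy.random.SeedSequence` so runs are independent and
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SampleDesign
from .differential import INVARIANT, PUTATIVELY_INVARIANT, Thresholds
from .impute import ImputationParams
from .integration import correlate_by_class, transcript_log2fc
from .io import AnnotationMap, parse_protein_groups_frame
from .pipeline import PipelineResult, analyze_tables
from .preprocess import NO_STAGE
from .simulate import SimConfig, SimulatedDataset, simulate_dataset

__all__ = [
    "run_on_dataset",
    "null_calibration",
    "recovery_study",
    "correlation_recovery",
    "CalibrationResult",
    "RecoveryResult",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_on_dataset(
    dataset: SimulatedDataset,
    thresholds: Thresholds = Thresholds(),
    fdr_method: str = "bh",
    seed: int | None = None,
) -> PipelineResult:
    """Run the quantification pipeline on an in-memory simulated dataset."""
    design = dataset.design
    intensities, meta = parse_protein_groups_frame(
        dataset.protein_groups, design, source="<simulated>"
    )
    impute_seed = dataset.config.seed if seed is None else seed
    return analyze_tables(
        intensities, meta, design,
        thresholds=thresholds,
        imputation=ImputationParams(seed=impute_seed),
        fdr_method=fdr_method,
    )


def _is_call(diff: pd.DataFrame, design: SampleDesign) -> pd.Series:
    """Differential call: enriched or stage-specific category."""
    ref, trt = design.conditions
    labels = {f"{ref}-enriched", f"{trt}-enriched", f"{ref}-specific", f"{trt}-specific"}
    return diff["category"].isin(labels)


@dataclass
class CalibrationResult:
    n_runs: int
    mean_fdp: float
    mean_calls: float


def null_calibration(
    n_runs: int = 200,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    fdr_cut: float = 0.05,
) -> CalibrationResult:
    """Mean false-discovery proportion of q < ``fdr_cut`` calls under the
    global null (no planted effects).

    The FDP of a run counts test-based discoveries (q below the cut among
    proteins quantified in both stages); stage-specific categories are
    presence/absence claims whose q-value is an artifact of the constant
    condition-absent fill, so they are excluded from the test calibration.
    Every discovery under the null is false, so a run's FDP is 1 when it
    makes any call and 0 otherwise; the mean over runs estimates the FDR.
    """
    fdps, calls = [], []
    for run_seed in _child_seeds(seed, n_runs):
        cfg = dataclasses.replace(
            config, frac_differential=0.0, frac_stage_specific=0.0, seed=run_seed
        )
        result = run_on_dataset(simulate_dataset(cfg))
        diff = result.differential
        testable = diff["stage_specific"] == NO_STAGE
        n_calls = int((testable & (diff["q_value"] < fdr_cut)).sum())
        calls.append(n_calls)
        fdps.append(1.0 if n_calls > 0 else 0.0)
    return CalibrationResult(
        n_runs=n_runs, mean_fdp=float(np.mean(fdps)), mean_calls=float(np.mean(calls))
    )


@dataclass
class RecoveryResult:
    n_runs: int
    sensitivity: float
    fdp: float


def recovery_study(
    n_runs: int = 20,
    n_proteins: int = 1000,
    log2fc: float = 1.0,
    replicate_sd: float = 0.25,
    frac_differential: float = 0.10,
    seed: int = 0,
) -> RecoveryResult:
    """Sensitivity and FDP for planted constant-magnitude fold-changes.

    Sensitivity is the fraction of truly differential proteins the
    pipeline calls differential (enriched or stage-specific); FDP the
    fraction of calls that are not truly differential.  Both are averaged
    over runs.
    """
    sens, fdps = [], []
    for run_seed in _child_seeds(seed, n_runs):
        cfg = SimConfig(
            n_proteins=n_proteins,
            frac_differential=frac_differential,
            frac_stage_specific=0.0,
            log2fc_range=(log2fc, log2fc),
            replicate_sd=replicate_sd,
            seed=run_seed,
        )
        dataset = simulate_dataset(cfg)
        result = run_on_dataset(dataset)
        diff = result.differential
        truth = dataset.truth.set_index("protein_id")["is_differential"]
        truth = truth.reindex(diff.index).fillna(False).astype(bool)
        call = _is_call(diff, dataset.design)
        n_true = int(truth.sum())
        tp = int((call & truth).sum())
        fp = int((call & ~truth).sum())
        sens.append(tp / n_true if n_true else np.nan)
        fdps.append(fp / max(tp + fp, 1))
    return RecoveryResult(
        n_runs=n_runs, sensitivity=float(np.mean(sens)), fdp=float(np.mean(fdps))
    )


def correlation_recovery(
    targets: tuple[float, ...] = (0.9, 0.5, 0.0, -0.1),
    n_per_class: int = 100,
    n_seeds: int = 50,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Recover per-class transcript-protein correlation targets.

    Simulates ``len(targets)`` classes of ``n_per_class`` proteins each,
    runs the pipeline, correlates the measured protein log2 ratios with the
    transcript ratios (pseudocount 0 — generated RPM are strictly
    positive) and averages the absolute estimation error per class over
    seeds.  Returns the grand mean absolute error and the per-class table.
    """
    n_classes = len(targets)
    class_names = tuple(f"class r={t:+.2f}" for t in targets)
    per_seed = []
    for run_seed in _child_seeds(seed, n_seeds):
        cfg = SimConfig(
            n_proteins=n_per_class * n_classes,
            n_classes=n_classes,
            class_names=class_names,
            class_target_r=tuple(targets),
            seed=run_seed,
        )
        dataset = simulate_dataset(cfg)
        result = run_on_dataset(dataset)
        ann_df = dataset.annotation
        annotation = AnnotationMap(
            go_terms={},
            functional_class=dict(
                zip(ann_df["protein_id"], ann_df["functional_class"])
            ),
            gene_id=dict(zip(ann_df["protein_id"], ann_df["gene_id"])),
        )
        tfc = transcript_log2fc(
            dataset.transcripts, dataset.design.conditions, pseudocount=0.0
        )
        corr = correlate_by_class(
            result.differential["log2_ratio"], tfc, annotation
        )
        row = {}
        for name, target in zip(class_names, targets):
            match = corr[corr["scope"] == name]
            if len(match):
                row[name] = abs(float(match["r"].iloc[0]) - target)
        per_seed.append(row)
    errors = pd.DataFrame(per_seed)
    per_class = pd.DataFrame(
        {
            "class": class_names,
            "target_r": targets,
            "mean_abs_error": [errors[c].mean() for c in class_names],
        }
    )
    return float(errors.to_numpy().mean()), per_class
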