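"""Synthetic LFQ proteomics + transcript data with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-protein baseline log2 LFQ intensities are normal across the
  proteome (default mean 25, SD 2 — the scale of summed MS1 intensities);
* two conditions x three biological replicates, with planted log2
  fold-changes split evenly around the baseline and independent normal
  replicate noise (default SD 0.25 log2 units);
* missing-not-at-random dropout: each cell vanishes (raw intensity 0)
  with a logistic probability that decreases with the cell's true log2
  intensity, so low-abundance proteins drop out preferentially — the
  regime that motivates downshifted-normal imputation;
* stage-specific proteins built by deterministic full dropout in one
  condition (complete in the other), giving exact 3:0 / 0:3 truth;
* per-gene transcript log2 fold-changes constructed per functional class
  so the in-sample correlation with the planted protein fold-changes
  equals the class target exactly, with the transcript dynamic range
  wider than the protein one by 1/slope (mRNA changes overshoot protein
  changes);
* GO terms planted so chosen terms are over-represented among
  differential proteins, plus background terms at a uniform rate;
* decoy / contaminant / site-only / low-evidence rows to exercise the
  identification-quality filters.

All outputs parse with :mod:`lfqpipe.io` and all randomness flows from
one seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SampleDesign, two_stage_design
from .io import write_results

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "dropout_probability",
    "simulate_dataset",
    "simulate_null",
    "DEFAULT_CLASS_NAMES",
    "CATEGORY_EXCLUDED",
]

#: fourteen broad functional classes, in the spirit of a manual GO grouping
DEFAULT_CLASS_NAMES = (
    "Cell wall metabolism",
    "Transport",
    "Vesicular trafficking",
    "Hormone biosynthesis and lipid metabolism",
    "Secondary metabolism",
    "C compound, sugar metabolism and photosynthesis",
    "Protein synthesis",
    "Protein folding and maturation",
    "Protein degradation",
    "Signalling",
    "Response to stress",
    "Energy metabolism",
    "Amino acid metabolism",
    "Other",
)

#: heterogeneous transcript-protein correlation targets across classes
DEFAULT_CLASS_TARGET_R = (
    0.88, 0.80, 0.63, 0.60, 0.55, 0.50, 0.45,
    0.40, 0.35, 0.30, 0.20, 0.10, 0.00, -0.04,
)

#: truth category for rows planted to fail the identification-quality filters
CATEGORY_EXCLUDED = "excluded"


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_proteins: int = 1000
    frac_differential: float = 0.10
    frac_stage_specific: float = 0.04
    log2fc_range: tuple[float, float] = (0.58, 3.0)
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    replicate_sd: float = 0.25
    dropout_midpoint: float = 20.5
    dropout_steepness: float = 0.8
    n_replicates: int = 3
    conditions: tuple[str, str] = ("MG30", "R45")
    n_classes: int = 14
    class_names: tuple[str, ...] | None = None
    class_target_r: tuple[float, ...] | None = None
    mrna_dynamic_range_slope: float = 0.6
    rpm_log2_mean: float = 7.0
    rpm_log2_sd: float = 1.5
    n_go_terms: int = 30
    n_planted_terms: int = 3
    planted_term_rate: float = 0.6
    background_term_rate: float = 0.05
    n_reverse: int = 5
    n_contaminants: int = 5
    n_site_only: int = 3
    n_low_evidence: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_differential", "frac_stage_specific"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_stage_specific > self.frac_differential:
            raise ValueError(
                "frac_stage_specific cannot exceed frac_differential "
                "(stage-specific proteins are a subset of the differential ones)"
            )
        if self.replicate_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.mrna_dynamic_range_slope <= 0:
            raise ValueError("mrna_dynamic_range_slope must be > 0")
        lo, hi = self.log2fc_range
        if not 0 < lo <= hi:
            raise ValueError("log2fc_range must satisfy 0 < lo <= hi")
        if self.n_classes < 1:
            raise ValueError("need at least one functional class")

    def resolved_class_names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            if len(self.class_names) != self.n_classes:
                raise ValueError("class_names length must equal n_classes")
            return self.class_names
        base = DEFAULT_CLASS_NAMES
        if self.n_classes <= len(base):
            return base[: self.n_classes]
        extra = tuple(f"Class {i}" for i in range(len(base) + 1, self.n_classes + 1))
        return base + extra

    def resolved_targets(self) -> tuple[float, ...]:
        if self.class_target_r is not None:
            if len(self.class_target_r) != self.n_classes:
                raise ValueError("class_target_r length must equal n_classes")
            return self.class_target_r
        reps = math.ceil(self.n_classes / len(DEFAULT_CLASS_TARGET_R))
        return (DEFAULT_CLASS_TARGET_R * reps)[: self.n_classes]


@dataclass
class SimulatedDataset:
    """In-memory simulated tables plus the planted truth."""

    config: SimConfig
    design: SampleDesign
    protein_groups: pd.DataFrame
    transcripts: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    planted_terms: list[str] = field(default_factory=list)

    def write(self, outdir) -> dict[str, str]:
        """Write the four tables plus the design; returns the file manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for name, frame, index in (
            ("proteinGroups.tsv", self.protein_groups, False),
            ("transcripts.tsv", self.transcripts.reset_index(), False),
            ("annotation.tsv", self.annotation, False),
            ("truth.tsv", self.truth, False),
            ("design.tsv", self.design.to_frame(), False),
        ):
            path = outdir / name
            write_results(frame, path, index=index)
            manifest[name.removesuffix(".tsv")] = str(path)
        return manifest


def dropout_probability(log2_intensity, config: SimConfig):
    """Logistic MNAR dropout probability, decreasing in intensity."""
    x = np.asarray(log2_intensity, dtype=float)
    return 1.0 / (1.0 + np.exp(config.dropout_steepness * (x - config.dropout_midpoint)))


def _correlated_mrna(
    protein_fc: np.ndarray, target_r: float, slope: float, rng: np.random.Generator
) -> np.ndarray:
    """Transcript log2 FCs with in-sample correlation ``target_r`` to
    ``protein_fc`` and dynamic range widened by 1/slope.

    Uses an exact Gram-Schmidt construction: the residual direction is
    orthogonalized against the standardized protein fold-changes, so the
    realized sample correlation equals the target whenever the protein
    fold-changes vary.  Degenerate classes (constant protein FC, e.g. a
    null simulation, or fewer than 3 members) fall back to independent
    normals.
    """
    n = len(protein_fc)
    sd_p = float(np.std(protein_fc))
    if n < 3 or sd_p == 0:
        return rng.normal(0.0, 0.5, size=n)
    z = (protein_fc - protein_fc.mean()) / sd_p
    e = rng.normal(size=n)
    e = e - e.mean()
    e = e - z * (e @ z) / (z @ z)
    sd_e = float(np.std(e))
    if sd_e == 0:  # pathological; independent fallback
        return rng.normal(0.0, 0.5, size=n)
    e /= sd_e
    m_std = target_r * z + math.sqrt(max(0.0, 1.0 - target_r**2)) * e
    return m_std * (sd_p / slope)


def simulate_dataset(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """Generate the full linked dataset (proteins, transcripts, annotation).

    Planted truth per protein: true log2 fold-change, intended category,
    functional class, gene id and the matching transcript fold-change.
    """
    rng = np.random.default_rng(config.seed)
    design = two_stage_design(config.conditions, config.n_replicates)
    ref, trt = design.conditions
    n = config.n_proteins
    n_rep = config.n_replicates

    n_diff = round(n * config.frac_differential)
    n_ss = round(n * config.frac_stage_specific)
    lo, hi = config.log2fc_range

    protein_ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    gene_ids = np.array([f"Solyc{i:05d}" for i in range(1, n + 1)])

    # planted fold-changes: first n_diff proteins differential, of which
    # the first n_ss are stage-specific (large FC, forced full dropout)
    true_fc = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    mags = rng.uniform(lo, hi, size=n_diff)
    mid = (lo + hi) / 2
    mags[:n_ss] = rng.uniform(max(mid, lo), hi, size=n_ss)
    true_fc[:n_diff] = signs * mags
    is_diff = np.zeros(n, dtype=bool)
    is_diff[:n_diff] = True
    is_ss = np.zeros(n, dtype=bool)
    is_ss[:n_ss] = True

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    cond_mean = {
        ref: baseline - true_fc / 2.0,
        trt: baseline + true_fc / 2.0,
    }
    log2_true = np.empty((n, 2 * n_rep))
    for j, sid in enumerate(design.sample_ids):
        cond = design.condition_of(sid)
        log2_true[:, j] = cond_mean[cond] + rng.normal(0, config.replicate_sd, size=n)

    # MNAR dropout on the true (pre-censoring) cell intensities
    p_drop = dropout_probability(log2_true, config)
    dropped = rng.random(size=log2_true.shape) < p_drop

    # stage-specific proteins: full dropout in the low condition, complete
    # in the high one
    for i in range(n_ss):
        low_cond = ref if true_fc[i] > 0 else trt
        for j, sid in enumerate(design.sample_ids):
            dropped[i, j] = design.condition_of(sid) == low_cond

    raw = np.where(dropped, 0.0, np.exp2(log2_true))

    # intended category given the planted design
    categories = np.full(n, "invariant", dtype=object)
    enriched = is_diff & ~is_ss
    categories[enriched & (true_fc > 0)] = f"{trt}-enriched"
    categories[enriched & (true_fc < 0)] = f"{ref}-enriched"
    categories[is_ss & (true_fc > 0)] = f"{trt}-specific"
    categories[is_ss & (true_fc < 0)] = f"{ref}-specific"

    # functional classes and class-wise correlated transcript fold-changes
    class_names = config.resolved_class_names()
    targets = config.resolved_targets()
    cls_idx = rng.integers(0, config.n_classes, size=n)
    mrna_fc = np.zeros(n)
    for c in range(config.n_classes):
        members = np.flatnonzero(cls_idx == c)
        if len(members) == 0:
            continue
        mrna_fc[members] = _correlated_mrna(
            true_fc[members], targets[c], config.mrna_dynamic_range_slope, rng
        )

    rpm_ref = np.exp2(rng.normal(config.rpm_log2_mean, config.rpm_log2_sd, size=n))
    rpm_trt = rpm_ref * np.exp2(mrna_fc)
    transcripts = pd.DataFrame(
        {f"rpm_{ref}": rpm_ref, f"rpm_{trt}": rpm_trt},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # GO annotation: planted terms enriched among differential proteins
    all_terms = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    planted = all_terms[: config.n_planted_terms]
    term_sets: list[set[str]] = [set() for _ in range(n)]
    for t, term in enumerate(all_terms):
        if term in planted:
            rate = np.where(
                is_diff, config.planted_term_rate, config.background_term_rate / 2
            )
        else:
            rate = np.full(n, config.background_term_rate)
        hit = rng.random(n) < rate
        for i in np.flatnonzero(hit):
            term_sets[i].add(term)

    razor = 2 + rng.poisson(6, size=n)
    unique = np.array([rng.integers(1, r + 1) for r in razor])

    rows = {
        "Protein IDs": list(protein_ids),
        "Protein names": [f"synthetic protein {pid}" for pid in protein_ids],
        "Razor + unique peptides": list(razor),
        "Unique peptides": list(unique),
        "Reverse": [""] * n,
        "Potential contaminant": [""] * n,
        "Only identified by site": [""] * n,
    }

    # planted failures of the identification-quality filters
    extra_rows: list[dict] = []

    def _extra(prefix: str, count: int, **flags) -> None:
        for k in range(1, count + 1):
            pid = f"{prefix}{k:03d}"
            r = int(2 + rng.poisson(4))
            extra_rows.append(
                {
                    "Protein IDs": pid,
                    "Protein names": f"synthetic {prefix.lower().rstrip('_')} {k}",
                    "Razor + unique peptides": r,
                    "Unique peptides": max(1, r // 2),
                    "Reverse": "+" if flags.get("reverse") else "",
                    "Potential contaminant": "+" if flags.get("contaminant") else "",
                    "Only identified by site": "+" if flags.get("site_only") else "",
                    "_intensity": np.exp2(
                        rng.normal(config.baseline_mean, config.baseline_sd)
                        + rng.normal(0, config.replicate_sd, size=2 * n_rep)
                    ),
                }
            )

    _extra("REV_", config.n_reverse, reverse=True)
    _extra("CON_", config.n_contaminants, contaminant=True)
    _extra("SITE_", config.n_site_only, site_only=True)
    for k in range(1, config.n_low_evidence + 1):
        extra_rows.append(
            {
                "Protein IDs": f"LOWEV_{k:03d}",
                "Protein names": f"synthetic low-evidence {k}",
                "Razor + unique peptides": 1,
                "Unique peptides": 1,
                "Reverse": "",
                "Potential contaminant": "",
                "Only identified by site": "",
                "_intensity": np.exp2(
                    rng.normal(config.baseline_mean, config.baseline_sd)
                    + rng.normal(0, config.replicate_sd, size=2 * n_rep)
                ),
            }
        )

    pg = pd.DataFrame(rows)
    for j, sid in enumerate(design.sample_ids):
        pg[f"LFQ intensity {sid}"] = raw[:, j]
    if extra_rows:
        extra_df = pd.DataFrame(
            [{k: v for k, v in row.items() if k != "_intensity"} for row in extra_rows]
        )
        for j, sid in enumerate(design.sample_ids):
            extra_df[f"LFQ intensity {sid}"] = [
                row["_intensity"][j] for row in extra_rows
            ]
        pg = pd.concat([pg, extra_df], ignore_index=True)

    annotation = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "go_terms": [";".join(sorted(s)) for s in term_sets],
            "functional_class": [class_names[c] for c in cls_idx],
            "gene_id": gene_ids,
        }
    )

    truth_main = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "gene_id": gene_ids,
            "true_log2fc": true_fc,
            "true_category": categories,
            "is_differential": is_diff,
            "is_stage_specific": is_ss,
            "functional_class": [class_names[c] for c in cls_idx],
            "true_transcript_log2fc": mrna_fc,
        }
    )
    if extra_rows:
        truth_extra = pd.DataFrame(
            {
                "protein_id": [row["Protein IDs"] for row in extra_rows],
                "gene_id": "",
                "true_log2fc": 0.0,
                "true_category": CATEGORY_EXCLUDED,
                "is_differential": False,
                "is_stage_specific": False,
                "functional_class": "",
                "true_transcript_log2fc": 0.0,
            }
        )
        truth = pd.concat([truth_main, truth_extra], ignore_index=True)
    else:
        truth = truth_main

    return SimulatedDataset(
        config=config,
        design=design,
        protein_groups=pg,
        transcripts=transcripts,
        annotation=annotation,
        truth=truth,
        planted_terms=planted,
    )


def simulate_null(
    config: SimConfig = SimConfig(), **overrides
) -> SimulatedDataset:
    """Dataset with no planted effects (for FDR calibration)."""
    cfg = dataclasses.replace(
        config, frac_differential=0.0, frac_stage_specific=0.0, **overrides
    )
    return simulate_dataset(cfg)
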