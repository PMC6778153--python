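"""Identification-quality filters, log transform, valid-value filtering.

The quantification filter implements the study's retention rule: a protein
is kept when it has a non-zero LFQ intensity in at least 4 of the 6 samples,
or when it is *stage-specific* — valid in all replicates of one stage and
in none of the other (pattern 3:0 or 0:3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SampleDesign
from .io import ProteinMeta

logger = logging.getLogger(__name__)

__all__ = [
    "apply_quality_filters",
    "log2_transform",
    "missingness_pattern",
    "filter_for_quantification",
    "QuantSet",
    "NO_STAGE",
]

#: stage_specific value for proteins quantified in both stages
NO_STAGE = "none"


def apply_quality_filters(
    meta: list[ProteinMeta],
    min_razor_unique: int = 2,
    min_unique: int = 1,
) -> list[str]:
    """Return ids of proteins passing the identification-quality filters.

    A protein is retained when it is not a reverse (decoy) hit, not a
    contaminant, not identified only by a modification site, and has at
    least ``min_razor_unique`` razor+unique peptides of which at least
    ``min_unique`` are unique.  With the defaults (2 razor+unique, 1
    unique) this is the stringent identification criterion; relaxing to
    ``min_razor_unique=1, min_unique=1`` gives the permissive one-peptide
    set.  Input order is preserved.
    """
    kept = [
        m.protein_id
        for m in meta
        if not (m.flag_reverse or m.flag_contaminant or m.flag_site_only)
        and m.razor_unique_peptides >= min_razor_unique
        and m.unique_peptides >= min_unique
    ]
    logger.info(
        "quality filters: retained %d / %d proteins (>=%d razor+unique, >=%d unique)",
        len(kept), len(meta), min_razor_unique, min_unique,
    )
    return kept


def log2_transform(intensities: pd.DataFrame) -> pd.DataFrame:
    """Log2-transform raw LFQ intensities; zeros become missing (NaN).

    Raises on negative input — intensity 0 is the only missing sentinel.
    """
    vals = intensities.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative raw intensities are not allowed")
    with np.errstate(divide="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)


def missingness_pattern(
    row: pd.Series, design: SampleDesign
) -> tuple[int, int]:
    """Count valid (non-missing) cells per condition for one protein row.

    Returns ``(valid_reference, valid_treatment)`` in design condition
    order.
    """
    missing = [s for s in design.sample_ids if s not in row.index]
    if missing:
        raise ValueError(f"row lacks design samples {missing}")
    ref, trt = design.conditions
    n_ref = int(row[design.samples_of(ref)].notna().sum())
    n_trt = int(row[design.samples_of(trt)].notna().sum())
    return n_ref, n_trt


@dataclass
class QuantSet:
    """Outcome of valid-value filtering.

    ``table`` is indexed by protein id with per-condition valid-value
    counts, the retention decision and the stage-specific flag (condition
    name, or ``"none"``).
    """

    design: SampleDesign
    table: pd.DataFrame

    @property
    def retained_ids(self) -> list[str]:
        return self.table.index[self.table["retained"]].tolist()

    @property
    def stage_specific(self) -> pd.Series:
        """Per retained protein: condition name where it is exclusively valid."""
        return self.table.loc[self.table["retained"], "stage_specific"]

    def pattern_of(self, protein_id: str) -> tuple[int, int]:
        row = self.table.loc[protein_id]
        ref, trt = self.design.conditions
        return int(row[f"valid_{ref}"]), int(row[f"valid_{trt}"])


def filter_for_quantification(
    log_table: pd.DataFrame,
    design: SampleDesign,
    min_valid_total: int = 4,
) -> QuantSet:
    """Apply the valid-value / stage-specific retention rule.

    Retains proteins with ``valid_ref + valid_trt >= min_valid_total`` (the
    study uses 4 of 6), plus stage-specific proteins: all replicates of one
    condition valid and all of the other missing.  Idempotent on an
    already-filtered table.
    """
    ref, trt = design.conditions
    ref_cols, trt_cols = design.samples_of(ref), design.samples_of(trt)
    n_ref_reps, n_trt_reps = len(ref_cols), len(trt_cols)

    valid_ref = log_table[ref_cols].notna().sum(axis=1).astype(int)
    valid_trt = log_table[trt_cols].notna().sum(axis=1).astype(int)

    ref_only = (valid_ref == n_ref_reps) & (valid_trt == 0)
    trt_only = (valid_trt == n_trt_reps) & (valid_ref == 0)
    retained = ((valid_ref + valid_trt) >= min_valid_total) | ref_only | trt_only

    stage = pd.Series(NO_STAGE, index=log_table.index, dtype=object)
    stage[ref_only] = ref
    stage[trt_only] = trt

    table = pd.DataFrame(
        {
            f"valid_{ref}": valid_ref,
            f"valid_{trt}": valid_trt,
            "retained": retained,
            "stage_specific": stage,
        }
    )
    counts = table.loc[retained, "stage_specific"].value_counts()
    logger.info(
        "valid-value filter: retained %d / %d proteins (%d %s-specific, %d %s-specific)",
        int(retained.sum()), len(retained),
        int(counts.get(ref, 0)), ref, int(counts.get(trt, 0)), trt,
    )
    return QuantSet(design=design, table=table)
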