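"""Transcript-protein fold-change correlation, global and per functional class.

Proteins are paired with transcripts through the gene id of the annotation
map; each quantified protein contributes one point (log2 mRNA ratio on x,
log2 protein ratio on y).  Pearson's r with its two-sided t-based p-value
(the cor.test convention) is reported for the full set and for every
functional class with at least three paired points.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AnnotationMap

logger = logging.getLogger(__name__)

__all__ = [
    "transcript_log2fc",
    "pearson_with_test",
    "correlate_by_class",
    "GLOBAL_SCOPE",
]

GLOBAL_SCOPE = "global"


def transcript_log2fc(
    transcripts: pd.DataFrame,
    conditions: tuple[str, str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((rpm_trt + eps) / (rpm_ref + eps)).

    With ``pseudocount=0``, genes with zero RPM in both stages are dropped
    (ratio undefined) with a logged count; a zero in only one stage yields
    +/-inf and is dropped as well.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ref, trt = conditions
    num = transcripts[f"rpm_{trt}"] + pseudocount
    den = transcripts[f"rpm_{ref}"] + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(num / den)
    fc = pd.Series(fc, index=transcripts.index, name="transcript_log2fc")
    bad = ~np.isfinite(fc)
    if bad.any():
        logger.warning(
            "dropping %d genes with undefined transcript ratio (zero RPM, "
            "pseudocount %g)", int(bad.sum()), pseudocount,
        )
        fc = fc[~bad]
    return fc


def pearson_with_test(x, y) -> tuple[float, float, int]:
    """Pearson r and its two-sided p from t = r*sqrt((n-2)/(1-r^2)).

    Requires n >= 3 and non-zero variance on both axes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def correlate_by_class(
    protein_fc: pd.Series,
    transcript_fc: pd.Series,
    annotation: AnnotationMap,
    min_points: int = 3,
    significance: float = 0.05,
) -> pd.DataFrame:
    """Pair protein and transcript ratios, correlate globally and per class.

    ``protein_fc`` is indexed by protein id (one point per quantified
    protein, including stage-specific ones), ``transcript_fc`` by gene id.
    Proteins lacking a gene id or a transcript value are dropped with a
    logged count.  Returns one row per scope: ``scope``, ``n``, ``r``,
    ``p_value``, ``slope`` (regression of protein on transcript) and a
    ``significant`` flag.
    """
    records = []
    for pid, pfc in protein_fc.items():
        gene = annotation.gene_id.get(pid)
        if gene is None or gene not in transcript_fc.index:
            continue
        records.append(
            {
                "protein_id": pid,
                "functional_class": annotation.class_of(pid) or "unclassified",
                "protein_log2fc": float(pfc),
                "transcript_log2fc": float(transcript_fc[gene]),
            }
        )
    dropped = len(protein_fc) - len(records)
    if dropped:
        logger.info("dropped %d proteins without a paired transcript", dropped)
    if not records:
        raise ValueError("no protein-transcript pairs; check gene ids")
    pairs = pd.DataFrame(records)

    def _row(scope: str, sub: pd.DataFrame) -> dict:
        r, p, n = pearson_with_test(
            sub["transcript_log2fc"], sub["protein_log2fc"]
        )
        sx = sub["transcript_log2fc"].std(ddof=1)
        sy = sub["protein_log2fc"].std(ddof=1)
        slope = r * sy / sx if sx > 0 else math.nan
        return {
            "scope": scope, "n": n, "r": r, "p_value": p,
            "slope": slope, "significant": p < significance,
        }

    rows = [_row(GLOBAL_SCOPE, pairs)]
    for cls, sub in pairs.groupby("functional_class", sort=True):
        if len(sub) < min_points:
            logger.info("class %r has %d < %d points; skipped", cls, len(sub), min_points)
            continue
        if sub["transcript_log2fc"].std() == 0 or sub["protein_log2fc"].std() == 0:
            logger.warning("class %r has zero variance; skipped", cls)
            continue
        rows.append(_row(cls, sub))
    return pd.DataFrame(rows)
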