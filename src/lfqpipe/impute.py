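"""Two-branch missing-value imputation for left-censored LFQ data.

LFQ dropout is missing-not-at-random: low-abundance proteins fall below
the detection limit preferentially.  The pipeline therefore fills missing
log2 intensities from the low tail rather than from the observed centre:

* **Branch A** (protein missing in 1 or 2 of the 6 samples): each missing
  cell in sample *s* is drawn from a normal distribution downshifted and
  narrowed relative to that sample's observed values —
  ``Normal(mean_s - downshift * sd_s, (width * sd_s)^2)`` with the
  conventional parameters width 0.3 and downshift 1.8.
* **Branch B** (stage-specific proteins, missing in all replicates of one
  condition): every missing cell is set to one deterministic constant, the
  unweighted mean over all samples of each sample's minimum observed log2
  intensity ("average minimum log-intensity across runs").

Branch A draws are seeded and filled in (protein id, sample id)
lexicographic order, so results are reproducible and independent of row
storage order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NO_STAGE, QuantSet

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationParams",
    "compute_sample_stats",
    "average_minimum_log_intensity",
    "impute_downshifted",
    "impute_condition_absent",
    "impute",
]

BRANCH_NONE = "complete"
BRANCH_DOWNSHIFT = "downshift"
BRANCH_MIN = "condition-absent"


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-normal parameters, in units of each sample's observed SD."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


def compute_sample_stats(log_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean, SD (n-1 denominator) and minimum of observed values.

    Raises if any sample has fewer than two observed values; warns when a
    sample's observed values are constant (SD 0), which would collapse the
    imputation distribution to a point.
    """
    n_obs = log_table.notna().sum(axis=0)
    short = n_obs[n_obs < 2]
    if len(short):
        raise ValueError(
            f"samples with < 2 observed values: {short.index.tolist()}"
        )
    stats = pd.DataFrame(
        {
            "mean": log_table.mean(axis=0),
            "sd": log_table.std(axis=0, ddof=1),
            "min": log_table.min(axis=0),
            "n_obs": n_obs,
        }
    )
    zero_sd = stats.index[stats["sd"] == 0].tolist()
    if zero_sd:
        logger.warning("samples with zero observed SD: %s", zero_sd)
    return stats


def average_minimum_log_intensity(stats: pd.DataFrame) -> float:
    """Unweighted mean of per-sample observed minima, over all samples."""
    return float(stats["min"].mean())


def _missing_cells(log_table: pd.DataFrame, protein_ids) -> list[tuple[str, str]]:
    ids = list(protein_ids)
    if not ids:
        return []
    sub = log_table.loc[ids]
    rows, cols = np.nonzero(sub.isna().to_numpy())
    cells = [(sub.index[r], sub.columns[c]) for r, c in zip(rows, cols)]
    cells.sort()
    return cells


def impute_downshifted(
    log_table: pd.DataFrame,
    protein_ids,
    params: ImputationParams,
    stats: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill branch-A cells of ``protein_ids`` with downshifted-normal draws.

    Cells are filled in (protein id, sample id) lexicographic order from a
    single seeded stream; observed cells are untouched.
    """
    if stats is None:
        stats = compute_sample_stats(log_table)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cells = _missing_cells(log_table, protein_ids)
    if not cells:
        return log_table.copy()
    mu = stats["mean"] - params.downshift * stats["sd"]
    sigma = params.width * stats["sd"]
    sids = [sid for _, sid in cells]
    draws = rng.normal(mu[sids].to_numpy(), sigma[sids].to_numpy())

    vals = log_table.to_numpy(dtype=float, copy=True)
    row_of = {pid: i for i, pid in enumerate(log_table.index)}
    col_of = {sid: j for j, sid in enumerate(log_table.columns)}
    rows = [row_of[pid] for pid, _ in cells]
    cols = [col_of[sid] for sid in sids]
    vals[rows, cols] = draws
    return pd.DataFrame(vals, index=log_table.index, columns=log_table.columns)


def impute_condition_absent(
    log_table: pd.DataFrame,
    protein_ids,
    fill_value: float,
) -> pd.DataFrame:
    """Fill every missing cell of stage-specific proteins with ``fill_value``."""
    out = log_table.copy()
    for pid in protein_ids:
        row = out.loc[pid]
        out.loc[pid, row.index[row.isna()]] = fill_value
    return out


def impute(
    log_table: pd.DataFrame,
    quantset: QuantSet,
    params: ImputationParams = ImputationParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Route every retained protein to its imputation branch and fill it.

    Returns the completed table (no missing cells remain) and an audit
    frame recording each protein's branch and the values filled in.
    Branch routing partitions the retained set: proteins complete as
    observed, proteins with 1-2 missing cells (downshift branch), and
    stage-specific proteins (condition-absent branch); any other
    incomplete pattern would have been removed by the valid-value filter
    and is asserted against.
    """
    table = log_table.loc[quantset.retained_ids]
    stats = compute_sample_stats(table)
    fill_value = average_minimum_log_intensity(stats)

    n_missing = table.isna().sum(axis=1)
    stage = quantset.stage_specific

    branch = pd.Series(BRANCH_NONE, index=table.index, dtype=object)
    is_ss = stage != NO_STAGE
    branch[is_ss] = BRANCH_MIN
    branch[(~is_ss) & (n_missing > 0)] = BRANCH_DOWNSHIFT

    bad = table.index[(branch == BRANCH_DOWNSHIFT) & ~n_missing.isin((1, 2))]
    assert len(bad) == 0, f"proteins with unroutable missingness: {bad.tolist()}"

    rng = np.random.default_rng(params.seed)
    out = impute_downshifted(
        table, table.index[branch == BRANCH_DOWNSHIFT], params, stats, rng
    )
    out = impute_condition_absent(out, table.index[branch == BRANCH_MIN], fill_value)
    assert not out.isna().any().any(), "missing cells remain after imputation"

    records = []
    for pid in table.index:
        filled = table.columns[table.loc[pid].isna()]
        records.append(
            {
                "protein_id": pid,
                "branch": branch[pid],
                "n_filled": len(filled),
                "filled_samples": ";".join(filled),
                "filled_values": ";".join(f"{out.at[pid, s]:.6g}" for s in filled),
            }
        )
    audit = pd.DataFrame(records).set_index("protein_id")
    logger.info(
        "imputation: %d complete, %d downshift, %d condition-absent (fill %.4g)",
        int((branch == BRANCH_NONE).sum()),
        int((branch == BRANCH_DOWNSHIFT).sum()),
        int((branch == BRANCH_MIN).sum()),
        fill_value,
    )
    return out, audit
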