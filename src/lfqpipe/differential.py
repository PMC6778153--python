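"""Relative abundance ratios, significance testing, five-category labels.

The relative abundance ratio of a protein is the difference in average
log2 intensity between the two stages (imputed values included), i.e.
log2(treatment/reference).  Each protein is then assigned one category:

* ``<ref>-specific`` / ``<trt>-specific`` — stage-specific presence
  pattern (3:0 / 0:3), assigned regardless of the test outcome;
* ``<ref>-enriched`` — log2 ratio <= -cut and FDR q < alpha;
* ``<trt>-enriched`` — log2 ratio >= +cut and q < alpha;
* ``invariant`` — |log2 ratio| <= cut (the closed interval wins at the
  boundary |ratio| == cut);
* ``putatively-invariant`` — |log2 ratio| > cut but q >= alpha.

The default cut is 0.58 log2 units (a 1.5-fold change printed to two
decimals) and the default gate FDR < 0.05.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import SampleDesign
from .preprocess import NO_STAGE, QuantSet

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "log2_ratio",
    "two_sample_test",
    "adjust_fdr",
    "permutation_fdr",
    "classify",
    "run_differential",
    "category_labels",
    "INVARIANT",
    "PUTATIVELY_INVARIANT",
]

INVARIANT = "invariant"
PUTATIVELY_INVARIANT = "putatively-invariant"


@dataclass(frozen=True)
class Thresholds:
    """Classification gates: |log2 ratio| cut and FDR significance level."""

    logfc_cut: float = 0.58
    fdr_cut: float = 0.05

    def __post_init__(self) -> None:
        if self.logfc_cut <= 0:
            raise ValueError("logfc_cut must be > 0")
        if not 0 < self.fdr_cut < 1:
            raise ValueError("fdr_cut must be in (0, 1)")


def category_labels(design: SampleDesign) -> list[str]:
    """All category labels for a design, reference first."""
    ref, trt = design.conditions
    return [
        f"{ref}-specific",
        f"{ref}-enriched",
        INVARIANT,
        PUTATIVELY_INVARIANT,
        f"{trt}-enriched",
        f"{trt}-specific",
    ]


def log2_ratio(table: pd.DataFrame, design: SampleDesign) -> pd.Series:
    """mean(log2 treatment) - mean(log2 reference) per protein.

    Requires a complete (post-imputation) table.
    """
    if table.isna().any().any():
        raise ValueError("log2_ratio requires a complete table (impute first)")
    ref, trt = design.conditions
    return (
        table[design.samples_of(trt)].mean(axis=1)
        - table[design.samples_of(ref)].mean(axis=1)
    ).rename("log2_ratio")


def two_sample_test(
    table: pd.DataFrame, design: SampleDesign, flavor: str = "student"
) -> tuple[pd.Series, pd.Series]:
    """Two-sided two-sample t-test per protein (treatment vs reference).

    ``student`` pools variances (df = n1 + n2 - 2); ``welch`` uses the
    Satterthwaite approximation.  Degenerate rows with zero variance in
    both groups yield t = 0, p = 1 when the group means are equal and
    p = 0 (infinite t) otherwise.
    """
    if flavor not in ("student", "welch"):
        raise ValueError(f"unknown test flavor {flavor!r}")
    ref, trt = design.conditions
    a = table[design.samples_of(trt)].to_numpy(dtype=float)
    b = table[design.samples_of(ref)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows (e.g. condition-absent imputation fills) are handled
        # by the degenerate-case contract below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=(flavor == "student"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    degen_same = zero_var & equal_means
    degen_diff = zero_var & ~equal_means
    t[degen_same], p[degen_same] = 0.0, 1.0
    if degen_diff.any():
        logger.warning(
            "%d proteins with zero within-group variance and unequal means (p=0)",
            int(degen_diff.sum()),
        )
        t[degen_diff] = np.sign(a.mean(axis=1) - b.mean(axis=1))[degen_diff] * np.inf
        p[degen_diff] = 0.0
    return (
        pd.Series(t, index=table.index, name="t_stat"),
        pd.Series(p, index=table.index, name="p_value"),
    )


def adjust_fdr(p_values: pd.Series, method: str = "bh", **kwargs) -> pd.Series:
    """FDR-adjust p-values.

    ``bh`` is Benjamini-Hochberg step-up (monotone by construction);
    ``permutation`` requires keyword arguments ``table``, ``design`` and
    ``t_stats`` and delegates to :func:`permutation_fdr`.
    """
    if len(p_values) == 0:
        return pd.Series(dtype=float, name="q_value")
    if method == "bh":
        q = multipletests(p_values.to_numpy(), method="fdr_bh")[1]
        return pd.Series(q, index=p_values.index, name="q_value")
    if method == "permutation":
        return permutation_fdr(
            kwargs["table"], kwargs["design"], kwargs["t_stats"]
        )
    raise ValueError(f"unknown FDR method {method!r}")


def _group_t(values: np.ndarray, idx_a: list[int], idx_b: list[int]) -> np.ndarray:
    a, b = values[:, idx_a], values[:, idx_b]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, _ = sps.ttest_ind(a, b, axis=1)
    return np.nan_to_num(np.asarray(t, dtype=float), nan=0.0)


def permutation_fdr(
    table: pd.DataFrame,
    design: SampleDesign,
    t_stats: pd.Series,
    max_permutations: int | None = None,
) -> pd.Series:
    """Label-permutation FDR on |t| statistics.

    Enumerates every distinct split of the samples into two groups of the
    original sizes (10 for a 3v3 design, the original labelling included)
    and pools the permuted t statistics into one null.  The q-value of a
    protein is the ratio of the mean null exceedance count to the observed
    exceedance count of its |t|, clipped to [0, 1], with BH-style
    monotonicity enforced.
    """
    cols = list(table.columns)
    ref_samples = design.samples_of(design.conditions[0])
    n_ref = len(ref_samples)
    all_idx = list(range(len(cols)))
    splits = []
    seen = set()
    for combo in itertools.combinations(all_idx, n_ref):
        key = frozenset(combo)
        other = frozenset(all_idx) - key
        if key in seen or other in seen:
            continue
        seen.add(key)
        splits.append((list(combo), sorted(set(all_idx) - set(combo))))
    if max_permutations is not None and len(splits) > max_permutations:
        splits = splits[:max_permutations]

    values = table.to_numpy(dtype=float)
    null_abs = np.concatenate(
        [np.abs(_group_t(values, b_idx, a_idx)) for a_idx, b_idx in splits]
    )
    obs_abs = np.abs(np.nan_to_num(t_stats.to_numpy(dtype=float), nan=0.0))
    n_perm = len(splits)

    null_sorted = np.sort(null_abs)
    obs_sorted = np.sort(obs_abs)
    # exceedance counts via searchsorted on the sorted arrays
    null_ge = len(null_sorted) - np.searchsorted(null_sorted, obs_abs, side="left")
    obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, obs_abs, side="left")
    q_raw = (null_ge / n_perm) / np.maximum(obs_ge, 1)
    q_raw = np.clip(q_raw, 0.0, 1.0)

    # enforce monotone non-increasing q in |t| (step-up style)
    order = np.argsort(-obs_abs)
    q_sorted = q_raw[order]
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_raw)
    q[order] = q_mono
    return pd.Series(q, index=t_stats.index, name="q_value")


def classify(
    ratio: float,
    q_value: float,
    stage_specific: str,
    design: SampleDesign,
    thresholds: Thresholds = Thresholds(),
) -> str:
    """Assign the abundance category for one protein."""
    ref, trt = design.conditions
    if stage_specific == ref:
        return f"{ref}-specific"
    if stage_specific == trt:
        return f"{trt}-specific"
    if abs(ratio) <= thresholds.logfc_cut:
        return INVARIANT
    if q_value < thresholds.fdr_cut:
        return f"{trt}-enriched" if ratio > 0 else f"{ref}-enriched"
    return PUTATIVELY_INVARIANT


def run_differential(
    complete_table: pd.DataFrame,
    quantset: QuantSet,
    design: SampleDesign,
    thresholds: Thresholds = Thresholds(),
    test: str = "student",
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Ratio, test, FDR and category for every retained protein.

    Returns a frame indexed by protein id with columns ``log2_ratio``,
    ``t_stat``, ``p_value``, ``q_value``, ``stage_specific``, ``category``.
    """
    table = complete_table.loc[quantset.retained_ids]
    ratios = log2_ratio(table, design)
    t, p = two_sample_test(table, design, flavor=test)

    # the FDR family contains only proteins quantified in both stages:
    # stage-specific proteins are categorized by their presence/absence
    # pattern, and their p-values are artifacts of the constant
    # condition-absent fill (zero within-group variance), so letting them
    # into the adjustment would anti-conservatively shrink everyone
    # else's q
    stage = quantset.stage_specific.reindex(table.index).fillna(NO_STAGE)
    testable = stage == NO_STAGE
    q = pd.Series(np.nan, index=table.index, name="q_value")
    if testable.any():
        if fdr_method == "permutation":
            q[testable] = permutation_fdr(
                table.loc[testable], design, t[testable]
            )
        else:
            q[testable] = adjust_fdr(p[testable], method=fdr_method)
    cats = [
        classify(ratios[pid], q[pid], stage[pid], design, thresholds)
        for pid in table.index
    ]
    out = pd.DataFrame(
        {
            "log2_ratio": ratios,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "stage_specific": stage,
            "category": cats,
        }
    )
    counts = out["category"].value_counts()
    logger.info(
        "categories: %s",
        ", ".join(f"{c}={int(counts.get(c, 0))}" for c in category_labels(design)),
    )
    return out
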