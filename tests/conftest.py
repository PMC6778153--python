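"""Shared fixtures and independent oracles.

The oracle functions are deliberately naive re-derivations (exact rational
arithmetic, brute-force enumeration) kept independent of the package's
implementation paths.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from lfqpipe.design import SampleDesign, two_stage_design


@pytest.fixture
def design() -> SampleDesign:
    return two_stage_design()


def make_log_table(rows: dict[str, list[float | None]], design) -> pd.DataFrame:
    """Build a log2 table from per-protein value lists (None = missing)."""
    data = {
        pid: [np.nan if v is None else float(v) for v in vals]
        for pid, vals in rows.items()
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=design.sample_ids
    ).rename_axis("protein_id")


def write_protein_groups_tsv(path, rows: list[dict], sample_ids: list[str]) -> None:
    """Write a minimal proteinGroups-dialect TSV from row dicts."""
    cols = [
        "Protein IDs", "Protein names", "Razor + unique peptides",
        "Unique peptides", "Reverse", "Potential contaminant",
        "Only identified by site",
    ] + [f"LFQ intensity {s}" for s in sample_ids]
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in cols))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- oracles

def hypergeom_tail_oracle(q_ann: int, q_not: int, r_ann: int, r_not: int) -> Fraction:
    """Exact upper-tail hypergeometric probability P(X >= q_ann)."""
    total = q_ann + q_not + r_ann + r_not
    n_ann = q_ann + r_ann
    n_query = q_ann + q_not
    num = sum(
        comb(n_ann, k) * comb(total - n_ann, n_query - k)
        for k in range(q_ann, min(n_ann, n_query) + 1)
    )
    return Fraction(num, comb(total, n_query))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up: q_i = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    stepped = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(stepped, 1.0)
    return out


def retention_oracle(valid_ref: int, valid_trt: int, n_reps: int = 3) -> tuple[bool, str]:
    """Brute-force evaluation of the valid-value / stage-specific rule.

    Keep when valid in >= 4 of 6 samples, or valid in all replicates of
    one stage and none of the other (the stage-specific patterns).
    """
    if valid_ref == n_reps and valid_trt == 0:
        return True, "MG30"
    if valid_ref == 0 and valid_trt == n_reps:
        return True, "R45"
    return valid_ref + valid_trt >= 4, "none"
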