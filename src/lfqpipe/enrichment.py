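"""GO-term over-representation of a protein set against a background.

One-sided Fisher exact test (upper hypergeometric tail): for each GO term
with at least one annotated background protein, the p-value is
P(X >= observed) where X is hypergeometric with population = background
size, successes = background proteins annotated with the term, and draws =
query size.  Fold enrichment is observed / expected with
expected = query_size * background_annotated / background_size.
Annotations are used exactly as given — any ancestor-term closure must be
precomputed upstream.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

logger = logging.getLogger(__name__)

__all__ = ["build_contingency", "over_representation_p", "enrich"]


def build_contingency(
    query_set: set[str],
    background_set: set[str],
    term: str,
    annotation: AnnotationMap,
) -> tuple[int, int, int, int]:
    """2x2 counts for one term.

    Returns ``(query_annotated, query_not, rest_annotated, rest_not)``;
    margins sum to the background size.  The query must be a subset of the
    background.
    """
    if not query_set or not background_set:
        raise ValueError("query and background must be non-empty")
    offenders = query_set - background_set
    if offenders:
        raise ValueError(
            f"query proteins not in background: {sorted(offenders)[:10]}"
        )
    annotated = {p for p in background_set if term in annotation.terms_for(p)}
    q_ann = len(query_set & annotated)
    q_not = len(query_set) - q_ann
    r_ann = len(annotated) - q_ann
    r_not = len(background_set) - len(query_set) - r_ann
    return q_ann, q_not, r_ann, r_not


def over_representation_p(counts: tuple[int, int, int, int]) -> float:
    """One-sided (greater) Fisher exact p — the upper hypergeometric tail."""
    q_ann, q_not, r_ann, r_not = counts
    total = q_ann + q_not + r_ann + r_not
    n_annotated = q_ann + r_ann
    n_query = q_ann + q_not
    # P(X >= q_ann), X ~ Hypergeom(N=total, K=n_annotated, n=n_query)
    return float(sps.hypergeom.sf(q_ann - 1, total, n_annotated, n_query))


def enrich(
    query_set: set[str],
    background_set: set[str],
    annotation: AnnotationMap,
    correction: str = "bh",
    significance: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of every annotated term in the query set.

    Tests all terms with >= 1 annotated background protein; corrects
    across tested terms (``bh`` or ``bonferroni``) and sorts by (q, p).
    Returns a frame with observed/expected counts, fold enrichment, p, q
    and a ``significant`` flag (q < ``significance``).
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    terms = sorted(
        {t for p in background_set for t in annotation.terms_for(p)}
    )
    if not terms:
        logger.warning("no annotated terms in background; empty result")
    rows = []
    n_query, n_bg = len(query_set), len(background_set)
    for term in terms:
        counts = build_contingency(query_set, background_set, term, annotation)
        q_ann, _, r_ann, _ = counts
        bg_ann = q_ann + r_ann
        expected = n_query * bg_ann / n_bg
        rows.append(
            {
                "term_id": term,
                "observed": q_ann,
                "expected": expected,
                "fold_enrichment": q_ann / expected if expected > 0 else float("nan"),
                "p_value": over_representation_p(counts),
                "background_annotated": bg_ann,
                "background_size": n_bg,
                "query_size": n_query,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    method = "fdr_bh" if correction == "bh" else "bonferroni"
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method=method)[1]
    out["significant"] = out["q_value"] < significance
    out = out.sort_values(["q_value", "p_value"], kind="mergesort").reset_index(
        drop=True
    )
    cols = [
        "term_id", "observed", "expected", "fold_enrichment",
        "p_value", "q_value", "significant",
        "background_annotated", "background_size", "query_size",
    ]
    return out[cols]
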