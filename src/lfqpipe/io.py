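"""Readers and writers for the tabular formats the pipeline touches.

Input side: a MaxQuant-style ``proteinGroups`` tab-separated table (one row
per protein group with ``LFQ intensity <sample>`` columns, peptide counts
and the ``+``-encoded quality flags), an annotation table mapping protein
ids to GO terms / functional class / gene id, and a transcript table of
normalized RPM per stage.  Output side: plain TSV result tables that
round-trip through the corresponding readers.

Conventions: UTF-8, tab separator, ``.`` decimal point, raw intensity 0 is
the missing-value sentinel (negative intensities are rejected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinMeta",
    "AnnotationMap",
    "read_protein_groups",
    "parse_protein_groups_frame",
    "read_annotation_table",
    "read_transcript_table",
    "write_results",
    "read_results",
]

#: proteinGroups flag columns; a "+" cell marks the row.
FLAG_COLUMNS = {
    "Reverse": "flag_reverse",
    "Potential contaminant": "flag_contaminant",
    "Only identified by site": "flag_site_only",
}

FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class ProteinMeta:
    """Identification-quality metadata for one protein group."""

    protein_id: str
    description: str = ""
    razor_unique_peptides: int = 0
    unique_peptides: int = 0
    flag_reverse: bool = False
    flag_contaminant: bool = False
    flag_site_only: bool = False

    def __post_init__(self) -> None:
        if self.razor_unique_peptides < 0 or self.unique_peptides < 0:
            raise ValueError(f"{self.protein_id}: negative peptide count")
        if self.unique_peptides > self.razor_unique_peptides:
            raise ValueError(
                f"{self.protein_id}: unique peptides ({self.unique_peptides}) exceed "
                f"razor + unique peptides ({self.razor_unique_peptides})"
            )


@dataclass
class AnnotationMap:
    """Protein-level annotation: GO terms, functional class, gene id.

    ``go_terms`` maps protein id to a set of GO identifiers; proteins absent
    from the table have an empty set.  ``functional_class`` is a single
    label per protein (the study groups proteins into fourteen broad
    classes compiled from GO biological-process terms).  ``gene_id`` links
    a protein to its transcript for mRNA-protein comparison.
    """

    go_terms: dict[str, set[str]] = field(default_factory=dict)
    functional_class: dict[str, str] = field(default_factory=dict)
    gene_id: dict[str, str] = field(default_factory=dict)

    def terms_for(self, protein_id: str) -> set[str]:
        return self.go_terms.get(protein_id, set())

    def class_of(self, protein_id: str) -> str | None:
        return self.functional_class.get(protein_id)

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.go_terms.values():
            out |= terms
        return out


def _parse_flag(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip() == "+"


def read_protein_groups(
    path, design: SampleDesign
) -> tuple[pd.DataFrame, list[ProteinMeta]]:
    """Read a proteinGroups-dialect TSV.

    Returns
    -------
    intensities
        DataFrame indexed by protein id with one column per design sample,
        raw LFQ intensity scale (0 = not quantified).
    meta
        One :class:`ProteinMeta` per row, in file order.

    Raises
    ------
    ValueError
        If an ``LFQ intensity <sample>`` column required by the design is
        absent, an intensity cell is non-numeric or negative, or protein
        ids are duplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return parse_protein_groups_frame(df, design, source=str(path))


def parse_protein_groups_frame(
    df: pd.DataFrame, design: SampleDesign, source: str = "<frame>"
) -> tuple[pd.DataFrame, list[ProteinMeta]]:
    """Parse an in-memory proteinGroups-dialect frame (string cells)."""
    path = source
    df = df.astype(str).replace("nan", "")
    if "Protein IDs" not in df.columns:
        raise ValueError(f"{path}: missing 'Protein IDs' column")

    lfq_cols = {}
    for sample in design.sample_ids:
        col = f"LFQ intensity {sample}"
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r} for design sample {sample!r}"
            )
        lfq_cols[sample] = col

    ids = df["Protein IDs"].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated protein ids {dups}")

    values = pd.DataFrame(index=pd.Index(ids, name="protein_id"))
    for sample, col in lfq_cols.items():
        raw = df[col].fillna("0").replace("", "0")
        try:
            parsed = raw.astype(float)
        except ValueError:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna()]
            row = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(
                f"{path}: non-numeric intensity {bad.iloc[0]!r} in column "
                f"{col!r}, line {row}"
            ) from None
        if (parsed < 0).any():
            row = int(parsed.index[parsed < 0][0]) + 2
            raise ValueError(f"{path}: negative intensity in {col!r}, line {row}")
        values[sample] = parsed.to_numpy()

    flags = {}
    for col, attr in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[attr] = _parse_flag(df[col])
        else:
            logger.warning("%s: flag column %r absent; assuming all negative", path, col)
            flags[attr] = pd.Series(False, index=df.index)

    def _count(col: str) -> pd.Series:
        if col in df.columns:
            return pd.to_numeric(df[col], errors="raise").fillna(0).astype(int)
        logger.warning("%s: column %r absent; assuming 0", path, col)
        return pd.Series(0, index=df.index)

    razor = _count("Razor + unique peptides")
    unique = _count("Unique peptides")
    desc = df.get("Protein names", pd.Series("", index=df.index)).fillna("")

    meta = [
        ProteinMeta(
            protein_id=ids.iloc[i],
            description=str(desc.iloc[i]),
            razor_unique_peptides=int(razor.iloc[i]),
            unique_peptides=int(unique.iloc[i]),
            flag_reverse=bool(flags["flag_reverse"].iloc[i]),
            flag_contaminant=bool(flags["flag_contaminant"].iloc[i]),
            flag_site_only=bool(flags["flag_site_only"].iloc[i]),
        )
        for i in range(len(df))
    ]

    known = (
        {"Protein IDs", "Protein names", "Razor + unique peptides", "Unique peptides"}
        | set(FLAG_COLUMNS)
        | set(lfq_cols.values())
    )
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.info("%s: ignoring %d unrecognized columns", path, len(extra))

    return values, meta


def read_annotation_table(path, go_delimiter: str = ";") -> AnnotationMap:
    """Read a protein annotation TSV.

    Expected columns: ``protein_id``, ``go_terms`` (delimiter-separated
    list, default ``;``), ``functional_class``, optional ``gene_id``.
    Duplicate rows for one protein merge their GO sets but must agree on
    the functional class.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "protein_id" not in df.columns:
        raise ValueError(f"{path}: missing 'protein_id' column")
    ann = AnnotationMap()
    for row in df.itertuples():
        pid = str(row.protein_id)
        terms = {
            t.strip()
            for t in str(getattr(row, "go_terms", "")).split(go_delimiter)
            if t.strip()
        }
        ann.go_terms.setdefault(pid, set()).update(terms)
        cls = str(getattr(row, "functional_class", "")).strip()
        if cls:
            prev = ann.functional_class.get(pid)
            if prev is not None and prev != cls:
                raise ValueError(
                    f"{path}: conflicting functional classes for {pid}: "
                    f"{prev!r} vs {cls!r}"
                )
            ann.functional_class[pid] = cls
        gene = str(getattr(row, "gene_id", "")).strip()
        if gene:
            ann.gene_id[pid] = gene
    return ann


def read_transcript_table(path) -> pd.DataFrame:
    """Read per-gene normalized RPM for both stages.

    Expected columns: ``gene_id`` plus one ``rpm_<condition>`` column per
    stage (e.g. ``rpm_MG30``, ``rpm_R45``).  RPM values must be finite and
    non-negative.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing 'gene_id' column")
    rpm_cols = [c for c in df.columns if c.startswith("rpm_")]
    if not rpm_cols:
        raise ValueError(f"{path}: no 'rpm_<condition>' columns")
    df = df.set_index("gene_id")[rpm_cols].astype(float)
    vals = df.to_numpy()
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValueError(f"{path}: RPM values must be finite and non-negative")
    return df


def write_results(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write a results table as TSV with stable column order.

    Floats are serialized to 6 significant digits; text columns round-trip
    bit-exactly.  An empty frame writes the header only.
    """
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_results(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
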