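"""Two-condition replicated sample design.

The pipeline compares exactly two conditions (for the tomato fruit study,
mature-green ``MG30`` and red-ripe ``R45`` pericarp) with a small number of
biological replicates each.  Every sample-to-condition assignment comes from
an explicit design table, never from parsing sample names, so mislabelled
columns fail loudly instead of silently swapping groups.

The ratio convention throughout the package is
``log2 ratio = mean(condition B) - mean(condition A)`` where A is the first
(reference) condition of the design — positive ratios mean "higher in B".
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

__all__ = ["SampleDesign", "two_stage_design"]


@dataclass(frozen=True)
class SampleDesign:
    """Ordered mapping of sample ids to (condition, replicate index).

    Parameters
    ----------
    assignments
        Tuple of ``(sample_id, condition, replicate)`` triples in column
        order of the intensity table.
    """

    assignments: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        ids = [a[0] for a in self.assignments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated sample ids in design")
        conds = self.conditions
        if len(conds) != 2:
            raise ValueError(
                f"design must have exactly two conditions, got {list(conds)}"
            )
        for cond in conds:
            if len(self.samples_of(cond)) < 2:
                raise ValueError(f"condition {cond!r} has fewer than 2 replicates")

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[str, int]]
    ) -> "SampleDesign":
        return cls(tuple((s, c, r) for s, (c, r) in mapping.items()))

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        """Read a design table with columns sample_id, condition, replicate."""
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
        for col in ("sample_id", "condition", "replicate"):
            if col not in df.columns:
                raise ValueError(f"design file missing column {col!r}")
        return cls(
            tuple(
                (row.sample_id, row.condition, int(row.replicate))
                for row in df.itertuples()
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.assignments, columns=["sample_id", "condition", "replicate"]
        )

    @property
    def sample_ids(self) -> list[str]:
        return [a[0] for a in self.assignments]

    @property
    def conditions(self) -> tuple[str, ...]:
        """Condition names in first-appearance order (reference first)."""
        seen: dict[str, None] = {}
        for _, cond, _ in self.assignments:
            seen.setdefault(cond)
        return tuple(seen)

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def treatment(self) -> str:
        return self.conditions[1]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c, _ in self.assignments if c == condition]

    def condition_of(self, sample_id: str) -> str:
        for s, c, _ in self.assignments:
            if s == sample_id:
                return c
        raise KeyError(sample_id)

    def __len__(self) -> int:
        return len(self.assignments)


def two_stage_design(
    conditions: Sequence[str] = ("MG30", "R45"), n_replicates: int = 3
) -> SampleDesign:
    """The study layout: two fruit stages, three biological replicates each."""
    ref, trt = conditions
    rows = [(f"{ref}_{i}", ref, i) for i in range(1, n_replicates + 1)]
    rows += [(f"{trt}_{i}", trt, i) for i in range(1, n_replicates + 1)]
    return SampleDesign(tuple(rows))
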