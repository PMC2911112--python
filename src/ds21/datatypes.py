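"""Core data containers for the dosage-imbalance analysis pipeline.

All expression values are normalized log2-scale intensities; upstream
array preprocessing (RMA/MAS5) is assumed to have happened before data
enter this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("induced", "uninduced", "parental")


class FormatError(ValueError):
    """Raised when an input file or table violates the expected format."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its valid range."""


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, probesets (rows) x samples (columns).

    Parameters
    ----------
    data : pandas.DataFrame
        Index holds unique probeset ids, columns hold unique sample ids,
        values are finite log2-scale intensities.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probeset ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values.astype(float)).all():
            bad = np.argwhere(~np.isfinite(values.astype(float)))[0]
            raise FormatError(
                f"non-finite expression value at probeset "
                f"{idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass
class SampleAnnotation:
    """Per-sample design metadata.

    ``table`` columns: sample_id, experiment_gene, clone_id, condition
    (induced / uninduced / parental), timepoint_h.  Parental samples carry
    no clone-specific transgene and use empty clone_id.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "experiment_gene", "clone_id", "condition", "timepoint_h")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample annotations: {dups.tolist()}")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown conditions: {sorted(bad)}")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must be annotated exactly once."""
        annotated = set(self.table["sample_id"])
        unannotated = [s for s in matrix.sample_ids if s not in annotated]
        if unannotated:
            raise FormatError(f"samples without annotation: {unannotated}")

    def samples_for(
        self, gene: str | None = None, condition: str | None = None
    ) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if gene is not None:
            mask &= t["experiment_gene"] == gene
        if condition is not None:
            mask &= t["condition"] == condition
        return t.loc[mask, "sample_id"].tolist()

    @property
    def genes(self) -> list[str]:
        g = self.table.loc[self.table["condition"] != "parental", "experiment_gene"]
        return sorted(g.unique())


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene or probeset identifiers."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class IdMap:
    """Source-to-target identifier conversion (possibly many-to-one)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, tgt in self.mapping.items():
            if not src or not tgt:
                raise FormatError("empty identifier in id map")

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, source_id: str) -> str | None:
        return self.mapping.get(source_id)

    def translate(self, ids: Iterable[str]) -> dict[str, str]:
        """Map each input id that has a target; unmapped ids are dropped."""
        return {i: self.mapping[i] for i in ids if i in self.mapping}


@dataclass
class DisorderProfile:
    """Per-gene intrinsically disordered regions of the encoded protein.

    ``intervals`` maps gene -> list of (start, end) residue intervals,
    1-based inclusive.  The disorder score of a gene is the number of
    distinct residues covered (overlaps merged before summation).
    """

    intervals: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        for gene, ivs in self.intervals.items():
            for start, end in ivs:
                if start > end:
                    raise FormatError(
                        f"inverted interval ({start}, {end}) for gene {gene!r}"
                    )
                if start < 1:
                    raise FormatError(
                        f"interval start {start} < 1 for gene {gene!r} "
                        "(residue coordinates are 1-based)"
                    )

    def score(self, gene: str) -> int:
        from .dosage import disorder_score

        return disorder_score(self.intervals.get(gene, []))

    def scores(self) -> dict[str, int]:
        return {g: self.score(g) for g in self.intervals}


def check_labels(labels: Mapping[str, str]) -> None:
    bad = {g: l for g, l in labels.items() if l not in ("effective", "silent")}
    if bad:
        raise ConfigurationError(f"labels must be 'effective' or 'silent': {bad}")
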