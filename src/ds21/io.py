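"""Readers and writers for the pipeline's tab-delimited formats.

Formats
-------
Expression matrix : TSV, first column probeset ids, header row sample ids.
Sample annotation : TSV with columns sample_id, experiment_gene, clone_id,
                    condition, timepoint_h.
Gene sets         : GMT — one set per line: name, description, members...
Id map            : two-column TSV (source_id, target_id).
Disorder          : three-column TSV (gene, start, end), 1-based inclusive.

Writers print numerics with 6 significant digits, which exceeds microarray
measurement precision; read(write(x)) is bit-exact on the text form.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    DisorderProfile,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    IdMap,
    SampleAnnotation,
)

log = logging.getLogger("ds21")

_FLOAT_FMT = "%.6g"


def read_expression_matrix(path: str | Path, linear: bool = False) -> ExpressionMatrix:
    """Read a probesets x samples expression matrix.

    With ``linear=True`` values are taken as linear-scale intensities and
    log2-transformed with pseudocount 1 on read.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-numeric cell at probeset {row!r}, sample {col!r} in {path}"
            )
        if numeric.isna().any():
            row = df.index[numeric.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(f"missing value at probeset {row!r}, sample {col!r}")
        df[col] = numeric.astype(float)
    if linear:
        if (df.to_numpy() < 0).any():
            raise FormatError("negative intensities cannot be log-transformed")
        df = np.log2(df + 1.0)
    matrix = ExpressionMatrix(df)
    log.info("read expression matrix %s: %d probesets x %d samples",
             path.name, *matrix.shape)
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="probeset_id")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "timepoint_h" in df.columns:
        df["timepoint_h"] = pd.to_numeric(df["timepoint_h"], errors="raise")
    return SampleAnnotation(df)


def write_sample_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read GMT-style gene sets: ``name<TAB>description<TAB>member...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: gene-set line needs name, description "
                    f"and at least one member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name, frozenset(members), description))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *sorted(gs.members)]))
            fh.write("\n")


def read_id_map(path: str | Path) -> IdMap:
    """Read a two-column source->target conversion table.

    Repeated identical pairs collapse with a warning; a source mapped to
    two different targets keeps the first pair (warned).  Many-to-one
    (several sources, one target) is legitimate and silently accepted.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: expected two non-empty columns")
            src, tgt = fields
            if src in mapping:
                if mapping[src] == tgt:
                    log.warning("%s:%d: duplicate pair %s -> %s", path, lineno, src, tgt)
                else:
                    log.warning(
                        "%s:%d: source %s already mapped to %s; ignoring %s",
                        path, lineno, src, mapping[src], tgt,
                    )
                continue
            mapping[src] = tgt
    return IdMap(mapping)


def write_id_map(idmap: IdMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, tgt in idmap.mapping.items():
            fh.write(f"{src}\t{tgt}\n")


def read_disorder_intervals(path: str | Path) -> DisorderProfile:
    """Read per-gene disordered intervals (gene, start, end; 1-based)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected gene, start, end")
            gene, start_s, end_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            intervals.setdefault(gene, [])
            # sentinel row "gene\t0\t0" declares a gene with no disordered region
            if (start, end) != (0, 0):
                intervals[gene].append((start, end))
    return DisorderProfile(intervals)


def write_disorder_intervals(profile: DisorderProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, ivs in profile.intervals.items():
            if not ivs:
                fh.write(f"{gene}\t0\t0\n")
            for start, end in ivs:
                fh.write(f"{gene}\t{start}\t{end}\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Generic TSV table reader used for DE tables, spot tables etc."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)
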