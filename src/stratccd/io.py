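"""Readers and writers for the plain-text formats the pipeline consumes.

Supported dialects: GCT 1.2 and plain TSV expression matrices, sample
metadata TSV, square labeled reference-matrix TSV, and newline-delimited
gene-panel lists. GMT gene sets live in :mod:`stratccd.genesets`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .ccd import ClockGenePanel, ReferenceMatrix
from .exceptions import FormatError, ValidationError
from .expression import ExpressionMatrix

METADATA_REQUIRED = ("sample_id", "tissue")


def _check_duplicates(ids: Sequence[str], what: str, path) -> None:
    s = pd.Series(ids)
    dups = sorted(s[s.duplicated()].unique())
    if dups:
        raise ValidationError(f"{path}: duplicated {what}: {dups}")


def read_expression(
    path, format: str | None = None, value_scale: str = "counts"
) -> ExpressionMatrix:
    """Read a genes × samples expression matrix from GCT 1.2 or TSV.

    ``format`` is inferred from the extension when omitted. Duplicate gene
    rows are an error, never silently aggregated.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        return _read_gct(path, value_scale)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.empty and frame.columns.empty:
            raise FormatError(f"{path}: no samples found in TSV header")
        _check_duplicates([str(g) for g in frame.index], "gene ids", path)
        _check_duplicates([str(s) for s in frame.columns], "sample ids", path)
        return ExpressionMatrix.from_frame(frame, value_scale)
    raise ValidationError(f"unknown expression format {format!r}")


def _read_gct(path: Path, value_scale: str) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise FormatError(f"{path}:1: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}:2: expected '<n_genes>\\t<n_samples>'")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}:2: non-integer dimensions {dims!r}") from exc
        table = pd.read_csv(fh, sep="\t")
    if list(table.columns[:2]) != ["Name", "Description"]:
        raise FormatError(
            f"{path}:3: GCT header must start with 'Name\\tDescription', got "
            f"{list(table.columns[:2])}"
        )
    if len(table) != n_genes or table.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path}: header declares ({n_genes} genes, {n_samples} samples) "
            f"but data has ({len(table)}, {table.shape[1] - 2})"
        )
    genes = [str(g) for g in table["Name"]]
    _check_duplicates(genes, "gene ids", path)
    samples = [str(c) for c in table.columns[2:]]
    _check_duplicates(samples, "sample ids", path)
    values = table.iloc[:, 2:].to_numpy(dtype=float)
    return ExpressionMatrix(genes, samples, values, value_scale)


def write_expression(expr: ExpressionMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")
        return
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            frame = expr.to_frame()
            frame.insert(0, "Description", "na")
            frame.to_csv(fh, sep="\t", index_label="Name")
        return
    raise ValidationError(f"unknown expression format {format!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata TSV.

    Requires ``sample_id`` and ``tissue`` plus either ``hardy_score`` or a
    pre-assigned ``group`` column; stratification covariates (``center``,
    ``sex``) are kept as strings.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: metadata lacks required columns {missing}")
    if "hardy_score" not in meta.columns and "group" not in meta.columns:
        raise FormatError(f"{path}: metadata needs hardy_score or group")
    _check_duplicates(list(meta["sample_id"]), "sample ids", path)
    return meta


def read_panel(path, min_genes: int = 8) -> ClockGenePanel:
    """Read a newline-delimited gene list as a clock panel."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    return ClockGenePanel(tuple(genes), min_genes=min_genes)


def write_panel(panel: ClockGenePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(panel.gene_ids) + "\n")


def read_reference_matrix(path, provenance: str | None = None) -> ReferenceMatrix:
    """Read a square labeled correlation matrix TSV as a reference."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    genes = [str(g) for g in frame.index]
    if genes != [str(c) for c in frame.columns]:
        raise FormatError(f"{path}: row and column gene labels must match in order")
    values = frame.to_numpy(dtype=float)
    return ReferenceMatrix(
        panel=ClockGenePanel(tuple(genes), min_genes=min(8, len(genes))),
        values=values,
        n_samples=3,
        provenance=provenance or f"read from {path}",
    )


def write_reference_matrix(ref: ReferenceMatrix, path) -> None:
    pd.DataFrame(
        ref.values, index=ref.panel.gene_ids, columns=ref.panel.gene_ids
    ).to_csv(path, sep="\t", index_label="gene_id")


__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "read_panel",
    "write_panel",
    "read_reference_matrix",
    "write_reference_matrix",
]
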