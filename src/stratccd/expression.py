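"""Gene-by-sample expression matrices and simple count preprocessing.

The :class:`ExpressionMatrix` is the unit every statistic in this package
consumes: a dense genes × samples array with ordered, unique gene and sample
identifiers and an explicit value scale (raw counts or log expression).

Count preprocessing follows a deliberately simple, fully reproducible recipe:
library-size normalization to counts per million (CPM) followed by a
log2(CPM + 1) transform, with lowly expressed genes (CPM > 0.5 in fewer than
20% of samples) removed before correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

VALUE_SCALES = ("counts", "log_expression")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValidationError(f"duplicated {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Dense genes × samples expression matrix.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers (rows).
    sample_ids
        Ordered unique sample identifiers (columns).
    values
        Array of shape ``(len(gene_ids), len(sample_ids))``. Must be finite;
        non-negative when ``value_scale == "counts"``.
    value_scale
        Either ``"counts"`` or ``"log_expression"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_scale: str = "log_expression"
    _gene_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.sample_ids, "sample_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if self.value_scale not in VALUE_SCALES:
            raise ValidationError(f"value_scale must be one of {VALUE_SCALES}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.value_scale == "counts" and np.any(self.values < 0):
            raise ValidationError("counts-scale values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- accessors ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[idx], self.value_scale
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        sidx = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [sidx[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, idx], self.value_scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_scale: str = "log_expression"):
        return cls(
            [str(g) for g in frame.index],
            [str(s) for s in frame.columns],
            frame.to_numpy(dtype=float),
            value_scale,
        )


def cpm_log2(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalize counts to CPM and apply log2(CPM + 1)."""
    if expr.value_scale != "counts":
        raise ValidationError("cpm_log2 expects a counts-scale matrix")
    libsize = expr.values.sum(axis=0)
    if np.any(libsize <= 0):
        bad = [s for s, t in zip(expr.sample_ids, libsize) if t <= 0]
        raise ValidationError(f"samples with zero library size: {bad}")
    cpm = expr.values / libsize * 1e6
    return ExpressionMatrix(
        list(expr.gene_ids), list(expr.sample_ids), np.log2(cpm + 1.0), "log_expression"
    )


def filter_low_expression(
    expr: ExpressionMatrix, min_cpm: float = 0.5, min_fraction: float = 0.2
) -> ExpressionMatrix:
    """Drop genes with CPM > ``min_cpm`` in fewer than ``min_fraction`` of samples.

    Operates on a counts matrix; returns the filtered counts matrix.
    """
    if expr.value_scale != "counts":
        raise ValidationError("filter_low_expression expects a counts-scale matrix")
    libsize = expr.values.sum(axis=0)
    cpm = expr.values / np.where(libsize > 0, libsize, 1.0) * 1e6
    keep = (cpm > min_cpm).mean(axis=1) >= min_fraction
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(expr.sample_ids), expr.values[keep], "counts")


def normalize_counts(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standard preprocessing: low-expression filter then log2(CPM + 1)."""
    return cpm_log2(filter_low_expression(expr))


__all__ = [
    "ExpressionMatrix",
    "cpm_log2",
    "filter_low_expression",
    "normalize_counts",
]
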