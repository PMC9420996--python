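"""Clock correlation distance (CCD) over a core-clock gene panel.

The core circadian oscillator is a transcriptional-translational feedback
loop whose components keep a well conserved mutual phase ordering: activators
(ARNTL, NPAS2, CLOCK) peak together and in antiphase to the repressors they
induce (PER and CRY family genes), with output drivers (DBP, TEF, NR1D1/2) in
between. Even without any time stamps, this ordering leaves a signature in
population expression data: same-phase clock genes correlate positively
across subjects, antiphase genes negatively. The CCD quantifies how far a
cohort's clock-gene Spearman correlation matrix lies from a reference matrix
derived from entrained tissue; larger CCD means a more disorganized clock.

ΔCCD compares two groups: under this package's sign convention

    ΔCCD = CCD(test group) − CCD(control group)

so positive values mean greater clock disorganization in the test group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .exceptions import EstimationError, ValidationError
from .expression import ExpressionMatrix

#: Canonical 12-gene core-clock panel: activators, repressors and
#: first-order output drivers of the mammalian TTFL.
DEFAULT_PANEL_GENES: tuple[str, ...] = (
    "ARNTL",
    "NPAS2",
    "CLOCK",
    "CRY1",
    "CRY2",
    "NR1D1",
    "NR1D2",
    "PER1",
    "PER2",
    "PER3",
    "DBP",
    "TEF",
)

METRICS = ("euclidean", "l1")


@dataclass(frozen=True)
class ClockGenePanel:
    """Ordered panel of core clock genes.

    The order is fixed so correlation-matrix layouts are comparable between
    observed and reference matrices. ``min_genes`` is the smallest panel size
    accepted after dropping genes missing from a dataset.
    """

    gene_ids: tuple[str, ...] = DEFAULT_PANEL_GENES
    min_genes: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("panel gene_ids must be unique")
        if len(self.gene_ids) < 3:
            raise ValidationError("panel needs at least 3 genes")
        if self.min_genes < 3:
            raise ValidationError("min_genes must be at least 3")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def restrict(self, available: Iterable[str]) -> "ClockGenePanel":
        """Drop panel genes absent from ``available``; error below ``min_genes``."""
        avail = set(available)
        kept = tuple(g for g in self.gene_ids if g in avail)
        if len(kept) < self.min_genes:
            missing = [g for g in self.gene_ids if g not in avail]
            raise EstimationError(
                f"only {len(kept)} of {len(self.gene_ids)} panel genes available "
                f"(minimum {self.min_genes}); missing: {missing}"
            )
        return ClockGenePanel(kept, self.min_genes)


def _validate_square(values: np.ndarray, n: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (n, n):
        raise ValidationError(f"correlation matrix shape {values.shape} != ({n}, {n})")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-9):
        raise ValidationError("correlation matrix must have unit diagonal")
    if np.any(np.abs(values) > 1 + 1e-9):
        raise ValidationError("correlation entries must lie in [-1, 1]")
    # enforce the invariants exactly
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return values


@dataclass
class CorrelationMatrix:
    """Symmetric rank-correlation matrix over a clock gene panel."""

    panel: ClockGenePanel
    values: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.values = _validate_square(self.values, len(self.panel))
        if self.n_samples < 3:
            raise ValidationError("a correlation matrix needs n_samples >= 3")

    def entry(self, gene_a: str, gene_b: str) -> float:
        return float(self.values[self.panel.index_of(gene_a), self.panel.index_of(gene_b)])

    def restrict(self, genes: Sequence[str]) -> "CorrelationMatrix":
        idx = [self.panel.index_of(g) for g in genes]
        sub = self.values[np.ix_(idx, idx)]
        return replace(
            self, panel=ClockGenePanel(tuple(genes), min_genes=3), values=sub
        )


@dataclass
class ReferenceMatrix(CorrelationMatrix):
    """A correlation matrix used as the entrained reference, with provenance."""

    provenance: str = ""


# ---------------------------------------------------------------------------
# rank-correlation core


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Row-wise average (midrank) ranks.

    Fast ordinal path for tie-free rows (ordinal equals average ranks when
    values are distinct); rows containing ties fall back to
    :func:`scipy.stats.rankdata`.
    """
    n = values.shape[1]
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty(values.shape, dtype=float)
    np.put_along_axis(
        ranks, order,
        np.broadcast_to(np.arange(1, n + 1, dtype=float), values.shape).copy(),
        axis=1,
    )
    sorted_vals = np.take_along_axis(values, order, axis=1)
    tied = np.nonzero((sorted_vals[:, 1:] == sorted_vals[:, :-1]).any(axis=1))[0]
    for i in tied:
        ranks[i] = rankdata(values[i])
    return ranks


def _rank_corr(values: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Spearman correlation (average ranks) between rows of ``values``.

    Returns the matrix and the indices of constant rows, whose correlations
    are defined as 0 rather than NaN.
    """
    ranks = _average_ranks(values)
    constant = np.where(ranks.std(axis=1) == 0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.asarray(corr, dtype=float)
    if constant.size:
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr, list(constant)


def spearman_matrix(expr: ExpressionMatrix, panel: ClockGenePanel) -> CorrelationMatrix:
    """Pairwise Spearman correlation of the panel genes across samples.

    Ties are handled by average ranks. A constant gene yields zero
    correlations (with a warning) instead of NaN so one flat gene cannot
    poison the matrix.
    """
    if expr.n_samples < 3:
        raise EstimationError(
            f"need at least 3 samples for a correlation matrix, got {expr.n_samples}"
        )
    missing = [g for g in panel.gene_ids if not expr.has_gene(g)]
    if missing:
        raise ValidationError(f"panel genes missing from expression matrix: {missing}")
    sub = expr.subset_genes(list(panel.gene_ids))
    corr, constant = _rank_corr(sub.values)
    if constant:
        names = [panel.gene_ids[i] for i in constant]
        warnings.warn(
            f"constant gene(s) {names}: correlations set to 0", stacklevel=2
        )
    return CorrelationMatrix(panel=panel, values=corr, n_samples=expr.n_samples)


# ---------------------------------------------------------------------------
# distances


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def ccd(
    observed: CorrelationMatrix,
    reference: CorrelationMatrix,
    metric: str = "euclidean",
) -> float:
    """Clock correlation distance between an observed and a reference matrix.

    The distance is taken over the strictly upper-triangular entries; the
    default is the Euclidean norm, with an L1 option. It is a pseudometric:
    symmetric, non-negative and zero iff the matrices agree off-diagonal.
    """
    if observed.panel.gene_ids != reference.panel.gene_ids:
        diff = set(observed.panel.gene_ids) ^ set(reference.panel.gene_ids)
        raise ValidationError(
            "observed and reference panels differ "
            f"(symmetric difference: {sorted(diff)}; order must also match)"
        )
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}")
    diff = _upper(observed.values) - _upper(reference.values)
    if metric == "euclidean":
        return float(np.linalg.norm(diff))
    return float(np.abs(diff).sum())


def _group_masks(
    labels: Sequence[str], group_test: str, group_control: str
) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    mask_t = labels == group_test
    mask_c = labels == group_control
    for name, mask in ((group_test, mask_t), (group_control, mask_c)):
        if mask.sum() < 3:
            raise EstimationError(
                f"group {name!r} has {int(mask.sum())} samples; need at least 3"
            )
    return mask_t, mask_c


def _delta_from_values(
    panel_values: np.ndarray,
    mask_test: np.ndarray,
    mask_control: np.ndarray,
    ref_upper: np.ndarray,
    metric: str,
) -> float:
    """ΔCCD from a pre-extracted panel submatrix; the permutation-loop core.

    Correlation matrices are recomputed from scratch for each label vector.
    """
    out = []
    for mask in (mask_test, mask_control):
        corr, _ = _rank_corr(panel_values[:, mask])
        diff = _upper(corr) - ref_upper
        if metric == "euclidean":
            out.append(float(np.linalg.norm(diff)))
        else:
            out.append(float(np.abs(diff).sum()))
    return out[0] - out[1]


def delta_ccd(
    expr: ExpressionMatrix,
    labels: Sequence[str],
    panel: ClockGenePanel,
    reference: ReferenceMatrix,
    group_test: str = "IC",
    group_control: str = "AD",
    metric: str = "euclidean",
) -> float:
    """ΔCCD = CCD(test group) − CCD(control group).

    ``labels`` aligns with ``expr.sample_ids``. Positive values mean the test
    group's clock correlation structure is further from the reference than
    the control group's, i.e. greater disruption in the test group.
    """
    if len(labels) != expr.n_samples:
        raise ValidationError("labels must align with expr.sample_ids")
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}")
    mask_t, mask_c = _group_masks(labels, group_test, group_control)
    panel, reference = align_panel_reference(panel, reference, expr.gene_ids)
    sub = expr.subset_genes(list(panel.gene_ids))
    return _delta_from_values(
        sub.values, mask_t, mask_c, _upper(reference.values), metric
    )


def align_panel_reference(
    panel: ClockGenePanel,
    reference: ReferenceMatrix,
    available_genes: Iterable[str],
) -> tuple[ClockGenePanel, ReferenceMatrix]:
    """Apply the missing-gene policy.

    Panel genes absent from ``available_genes`` are dropped from both the
    panel and the reference; if fewer than ``panel.min_genes`` remain an
    :class:`EstimationError` is raised rather than returning a silently
    weaker statistic.
    """
    if panel.gene_ids != reference.panel.gene_ids:
        diff = set(panel.gene_ids) ^ set(reference.panel.gene_ids)
        detail = sorted(diff) if diff else "same genes, different order"
        raise ValidationError(f"panel and reference disagree on genes: {detail}")
    reduced = panel.restrict(available_genes)
    if reduced.gene_ids == panel.gene_ids:
        return panel, reference
    ref_sub = reference.restrict(list(reduced.gene_ids))
    ref_reduced = ReferenceMatrix(
        panel=ClockGenePanel(reduced.gene_ids, reduced.min_genes),
        values=ref_sub.values,
        n_samples=reference.n_samples,
        provenance=reference.provenance + " [restricted to available genes]",
    )
    return ClockGenePanel(reduced.gene_ids, reduced.min_genes), ref_reduced


def build_reference(
    cohorts: Sequence[CorrelationMatrix], provenance: str = ""
) -> ReferenceMatrix:
    """Element-wise median of cohort correlation matrices as a reference.

    Inputs must share a panel (same genes, same order). The result is
    re-symmetrized with a unit diagonal and carries provenance describing the
    inputs.
    """
    if not cohorts:
        raise ValidationError("need at least one cohort matrix")
    panel = cohorts[0].panel
    for c in cohorts[1:]:
        if c.panel.gene_ids != panel.gene_ids:
            diff = set(c.panel.gene_ids) ^ set(panel.gene_ids)
            raise ValidationError(f"cohort panels differ: {sorted(diff)}")
    stack = np.stack([c.values for c in cohorts])
    med = np.median(stack, axis=0)
    med = np.clip((med + med.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(med, 1.0)
    if not provenance:
        provenance = f"element-wise median of {len(cohorts)} cohort matrices"
    return ReferenceMatrix(
        panel=panel,
        values=med,
        n_samples=int(min(c.n_samples for c in cohorts)),
        provenance=provenance,
    )


__all__ = [
    "DEFAULT_PANEL_GENES",
    "ClockGenePanel",
    "CorrelationMatrix",
    "ReferenceMatrix",
    "spearman_matrix",
    "ccd",
    "delta_ccd",
    "align_panel_reference",
    "build_reference",
]
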