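"""Per-tissue ΔCCD analysis pipeline and report writing.

Front end shaped like a multi-tissue disruption table: assign samples to
groups from Hardy death scores (0 = died on a ventilator → intensive care,
IC; 1–2 = sudden/acute death → AD; 3–4 excluded), keep tissues with more
than ``min_per_group`` samples in each group, run the stratified ΔCCD
permutation test per tissue, and write a TSV report sorted by ΔCCD plus a
machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ccd import ClockGenePanel, ReferenceMatrix, align_panel_reference, delta_ccd
from .exceptions import AnalysisError, ValidationError
from .expression import ExpressionMatrix, normalize_counts
from .inference import (
    StrataAssignment,
    bonferroni_adjust,
    null_distribution,
    perm_pvalue,
)

logger = logging.getLogger("stratccd")

HARDY_TO_GROUP = {0: "IC", 1: "AD", 2: "AD", 3: "excluded", 4: "excluded"}

#: If stratification leaves more than this fraction of samples in strata
#: containing a single group, fall back to the first covariate alone.
SINGLE_GROUP_FALLBACK_FRACTION = 0.2


def assign_groups(annotations: pd.DataFrame) -> pd.DataFrame:
    """Derive group labels from Hardy death scores.

    Score 0 (died on a ventilator) → IC; 1 and 2 (violent/sudden or sudden
    terminal medical event, terminal phase under an hour) → AD; 3 and 4 →
    excluded. Returns a copy with a ``group`` column; assignment is total.
    """
    out = annotations.copy()
    if "hardy_score" not in out.columns:
        if "group" in out.columns:
            return out
        raise ValidationError("annotations need a hardy_score or group column")
    scores = out["hardy_score"]
    bad = scores[~scores.isin(HARDY_TO_GROUP) & scores.notna()]
    if len(bad):
        raise ValidationError(
            f"hardy_score outside 0-4 for samples: "
            f"{out.loc[bad.index, 'sample_id'].tolist()}"
        )
    if scores.isna().any():
        if "group" not in out.columns:
            raise ValidationError("samples with missing hardy_score and no group")
        mask = scores.notna()
        out.loc[mask, "group"] = scores[mask].map(HARDY_TO_GROUP)
    else:
        out["group"] = scores.map(HARDY_TO_GROUP)
    return out


def select_tissues(
    annotations: pd.DataFrame, min_per_group: int = 50
) -> list[str]:
    """Tissues with strictly more than ``min_per_group`` samples per group.

    Returned sorted for determinism. The strict inequality means a tissue
    with exactly ``min_per_group`` samples in either group is excluded.
    """
    if "group" not in annotations.columns:
        raise ValidationError("assign groups before selecting tissues")
    counts = (
        annotations[annotations["group"].isin(["AD", "IC"])]
        .groupby(["tissue", "group"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    keep = []
    for tissue, row in counts.iterrows():
        if row.get("AD", 0) > min_per_group and row.get("IC", 0) > min_per_group:
            keep.append(str(tissue))
    return sorted(keep)


@dataclass
class TissueCCDReport:
    """Per-tissue ΔCCD result with its permutation null and diagnostics."""

    tissue: str
    n_AD: int
    n_IC: int
    ccd_AD: float
    ccd_IC: float
    delta_ccd: float
    null_values: np.ndarray
    p_raw: float
    strata_summary: pd.DataFrame
    strata_vars: tuple[str, ...]
    n_permutations: int
    seed: int
    p_bonferroni: float | None = None


def run_tissue_analysis(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    panel: ClockGenePanel,
    reference: ReferenceMatrix,
    strata_vars: Sequence[str] = ("center", "sex"),
    n_permutations: int = 1000,
    seed: int = 0,
    tissue: str | None = None,
    metric: str = "euclidean",
    alternative: str = "greater",
) -> TissueCCDReport:
    """Stratified ΔCCD permutation analysis of one tissue.

    Counts matrices are normalized (CPM, log2, low-expression filter) first.
    If stratifying by all of ``strata_vars`` leaves more than 20% of samples
    in single-group strata, the analysis warns and falls back to the first
    covariate alone; if even that leaves every stratum single-group, an
    :class:`AnalysisError` asks for covariate reduction. The report is a
    pure function of (inputs, config, seed).
    """
    ann = annotations
    if tissue is not None:
        ann = ann[ann["tissue"] == tissue]
    tissue_name = tissue if tissue is not None else str(ann["tissue"].iloc[0])
    ann = ann[ann["group"].isin(["AD", "IC"])]
    ann = ann[ann["sample_id"].isin(expr.sample_ids)]
    n_ad = int((ann["group"] == "AD").sum())
    n_ic = int((ann["group"] == "IC").sum())
    if n_ad < 3 or n_ic < 3:
        raise AnalysisError(
            f"tissue {tissue_name!r}: need >=3 samples per group "
            f"(AD={n_ad}, IC={n_ic})"
        )
    sub = expr.subset_samples(list(ann["sample_id"]))
    if sub.value_scale == "counts":
        sub = normalize_counts(sub)

    strata_vars = tuple(strata_vars)
    strata = StrataAssignment.from_frame(ann, strata_vars)
    frac = strata.single_group_fraction()
    if frac >= 1.0 and len(strata_vars) > 1:
        frac_reduced = StrataAssignment.from_frame(
            ann, strata_vars[:1]
        ).single_group_fraction()
        if frac_reduced >= 1.0:
            raise AnalysisError(
                f"tissue {tissue_name!r}: all strata single-group even after "
                f"reducing to {strata_vars[0]!r}; reduce covariates further"
            )
    if frac >= 1.0 and len(strata_vars) <= 1:
        raise AnalysisError(
            f"tissue {tissue_name!r}: every stratum contains one group only; "
            "reduce the stratification covariates"
        )
    if frac > SINGLE_GROUP_FALLBACK_FRACTION and len(strata_vars) > 1:
        warnings.warn(
            f"tissue {tissue_name!r}: {frac:.0%} of samples sit in "
            f"single-group strata under {strata_vars}; falling back to "
            f"({strata_vars[0]!r},)",
            stacklevel=2,
        )
        strata_vars = strata_vars[:1]
        strata = StrataAssignment.from_frame(ann, strata_vars)

    panel_r, reference_r = align_panel_reference(panel, reference, sub.gene_ids)
    labels = strata.labels
    observed = delta_ccd(
        sub, labels, panel_r, reference_r, metric=metric
    )
    from .ccd import ccd as _ccd, spearman_matrix  # local to avoid cycle noise

    ccd_ad = _ccd(
        spearman_matrix(sub.subset_samples(
            [s for s, l in zip(sub.sample_ids, labels) if l == "AD"]
        ), panel_r),
        reference_r,
        metric,
    )
    ccd_ic = _ccd(
        spearman_matrix(sub.subset_samples(
            [s for s, l in zip(sub.sample_ids, labels) if l == "IC"]
        ), panel_r),
        reference_r,
        metric,
    )
    null = null_distribution(
        sub, strata, panel_r, reference_r, n_permutations, seed, metric=metric
    )
    p_raw = perm_pvalue(observed, null, alternative=alternative)
    logger.info(
        "tissue %s: n_AD=%d n_IC=%d strata=%s dCCD=%.3f p=%.4g",
        tissue_name, n_ad, n_ic, strata_vars, observed, p_raw,
    )
    return TissueCCDReport(
        tissue=tissue_name,
        n_AD=n_ad,
        n_IC=n_ic,
        ccd_AD=ccd_ad,
        ccd_IC=ccd_ic,
        delta_ccd=observed,
        null_values=null.values,
        p_raw=p_raw,
        strata_summary=strata.summary(),
        strata_vars=strata_vars,
        n_permutations=n_permutations,
        seed=seed,
    )


def write_report(
    reports: Sequence[TissueCCDReport],
    out_path,
    k_tests: int | None = None,
    manifest_extra: dict | None = None,
) -> pd.DataFrame:
    """Write the per-tissue table (TSV) and a JSON run manifest.

    Rows are sorted by ΔCCD descending; ``p_bonferroni = min(1, k·p_raw)``
    with ``k`` defaulting to the number of reports. Returns the table.
    """
    if k_tests is None:
        k_tests = len(reports)
    p_raw = [r.p_raw for r in reports]
    p_bonf = bonferroni_adjust(p_raw, k_tests)
    rows = []
    for r, pb in zip(reports, p_bonf):
        r.p_bonferroni = float(pb)
        rows.append(
            {
                "tissue": r.tissue,
                "n_AD": r.n_AD,
                "n_IC": r.n_IC,
                "ccd_AD": r.ccd_AD,
                "ccd_IC": r.ccd_IC,
                "delta_ccd": r.delta_ccd,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "delta_ccd", ascending=False, kind="mergesort"
    )
    out_path = Path(out_path)
    out_path.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path / "delta_ccd_report.tsv", sep="\t", index=False)
    manifest = {
        "software": "stratccd",
        "version": __version__,
        "k_tests": int(k_tests),
        "tissues": [r.tissue for r in reports],
        "n_permutations": [r.n_permutations for r in reports],
        "seeds": [r.seed for r in reports],
        "strata_vars": [list(r.strata_vars) for r in reports],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out_path / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    for r in reports:
        np.savetxt(
            out_path / f"null_{r.tissue.replace(' ', '_').replace('/', '_')}.tsv",
            r.null_values,
            fmt="%.10g",
        )
    return table


__all__ = [
    "HARDY_TO_GROUP",
    "TissueCCDReport",
    "assign_groups",
    "select_tissues",
    "run_tissue_analysis",
    "write_report",
]
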