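"""Gene-set overlap statistics: Fisher exact overrepresentation, Jaccard,
Benjamini–Hochberg adjustment, and GMT I/O.

These are the set-level statistics used around the clock analysis, e.g. to
ask whether core-clock genes or robust circadian output genes are
overrepresented among the genes a condition affects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .exceptions import FormatError, ValidationError


def _normalize(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(str(g).strip().upper() for g in genes if str(g).strip())


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (uppercased, whitespace-stripped)."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", _normalize(self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OverlapResult:
    """Result of a Fisher-exact overrepresentation test between two sets."""

    set_a: str
    set_b: str
    universe_size: int
    contingency: np.ndarray  # [[both, a_only], [b_only, neither]]
    odds_ratio: float
    p: float
    jaccard: float
    q: float | None = None

    def __post_init__(self) -> None:
        self.contingency = np.asarray(self.contingency, dtype=int)
        if self.contingency.sum() != self.universe_size:
            raise ValidationError("contingency cells must sum to universe_size")


def jaccard(set_a: GeneSet, set_b: GeneSet) -> float:
    """Jaccard coefficient |A∩B| / |A∪B| of two non-empty gene sets."""
    union = set_a.genes | set_b.genes
    if not union:
        raise ValidationError("Jaccard undefined for two empty sets")
    return len(set_a.genes & set_b.genes) / len(union)


def fisher_overlap(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> OverlapResult:
    """One-sided (enrichment) Fisher exact test for set overlap in a universe.

    Genes outside the universe are trimmed from both sets with a warning.
    The p-value is the exact hypergeometric tail, not simulated.
    """
    if not universe.genes:
        raise ValidationError("universe is empty")
    a = set_a.genes & universe.genes
    b = set_b.genes & universe.genes
    stray = (set_a.genes | set_b.genes) - universe.genes
    if stray:
        warnings.warn(
            f"{len(stray)} gene(s) outside the universe were trimmed "
            f"(e.g. {sorted(stray)[:5]})",
            stacklevel=2,
        )
    if not a or not b:
        raise ValidationError("a gene set is empty after trimming to the universe")
    u = len(universe.genes)
    both = len(a & b)
    table = np.array(
        [[both, len(a) - both], [len(b) - both, u - len(a) - len(b) + both]]
    )
    odds, p = fisher_exact(table, alternative="greater")
    inter, union = len(a & b), len(a | b)
    return OverlapResult(
        set_a=set_a.name,
        set_b=set_b.name,
        universe_size=u,
        contingency=table,
        odds_ratio=float(odds),
        p=float(p),
        jaccard=inter / union,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    "at least one gene"
                )
            sets.append(GeneSet(parts[0], frozenset(parts[2:]), source=parts[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "na", *sorted(s.genes)]) + "\n")


__all__ = [
    "GeneSet",
    "OverlapResult",
    "jaccard",
    "fisher_overlap",
    "bh_adjust",
    "read_gmt",
    "write_gmt",
]
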