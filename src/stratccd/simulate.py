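"""Synthetic circadian cohort generator.

Emulates the statistical structure the ΔCCD analysis assumes, without any
external data:

* each subject is sampled (e.g. at death) at an unknown circadian phase,
  drawn uniformly on [0, 24) hours — no time stamps are recorded;
* ~12 core clock genes follow a cosinor model with fixed relative peak
  phases and amplitudes, so same-phase genes correlate positively across
  subjects and antiphase genes negatively;
* a disruption parameter attenuates clock amplitudes (and can decohere
  phases) in one group, weakening that group's correlation structure;
* covariate strata (two collection centers, two sexes) are assigned with
  group-specific probabilities mirroring the unbalanced composition typical
  of multi-center autopsy cohorts (~55% vs ~85% from one center), and can
  optionally shift baselines or scale clock amplitudes — the confounding
  scenario the stratified permutation test exists for;
* background genes are pure noise; an optional counts mode draws
  negative-binomial reads around the exponentiated log-expression mean.

Default parameter values are documented in ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ccd import ClockGenePanel, ReferenceMatrix, spearman_matrix
from .exceptions import ValidationError
from .expression import ExpressionMatrix
from .genesets import GeneSet

#: Peak times (hours) encoding the canonical TTFL ordering: activators near
#: hour 0, repressors and first-order outputs mid-day. Keys follow the
#: canonical panel order so simulated matrices align with the default panel.
DEFAULT_PHASES: dict[str, float] = {
    "ARNTL": 0.0,
    "NPAS2": 1.0,
    "CLOCK": 23.0,
    "CRY1": 14.0,
    "CRY2": 12.0,
    "NR1D1": 6.0,
    "NR1D2": 8.0,
    "PER1": 10.0,
    "PER2": 12.0,
    "PER3": 10.0,
    "DBP": 10.0,
    "TEF": 10.0,
}

#: Peak-to-mean amplitudes on the log2 scale; strongly rhythmic output
#: drivers (NR1D1, DBP) larger than the weakly cycling CLOCK.
DEFAULT_AMPLITUDES: dict[str, float] = {
    "ARNTL": 1.2,
    "NPAS2": 1.0,
    "CLOCK": 0.5,
    "CRY1": 0.8,
    "CRY2": 0.7,
    "NR1D1": 1.5,
    "NR1D2": 1.2,
    "PER1": 1.0,
    "PER2": 1.0,
    "PER3": 1.1,
    "DBP": 1.5,
    "TEF": 1.0,
}


@dataclass(frozen=True)
class CovariateSpec:
    """A categorical covariate with group-specific level probabilities.

    ``level_probs`` maps each group label to a probability vector over
    ``levels`` — unequal vectors make the covariate a potential confounder.
    ``shifts`` adds a per-level offset to every gene's log expression;
    ``amplitude_multipliers`` scales clock amplitudes per level, which
    changes the clock correlation structure itself.
    """

    name: str
    levels: tuple[str, ...]
    level_probs: Mapping[str, tuple[float, ...]]
    shifts: Mapping[str, float] = field(default_factory=dict)
    amplitude_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, probs in self.level_probs.items():
            if len(probs) != len(self.levels):
                raise ValidationError(
                    f"covariate {self.name!r}: probability vector for group "
                    f"{group!r} must have {len(self.levels)} entries"
                )
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or np.any(p > 1) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValidationError(
                    f"covariate {self.name!r}: probabilities for group "
                    f"{group!r} must be in [0,1] and sum to 1"
                )
        for level in (*self.shifts, *self.amplitude_multipliers):
            if level not in self.levels:
                raise ValidationError(
                    f"covariate {self.name!r}: effect on unknown level {level!r}"
                )


def default_covariates() -> tuple[CovariateSpec, ...]:
    """Two-center, two-sex covariates with realistically unbalanced mixes.

    Roughly 55% of acute-death vs 85% of intensive-care samples from center
    B1, and female fractions near 23% vs 38% — the kind of imbalance seen in
    multi-center autopsy cohorts. No expression effects by default.
    """
    return (
        CovariateSpec(
            name="center",
            levels=("B1", "C1"),
            level_probs={"AD": (0.55, 0.45), "IC": (0.85, 0.15)},
        ),
        CovariateSpec(
            name="sex",
            levels=("male", "female"),
            level_probs={"AD": (0.77, 0.23), "IC": (0.62, 0.38)},
        ),
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterization of the cosinor cohort simulator.

    ``disruption_rho`` multiplies clock amplitudes in ``disrupted_group``
    (1 = intact, 0 = rhythms abolished); ``phase_noise_sd`` adds per-subject
    phase jitter (hours) in that group. See module docstring for the
    generative model.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"AD": 150, "IC": 300}
    )
    panel_phases: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PHASES))
    panel_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    baseline: Mapping[str, float] | float = 6.0
    disruption_rho: float = 1.0
    disrupted_group: str = "IC"
    phase_noise_sd: float = 0.0
    n_background_genes: int = 50
    background_baseline: float = 4.0
    noise_sd: float = 0.5
    covariates: tuple[CovariateSpec, ...] = field(default_factory=default_covariates)
    output_scale: str = "log_expression"
    nb_dispersion: float = 0.1
    tissue: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.panel_phases) != set(self.panel_amplitudes):
            raise ValidationError("panel_phases and panel_amplitudes must share genes")
        for g, ph in self.panel_phases.items():
            if not 0 <= ph < 24:
                raise ValidationError(f"phase of {g} must lie in [0, 24)")
        if any(a < 0 for a in self.panel_amplitudes.values()):
            raise ValidationError("amplitudes must be >= 0")
        if not 0 <= self.disruption_rho <= 1:
            raise ValidationError("disruption_rho must lie in [0, 1]")
        if self.phase_noise_sd < 0 or self.noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValidationError("group sizes must be >= 0")
        if self.output_scale not in ("log_expression", "counts"):
            raise ValidationError("output_scale must be log_expression or counts")
        if self.output_scale == "counts" and self.nb_dispersion <= 0:
            raise ValidationError("counts mode requires nb_dispersion > 0")
        for cov in self.covariates:
            for group in self.n_per_group:
                if group not in cov.level_probs:
                    raise ValidationError(
                        f"covariate {cov.name!r} lacks probabilities for group "
                        f"{group!r}"
                    )

    @property
    def panel(self) -> ClockGenePanel:
        return ClockGenePanel(tuple(self.panel_phases))

    def baseline_of(self, gene: str) -> float:
        if isinstance(self.baseline, Mapping):
            return float(self.baseline.get(gene, 6.0))
        return float(self.baseline)


def expected_correlation(phase_a: float, phase_b: float) -> float:
    """Large-sample correlation of two noiseless equal-amplitude cosines.

    Under uniform phase sampling, Pearson correlation of
    cos(2π(t−φa)/24) and cos(2π(t−φb)/24) is cos(2π(φa−φb)/24).
    """
    for ph in (phase_a, phase_b):
        if not 0 <= ph < 24:
            raise ValidationError("phases must lie in [0, 24)")
    return math.cos(2 * math.pi * (phase_a - phase_b) / 24.0)


def _clock_log_expression(
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    phases_t: np.ndarray,
    rho: np.ndarray,
    phase_jitter: np.ndarray,
    amp_mult: np.ndarray,
    shift: np.ndarray,
) -> np.ndarray:
    """Cosinor log expression for the clock panel; genes × subjects."""
    genes = list(config.panel_phases)
    n = phases_t.size
    out = np.empty((len(genes), n))
    for gi, g in enumerate(genes):
        amp = config.panel_amplitudes[g] * rho * amp_mult
        angle = 2 * np.pi * (phases_t + phase_jitter - config.panel_phases[g]) / 24.0
        out[gi] = (
            config.baseline_of(g)
            + shift
            + amp * np.cos(angle)
            + rng.normal(0.0, config.noise_sd, size=n)
        )
    return out


def simulate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Draw a synthetic cohort: expression, sample annotations, truth record.

    Subjects draw uniform circadian phases; clock genes follow the cosinor
    model with group-specific disruption and covariate effects; background
    genes are pure noise. With a fixed config (including seed) the output is
    byte-identical across calls.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    groups = []
    for g, n in config.n_per_group.items():
        groups.extend([g] * n)
    groups = np.asarray(groups)
    n = groups.size
    sample_ids = [f"S{i:05d}" for i in range(n)]

    # latent circadian phases, unknown to the analyst
    phases_t = rng.uniform(0.0, 24.0, size=n)
    disrupted = groups == config.disrupted_group
    rho = np.where(disrupted, config.disruption_rho, 1.0)
    phase_jitter = np.where(
        disrupted, rng.normal(0.0, config.phase_noise_sd or 0.0, size=n), 0.0
    )

    # covariate levels and their expression effects
    levels: dict[str, np.ndarray] = {}
    shift = np.zeros(n)
    amp_mult = np.ones(n)
    for cov in config.covariates:
        lv = np.empty(n, dtype=object)
        for g in config.n_per_group:
            mask = groups == g
            lv[mask] = rng.choice(
                cov.levels, size=int(mask.sum()), p=np.asarray(cov.level_probs[g])
            )
        levels[cov.name] = lv.astype(str)
        for level, s in cov.shifts.items():
            shift[lv == level] += s
        for level, m in cov.amplitude_multipliers.items():
            amp_mult[lv == level] *= m

    clock = _clock_log_expression(config, rng, phases_t, rho, phase_jitter, amp_mult, shift)
    bg = (
        config.background_baseline
        + shift
        + rng.normal(0.0, config.noise_sd, size=(config.n_background_genes, n))
    )
    values = np.vstack([clock, bg])
    gene_ids = list(config.panel_phases) + [
        f"BG{i:04d}" for i in range(config.n_background_genes)
    ]

    scale = "log_expression"
    if config.output_scale == "counts":
        mu = np.maximum(2.0**values, 1e-8)
        r = 1.0 / config.nb_dispersion
        values = rng.negative_binomial(r, r / (r + mu)).astype(float)
        scale = "counts"

    expr = ExpressionMatrix(gene_ids, sample_ids, values, scale)

    hardy = np.where(groups == "IC", 0, rng.choice([1, 2], size=n))
    annotations = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [f"SUBJ{i:05d}" for i in range(n)],
            "group": groups,
            "hardy_score": hardy,
            "tissue": config.tissue,
            "age_mid": rng.choice([35, 45, 55, 65], size=n, p=[0.1, 0.2, 0.4, 0.3]),
            **levels,
        }
    )
    truth = {
        "config": config,
        "phase_hours": phases_t,
        "phase_jitter_hours": phase_jitter,
        "amplitude_factor": rho * amp_mult,
        "covariate_levels": levels,
    }
    return expr, annotations, truth


def make_reference_fixture(
    config: SyntheticCohortConfig | None = None,
    n_subjects: int = 5000,
    seed: int = 0,
) -> ReferenceMatrix:
    """Reference matrix from a large simulated, fully entrained cohort.

    Requires an intact-clock config (``disruption_rho == 1`` and no phase
    jitter); covariates are stripped so the reference reflects clock
    structure only. Provenance records the full recipe.
    """
    config = config or SyntheticCohortConfig()
    if config.disruption_rho != 1.0 or config.phase_noise_sd != 0.0:
        raise ValidationError("reference fixture requires an entrained config")
    ref_config = replace(
        config,
        n_per_group={"REF": n_subjects},
        covariates=(),
        n_background_genes=0,
        output_scale="log_expression",
        disrupted_group="NONE",
        seed=seed,
    )
    expr, _, _ = simulate_cohort(ref_config)
    corr = spearman_matrix(expr, config.panel)
    return ReferenceMatrix(
        panel=config.panel,
        values=corr.values,
        n_samples=n_subjects,
        provenance=(
            f"synthetic: Spearman matrix of {n_subjects} simulated entrained "
            f"subjects (cosinor model, noise_sd={config.noise_sd}, seed={seed})"
        ),
    )


@lru_cache(maxsize=1)
def default_reference() -> ReferenceMatrix:
    """The shipped default reference: a large entrained synthetic cohort.

    Deterministic (fixed internal seed). Analyses of real data should supply
    the published entrained-tissue reference instead.
    """
    return make_reference_fixture(SyntheticCohortConfig(), n_subjects=5000, seed=20_201)


# ---------------------------------------------------------------------------
# scenario helpers


def null_config(
    n_per_group: Mapping[str, int] | None = None, seed: int = 0, **kwargs
) -> SyntheticCohortConfig:
    """Exchangeable null: intact clocks, unbalanced strata, no covariate effects."""
    return SyntheticCohortConfig(
        n_per_group=dict(n_per_group or {"AD": 60, "IC": 60}),
        disruption_rho=1.0,
        seed=seed,
        **kwargs,
    )


def confounded_null_config(
    n_per_group: Mapping[str, int] | None = None,
    amplitude_multiplier: float = 0.3,
    seed: int = 0,
) -> SyntheticCohortConfig:
    """Covariate-driven null: no group effect, but collection center B1
    scales clock amplitudes by ``amplitude_multiplier`` and the two groups
    draw from B1 at 55% vs 85% — the scenario a naive permutation test
    mistakes for a group effect."""
    center = CovariateSpec(
        name="center",
        levels=("B1", "C1"),
        level_probs={"AD": (0.55, 0.45), "IC": (0.85, 0.15)},
        amplitude_multipliers={"B1": amplitude_multiplier},
    )
    return SyntheticCohortConfig(
        n_per_group=dict(n_per_group or {"AD": 60, "IC": 60}),
        disruption_rho=1.0,
        covariates=(center,),
        seed=seed,
    )


def disrupted_config(
    disruption_rho: float,
    n_per_group: Mapping[str, int] | None = None,
    seed: int = 0,
    **kwargs,
) -> SyntheticCohortConfig:
    """Group effect: IC clock amplitudes attenuated by ``disruption_rho``."""
    return SyntheticCohortConfig(
        n_per_group=dict(n_per_group or {"AD": 100, "IC": 100}),
        disruption_rho=disruption_rho,
        seed=seed,
        **kwargs,
    )


def simulate_de_genelist(
    config: SyntheticCohortConfig,
    n_affected: int,
    clock_overlap: int = 0,
    output_overlap: int = 0,
    n_output_genes: int = 20,
    seed: int = 0,
) -> dict[str, GeneSet]:
    """Emit gene sets with a known overlap structure for overlap statistics.

    Returns ``universe`` (all simulated genes), ``core_clock`` (the panel),
    ``circadian_output`` (``n_output_genes`` background genes) and
    ``affected`` containing exactly ``clock_overlap`` panel genes and
    ``output_overlap`` circadian-output genes, with the remainder drawn from
    unaffiliated background genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    clock_genes = sorted(config.panel_phases)
    background = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    if n_output_genes > len(background):
        raise ValidationError("not enough background genes for the output set")
    output_genes = sorted(rng.choice(background, size=n_output_genes, replace=False))
    other = sorted(set(background) - set(output_genes))
    total = len(clock_genes) + len(background)
    if n_affected > total:
        raise ValidationError("n_affected exceeds the number of simulated genes")
    if clock_overlap > min(len(clock_genes), n_affected):
        raise ValidationError("clock_overlap exceeds panel or affected size")
    if output_overlap > min(len(output_genes), n_affected):
        raise ValidationError("output_overlap exceeds output-set or affected size")
    n_rest = n_affected - clock_overlap - output_overlap
    if n_rest < 0 or n_rest > len(other):
        raise ValidationError("inconsistent overlap request")
    affected = (
        list(rng.choice(clock_genes, size=clock_overlap, replace=False))
        + list(rng.choice(output_genes, size=output_overlap, replace=False))
        + list(rng.choice(other, size=n_rest, replace=False))
    )
    return {
        "universe": GeneSet("universe", frozenset(clock_genes + background), "synthetic"),
        "core_clock": GeneSet("core_clock", frozenset(clock_genes), "synthetic"),
        "circadian_output": GeneSet(
            "circadian_output", frozenset(output_genes), "synthetic"
        ),
        "affected": GeneSet("affected", frozenset(affected), "synthetic"),
    }


__all__ = [
    "DEFAULT_PHASES",
    "DEFAULT_AMPLITUDES",
    "CovariateSpec",
    "SyntheticCohortConfig",
    "default_covariates",
    "expected_correlation",
    "simulate_cohort",
    "make_reference_fixture",
    "default_reference",
    "null_config",
    "confounded_null_config",
    "disrupted_config",
    "simulate_de_genelist",
]
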