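# Methods

## The statistic

Let `P = (g1, …, gk)` be an ordered panel of core-clock genes (default 12:
ARNTL, NPAS2, CLOCK, CRY1, CRY2, NR1D1, NR1D2, PER1, PER2, PER3, DBP, TEF)
and `S` the k×k Spearman (average-rank) correlation matrix of those genes
across the samples of one group. With a reference matrix `R` on the same
panel, the clock correlation distance is

    CCD = || u(S) − u(R) ||_2        (L1 optional)

over the strictly upper-triangular entries `u(·)`. The group comparison is

    ΔCCD = CCD(test) − CCD(control),

positive when the test group's clock co-expression is further from the
entrained pattern. CCD is a pseudometric on correlation matrices
(non-negative, symmetric, triangle inequality); because Spearman is
rank-based, both CCD and ΔCCD are invariant to strictly monotone per-gene
transforms of expression, which makes the statistic robust to normalization
choices.

The distance metric is a genuine free choice — the statistic's definition
only requires a discrepancy between correlation matrices — and the
permutation test below is valid for any fixed choice, since observed and
permuted statistics use the same metric. We default to Euclidean and record
the metric in the run manifest.

## Stratified permutation inference

Null hypothesis: group labels are exchangeable within covariate strata
(i.e. no group effect on clock co-expression beyond what the covariates
explain). The test:

1. form strata as the cross-product of the declared covariates
   (default `center × sex`);
2. for each of `m` permutations, shuffle the group labels independently
   within every stratum and rejoin — each permutation preserves per-stratum
   and total group sizes exactly;
3. recompute ΔCCD from scratch for each permuted labeling (correlation
   matrices are never cached across permutations);
4. report the add-one estimate `p = (b + 1)/(m + 1)` with
   `b = #{null ΔCCD ≥ observed}` (ties count toward `b`), one-sided in the
   direction "test group more disrupted"; a two-sided option compares
   magnitudes.

The floor is `1/(m+1)`; with the default `m = 1000` and Bonferroni
correction over 25 tissues, the smallest attainable corrected p is
`25/1001 ≈ 0.025`. The add-one estimator makes the test exact (slightly
conservative) under within-stratum exchangeability, which our calibration
tests confirm empirically; the unstratified variant is retained
(`naive_permutation_null`) purely as a comparison arm and over-rejects
whenever a covariate that alters clock correlations is unequally
distributed between groups.

Randomness: permutation `i` of a run seeded with `s` uses the substream
`SeedSequence(s, spawn_key=(i,))`, so the null is reproducible and
independent of evaluation order.

### Covariate fallback

Fine stratification can strand samples in strata containing a single group,
where labels cannot move. If more than 20% of samples sit in single-group
strata, the analysis warns and falls back to the first covariate alone
(typically center); if even single-covariate stratification leaves every
stratum single-group, the analysis errors and asks for covariate reduction.
This mirrors the practical situation where a small tissue cannot support
sex-adjusted analysis and is adjusted for center only.

## Group assignment and tissue selection

Groups derive from the Hardy death scale: score 0 (death on a ventilator)
→ intensive care (IC); scores 1–2 (terminal phase under an hour) → acute
death (AD); scores 3–4 → excluded. Assignment is total and scores outside
0–4 are errors. Tissue inclusion requires strictly more than
`min_per_group` (default 50) samples in each group.

## Preprocessing

Counts matrices are library-size normalized to CPM, and genes with
CPM > 0.5 in fewer than 20% of samples are removed before a
`log2(CPM + 1)` transform. This is a deliberately simple, fully
reproducible recipe recorded in the run manifest; because the statistic is
rank-based, the results are insensitive to the particular monotone
transform. Panel genes lost to filtering are dropped from both the observed
and reference matrices; if fewer than `min_genes` (default 8 of 12) remain,
the tissue errors out rather than silently reporting a weaker statistic.
A constant gene gets zero correlations (with a warning) instead of NaN.

## The reference matrix

The default reference ships as a deterministic synthetic fixture: the
Spearman matrix of 5,000 simulated entrained subjects under the default
cosinor model (fixed internal seed; provenance embedded in the object). Its
sign structure matches the biology — activators positively correlated with
each other, negatively with repressors (ARNTL–PER2 ≈ −0.72). Studies aiming
to reproduce published CCD values must supply the published
entrained-tissue reference as a TSV (`stratccd.io.read_reference_matrix`);
the numeric values of that matrix are not shipped here.
`build_reference` constructs a reference as the element-wise median of
cohort matrices for users deriving their own.

## The synthetic cohort generator

Subject `i` draws an unknown sampling phase `t_i ~ Uniform[0, 24)` hours.
Clock gene `g` has log2 expression

    x_gi = b_g + c_i + ρ_i · a_i · A_g · cos(2π (t_i + ε_i − φ_g) / 24) + e_gi

with baseline `b_g` (default 6.0 log2 units), covariate shift `c_i`,
amplitude `A_g`, disruption factor `ρ_i` (= `disruption_rho` in the
disrupted group, default group IC; 1 otherwise), covariate amplitude factor
`a_i`, phase jitter `ε_i ~ N(0, phase_noise_sd)` in the disrupted group,
and residual `e_gi ~ N(0, noise_sd²)` with `noise_sd = 0.5`. Background
genes (default 50) are pure noise around baseline 4.0. Counts mode
exponentiates the log mean and draws negative-binomial counts with
dispersion `nb_dispersion` (default 0.1, variance `μ + 0.1 μ²`).

Default phases encode the canonical feedback-loop ordering (activators near
hour 0 — ARNTL 0, NPAS2 1, CLOCK 23 — repressors and outputs mid-day:
NR1D1 6, NR1D2 8, DBP/TEF/PER1/PER3 10, PER2/CRY2 12, CRY1 14). Default
amplitudes span 0.5–1.5 log2 units, largest for the strongly rhythmic
output drivers (NR1D1, DBP) and smallest for CLOCK, which cycles weakly.
These values are chosen as field-typical, not fitted to any dataset; all
are configurable.

Default covariates mirror a two-center autopsy cohort with unbalanced
composition: center B1 sampled at 55% in AD vs 85% in IC, and female
fractions 23% vs 38%. By default the covariates carry **no** expression
effects, making the default configuration an exchangeable null with
realistic confounder structure. The confounded-null scenario
(`confounded_null_config`) multiplies clock amplitudes by 0.3 at center B1,
so the group correlation matrices differ with no group effect — the case a
naive shuffle mistakes for disruption and the stratified test must not.

Disruption has two orthogonal knobs — amplitude attenuation
(`disruption_rho`) and phase decoherence (`phase_noise_sd`) — because a
correlation-pattern statistic cannot distinguish them; defaults exercise
amplitude attenuation only. Uniform phase sampling is the default
(entrainment to a shared environment with unknown sampling times).

What the generator does *not* emulate: post-mortem degradation,
tissue-specific transcriptome composition, realistic correlation structure
among background genes (they are independent), or library-size variation
beyond the NB noise. Passing tests therefore demonstrate the statistical
behaviour of the method under its stated model, not performance on any real
cohort.

## Numerical choices

* Spearman matrices use average (midrank) ranks; a fast ordinal-rank path
  serves tie-free rows, and rows with ties fall back to full midranking —
  the two agree exactly on tie-free data.
* Correlation matrices are explicitly re-symmetrized and clipped to
  [−1, 1] with unit diagonal to hold the invariants to machine precision.
* p-values and Bonferroni adjustments validate their (0, 1] domain;
  Bonferroni caps at 1; Benjamini–Hochberg uses the standard step-up via
  statsmodels.
* Replicate experiments derive one simulation seed and one permutation seed
  per replicate from a master seed via `SeedSequence.generate_state`,
  keeping all seeds below 2³¹.

## Problem sizes in the shipped experiments

The calibration, confounding and power experiments run at 500 replicates ×
200 permutations (n = 60/group), 300 × 200, and 100 × 1000 (n = 100/group)
respectively in the test suite; the acceptance script uses 300/200/50
replicates for the same designs. These sizes put the binomial Monte-Carlo
error of an estimated rejection rate near 0.01, small enough to
distinguish a calibrated 0.05 test from the inflated naive alternative.

## Known limitations

* The CCD compares correlation *patterns*; it cannot localize which gene
  pair drives a difference, and it carries no time-of-day information.
* The permutation test conditions on the observed covariate–group
  composition; covariates not declared (or unmeasured) are not protected
  against.
* ΔCCD magnitudes depend on the reference matrix and metric, so they are
  comparable across tissues only within one run configuration.
* Very fine stratification loses power as more samples land in
  single-group strata; the fallback trades covariate resolution for a
  usable null.
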