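# Methods

## Model and design

The package implements two-sample Mendelian randomization under the linear
structural model

    γ̂ⱼ ~ N(γⱼ, se²(γ̂ⱼ))            instrument–exposure associations
    Γ̂ⱼ ~ N(β·γⱼ + αⱼ, se²(Γ̂ⱼ))     instrument–outcome associations

where β is the causal effect of interest (log-odds per unit exposure for
binary outcomes) and αⱼ is a per-SNP horizontal-pleiotropy effect, zero for
a valid instrument. The three instrumental-variable assumptions are
relevance (γⱼ ≠ 0), independence from confounders, and exclusion
restriction (αⱼ = 0). Estimators differ in which violations they tolerate:
IVW assumes all instruments valid; MR-Egger allows directional pleiotropy
provided pleiotropy is independent of instrument strength (the InSIDE
condition), estimating its average as the regression intercept; the
weighted median is consistent while less than half the instrument weight is
invalid.

Mediation uses the two-step design: β₁ (exposure → mediator) and β₂
(mediator → outcome) are estimated by separate MR analyses in
non-overlapping samples, the indirect effect is the product β₁β₂, the
direct effect the difference from the total, and the mediated proportion
their ratio in percent. Variances use the first-order delta method with the
three estimates treated as independent — justified by the three-sample
design; a Monte-Carlo interval (`monte_carlo_proportion_ci`) is provided as
a cross-check and agrees with the delta interval to within a few percent of
relative width when each estimate's relative SE is ≲ 15%. The proportion CI
is deliberately not truncated to [0, 100]%: sign-discordant pathways
legitimately produce negative proportions and are retained, flagged
`valid=False`, rather than dropped.

## Key defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| exposure instrument screen | P < 1e-4 | drug-target exposures rarely have genome-wide-significant cis instruments |
| mediator instrument screen | P < 5e-8 | genome-wide significance for well-powered metabolite GWAS |
| clumping | r² < 0.8 within 250 kb | deliberately permissive cis-region pruning; the most significant SNP of each correlated set is kept, ties broken lexically |
| weak-instrument filter | F ≥ 10, F = (β/se)² | the squared instrument z-score; 10 is the conventional weak-instrument bound |
| mediator/outcome screens | P < .01 / P < .05 | raw screens, no multiplicity correction by default (a Benjamini–Hochberg option exists on `screen_mediators` via pre-filtering) |
| random-effects gate | Cochran-Q p < .05 | multiplicative over-dispersion, inflation floored at 1 |
| palindromic policy | infer_by_eaf, tolerance 0.08 | A/T and G/C SNPs kept only when both allele frequencies sit on the same side of 0.5 and outside 0.5 ± 0.08; dropped when frequency is missing |
| coloc priors | p1 = p2 = 1e-4, p12 = 1e-5 | standard single-causal-variant priors; effect-size prior SD 0.15 (quantitative traits) |
| weighted-median bootstrap | n_boot = 5000 (CLI), seed mandatory | parametric bootstrap of (γ̂, Γ̂); SD of the replicate statistics |

Inference conventions: IVW and weighted-median use normal quantiles;
MR-Egger uses t with J−2 df and a freely estimated weighted-least-squares
dispersion — pairing the estimated dispersion with t quantiles keeps the
intercept test exactly calibrated at small J, whereas flooring the
dispersion at 1 (a convention sometimes paired with random-effects IVW)
makes it conservative.

## Pleiotropy outlier test

The global statistic is the weighted sum of squared leave-one-out predicted
residuals, Σⱼ wⱼ(Γ̂ⱼ − β₋ⱼγ̂ⱼ)², with wⱼ = 1/se²(Γ̂ⱼ). Its null
distribution is simulated by drawing outcome effects around the single
full-data slope with sd √(se²(Γ̂ⱼ) + β²se²(γ̂ⱼ)) and recomputing the same
statistic. Two calibration details matter and were verified by simulation:

1. centering the draws on the per-SNP leave-one-out slopes (rather than one
   common slope) injects the sampling spread of those slopes into the null
   and drives the empirical size at nominal .05 down to ≈ .02;
2. omitting the exposure-noise term β²se²(γ̂ⱼ) from the simulation sd makes
   the test slightly liberal (size ≈ .064), because the observed residual
   Γ̂ⱼ − βγ̂ⱼ carries exposure-side noise scaled by β.

With both choices the measured size is 0.047 (2000 null replicates,
n_sim = 1000). Per-SNP outlier p-values are empirical exceedances of each
observed squared residual among its simulated counterparts, compared
against α/J (Bonferroni). When outliers are found, the corrected estimate
is IVW on the retained set and the distortion p compares the observed slope
change with the change from removing equally many random SNPs.

## Two-step pipeline

`run_total_effects` selects instruments once (screen → clump → F filter,
with a per-variant selection log and stage counts in the manifest), then
per outcome: harmonize, IVW (auto), MR-Egger, weighted median, Cochran Q,
the Egger intercept test, the outlier test (gated on the intercept p-value
by default), and leave-one-out. Failures are isolated per outcome.

`run_two_step` screens mediators on the step-1 IVW p-value, carries forward
outcomes whose total-effect p passes the significance gate, instruments
each surviving mediator from its own summary statistics, and decomposes
every (mediator, outcome) pathway. One design choice deserves emphasis: the
exposure's own instruments are excluded from each mediator's candidate
instrument pool. Such SNPs act on the mediator through the exposure, so in
the mediator → outcome regression they proxy the exposure's direct path and
violate the exclusion restriction; with a strong exposure signal they pass
a genome-wide mediator screen and inflate β₂ substantially (about two-fold
in simulation).

Outputs are fixed-format TSVs (3 decimals for effects, scientific notation
for p-values) so repeated runs with the same config and seed are
byte-identical; the manifest records thresholds, seed, instrument counts,
and failures for exact replay.

## Synthetic-data generator

`simulate_two_sample` / `simulate_mediation_triplet` simulate directly at
the summary level: true instrument effects γⱼ ~ N(0, gamma_sd²), per-SNP
standard errors from the single-variant approximation
se ≈ 1/√(2·maf(1−maf)·n) (optionally scaled by 1/√(φ(1−φ)) for a binary
outcome with case fraction φ), observed estimates drawn around the truth,
and optional LD blocks inducing correlated sampling noise (the block
correlation matrix is exported as the true LD matrix). Defaults mirror the
case study: 10 instruments, gamma_sd = 0.015, biobank-scale samples
(n ≈ 344k exposure, 490k outcome, 121k mediator), which reproduce the
printed instrument F range of roughly 13–72. A configurable fraction of
SNPs (default 0.2) receives palindromic alleles to exercise harmonization.

Pleiotropy modes: `balanced` (mean-zero αⱼ), `directional` (positive mean
shift), `inside_violating` (αⱼ proportional to instrument strength).
Directional pleiotropy is defined on the exposure-increasing allele —
harmonization orients every SNP that way, and a shift applied in the raw
allele frame would cancel under orientation instead of appearing in the
Egger intercept.

The mediation mode emits two instrument groups: exposure instruments
(`snpE*`, carrying γⱼ, β₁γⱼ, and total·γⱼ + αⱼ on the three traits) and
mediator instruments (`snpM*`, carrying δⱼ ~ N(0, delta_sd²) on the
mediator and β₂δⱼ on the outcome, nothing on the exposure) — the latter are
what a genome-wide mediator screen finds and what step 2 requires.

What the generator does **not** emulate: realistic LD from reference
panels, allele-frequency differences between samples, sample overlap,
winner's-curse selection of published instruments, case-control ascertainment
beyond the variance scaling, and non-linear or interaction effects. Passing
simulation tests therefore demonstrate correctness of the estimators under
the stated sampling model, not robustness to every artefact of real GWAS
data.

## Simulation scales used by the test suite

Recovery and calibration tests use 200–1000 replicates at 8–12 SNPs with
sample sizes of 50,000 (and the biobank-scale exposure where instrument
orientation matters), chosen so each Monte-Carlo check resolves the effects
it asserts: recovery assertions use 3 Monte-Carlo standard errors, size
assertions use 3-sigma binomial bands. Egger recovery scenarios apply the
instrument screen before estimation, as the pipeline does, because
unscreened sets include near-null SNPs whose allele orientation is decided
by sampling noise, biasing the intercept toward zero.

## Known limitations

- Instruments surviving r² < 0.8 clumping retain residual correlation, but
  the estimators treat them as independent (matching common practice for
  permissive cis-region instrument sets); SEs are accordingly somewhat
  optimistic.
- Colocalization assumes at most one causal variant per trait in the
  region; the regional H4 gate is the default decision rule, with per-SNP
  attribution left to the caller.
- No Steiger directionality filtering, multivariable MR, or mode-based
  estimators; mediation is product-of-coefficients only, without
  exposure–mediator interactions.
- The delta-method proportion CI degrades when the total effect is weakly
  estimated (|β|/se ≲ 5); use the Monte-Carlo interval there.
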