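# Methods

## The variance model

Each measured intensity of channel *c* in cell *i* of animal *a* is modeled
as a product of independent, median-1 lognormal factors on top of a
cell-fate specific setpoint:

    I_c = background_c + setpoint(promoter_c, ring)
          · G_animal(a) · G_cell(i) · P(promoter_c, i) · γ(allele_c, i) · ε(c, i)

with log-space scales σ_G,animal, σ_G,cell, σ_P, σ_γ, σ_meas. `G_animal`
is shared by all cells of an animal and `G_cell` by both channels of a
cell — together they are the expression-capacity factor. `P` is drawn once
per distinct promoter per cell, so a Type I pair (one promoter, two colors)
shares its pathway draw while a Type II pair does not. `γ` is drawn per
reporter copy, and `ε` is per-channel measurement noise.

Multiplicative, positive factors were chosen because fluorescence
intensities are positive and the dominant biological effects scale
expression rather than offsetting it. The lognormal family is an
assumption — the true distributional family of in vivo intensity variation
is not established — but it buys exact closed forms. Writing
σ_G² = σ_G,animal² + σ_G,cell², the population values of the estimators are

    η²(G)     = e^{σ_G²} − 1                         (Type II correlated)
    η²(P)     = e^{σ_G²}(e^{σ_P²} − 1)               (Type II uncorrelated − Type I γ̄)
    η²(γ)     = e^{σ_G²+σ_P²}(e^{σ_γ²+σ_meas²} − 1)  (Type I uncorrelated)
    Type I correlated = e^{σ_G²+σ_P²} − 1

These sum exactly to the per-channel CV² = e^{σ_G²+σ_P²+σ_γ²+σ_meas²} − 1,
so the three bins partition the squared coefficient of variation. Note two
consequences of the scheme that hold for real data too: per-channel
measurement noise is uncorrelated between channels and therefore lands in
the intrinsic bin, and the bins are "nested" multiplicatively, so η²(P)
carries an e^{σ_G²} prefactor rather than being a bare e^{σ_P²} − 1.

## Estimators and conventions

All η² values are computed on linear-scale intensities normalized to mean 1
within a cell-fate group (experiment × intestine ring by default); no log
transform is applied. Moments use plain means (population convention),
which makes `correlated + uncorrelated = (CV²x + CV²y)/2` an exact identity
and the estimators slightly conservative at small n (the sample-covariance
bias is O(1/n_animals) when animal-level capacity dominates). The
pre-normalization ratio of group means is recorded per group as the
relative gain/setpoint `A`; a total-least-squares slope is available as an
alternative gain estimator (`gain_estimator="tls"`) for data with
comparable noise in both channels.

Type II subtraction uses the ring-matched Type I η²(γ) when a Type I
estimate exists for that ring, otherwise the across-ring mean; the source
is recorded per group. Negative η²(P) after subtraction (sampling
overshoot) is clamped to zero for summaries with the raw value and a flag
preserved. Groups below 5 cells are skipped and logged — in the real
experimental design cells are occasionally unmeasurable, mostly in rings
2 and 4, and tiny groups make the moment estimators unstable. No outlier
removal is performed; deviant cells are kept.

Cross-experiment aggregation is the unweighted mean over groups, with
per-experiment means retained as replicate values for the statistical
layer. `compare_bins` runs a Shapiro–Wilk normality pre-check per bin
(α = 0.05; a constant bin counts as non-normal since the test is undefined
there) and then a two-tailed two-sample t-test (2 bins) or one-way ANOVA
with Tukey HSD contrasts (≥ 3 bins), switching to Mann–Whitney /
Kruskal–Wallis when normality is rejected; the chosen method is recorded in
the report. With only three replicate experiments per bin the rank-based
branch has little power — pairwise conclusions at this scale rest mainly on
the effect sizes, which the pipeline reports alongside the p-values.

## Synthetic-data defaults and what they do (and do not) show

The default design mirrors the experimental structure: 3 independent
experiments × 10 animals × 8 cells spread two-per-ring over rings 1–4
(240 cells per pair), two channels per cell, binucleate cells recorded as
the two-nucleus average. Ring-specific setpoints (arbitrary units, ratios
differing by ring) encode the rigid ratiometric setpoints that make ring
grouping necessary. Seeding is counter-based per (experiment, animal) and
(experiment, animal, cell), so subsetting animals never shifts other
animals' draws. An optional per-cell dropout probability (default 0)
emulates unmeasurable cells.

The `paper_like` scenario uses σ_G,animal = 0.25, σ_G,cell = 0.31,
σ_P = 0.10, σ_γ = 0.03, σ_meas = 0.03. These were fixed once, by three
design requirements evaluated on the closed forms: Type I allele-vs-allele
R² ≈ 0.98 ≥ 0.9 (one allele's expression accounts for ≥ 90% of the
other's), η²(G) ≈ 0.17 more than ten-fold above η²(γ) ≈ 0.002 so capacity
dominates, and an animal/cell split of σ_G under which the 30-animal design
recovers η²(G) within ±30% in ≳ 90% of replicates (an all-animal-level σ_G
would leave the animal sample alone contributing ~30% relative sampling
error). `yeast_like` triples σ_γ, `high_signaling` raises σ_P to 0.4, and
`null_no_variation` zeroes every σ.

What passing tests on this generator shows: the estimators, grouping,
subtraction and statistics recover a known multiplicative ground truth at
both asymptotic and study-scale sample sizes, and the qualitative regime
(capacity-dominated variation, tight Type I diagonal, pooling artifact) is
reproduced. What it does not show: anything about the true distributional
family, spatial correlation between neighboring cells, developmental
bursting, autofluorescence structure, or segmentation error in real
microscopy — none of which are modeled.

## Timer kinetics

The timer protein is translated green and matures irreversibly to red with
a single first-order step, half-time 48 h (k_m = ln2/48 h⁻¹); both forms
share one degradation/dilution rate d (default half-time 24 h, a young
adult's combined turnover and growth dilution). From dark initial
conditions

    dG/dt = s − (k_m + d)·G        dR/dt = k_m·G − d·R

is solved exactly (expm1-based forms keep small-t evaluation accurate; the
d = 0 and k_m = 0 limits are handled separately). At steady state
G*/R* = d/k_m independently of s — the basis of the contrast: ranking
animals by total signal and comparing the mean new/old ratio in the top and
bottom deciles leaves the ratio flat when production varies between animals
and depresses it in bright animals when turnover varies. A two-step
maturation model and distinct degradation rates for the two forms were
considered and left out: the single-step model already captures the
ratio-based logic, and nothing constrains the extra parameters.

## Numerical choices and degenerate inputs

- Group normalization divides by group means; a zero mean skips the group
  with an explicit reason rather than producing infinities.
- `correlated_uncorrelated` requires n ≥ 2 and positive means;
  `pearson_r` requires n ≥ 3 and nonzero variance in both inputs.
- The null (all-σ-zero) scenario propagates exact zeros through every bin;
  the statistical layer refuses all-identical inputs ("zero variance, test
  undefined") instead of emitting NaN.
- Validation of measurement tables is row-wise where a row is at fault
  (non-numeric or negative intensity, ring outside 1–9, bad nucleus count —
  rejected with CSV line numbers) and file-wise where the table is at fault
  (missing mandatory column, duplicate cell key).
- All simulations are reproducible from a single integer seed; derived
  seeds are generated with `numpy.random.SeedSequence` spawn keys.

## Problem sizes used in the shipped analyses

The numbered drivers and the acceptance script use the study-scale design
(240 cells per pair) for the headline decomposition, 10⁴ cells for the
Type I R² check, 10⁵ cells for closed-form convergence (estimates land
within ~1–2% of truth there), 8 000 cells for the pooling contrast, and 500
animals for the timer populations — sizes at which Monte-Carlo error is
comfortably inside the assertions' tolerances.

## Known limitations

- The moment estimators are slightly biased downward at the study scale
  (≈ −10% for η²(G) with 30 animals) because plain-mean covariance
  estimation under-counts the dominant animal-level factor; the recovery
  envelope test quantifies this.
- η²(P) inherits the subtraction's sampling noise from two Type I
  experiments and can go negative at small n; only the clamped value feeds
  summaries.
- Ring grouping assumes ring identity is known and correct; misassigned
  cells would leak setpoint ratios into η²(P) exactly like pooling does.
- No mixed-effects or Bayesian variance-component machinery: the scheme is
  deliberately the moment-based one, so results are directly comparable to
  the dual-reporter literature.
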