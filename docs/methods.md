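# Methods

## The statistical model

The target is total free urinary cortisol per void, modelled on the log₁₀
scale as a sparse linear function of standardized log₁₀ VOC abundances with
categorical modulation:

log₁₀(Y) = β₀ + Σⱼ βⱼ xⱼ + Σ₍ⱼ,d₎ cⱼd xⱼ·1[d] + ε,

where xⱼ is a metabolite's log₁₀ abundance after per-sample dilution
correction, centering and scaling (so βⱼ is in log₁₀ µg per SD), and d runs
over the binary dummies Male, Morning, Afternoon with the reference cell
female/evening. The response is log-transformed because cortisol spans more
than an order of magnitude within a day and residual structure on the raw
scale violates homoskedasticity; residuals back-transform multiplicatively
(10^r is the observed/predicted ratio).

The pipeline estimates this model in three stages because p ≫ n: an ANOVA
screen chooses which dummies may form interactions; bootstrapped
elastic-net selection frequency reduces ~500 features to top-k candidate
subsets; stepwise AICc/BIC search over the candidate design picks the final
term set, which is then fitted by OLS with naive (post-selection) t-based
inference — the same inferential convention as the original analysis
tradition, reported as such and not corrected for selection.

## Preprocessing

- **PQN**: reference spectrum = per-feature median over samples where the
  feature is observed; per-sample quotient = median over observed features
  of abundance/reference; no prior integral normalization. On tables whose
  rows are scalar multiples of one spectrum the transform is exactly
  idempotent and exactly undoes dilution; on generic tables the re-computed
  median reference shifts slightly between passes, so idempotence and
  dilution recovery hold to ~1–2 % rather than machine precision. Tests
  assert both regimes separately.
- **Filters**, fixed order: blank/early-elution (rt₁ < 358 s or blank
  flag) → PQN → presence (≥ 50 % of samples observed, ties retained) →
  cortisol range (> 45 µg dropped; an explicit exclusion list covers
  removals a range rule cannot express, e.g. borderline values excluded on
  clinical judgment). Sample-level normalization precedes feature pruning
  so quotients use the full spectrum.
- **Imputation**: remaining missing entries are treated as left-censored
  (below detection) and default to half the feature's minimum observed
  value before the log; `min` and fixed-value strategies are available.
- **Standardization** uses the n−1 sample SD, computed once on the final
  analysis set and frozen (`transform_params.json`) so the published model
  can be applied to new samples. Standardizing before the bootstrap splits
  is a deliberate, documented leakage-risk trade-off: it mirrors the
  post-processing-then-selection ordering of the emulated workflow.

## Factor screen

Two-way ANOVA with replication of log₁₀ cortisol on sex × timepoint.
Type-II sums of squares keep the screen well-defined after outlier removal
unbalances cells; on balanced designs they reduce to the textbook cell-mean
decomposition (tested against that oracle). A constant response reports
F = 0, p = 1 ("no evidence") instead of the 0/0 NaN. Only main factors
passing p < α (default 0.05) form interaction terms downstream. Repeated
measures within subject are ignored here by design — the screen mirrors the
plain two-way ANOVA of the emulated workflow; a mixed model would be the
statistically stricter choice and is a known limitation.

## Stability selection

Elastic net in the glmnet parameterisation, RSS/(2n) + λ(α‖β‖₁ +
(1−α)/2‖β‖₂²), α = 0.5, intercept unpenalized; scikit-learn's coordinate
descent is the solver (identical objective; `elastic_net_fit` honors a
1e-7 tolerance, the path solver inside the bootstrap uses the standard
1e-4). "Bootstrapping" is repeated subject-level 80/20 subsampling without
replacement — the 48/12-subject arithmetic of the emulated design — with a
with-replacement mode available. Subjects, never samples, are split, so a
subject's three timepoints stay on one side. Per iteration a 100-point
log-spaced λ grid from the data-driven λ_max down to 10⁻⁴λ_max is fitted
on the training samples and the λ minimizing held-out MSE decides the
selected (nonzero) set; per-iteration in-train cross-validation is the
config alternative. Counts over iterations give the selection frequency;
`top_k` ranks by count, breaking ties by mean |coefficient| over selecting
iterations, then column position, so subsets are deterministic. Optional
inclusion of the Male/Morning/Afternoon dummies in the selection design
(never counted as selectable features) absorbs diurnal/sex mean structure.

Known behavior worth stating: the min-test-MSE λ rule over-selects when
residual noise is small (prediction-optimal penalties are tiny), so
per-iteration models can be large; the frequency ranking, not the
per-iteration sparsity, is the product of this stage.

## Model selection

`build_design` emits candidate main effects, the screened dummies and all
candidate × dummy products. Stepwise search is greedy over single-term
add/drop moves, accepting the largest decrease of the criterion and
stopping at a local minimum; ties break by design-column order. Hierarchy
(default on) lets an interaction enter only while its metabolite main
effect is present and blocks a main effect from leaving while its
interaction remains. Both directions are provided because they fail
differently: forward addition can stall when an interaction cancels its
main effect's marginal signal (the pair only helps jointly), which backward
elimination from the full design handles.

Information criteria use the Gaussian form with the constant dropped:
aic = n·ln(rss/n) + 2k, aicc = aic + 2k(k+1)/(n−k−1), bic = n·ln(rss/n) +
k·ln(n), with k counting intercept plus slopes. These match the convention
of mainstream statistical environments, so values are comparable across
models on the same samples but are not absolute likelihoods. Model
comparison ranks by AICc then BIC and flags k > n/3 as overfitting.

OLS inference: SEs from σ̂²(XᵀX)⁻¹ with σ̂² = rss/(n−k), 95 % CIs and
two-sided p-values on t(n−k), adjusted R² = 1 − (rss/(n−k))/(tss/(n−1)),
BH adjustment over all terms of the final model as the multiple-testing
family. Rank-deficient designs are rejected with the collinear columns
named.

## Diagnostics

VIF per term from the auxiliary regression 1/(1−R²ⱼ) with intercept,
capped near 10¹² for numerically perfect collinearity; cutoff 5.
Shapiro–Wilk (normality) and Breusch–Pagan (homoskedasticity) at α = 0.01
back the visual diagnostics — chosen loose deliberately, to flag only gross
violations. Standardized residuals are internally studentized
(r/(σ̂√(1−hᵢᵢ))). Subgroup comparisons are Welch t-tests (pooled by flag)
over the family {each model metabolite} × {male vs female within each
timepoint; each timepoint pair within each sex}, with one BH pass over the
whole family at FDR 0.10. Residual summaries report per-group min/max/mean/
SE on the log scale and their 10^r µg ratio back-transforms to 3
significant figures.

## The published predictor

The final 22-coefficient model ships as versioned JSON at printed 3-decimal
precision (the citable artifact; no attempt to recover unrounded values),
with per-term CIs, adjusted p-values, retention coordinates and MSI ID
levels. Unnamed compounds are addressed by variable label plus (¹t_R, ²t_R),
and `map_by_retention` matches a user table within ±2 s / ±0.2 s (the
alignment windows). Prediction is affine in x; changing sex or timepoint
touches only the corresponding interaction contributions (both properties
are tested). `evaluate_on_cohort` applies the frozen coefficients to a
standardized matrix through an explicit label→column mapping and fails
loudly, naming every unmapped variable.

## Compound identification

Linear retention indices anchor alkanes at 100·n and interpolate rt₁
between bracketing rungs; outside the C₈–C₂₀ span the nearest rung pair
extrapolates and the value is flagged. Cross-phase consistency is the
polarity percentage 100·(RI_exp − RI_np)/(RI_p − RI_np), accepted in
[5, 35] % for the mid-polar separation phase. MSI levels: spectral match
< 800/1000 → level 4 with the name replaced by a functional-group label or
"unknown"; ≥ 800 with polarity-window confirmation → level 2, upgraded to 1
by an analytical standard; ≥ 800 without it → level 3, where an
experimental RI within 6 % (relative) of the non-polar library value
supports the name without reaching level 2. A match of exactly 800 is
treated as level-3-eligible (the threshold wording is ambiguous between
"≥ 80 %" and "≤ 80 %"; this package resolves it in favor of the name).
Levels are monotone in evidence: adding RI consistency or a standard never
increases the level number.

## The synthetic cohort generator

What it emulates: 60 subjects (even sex split), one sample per subject per
timepoint (180 samples), 512 retained features with lognormal abundances
(per-feature location U(4.5, 6.5), spread U(0.2, 0.5) in log₁₀ units), a
planted support of 14 features whose standardized log abundances drive
log₁₀ cortisol with coefficients of magnitude U(1−s, 1+s)·effect_scale
(default effect_scale 0.1, matching the magnitude range of the published
coefficients; spread s default 0.5), sex/time interaction effects on
support features at 1.5× that scale, a declining diurnal mean profile
(0.9/0.6/0.3 log₁₀ µg ≈ 8/4/2 µg — plausible per-void free cortisol),
between-subject effects (SD 0.1), Gaussian noise (SD 0.2, giving a
realistic mid-0.5s attainable R²), left-censored missingness and two
out-of-range cortisol samples per 180 (resampled above the 45 µg reference
ceiling so the range filter has known true positives).

Design choices:

- **Causal direction**: cortisol = f(VOCs) + ε is simulated directly so the
  regression target is well-specified and support recovery is measurable.
  Real biology runs the other way (cortisol drives metabolite excretion);
  the generator makes no claim about mechanism, only about the joint
  distribution the estimator faces.
- **Missingness is left-censoring**, not MCAR: per feature, the lowest
  entries fall below detection, so the censoring property max(missing) <
  min(observed) holds per feature. Non-support features draw heterogeneous
  censoring rates (Beta with mean missing_rate) so the presence filter has
  real work; support features are censored at exactly the nominal rate so
  the planted truth stays identifiable through the filter.
- **Outlier truth labels are exact**: when outliers are injected, any
  non-injected sample whose noisy draw strays above the ceiling is
  truncated to it, so the planted set is precisely the out-of-range set and
  the 180 → 178 structure is deterministic, not seed-dependent. With
  outlier_rate = 0 no truncation occurs and the noiseless cohort is exactly
  linear in the planted design.
- One integer seed feeds a spawned seed-sequence tree; all draws are
  reproducible bit-for-bit.

What it does **not** emulate — and what passing tests therefore do not
show about real data: feature–feature correlation (real VOC tables are
blocky and collinear), retention-time drift and alignment error, batch and
instrument effects, non-lognormal abundance tails, informative missingness
beyond the detection limit, and any real biochemical linkage between the
named compounds and cortisol. Recovery results on this generator are
best-case for the statistical machinery, not evidence about the biology.

## Study sizes used in the shipped analyses

The acceptance suite runs the support-recovery study at 20 replicates ×
100 bootstrap iterations (scaled down from the canonical 250; the
frequency ranking stabilizes well before 100 on these sizes). The stated
high-SNR recovery condition is effect_scale 0.15 with spread 0.25 (planted
|β| ∈ [0.1125, 0.1875]), noise SD 0.05, subject SD 0.05, no censoring, no
planted interactions, dummies included in the selection design. Two
structural facts motivate it: the study dimensions sit essentially at the
sparse-recovery boundary n ≈ 2·s·ln p (178 ≈ 175 for s = 14, p = 512), so
widely spread coefficient magnitudes push the weakest support feature below
the chance-correlation level no matter the overall scale; and a planted
interaction can cancel its feature's marginal effect, which is invisible to
a main-effects-only selector — interaction recovery is therefore exercised
separately through backward stepwise search on a smaller cohort. Both
phenomena are properties of the method, and the split into two recovery
studies makes each one measurable.

## Known limitations

- Naive post-selection inference (by design, matching the emulated
  workflow); CIs and p-values of stepwise-selected terms are optimistic.
- Full-set standardization leaks means/SDs across bootstrap splits (see
  Preprocessing); selection frequencies are slightly optimistic.
- The greedy stepwise search finds local optima; the exhaustive oracle in
  the test suite quantifies how often (≥ 80 % criterion agreement on ≤ 10
  terms).
- The generator's independent features make selection easier than real
  chromatographic data; see the non-goals above.
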