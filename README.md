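# cortivoc

Predicting diurnal total free urinary cortisol from untargeted GC×GC-TOFMS
volatile-metabolite profiles.

Cortisol, the terminal effector of the HPA axis, follows a pronounced
diurnal rhythm — high after waking, declining to evening — and its
dysregulation is implicated in depression, bipolar disorder and other
stress-related conditions. Direct cortisol quantification needs LC-MS/MS or
immunoassay; volatile organic compounds (VOCs) in urine headspace, sampled
by HS-SPME-GC×GC-TOFMS, offer a cheaper point-of-care proxy. This package
implements the full statistical pipeline for building and applying a
VOC-based cortisol predictor on an aligned peak table:

1. **Preprocessing** — probabilistic quotient normalization (PQN),
   blank/early-elution and ≥50%-presence filters, physiologic-range outlier
   removal (> 45 µg per void), log₁₀/center/scale standardization with
   half-minimum imputation of left-censored entries.
2. **Factor screening** — two-way ANOVA with replication (Type-II SS) of
   log₁₀ cortisol on sex × time-of-day, to choose interaction factors.
3. **Stability selection** — bootstrapped elastic net (α = 0.5) over
   subject-level 80/20 train/test splits; per split the penalty λ minimizing
   held-out MSE decides the selected set; features are ranked by selection
   frequency into top-25/35/50 candidate subsets.
4. **Model selection** — forward/backward stepwise minimization of AICc
   (BIC as tie-breaker) over metabolite main effects and metabolite × dummy
   interactions (Male, Morning, Afternoon; reference cell female evening),
   with OLS t-based inference and Benjamini–Hochberg adjustment.
5. **Diagnostics** — residual/QQ/lag/drift data, VIF (cutoff 5),
   Shapiro–Wilk and Breusch–Pagan backstops, predicted-vs-observed CI band,
   subgroup Welch t-tests at FDR 0.10.
6. **The published predictor** — a frozen 22-coefficient model

   log₁₀(cortisol/µg) = 0.496 + Σⱼ βⱼ xⱼ + Σⱼ,d cⱼd xⱼ·1[d],

   with 14 standardized log₁₀ metabolite abundances x₁…x₁₄ (pyrrole,
   6-methyl-5-hepten-2-one, 1-iodo-2-methylundecane, 4,6-dimethyl-dodecane
   and ten unidentified compounds addressed by retention coordinates) and 7
   sex/time interaction terms, shipped as versioned JSON and executable on
   any mapped feature table.
7. **Compound identification** — van den Dool–Kratz retention indices
   against a C₈–C₂₀ alkane ladder, cross-phase polarity consistency
   (5–35 % window) and MSI confidence levels 1–4.

Because the original cohort requires proprietary chromatogram processing, a
first-class **synthetic cohort generator** reproduces the study's structure
(60 subjects, 30 male / 30 female, 3 timepoints, 512 retained features, a
14-feature planted sparse log-linear relation with interaction effects,
left-censored missingness, planted out-of-range cortisol samples) so that
every stage is testable with known ground truth.

## Worked example

The numbered scripts under `analysis/` run the pipeline end-to-end on the
default synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_screen_factors.py
python analysis/04_select_features.py
python analysis/05_fit_models.py
python analysis/06_diagnostics.py
python analysis/07_published_model.py
python analysis/08_compound_id.py
```

`02_preprocess.py` prints

```
samples: 180 -> 178 after the 45 µg range filter (dropped ['M17_evening', 'M30_morning'])
features: 512 -> 507 after presence filter
```

— the two planted out-of-range samples are removed, leaving the 178-sample
analysis set. `05_fit_models.py` ranks the stepwise models from the three
candidate subsets:

```
top50 -536.7 (AICc)  -414.2 (BIC)  adj R2 0.916  52 terms
top35 -474.9         -375.3        adj R2 0.856  37 terms
top25 -446.3         -359.1        adj R2 0.820  31 terms
```

and `07_published_model.py` exercises the frozen predictor:

```
reference prediction (female, evening, x = 0): 0.496 log10 µg = 3.13 µg
+1 SD pyrrole: 0.566 log10 µg
residual +0.650 log10 -> 4.47 µg (ratio scale)
self-consistency: max |residual| = 5.55e-17 log10 µg over 120 samples
```

A baseline (female, evening, all metabolites at their cohort mean) excretes
a predicted 10^0.496 ≈ 3.1 µg of free cortisol; one standard deviation more
urinary pyrrole raises the prediction by its coefficient, +0.070 log₁₀ µg.
Residuals back-transform multiplicatively: +0.650 means the observation was
4.47× the prediction.

The same stages are available as a CLI (`cortivoc simulate|preprocess|
screen|select|fit|diagnose|predict|idlevel|run-all`) with a YAML run
configuration and manifest.

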