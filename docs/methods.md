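# Methods

`hdpanel` evaluates multi-modal biomarker panels in a 2×2 (genotype ×
treatment) preclinical design: wild-type and R6/2 Huntington's-disease
model mice, each given vehicle or the p75NTR ligand LM11A-31 ("C31").
Because no subject-level data from such studies are deposited, the package
pairs each analysis stage with a synthetic-cohort generator calibrated to
published standardized effect sizes, so every statistical and machine
learning procedure can be exercised, tested, and benchmarked end to end.

## Synthetic cohort model

Each of the 27 panel features (regional proportional volumes, MD, FA, ODI,
raw R2*, plasma cytokines, urinary p75NTR-ecd/creatinine) is drawn from a
Gaussian location-shift model. For feature *f* with WT-Veh baseline mean
μ₀ and coefficient of variation cv, the within-group SD is σ = μ₀·cv for
all groups (homoscedastic), and group means are

    WT-Veh:    μ₀
    R6/2-Veh:  μ₀ + d_gen·σ
    R6/2-C31:  μ₀ + (d_gen + d_trt)·σ
    WT-C31:    μ₀ + d_wt·σ

where d_gen, d_trt, d_wt are signed Cohen's d values. The Gaussian choice
matches a design analyzed primarily with parametric tests on group means;
a moment-matched log-normal marginal is available (`lognormal=True`) as a
sensitivity mode for skewed biofluid assays.

Default effects use the published values where printed — striatal volume
−3.13, cortical volume −3.66, globus pallidus −2.00, corpus callosum
−1.90, R2* striatum −2.57 / GP −1.60 / cortex −1.83, striatal FA
treatment −1.32, urinary p75 +1.71 (genotype) and −0.68 (treatment),
treatment volume effects 0.97–2.00 — and default to |d_gen| = 1.5,
|d_trt| = 1.0 elsewhere, with directions following the reported direction
of change (disease: volumes ↓, MD ↑, striatal FA ↑ / other FA ↓, ODI ↓,
raw R2* ↓, cytokines ↑, urinary p75 ↑; treatment moves the disease group
toward wild type). Where a percent change was published alongside d, the
CV is derived as cv = |%Δ|/100/|d| so both calibrations hold at once
(striatum 0.0511, cortex 0.0437, GP 0.110, CC 0.0474, p75 0.257).
Remaining CVs are set to modality-typical values: 0.05 for volumes/MD/R2*,
0.08 for FA/ODI, 0.30 for cytokine immunoassays.

Noise terms within one modality share an equicorrelation ρ (default 0.2,
Gaussian copula; modalities independent) — published results give no
covariance information, and a mild within-modality correlation reflects
that regional measures of one modality co-vary. Negative draws for these
positively-supported quantities are clipped at a tiny positive floor and
counted in a warning; for realistic configurations (cv ≤ 0.25, |d| ≤ 4)
clipping never triggers.

Contamination is injected separately and ground-truthed in metadata:
gross outliers displace a cell by `outlier_scale` SDs (per-cell rate
`outlier_rate`), and values below a per-feature `detection_floor` are
censored to missing — emulating assay values below the detection limit
that force a feature's exclusion.

Default group sizes (12/8/14/16) are the imaging cohort's; biofluid-sized
groups (16–17) are passed per run. Seeding is strict: identical config and
seed give a bit-identical table.

**What the generator does not emulate.** Real cohorts have heavier tails,
inter-modality correlation (atrophy drives several MRI measures at once),
litter and batch effects, and heteroscedasticity across groups. Passing
tests therefore demonstrate that the *procedures* behave correctly under
the calibrated location-shift model, not that real data would yield the
same accuracies.

## Univariate statistics

Per feature and planned contrast (WT-Veh vs R6/2-Veh; R6/2-Veh vs
R6/2-C31; WT-Veh vs WT-C31), `BiomarkerStats.fit()` applies:

1. **Outlier filter** — one pass per feature per group: values more than
   2 sample SDs (ddof = 1) from the group mean are removed; zero-SD
   groups are untouched; removals are logged. Filtering precedes the
   normality check (the alternative ordering is defensible but one had to
   be fixed).
2. **Normality** — Kolmogorov–Smirnov with mean/SD estimated from the
   sample. Estimated parameters make the textbook KS null
   anti-conservative, so the null is simulated (Lilliefors construction):
   10⁴ standard-normal samples of the same size at a fixed internal seed,
   cached per n; p = (1 + #{null ≥ obs})/(1 + 10⁴). Groups smaller than 5
   are treated as normal and flagged.
3. **Dispatch** — both groups normal (p > α) and a two-group variance
   F-ratio test not significant → one-way ANOVA over all groups with
   Fisher's LSD on the planned contrast, t = (m_a−m_b)/√(MSE(1/n_a+1/n_b)),
   df = N−k, reported regardless of the omnibus; normal but unequal
   variances → Welch's t (Satterthwaite df); any group non-normal →
   Mann–Whitney U (exact when min(n) ≤ 8 without ties, tie-corrected
   normal approximation otherwise).
4. **FDR** — Benjamini–Krieger–Yekutieli two-stage adaptive step-up at
   q = 0.05 within each modality family (all features × contrasts of one
   modality; the single urinary p75 feature is tested unadjusted at α).
   Stage 1 is BH at q′ = q/(1+q); with 0 < r₁ < m rejections, stage 2
   reruns BH at q′·m/(m−r₁). Note the adaptive set provably contains the
   BH rejections at level q′, not at q.
5. **Effect descriptors** — Cohen's d with pooled SD (reported as the
   standardized shift of the second group relative to the first, matching
   the generator's sign convention), post-hoc power of the two-sided
   two-sample t-test from the noncentral t (ncp = d√(n_a·n_b/(n_a+n_b))),
   and percent change relative to the first-named group.

Features missing in more than half the subjects are excluded with a
logged reason. Groups smaller than 3 after filtering flag the result
instead of testing.

## Relaxometry

R2* is fitted from multi-echo gradient-echo magnitudes by unweighted OLS
of ln S on echo time (slope = −R2*, ms⁻¹ → s⁻¹ ×1000; intercept = ln S0).
The default echo grid is 3.5 + 5k ms, k = 0..7. Non-positive signals are
dropped, not floored — a floor would bias the slope — and at least 3
positive echoes are required. The log-linear estimator is noiseless-exact
for any rate in [0, 200] s⁻¹ and is slightly biased under additive noise
(late, low-SNR echoes dominate the log residuals); recovery within ±2% is
asserted at SNR ≥ 100. The ROI-volume correction R2*/V (s⁻¹·mm⁻³,
iron load per volume) is homogeneous of degree −1 in volume, so strong
atrophy can reverse the direction of a raw R2* group difference.

## Stability selection

Tasks code the reference group 0 and the contrast group 1 (genotype:
WT-Veh vs R6/2-Veh; treatment: R6/2-Veh vs R6/2-C31). Features are
z-scored over the full task table by default, mirroring a pre-standardized
input table; a train-only scope avoids the (mild) leakage of test rows
into the standardization constants and is available per run.

Each of the `n_permutations` (default 1000) iterations draws a stratified
split — exactly 6 test subjects per class, at most 7 training subjects
per class (so 12–13 subjects per class are used per split) — then:

- **Ranking.** `svm_linear`: features ordered by |weight| of a
  linear-kernel SVC (C = 1); `xgb`: by total split gain of a gradient
  boosted ensemble (100 rounds, depth 3, learning rate 0.3, seeded per
  permutation). Ties break by panel column order (stable sort). Ranking
  happens once per permutation; nested top-k subsets are then evaluated
  (k from 27 down to 2). This single-shot reading is the one in which a
  KNN classifier can partner an importance ranker; classic
  refit-per-elimination RFE is available via `refit_per_step=True`.
- **Classification.** KNN (k = 3, inverse-distance weights, Euclidean) or
  random forest (200 trees, per-permutation seed) fit on the top-k
  training columns and scored on the test subjects: accuracy, and
  precision/recall with class 1 positive.

Aggregation yields mean ± SD accuracy/precision/recall per k and the
occurrence matrix: the percentage of permutations in which each feature
ranked in the top 15 of the per-permutation ordering (independent of k;
exactly min(15, n_features) features count per permutation, so occurrence
sums to 1500 percentage points for the 27-feature panel).
`logistic_rank` fits one ridge-penalized (C = 1, lbfgs, tol 1e-8)
logistic regression on all z-scored features jointly for the coefficient
view; `compare_models` orders combos by mean accuracy at each combo's
best k. With balanced 6+6 test sets, chance accuracy is 0.5.

Per-permutation seeds derive from the master seed by counter
(`SeedSequence(seed, spawn_key=(i,))`), making curves and occurrence
matrices bit-reproducible.

## Pipeline

`run_pipeline(RunConfig)` composes simulate → stats → select, writes
cohort/stats/curves/occurrence/coefficient CSVs plus a JSON report and
text summary, and is byte-reproducible from the master seed (stage seeds
derive by stable counters). The config schema rejects unknown keys; every
generator, stats, and ML option above is settable there and echoed into
the report. The `hdpanel` CLI exposes `simulate`, `stats`, `select`,
`relaxfit`, and `run`.

## Problem sizes in tests and the acceptance script

Generator calibration checks run at n = 10⁴/group (standardized-shift and
correlation convergence within ±0.05) and n = 4000/group for null-effect
mean equality. Effect-size/percent-change recovery uses 2000 replicate
cohorts at the study group sizes; the mean |d| tolerance (±0.2 / ±0.15)
absorbs the ≈ +3% small-sample inflation of the d estimator at df ≈ 24.
Classification benchmarks average 8 independent cohort replicates × 25
stratified splits (200 splits total): with treatment effects near d = 1,
the accuracy of any single simulated cohort varies by several points from
draw to draw, so the expectation over cohorts is the stable quantity.
Null-calibration checks (FDR, chance-level ML accuracy) use Monte-Carlo
slack of 2–3.5 binomial SEs.

## Known limitations

- The location-shift generator is an idealization; see above for the real
  data features it omits. Accuracies on real cohorts would be lower than
  on independent Gaussian features at the same effect sizes.
- The 2-SD outlier filter is applied once (no iteration) and interacts
  with the normality test order; both choices are fixed and documented.
- The KS Monte-Carlo null assumes complete, untied samples; heavy ties
  from detection-floor censoring should be excluded upstream (and are,
  via the missingness rule).
- Post-hoc ("observed") power is a deterministic transform of the
  observed d and n; it is reported for parity with common practice, not
  as evidence beyond the p-value and effect size.
- The XGB importance ranking depends on the library's tree-growing
  implementation; rankings are reproducible for a pinned version but may
  shift across major xgboost releases.
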