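# hdpanel

Multi-modal biomarker panel evaluation for 2×2 preclinical cohorts
(genotype × treatment), built around the R6/2 Huntington's-disease mouse
design with a candidate therapeutic (the p75NTR ligand LM11A-31, "C31").
It is aimed at researchers asking two questions of a panel of imaging and
biofluid markers: *does each marker separate the groups?* and *which
combination of markers classifies disease state or treatment response?*

The package provides:

- **`generate_cohort`** — a seeded synthetic-cohort generator for the
  four groups (WT-Veh, WT-C31, R6/2-Veh, R6/2-C31) and a 27-feature
  panel spanning MRI volumetry, diffusion (MD/FA), NODDI (ODI), R2*
  relaxometry, plasma cytokines and urinary p75NTR-ecd. Group means
  follow a location-shift model μ_g = μ₀ + d_g·σ calibrated by published
  standardized effect sizes (Cohen's d up to 3.7 for genotype, 0.7–2.0
  for treatment), with within-modality correlated noise, optional
  outliers and detection-limit censoring.
- **`BiomarkerStats`** — the univariate pipeline per feature and planned
  contrast: 2-SD outlier filtering, Monte-Carlo-calibrated KS normality,
  dispatch to ANOVA + Fisher's LSD / Welch's t / Mann–Whitney U,
  two-stage Benjamini–Krieger–Yekutieli FDR at q = 0.05 within modality
  families, pooled-SD Cohen's d, noncentral-t post-hoc power and percent
  change.
- **`R2StarModel`** — mono-exponential relaxometry: OLS of ln S(TE) on
  echo time gives R2* (s⁻¹); plus ROI-volume-corrected R2* and a decay
  simulator.
- **`StabilitySelection`** — the two-step machine-learning procedure:
  over permuted stratified train/test splits (6 test, ≤ 7 train per
  class), rank features by linear-SVM weights or XGBoost split gain,
  classify nested top-k subsets (k = 27…2) with distance-weighted 3-NN
  or a 200-tree random forest, and aggregate accuracy/precision/recall
  curves and a top-15 occurrence matrix. `logistic_rank` gives the
  one-shot ridge-logistic coefficient view.
- **`run_pipeline` / the `hdpanel` CLI** — one seeded, byte-reproducible
  run of simulate → stats → select with CSV/JSON artifacts
  (`hdpanel simulate|stats|select|relaxfit|run`).

## Worked example

```python
import hdpanel as h

table = h.generate_cohort(h.CohortConfig(seed=7))      # 50 mice x 27 features
res = h.BiomarkerStats(table).fit()
df = res.to_frame()
print(df[df.contrast == "genotype"].head(4).round(4).to_string(index=False))
```

```
            feature         test  p_raw  fdr_reject  cohens_d  power  percent_change
       vol_striatum    anova_lsd 0.0000        True   -3.3148 1.0000        -15.7152
vol_globus_pallidus    anova_lsd 0.0000        True   -3.0653 1.0000        -29.8834
         vol_cortex mann_whitney 0.0000        True   -3.0422 1.0000        -12.8285
vol_corpus_callosum    anova_lsd 0.0011        True   -1.8613 0.9936         -6.3011
```

Each row is one feature × contrast: the dispatched test and its raw p,
the adaptive-FDR decision, the standardized shift of the disease group
relative to WT (here striatal proportional volume is ~3.3 pooled SDs
smaller, a ~16% reduction), and the post-hoc power at that d and n.

```python
sel = h.StabilitySelection(
    table, h.GENOTYPE_TASK, h.ModelCombo("svm_linear", "knn3_distance"),
    n_permutations=200, seed=7, k_range=range(17, 21),
).fit()
print(sel.summary())
```

```
Stability selection: SVM-KNN on task 'genotype' (200 permutations, seed 7)
best mean accuracy 1.000 at k = 18
top occurrence (% of permutations in the top 15):
  vol_striatum: 97.0%
  r2s_striatum: 97.0%
  vol_globus_pallidus: 95.0%
  p75_urinary: 93.5%
  r2s_cortex: 89.5%
```

With 17–20 features the SVM-ranked, KNN-classified model separates
held-out WT from R6/2 mice essentially perfectly on this synthetic
cohort; striatal volume and striatal R2* sit in the top 15 ranked
features in ~97% of splits. And the relaxometry fit:

```python
r = h.fit_r2star_loglinear(h.simulate_decay(31.0, 100.0, noise_sd=1.0, seed=0))
print(f"R2* = {r.r2star:.2f} 1/s, S0 = {r.s0:.1f}, R^2 = {r.fit_r2:.4f}")
# R2* = 30.10 1/s, S0 = 99.1, R^2 = 0.9990
```

See `docs/methods.md` for the model details, defaults, and limitations.

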