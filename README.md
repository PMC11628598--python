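# lipidsig

Serum lipidomic signatures for gastric cancer: a diagnostic lipid panel
and a survival-based prognostic subtyping, implemented as a tested,
reusable Python pipeline.

Untargeted serum lipidomics yields hundreds of correlated lipid features
per patient. This package turns such a feature table into two clinical
models:

- **Diagnostic signature (SLMS-style).** After internal-standard
  normalization (`log2(raw/IS) + 5`), QC-based RSD filtering and
  autoscaling, lipids are ranked by PLS-DA VIP scores,

  `VIP_k = sqrt( p · Σ_a SSY_a w_ak² / Σ_a SSY_a )`,

  the top 50 are pruned by a stepwise Spearman redundancy rule (keep a
  lipid only if |ρ| < 0.5 against every lipid already kept), and panel
  size × algorithm are chosen on a 10-fold × 10-repeat cross-validation
  grid over sizes 2–50. The final model is Gaussian LDA: the score of
  sample *j* is the logistic transform of `Σ_k α_k x_kj + α_0`, the
  posterior probability of cancer, with samples above 0.5 called positive.
  Performance is reported with exact Clopper–Pearson 95% CIs and DeLong
  AUC CIs, alongside a conventional-tumor-marker comparator (positive if
  any of CEA/CA19-9/CA72-4 exceeds its clinical cutoff).

- **Prognostic subtypes (GCPS-style).** Among cancer patients, lipids are
  screened by univariable Cox regression (p < 0.05, Efron ties), pruned by
  the same redundancy rule, and patients are grouped by Monti consensus
  clustering (1000 × 80% subsamples); K is chosen by the consensus-CDF
  delta-area restricted to unambiguous K values. Subtypes are named by
  worse survival (SI worse than SII), contrasted by Kaplan–Meier curves,
  log-rank test and Cox hazard ratio, and an elastic-net logistic
  predictor (`min (1/N) Σ w_i l(y_i, β₀+βᵀx_i) + λ[(1−α)‖β‖₂²/2 + α‖β‖₁]`)
  assigns new samples to the subtype with the higher score.

A first-class synthetic cohort generator emulates the assumed data
structure — correlated lipid blocks, stage-dependent disease effects,
internal standards, QC replicates every 20 samples, and two latent
prognostic subtypes driving censored survival — so the full pipeline is
testable end-to-end with no external data. See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

```python
from lipidsig import (SimulationConfig, generate_cohort,
                      DiagnosticSignature, PrognosticSubtypes)
from lipidsig.preprocess import rsd_qc_filter, normalize_log, split_cohort

table, ann, truth = generate_cohort(SimulationConfig(seed=1))
table, removed = rsd_qc_filter(table)          # QC RSD < 30%
pm = normalize_log(table.study_samples())      # log2(raw/IS) + 5
train, test = split_cohort(ann, 0.85, seed=1)  # stratified 85/15

res = DiagnosticSignature(pm.subset_samples(train),
                          ann.loc[train, "group"].to_numpy()).fit(seed=1)
print(res.summary())
```

```
Diagnostic lipid signature (LDA posterior score)
====================================================
algorithm:         lda
panel size:        12 (from 20 decorrelated of top 50 by VIP)
CV mean accuracy:  0.934 (10-fold x 10)
intercept alpha_0: +0.0000

panel lipid        alpha       VIP
------------------------------------
L0011              +1.2727     3.702
L0015              +1.4157     3.647
...
```

The cross-validation grid picked LDA on a 12-lipid panel with mean CV
accuracy 0.934; `alpha` are the per-lipid log-odds coefficients of the
score equation. Evaluating on the held-out 15%:

```python
rep = res.evaluate(pm.subset_samples(test), ann.loc[test, "group"].to_numpy())
print(rep.to_frame().to_string(index=False))
```

```
   Accuracy (95%CI) Sensitivity (95%CI) Specificity (95%CI)         AUC (95%CI)
0.936 (0.857-0.979) 0.923 (0.791-0.984) 0.949 (0.827-0.994) 0.981 (0.957-1.000)
```

i.e. the signature separates cancer from healthy on unseen samples with
AUC 0.981, and each proportion carries its exact binomial interval.
Prognostic subtyping of the cancer patients:

```python
gc = ann[ann.group == "GC"]
pres = PrognosticSubtypes(pm.subset_samples(gc.index),
                          gc.time_months, gc.event).fit(seed=1)
print(pres.summary())
```

```
Prognostic subtypes from serum lipids (consensus clustering)
============================================================
lipids screened:    561 -> 56 at p<0.05 -> 40 after decorrelation
chosen K:           2
subtype sizes:      SI=142, SII=124
log-rank:           chi2=43.30, p=4.69e-11
HR (SI vs SII):     3.77 (95% CI 2.47-5.76)
OS at 24 months:  SI: 57.6%, SII: 88.9%
subtype predictor:  elastic net (alpha=1.0, lambda=0.00663), 20 nonzero coefficients
```

Two stable subtypes emerge; SI (the worse-prognosis group) has 57.6%
two-year overall survival against 88.9% for SII, hazard ratio 3.77. The
fitted elastic-net predictor transfers the subtyping to new cohorts via
`pres.predict(new_matrix)`.

A thin command-line interface mirrors the library
(`lipidsig simulate | preprocess | rank | select | train-diagnostic |
evaluate | subtype | differential | trends | enrich`).

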