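# hazardcut

Bootstrap cutoff selection and multivariable Cox analysis for
gene-expression biomarkers of chemo-radiotherapy outcome in head and neck
squamous cell carcinoma (HNSCC).

## The problem

Continuous biomarker scores (hypoxia signatures, stem-cell markers such as
CD44/SLC3A2, immune-infiltration scores, EMT, proliferation, EGFR
expression, tumor volume) are routinely dichotomized into "low" vs "high"
patient groups before survival modelling. An arbitrary cutoff makes the
resulting hazard ratios fragile. `hazardcut` implements a resampling
procedure that selects, per marker and per endpoint, the cutoff whose
low/high split is most *reproducibly* associated with outcome:

1. Draw `B` bootstrap cohorts (patients resampled with replacement, size n).
2. At every admissible cutoff `c` (each midpoint between consecutive
   distinct marker values whose split leaves ≥ 10% of patients on each
   side), dichotomize the marker and fit the multivariable Cox
   proportional-hazards model

   h(t | x) = h₀(t) · exp(β·1[marker > c] + γᵀ·z),

   where `z` is the endpoint's clinical adjustment set.
3. Record per cutoff the fraction of bootstrap cohorts with a significant
   marker term (Wald p < 0.05), smooth the fraction curve over nine
   adjacent cutoffs, and select the argmax.
4. Refit on the original cohort at the selected cutoff ("low" group as
   reference) to report HR = exp(β̂) with its 95% Wald CI.

Around this core the package provides: four time-to-event endpoints with
death-censoring semantics (locoregional control LRC, distant metastasis DM,
overall survival OS, progression-free survival PFS), single-sample
gene-set scoring of an expression matrix (TPM for single genes, rank-z
mean scores for gene sets), Spearman correlation / VIF / hierarchical
clustering reports, backward model selection by AIC over all markers and
clinical variables, cutoff-averaged hazard-ratio profiles for
cutoff-independent marker ranking, and a synthetic cohort generator with
known ground truth (Gaussian copula marker scores, proportional-hazards
event times).

The Cox fitter maximizes the Efron tie-corrected partial likelihood by
Newton–Raphson (|score|∞ < 1e-7, step-halving, separation flagged at
|β| > 15). Because a single scan refits the model `B × #cutoffs` times, the
default engine is a numba-compiled kernel; a vectorized numpy engine
implements the identical algorithm and both are cross-checked against each
other and against `lifelines` in the test suite.

## Worked example

```python
import hazardcut as hc

# a 197-patient synthetic cohort emulating the target study's structure:
# 12 correlated marker scores, clinical covariates, 4 endpoints
cohort = hc.simulate_cohort(hc.SimulationConfig(n_patients=197, seed=11))

spec = hc.default_endpoint_spec("LRC")   # adjusts for sex + cisplatin dose
scan = hc.bootstrap_scan(cohort, "chronic_hypoxia", spec, B=200, seed=11)
fit = hc.final_fit(cohort, "chronic_hypoxia", scan.selected_cutoff, spec)
print(f"selected cutoff: {scan.selected_cutoff:.3f}")
print(f"max smoothed significant fraction: {scan.frac_smoothed.max():.2f}")
t = fit.terms.loc["chronic_hypoxia_high"]
print(f"HR (high vs low): {t.hr:.2f}  95% CI ({t.ci_low:.2f}, {t.ci_high:.2f})  p={t.p:.4f}")
```

prints (seed 11):

```
selected cutoff: -0.002
max smoothed significant fraction: 1.00
HR (high vs low): 6.72  95% CI (3.35, 13.47)  p=0.0000
```

The generator's ground truth gives the chronic-hypoxia-high group a true
LRC hazard ratio of 3.95 switching on at the marker median (a standard
normal score, so at 0): the scan recovers a cutoff essentially at the
median and the marker is significant in ~100% of bootstrap cohorts there.
The adjusted fit's CI brackets the true 3.95, while the inflated point
estimate illustrates the optimism that fitting at the *selected* cutoff
introduces (see `docs/methods.md`). The smoothed fraction curve
(`scan.to_frame()`) is the per-cutoff stability profile behind the
selection.

The same analysis runs end to end from a shell:

```bash
hazardcut simulate --n 197 --seed 11 --out cohort.tsv
hazardcut scan --cohort cohort.tsv --marker chronic_hypoxia --endpoint LRC \
    --B 200 --seed 11 --out chronic_lrc
hazardcut run --out full_run --seed 11     # all markers x endpoints + selection + profiles
```

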