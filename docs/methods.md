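# Methods

This note documents the statistical procedures `hazardcut` implements, the
modelling choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Endpoints and censoring

Four endpoints are constructed from per-patient records (time origin =
first day of treatment):

- **LRC** (locoregional control): event = recurrence in the irradiated
  region. A death occurring before any locoregional event *censors* the
  patient at the death date.
- **DM** (distant metastasis): analogous, with death-censoring.
- **OS** (overall survival): event = death from any cause.
- **PFS** (progression-free survival): event = earliest of locoregional
  recurrence, distant metastasis, or death.

These rules imply two row-wise invariants that the generator and the
endpoint builder are tested against: `time_PFS <= min(time_LRC, time_DM,
time_OS)`, and `event_PFS = 1` exactly when some component event occurs at
the PFS time. Treating death as censoring (rather than a competing risk)
matches the analysis being reproduced; cause-specific hazards are the
implicit estimand and cumulative-incidence quantities are out of scope.

## Cox proportional-hazards fitting

`fit_cox` maximizes the partial likelihood with **Efron's tie correction**
by Newton–Raphson: convergence at `max|score| < 1e-7`, at most 100
iterations, step-halving whenever a proposed step would decrease the
likelihood. The paper trail for ties is silent in this literature's usual
reporting; Efron is the better approximation and the default of R's
`survival`, so it is the default here, with Breslow available via
`ties="breslow"` for cross-checks. Separation / non-identifiability is
flagged (never silently returned) when any |β| escapes 15; a constant
design column raises immediately. Wald standard errors, 95% CIs and
p-values come from the observed information; `AIC = -2 logPL + 2k` with
`k` the number of estimated coefficients (no baseline-hazard terms).

Categorical variables are dummy-coded with the **most frequent observed
level as the reference**, ties between equally frequent levels broken
lexicographically. Rows with missing values in active columns are dropped
per fit (complete case) and the count logged; no imputation.

Two engines implement the identical algorithm: a numba-compiled per-model
kernel (default; the bootstrap scan fits `B x #cutoffs` models per marker
and endpoint, so per-fit overhead dominates runtime) and a vectorized
numpy path. Their agreement — coefficients, log-likelihoods, information
matrices, convergence and failure flags — is property-tested, and both are
checked against `lifelines` and against brute-force grid maximization of
an independently coded Efron partial likelihood on small instances.

## Bootstrap cutoff selection

For a marker/endpoint pair:

- **Candidate grid**: midpoints between consecutive distinct observed
  marker values. Midpoints avoid the ambiguity of cutting *at* an observed
  value. A candidate is admissible only if both groups keep at least
  `ceil(0.10 n)` patients; the constraint is applied on the full cohort
  (whether it applies per resample is unspecified in the source analysis),
  and resample fits that degenerate anyway are counted as failed.
- **Resampling**: `B` (default 10,000) patient-level bootstrap samples of
  size n, uniform with replacement, unstratified. All cutoffs are
  evaluated against the same `B` cohorts. Every resample fit is a
  multivariable model: marker group plus the endpoint's clinical
  adjustment set (LRC: sex, cisplatin dose category; OS: sex, subsite,
  cisplatin; PFS: stage, subsite, cisplatin; DM: sex, alcohol). These
  frozen sets reproduce the screening outcome of the original analysis; a
  caller can substitute any `EndpointSpec`.
- **Fraction curve**: per cutoff, the fraction of *valid* resample fits
  with marker Wald p < 0.05. Failed fits (no events, < 2 distinct event
  times, constant design column, separation, singular information) are
  excluded from the denominator and reported; significant + nonsignificant
  + failed = B at every cutoff.
- **Smoothing**: centered moving average over 9 adjacent cutoffs. At the
  edges the window truncates to the available neighbours (a shrinking
  window invents no data, unlike reflection).
- **Selection**: argmax of the smoothed curve; exact ties break toward the
  cutoff nearest the marker median, then toward the smaller cutoff —
  deterministic and stable.
- **Final fit**: the original (non-resampled) cohort, marker dichotomized
  at the selected cutoff with the low group as reference, same covariates.

**Post-selection optimism.** The final fit reuses the data that selected
the cutoff, so under a null marker its p-value is anti-conservative. This
is a property of the procedure being reproduced, not a defect of the
implementation; the test suite *asserts* the inflation (null rejection
rate significantly above 5% across seeds) rather than correcting it.
Selected cutoffs and their p-values should be treated as exploratory.

## Backward selection by AIC

Starting from the full model (all dichotomized markers at their
endpoint-specific selected cutoffs, plus clinical variables), the single
variable whose removal most lowers the AIC is dropped, repeatedly, while
any removal lowers it. Categorical variables leave as whole blocks. The
complete-case sample is fixed once from the full variable set so AICs are
comparable across nested models. Candidate comparisons break ties by AIC
then variable name, so permuting the input order cannot change the trace.
Greedy descent can in principle miss the all-subsets optimum; agreement
with exhaustive search on 5-variable strong-signal cohorts is measured in
the acceptance checks (25/25 in the shipped configuration).

## Cutoff-averaged hazard-ratio profiles

To compare markers without committing to one cutoff, the multivariable
model is refit at *every* admissible cutoff on the full cohort and the
marker HRs averaged — the area under the HR-vs-cutoff-rank curve
normalized by its width. The default is the arithmetic mean of HRs;
because averaging ratios on the raw scale is asymmetric around 1, a
geometric (log-scale) mean is available (`average="geometric"`). Failed
fits are excluded and counted, never imputed. The profile is deterministic
and invariant to strictly monotone transformations of the marker.

## Signature scoring

- **TPM**: per sample, `rate_g = count_g / length_g`,
  `TPM_g = 1e6 * rate_g / sum(rate)`; every column sums to one million.
- **Rank-z set score**: within each sample, genes are converted to average
  ranks, the rank vector standardized to mean 0 / sd 1, and the score is
  the mean standardized rank over the signature's up-genes minus the mean
  over its down-genes. This is *not* GSVA: GSVA's kernel-density rank
  statistic has unstated parameters in this setting and is an external
  method; the rank-z mean preserves the per-sample ordering such scores
  target, is exactly unit-testable, and is invariant (bit-identical) to
  any strictly monotone per-sample transformation — which also makes the
  counts-vs-TPM input question immaterial for set scores.
- **Set contrast (e.g. CD8+ vs Treg)**: implemented as the difference of
  standardized set scores rather than a literal quotient, because
  standardized scores cross zero; `quotient=True` is available for
  strictly positive inputs.
- Signature genes absent from the matrix are dropped with a warning when
  fewer than half the set is missing, otherwise scoring errors out. All
  markers go through these generic scorers; reproducing each signature's
  original classifier protocol is out of scope, and gene lists are
  user-supplied (GMT).

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the analysis
assumes, with known ground truth for recovery tests. It is not a tumor
biology model: it emulates correlations, marginal frequencies and
proportional hazards, not recurrence dynamics, dose–response, or RNA-seq
read noise.

- **Marker scores**: Gaussian copula. Target Spearman correlations are
  mapped to the Pearson scale by `2 sin(pi r / 6)`, the matrix repaired to
  the nearest PSD matrix by eigenvalue clipping at 1e-8 (repair beyond a
  0.1 entry-wise tolerance is a configuration error), and scores drawn
  with standard-normal marginals. Shipped default targets: CD44–SLC3A2
  0.57, acute-hypoxia–proliferation 0.58, acute-hypoxia–TIS 0.51,
  acute-hypoxia–CD8 0.54, acute–chronic hypoxia 0.26 — the reported
  correlations of the emulated cohort. Empirical Spearman converges to the
  targets (|error| < 0.05 at n = 5000, tested).
- **Clinical covariates**: independent multinomial draws at the published
  marginal frequencies (sex 142:55 M:F; alcohol 146:22:22 yes:former:no;
  subsite 85:78:34 oro:hypo:larynx; stage 135:40:20:2; cisplatin >=200
  126:67), independence being consistent with the reported absence of
  marker–clinical associations. Tumor volume is log-normal with median
  23.2 cm³ and sdlog 1.1 (chosen so the observed range at n~200 spans
  ~1–750 cm³). Cross-tabulations (e.g. sex x alcohol) are not reproduced —
  only marginals are published.
- **Event times**: exponential given the linear predictor,
  `T ~ Exp(h0 * exp(lp))`, which keeps the events-per-person-time ratio an
  exact closed-form oracle for the hazard ratio; a Weibull shape parameter
  is exposed. Marker effects act as steps at a configurable quantile of
  the theoretical N(0,1) marginal (default: the median); `"linear"` uses
  the score directly. Background death is an independent exponential given
  covariates (no shared frailty — a documented simplification), censors
  LRC/DM when it comes first, and drives OS; PFS is the minimum of the
  three latent event times; administrative censoring (exponential) applies
  last.
- **Default rates**: baseline LRC and DM hazards 0.02/year each, death
  0.04/year, administrative censoring 0.19/year. These were calibrated
  once, analytically, so the default cohort shows roughly the published
  event fractions (~24% locoregional recurrences, ~20% distant metastases)
  and a median follow-up near 5.2 years. Default effect sizes mirror the
  strongest reported associations per endpoint (e.g. chronic hypoxia
  HR 3.95 and acute hypoxia HR 1.9 on LRC; EMT HR 3.14 and acute hypoxia
  HR 2.44 on DM; cisplatin < 200 mg/m² HR 2.57 and female sex HR 0.52 on
  LRC), with all marker cutoffs at the median since the cohort-specific
  selected cutoffs are not public.
- **Expression simulator**: log-normal background counts with signature
  genes mean-shifted proportionally to the target score (in log space),
  rounded to non-negative integers — just enough structure for end-to-end
  tests of the scorers (recovered scores correlate with the generating
  scores at Spearman > 0.8 for amplitude 2.0, pilot-fixed).
- **Randomness**: one global seed; every operation draws from its own
  stream derived from the seed plus a stable hash of the operation name,
  so cohorts, scores and scans are individually reproducible and
  bit-identical across reruns.

Because the generator satisfies the proportional-hazards and independence
assumptions by construction, passing recovery tests demonstrates the
correctness of the estimators and of the selection machinery — not
robustness to violations (non-proportional hazards, informative censoring,
marker–clinical dependence) that real cohorts may exhibit.

## Numerical choices and degenerate inputs

- Newton tolerance 1e-7 on the sup-norm of the score; max 100 iterations;
  step-halving up to 40 times; separation bound |β| > 15.
- The compiled kernel solves the p x p Newton system by an explicit
  Cholesky factorization; a collapsing pivot (<= 1e-12 of the diagonal
  scale) marks the fit failed instead of raising.
- Constant markers have no admissible cutoff (error); constant covariates
  in a *resample* mark that resample's fits failed; zero-event inputs are
  errors.
- Smoothing windows must be odd; undefined (all-failed) fractions
  propagate as missing and are excluded from smoothed averages.
- Log transforms ahead of clustering (`tumor volume`, `EGFR`) use
  `log1p` and are skipped with a warning for columns that are not
  positive — synthetic scores are already centred, real TPM columns are
  transformed. Clustering is complete-linkage on Euclidean distances of
  z-scored columns (the linkage/distance pair is not specified in the
  source analysis), with scipy's deterministic ordering.
- No multiple-testing correction anywhere, matching the reproduced
  analysis; correlation-report p-values are explicitly unadjusted.

## Analysis problem sizes

The shipped tests and the acceptance script use scaled-down but structurally
faithful sizes chosen as standard desk-scale experiments: bootstrap scans
with B = 200–500 (the procedure's reference configuration is B = 10,000;
selected cutoffs at B = 500 vs 2000 agree within a few percentile ranks in
the strong-effect scenario, and the B = 200 vs 500 agreement is tested),
25-seed replication for recovery/coverage/optimism rates, 2000 replicates
for Wald calibration, and n = 5000 for copula calibration.

## Known limitations

- Post-selection inference is reported uncorrected (by design, see above).
- Death is censoring, not a competing risk; no frailty.
- The rank-z set score is a documented stand-in for GSVA-style scoring:
  it preserves sample ordering but its absolute scale differs from GSVA
  output, so externally derived GSVA cutoffs do not transfer.
- Greedy backward AIC is not guaranteed to find the all-subsets optimum.
- The generator draws clinical covariates independently of marker scores;
  confounding structures cannot be simulated without extending it.
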