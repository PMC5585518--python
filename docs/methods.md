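# Methods

This note documents the models implemented in `impscore`, the assumptions
behind them, the synthetic-registry generator used to validate them, and the
numerical and design choices that were genuinely open.

## Data model and exclusion cascade

A registry patient carries demographics (age, sex), an injury-mechanism
category (one of six: low fall, motor-vehicle crash, violence, blunt, stab,
gunshot), a Glasgow Coma Score (3–15, possibly missing), a hospital
identifier, an in-hospital death indicator, a length of stay, and one or more
AIS-coded injuries. Each AIS code splits into a six-digit predot identifier
and a postdot severity in {1..6, 9}. The body region of an injury is derived
from the first predot digit by the standard AIS chapter convention (1 head,
2 face, 3 neck, 4 thorax, 5 abdomen, 6 spine, 7 upper extremity, 8 lower
extremity, 9 external/other); the mapping is user-overridable so a finer
regional scheme (e.g. 12 regions) can be supplied. Burn/non-traumatic status
and disposition (dead on arrival, transfer out) are boolean flags in the
input schema because the underlying diagnosis and disposition code systems
are not modelled.

The exclusion cascade removes, in a fixed order, patients with: no AIS
codes; a burn or non-traumatic diagnosis; missing age, sex, length of stay or
outcome; a single injury whose only code has severity 9; age outside 1–89;
death on arrival; transfer to another facility; and finally patients at
hospitals below a minimum annual volume (default 500). Each patient is
attributed to the first rule it violates, so the audit counts plus the
retained count always partition the input. The cascade is idempotent.

The 60/20/20 derivation/estimation/validation split is a seeded per-patient
shuffle (hospital-stratified splitting is available but off by default, since
there is no evidence the original analysis stratified).

## Stage 1: the per-code severity dictionary (WADP)

**TMR.** The trauma mortality rate of code *c* is d/n over the derivation
patients carrying it (a patient counts once per code). Two endpoint
corrections keep every TMR strictly inside (0,1): codes with zero deaths
get the floor 0.008 × 0.618 = 0.004944 — the ≈0.8% crude death rate of the
US population in the study years, scaled by the golden-ratio point to
reflect that injured cohorts skew young — and codes with 100% observed
mortality get d/(n+1), i.e. one artificial survivor. Both constants are
configurable.

**Component models.** Three logistic regressions of death are fitted on the
derivation split: (i) a TMR model whose injury covariate is the logit of the
patient's maximum code TMR (sum- and mean-of-logits summaries are
selectable); (ii) a GCS model on the total score, fitted only on patients
with observed GCS; (iii) a body-region model on indicators of the injured
regions. All three include the comprehensive covariates: NBR (number of
distinct injured regions), ln(age), sex, mechanism dummies (low fall as
reference) and hospital fixed effects (largest hospital as reference;
hospitals under a configurable patient count are pooled into "other" to
avoid separation).

**TDP blending.** The traumatic death probability of a patient is the convex
blend w·(p_tmr, p_gcs, p_br). The original description fixes neither the
selection criterion nor the grid; here the weights are chosen by exhaustive
search over the simplex lattice (default step 0.05, 231 candidates),
maximising the AUC of the blended score against death on a seeded 20%
held-out fold of the derivation split. Ties break toward larger TMR weight,
then larger GCS weight. When a patient's GCS is missing the weights
renormalise over the TMR and BR components, so a TDP is defined for every
derivation patient.

**WADP aggregation.** The severity value of code *c* is the mean of the 3
highest transformed scores among its carriers; with fewer than 3 carriers,
the mean of all of them. An optional weight vector over the descending top-3
replaces the plain mean (the default is equal weights). The transform is
h(p) = −ln(1−p), the cumulative-hazard scale: h(p) ≈ p for small p, and
h(0.975) ≈ 3.69, which is how a "probability average" can exceed 1 for
unsurvivable injuries. The identity transform is selectable.

Two aggregation modes exist, and the difference matters:

* **code-anchored (default)** — the score of the (patient, code) pair uses
  the TMR component evaluated at *the code's own TMR*, keeping the patient's
  remaining covariates and the patient's GCS/BR component predictions. A
  minor code then keeps a low severity value even when some of its carriers
  die of unrelated co-injuries.
* **patient-level** (`DerivationConfig(anchor="patient")`) — the top-3 of
  the carriers' own TDPs. This is simpler, but for a code with hundreds of
  carriers the top-3 are extreme order statistics of the carrier pool and
  are dominated by the worst co-injury ever seen with the code; severity
  values compress toward the patient-risk tail and lose rank fidelity
  (measured ground-truth Spearman drops from ≈0.9 to ≈0.2–0.8 on the
  synthetic registry). The code-anchored mode is also the only reading under
  which a truly minor injury can end up with a severity value near the TMR
  floor, as published dictionaries of this kind do.

Codes never seen in the derivation split fall back, with a warning, to the
floor TMR pushed through the transform (≈0.00496 on the hazard scale).
Severity-9 codes carried inside multi-injury patients are retained and
receive WADP values; the postdot severity is never used numerically.

## Stage 2: mortality models

The IMP feature vector is: the five largest severity values among the
patient's injuries in decreasing order (zero-padded below five — a zero is
"no injury"); an indicator that the worst and second-worst injuries share a
body region; the product of the two worst values; and the fractional-
polynomial terms ln(NBR) and NBR^0.382 (the exponent is configurable but
fixed by default). Ties in the severity ordering break by body region then
predot, so features are invariant to the order injuries are listed. SWI uses
the single worst value; TMPM uses the IMP structure over an externally
supplied MARC dictionary (code → value CSV, same layout as the WADP table).
Augmented variants append ln(age) — log-age rather than linear age, since
trauma mortality rises multiplicatively with age; linear age is selectable —
a male indicator and five mechanism dummies.

Models are maximum-likelihood logistic regressions (statsmodels). Because
outcomes within a trauma centre are correlated, the reported covariance is
the hospital-clustered sandwich. The small-sample correction factor is off
by default, so with one observation per cluster the covariance reduces
exactly to the HC0 sandwich; the Stata-style correction is available via
`fit(cov_correction=True)`. L-BFGS with a tight gradient tolerance is used
first and a Newton polish is applied if it stalls (the ln(NBR)/NBR^0.382
pair is nearly collinear, which is harmless for prediction but slows
first-order optimisers). Predicted probabilities are clipped to
[1e-12, 1−1e-12] to keep downstream statistics defined when linear
predictors are extreme.

## Evaluation

* **AUC**: the Mann–Whitney probability with ties counted ½, computed from
  ranks.
* **Hosmer–Lemeshow**: deciles-of-risk grouping — quantile bins of predicted
  risk, ties assigned to the lower bin, bins emptied by tie collapsing
  dropped with a warning — and statistic Σ (O−E)²/(E(1−E/n_bin)) over the
  event counts. g = 10 by default.
* **AIC**: 2k − 2·loglik. At fit time this uses the estimation-set
  likelihood. In model comparison the AIC is computed from the
  validation-set Bernoulli log-likelihood of each model's predictions with
  the model's parameter count, so competing models are ranked on the same
  held-out data.
* **Bootstrap CIs**: bias-corrected percentile intervals (z₀ from the
  fraction of replicates below the point estimate, endpoints at
  Φ(2z₀ ± 1.96)), patient-level resampling with replacement, 1000
  replications by default, seeded. Resamples on which a metric is undefined
  (e.g. a single-class AUC draw) are skipped up to 1% of replications. A
  cluster bootstrap is not used because the published procedure resamples
  records. A degenerate (constant) replicate distribution collapses the
  interval to the point estimate.
* **Calibration**: equal-count quantile bins (default 20) of predicted risk,
  observed mortality with exact Clopper–Pearson 95% intervals per bin, and
  an OLS line of observed on predicted bin means with its R².

## The synthetic registry

The generator stands in for access-restricted national registry data. It
emulates: a code dictionary with latent per-code lethality log-uniform on
[1e-4, 0.95] (four orders of magnitude) and 10 codes in each of 9 body
regions; truncated-geometric injury counts with mean ≈2.5 (max 10); six
mechanisms at shares 38.6/36.2/10/9/3/3.2%; 35.5% female; 20 hospitals with
N(0, 0.3²) log-odds effects; GCS = 15 minus a Poisson deficit growing with
the worst head-region lethality, missing completely at random at 5%; and
true death log-odds β₀ + 2.0·h(worst lethality) + 0.8·h(second) +
0.5·ln(NBR) + 0.015·(age−40) + hospital effect, with β₀ calibrated by
bisection to an overall mortality of 2.76%.

Injury severities are correlated within a patient: each patient draws a
latent severity level (SD 1.0) shifted by mechanism (gunshot +0.9, low fall
−0.6, …) that tilts code sampling (Gumbel-max with tilt 1.5 on standardised
log-lethality). Real polytrauma is mechanism-correlated; with independent
sampling every minor code would accumulate severely injured carriers at base
rates and no top-k aggregation could order codes by lethality. The worst-
injury coefficient (2.0 on the hazard scale) is chosen so that a near-lethal
code actually kills most of its carriers despite the low-mortality
intercept; 10 codes per region keeps per-code carrier support (~800 in a
30,000-patient derivation split) within an order of magnitude of large-
registry practice.

What the generator does **not** emulate: real AIS coding practice and code
frequencies, comorbidity and physiology beyond GCS, time trends, inter-rater
coding error, informative missingness, and transfer patterns. Passing tests
therefore demonstrate internal correctness and recoverability of a known
generative process, not clinical performance on real registry data.

A "dirty" mode injects known counts of each exclusion-rule violation into an
otherwise clean cohort so the audit can be tested; single-injury patients
are never assigned severity-9 codes in clean mode (such records would be
excluded wholesale).

## Problem sizes and determinism

The test suite and the acceptance script run the full method on synthetic
registries of 5,000–50,000 patients, coefficient-recovery simulations at
n = 100,000, and bootstrap-coverage studies with 200 repetitions at
n = 2,000 — sizes at which every stage's statistical behaviour is already
stable. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); a pipeline run writes a config snapshot and a
hash of the scientific configuration (output paths excluded), and re-running
the same configuration reproduces every artifact byte for byte.

## Known limitations

* The blend-weight criterion (held-out AUC) and the h-transform are
  reasoned reconstructions of a procedure whose appendix formulas are not
  public; both are configurable and recorded in the derivation result.
* WADP values inherit derivation-split sampling noise; codes with few
  carriers (n_support < ~20) are rank-unstable, as the recovery tests show.
* The TMPM comparator consumes a MARC dictionary; it does not re-derive one
  (that would require Bayesian model averaging over code models, out of
  scope here).
* Hospital fixed effects are plain dummies; no shrinkage is applied, so
  very small hospitals must be pooled to avoid separation.
* The validation-set AIC ranks models by held-out likelihood; it is not the
  estimation-set AIC a fitting report would show, and the two can disagree
  when calibration drifts between splits.
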