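# Methods

## Scope and data model

The package implements a structured biomarker analysis plan for a
placebo-controlled exacerbation trial: descriptive preparation, continuous
predictive screening, subgroup search with resampling-based uncertainty,
cut-off refinement, and longitudinal consistency checks.  The common
currency is a `TrialDataset`: one row per participant (arm, five biomarkers
on native scales, region, age, prior-year exacerbations, exacerbation count,
follow-up years, baseline endpoint scores) plus a long table of per-visit
endpoint values.  Arms are four-level at load time
(`tralo_q2w/placebo_q2w/tralo_q4w/placebo_q4w`); `prepare_analysis_set`
pools the two placebo arms, applies explicit (never automatic) outlier
rules with a full exclusion log, and derives the modelling covariates.
Every comparison is an active arm versus the pooled placebo; the
every-4-weeks arm is analysed only as a supportive repeat, never combined
with the every-2-weeks arm in one model.

Conventions chosen where the plan leaves them open:

* age group: adolescent iff 12 ≤ age < 18 years;
* periostin group: dichotomised at the in-sample median (configurable);
* prior exacerbations: ordered categories 1 / 2 / ≥3;
* a missing biomarker excludes a participant from analyses of that
  biomarker only;
* CSV dialect: comma-separated, UTF-8, header row, empty field = missing.

## Negative-binomial engine

Counts over unequal follow-up are NB2 (log link, variance μ + k·μ², offset
log follow-up-years), fitted by joint maximum likelihood over (β, k) via
statsmodels, with Wald inference on the coefficient scale and normal
critical values.  When the interior optimiser degenerates because the MLE
sits on the k → 0 boundary (underdispersed small samples), the Poisson
boundary fit is returned with k = 0; an all-zero outcome returns a flagged
non-converged fit with an infinite-SE guard rather than an error.  Rate
ratios map to AAER reductions as (1 − RR)·100 with the CI transformed
endpoint-wise.  Likelihood-ratio tests require both fits to use identical
rows, preventing silently different complete-case sets.

The subgroup search needs thousands of *treatment-only* NB fits
(intercept + treatment + offset).  For that fixed model the likelihood
separates by arm given k, so a specialised exact MLE is used: a 1-D Newton
solve of each arm's rate equation inside a golden-section profile of log k
(bracket k ∈ [1e-4, 30], tolerance 5% on k, where the profile is flat).
Because the expected β–k cross-information vanishes under NB2, Wald SEs from
the per-arm observed information are asymptotically exact; the fitter agrees
with the statsmodels joint MLE to ~1e-3 on β and SE (tested).  Inside the
search all cut-offs of a biomarker are scored in one vectorised batch (a
synchronised golden-section over children with batched Newton steps),
numerically identical to the scalar path (tested to machine precision).

## Screening (Question 1)

Interaction tests enter each biomarker on its raw scale (log scale
available) in a separate model with treatment, region, age, prior-year
exacerbation category, biomarker, and treatment×biomarker; the panel-level
test is a 5-df LRT of all interactions jointly.  Effect curves are
predictions at reference covariates (modal category / median continuous)
over the 5–95% quantile range.  The smooth display fits per-arm penalized
cubic B-splines (second-difference penalty, GCV-selected smoothing at fixed
dispersion taken from a covariate-only pre-fit) — a deliberate substitution
for thin-plate regression splines — then passes per-participant link
predictions through a tricube local-linear smoother with span 0.67 before
exponentiating.  Forests use type-7 sample quartiles with ties assigned to
the lower quartile; quartile effects come from one saturated
treatment×quartile model, cumulative effects from treatment×(above/below)
models at each quartile cut.

## SIDES search (Question 2)

Candidate cut-offs sit at quantiles j/(n_splits+1), j = 1..n_splits
(default 50), deduplicated; a cut-off whose children could not seed any
admissible subgroup (both below N_min) is dropped.  Each split fits the
treatment-only NB model in both children; the benefit statistic per child is
z = −β̂/SE (positive = fewer exacerbations on treatment).  Criteria:

1. differential effect: p = 2(1 − Φ(|z₁ − z₂|/√2));
2. maximum effect: p = 2·min(1 − Φ(z₁), 1 − Φ(z₂));
3. criterion 1 plus a one-sided benefit requirement (p < 0.05) on the
   better child.

Defaults: depth L = 1 (one biomarker per subgroup), M = 5 candidates,
N_min = 60, 30% minimum prevalence, criterion 1, continuation factor
γ = 1 (inactive at depth 1), selection threshold 0% reduction.

Two readings of the pre-specified prevalence floor were possible: bind only
the reported (better-child) subgroup, or bind the cut-off itself.  The
package binds the cut-off: both children must hold at least 30% of the
participants non-missing for that biomarker.  Rationale: the floor was
pre-specified to "restrict complexity", either child can be the reported
subgroup, and without the two-sided bound the differential criterion is
dominated by degenerate splits — a near-whole-population child carrying the
marginal treatment effect against a tiny noisy complement — which makes the
search's ranking of biomarkers unstable (observed directly in simulation:
top-biomarker recovery drops from the mid-80%s to ~55–65%).  The best split
per biomarker is then the admissible split with the smallest criterion p
(ties: smaller cut-off, then biomarker name).  Identified subgroups are
re-evaluated — and their complements alongside — with the covariate-adjusted
model (treatment, region, age, prior-exacerbation category, offset) fitted
separately on each membership set.

The search trace records every cut-off evaluated at every node with its
scores or rejection reason, and re-running on the same data is bit-identical.

## Resampling (Question 2 uncertainty)

*Bootstrap*: B (default 500) participant-level resamples with replacement,
stratified by arm to preserve the allocation ratio (unstratified available);
the search re-runs per draw and the chosen cut-off per biomarker is
histogrammed over the original data's candidate grid so bins are comparable
across draws.  Sub-seeds spawn from the master seed, so draw k is identical
alone or in batch.  An identity-resample hook exists purely for testing.

*Permutation null*: the five-biomarker block is permuted as one unit across
participants (preserving the panel's internal correlation, breaking all
biomarker–outcome and biomarker–treatment links; independent per-biomarker
permutation available), the search re-runs, and the best selected subgroup's
apparent reduction is recorded; if no subgroup passes the constraints the
draw contributes the all-comers reduction (counted separately).  With a
genuinely beneficial treatment the null median is positive — the
quantitative face of subgroup selection bias — and the observed best effect
is reported as a mid-rank percentile of the null.

## Refinement and endpoints (Question 3)

The cut-off scan refits, at each grid value, one NB model with treatment,
region, age group, periostin group, prior-exacerbation category and
treatment×(at-or-above/below) interaction, reporting both sides with nominal
p-values (no multiplicity adjustment anywhere in this layer; the at-or-above
side is inclusive, matching the scan convention, while SIDES cut-offs are
strict).

Secondary endpoints use maximum-likelihood repeated-measures models with
fixed effects treatment + region + age group + periostin group +
prior-exacerbation category + visit + treatment×visit +
treatment×subgroup-side (score endpoints add the baseline score, and their
response is change from baseline).  The visit covariance is unstructured for
FEV₁ % change — fitted by EM for the incomplete multivariate normal
(conditional-moment E-step over missing visits, GLS coefficient step), valid
under missing-at-random dropout — and compound-symmetric for the scores,
fitted by direct ML over the two variance components with the GLS
coefficient profile; the CS fit matches a random-intercept ML oracle to
1e-4 (tested).  A non-convergent or non-PD unstructured fit falls back to
compound symmetry with the downgrade recorded.  The reported effect is the
treatment difference at the final scheduled visit within each side; SEs are
model-based with normal quantiles (no small-sample df correction).

The decision summary is a pure function of its inputs: per candidate
subgroup it tabulates prevalence % (n/N), adjusted reduction with CI, the
continuous interaction p (flagged nominally significant below 0.10), the
count of secondary endpoints with nominal p < 0.05 benefit in the subgroup,
and a supportive-arm consistency flag; candidates are ranked by interaction
significance, then endpoint consistency, then effect size.

## Simulator

The generator emulates the stated world rather than fitting any particular
dataset.  Biomarkers are log-normal, moment-matched to published marginal
summaries via μ = ln(median), σ² = 2·ln(mean/median) — targets
(median, mean): FeNO (20.3, 30) ppb, periostin (23, 26) ng/ml, eosinophils
(200, 290) cells/μl, DPP-4 (250, 264) ng/ml, IgE (150, 430) IU/ml — with a
Gaussian copula on logs (default pairwise 0.3 among FeNO/periostin/
eosinophils, 0 elsewhere; correlations are otherwise unreported).
Allocation is largest-remainder 2:1:2:1 (ties to the earlier arm) with
seeded label shuffling.  Counts are gamma-frailty Poisson (exact NB2,
default k = 1; k = 0 gives Poisson), log-rate = log placebo AAER
(default 0.80 events/year, a typical severe-asthma placebo rate) +
prognostic terms on standardised log biomarkers + arm effect + an optional
threshold interaction: treated participants above the biomarker's planted
quantile multiply their rate by subgroup_rr, so the rate ratio inside the
truth subgroup is all_comers_rr × subgroup_rr.  A smooth (linear-in-log)
interaction variant exists.  Dropout is exponential, independent of outcome,
truncated at 1 year (default 10% by week 52); follow-up enters the offset
exactly as generated, so the truth record reproduces every expected count
bit-for-bit (tested).  Endpoints are visit-indexed with a random subject
intercept (compound-symmetric covariance) and a treatment effect at steady
state from the first post-baseline visit — deliberately matching the
estimand of the endpoint model, which carries no treatment×visit×subgroup
term — with monotone missingness after dropout.

What a green simulation test does *not* establish: the generator has no
measurement error in biomarkers, no informative dropout, no
region-by-treatment structure, no within-year seasonality, and endpoint
residuals are exactly compound-symmetric — so unstructured-covariance
machinery is exercised for correctness, not stressed by misspecification.

## Operating characteristics and numerical choices

* Convergence: NB fits iterate to relative log-likelihood change < 1e-8
  (max 200); the fast fitter's Newton tolerance is 1e-9 with a ±5 step clamp;
  EM stops at relative log-likelihood change < 1e-8 (max 200).
* "n" for a simulated property always means the analysed two-arm comparison
  (active every-2-weeks + pooled placebo), since every model is fitted to
  that comparison; a 2:1:2:1 trial of 1,800 yields a comparison of 1,200.
* Known limitation: with a planted threshold interaction at 60th percentile
  and subgroup rate-ratio multiplier 0.5 at comparison n = 1,200, the
  differential-effect search ranks the true biomarker first in ~83–88% of
  replicates (100-replicate runs across seed blocks).  The residual
  failures are split between correlated biomarkers partially carrying the
  true signal and in-band noise maxima over ~20 admissible splits × 4
  competing biomarkers riding the marginal treatment effect.  This is the
  intrinsic behaviour of the criterion at this effect size and sample size;
  the corresponding acceptance test asserts the stated ≥90% bound and is
  expected to fail by that margin.
* Reduced-scale defaults for tests and the pipeline (B = P = 50; the
  acceptance driver uses 30) keep runtimes bounded; the documented
  production profile is B = P = 500.
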