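# Methods

`graftrisk` implements a sequential population-pharmacokinetic /
pharmacodynamic analysis for adult kidney-transplant recipients on
tacrolimus and mycophenolate mofetil (MMF): population PK models of both
immunosuppressants, individual exposure prediction, and a visit-level
logistic regression linking urinary biomarkers and drug exposure to the
probability of acute rejection (AR) — together with the model-evaluation
machinery (pcVPC, categorical VPC, npde, nonparametric bootstrap) and a
synthetic-trial generator that stands in for the clinical dataset.

## Structural PK model

Both drugs follow a two-compartment disposition model with first-order
absorption through a depot, an absorption lag time, and linear elimination
from the central compartment.  Only oral data are available, so all
disposition parameters are apparent (CL/F, Vc/F, Q/F, Vp/F).  Parameters
are referenced to 70 kg and scaled by fixed-exponent allometry: flows with
(WT/70)^0.75, volumes with (WT/70)^1.

Concentrations are evaluated with the closed-form tri-exponential
single-dose solution superposed over the recorded dose history.  Runs of
uniformly spaced equal doses are collapsed into geometric sums of the
exponential terms, which is algebraically identical to dose-by-dose
superposition but reduces a six-month twice-daily history (~360 doses) to a
handful of terms.  The closed form is validated against stiff numerical
integration of the three-state ODE system to a relative tolerance of 1e-6.
When Ka falls within 1e-8 (relative) of a disposition exponent the roots
are degenerate; Ka is then nudged by 1e-7 (relative), which perturbs the
profile by far less than the validated accuracy.

Cumulative exposure AUC(0→t) is integrated analytically per exponential
term (the multiple-dose accumulation uses the same geometric-sum identity);
at t→∞ it satisfies the mass balance AUC = dose/(CL/F) to 0.1%, which the
tests assert.  "Mean trough" exposure is the running arithmetic mean of the
model-predicted pre-dose concentrations at the visits seen so far.  MMF
doses enter as mycophenolic-acid molar equivalents via the molecular-weight
ratio 320.34/433.49.

Units: time in hours, doses in mg, tacrolimus in ng/mL (whole blood), MPA
in µg/mL (plasma).  A per-model `conc_scale` (1000 for tacrolimus, 1 for
MPA) maps the mg/L prediction of the dose/volume algebra onto the
observation unit.

## Population estimation

Between-subject variability (BSV) is log-normal: parameter_i = typical ×
allometry × covariate factors × exp(eta_i), with eta ~ N(0, Ω).  BSV is
reported as 100·sqrt(ω²) % — the log-scale SD convention, which matches the
magnitude of variabilities above 100% that a CV-based convention could not
express.  Residual error models: additive on log-transformed concentrations
(tacrolimus; reported as a percentage it plays the role of a proportional
error), proportional (MPA), additive, and combined.

The marginal likelihood is approximated per subject by Laplace's method
around the empirical Bayes (EB) mode.  The inner problem — the EB modes of
all subjects — is solved simultaneously: population predictions are one
vectorized pass through the closed-form kinetics (a numba kernel with a
pure-numpy reference path), Jacobians with respect to eta come from central
differences of that pass, and the per-subject Newton systems are solved as
a batched stack of small linear systems with per-subject Levenberg-
Marquardt damping.  For the proportional-error kinds the gradient carries
the full interaction terms (the residual variance depends on eta through
the prediction) and the curvature uses the expected (Fisher) information,
1/v + 2σ⁴f²/v², whose variance-mean coupling term is essential for a fast
convergence rate.  Subjects are independent, so converged subjects are
frozen and later iterations touch only the stragglers' observation pairs.
The approximation is exact for predictions linear in eta and is verified
against exact Gauss-Hermite quadrature on single-random-effect models: to
1e-4 in the small-variance limit, to ~0.2% relative at ω = 0.3.

The outer problem maximizes the approximate marginal likelihood by L-BFGS-B
over log-transformed parameters (typical values, diagonal ω² or a block
Cholesky, σ) inside wide plausibility bounds; finite-difference gradients
use a 5e-4 log-scale step.  The inner solver is warm-started from the etas
of the best point seen so far — never the previous call — so the objective
is a deterministic function of the parameters, which finite differences
require.  L-BFGS is restarted (fresh quasi-Newton memory) until a round
improves the objective by less than 1e-3; convergence is declared at a
relative objective change below `rel_tol` (default 1e-6).  Initial values
come from a naive-pooled log-scale least-squares pre-fit with ω² = 0.1 and
σ from the pooled residuals.

The likelihood surface is multimodal in the absorption parameters: with
sparse absorption-phase sampling, a near-instantaneous Ka with the lag time
absorbing the delay can imitate slower first-order uptake.
`fit_pop_multistart` therefore refits from the pooled Ka and from a neutral
moderate-absorption start (Ka = 1/h) and keeps the better objective.

Precision (RSE%) comes from the inverse finite-difference Hessian of the
objective (cov = 2·H⁻¹); since parameters are estimated on the log scale
the SE of log θ is directly the relative SE of θ.  The condition number is
the extreme-eigenvalue ratio of that covariance matrix, flagged above 1000.
Eta-shrinkage is 100·(1 − SD(EBE)/ω), epsilon-shrinkage 100·(1 − SD(IWRES)).
CWRES uses the first-order-conditional linearization around the EB modes
(marginal mean m(η̂) − Jη̂, covariance JΩJ' + V, Cholesky decorrelation per
subject).  Covariate selection is stepwise: forward inclusion at ΔMOFV ≥
χ²₁(0.05) = 3.841, backward elimination retaining only effects whose removal
costs ≥ χ²₁(0.001) = 10.828, with linear, power and exponential forms and
AIC reported for non-nested comparisons.  Interoccasion variability is
supported in simulation only (below), never estimated — the final published
models carry none.

## Exposure–response logistic model

The binary outcome is AR at a visit; to measure prognostic (not diagnostic)
value, each rejection episode is scored on the subject's latest available
visit *before* the diagnosis, carrying that earlier visit's predictor
values.  Episodes diagnosed at the first available visit have no
predecessor and are scored on that same record (counted separately) — this
preserves the week-1 events, which are a large share of all episodes.
Candidate explanatory variables are cumulative AUC and running mean trough
of each drug (individual EB predictions, PK parameters fixed) and the
urinary biomarkers miR155-5p (relative expression, 2^-ΔCq scale, entered
untransformed) and CXCL-10 (pg/mL).

The risk model is a plain fixed-effects logit fitted by Bernoulli maximum
likelihood (iteratively reweighted least squares with step halving);
complete separation raises an error naming the offending predictor.
Forward/backward selection uses the same χ² cut-offs as the PK covariate
machinery.  A subject-level random intercept is out of scope: the final
published model is fixed-effects only.

## Model evaluation

All diagnostics simulate replicate datasets at the original design and are
bit-reproducible given (seed, n_sim).

* **pcVPC** — observed and simulated values are corrected by
  pcY = Y · median(PRED in bin)/PRED and compared as binned percentiles
  (2.5/50/97.5) against the 95% band of the same percentile across
  replicates.  Binning is quantile-based on time after dose (default 8
  bins); bins with fewer than two observations merge with a neighbour.
* **Categorical VPC** — binary outcomes re-simulated at the observed
  predictor values; observed AR proportion per miR155-5p bin against the
  simulated median and 95% prediction interval.
* **Grouped bars** — observed vs mean-predicted AR proportion in 10
  contiguous equal-width bins of the explanatory variable.
* **npde** — per subject, observed and simulated vectors are decorrelated
  with the simulated mean and covariance (Cholesky; ridge if singular); the
  rank of each decorrelated observation among its simulated marginals maps
  through the inverse normal CDF.  Per-subject generators are keyed on the
  subject identifier, making the values invariant to cohort ordering.
  Under a correct model the npde are ≈ N(0, 1), asserted on self-simulated
  data (mean within ±0.1, variance within [0.85, 1.15]).
* **Bootstrap** — plain (unstratified) subject resampling with refits;
  failed refits are counted and a failure rate above 20% flags the result
  unstable.  Defaults follow the study scale (1000 resamples for PK, 200
  for the logistic model); the test suite uses 50 PK resamples.

## Synthetic-trial generator

The generator emulates the study design: 58 subjects; visits at week 1
(day drawn uniformly from 1–11) and months 1, 2, 3, 6; rich week-1 sampling
(0, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12 h post-dose) and sparse later sampling
(0, 1.5, 2, 4 h); twice-daily dosing at the published per-occasion mean
daily doses (tacrolimus 14.60/10.63/7.78/6.79/5.29 mg/day; MMF
1875.91/1655.41/1552.02/1402.64/1238.67 mg/day, converted to MPA
equivalents), with each occasion's level starting ahead of its visit so
every visit is sampled after a run-in on its own level.  Body weight is
log-normal matched to the cohort median 73 kg and IQR 62.9–86.8 kg;
demographic covariates (age, sex, donor type and age, GFR, diabetes) mirror
the cohort table and carry no PK effect in the default truth models.

PK observations are simulated from the published final models (the same
models the recovery experiments refit).  Residual noise is exact for the
tacrolimus log-additive model; for the normal-on-concentration kinds,
non-positive draws are redrawn, preserving the positivity of observed
concentrations at the cost of a small (<1%) truncation bias at the MPA
error magnitude.  Therapeutic drug monitoring is emulated statically, not
as a feedback loop: each subject's doses are scaled by
(target/predicted week-1 trough)^0.5 with the target set to the observed
week-1 trough geometric mean (8.85 ng/mL, tacrolimus only).  This
reproduces the two signatures of a monitored cohort — doses correlated with
clearance and a trough spread much narrower than the raw between-subject
variability would give — while keeping the administered regimen an
exogenous input to the likelihood.  Interoccasion variability can be
switched on for simulation (`iov_sd`), in which case profiles are
integrated numerically occasion by occasion (the closed form assumes
time-constant parameters); the default trial has none.

Biomarkers are log-normal per occasion, matched to the published geometric
means and IQRs.  A fraction `p_elevated = 0.16` of subjects receives an
elevation episode (week 1 with probability 7/8, month 3 with 1/8, matching
the observed timing of rejections) whose miR155-5p and CXCL-10 come from
the elevated (rejection-group) distributions: GM 1.5 and 171.2.  AR is then
a Bernoulli draw per visit from the published logit
(β₀ = −5.89, β₁ = 3.51) evaluated at the *previous* visit's miR155-5p (the
week-1 visit uses its own value), so elevated biomarkers precede rejection.
Background miR155-5p draws are upper-truncated at 1.2: the published IQRs
include rejecting patients, and an untruncated log-normal tail would
contradict the published risk model by implying several times the observed
event rate.  `p_elevated` is calibrated once so the expected number of
subjects with at least one episode matches the observed 8/58.  Visit
records are dropped independently at rate 1 − 183/290, reproducing the 183
analyzable visit rows.

What the generator deliberately does not emulate: the TDM feedback loop
itself (dose changes within an occasion), assay error structure beyond the
residual model, correlated biomarker trajectories within subject
(elevation is a single-visit episode), the 22 excluded patients of the
recruited cohort, and dropout mechanisms other than independent visit
missingness.  Passing recovery tests therefore demonstrate that the
estimation machinery is unbiased at the study design under the published
models — not that those models are correct for real patients.

## Problem sizes and numerical defaults

Recovery experiments simulate full 58-subject trials.  The acceptance
script refits 5 replicate trials per drug; the test suite uses 3 replicates
per drug, 50 bootstrap resamples, and simulation counts of 200–400 for the
VPC/npde calibration checks, with looser optimizer tolerances (1e-5
relative; 1e-4 for bootstrap refits) where only median-level accuracy is
asserted.  Other notable constants: inner EB convergence at step < 1e-7
with per-subject stagnation detection at 1e-9 relative; eta
finite-difference step 1e-4; prediction floor 1e-12; Ka multistart points
{pooled, 1.0}/h.

## Known limitations

* The objective is an approximate marginal likelihood; its approximation
  error varies over the parameter space, so model comparison between very
  different structural regions (e.g. extreme absorption rates) inherits
  that error.  The multistart picks the better approximate objective, which
  on rare data realizations may not be the better exact likelihood.
* Tacrolimus Vp/F is reported but poorly identified from six-month sparse
  sampling (the terminal phase is far longer than the study); its recovery
  is not asserted anywhere.
* The proportional-error EB modes use Fisher-information curvature; the
  reported MOFV is therefore a FOCE-interaction-flavoured Laplace value,
  not the exact-Hessian Laplace value (differences are absorbed in the
  recovery tolerances).
* Estimates are invariant to subject relabelling only up to optimizer
  precision (floating-point summation order changes the finite-difference
  path), asserted at 1% on fixed effects.
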