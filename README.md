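# graftrisk

Early risk assessment of acute rejection (AR) in adult kidney-transplant
recipients, combining population pharmacokinetics of the two maintenance
immunosuppressants with a visit-level exposure–response logistic model.

The package is aimed at pharmacometricians and transplant researchers who
want to (a) fit hierarchical PK models of tacrolimus and mycophenolic acid
(MPA) to event-record datasets, (b) derive individual drug exposures
(cumulative AUC, mean troughs), (c) quantify how urinary biomarkers —
miR155-5p pellet expression and CXCL-10 — and drug exposure relate to the
probability of rejection, and (d) evaluate every model with the field's
standard simulation diagnostics.  A synthetic-trial generator emulating the
original 58-patient study design makes the whole pipeline testable without
access to clinical data.

## Models

**Population PK.**  Two-compartment disposition with first-order absorption
and lag time; apparent parameters CL/F, Vc/F, Q/F, Vp/F, Ka, tlag,
referenced to 70 kg with fixed allometric exponents (0.75 on flows, 1 on
volumes).  Between-subject variability is log-normal,

    P_i = P_pop · (WT_i/70)^k · exp(η_i),   η ~ N(0, Ω),

with additive-on-log (tacrolimus) or proportional (MPA) residual error.
Estimation maximizes a deterministic Laplace/FOCE-type approximation of the
marginal likelihood (see `docs/methods.md`).  Cumulative exposure is the
analytic integral AUC(0→t) = ∫₀ᵗ C dτ of the individual predicted profile.

**Exposure–response.**  One record per subject-visit; a rejection episode is
scored on the visit *preceding* its diagnosis (prognostic orientation):

    logit(P_i) = β₀ + Σ_k β_k · x_ik,    P_i = expit(·),

fitted by Bernoulli maximum likelihood, with forward/backward selection of
the candidate predictors (AUC and mean trough of each drug, miR155-5p,
CXCL-10) at the χ²(1) cut-offs 3.841 (in) / 10.828 (out).

**Evaluation.**  Prediction-corrected VPC for the PK models, categorical VPC
and a 10-bin grouped-bar calibration plot for the logistic model,
normalized prediction distribution errors (npde), and nonparametric
subject-resampling bootstraps.

## Worked example

Simulate a trial at the study design and fit the AR-risk model:

```python
from graftrisk.study_sim import TrialConfig, simulate_trial
from graftrisk.rejection_logit import fit_logistic, risk

trial = simulate_trial(TrialConfig(), seed=7)
print(len(trial.logistic), int(trial.logistic.AR.sum()))  # 196 rows, 6 AR rows

fit = fit_logistic(trial.logistic, ["MIR155"])
print(f"beta0 = {fit.beta0:.2f} (se {fit.se['intercept']:.2f})")
print(f"beta1 = {fit.betas['MIR155']:.2f} (se {fit.se['MIR155']:.2f})")
for x in (0.1, 1.0, 1.5):
    print(f"risk at miR155={x}: {risk(fit, [x]):.3f}")
```

prints

```
beta0 = -4.96 (se 0.79)
beta1 = 3.11 (se 0.92)
risk at miR155=0.1: 0.009
risk at miR155=1.0: 0.136
risk at miR155=1.5: 0.426
```

i.e. this simulated cohort (generated from the model β₀ = −5.89, β₁ = 3.51)
refits to an intercept of −4.96 and a slope of 3.11 from only six rejection
rows, and a subject whose urinary miR155-5p reaches the rejection-group
level of 1.5 carries a ~40% predicted rejection probability against under
1% at baseline expression.

The same pipeline is available from the shell:

```bash
graftrisk simulate --seed 7 --out sim/
graftrisk fit-pk sim/tacrolimus_pk.csv --drug tacrolimus --out fit/
graftrisk exposure sim/tacrolimus_pk.csv --ebes fit/tacrolimus_ebes.csv --out exposures.csv
graftrisk fit-logit sim/logistic.csv --predictors MIR155
graftrisk evaluate sim/tacrolimus_pk.csv --vpc --npde --out eval/
```

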