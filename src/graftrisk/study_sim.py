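"""Synthetic-trial generator emulating the kidney-transplant PK/PD study.

The generator reproduces the study design end to end: 58 de-novo kidney
transplant recipients on twice-daily tacrolimus and mycophenolate mofetil,
five visits (week 1 on a day drawn uniformly from 1-11, then months 1, 2, 3
and 6), rich blood sampling at week 1 (0, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12 h
post-dose) and sparse sampling later (0, 1.5, 2, 4 h), occasion-specific
dose levels (therapeutic drug monitoring is reflected through the published
per-occasion mean doses, not modelled dynamically), urinary biomarkers per
visit, and rare binary acute-rejection outcomes.

PK observations are simulated from the published final population models;
biomarkers are log-normal per occasion; AR events are Bernoulli draws from
the published logistic risk model evaluated at the prognostic (prior-visit)
miR155-5p value, with a latent "elevation" episode planting high biomarker
levels in a fraction of subjects.  All randomness flows from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import SubjectCourse, spawn_rngs
from .nlme_fit import (
    PopPKModel,
    RandomEffectsSpec,
    ResidualSpec,
    compile_design,
    individual_params,
    simulate_observations,
)
from .pk_model import (
    ConcObservation,
    DoseEvent,
    StructuralParams,
    cumulative_auc,
    mean_trough,
    mmf_to_mpa_equivalent,
    predict_concentration,
)
from .rejection_logit import LogisticFit, VISIT_ORDER, build_logistic_dataset, risk

__all__ = [
    "TrialConfig",
    "TrialSubject",
    "TrialData",
    "TAC_TRUTH",
    "MPA_TRUTH",
    "LOGIT_TRUTH",
    "sample_population",
    "simulate_pk",
    "simulate_biomarkers_and_ar",
    "simulate_trial",
    "to_courses",
]

log = logging.getLogger("graftrisk")

# ---------------------------------------------------------------------------
# published final models used as simulation truth
# ---------------------------------------------------------------------------

#: tacrolimus: two-compartment, lag, BSV on CL/Q/Vc, additive-log residual
TAC_TRUTH = PopPKModel(
    typical=StructuralParams(cl=16.5, vc=311.0, q=20.5, vp=56300.0, ka=3.08, tlag=0.295),
    random=RandomEffectsSpec.diagonal(cl=0.576**2, q=0.689**2, vc=0.556**2),
    residual=ResidualSpec("additive_log", sigma=0.366),
    conc_scale=1000.0,  # mg doses, L volumes -> ng/mL whole-blood concentrations
)

#: MPA: two-compartment, lag, Vp fixed at 800 L, BSV on CL/Vc/Vp, proportional residual
MPA_TRUTH = PopPKModel(
    typical=StructuralParams(cl=11.8, vc=106.0, q=37.1, vp=800.0, ka=1.79, tlag=0.243),
    random=RandomEffectsSpec.diagonal(cl=0.349**2, vc=1.338**2, vp=1.646**2),
    residual=ResidualSpec("proportional", sigma=0.553),
    fixed_parameters=("vp",),
)

#: AR risk: logit(P) = beta0 + beta1 * miR155-5p
LOGIT_TRUTH = LogisticFit(beta0=-5.89, betas={"MIR155": 3.51},
                          se={}, mofv=np.nan)


def _ln(gm, q25, q75):
    """(mu, sigma) of a log-normal matched to a geometric mean and IQR."""
    return np.log(gm), np.log(q75 / q25) / 1.349


#: per-occasion log-normal biomarker distributions (geometric mean, IQR)
_MIR155_OCC = {
    "W1": _ln(0.08, 0.03, 0.23),
    "M1": _ln(0.20, 0.05, 0.96),
    "M2": _ln(0.21, 0.06, 0.81),
    "M3": _ln(0.12, 0.04, 0.40),
    "M6": _ln(0.14, 0.04, 0.61),
}
_MIR155_ELEVATED = _ln(1.50, 1.15, 1.85)
_CXCL10_OCC = {
    "W1": _ln(73.81, 37.98, 144.49),
    "M1": _ln(38.04, 18.59, 72.44),
    "M2": _ln(36.65, 15.81, 66.12),
    "M3": _ln(43.90, 23.65, 86.83),
    "M6": _ln(43.66, 20.19, 107.53),
}
_CXCL10_ELEVATED = _ln(171.2, 148.09, 206.64)

#: per-occasion mean daily doses (mg/day): tacrolimus, and MMF (converted to
#: MPA molar equivalents at dose-building time); twice-daily halves
_TAC_DAILY = {"W1": 14.60, "M1": 10.63, "M2": 7.78, "M3": 6.79, "M6": 5.29}
_MMF_DAILY = {"W1": 1875.91, "M1": 1655.41, "M2": 1552.02, "M3": 1402.64, "M6": 1238.67}

#: dose-level switch days: each occasion's level runs until the next boundary,
#: so every visit is sampled on its occasion's level after a run-in
_SEGMENT_START_DAYS = {"W1": 0.0, "M1": 14.0, "M2": 45.0, "M3": 75.0, "M6": 135.0}
_VISIT_DAYS = {"M1": 30.0, "M2": 60.0, "M3": 91.0, "M6": 182.0}
_END_DAY = 183.0

_RICH_TIMES = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)
_SPARSE_TIMES = (0.0, 1.5, 2.0, 4.0)


@dataclass(frozen=True)
class TrialConfig:
    """Design and calibration of one synthetic trial.

    ``p_elevated`` is the fraction of subjects given a high-miR155 episode
    (elevation visit mostly week 1, occasionally month 3), calibrated so the
    expected number of subjects with at least one AR matches the observed
    8/58 incidence.  ``visit_missing_rate`` drops biomarker visit records so
    that on average ~183 of the 290 possible logistic rows survive.
    """

    n_subjects: int = 58
    week1_day_range: tuple[int, int] = (1, 11)
    rich_times: tuple[float, ...] = _RICH_TIMES
    sparse_times: tuple[float, ...] = _SPARSE_TIMES
    tac_daily_dose: dict = field(default_factory=lambda: dict(_TAC_DAILY))
    mmf_daily_dose: dict = field(default_factory=lambda: dict(_MMF_DAILY))
    dose_interval: float = 12.0
    weight_median: float = 73.0
    weight_sigma: float = 0.2388  # log-scale SD matching IQR 62.9-86.8 kg
    p_elevated: float = 0.16
    elevation_visit_probs: dict = field(
        default_factory=lambda: {"W1": 0.875, "M3": 0.125})
    visit_missing_rate: float = 1.0 - 183.0 / 290.0
    tdm_strength: float = 0.5
    tdm_target_trough: float = 8.85  # ng/mL, observed week-1 geometric mean
    mir_background_cap: float = 1.2
    tac_truth: PopPKModel = TAC_TRUTH
    mpa_truth: PopPKModel = MPA_TRUTH
    logit_truth: LogisticFit = field(default_factory=lambda: LOGIT_TRUTH)
    iov_sd: dict | None = None

    def __post_init__(self) -> None:
        for p in (self.p_elevated, self.visit_missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


@dataclass
class TrialSubject:
    """One simulated subject: design, covariates, simulated values, truth."""

    subject_id: str
    weight: float
    covariates: dict
    week1_day: int
    visit_days: dict[str, float]
    sample_times: dict[str, tuple[float, ...]]
    doses: dict[str, list[DoseEvent]] = field(default_factory=dict)
    observations: dict[str, list[ConcObservation]] = field(default_factory=dict)
    biomarkers: dict[str, dict[str, float]] = field(default_factory=dict)
    elevated_visit: str | None = None
    ar_visits: list[str] = field(default_factory=list)
    eta: dict[str, np.ndarray] = field(default_factory=dict)
    visit_retained: dict[str, bool] = field(default_factory=dict)


@dataclass
class TrialData:
    """Simulated trial: per-drug PK datasets, logistic table, and the truth."""

    subjects: list[TrialSubject]
    tac_courses: list[SubjectCourse]
    mpa_courses: list[SubjectCourse]
    logistic: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# population skeletons
# ---------------------------------------------------------------------------

def sample_population(config: TrialConfig, seed_or_rng) -> list[TrialSubject]:
    """Draw subject skeletons: weights, covariates, visit schedule, doses.

    Weights are log-normal (median 73 kg, IQR matched); covariates mirror
    the published demographics table and carry no PK effect in the default
    truth models.  Dose events for both drugs are laid out twice daily at
    the occasion-specific published mean doses.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    subjects = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        weight = float(np.exp(np.log(config.weight_median)
                              + config.weight_sigma * rng.standard_normal()))
        covariates = {
            "AGE": float(np.clip(rng.normal(48.0, 14.8), 18.0, 70.0)),
            "SEX": float(rng.random() < 20.0 / 58.0),          # 1 = female
            "DONOR_LIVING": float(rng.random() < 30.0 / 58.0),
            "DONOR_AGE": float(np.clip(rng.normal(52.0, 11.1), 18.0, 80.0)),
            "GFR": float(np.clip(rng.normal(44.0, 29.7), 5.0, 120.0)),
            "DIABETES": float(rng.random() < 5.0 / 58.0),
        }
        w1 = int(rng.integers(config.week1_day_range[0], config.week1_day_range[1] + 1))
        visit_days = {"W1": float(w1), **_VISIT_DAYS}
        sample_times = {v: (config.rich_times if v == "W1" else config.sparse_times)
                        for v in VISIT_ORDER}
        subj = TrialSubject(sid, weight, covariates, w1, visit_days, sample_times)
        subj.doses = {
            "tacrolimus": _build_doses(sid, config.tac_daily_dose, config.dose_interval),
            "MPA": _build_doses(sid, {k: mmf_to_mpa_equivalent(v)
                                      for k, v in config.mmf_daily_dose.items()},
                                config.dose_interval),
        }
        subjects.append(subj)
    return subjects


def _build_doses(sid, daily_by_occ, tau):
    doses = []
    bounds = sorted(_SEGMENT_START_DAYS.items(), key=lambda kv: kv[1])
    for (occ, start_day), (_, end_day) in zip(
            bounds, bounds[1:] + [("end", _END_DAY)]):
        per_dose = daily_by_occ[occ] / 2.0
        t = start_day * 24.0
        while t < end_day * 24.0 - 1e-9:
            doses.append(DoseEvent(sid, t, per_dose))
            t += tau
    return doses


def _planned_times(subj: TrialSubject) -> dict[str, np.ndarray]:
    out = {}
    for v in VISIT_ORDER:
        t0 = subj.visit_days[v] * 24.0
        out[v] = t0 + np.asarray(subj.sample_times[v], dtype=float)
    return out


# ---------------------------------------------------------------------------
# PK simulation
# ---------------------------------------------------------------------------

def simulate_pk(
    subjects: Sequence[TrialSubject],
    pk_truth: PopPKModel,
    seed_or_rng,
    drug: str = "tacrolimus",
    iov_sd: dict | None = None,
    tdm_strength: float = 0.0,
    tdm_target: float = 8.85,
) -> list[SubjectCourse]:
    """Simulate concentration observations at the planned sampling times.

    Per-subject random effects are drawn from the truth model's omega and
    recorded in ``TrialSubject.eta[drug]``; residual noise follows the truth
    residual model.  ``tdm_strength`` emulates the *outcome* of therapeutic
    drug monitoring without modelling the titration loop: each subject's
    dose amounts are scaled by ``(target / predicted trough)**strength``,
    where the predicted trough is the subject's true-model week-1 pre-dose
    concentration at the nominal regimen and ``tdm_target`` the clinical
    target trough (the observed cohort week-1 geometric mean, 8.85 ng/mL for
    tacrolimus).  Titrated doses thus correlate with individual clearance
    and the trough spread contracts toward the target, as in monitored
    cohorts.  The scaled doses are recorded in ``TrialSubject.doses`` — they
    are the administered regimen.  With ``iov_sd`` set, occasion-level
    exponential effects are added and profiles are integrated numerically
    occasion by occasion (the closed form assumes time-constant parameters).
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    d = pk_truth.n_random
    L = np.linalg.cholesky(pk_truth.random.omega) if d else np.zeros((0, 0))
    etas = rng.standard_normal((len(subjects), d)) @ L.T if d else np.zeros(
        (len(subjects), 0))
    courses = []
    for i, subj in enumerate(subjects):
        if tdm_strength:
            p_i = individual_params(pk_truth, etas[i], subj.weight,
                                    subj.covariates)
            t_w1 = subj.visit_days["W1"] * 24.0
            trough = predict_concentration(
                p_i, subj.doses[drug], [t_w1])[0] * pk_truth.conc_scale
            dose_factor = float((tdm_target / max(trough, 1e-6)) ** tdm_strength)
            subj.doses[drug] = [replace(dd, amount=dd.amount * dose_factor)
                                for dd in subj.doses[drug]]
        times = _planned_times(subj)
        obs = [ConcObservation(subj.subject_id, float(t), 1.0, v)
               for v in VISIT_ORDER for t in times[v]]
        courses.append(SubjectCourse(subj.subject_id, subj.weight,
                                     doses=list(subj.doses[drug]),
                                     observations=obs,
                                     covariates=dict(subj.covariates)))
    design = compile_design(courses)
    if iov_sd:
        y, eta_list = _simulate_iov(courses, pk_truth, iov_sd, rng, design,
                                    etas=etas)
    else:
        from .nlme_fit import PARAM_NAMES, _base_struct, _moments, _predict_eta

        base = _base_struct(pk_truth, design)
        if d:
            label_idx = np.array([PARAM_NAMES.index(l)
                                  for l in pk_truth.random.labels])
            f = _predict_eta(design, base, label_idx, etas, pk_truth.conc_scale)
        else:
            from .nlme_fit import _predict_struct
            f = _predict_struct(design, base, pk_truth.conc_scale)
        kind, sigma, sigma2 = (pk_truth.residual.kind, pk_truth.residual.sigma,
                               pk_truth.residual.sigma2)
        if kind == "additive_log":
            y = np.exp(np.log(np.maximum(f, 1e-12))
                       + sigma * rng.standard_normal(design.n_obs))
        else:
            _, v = _moments(kind, f, sigma, sigma2)
            sd = np.sqrt(v)
            y = f + sd * rng.standard_normal(design.n_obs)
            bad = y <= 0
            for _ in range(100):
                if not bad.any():
                    break
                y[bad] = f[bad] + sd[bad] * rng.standard_normal(bad.sum())
                bad = y <= 0
        eta_list = list(etas)
    # write values back
    k = 0
    for i, (subj, course) in enumerate(zip(subjects, courses)):
        new_obs = []
        for o in course.observations:
            new_obs.append(replace(o, value=float(y[k])))
            k += 1
        course.observations = new_obs
        subj.observations[drug] = new_obs
        subj.eta[drug] = np.asarray(eta_list[i])
    return courses


def _simulate_iov(courses, model, iov_sd, rng, design, etas=None):
    """Occasion-varying parameters: numerical integration per subject."""
    from scipy.integrate import solve_ivp

    d = model.n_random
    L = np.linalg.cholesky(model.random.omega) if d else np.zeros((0, 0))
    if etas is None:
        etas = [(L @ rng.standard_normal(d)) if d else np.zeros(0)
                for _ in courses]
    etas = [np.asarray(e) for e in etas]
    ys = []
    bounds_h = sorted(v * 24.0 for v in _SEGMENT_START_DAYS.values()) + [_END_DAY * 24.0]
    for course, eta in zip(courses, etas):
        tq = np.array([o.time for o in course.observations])
        f = np.zeros_like(tq)
        occ_eta = {name: rng.normal(0.0, sd, size=len(bounds_h) - 1)
                   for name, sd in iov_sd.items()}
        y0 = np.zeros(3)
        t_cursor = 0.0
        dose_iter = sorted(course.doses, key=lambda dd: dd.time)
        for seg_idx, (t0, t1) in enumerate(zip(bounds_h, bounds_h[1:])):
            p = individual_params(model, eta, course.weight, course.covariates)
            pv = {n: getattr(p, n) for n in ("cl", "vc", "q", "vp", "ka", "tlag")}
            for name, draws in occ_eta.items():
                pv[name] = pv[name] * np.exp(draws[seg_idx])
            k10, k12, k21 = pv["cl"] / pv["vc"], pv["q"] / pv["vc"], pv["q"] / pv["vp"]
            ka = pv["ka"]

            def rhs(t, yv):
                a, c, per = yv
                return [-ka * a, ka * a - (k10 + k12) * c + k21 * per,
                        k12 * c - k21 * per]

            events = sorted({round(dd.time + pv["tlag"], 9) for dd in dose_iter
                             if t0 <= dd.time + pv["tlag"] < t1}
                            | {float(t) for t in tq if t0 < t <= t1} | {t0, t1})
            amounts = {}
            for dd in dose_iter:
                ta = round(dd.time + pv["tlag"], 9)
                if t0 <= ta < t1:
                    amounts[ta] = amounts.get(ta, 0.0) + dd.amount
            y = y0
            for ta, tb in zip(events, events[1:]):
                if ta in amounts:
                    y = y + np.array([amounts[ta], 0.0, 0.0])
                sol = solve_ivp(rhs, (ta, tb), y, rtol=1e-8, atol=1e-10,
                                method="LSODA")
                y = sol.y[:, -1]
                sel = np.isclose(tq, tb) & (tq > t0) & (tq <= t1)
                f[sel] = y[1] / pv["vc"]
            if events and events[-1] in amounts:
                y = y + np.array([amounts[events[-1]], 0.0, 0.0])
            y0 = y
        ys.append(f)
    f_all = np.concatenate(ys) * model.conc_scale
    kind, sigma = model.residual.kind, model.residual.sigma
    if kind == "additive_log":
        y_all = np.exp(np.log(np.maximum(f_all, 1e-12))
                       + sigma * rng.standard_normal(f_all.size))
    else:
        sd = np.maximum(sigma * f_all, 1e-12)
        y_all = np.abs(f_all + sd * rng.standard_normal(f_all.size))
        y_all = np.maximum(y_all, 1e-12)
    return y_all, etas


# ---------------------------------------------------------------------------
# biomarkers and AR events
# ---------------------------------------------------------------------------

def simulate_biomarkers_and_ar(
    subjects: Sequence[TrialSubject],
    logit_truth: LogisticFit,
    config: TrialConfig,
    seed_or_rng,
) -> pd.DataFrame:
    """Draw per-visit biomarkers and Bernoulli AR events.

    A fraction ``p_elevated`` of subjects receives an elevation episode: the
    episode visit's miR155-5p and CXCL-10 are drawn from the elevated (AR
    group) distributions.  Every visit's AR indicator is then a Bernoulli
    draw from the logistic truth evaluated at the *previous* visit's
    miR155-5p (the week-1 visit, having no predecessor, uses its own value),
    so elevated biomarkers precede rejection, mirroring the prognostic
    design.  Returns the long-format biomarker table (retained visits only).
    """
    if "MIR155" not in logit_truth.betas:
        raise ValueError("logistic truth must carry a miR155 coefficient")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    ev_visits = list(config.elevation_visit_probs)
    ev_probs = np.array([config.elevation_visit_probs[v] for v in ev_visits])
    ev_probs = ev_probs / ev_probs.sum()
    cap = config.mir_background_cap
    rows = []
    for subj in subjects:
        subj.biomarkers = {}
        for v in VISIT_ORDER:
            mu, sd = _MIR155_OCC[v]
            mu_c, sd_c = _CXCL10_OCC[v]
            # background (no rejection pending) miR155 draws are upper-
            # truncated: the tabulated IQRs include rejecting patients, and
            # an untruncated log-normal tail would contradict the published
            # risk model (it would imply far more than 8/58 events)
            x = np.exp(mu + sd * rng.standard_normal())
            for _ in range(100):
                if x <= cap:
                    break
                x = np.exp(mu + sd * rng.standard_normal())
            subj.biomarkers[v] = {
                "MIR155": float(min(x, cap)),
                "CXCL10": float(np.exp(mu_c + sd_c * rng.standard_normal())),
            }
        subj.elevated_visit = None
        if rng.random() < config.p_elevated:
            ev = ev_visits[rng.choice(len(ev_visits), p=ev_probs)]
            mu, sd = _MIR155_ELEVATED
            mu_c, sd_c = _CXCL10_ELEVATED
            subj.biomarkers[ev] = {
                "MIR155": float(np.exp(mu + sd * rng.standard_normal())),
                "CXCL10": float(np.exp(mu_c + sd_c * rng.standard_normal())),
            }
            subj.elevated_visit = ev
        subj.ar_visits = []
        for k, v in enumerate(VISIT_ORDER):
            prior = VISIT_ORDER[k - 1] if k else v
            x = subj.biomarkers[prior]["MIR155"]
            if rng.random() < risk(logit_truth, {"MIR155": x}):
                subj.ar_visits.append(v)
        subj.visit_retained = {
            v: bool(rng.random() >= config.visit_missing_rate) for v in VISIT_ORDER}
        for v in VISIT_ORDER:
            if subj.visit_retained[v]:
                rows.append({"ID": subj.subject_id, "VISIT": v,
                             **subj.biomarkers[v]})
    return pd.DataFrame(rows, columns=["ID", "VISIT", "MIR155", "CXCL10"])


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------

def simulate_trial(config: TrialConfig = TrialConfig(), seed: int = 0) -> TrialData:
    """Simulate one full trial: PK datasets, logistic table, truth record.

    The logistic table's exposure predictors (cumulative AUC to the visit,
    running mean trough) are computed from the *true* individual parameters
    — the bookkeeping a recovery experiment needs; the analysis pipeline
    recomputes them from empirical Bayes estimates after fitting.
    """
    rng_pop, rng_tac, rng_mpa, rng_bio = spawn_rngs(seed, 4)
    subjects = sample_population(config, rng_pop)
    tac_courses = simulate_pk(subjects, config.tac_truth, rng_tac,
                              drug="tacrolimus", iov_sd=config.iov_sd,
                              tdm_strength=config.tdm_strength,
                              tdm_target=config.tdm_target_trough)
    mpa_courses = simulate_pk(subjects, config.mpa_truth, rng_mpa,
                              drug="MPA", iov_sd=config.iov_sd)
    biomarkers = simulate_biomarkers_and_ar(subjects, config.logit_truth,
                                            config, rng_bio)
    exposures = true_exposures(subjects, config)
    ar_events = [(s.subject_id, v) for s in subjects for v in s.ar_visits]
    logistic = build_logistic_dataset(exposures, biomarkers, ar_events)
    truth = {
        "tac_model": config.tac_truth,
        "mpa_model": config.mpa_truth,
        "logit": config.logit_truth,
        "eta_tac": {s.subject_id: s.eta["tacrolimus"] for s in subjects},
        "eta_mpa": {s.subject_id: s.eta["MPA"] for s in subjects},
        "elevated": {s.subject_id: s.elevated_visit for s in subjects},
        "ar_events": ar_events,
        "n_ar_subjects": len({sid for sid, _ in ar_events}),
    }
    return TrialData(list(subjects), tac_courses, mpa_courses, logistic, truth)


def true_exposures(subjects: Sequence[TrialSubject], config: TrialConfig) -> pd.DataFrame:
    """Per subject-visit cumulative AUC and running mean trough, truth-based."""
    rows = []
    for subj in subjects:
        p_tac = individual_params(config.tac_truth, subj.eta["tacrolimus"],
                                  subj.weight, subj.covariates)
        p_mpa = individual_params(config.mpa_truth, subj.eta["MPA"],
                                  subj.weight, subj.covariates)
        visit_t = np.array([subj.visit_days[v] * 24.0 for v in VISIT_ORDER])
        auc_tac = cumulative_auc(p_tac, subj.doses["tacrolimus"], visit_t)
        auc_mpa = cumulative_auc(p_mpa, subj.doses["MPA"], visit_t)
        tr_tac = predict_concentration(p_tac, subj.doses["tacrolimus"], visit_t)
        tr_mpa = predict_concentration(p_mpa, subj.doses["MPA"], visit_t)
        for k, v in enumerate(VISIT_ORDER):
            rows.append({
                "ID": subj.subject_id, "VISIT": v,
                "AUC_TAC": auc_tac[k],
                "AUC_MPA": auc_mpa[k],
                "TROUGH_TAC": float(np.mean(tr_tac[:k + 1])),
                "TROUGH_MPA": float(np.mean(tr_mpa[:k + 1])),
            })
    return pd.DataFrame(rows)


def to_courses(subjects: Sequence[TrialSubject], drug: str) -> list[SubjectCourse]:
    """Flatten trial subjects to per-drug fitting containers."""
    return [SubjectCourse(s.subject_id, s.weight, doses=list(s.doses[drug]),
                          observations=list(s.observations.get(drug, [])),
                          covariates=dict(s.covariates))
            for s in subjects]
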