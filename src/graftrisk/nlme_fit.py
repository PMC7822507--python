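"""Nonlinear mixed-effects estimation of the population PK models.

Between-subject variability enters through exponential (log-normal) random
effects on structural parameters; the marginal likelihood is approximated
per subject by Laplace's method around the empirical Bayes mode, with the
curvature taken from the Gauss-Newton (FOCE-type) Hessian of the conditional
objective.  The approximation is deterministic, additive over subjects, and
exact for models whose prediction is linear in the random effects.

The inner (empirical-Bayes) problem is solved for all subjects at once:
predictions for the whole population are a single vectorized pass through
the closed-form PK solution, Jacobians with respect to the random effects
come from central differences of that pass, and the per-subject Newton
systems (Levenberg-Marquardt damped, Fisher-information curvature for the
proportional-error kinds) are solved as a batched stack of small linear
systems; converged subjects are frozen so late iterations only touch the
remaining subjects' observation pairs.

Residual-error models: ``additive_log`` (additive on log-transformed
concentrations; reported as a percentage, it plays the role of a
proportional error), ``proportional``, ``additive`` and ``combined``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import SubjectCourse
from .pk_model import (
    PARAM_NAMES,
    AllometricRule,
    StructuralParams,
    _run_exp_sums,
    group_dose_runs,
    macro_constants,
)

__all__ = [
    "RandomEffectsSpec",
    "ResidualSpec",
    "CovariateEffect",
    "PopPKModel",
    "PopFitResult",
    "CompiledDesign",
    "compile_design",
    "individual_params",
    "neg2ll",
    "fit_pop",
    "ebe",
    "shrinkage",
    "lrt_threshold",
    "stepwise_covariates",
    "condition_number",
    "residual_diagnostics",
    "simulate_observations",
    "pooled_init",
    "fit_pop_multistart",
    "ebe_correlation_screen",
]

log = logging.getLogger("graftrisk")

_FLOW_PARAMS = ("cl", "q")
_VOLUME_PARAMS = ("vc", "vp")
_F_FLOOR = 1e-12  # floor for predictions entering logs / proportional variances


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomEffectsSpec:
    """Log-scale random-effect specification.

    ``labels`` are the structural parameters carrying between-subject
    variability; ``omega`` is their log-scale covariance matrix.  ``iov_sd``
    optionally gives occasion-level (interoccasion) log-scale SDs used by the
    trial simulator only — IOV is never estimated here.
    """

    labels: tuple[str, ...]
    omega: np.ndarray
    structure: str = "diagonal"  # {"diagonal", "block"}
    iov_sd: dict[str, float] | None = None

    def __post_init__(self) -> None:
        om = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if om.shape != (len(self.labels), len(self.labels)):
            raise ValueError("omega dimension must match number of labels")
        if len(self.labels) and np.min(np.linalg.eigvalsh(om)) < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        object.__setattr__(self, "omega", om)
        if self.structure not in ("diagonal", "block"):
            raise ValueError("structure must be 'diagonal' or 'block'")
        unknown = set(self.labels) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown random-effect labels {unknown}")

    @staticmethod
    def diagonal(**variances: float) -> "RandomEffectsSpec":
        labels = tuple(variances)
        return RandomEffectsSpec(labels, np.diag([variances[k] for k in labels]))


@dataclass(frozen=True)
class ResidualSpec:
    """Residual-error model.

    ``sigma`` is the log-scale SD for ``additive_log``, the fractional CV for
    ``proportional``, or a concentration-unit SD for ``additive``; for
    ``combined`` (proportional + additive) ``sigma2`` is the additive part.
    """

    kind: str
    sigma: float
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("additive_log", "proportional", "additive", "combined"):
            raise ValueError(f"unknown residual kind {self.kind!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.sigma2 < 0 or (self.sigma2 > 0 and self.kind != "combined"):
            raise ValueError("sigma2 only valid (and >=0) for the combined model")


@dataclass(frozen=True)
class CovariateEffect:
    """Multiplicative covariate factor on a structural parameter.

    linear:       1 + theta * (c - reference)
    power:        (c / reference) ** theta
    exponential:  exp(theta * (c - reference))
    """

    parameter: str
    covariate: str
    form: str
    theta: float = 0.0
    reference: float = 1.0

    def factor(self, c: np.ndarray) -> np.ndarray:
        if self.form == "linear":
            return 1.0 + self.theta * (c - self.reference)
        if self.form == "power":
            return (c / self.reference) ** self.theta
        if self.form == "exponential":
            return np.exp(self.theta * (c - self.reference))
        raise ValueError(f"unknown covariate form {self.form!r}")


@dataclass(frozen=True)
class PopPKModel:
    """Population PK model: typical values, allometry, BSV, residual error.

    ``conc_scale`` converts model predictions (dose-mass per litre) to the
    observation unit — 1000 for tacrolimus (mg doses, ng/mL whole-blood
    concentrations), 1 for MPA (mg doses, ug/mL plasma concentrations).
    """

    typical: StructuralParams
    random: RandomEffectsSpec
    residual: ResidualSpec
    allometry: AllometricRule = AllometricRule()
    fixed_parameters: tuple[str, ...] = ()
    covariate_effects: tuple[CovariateEffect, ...] = ()
    conc_scale: float = 1.0

    def __post_init__(self) -> None:
        bad = set(self.fixed_parameters) - set(PARAM_NAMES)
        if bad:
            raise ValueError(f"unknown fixed parameters {bad}")

    @property
    def n_random(self) -> int:
        return len(self.random.labels)


@dataclass
class PopFitResult:
    """Result of a population fit.

    ``mofv`` is -2 x the approximate log marginal likelihood (the objective
    function value); ``rse`` holds percentage relative standard errors per
    estimated parameter; ``ebes`` are per-subject log-scale random-effect
    modes ordered as ``model.random.labels``.
    """

    model: PopPKModel
    mofv: float
    ebes: np.ndarray
    eta_shrinkage: dict[str, float]
    eps_shrinkage: float
    converged: bool
    n_iter: int
    param_names: list[str]
    estimates: np.ndarray
    rse: dict[str, float] | None = None
    covariance: np.ndarray | None = None
    condition_number: float = np.nan
    design: "CompiledDesign | None" = None

    def to_table(self) -> pd.DataFrame:
        """Parameter report (estimate, RSE%, shrinkage%), Table-style layout."""
        rows = []
        m = self.model
        for name in PARAM_NAMES:
            est = getattr(m.typical, name)
            fixed = name in m.fixed_parameters
            rows.append({
                "parameter": name.upper(),
                "estimate": est,
                "rse_pct": np.nan if fixed or not self.rse else self.rse.get(name, np.nan),
                "shrinkage_pct": np.nan,
                "fixed": fixed,
            })
        for k, lab in enumerate(m.random.labels):
            bsv = 100.0 * np.sqrt(m.random.omega[k, k])
            rows.append({
                "parameter": f"BSV_{lab.upper()}",
                "estimate": bsv,
                "rse_pct": self.rse.get(f"omega_{lab}", np.nan) if self.rse else np.nan,
                "shrinkage_pct": self.eta_shrinkage.get(lab, np.nan),
                "fixed": False,
            })
        rows.append({
            "parameter": "RESIDUAL",
            "estimate": 100.0 * m.residual.sigma
            if m.residual.kind in ("additive_log", "proportional")
            else m.residual.sigma,
            "rse_pct": self.rse.get("sigma", np.nan) if self.rse else np.nan,
            "shrinkage_pct": self.eps_shrinkage,
            "fixed": False,
        })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledDesign:
    """Flat-array view of a subject-course list for vectorized evaluation."""

    subject_ids: list[str]
    weights: np.ndarray          # (n_sub,)
    covariates: dict[str, np.ndarray]
    obs_time: np.ndarray         # (n_obs,)
    obs_y: np.ndarray
    obs_subject: np.ndarray      # (n_obs,) int
    obs_tad: np.ndarray          # time after most recent prior dose
    obs_occasion: np.ndarray     # (n_obs,) object
    run_start: np.ndarray        # (n_runs,)
    run_tau: np.ndarray
    run_n: np.ndarray
    run_amt: np.ndarray
    run_subject: np.ndarray
    pair_obs: np.ndarray         # (n_pairs,) int indices into obs
    pair_run: np.ndarray
    pair_subject: np.ndarray
    pair_t: np.ndarray
    pair_start: np.ndarray
    pair_tau: np.ndarray
    pair_n: np.ndarray
    pair_amt: np.ndarray

    @property
    def n_sub(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_time)


def compile_design(courses: Sequence[SubjectCourse]) -> CompiledDesign:
    """Flatten subject courses into pair-indexed arrays (obs x dose-run)."""
    ids, weights = [], []
    cov_keys = sorted({k for c in courses for k in c.covariates
                       if isinstance(c.covariates[k], (int, float, np.floating))})
    covs: dict[str, list] = {k: [] for k in cov_keys}
    obs_t, obs_y, obs_s, obs_tad, obs_occ = [], [], [], [], []
    r_start, r_tau, r_n, r_amt, r_sub = [], [], [], [], []
    for i, c in enumerate(courses):
        ids.append(c.subject_id)
        weights.append(c.weight)
        for k in cov_keys:
            covs[k].append(float(c.covariates.get(k, np.nan)))
        dose_times = np.array(sorted(d.time for d in c.doses)) if c.doses else np.array([])
        for o in c.observations:
            obs_t.append(o.time)
            obs_y.append(o.value)
            obs_s.append(i)
            obs_occ.append(o.occasion)
            prior = dose_times[dose_times < o.time]
            obs_tad.append(o.time - prior[-1] if len(prior) else np.nan)
        for r in group_dose_runs(c.doses):
            r_start.append(r.start)
            r_tau.append(r.tau)
            r_n.append(r.n)
            r_amt.append(r.amount)
            r_sub.append(i)
    obs_s = np.asarray(obs_s, dtype=np.intp)
    r_sub = np.asarray(r_sub, dtype=np.intp)
    # same-subject (obs, run) pairs
    by_sub_runs: dict[int, list[int]] = {}
    for j, s in enumerate(r_sub):
        by_sub_runs.setdefault(int(s), []).append(j)
    pair_obs, pair_run = [], []
    for k, s in enumerate(obs_s):
        for j in by_sub_runs.get(int(s), []):
            pair_obs.append(k)
            pair_run.append(j)
    pair_obs = np.asarray(pair_obs, dtype=np.intp)
    pair_run = np.asarray(pair_run, dtype=np.intp)
    obs_t = np.asarray(obs_t, dtype=float)
    r_start = np.asarray(r_start, dtype=float)
    r_tau = np.asarray(r_tau, dtype=float)
    r_n = np.asarray(r_n, dtype=float)
    r_amt = np.asarray(r_amt, dtype=float)
    return CompiledDesign(
        subject_ids=ids,
        weights=np.asarray(weights, dtype=float),
        covariates={k: np.asarray(v, dtype=float) for k, v in covs.items()},
        obs_time=obs_t,
        obs_y=np.asarray(obs_y, dtype=float),
        obs_subject=obs_s,
        obs_tad=np.asarray(obs_tad, dtype=float),
        obs_occasion=np.asarray(obs_occ, dtype=object),
        run_start=r_start, run_tau=r_tau, run_n=r_n, run_amt=r_amt,
        run_subject=r_sub,
        pair_obs=pair_obs, pair_run=pair_run,
        pair_subject=obs_s[pair_obs] if len(pair_obs) else np.array([], dtype=np.intp),
        pair_t=obs_t[pair_obs] if len(pair_obs) else np.array([]),
        pair_start=r_start[pair_run] if len(pair_run) else np.array([]),
        pair_tau=r_tau[pair_run] if len(pair_run) else np.array([]),
        pair_n=r_n[pair_run] if len(pair_run) else np.array([]),
        pair_amt=r_amt[pair_run] if len(pair_run) else np.array([]),
    )


# ---------------------------------------------------------------------------
# individual parameters and population prediction
# ---------------------------------------------------------------------------

def _base_struct(model: PopPKModel, design: CompiledDesign) -> np.ndarray:
    """(n_sub, 6) individual structural parameters before random effects."""
    n = design.n_sub
    mat = np.tile(model.typical.as_array(), (n, 1))
    fw = (design.weights / model.allometry.reference_weight) ** model.allometry.exponent_flow
    fv = (design.weights / model.allometry.reference_weight) ** model.allometry.exponent_volume
    for j, name in enumerate(PARAM_NAMES):
        if name in _FLOW_PARAMS:
            mat[:, j] *= fw
        elif name in _VOLUME_PARAMS:
            mat[:, j] *= fv
    for eff in model.covariate_effects:
        if eff.covariate not in design.covariates:
            raise ValueError(f"covariate {eff.covariate!r} not present in data")
        j = PARAM_NAMES.index(eff.parameter)
        mat[:, j] *= eff.factor(design.covariates[eff.covariate])
    return mat


def individual_params(
    model: PopPKModel,
    eta: Sequence[float] | np.ndarray,
    weight: float,
    covariates: dict[str, float] | None = None,
) -> StructuralParams:
    """Individual parameters: typical x allometry x covariates x exp(eta)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (model.n_random,):
        raise ValueError("eta length must match the number of random effects")
    vals = dict(zip(PARAM_NAMES, model.typical.as_array()))
    fw = (weight / model.allometry.reference_weight) ** model.allometry.exponent_flow
    fv = (weight / model.allometry.reference_weight) ** model.allometry.exponent_volume
    for name in _FLOW_PARAMS:
        vals[name] *= fw
    for name in _VOLUME_PARAMS:
        vals[name] *= fv
    for eff in model.covariate_effects:
        c = (covariates or {}).get(eff.covariate)
        if c is None:
            raise ValueError(f"covariate {eff.covariate!r} value required")
        vals[eff.parameter] *= float(eff.factor(np.asarray(c, dtype=float)))
    for k, lab in enumerate(model.random.labels):
        vals[lab] *= np.exp(eta[k])
    return StructuralParams(**vals)


try:  # optional fast path; the numpy implementation is the reference
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True, error_model="numpy")
    def _pair_kernel(pair_obs, pair_sub, pair_t, pair_start, pair_tau, pair_n,
                     pair_amt, lams, coefs, tlag, out):  # pragma: no cover
        for p in range(pair_obs.shape[0]):
            s = pair_sub[p]
            rel = pair_t[p] - tlag[s] - pair_start[p]
            if rel < 0.0:
                continue
            tau = pair_tau[p]
            nmax = pair_n[p]
            if tau > 0.0:
                m = np.floor(rel / tau) + 1.0
                if m > nmax:
                    m = nmax
            else:
                m = 1.0
            dmin = rel - (m - 1.0) * tau
            acc = 0.0
            for k in range(3):
                lam = lams[k, s]
                x = lam * tau
                if tau > 0.0 and x > 1e-12:
                    geo = (1.0 - np.exp(-x * m)) / (1.0 - np.exp(-x))
                else:
                    geo = m
                acc += coefs[k, s] * np.exp(-lam * dmin) * geo
            out[pair_obs[p]] += pair_amt[p] * acc

    @_numba.njit(cache=True, fastmath=True, error_model="numpy")
    def _pair_kernel_full(pair_obs, pair_sub, pair_t, pair_start, pair_tau,
                          pair_n, pair_amt, cl, vc, q, vp, ka, tlag,
                          out):  # pragma: no cover
        n_sub = cl.shape[0]
        lams = np.empty((3, n_sub))
        coefs = np.empty((3, n_sub))
        for s in range(n_sub):
            k10 = cl[s] / vc[s]
            k12 = q[s] / vc[s]
            k21 = q[s] / vp[s]
            ssum = k10 + k12 + k21
            disc = np.sqrt(max(ssum * ssum - 4.0 * k10 * k21, 0.0))
            alpha = 0.5 * (ssum + disc)
            beta = (k10 * k21) / alpha
            kas = ka[s]
            if min(abs(kas - alpha), abs(kas - beta)) < 1e-8 * kas:
                kas = kas * (1.0 + 1e-7)
            pref = kas / vc[s]
            lams[0, s] = alpha
            lams[1, s] = beta
            lams[2, s] = kas
            coefs[0, s] = pref * (k21 - alpha) / ((kas - alpha) * (beta - alpha))
            coefs[1, s] = pref * (k21 - beta) / ((kas - beta) * (alpha - beta))
            coefs[2, s] = pref * (k21 - kas) / ((alpha - kas) * (beta - kas))
        _pair_kernel(pair_obs, pair_sub, pair_t, pair_start, pair_tau, pair_n,
                     pair_amt, lams, coefs, tlag, out)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _predict_struct(design: CompiledDesign, struct: np.ndarray,
                    scale: float = 1.0) -> np.ndarray:
    """Population predictions at all observations for per-subject params."""
    if design.n_obs == 0:
        return np.zeros(0)
    cl, vc, q, vp, ka, tlag = (struct[:, j] for j in range(6))
    lams, coefs = macro_constants(cl, vc, q, vp, ka)     # (3, n_sub)
    if _HAVE_NUMBA:
        out = np.zeros(design.n_obs)
        _pair_kernel(design.pair_obs, design.pair_subject, design.pair_t,
                     design.pair_start, design.pair_tau, design.pair_n,
                     design.pair_amt, np.ascontiguousarray(lams),
                     np.ascontiguousarray(coefs), np.ascontiguousarray(tlag), out)
        return out * scale
    ps = design.pair_subject
    s, _ = _run_exp_sums(
        design.pair_t, design.pair_start, design.pair_tau, design.pair_n,
        tlag[ps], lams[:, ps],
    )
    contrib = design.pair_amt * np.einsum("ij,ij->j", coefs[:, ps], s)
    return np.bincount(design.pair_obs, weights=contrib,
                       minlength=design.n_obs) * scale


def _predict_eta(design, base_struct, label_idx, eta, scale: float = 1.0):
    """Predictions with random effects applied to the labelled columns."""
    struct = base_struct.copy()
    if eta is not None and eta.size:
        struct[:, label_idx] *= np.exp(eta)
    return _predict_struct(design, struct, scale)

# ---------------------------------------------------------------------------
# residual-error algebra
# ---------------------------------------------------------------------------

def _obs_transform(kind: str, y: np.ndarray) -> np.ndarray:
    return np.log(y) if kind == "additive_log" else y


def _moments(kind, f, sigma, sigma2):
    """Mean of the transformed observation and residual variance given f."""
    f = np.maximum(f, _F_FLOOR)
    if kind == "additive_log":
        return np.log(f), np.full_like(f, sigma**2)
    if kind == "proportional":
        return f, (sigma * f) ** 2
    if kind == "additive":
        return f, np.full_like(f, sigma**2)
    return f, (sigma * f) ** 2 + sigma2**2  # combined


def _mean_jacobian_scale(kind, f):
    """d(mean_z)/df: chain-rule factor applied to prediction Jacobians."""
    return 1.0 / np.maximum(f, _F_FLOOR) if kind == "additive_log" else np.ones_like(f)


# ---------------------------------------------------------------------------
# inner (empirical Bayes) problem, vectorized across subjects
# ---------------------------------------------------------------------------

_ETA_FD_STEP = 1e-4


def _inner_foce(design, base_struct, label_idx, omega, z, kind, sigma, sigma2,
                eta0=None, max_iter=40, tol=1e-6, scale=1.0):
    """Batched Gauss-Newton for all subjects' empirical Bayes modes.

    Returns ``(eta_hat, H, obj_obs_sums, mofv_vec)`` where ``H`` is the
    (n_sub, d, d) Gauss-Newton curvature at the mode and ``mofv_vec`` the
    per-subject -2 log marginal likelihood contributions.
    """
    n_sub, d = design.n_sub, len(label_idx)
    omega = np.atleast_2d(omega)
    omega_inv = np.linalg.inv(omega)
    _, omega_logdet = np.linalg.slogdet(omega)
    sub = design.obs_subject

    def per_subject_g(f, eta):
        mz, v = _moments(kind, f, sigma, sigma2)
        r = z - mz
        t = r * r / v + np.log(2.0 * np.pi * v)
        sums = np.bincount(sub, weights=t, minlength=n_sub)
        prior = np.einsum("ij,jk,ik->i", eta, omega_inv, eta)
        return 0.5 * (sums + prior), v, r, sums

    def subset_of(mask):
        pm = mask[design.pair_subject]
        return (design.pair_obs[pm], design.pair_subject[pm], design.pair_t[pm],
                design.pair_start[pm], design.pair_tau[pm], design.pair_n[pm],
                design.pair_amt[pm], mask[design.obs_subject])

    def predict_into(subset, eta_m, f_base):
        """Predictions of the subset's observations folded into f_base."""
        struct = base_struct.copy()
        if eta_m.size:
            struct[:, label_idx] *= np.exp(eta_m)
        out = np.zeros(design.n_obs)
        if _HAVE_NUMBA:
            _pair_kernel_full(
                subset[0], subset[1], subset[2], subset[3], subset[4],
                subset[5], subset[6],
                np.ascontiguousarray(struct[:, 0]), np.ascontiguousarray(struct[:, 1]),
                np.ascontiguousarray(struct[:, 2]), np.ascontiguousarray(struct[:, 3]),
                np.ascontiguousarray(struct[:, 4]), np.ascontiguousarray(struct[:, 5]),
                out)
        else:
            lams, coefs = macro_constants(struct[:, 0], struct[:, 1],
                                          struct[:, 2], struct[:, 3], struct[:, 4])
            ps = subset[1]
            s_, _ = _run_exp_sums(subset[2], subset[3], subset[4], subset[5],
                                  struct[:, 5][ps], lams[:, ps])
            contrib = subset[6] * np.einsum("ij,ij->j", coefs[:, ps], s_)
            out = np.bincount(subset[0], weights=contrib, minlength=design.n_obs)
        f_out = f_base.copy()
        obs_mask = subset[7]
        f_out[obs_mask] = out[obs_mask] * scale
        return f_out

    eta = np.zeros((n_sub, d)) if eta0 is None else np.array(eta0, dtype=float)
    if not np.all(np.isfinite(eta)):
        eta = np.zeros((n_sub, d))
    f = _predict_eta(design, base_struct, label_idx, eta, scale)
    g_cur, v, r, _ = per_subject_g(f, eta)
    if not np.all(np.isfinite(g_cur)):
        eta = np.zeros((n_sub, d))
        f = _predict_eta(design, base_struct, label_idx, eta, scale)
        g_cur, v, r, _ = per_subject_g(f, eta)
    H = np.tile(omega_inv, (n_sub, 1, 1))
    lam = np.full(n_sub, 1e-3)
    eye = np.eye(d)[None, :, :]
    diag_idx = np.arange(d)
    # subjects' conditional problems are independent: once a subject's step
    # falls below tol it is frozen and excluded from further prediction work
    active = np.ones(n_sub, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        jac_scale = _mean_jacobian_scale(kind, f)
        subset_active = subset_of(active)
        J = np.zeros((design.n_obs, d))
        for k in range(d):
            step = np.zeros((n_sub, d))
            step[:, k] = _ETA_FD_STEP
            f_p = predict_into(subset_active, eta + step, f)
            f_m = predict_into(subset_active, eta - step, f)
            J[:, k] = jac_scale * (f_p - f_m) / (2.0 * _ETA_FD_STEP)
        w = 1.0 / v
        # curvature uses the expected (Fisher) information of the residual
        # model: the variance-mean coupling of proportional error adds
        # 2 sigma^4 f^2 / v^2, without which convergence degrades to a slow
        # linear rate
        if kind in ("proportional", "combined"):
            w_curv = w + 2.0 * sigma**4 * f * f / (v * v)
        else:
            w_curv = w
        A = np.empty((n_sub, d, d))
        b = np.empty((n_sub, d))
        for k in range(d):
            b[:, k] = np.bincount(sub, weights=J[:, k] * w * r, minlength=n_sub)
            for l in range(k, d):
                akl = np.bincount(sub, weights=J[:, k] * J[:, l] * w_curv,
                                  minlength=n_sub)
                A[:, k, l] = akl
                A[:, l, k] = akl
        H_new = A + omega_inv[None, :, :]
        H[active] = H_new[active]
        grad = -b + eta @ omega_inv
        if kind in ("proportional", "combined"):
            # interaction terms: the residual variance v = sigma^2 f^2 (+ add)
            # depends on eta, contributing d(0.5 log v)/deta and the
            # derivative of 1/v inside the weighted residual; together
            # 0.5 * dv/deta * (v - r^2) / v^2 with dv/deta = 2 sigma^2 f J
            fsafe = np.maximum(f, _F_FLOOR)
            inter = (sigma**2 * fsafe * (v - r * r) / (v * v))[:, None] * J
            for k in range(d):
                grad[:, k] += np.bincount(sub, weights=inter[:, k],
                                          minlength=n_sub)
        # per-subject Levenberg-Marquardt step: damping interpolates between
        # the (Gauss-)Newton direction and gradient descent, which keeps the
        # iteration robust where the curvature model is poor (strong
        # residual-variance interaction, large random-effect variances)
        accepted = np.zeros(n_sub, dtype=bool)
        eta_new = eta.copy()
        f_new = f.copy()
        g_acc = g_cur.copy()
        lam_try = lam.copy()
        for _attempt in range(8):
            todo = active & ~accepted
            if not todo.any():
                break
            Hd = H + lam_try[:, None, None] * (
                np.abs(H[:, diag_idx, diag_idx])[:, :, None] * eye + 1e-8 * eye)
            try:
                delta = np.linalg.solve(Hd, -grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                delta = np.stack([np.linalg.lstsq(Hd[i], -grad[i], rcond=None)[0]
                                  for i in range(n_sub)])
            trial_eta = eta_new.copy()
            trial_eta[todo] = eta[todo] + delta[todo]
            f_try = predict_into(subset_of(todo), trial_eta, f_new)
            g_try, _, _, _ = per_subject_g(f_try, trial_eta)
            better = todo & (g_try <= g_cur + 1e-12) & np.isfinite(g_try)
            eta_new[better] = trial_eta[better]
            obs_better = better[sub]
            f_new[obs_better] = f_try[obs_better]
            g_acc[better] = g_try[better]
            lam[better] = np.maximum(lam_try[better] / 3.0, 1e-6)
            accepted |= better
            lam_try = np.where(accepted, lam_try, lam_try * 10.0)
        rejected = active & ~accepted
        lam[rejected] = np.minimum(lam_try[rejected], 1e6)
        step_sizes = np.max(np.abs(eta_new - eta), axis=1) if d else np.zeros(n_sub)
        # a subject is converged when its step is tiny, its LM step was
        # rejected outright, or its conditional objective has stagnated
        # (flat-valley crawl along weakly informed random effects)
        g_decrease = g_cur - g_acc
        converged_now = active & ((step_sizes < tol) | rejected
                                  | (accepted & (g_decrease
                                                 < 1e-9 * (1.0 + np.abs(g_acc)))))
        active = active & ~converged_now
        eta, f, g_cur = eta_new, f_new, g_acc
        _, v, r, _ = per_subject_g(f, eta)  # refresh residuals/variances
    # -2 log L per subject at the mode
    g_fin, v, r, sums = per_subject_g(f, eta)
    prior = np.einsum("ij,jk,ik->i", eta, omega_inv, eta)
    sign, logdetH = np.linalg.slogdet(H)
    mofv_vec = sums + prior + omega_logdet + logdetH
    return eta, H, sums, mofv_vec


def _neg2ll_no_random(design, base_struct, z, kind, sigma, sigma2, scale=1.0):
    f = _predict_struct(design, base_struct, scale)
    mz, v = _moments(kind, f, sigma, sigma2)
    r = z - mz
    return float(np.sum(r * r / v + np.log(2.0 * np.pi * v)))


# ---------------------------------------------------------------------------
# public likelihood / EBE operations
# ---------------------------------------------------------------------------

def _effective_random(model: PopPKModel):
    """Drop random effects whose variance is numerically zero."""
    labels = model.random.labels
    om = model.random.omega
    keep = [k for k in range(len(labels)) if om[k, k] > 1e-12]
    if len(keep) == len(labels):
        return labels, om
    idx = np.array(keep, dtype=int)
    return tuple(labels[k] for k in keep), om[np.ix_(idx, idx)]


def neg2ll(
    model: PopPKModel,
    data: Sequence[SubjectCourse] | CompiledDesign,
    eta0: np.ndarray | None = None,
) -> float:
    """-2 x log approximate marginal likelihood (the objective function value)."""
    design = data if isinstance(data, CompiledDesign) else compile_design(data)
    if design.n_obs == 0:
        raise ValueError("every subject must carry at least one observation")
    base = _base_struct(model, design)
    f = _predict_struct(design, base, model.conc_scale)
    if not np.all(np.isfinite(f)):
        bad = design.obs_subject[~np.isfinite(f)][0]
        raise FloatingPointError(
            f"non-finite prediction for subject {design.subject_ids[bad]}")
    z = _obs_transform(model.residual.kind, design.obs_y)
    labels, omega = _effective_random(model)
    if not labels:
        return _neg2ll_no_random(design, base, z, model.residual.kind,
                                 model.residual.sigma, model.residual.sigma2,
                                 model.conc_scale)
    label_idx = np.array([PARAM_NAMES.index(l) for l in labels])
    _, _, _, mofv_vec = _inner_foce(
        design, base, label_idx, omega, z, model.residual.kind,
        model.residual.sigma, model.residual.sigma2, eta0=eta0,
        scale=model.conc_scale)
    return float(np.sum(mofv_vec))


def ebe(model: PopPKModel, subject: SubjectCourse) -> np.ndarray:
    """Empirical Bayes mode of the subject's random-effect distribution."""
    if model.n_random == 0:
        raise ValueError("model has no random effects")
    if not subject.observations:
        return np.zeros(model.n_random)
    design = compile_design([subject])
    base = _base_struct(model, design)
    z = _obs_transform(model.residual.kind, design.obs_y)
    labels, omega = _effective_random(model)
    out = np.zeros(model.n_random)
    if not labels:
        return out
    label_idx = np.array([PARAM_NAMES.index(l) for l in labels])
    eta, _, _, _ = _inner_foce(design, base, label_idx, omega, z,
                               model.residual.kind, model.residual.sigma,
                               model.residual.sigma2, scale=model.conc_scale)
    if not np.all(np.isfinite(eta)):
        raise RuntimeError(f"EBE optimization failed for subject {subject.subject_id}")
    for k, lab in enumerate(labels):
        out[model.random.labels.index(lab)] = eta[0, k]
    return out


# ---------------------------------------------------------------------------
# parameter packing for estimation
# ---------------------------------------------------------------------------

#: plausibility bounds (natural scale) keeping the optimizer out of absurd
#: regions (e.g. instantaneous absorption with the lag soaking up the delay)
_STRUCT_BOUNDS = {
    "cl": (1e-2, 1e4), "vc": (1e-1, 1e6), "q": (1e-2, 1e5),
    "vp": (1e-1, 1e8), "ka": (1e-2, 50.0), "tlag": (1e-2, 6.0),
}
_OMEGA_VAR_BOUNDS = (1e-6, 25.0)
_SIGMA_BOUNDS = (1e-4, 10.0)


class _Packer:
    """Maps a PopPKModel to/from a flat unconstrained parameter vector.

    Positive quantities (structural typical values, omega variances, sigma)
    are log-transformed; omega block structure is parametrized through its
    Cholesky factor (log diagonal, free off-diagonal); covariate thetas are
    untransformed.
    """

    def __init__(self, template: PopPKModel):
        self.template = template
        self.struct_names = [n for n in PARAM_NAMES if n not in template.fixed_parameters]
        self.cov_names = [f"{e.parameter}~{e.covariate}" for e in template.covariate_effects]
        self.labels = template.random.labels
        self.structure = template.random.structure
        d = len(self.labels)
        if self.structure == "block" and d > 1:
            self.omega_names = [f"omega_chol_{i}{j}" for i in range(d) for j in range(i + 1)]
        else:
            self.omega_names = [f"omega_{l}" for l in self.labels]
        self.sigma_names = ["sigma"] + (["sigma2"] if template.residual.kind == "combined" else [])
        self.names = self.struct_names + self.cov_names + self.omega_names + self.sigma_names

    @property
    def n(self) -> int:
        return len(self.names)

    def bounds(self) -> list[tuple[float, float]]:
        out = [tuple(np.log(_STRUCT_BOUNDS[n])) for n in self.struct_names]
        out += [(-1e3, 1e3)] * len(self.cov_names)
        d = len(self.labels)
        if self.structure == "block" and d > 1:
            for i in range(d):
                for j in range(i + 1):
                    out.append((0.5 * np.log(_OMEGA_VAR_BOUNDS[0]),
                                0.5 * np.log(_OMEGA_VAR_BOUNDS[1]))
                               if i == j else (-5.0, 5.0))
        else:
            out += [tuple(np.log(_OMEGA_VAR_BOUNDS))] * d
        out += [tuple(np.log(_SIGMA_BOUNDS))] * len(self.sigma_names)
        return out

    def pack(self, model: PopPKModel) -> np.ndarray:
        x = [np.log(getattr(model.typical, n)) for n in self.struct_names]
        x += [e.theta for e in model.covariate_effects]
        d = len(self.labels)
        om = model.random.omega
        if self.structure == "block" and d > 1:
            L = np.linalg.cholesky(om + 1e-12 * np.eye(d))
            for i in range(d):
                for j in range(i + 1):
                    x.append(np.log(L[i, i]) if i == j else L[i, j])
        else:
            x += [np.log(om[k, k]) for k in range(d)]
        x.append(np.log(model.residual.sigma))
        if model.residual.kind == "combined":
            x.append(np.log(max(model.residual.sigma2, 1e-8)))
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray) -> PopPKModel:
        t = self.template
        pos = 0
        vals = {n: getattr(t.typical, n) for n in PARAM_NAMES}
        for n in self.struct_names:
            vals[n] = np.exp(x[pos]); pos += 1
        typical = StructuralParams(**vals)
        effects = []
        for e in t.covariate_effects:
            effects.append(replace(e, theta=float(x[pos]))); pos += 1
        d = len(self.labels)
        if self.structure == "block" and d > 1:
            L = np.zeros((d, d))
            for i in range(d):
                for j in range(i + 1):
                    L[i, j] = np.exp(x[pos]) if i == j else x[pos]
                    pos += 1
            omega = L @ L.T
        else:
            omega = np.diag(np.exp(x[pos:pos + d])); pos += d
        sigma = float(np.exp(x[pos])); pos += 1
        sigma2 = float(np.exp(x[pos])) if t.residual.kind == "combined" else 0.0
        random = replace(t.random, omega=omega) if d else t.random
        residual = replace(t.residual, sigma=sigma, sigma2=sigma2)
        return replace(t, typical=typical, random=random, residual=residual,
                       covariate_effects=tuple(effects))


# ---------------------------------------------------------------------------
# population fit
# ---------------------------------------------------------------------------

_PENALTY = 1e10


def fit_pop(
    init: PopPKModel,
    data: Sequence[SubjectCourse] | CompiledDesign,
    *,
    max_iter: int = 200,
    rel_tol: float = 1e-6,
    seed: int | None = None,
    compute_se: bool = True,
) -> PopFitResult:
    """Maximize the approximate marginal likelihood from ``init``.

    The outer problem is solved with L-BFGS-B on log-transformed parameters;
    the inner empirical-Bayes problem is warm-started across outer
    evaluations.  ``seed`` is accepted for interface uniformity — the
    objective is deterministic.  On non-convergence the best iterate is
    returned with ``converged=False``.
    """
    design = data if isinstance(data, CompiledDesign) else compile_design(data)
    if design.n_obs == 0:
        raise ValueError("no observations in data")
    packer = _Packer(init)
    z_all = {}  # residual transform cache per kind

    labels = init.random.labels
    d = len(labels)
    eta_store = {"eta": np.zeros((design.n_sub, d)) if d else None}
    best = {"x": packer.pack(init), "f": np.inf}
    n_eval = [0]

    def objective(x):
        n_eval[0] += 1
        try:
            model = packer.unpack(x)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return _PENALTY
        base = _base_struct(model, design)
        kind = model.residual.kind
        if kind not in z_all:
            z_all[kind] = _obs_transform(kind, design.obs_y)
        z = z_all[kind]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if d == 0:
                val = _neg2ll_no_random(design, base, z, kind,
                                        model.residual.sigma, model.residual.sigma2,
                                        model.conc_scale)
            else:
                label_idx = np.array([PARAM_NAMES.index(l) for l in labels])
                # warm start from the best-so-far snapshot (never the last
                # call) so the objective is a deterministic function of x —
                # essential for clean finite-difference gradients
                try:
                    eta, _, _, mofv_vec = _inner_foce(
                        design, base, label_idx, model.random.omega, z, kind,
                        model.residual.sigma, model.residual.sigma2,
                        eta0=eta_store["eta"], max_iter=80, tol=1e-7,
                        scale=model.conc_scale)
                except np.linalg.LinAlgError:
                    return _PENALTY
                val = float(np.sum(mofv_vec))
        if not np.isfinite(val):
            return _PENALTY
        if val < best["f"]:
            best["f"], best["x"] = val, x.copy()
            if d and np.all(np.isfinite(eta)):
                eta_store["eta"] = eta.copy()
        return val

    x0 = packer.pack(init)
    bl, bh = np.array(packer.bounds()).T
    x0 = np.clip(x0, bl + 1e-6, bh - 1e-6)
    f0 = objective(x0)
    # repeated L-BFGS rounds from the incumbent: restarting resets the
    # quasi-Newton memory, which reliably escapes premature stalls of the
    # first round on this noisy-curvature objective
    n_iter_total = 0
    success = False
    x_start = x0
    for _round in range(4):
        f_before = best["f"]
        res = optimize.minimize(
            objective, x_start, method="L-BFGS-B", bounds=packer.bounds(),
            options={"maxiter": max_iter, "ftol": rel_tol, "gtol": 1e-4,
                     "eps": 5e-4, "maxfun": 100 * max_iter},
        )
        n_iter_total += int(res.nit)
        success = bool(res.success)
        if f_before - best["f"] < max(1e-3, rel_tol * abs(best["f"])):
            break
        x_start = best["x"]
    x_hat = best["x"]
    mofv = best["f"]
    converged = success and mofv <= f0 + 1e-9
    model_hat = packer.unpack(x_hat)

    # final inner solve at the optimum
    base = _base_struct(model_hat, design)
    kind = model_hat.residual.kind
    z = _obs_transform(kind, design.obs_y)
    if d:
        label_idx = np.array([PARAM_NAMES.index(l) for l in labels])
        ebes, _, _, mofv_vec = _inner_foce(
            design, base, label_idx, model_hat.random.omega, z, kind,
            model_hat.residual.sigma, model_hat.residual.sigma2,
            eta0=eta_store["eta"], max_iter=120, tol=1e-8,
            scale=model_hat.conc_scale)
        mofv = float(np.sum(mofv_vec))
    else:
        ebes = np.zeros((design.n_sub, 0))

    # shrinkages
    eta_shr = {}
    for k, lab in enumerate(labels):
        om = np.sqrt(model_hat.random.omega[k, k])
        sd = np.std(ebes[:, k], ddof=1) if design.n_sub > 1 else 0.0
        eta_shr[lab] = 100.0 * (1.0 - sd / om) if om > 0 else np.nan
    iwres = _iwres(model_hat, design, ebes)
    eps_shr = 100.0 * (1.0 - np.std(iwres, ddof=1)) if design.n_obs > 1 else np.nan

    rse = cov = None
    cond = np.nan
    if compute_se:
        cov, rse, cond = _precision(objective, x_hat, packer)

    return PopFitResult(
        model=model_hat, mofv=mofv, ebes=ebes, eta_shrinkage=eta_shr,
        eps_shrinkage=float(eps_shr), converged=converged, n_iter=n_iter_total,
        param_names=list(packer.names), estimates=x_hat.copy(), rse=rse,
        covariance=cov, condition_number=cond, design=design,
    )


def _precision(objective, x_hat, packer):
    """Inverse-Hessian covariance, RSE%, and covariance condition number.

    The observed information of the log-likelihood is half the Hessian of the
    -2LL objective, so cov = 2 H^-1.  Parameters are log-scale, hence the SE
    of log-theta is directly the relative SE of theta (delta method).
    """
    n = len(x_hat)
    h = 1e-3
    hess = np.zeros((n, n))
    f0 = objective(x_hat)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        e = np.zeros(n); e[i] = h
        fp[i] = objective(x_hat + e)
        fm[i] = objective(x_hat - e)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = objective(x_hat + ei + ej)
            hess[i, j] = hess[j, i] = (fpp - fp[i] - fp[j] + f0) / h**2
    try:
        cov = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None, None, np.inf
    se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    rse = {}
    for name, s, xi in zip(packer.names, se_log, x_hat):
        if name.startswith("omega_") and not name.startswith("omega_chol"):
            # variance scale -> SD scale: RSE(sd) = RSE(var)/2
            rse[name] = 100.0 * s / 2.0
        elif "~" in name or name.startswith("omega_chol"):
            rse[name] = 100.0 * s / max(abs(xi), 1e-12)
        else:
            rse[name] = 100.0 * s
    cond = condition_number(cov)
    return cov, rse, cond


def _iwres(model, design, ebes):
    """Individual weighted residuals at the empirical Bayes modes."""
    base = _base_struct(model, design)
    labels = model.random.labels
    if labels:
        label_idx = np.array([PARAM_NAMES.index(l) for l in labels])
        f = _predict_eta(design, base, label_idx, ebes, model.conc_scale)
    else:
        f = _predict_struct(design, base, model.conc_scale)
    z = _obs_transform(model.residual.kind, design.obs_y)
    mz, v = _moments(model.residual.kind, f, model.residual.sigma, model.residual.sigma2)
    return (z - mz) / np.sqrt(v)


def shrinkage(fit: PopFitResult) -> dict:
    """Eta-shrinkage (%) per random effect and epsilon-shrinkage (%)."""
    if fit.design is not None and fit.design.n_sub < 2:
        raise ValueError("shrinkage undefined for fewer than 2 subjects")
    return {"eta": dict(fit.eta_shrinkage), "eps": fit.eps_shrinkage}


def lrt_threshold(df: int, alpha: float) -> float:
    """Chi-square likelihood-ratio cut-off in -2LL (MOFV) units."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.chi2.isf(alpha, df))


def condition_number(x) -> float:
    """Largest/smallest eigenvalue ratio of a covariance matrix (or fit).

    A ratio >= 1000 flags ill-conditioning; a singular matrix reports inf.
    """
    mat = x.covariance if isinstance(x, PopFitResult) else np.atleast_2d(np.asarray(x, float))
    if mat is None:
        raise ValueError("fit carries no covariance matrix")
    w = np.linalg.eigvalsh(mat)
    if w[-1] <= 0:
        return np.inf
    if w[0] <= 0:
        return np.inf
    return float(w[-1] / w[0])


# ---------------------------------------------------------------------------
# covariate stepwise machinery
# ---------------------------------------------------------------------------

def stepwise_covariates(
    base: PopPKModel,
    data: Sequence[SubjectCourse] | CompiledDesign,
    candidates: Sequence[tuple[str, str, str]],
    *,
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.001,
    **fit_kwargs,
):
    """Forward-inclusion / backward-elimination covariate selection.

    ``candidates`` are ``(parameter, covariate, form)`` triples.  A candidate
    enters if it drops the MOFV by at least the chi-square(1) cut-off at
    ``forward_alpha`` and survives elimination only if its removal raises the
    MOFV by at least the cut-off at ``backward_alpha``.  Returns the selected
    model's fit and a decision trace (including AIC for non-nested use).
    """
    design = data if isinstance(data, CompiledDesign) else compile_design(data)
    fit_kwargs.setdefault("compute_se", False)
    fwd_cut = lrt_threshold(1, forward_alpha)
    bwd_cut = lrt_threshold(1, backward_alpha)
    trace: list[dict] = []

    def ref_value(covariate):
        vals = design.covariates[covariate]
        return float(np.nanmedian(vals))

    current_fit = fit_pop(base, design, **fit_kwargs)
    remaining = list(candidates)
    # forward inclusion
    while remaining:
        results = []
        for parameter, covariate, form in remaining:
            eff = CovariateEffect(parameter, covariate, form,
                                  theta=0.0, reference=ref_value(covariate))
            cand_model = replace(current_fit.model,
                                 covariate_effects=current_fit.model.covariate_effects + (eff,))
            try:
                fit = fit_pop(cand_model, design, **fit_kwargs)
            except Exception as exc:  # noqa: BLE001 - candidate skipped, logged
                log.warning("candidate %s on %s skipped: %s", covariate, parameter, exc)
                trace.append({"step": "forward", "candidate": (parameter, covariate, form),
                              "status": "failed", "error": str(exc)})
                continue
            dm = current_fit.mofv - fit.mofv
            trace.append({"step": "forward", "candidate": (parameter, covariate, form),
                          "delta_mofv": dm, "mofv": fit.mofv,
                          "aic": fit.mofv + 2 * len(fit.param_names),
                          "status": "tested"})
            results.append((dm, (parameter, covariate, form), fit))
        results = [rr for rr in results if np.isfinite(rr[0])]
        if not results:
            break
        results.sort(key=lambda rr: -rr[0])
        dm, cand, fit = results[0]
        if dm >= fwd_cut:
            trace.append({"step": "forward", "candidate": cand,
                          "delta_mofv": dm, "status": "included"})
            current_fit = fit
            remaining = [c for c in remaining if c != cand]
        else:
            break
    # backward elimination
    changed = True
    while changed and current_fit.model.covariate_effects:
        changed = False
        for eff in current_fit.model.covariate_effects:
            reduced = replace(
                current_fit.model,
                covariate_effects=tuple(e for e in current_fit.model.covariate_effects
                                        if e is not eff))
            fit = fit_pop(reduced, design, **fit_kwargs)
            dm = fit.mofv - current_fit.mofv  # increase on removal
            kept = dm >= bwd_cut
            trace.append({"step": "backward",
                          "candidate": (eff.parameter, eff.covariate, eff.form),
                          "delta_mofv": dm,
                          "status": "kept" if kept else "removed"})
            if not kept:
                current_fit = fit
                changed = True
                break
    return current_fit, trace


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(fit: PopFitResult, data=None) -> pd.DataFrame:
    """Per-observation PRED, IPRED, IWRES and CWRES.

    CWRES uses the first-order-conditional linearization of the marginal
    distribution around the empirical Bayes modes: the marginal mean is
    ``m(eta_hat) - J eta_hat`` and the marginal covariance
    ``J Omega J' + V``, decorrelated subject-wise by Cholesky.
    """
    design = fit.design if data is None else (
        data if isinstance(data, CompiledDesign) else compile_design(data))
    model = fit.model
    base = _base_struct(model, design)
    labels = model.random.labels
    kind = model.residual.kind
    z = _obs_transform(kind, design.obs_y)
    d = len(labels)
    if d:
        label_idx = np.array([PARAM_NAMES.index(l) for l in labels])
        f_ind = _predict_eta(design, base, label_idx, fit.ebes, model.conc_scale)
    else:
        f_ind = _predict_struct(design, base, model.conc_scale)
    f_pop = _predict_struct(design, base, model.conc_scale)
    mz_ind, v_ind = _moments(kind, f_ind, model.residual.sigma, model.residual.sigma2)
    iwres = (z - mz_ind) / np.sqrt(v_ind)

    cwres = np.zeros(design.n_obs)
    if d:
        jac_scale = _mean_jacobian_scale(kind, f_ind)
        J = np.empty((design.n_obs, d))
        for k in range(d):
            step = np.zeros((design.n_sub, d))
            step[:, k] = _ETA_FD_STEP
            f_k = _predict_eta(design, base, label_idx, fit.ebes + step,
                               model.conc_scale)
            J[:, k] = jac_scale * (f_k - f_ind) / _ETA_FD_STEP
        omega = model.random.omega
        for i in range(design.n_sub):
            mask = design.obs_subject == i
            if not mask.any():
                continue
            Ji = J[mask]
            mean_i = mz_ind[mask] - Ji @ fit.ebes[i]
            cov_i = Ji @ omega @ Ji.T + np.diag(v_ind[mask])
            L = np.linalg.cholesky(cov_i)
            cwres[mask] = np.linalg.solve(L, z[mask] - mean_i)
    else:
        cwres = iwres.copy()
    return pd.DataFrame({
        "subject": [design.subject_ids[i] for i in design.obs_subject],
        "time": design.obs_time,
        "tad": design.obs_tad,
        "occasion": design.obs_occasion,
        "obs": design.obs_y,
        "PRED": f_pop,
        "IPRED": f_ind,
        "IWRES": iwres,
        "CWRES": cwres,
    })


# ---------------------------------------------------------------------------
# simulation at a compiled design (used by the trial generator and VPC/npde)
# ---------------------------------------------------------------------------

def simulate_observations(
    model: PopPKModel,
    design: CompiledDesign,
    rng: np.random.Generator,
    return_eta: bool = False,
):
    """Simulate one replicate of the design's observation vector.

    Random effects are drawn from ``Omega``; residual noise follows the
    residual spec.  For the normal-on-concentration kinds (proportional,
    additive, combined) draws are repeated until positive, preserving the
    positivity of observed concentrations (see methods note).
    """
    d = model.n_random
    base = _base_struct(model, design)
    if d:
        L = np.linalg.cholesky(model.random.omega + 1e-300 * np.eye(d))
        eta = rng.standard_normal((design.n_sub, d)) @ L.T
        label_idx = np.array([PARAM_NAMES.index(l) for l in model.random.labels])
        f = _predict_eta(design, base, label_idx, eta, model.conc_scale)
    else:
        eta = np.zeros((design.n_sub, 0))
        f = _predict_struct(design, base, model.conc_scale)
    kind = model.residual.kind
    sigma, sigma2 = model.residual.sigma, model.residual.sigma2
    if kind == "additive_log":
        y = np.exp(np.log(np.maximum(f, _F_FLOOR)) + sigma * rng.standard_normal(design.n_obs))
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
        y = np.maximum(y, _F_FLOOR)
    return (y, eta) if return_eta else y


# ---------------------------------------------------------------------------
# naive pooled initialization
# ---------------------------------------------------------------------------

def pooled_init(
    template: PopPKModel,
    data: Sequence[SubjectCourse] | CompiledDesign,
    omega_var: float = 0.1,
) -> PopPKModel:
    """Naive-pooled nonlinear least-squares pre-fit for initial values.

    Typical values are fitted to all observations jointly on the log scale
    (ignoring the hierarchy); omega is reset to a diagonal 0.1 variance and
    sigma to the pooled residual SD.
    """
    design = data if isinstance(data, CompiledDesign) else compile_design(data)
    free = [n for n in PARAM_NAMES if n not in template.fixed_parameters]
    idx = [PARAM_NAMES.index(n) for n in free]
    logy = np.log(design.obs_y)

    def resid(xlog):
        vals = template.typical.as_array().copy()
        vals[idx] = np.exp(xlog)
        struct = _base_struct(
            replace(template, typical=StructuralParams(*vals)), design)
        f = _predict_struct(design, struct, template.conc_scale)
        return np.log(np.maximum(f, _F_FLOOR)) - logy

    x0 = np.log(template.typical.as_array()[idx])
    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=400)
    vals = template.typical.as_array().copy()
    vals[idx] = np.exp(sol.x)
    typical = StructuralParams(*vals)
    d = template.n_random
    random = replace(template.random, omega=np.eye(d) * omega_var) if d else template.random
    sigma = float(np.std(sol.fun, ddof=len(free))) if len(sol.fun) > len(free) else template.residual.sigma
    residual = replace(template.residual, sigma=max(sigma, 1e-3))
    return replace(template, typical=typical, random=random, residual=residual)


def fit_pop_multistart(
    template: PopPKModel,
    data: Sequence[SubjectCourse] | CompiledDesign,
    ka_inits: Sequence[float | None] = (None, 1.0),
    **fit_kwargs,
) -> PopFitResult:
    """Population fit from several absorption starting points.

    The marginal-likelihood surface is multimodal in the absorption
    parameters (a very fast Ka with the lag absorbing the delay can mimic a
    slower first-order uptake on sparse absorption-phase sampling), so the
    fit is repeated from the naive-pooled initial values with Ka reset to
    each entry of ``ka_inits`` (``None`` keeps the pooled estimate; 1.0/h is
    a neutral moderate-absorption start) and the best objective wins.
    """
    design = data if isinstance(data, CompiledDesign) else compile_design(data)
    init = pooled_init(template, design)
    leg_kwargs = dict(fit_kwargs)
    want_se = leg_kwargs.pop("compute_se", True)
    best: PopFitResult | None = None
    for ka0 in ka_inits:
        start = init if ka0 is None else replace(
            init, typical=replace(init.typical, ka=float(ka0)))
        try:
            fit = fit_pop(start, design, compute_se=False, **leg_kwargs)
        except Exception as exc:  # noqa: BLE001 - one bad start is not fatal
            log.warning("multistart from ka=%s failed: %s", ka0, exc)
            continue
        if best is None or fit.mofv < best.mofv:
            best = fit
    if best is None:
        raise RuntimeError("all multistart fits failed")
    if want_se:
        best = fit_pop(best.model, design, compute_se=True, **leg_kwargs)
    return best


def ebe_correlation_screen(fit: PopFitResult, threshold: float = 0.4):
    """Pairs of random effects whose EBE correlation suggests a block omega.

    The default diagonal omega is extended to a block structure only when
    the empirical Bayes estimates of two effects correlate beyond the
    threshold; refit with ``RandomEffectsSpec(structure="block")`` to
    estimate the covariance.
    """
    labels = fit.model.random.labels
    out = []
    if fit.ebes.shape[1] < 2 or fit.ebes.shape[0] < 3:
        return out
    corr = np.corrcoef(fit.ebes, rowvar=False)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            if abs(corr[a, b]) > threshold:
                out.append((labels[a], labels[b], float(corr[a, b])))
    return out
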