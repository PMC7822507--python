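"""Visit-level logistic regression of acute-rejection risk.

The binary outcome is acute rejection (AR); to probe prognostic rather than
diagnostic value, an AR episode is scored on the visit *preceding* its
diagnosis, carrying that earlier visit's predictor values (biomarkers and
model-predicted drug exposures).  The risk model is a plain fixed-effects
logit,

    logit(P_i) = beta0 + sum_k beta_k x_ik,    P_i = expit(.)

fitted by Bernoulli maximum likelihood.  Candidate explanatory variables are
cumulative AUC and mean trough concentration of each immunosuppressant
(individual model predictions) plus the urinary biomarkers miR155-5p
(relative expression, 2^-dCq scale as tabulated) and CXCL-10 (pg/mL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .nlme_fit import lrt_threshold

__all__ = [
    "VISIT_ORDER",
    "VisitRecord",
    "LogisticFit",
    "SeparationError",
    "build_logistic_dataset",
    "risk",
    "fit_logistic",
    "select_explanatory",
]

log = logging.getLogger("graftrisk")

VISIT_ORDER = ("W1", "M1", "M2", "M3", "M6")

#: canonical predictor column names in the visit table
PREDICTORS = ("MIR155", "CXCL10", "AUC_TAC", "AUC_MPA", "TROUGH_TAC", "TROUGH_MPA")


@dataclass(frozen=True)
class VisitRecord:
    """One subject-visit row of the logistic dataset."""

    subject_id: str
    visit: str
    miR155: float
    CXCL10: float
    auc_tac: float = np.nan
    auc_mpa: float = np.nan
    trough_tac: float = np.nan
    trough_mpa: float = np.nan
    outcome: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be binary")


@dataclass
class LogisticFit:
    """Fitted logit model: intercept beta0 and slope per retained predictor."""

    beta0: float
    betas: dict[str, float]
    se: dict[str, float]
    mofv: float
    n: int = 0

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.betas)


class SeparationError(RuntimeError):
    """Complete separation: the ML estimate diverges for a predictor."""


# ---------------------------------------------------------------------------
# dataset construction (prior-visit shift)
# ---------------------------------------------------------------------------

def build_logistic_dataset(
    pk_exposures: pd.DataFrame | None,
    biomarker_series: pd.DataFrame,
    ar_events: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Assemble the visit-level logistic table with the prognostic shift.

    ``biomarker_series`` needs columns ID, VISIT, MIR155, CXCL10 (one row per
    available subject-visit); ``pk_exposures`` optionally adds AUC_TAC,
    AUC_MPA, TROUGH_TAC, TROUGH_MPA keyed on ID, VISIT.  ``ar_events`` are
    ``(subject_id, diagnosis_visit)`` pairs; each event sets outcome=1 on the
    subject's latest available visit *before* the diagnosis visit.  An event
    at the subject's first available visit, having no predecessor, is scored
    on that same record (counted separately in ``df.attrs``).  Rows with
    missing predictor values are dropped and counted.
    """
    df = biomarker_series.copy()
    if pk_exposures is not None and len(pk_exposures):
        df = df.merge(pk_exposures, on=["ID", "VISIT"], how="left")
    order = {v: i for i, v in enumerate(VISIT_ORDER)}
    bad = set(df["VISIT"]) - set(order)
    if bad:
        raise ValueError(f"unknown visit labels {sorted(bad)}")
    df["_vi"] = df["VISIT"].map(order)
    pred_cols = [c for c in PREDICTORS if c in df.columns]
    n0 = len(df)
    df = df.dropna(subset=pred_cols)
    n_dropped = n0 - len(df)
    df = df.sort_values(["ID", "_vi"]).reset_index(drop=True)
    df["AR"] = 0
    df["ID"] = df["ID"].astype(str)

    n_first_visit_events = 0
    n_unplaceable = 0
    for sid, visit in ar_events:
        sid = str(sid)
        if visit not in order:
            raise ValueError(f"AR event at unknown visit {visit!r}")
        rows = df[df["ID"] == sid]
        if rows.empty:
            n_unplaceable += 1
            log.warning("AR event for subject %s: no visit records survive", sid)
            continue
        prior = rows[rows["_vi"] < order[visit]]
        if len(prior):
            target = prior.index[-1]
        else:
            # diagnosis at the subject's first available visit: no predecessor
            same = rows[rows["_vi"] == order[visit]]
            if same.empty:
                n_unplaceable += 1
                log.warning("AR event for subject %s at %s: record missing", sid, visit)
                continue
            target = same.index[0]
            n_first_visit_events += 1
            log.info("AR at first available visit for subject %s: scored on %s",
                     sid, visit)
        df.loc[target, "AR"] = 1
    df = df.drop(columns="_vi")
    df.attrs["n_dropped_missing"] = n_dropped
    df.attrs["n_first_visit_events"] = n_first_visit_events
    df.attrs["n_unplaceable_events"] = n_unplaceable
    return df


# ---------------------------------------------------------------------------
# risk and maximum likelihood fit
# ---------------------------------------------------------------------------

def risk(fit: LogisticFit, x: Sequence[float] | np.ndarray | dict) -> float | np.ndarray:
    """AR probability expit(beta0 + sum beta_k x_k) for a predictor vector.

    ``x`` may be a dict keyed by predictor name, or an array ordered like
    ``fit.predictors`` (2-D input returns one probability per row).
    """
    if isinstance(x, dict):
        xv = np.array([x[k] for k in fit.predictors], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
    beta = np.array([fit.betas[k] for k in fit.predictors])
    if xv.ndim == 1 and xv.shape[-1] != len(beta):
        raise ValueError(f"expected {len(beta)} predictor values, got {xv.shape[-1]}")
    if xv.ndim == 2 and xv.shape[1] != len(beta):
        raise ValueError(f"expected {len(beta)} predictor columns, got {xv.shape[1]}")
    eta = fit.beta0 + xv @ beta
    out = expit(eta)
    return float(out) if np.isscalar(eta) or np.ndim(eta) == 0 else out


def fit_logistic(
    records: pd.DataFrame,
    predictors: Sequence[str],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logit fit by iteratively reweighted least squares.

    Raises :class:`SeparationError` (naming the offending predictor) when the
    likelihood diverges under complete separation, and ``ValueError`` when
    only one outcome class is present.
    """
    y = records["AR"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = np.column_stack([np.ones(len(y))] +
                        [records[p].to_numpy(dtype=float) for p in predictors])
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors contain missing/non-finite values")
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for it in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        g = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(beta)), g)
        except np.linalg.LinAlgError:
            raise SeparationError(_separation_culprit(beta, predictors))
        # step-halving on the log-likelihood
        ll = _bernoulli_ll(y, eta)
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            ll_new = _bernoulli_ll(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        ll_new = _bernoulli_ll(y, X @ beta)
        slope_max = np.max(np.abs(beta[1:])) if len(beta) > 1 else 0.0
        if slope_max > 50.0 or np.max(np.abs(beta)) > 500.0:
            raise SeparationError(_separation_culprit(beta, predictors))
        if abs(ll_new - ll_old) < tol * (1 + abs(ll_new)):
            break
        ll_old = ll_new
    eta = X @ beta
    p = expit(eta)
    W = p * (1 - p)
    H = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise SeparationError(_separation_culprit(beta, predictors))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    names = ["intercept"] + list(predictors)
    return LogisticFit(
        beta0=float(beta[0]),
        betas={p_: float(b) for p_, b in zip(predictors, beta[1:])},
        se=dict(zip(names, se)),
        mofv=float(-2.0 * _bernoulli_ll(y, eta)),
        n=len(y),
    )


def _bernoulli_ll(y, eta):
    # numerically stable: log(1+e^eta) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _separation_culprit(beta, predictors):
    if len(beta) <= 1 or not len(predictors):
        return "complete separation (intercept-only degenerate fit)"
    k = int(np.argmax(np.abs(beta[1:])))
    return f"complete separation driven by predictor {predictors[k]!r}"


# ---------------------------------------------------------------------------
# explanatory-variable selection
# ---------------------------------------------------------------------------

def select_explanatory(
    records: pd.DataFrame,
    candidates: Sequence[str] = PREDICTORS,
    *,
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.001,
):
    """Forward-inclusion / backward-elimination over the candidate predictors.

    Inclusion requires a -2LL drop of at least the chi-square(1) cut-off at
    ``forward_alpha``; retention at elimination requires a rise of at least
    the cut-off at ``backward_alpha``.  Returns the retained predictor list
    and the decision trace of MOFV changes.
    """
    candidates = [c for c in candidates if c in records.columns]
    fwd_cut = lrt_threshold(1, forward_alpha)
    bwd_cut = lrt_threshold(1, backward_alpha)
    retained: list[str] = []
    trace: list[dict] = []
    current_mofv = fit_logistic(records, retained).mofv

    improving = True
    while improving and len(retained) < len(candidates):
        improving = False
        results = []
        for cand in candidates:
            if cand in retained:
                continue
            col = records[cand].to_numpy(dtype=float)
            if np.nanstd(col) <= 1e-12 * (1.0 + abs(np.nanmean(col))):
                trace.append({"step": "forward", "candidate": cand,
                              "delta_mofv": 0.0, "status": "constant"})
                continue
            try:
                fit = fit_logistic(records, retained + [cand])
            except (SeparationError, ValueError) as exc:
                trace.append({"step": "forward", "candidate": cand,
                              "status": "failed", "error": str(exc)})
                continue
            dm = current_mofv - fit.mofv
            trace.append({"step": "forward", "candidate": cand,
                          "delta_mofv": dm, "status": "tested"})
            results.append((dm, cand, fit))
        if results:
            results.sort(key=lambda r: -r[0])
            dm, cand, fit = results[0]
            if dm >= fwd_cut:
                retained.append(cand)
                current_mofv = fit.mofv
                trace.append({"step": "forward", "candidate": cand,
                              "delta_mofv": dm, "status": "included"})
                improving = True
    # backward elimination
    changed = True
    while changed and retained:
        changed = False
        for cand in list(retained):
            reduced = [c for c in retained if c != cand]
            fit = fit_logistic(records, reduced)
            dm = fit.mofv - current_mofv
            keep = dm >= bwd_cut
            trace.append({"step": "backward", "candidate": cand,
                          "delta_mofv": dm, "status": "kept" if keep else "removed"})
            if not keep:
                retained = reduced
                current_mofv = fit.mofv
                changed = True
                break
    return retained, trace
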