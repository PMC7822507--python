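"""Model-evaluation machinery: VPCs, npde, nonparametric bootstrap.

All diagnostics are simulation-based and fully reproducible given
``(seed, n_sim)``: replicate datasets are simulated at the original design
(doses, sampling times, weights) and observed statistics are compared with
the simulated reference distribution.

* pcVPC — prediction-corrected visual predictive check for continuous
  concentration data, binned on time after dose;
* categorical VPC — observed vs simulated acute-rejection proportion as a
  function of the explanatory biomarker;
* grouped bar — observed vs model-predicted rejection proportion in 10
  contiguous bins of the explanatory variable;
* npde — normalized prediction distribution errors (subject-wise
  decorrelation against the simulated mean/covariance, rank-based
  discrepancies mapped through the inverse normal CDF);
* bootstrap — subject-resampling refits for model stability and precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nlme_fit import (
    CompiledDesign,
    PopPKModel,
    compile_design,
    simulate_observations,
    _base_struct,
    _predict_struct,
)
from .rejection_logit import LogisticFit, risk

__all__ = [
    "VPCResult",
    "NPDEResult",
    "BootstrapResult",
    "pcvpc",
    "categorical_vpc",
    "grouped_bar",
    "npde",
    "bootstrap",
    "plot_vpc",
    "plot_grouped_bar",
]

log = logging.getLogger("graftrisk")

_PCTS = (2.5, 50.0, 97.5)


@dataclass
class VPCResult:
    """Binned observed statistics with simulated 95% confidence bands.

    ``obs`` maps a statistic label (percentile, or "proportion" for the
    categorical check) to its per-bin observed value; ``sim_median`` /
    ``sim_lo`` / ``sim_hi`` give the simulation median and 95% band of the
    same statistic.
    """

    bin_edges: np.ndarray
    bin_center: np.ndarray
    n_per_bin: np.ndarray
    obs: dict[str, np.ndarray]
    sim_median: dict[str, np.ndarray]
    sim_lo: dict[str, np.ndarray]
    sim_hi: dict[str, np.ndarray]
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (bin, statistic)."""
        rows = []
        for stat in self.obs:
            for b in range(len(self.bin_center)):
                rows.append({
                    "bin_lo": self.bin_edges[b], "bin_hi": self.bin_edges[b + 1],
                    "bin_center": self.bin_center[b], "n": self.n_per_bin[b],
                    "statistic": stat, "observed": self.obs[stat][b],
                    "sim_median": self.sim_median[stat][b],
                    "sim_lo": self.sim_lo[stat][b], "sim_hi": self.sim_hi[stat][b],
                })
        return pd.DataFrame(rows)

    def coverage(self) -> dict[str, float]:
        """Fraction of bins whose observed statistic lies inside the band."""
        out = {}
        for stat in self.obs:
            ok = (self.obs[stat] >= self.sim_lo[stat]) & (self.obs[stat] <= self.sim_hi[stat])
            out[stat] = float(np.mean(ok))
        return out


@dataclass
class NPDEResult:
    """Per-observation normalized prediction distribution errors."""

    npde: np.ndarray
    mean: float
    variance: float
    normality_stat: float
    normality_p: float


@dataclass
class BootstrapResult:
    """Subject-resampling bootstrap summary (median and 95% percentile CI)."""

    table: pd.DataFrame  # parameter, median, p2.5, p97.5
    n_resamples: int
    n_failed: int
    unstable: bool

    def __post_init__(self) -> None:
        if self.n_failed and self.n_failed > 0.2 * self.n_resamples:
            self.unstable = True


# ---------------------------------------------------------------------------
# binning helpers
# ---------------------------------------------------------------------------

def _quantile_bins(x: np.ndarray, n_bins: int, min_per_bin: int = 2) -> np.ndarray:
    """Quantile bin edges over x; sparse bins are merged with a neighbour."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(x, qs))
    if len(edges) < 2:
        edges = np.array([x.min(), x.max() + 1e-9])
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    while len(edges) > 2:
        counts, _ = np.histogram(x, edges)
        if counts.min() >= min_per_bin:
            break
        k = int(np.argmin(counts))
        drop = k if k > 0 else 1
        log.info("merging sparse bin %d (%d observations) with neighbour", k, counts.min())
        edges = np.delete(edges, drop)
    return edges


def _bin_stats(x, values, edges, stat_fn):
    idx = np.digitize(x, edges) - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    out = []
    for b in range(len(edges) - 1):
        sel = idx == b
        out.append(stat_fn(values[sel]) if sel.any() else np.nan)
    return np.asarray(out), idx


# ---------------------------------------------------------------------------
# prediction-corrected VPC (continuous data)
# ---------------------------------------------------------------------------

def pcvpc(
    model: PopPKModel,
    data,
    n_sim: int = 1000,
    bins: int = 8,
    seed: int = 0,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observed and simulated concentrations are corrected by
    ``pcY = Y * median(PRED in bin) / PRED`` with the population prediction
    ``PRED``; the check then compares binned percentiles (2.5/50/97.5) of
    the corrected observations against the 95% confidence band of the same
    percentile across ``n_sim`` replicates simulated at the original design.
    Binning is quantile-based on time after dose.
    """
    design = data if isinstance(data, CompiledDesign) else compile_design(data)
    rng = np.random.default_rng(seed)
    pred = np.maximum(
        _predict_struct(design, _base_struct(model, design), model.conc_scale), 1e-12)
    tad = np.where(np.isfinite(design.obs_tad), design.obs_tad, design.obs_time)
    edges = _quantile_bins(tad, bins)
    idx = np.clip(np.digitize(tad, edges) - 1, 0, len(edges) - 2)
    med_pred = np.array([np.median(pred[idx == b]) if (idx == b).any() else np.nan
                         for b in range(len(edges) - 1)])
    corr = med_pred[idx] / pred

    def binned_percentiles(y):
        pc = y * corr
        return np.vstack([
            np.array([np.percentile(pc[idx == b], p) if (idx == b).any() else np.nan
                      for b in range(len(edges) - 1)])
            for p in _PCTS])

    obs_p = binned_percentiles(design.obs_y)
    sim_p = np.empty((n_sim, len(_PCTS), len(edges) - 1))
    for s in range(n_sim):
        sim_p[s] = binned_percentiles(simulate_observations(model, design, rng))
    center = np.array([np.median(tad[idx == b]) if (idx == b).any() else np.nan
                       for b in range(len(edges) - 1)])
    n_per_bin = np.bincount(idx, minlength=len(edges) - 1)
    labels = [f"p{p:g}" for p in _PCTS]
    return VPCResult(
        bin_edges=edges, bin_center=center, n_per_bin=n_per_bin,
        obs={l: obs_p[i] for i, l in enumerate(labels)},
        sim_median={l: np.median(sim_p[:, i], axis=0) for i, l in enumerate(labels)},
        sim_lo={l: np.percentile(sim_p[:, i], 2.5, axis=0) for i, l in enumerate(labels)},
        sim_hi={l: np.percentile(sim_p[:, i], 97.5, axis=0) for i, l in enumerate(labels)},
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# categorical VPC (binary outcome vs biomarker)
# ---------------------------------------------------------------------------

def categorical_vpc(
    fit: LogisticFit,
    records: pd.DataFrame,
    n_sim: int = 1000,
    n_bins: int = 6,
    seed: int = 0,
    predictor: str = "MIR155",
) -> VPCResult:
    """VPC for the binary AR outcome as a function of the biomarker.

    Outcomes are re-simulated ``n_sim`` times as Bernoulli draws at the
    observed predictor values; the observed per-bin AR proportion is
    compared with the simulated median and 95% prediction interval.
    """
    rng = np.random.default_rng(seed)
    x = records[predictor].to_numpy(dtype=float)
    y = records["AR"].to_numpy(dtype=float)
    X = records[list(fit.predictors)].to_numpy(dtype=float)
    p = np.asarray(risk(fit, X))
    edges = _quantile_bins(x, n_bins)
    obs_prop, idx = _bin_stats(x, y, edges, np.mean)
    nb = len(edges) - 1
    sim = rng.random((n_sim, len(y))) < p[None, :]
    sim_prop = np.vstack([
        np.array([sim[s, idx == b].mean() if (idx == b).any() else np.nan
                  for b in range(nb)])
        for s in range(n_sim)])
    center = np.array([np.median(x[idx == b]) if (idx == b).any() else np.nan
                       for b in range(nb)])
    return VPCResult(
        bin_edges=edges, bin_center=center,
        n_per_bin=np.bincount(idx, minlength=nb),
        obs={"proportion": obs_prop},
        sim_median={"proportion": np.nanmedian(sim_prop, axis=0)},
        sim_lo={"proportion": np.nanpercentile(sim_prop, 2.5, axis=0)},
        sim_hi={"proportion": np.nanpercentile(sim_prop, 97.5, axis=0)},
        n_sim=n_sim,
    )


def grouped_bar(
    fit: LogisticFit,
    records: pd.DataFrame,
    n_bins: int = 10,
    predictor: str = "MIR155",
) -> pd.DataFrame:
    """Observed vs predicted rejection proportion in contiguous bins.

    Bins are equal-width over [min, max] of the explanatory variable;
    observed is the mean outcome, predicted the mean model risk, per bin.
    Empty bins are reported with NaN proportions.
    """
    x = records[predictor].to_numpy(dtype=float)
    y = records["AR"].to_numpy(dtype=float)
    X = records[list(fit.predictors)].to_numpy(dtype=float)
    p = np.asarray(risk(fit, X))
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    edges[-1] += 1e-9
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        rows.append({
            "bin_lo": edges[b], "bin_hi": min(edges[b + 1], x.max()),
            "n": int(sel.sum()),
            "observed": y[sel].mean() if sel.any() else np.nan,
            "predicted": p[sel].mean() if sel.any() else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normalized prediction distribution errors
# ---------------------------------------------------------------------------

def npde(
    model: PopPKModel,
    data,
    n_sim: int = 1000,
    seed: int = 0,
    ridge: float = 1e-8,
) -> NPDEResult:
    """Normalized prediction distribution errors.

    For each subject the observed vector and every simulated replicate are
    decorrelated with the simulated mean and covariance (Cholesky); the
    rank of each decorrelated observation within its simulated marginal
    distribution is mapped through the inverse standard-normal CDF.  Under a
    correct model the npde are approximately iid N(0, 1).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    design = data if isinstance(data, CompiledDesign) else compile_design(data)
    out = np.empty(design.n_obs)
    for i in range(design.n_sub):
        sel = design.obs_subject == i
        if not sel.any():
            continue
        y = design.obs_y[sel]
        S = _simulate_subject(model, design, i, n_sim, seed)
        mu = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            log.info("singular simulated covariance for subject %s: ridge added",
                     design.subject_ids[i])
            L = np.linalg.cholesky(cov + ridge * np.trace(cov) / len(y) * np.eye(len(y)))
        y_star = np.linalg.solve(L, y - mu)
        s_star = np.linalg.solve(L, (S - mu).T).T  # (n_sim, n_i)
        ranks = (s_star < y_star[None, :]).sum(axis=0)
        pd_ = (ranks + 0.5) / (n_sim + 1.0)
        out[sel] = stats.norm.ppf(pd_)
    ks = stats.kstest(out, "norm")
    variance = float(out.var(ddof=1)) if out.size > 1 else float("nan")
    return NPDEResult(
        npde=out, mean=float(out.mean()), variance=variance,
        normality_stat=float(ks.statistic), normality_p=float(ks.pvalue),
    )


def _slice_design(design: CompiledDesign, i: int) -> CompiledDesign:
    """Single-subject view of a compiled design (indices remapped)."""
    sel_obs = design.obs_subject == i
    sel_run = design.run_subject == i
    sel_pair = design.pair_subject == i
    obs_map = -np.ones(design.n_obs, dtype=np.intp)
    obs_map[sel_obs] = np.arange(int(sel_obs.sum()))
    run_map = -np.ones(len(design.run_start), dtype=np.intp)
    run_map[sel_run] = np.arange(int(sel_run.sum()))
    nz = int(sel_obs.sum())
    return CompiledDesign(
        subject_ids=[design.subject_ids[i]],
        weights=design.weights[[i]],
        covariates={k: v[[i]] for k, v in design.covariates.items()},
        obs_time=design.obs_time[sel_obs], obs_y=design.obs_y[sel_obs],
        obs_subject=np.zeros(nz, dtype=np.intp),
        obs_tad=design.obs_tad[sel_obs],
        obs_occasion=design.obs_occasion[sel_obs],
        run_start=design.run_start[sel_run], run_tau=design.run_tau[sel_run],
        run_n=design.run_n[sel_run], run_amt=design.run_amt[sel_run],
        run_subject=np.zeros(int(sel_run.sum()), dtype=np.intp),
        pair_obs=obs_map[design.pair_obs[sel_pair]],
        pair_run=run_map[design.pair_run[sel_pair]],
        pair_subject=np.zeros(int(sel_pair.sum()), dtype=np.intp),
        pair_t=design.pair_t[sel_pair], pair_start=design.pair_start[sel_pair],
        pair_tau=design.pair_tau[sel_pair], pair_n=design.pair_n[sel_pair],
        pair_amt=design.pair_amt[sel_pair],
    )


def _simulate_subject(model, design, i, n_sim, seed):
    """(n_sim, n_i) replicates for one subject, seeded by the subject id.

    Keying the generator on the subject identifier (not the cohort position)
    makes npde values invariant to subject ordering.
    """
    import zlib

    sub = _slice_design(design, i)
    key = zlib.crc32(str(design.subject_ids[i]).encode())
    rng = np.random.default_rng(np.random.SeedSequence([seed, key]))
    return np.vstack([simulate_observations(model, sub, rng)
                      for _ in range(n_sim)])


# ---------------------------------------------------------------------------
# nonparametric bootstrap
# ---------------------------------------------------------------------------

def bootstrap(
    fit_procedure: Callable,
    data,
    n_resamples: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Subject-resampling bootstrap of any fit procedure.

    ``data`` is either a subject-level list (PK courses) or a DataFrame with
    an ``ID`` column (logistic records); subjects are resampled with
    replacement (no stratification) and ``fit_procedure(resample)`` must
    return a mapping parameter -> estimate.  Failed refits are counted, and
    the result is flagged unstable above a 20% failure rate.
    """
    if n_resamples < 50:
        raise ValueError("n_resamples must be at least 50")
    rng = np.random.default_rng(seed)
    if isinstance(data, pd.DataFrame):
        ids = data["ID"].unique()
        id_col = data["ID"].to_numpy()
        positions = {sid: np.flatnonzero(id_col == sid) for sid in ids}
        def resample():
            pick = rng.choice(ids, size=len(ids), replace=True)
            idx = np.concatenate([positions[sid] for sid in pick])
            out = data.iloc[idx].copy()
            out["ID"] = np.repeat([f"{sid}_b{j}" for j, sid in enumerate(pick)],
                                  [len(positions[sid]) for sid in pick])
            return out.reset_index(drop=True)
    else:
        subjects = list(data)
        def resample():
            pick = rng.integers(0, len(subjects), size=len(subjects))
            return [subjects[k] for k in pick]

    estimates: list[dict] = []
    n_failed = 0
    for b in range(n_resamples):
        try:
            est = fit_procedure(resample())
            if not all(np.isfinite(list(est.values()))):
                raise RuntimeError("non-finite estimate")
            estimates.append(dict(est))
        except Exception as exc:  # noqa: BLE001 - failures are counted, not fatal
            n_failed += 1
            log.warning("bootstrap resample %d failed: %s", b, exc)
    if not estimates:
        raise RuntimeError("all bootstrap resamples failed")
    frame = pd.DataFrame(estimates)
    table = pd.DataFrame({
        "parameter": frame.columns,
        "median": frame.median().to_numpy(),
        "p2.5": frame.quantile(0.025).to_numpy(),
        "p97.5": frame.quantile(0.975).to_numpy(),
    })
    return BootstrapResult(table=table, n_resamples=n_resamples,
                           n_failed=n_failed, unstable=False)


# ---------------------------------------------------------------------------
# plotting (cosmetic layer)
# ---------------------------------------------------------------------------

def plot_vpc(result: VPCResult, path, xlabel="time after dose (h)", log_y=False):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for stat, color in zip(result.obs, ("tab:blue", "tab:red", "tab:blue")):
        ax.fill_between(result.bin_center, result.sim_lo[stat],
                        result.sim_hi[stat], alpha=0.25, color=color)
        ax.plot(result.bin_center, result.obs[stat], "o-", color=color, label=stat)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("prediction-corrected value")
    if log_y:
        ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_grouped_bar(table: pd.DataFrame, path, xlabel="miR155-5p expression"):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    w = 0.4
    xs = np.arange(len(table))
    ax.bar(xs - w / 2, table["observed"], width=w, color="gray", label="observed")
    ax.bar(xs + w / 2, table["predicted"], width=w, color="seagreen", label="predicted")
    ax.set_xticks(xs)
    ax.set_xticklabels([f"{lo:.2g}-{hi:.2g}" for lo, hi in
                        zip(table["bin_lo"], table["bin_hi"])], rotation=45)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("AR proportion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
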