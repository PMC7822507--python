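"""Model-evaluation machinery: VPCs, npde, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from graftrisk.diagnostics import (
    bootstrap,
    categorical_vpc,
    grouped_bar,
    npde,
    pcvpc,
)
from graftrisk.nlme_fit import compile_design
from graftrisk.rejection_logit import LogisticFit, fit_logistic

from conftest import make_small_model, simulate_small


def logistic_records(n, beta0=-2.0, beta1=2.5, seed=0):
    rng = np.random.default_rng(seed)
    x = np.exp(rng.normal(-0.7, 0.9, n)).clip(max=3.0)
    y = (rng.random(n) < expit(beta0 + beta1 * x)).astype(int)
    return pd.DataFrame({"ID": [f"S{i}" for i in range(n)], "MIR155": x,
                         "AR": y})


# ---------------------------------------------------------------------------
# prediction-corrected VPC
# ---------------------------------------------------------------------------

class TestPcvpc:
    def test_self_consistency(self, tac_truth, trial):
        res = pcvpc(tac_truth, trial.tac_courses, n_sim=200, seed=3)
        cov = res.coverage()
        # observed percentiles of self-simulated data sit inside the bands
        assert cov["p50"] >= 0.9
        assert (cov["p2.5"] + cov["p50"] + cov["p97.5"]) / 3 >= 0.8

    def test_band_ordering_invariant(self, tac_truth, trial):
        res = pcvpc(tac_truth, trial.tac_courses, n_sim=150, seed=4)
        assert np.all(res.sim_median["p2.5"] <= res.sim_median["p50"] + 1e-12)
        assert np.all(res.sim_median["p50"] <= res.sim_median["p97.5"] + 1e-12)
        assert res.n_sim == 150

    def test_detects_halved_clearance(self, tac_truth, trial):
        from dataclasses import replace
        wrong = replace(tac_truth,
                        typical=replace(tac_truth.typical, cl=tac_truth.typical.cl / 2))
        res = pcvpc(wrong, trial.tac_courses, n_sim=150, seed=5)
        med = res.obs["p50"]
        outside = (med < res.sim_lo["p50"]) | (med > res.sim_hi["p50"])
        assert outside.sum() >= 1

    def test_reproducible_given_seed(self, tac_truth, trial):
        a = pcvpc(tac_truth, trial.tac_courses, n_sim=60, seed=9)
        b = pcvpc(tac_truth, trial.tac_courses, n_sim=60, seed=9)
        np.testing.assert_array_equal(a.sim_lo["p50"], b.sim_lo["p50"])

    def test_identity_correction_when_predictions_equal(self):
        # identical subjects sampled at one time point per bin: population
        # predictions are constant within each bin, so the prediction
        # correction must be the identity
        model = make_small_model(omega_cl=0.2**2)
        courses, _ = simulate_small(model, 8, seed=6, rich=False)
        for c in courses:
            c.weight = 70.0
        design = compile_design(courses)
        res = pcvpc(model, design, n_sim=80, bins=2, seed=7)
        obs = design.obs_y
        tad = design.obs_tad
        edges = res.bin_edges
        idx = np.clip(np.digitize(tad, edges) - 1, 0, len(edges) - 2)
        for b_ in range(len(edges) - 1):
            sel = idx == b_
            assert len(np.unique(tad[sel])) == 1
            assert res.obs["p50"][b_] == pytest.approx(
                np.percentile(obs[sel], 50), rel=1e-9)


# ---------------------------------------------------------------------------
# categorical VPC and grouped bars
# ---------------------------------------------------------------------------

class TestCategoricalVpc:
    def test_flat_when_slope_zero(self):
        records = logistic_records(600, seed=1)
        fit = LogisticFit(beta0=-1.5, betas={"MIR155": 0.0}, se={}, mofv=np.nan)
        res = categorical_vpc(fit, records, n_sim=300, seed=2)
        med = res.sim_median["proportion"]
        assert np.nanmax(med) - np.nanmin(med) < 0.08
        assert np.nanmean(med) == pytest.approx(expit(-1.5), abs=0.05)

    def test_self_consistency(self):
        records = logistic_records(500, seed=3)
        fit = fit_logistic(records, ["MIR155"])
        res = categorical_vpc(fit, records, n_sim=400, seed=4)
        assert res.coverage()["proportion"] >= 0.9

    def test_monotone_trend_with_positive_slope(self):
        records = logistic_records(2000, seed=5)
        fit = LogisticFit(beta0=-2.0, betas={"MIR155": 2.5}, se={}, mofv=np.nan)
        res = categorical_vpc(fit, records, n_sim=300, n_bins=5, seed=6)
        med = res.sim_median["proportion"]
        assert np.all(np.diff(med[~np.isnan(med)]) > -0.02)


class TestGroupedBar:
    def test_partition_covers_range_contiguously(self):
        records = logistic_records(400, seed=7)
        fit = fit_logistic(records, ["MIR155"])
        table = grouped_bar(fit, records)
        assert len(table) == 10
        assert table.bin_lo.iloc[0] == pytest.approx(records.MIR155.min())
        assert table.bin_hi.iloc[-1] == pytest.approx(records.MIR155.max())
        np.testing.assert_allclose(table.bin_lo.iloc[1:], table.bin_hi.iloc[:-1],
                                   rtol=1e-9, atol=1e-9)

    def test_all_zero_outcomes_give_zero_observed_bars(self):
        records = logistic_records(200, seed=8)
        records["AR"] = 0
        fit = LogisticFit(beta0=-3.0, betas={"MIR155": 1.0}, se={}, mofv=np.nan)
        table = grouped_bar(fit, records)
        filled = table.dropna(subset=["observed"])
        assert (filled.observed == 0).all()

    def test_calibration_at_large_n(self):
        # outcomes drawn from the model's own risk: observed and predicted
        # proportions agree within 3 binomial SEs in every bin
        rng = np.random.default_rng(9)
        n = 20000
        x = rng.uniform(0.0, 2.5, n)
        fit = LogisticFit(beta0=-2.5, betas={"MIR155": 2.0}, se={}, mofv=np.nan)
        p = expit(-2.5 + 2.0 * x)
        records = pd.DataFrame({"ID": np.arange(n).astype(str), "MIR155": x,
                                "AR": (rng.random(n) < p).astype(int)})
        table = grouped_bar(fit, records)
        for _, row in table.dropna().iterrows():
            se = np.sqrt(max(row.predicted * (1 - row.predicted), 1e-6) / row.n)
            assert abs(row.observed - row.predicted) <= 3 * se + 1e-9


# ---------------------------------------------------------------------------
# npde
# ---------------------------------------------------------------------------

class TestNpde:
    def test_standard_normal_under_correct_model(self, tac_truth, trial):
        res = npde(tac_truth, trial.tac_courses, n_sim=400, seed=10)
        assert abs(res.mean) < 0.1
        assert 0.85 < res.variance < 1.15

    def test_detects_inflated_residual_error(self, tac_truth, trial):
        from dataclasses import replace
        inflated = replace(tac_truth,
                           residual=replace(tac_truth.residual,
                                            sigma=2 * tac_truth.residual.sigma))
        res = npde(inflated, trial.tac_courses, n_sim=300, seed=11)
        assert res.variance < 0.7

    def test_single_observation_subject_reduces_to_rank_score(self, tac_truth):
        from graftrisk.dataio import SubjectCourse
        from graftrisk.pk_model import ConcObservation, DoseEvent
        course = SubjectCourse(
            "solo", 70.0, [DoseEvent("solo", 0.0, 5.0)],
            [ConcObservation("solo", 13.0, 8.0)])
        res = npde(tac_truth, [course], n_sim=200, seed=12)
        assert res.npde.shape == (1,)
        assert np.isfinite(res.npde[0])

    def test_invariant_to_subject_order(self, tac_truth, trial):
        courses = trial.tac_courses
        a = npde(tac_truth, courses, n_sim=150, seed=13)
        order = np.random.default_rng(0).permutation(len(courses))
        b = npde(tac_truth, [courses[i] for i in order], n_sim=150, seed=13)
        # map b's values back to a's observation order
        design_a = compile_design(courses)
        design_b = compile_design([courses[i] for i in order])
        for subj in (0, 5, 17):
            sid = design_a.subject_ids[subj]
            j = design_b.subject_ids.index(sid)
            np.testing.assert_allclose(
                a.npde[design_a.obs_subject == subj],
                b.npde[design_b.obs_subject == j])

    def test_minimum_simulation_count_enforced(self, tac_truth, trial):
        with pytest.raises(ValueError):
            npde(tac_truth, trial.tac_courses, n_sim=50)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_degenerate_single_profile_zero_width(self):
        records = logistic_records(40, seed=14)
        records["ID"] = "same"  # one subject: every resample is identical
        def refit(df):
            f = fit_logistic(df, ["MIR155"])
            return {"beta0": f.beta0, "beta1": f.betas["MIR155"]}
        res = bootstrap(refit, records, n_resamples=50, seed=15)
        width = res.table["p97.5"] - res.table["p2.5"]
        assert np.all(width.abs() < 1e-9)

    def test_logistic_bootstrap_median_near_point_estimate(self):
        records = logistic_records(400, seed=16)
        point = fit_logistic(records, ["MIR155"])
        def refit(df):
            f = fit_logistic(df, ["MIR155"])
            return {"beta0": f.beta0, "beta1": f.betas["MIR155"]}
        res = bootstrap(refit, records, n_resamples=200, seed=17)
        med = res.table.set_index("parameter")["median"]
        assert med["beta1"] == pytest.approx(point.betas["MIR155"], rel=0.15)
        assert res.n_failed <= 0.2 * res.n_resamples and not res.unstable

    def test_interval_width_shrinks_with_sample_size(self):
        def width_at(n, seed):
            records = logistic_records(n, seed=seed)
            def refit(df):
                f = fit_logistic(df, ["MIR155"])
                return {"beta1": f.betas["MIR155"]}
            res = bootstrap(refit, records, n_resamples=120, seed=seed)
            return float(res.table["p97.5"].iloc[0] - res.table["p2.5"].iloc[0])
        assert width_at(1600, 18) < width_at(400, 19)

    def test_minimum_resamples_enforced(self):
        with pytest.raises(ValueError):
            bootstrap(lambda d: {"x": 1.0}, logistic_records(50), n_resamples=10)

    def test_failures_counted_and_flagged(self):
        records = logistic_records(60, seed=20)
        calls = {"n": 0}
        def flaky(df):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            f = fit_logistic(df, ["MIR155"])
            return {"beta1": f.betas["MIR155"]}
        res = bootstrap(flaky, records, n_resamples=60, seed=21)
        assert res.n_failed >= 15
        assert res.unstable
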