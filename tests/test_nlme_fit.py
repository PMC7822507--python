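"""Mixed-effects machinery: likelihood, EBEs, shrinkage, selection, diagnostics."""

import numpy as np
import pytest
from scipy import optimize

from graftrisk.dataio import SubjectCourse
from graftrisk.nlme_fit import (
    CovariateEffect,
    PopPKModel,
    RandomEffectsSpec,
    ResidualSpec,
    compile_design,
    condition_number,
    ebe,
    fit_pop,
    individual_params,
    lrt_threshold,
    neg2ll,
    pooled_init,
    residual_diagnostics,
    shrinkage,
    simulate_observations,
    stepwise_covariates,
)
from graftrisk.pk_model import ConcObservation, DoseEvent, StructuralParams

from conftest import make_small_courses, make_small_model, simulate_small


# ---------------------------------------------------------------------------
# individual parameters
# ---------------------------------------------------------------------------

class TestIndividualParams:
    def test_zero_eta_reference_weight_gives_typicals(self, tac_truth):
        p = individual_params(tac_truth, np.zeros(3), 70.0)
        assert p.cl == pytest.approx(16.5) and p.vc == pytest.approx(311.0)

    def test_log2_eta_doubles_clearance(self, tac_truth):
        eta = np.array([np.log(2.0), 0.0, 0.0])  # labels: cl, q, vc
        p = individual_params(tac_truth, eta, 70.0)
        assert p.cl == pytest.approx(33.0)

    def test_ratio_distribution_matches_omega(self, mpa_truth):
        # log(individual/typical) of the random-effect parameters is normal
        # with the specified covariance (Monte-Carlo moment check)
        rng = np.random.default_rng(5)
        n = 100_000
        L = np.linalg.cholesky(mpa_truth.random.omega)
        etas = rng.standard_normal((n, 3)) @ L.T
        # exponential model: the log-ratio IS eta, so check sample covariance
        cov = np.cov(etas, rowvar=False)
        np.testing.assert_allclose(cov, mpa_truth.random.omega, atol=0.03)

    def test_eta_length_must_match(self, tac_truth):
        with pytest.raises(ValueError):
            individual_params(tac_truth, np.zeros(2), 70.0)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def gauss_hermite_neg2ll(model, courses, n_nodes=120):
    """Exact marginal -2LL for a single-random-effect model by quadrature."""
    from graftrisk.nlme_fit import (_base_struct, _moments, _obs_transform,
                                    _predict_eta, PARAM_NAMES)

    design = compile_design(courses)
    base = _base_struct(model, design)
    label_idx = np.array([PARAM_NAMES.index(l) for l in model.random.labels])
    omega = float(model.random.omega[0, 0])
    z = _obs_transform(model.residual.kind, design.obs_y)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    total = 0.0
    for i in range(design.n_sub):
        sel = design.obs_subject == i
        logls = []
        for x in nodes:
            eta = np.zeros((design.n_sub, 1))
            eta[i, 0] = x * np.sqrt(omega)
            f = _predict_eta(design, base, label_idx, eta, model.conc_scale)
            mz, v = _moments(model.residual.kind, f[sel],
                             model.residual.sigma, model.residual.sigma2)
            r = z[sel] - mz
            logls.append(-0.5 * np.sum(r * r / v + np.log(2 * np.pi * v)))
        logls = np.array(logls)
        m = logls.max()
        total += -2.0 * (np.log(np.sum(weights * np.exp(logls - m)))
                         + m - 0.5 * np.log(2 * np.pi))
    return total


class TestNeg2ll:
    def test_matches_fixed_effects_likelihood_without_random_effects(self):
        model = make_small_model()
        model = PopPKModel(model.typical,
                           RandomEffectsSpec((), np.zeros((0, 0))),
                           model.residual)
        courses, design = simulate_small(make_small_model(), 6, seed=1)
        from graftrisk.nlme_fit import _base_struct, _predict_struct
        f = _predict_struct(design, _base_struct(model, design))
        z = np.log(design.obs_y)
        sig = model.residual.sigma
        expected = float(np.sum((z - np.log(f)) ** 2 / sig**2
                                + np.log(2 * np.pi * sig**2)))
        assert neg2ll(model, design) == pytest.approx(expected, rel=1e-10)

    def test_laplace_exact_in_small_variance_limit(self):
        # with a single random effect of tiny variance the conditional density
        # is effectively Gaussian, so the mode-based approximation must agree
        # with exact Gauss-Hermite quadrature to high accuracy
        model = make_small_model(omega_cl=0.001**2, sigma=0.15)
        courses, _ = simulate_small(model, 5, seed=2)
        approx = neg2ll(model, courses)
        exact = gauss_hermite_neg2ll(model, courses)
        assert approx == pytest.approx(exact, abs=1e-4)

    def test_laplace_close_at_moderate_variance(self):
        model = make_small_model(omega_cl=0.3**2, sigma=0.15)
        courses, _ = simulate_small(model, 5, seed=3)
        approx = neg2ll(model, courses)
        exact = gauss_hermite_neg2ll(model, courses)
        assert approx == pytest.approx(exact, rel=2e-3)

    def test_additive_over_subjects(self):
        model = make_small_model()
        courses, _ = simulate_small(model, 4, seed=4)
        doubled = []
        for k, c in enumerate(courses + courses):
            doubled.append(SubjectCourse(f"D{k}", c.weight, list(c.doses),
                                         list(c.observations), dict(c.covariates)))
        assert neg2ll(model, doubled) == pytest.approx(
            2.0 * neg2ll(model, courses), rel=1e-9)

    def test_requires_observations(self):
        model = make_small_model()
        empty = SubjectCourse("E", 70.0, [DoseEvent("E", 0.0, 5.0)], [])
        with pytest.raises(ValueError):
            neg2ll(model, [empty])


# ---------------------------------------------------------------------------
# empirical Bayes estimates
# ---------------------------------------------------------------------------

class TestEbe:
    def test_no_observations_gives_prior_mode(self):
        model = make_small_model()
        subject = SubjectCourse("E", 70.0, [DoseEvent("E", 0.0, 5.0)], [])
        np.testing.assert_array_equal(ebe(model, subject), np.zeros(1))

    def test_vanishing_omega_shrinks_to_zero(self):
        courses, _ = simulate_small(make_small_model(), 1, seed=6)
        tiny = make_small_model(omega_cl=1e-8)
        assert abs(ebe(tiny, courses[0])[0]) < 1e-3

    def test_recovers_simulated_eta_on_rich_design(self):
        model = make_small_model(omega_cl=0.5**2, sigma=0.08)
        rng = np.random.default_rng(7)
        courses = make_small_courses(60, rng)
        design = compile_design(courses)
        y, eta_true = simulate_observations(model, design, rng, return_eta=True)
        k = 0
        errs = []
        for i, c in enumerate(courses):
            new = []
            for o in c.observations:
                new.append(ConcObservation(o.subject_id, o.time, float(y[k])))
                k += 1
            c.observations = new
            est = ebe(model, c)[0]
            if abs(eta_true[i, 0]) > 0.05:
                errs.append(abs(est - eta_true[i, 0]) / abs(eta_true[i, 0]))
        assert np.median(errs) < 0.10

    def test_requires_random_effects(self):
        model = make_small_model()
        model = PopPKModel(model.typical, RandomEffectsSpec((), np.zeros((0, 0))),
                           model.residual)
        with pytest.raises(ValueError):
            ebe(model, SubjectCourse("E", 70.0, [], []))


# ---------------------------------------------------------------------------
# likelihood-ratio thresholds and conditioning
# ---------------------------------------------------------------------------

class TestLrtThreshold:
    @pytest.mark.parametrize("alpha, expected", [(0.05, 3.841), (0.005, 7.879),
                                                 (0.001, 10.828)])
    def test_chi_square_cutoffs(self, alpha, expected):
        assert lrt_threshold(1, alpha) == pytest.approx(expected, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lrt_threshold(0, 0.05)
        with pytest.raises(ValueError):
            lrt_threshold(1, 1.5)


class TestConditionNumber:
    def test_identity_is_one(self):
        assert condition_number(np.eye(3)) == pytest.approx(1.0)

    def test_eigenvalue_ratio(self):
        assert condition_number(np.diag([100.0, 1.0])) == pytest.approx(100.0)

    def test_singular_is_infinite(self):
        assert condition_number(np.diag([1.0, 0.0])) == np.inf


# ---------------------------------------------------------------------------
# population fit
# ---------------------------------------------------------------------------

class TestFitPop:
    def test_reduces_to_least_squares_without_random_effects(self):
        truth = make_small_model(omega_cl=1e-12, sigma=0.05)
        courses, design = simulate_small(truth, 1, seed=8)
        fixed = PopPKModel(truth.typical, RandomEffectsSpec((), np.zeros((0, 0))),
                           ResidualSpec("additive_log", 0.05))
        fit = fit_pop(fixed, design, compute_se=False)

        # independent oracle: with sigma fixed and no hierarchy the fit is a
        # log-scale nonlinear least-squares problem; a derivative-free
        # minimization of the same fixed-effects objective must not beat it
        def mofv_of(x):
            p = StructuralParams(*np.exp(x))
            model = PopPKModel(p, RandomEffectsSpec((), np.zeros((0, 0))),
                               ResidualSpec("additive_log", 0.05))
            return neg2ll(model, design)

        res = optimize.minimize(mofv_of, np.log(truth.typical.as_array()),
                                method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-9,
                                         "fatol": 1e-10})
        assert fit.mofv <= res.fun + 0.2

    def test_basin_stability_from_perturbed_init(self):
        truth = make_small_model(omega_cl=0.25**2, sigma=0.08)
        courses, design = simulate_small(truth, 24, seed=9)
        fit_a = fit_pop(truth, design, compute_se=False)
        shaken = PopPKModel(
            StructuralParams(truth.typical.cl * 1.5, truth.typical.vc * 0.7,
                             truth.typical.q * 1.4, truth.typical.vp * 0.6,
                             truth.typical.ka * 1.3, truth.typical.tlag),
            truth.random, truth.residual)
        fit_b = fit_pop(shaken, design, compute_se=False)
        assert fit_b.model.typical.cl == pytest.approx(fit_a.model.typical.cl,
                                                       rel=0.01)

    def test_mofv_does_not_increase_from_init(self):
        truth = make_small_model()
        courses, design = simulate_small(truth, 8, seed=10)
        f0 = neg2ll(truth, design)
        fit = fit_pop(truth, design, compute_se=False)
        assert fit.mofv <= f0 + 1e-6

    def test_invariant_to_subject_relabelling(self):
        # floating-point summation order differs between subject orderings,
        # so endpoints agree to optimizer precision rather than bit-for-bit
        truth = make_small_model(omega_cl=0.2**2, sigma=0.08)
        courses, _ = simulate_small(truth, 12, seed=12)
        fit1 = fit_pop(truth, courses, compute_se=False)
        order = [3, 1, 4, 0, 9, 2, 7, 5, 8, 6, 11, 10]
        shuffled = [courses[i] for i in order]
        fit2 = fit_pop(truth, shuffled, compute_se=False)
        assert fit2.model.typical.cl == pytest.approx(fit1.model.typical.cl,
                                                      rel=0.01)
        assert fit2.mofv == pytest.approx(fit1.mofv, abs=0.5)
        # BSV% agrees as well
        bsv1 = np.sqrt(fit1.model.random.omega[0, 0])
        bsv2 = np.sqrt(fit2.model.random.omega[0, 0])
        assert bsv2 == pytest.approx(bsv1, rel=0.05)

    def test_precision_and_conditioning_reported(self):
        truth = make_small_model(omega_cl=0.3**2, sigma=0.12)
        courses, design = simulate_small(truth, 12, seed=13)
        fit = fit_pop(truth, design, compute_se=True)
        assert fit.rse is not None and fit.covariance is not None
        assert fit.rse["cl"] > 0
        assert fit.condition_number >= 1.0
        table = fit.to_table()
        assert {"parameter", "estimate", "rse_pct", "shrinkage_pct"} <= set(table)


# ---------------------------------------------------------------------------
# shrinkage
# ---------------------------------------------------------------------------

class TestShrinkage:
    def _fit(self, rich, seed=14, n=12):
        truth = make_small_model(omega_cl=0.3**2, sigma=0.25)
        courses, design = simulate_small(truth, n, seed=seed, rich=rich)
        return fit_pop(truth, design, compute_se=False, max_iter=40)

    def test_sparser_design_shrinks_more(self):
        rich = self._fit(rich=True)
        sparse = self._fit(rich=False)
        assert sparse.eta_shrinkage["cl"] > rich.eta_shrinkage["cl"]

    def test_all_zero_ebes_is_full_shrinkage(self):
        fit = self._fit(rich=True)
        fit.ebes = np.zeros_like(fit.ebes)
        omega = np.sqrt(fit.model.random.omega[0, 0])
        sd = np.std(fit.ebes[:, 0], ddof=1)
        assert 100.0 * (1.0 - sd / omega) == pytest.approx(100.0)

    def test_shrinkage_accessor(self):
        fit = self._fit(rich=True)
        out = shrinkage(fit)
        assert set(out) == {"eta", "eps"}
        assert -30.0 < out["eta"]["cl"] < 100.0


# ---------------------------------------------------------------------------
# covariate machinery
# ---------------------------------------------------------------------------

class TestStepwiseCovariates:
    def test_empty_candidates_keep_base(self):
        truth = make_small_model(omega_cl=0.2**2)
        courses, design = simulate_small(truth, 8, seed=15)
        fit, trace = stepwise_covariates(truth, design, [], max_iter=40)
        assert fit.model.covariate_effects == ()
        assert trace == []

    def test_null_covariate_rarely_retained(self):
        # type-I control: data carry no covariate effect, so the forward step
        # at alpha=0.05 should retain the candidate in roughly 1 in 20 runs
        truth = make_small_model(omega_cl=0.25**2, sigma=0.15)
        retained = 0
        n_rep = 8
        for rep in range(n_rep):
            courses, design = simulate_small(truth, 10, seed=100 + rep)
            fit, _ = stepwise_covariates(
                truth, design, [("cl", "GFR", "power")], max_iter=40)
            retained += bool(fit.model.covariate_effects)
        assert retained <= 2  # P(X >= 3 | n=8, p~0.05) < 1%

    def test_strong_covariate_effect_detected(self):
        truth = make_small_model(omega_cl=0.15**2, sigma=0.12)
        detected = 0
        n_rep = 5
        for rep in range(n_rep):
            rng = np.random.default_rng(200 + rep)
            courses = make_small_courses(12, rng)
            # inject a strong GFR power effect on CL into the generator
            gen = PopPKModel(truth.typical, truth.random, truth.residual,
                             covariate_effects=(CovariateEffect(
                                 "cl", "GFR", "power", theta=0.8,
                                 reference=50.0),))
            design = compile_design(courses)
            y = simulate_observations(gen, design, rng)
            k = 0
            for c in courses:
                new = []
                for o in c.observations:
                    new.append(ConcObservation(o.subject_id, o.time, float(y[k])))
                    k += 1
                c.observations = new
            fit, trace = stepwise_covariates(
                truth, compile_design(courses), [("cl", "GFR", "power")],
                max_iter=40)
            detected += bool(fit.model.covariate_effects)
        assert detected >= 4

    def test_lrt_consistency_of_trace(self):
        truth = make_small_model(omega_cl=0.2**2)
        courses, design = simulate_small(truth, 10, seed=16)
        _, trace = stepwise_covariates(truth, design,
                                       [("cl", "AGE", "exponential")],
                                       max_iter=40)
        tested = [t for t in trace if t["status"] in ("tested", "included")]
        assert tested and all(np.isfinite(t["delta_mofv"]) for t in tested)


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------

class TestResidualDiagnostics:
    def test_zero_noise_gives_zero_iwres(self):
        truth = make_small_model(omega_cl=0.2**2, sigma=1e-6)
        rng = np.random.default_rng(17)
        courses = make_small_courses(5, rng)
        design = compile_design(courses)
        y, eta = simulate_observations(truth, design, rng, return_eta=True)
        k = 0
        for c in courses:
            new = []
            for o in c.observations:
                new.append(ConcObservation(o.subject_id, o.time, float(y[k])))
                k += 1
            c.observations = new
        fit = fit_pop(truth, compile_design(courses), compute_se=False,
                      max_iter=30)
        table = residual_diagnostics(fit)
        assert np.max(np.abs(table["IWRES"])) < 0.05

    def test_cwres_calibrated_on_self_simulated_data(self, tac_truth, trial):
        # fitting is not needed for calibration: evaluate at the generating
        # model, where CWRES should be approximately standard normal
        from graftrisk.nlme_fit import PopFitResult, _base_struct
        from graftrisk.nlme_fit import _inner_foce, _obs_transform, PARAM_NAMES

        design = compile_design(trial.tac_courses)
        base = _base_struct(tac_truth, design)
        z = _obs_transform("additive_log", design.obs_y)
        li = np.array([PARAM_NAMES.index(l) for l in tac_truth.random.labels])
        ebes, _, _, _ = _inner_foce(design, base, li, tac_truth.random.omega,
                                    z, "additive_log", tac_truth.residual.sigma,
                                    0.0, scale=tac_truth.conc_scale)
        fit = PopFitResult(model=tac_truth, mofv=0.0, ebes=ebes,
                           eta_shrinkage={}, eps_shrinkage=0.0, converged=True,
                           n_iter=0, param_names=[], estimates=np.zeros(1),
                           design=design)
        table = residual_diagnostics(fit)
        cwres = table["CWRES"].to_numpy()
        assert abs(cwres.mean()) < 0.1
        assert 0.85 < cwres.std(ddof=1) < 1.15

    def test_misspecified_model_inflates_cwres(self, tac_truth, trial):
        from graftrisk.nlme_fit import PopFitResult, _base_struct
        from graftrisk.nlme_fit import _inner_foce, _obs_transform, PARAM_NAMES
        from dataclasses import replace as dc_replace

        design = compile_design(trial.tac_courses)

        def mean_abs_cwres(model):
            base = _base_struct(model, design)
            z = _obs_transform("additive_log", design.obs_y)
            li = np.array([PARAM_NAMES.index(l) for l in model.random.labels])
            ebes, _, _, _ = _inner_foce(design, base, li, model.random.omega,
                                        z, "additive_log",
                                        model.residual.sigma, 0.0,
                                        scale=model.conc_scale)
            fit = PopFitResult(model=model, mofv=0.0, ebes=ebes,
                               eta_shrinkage={}, eps_shrinkage=0.0,
                               converged=True, n_iter=0, param_names=[],
                               estimates=np.zeros(1), design=design)
            return np.abs(residual_diagnostics(fit)["CWRES"]).mean()

        # a one-compartment-like misspecification: collapse the peripheral
        # compartment (tiny Vp and Q)
        wrong = dc_replace(tac_truth, typical=dc_replace(
            tac_truth.typical, vp=1.0, q=0.01))
        assert mean_abs_cwres(wrong) > 1.1 * mean_abs_cwres(tac_truth)


class TestOmegaStructure:
    def test_correlated_ebes_flagged_for_block_omega(self):
        from graftrisk.nlme_fit import ebe_correlation_screen

        truth = make_small_model(omega_cl=0.2**2)
        courses, design = simulate_small(truth, 10, seed=30)
        fit = fit_pop(truth, design, compute_se=False, max_iter=30)
        # single effect: nothing to screen
        assert ebe_correlation_screen(fit) == []
        # synthetic two-effect EBEs with strong correlation
        rng = np.random.default_rng(0)
        e1 = rng.standard_normal(40)
        fit.ebes = np.column_stack([e1, 0.9 * e1 + 0.1 * rng.standard_normal(40)])
        from dataclasses import replace as dc_replace
        fit.model = dc_replace(
            fit.model, random=RandomEffectsSpec.diagonal(cl=0.04, vc=0.04))
        pairs = ebe_correlation_screen(fit)
        assert pairs and pairs[0][:2] == ("cl", "vc") and pairs[0][2] > 0.4

    def test_block_omega_round_trips_through_packer(self):
        from graftrisk.nlme_fit import _Packer

        om = np.array([[0.09, 0.03], [0.03, 0.16]])
        model = PopPKModel(
            make_small_model().typical,
            RandomEffectsSpec(("cl", "vc"), om, structure="block"),
            ResidualSpec("additive_log", 0.2))
        packer = _Packer(model)
        back = packer.unpack(packer.pack(model))
        np.testing.assert_allclose(back.random.omega, om, atol=1e-10)


class TestCombinedResidual:
    def test_combined_error_collapses_to_components(self):
        from graftrisk.nlme_fit import _moments

        f = np.array([1.0, 5.0, 20.0])
        _, v = _moments("combined", f, sigma=0.2, sigma2=0.5)
        np.testing.assert_allclose(v, (0.2 * f) ** 2 + 0.25)

    def test_neg2ll_finite_for_combined_model(self):
        truth = make_small_model(omega_cl=0.2**2)
        courses, design = simulate_small(truth, 4, seed=31)
        model = PopPKModel(truth.typical, truth.random,
                           ResidualSpec("combined", sigma=0.15, sigma2=0.05))
        val = neg2ll(model, design)
        assert np.isfinite(val)
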