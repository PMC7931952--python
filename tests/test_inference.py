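import math

import numpy as np
import pytest
from scipy import stats

from latentshift import (
    FitOptions,
    LongitudinalDataset,
    ModelSpec,
    Parameters,
    Subject,
    SubjectDesign,
    Visit,
    build_designs,
    count_df,
    effective_params,
    fit_ml,
    information_criteria,
    lme_step,
    nll_conditional,
    nll_exact_marginal,
    pnls_step,
)
from latentshift.covariance import VarianceParams, process_cov
from latentshift.inference import (
    FitError,
    _initialize,
    _laplace_neg2ll,
    _laplace_value_grad,
    _Work,
    exact_neg2ll,
)
from latentshift.simulate import SimulationConfig, default_true_parameters, simulate_dataset


# ---------------------------------------------------------------------------
# degrees of freedom and information criteria

class TestCriteria:
    def test_basic_model_df(self):
        assert count_df(ModelSpec()) == 12

    def test_treatment_on_stage_and_level_df(self):
        spec = ModelSpec(effects_on_s=("chei",), effects_on_v=("chei",))
        assert count_df(spec) == 14

    def test_biomarker_model_df(self):
        spec = ModelSpec(
            effects_on_s=("fdg", "hippo", "florbetapir", "abeta_ratio", "nfl"),
            effects_on_g=("age", "sex"),
            effects_on_v=("age", "sex", "education"),
        )
        assert count_df(spec) == 22

    def test_single_group_no_covariates_df(self):
        assert count_df(ModelSpec(group_levels=("cognitively normal",))) == 8

    @pytest.mark.parametrize(
        "neg2ll, df, n, aic, bic",
        [
            (59468.52, 12, 9830, 59492.52, 59578.84),
            (59277.59, 14, 9830, 59305.59, 59406.29),
            (15182.34, 22, 2614, 15226.34, 15355.45),
        ],
    )
    def test_printed_criterion_pairs(self, neg2ll, df, n, aic, bic):
        got_aic, got_bic = information_criteria(neg2ll, df, n)
        assert got_aic == pytest.approx(aic, abs=0.005)
        assert got_bic == pytest.approx(bic, abs=0.005)

    def test_zero_df_degenerate(self):
        assert information_criteria(0.0, 0, 100) == (0.0, 0.0)

    def test_natural_log_observation_count_convention(self):
        # both printed criteria must follow from one (df, N) convention;
        # log10 or N = subjects would break at least one of them
        aic, bic = information_criteria(59468.52, 12, 9830)
        assert bic - aic == pytest.approx((math.log(9830) - 2) * 12, abs=1e-9)
        _, bic_subjects = information_criteria(59468.52, 12, 2142)
        assert abs(bic_subjects - 59578.84) > 5


# ---------------------------------------------------------------------------
# effective parameters

class TestEffectiveParams:
    def test_reference_subject_is_population_curve(self, true_params):
        subj = Subject("r", "cognitively normal", {}, [Visit(0.0, 10.0)])
        design = SubjectDesign(np.zeros(4), np.zeros(0), np.zeros(0))
        l, g, v, d = effective_params(subj, true_params, design)
        assert (l, g, v, d) == (true_params.l, true_params.g, true_params.v, 0.0)

    def test_group_shift_lookup(self, true_params):
        subj = Subject("d", "dementia", {}, [Visit(0.0, 30.0)])
        design = SubjectDesign(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(0), np.zeros(0))
        _, _, _, d = effective_params(subj, true_params, design)
        assert d == 136.0

    def test_level_covariate_linearity(self, true_params):
        p = Parameters(
            l=true_params.l, g=true_params.g, v=true_params.v,
            beta_s=true_params.beta_s, beta_v=np.array([2.5]),
            variance=true_params.variance,
        )
        subj = Subject("x", "cognitively normal", {}, [Visit(0.0, 10.0)])
        d0 = SubjectDesign(np.zeros(4), np.zeros(0), np.array([1.0]))
        d1 = SubjectDesign(np.zeros(4), np.zeros(0), np.array([2.0]))
        v0 = effective_params(subj, p, d0)[2]
        v1 = effective_params(subj, p, d1)[2]
        assert v1 - v0 == pytest.approx(2.5)

    def test_dimension_mismatch_raises(self, true_params):
        subj = Subject("x", "dementia", {}, [Visit(0.0, 30.0)])
        with pytest.raises(ValueError, match="mismatch|match"):
            effective_params(subj, true_params,
                             SubjectDesign(np.zeros(2), np.zeros(0), np.zeros(0)))


# ---------------------------------------------------------------------------
# conditional and marginal likelihoods

def _flat_params(vp):
    return Parameters(l=0.0, g=0.0, v=12.0, beta_s=np.zeros(4), variance=vp)


class TestConditionalLikelihood:
    def test_flat_curve_closed_form(self):
        vp = VarianceParams(tau2=100.0, sigma2_bm=0.1, sigma2_0=2.0,
                            sigma2_eps=1.0, rho=0.0)
        subj = Subject("a", "cognitively normal", {},
                       [Visit(0.0, 11.0), Visit(6.0, 13.0), Visit(12.0, 12.5)])
        got = nll_conditional(subj, 0.0, _flat_params(vp))
        cov = process_cov(subj.times, vp)
        expected = -stats.multivariate_normal.logpdf(subj.scores, mean=np.full(3, 12.0),
                                                     cov=cov)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_matches_generic_density_oracle(self, true_params, rng):
        from latentshift.covariance import conditional_given_shift

        subj = Subject("b", "dementia", {},
                       [Visit(float(t), float(y)) for t, y in
                        zip([0.0, 6.0, 18.0], rng.normal(35, 5, 3))])
        design = SubjectDesign(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(0), np.zeros(0))
        s = 7.3
        got = nll_conditional(subj, s, true_params, design)
        offset, cov = conditional_given_shift(s, subj.times, true_params.variance)
        from latentshift.curves import theta, CurveParams

        mean = theta(subj.times + 136.0 + s,
                     CurveParams(true_params.l, true_params.g, true_params.v)) + offset
        expected = -stats.multivariate_normal.logpdf(subj.scores, mean=mean, cov=cov)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_noise_variance_changes_value(self, true_params):
        subj = Subject("c", "cognitively normal", {},
                       [Visit(0.0, 10.0), Visit(6.0, 11.0)])
        design = SubjectDesign(np.zeros(4), np.zeros(0), np.zeros(0))
        v1 = nll_conditional(subj, 0.0, true_params, design)
        doubled = Parameters(
            l=true_params.l, g=true_params.g, v=true_params.v,
            beta_s=true_params.beta_s,
            variance=true_params.variance.replace(
                sigma2_eps=2 * true_params.variance.sigma2_eps),
        )
        v2 = nll_conditional(subj, 0.0, doubled, design)
        assert v1 != pytest.approx(v2)


class TestExactMarginal:
    def test_flat_curve_gaussian_limit(self):
        vp = VarianceParams(tau2=400.0, sigma2_bm=0.05, sigma2_0=3.0,
                            sigma2_eps=2.0, rho=0.0)
        subj = Subject("a", "cognitively normal", {},
                       [Visit(0.0, 11.0), Visit(12.0, 13.0)])
        p = _flat_params(vp)
        exact = nll_exact_marginal(subj, p)
        closed = nll_conditional(subj, 0.0, p)
        assert exact == pytest.approx(closed, abs=1e-8)

    def test_degenerate_prior_limit(self, true_params):
        subj = Subject("a", "cognitively normal", {},
                       [Visit(0.0, 10.0), Visit(6.0, 10.5)])
        design = SubjectDesign(np.zeros(4), np.zeros(0), np.zeros(0))
        tight = Parameters(
            l=true_params.l, g=true_params.g, v=true_params.v,
            beta_s=true_params.beta_s,
            variance=true_params.variance.replace(tau2=1e-6, rho=0.0),
        )
        got = nll_exact_marginal(subj, tight, design)
        assert got == pytest.approx(nll_conditional(subj, 0.0, tight, design), abs=1e-4)
        zero = Parameters(
            l=true_params.l, g=true_params.g, v=true_params.v,
            beta_s=true_params.beta_s,
            variance=VarianceParams(0.0, 0.08, 4.0, 6.25, 0.0),
        )
        assert nll_exact_marginal(subj, zero, design) == pytest.approx(
            nll_conditional(subj, 0.0, zero, design))

    def test_node_count_stability(self, true_params, rng):
        subj = Subject("b", "MCI (late)", {},
                       [Visit(float(t), float(y)) for t, y in
                        zip([0.0, 6.0, 24.0], rng.normal(18, 4, 3))])
        design = SubjectDesign(np.array([0.0, 0.0, 1.0, 0.0]), np.zeros(0), np.zeros(0))
        a = nll_exact_marginal(subj, true_params, design, n_nodes=50)
        b = nll_exact_marginal(subj, true_params, design, n_nodes=100)
        assert a == pytest.approx(b, abs=1e-6)


# ---------------------------------------------------------------------------
# the two estimation steps

class TestPnlsStep:
    def test_noiseless_truth_is_fixed_point(self):
        # single-group cohort: the l / group-shift ridge would otherwise
        # amplify machine-epsilon residuals beyond the asserted precision
        gen_vp = VarianceParams(tau2=576.0, sigma2_bm=0.0, sigma2_0=0.0,
                                sigma2_eps=0.0, rho=0.0)
        gen = Parameters(l=1.0, g=math.log(45.0), v=9.0,
                         beta_s=np.zeros(0), variance=gen_vp)
        spec = ModelSpec(group_levels=("cognitively normal",))
        cfg = SimulationConfig(
            n_subjects=40, seed=21, params=gen, spec=spec, retention=1.0,
            group_proportions={"cognitively normal": 1.0})
        ds, truth = simulate_dataset(cfg)
        fit_vp = gen_vp.replace(sigma2_eps=1e-12)
        params = Parameters(l=gen.l, g=gen.g, v=gen.v, beta_s=np.zeros(0),
                            variance=fit_vp)
        s_true = truth["subjects"]["s_true"].to_numpy()
        updated, s_new, _ = pnls_step(ds, spec, params, s_modes=s_true)
        assert updated.l == pytest.approx(gen.l, abs=1e-8)
        assert updated.g == pytest.approx(gen.g, abs=1e-8)
        assert updated.v == pytest.approx(gen.v, abs=1e-8)
        assert np.allclose(s_new, s_true, atol=1e-6)

    def test_shift_modes_match_dense_grid(self, small_cohort, true_params, basic_spec):
        ds, _ = small_cohort
        designs = build_designs(ds, basic_spec)
        # one sweep: the returned modes correspond to the input parameters
        opts = FitOptions(pnls_sweeps=1, s_grid_points=241)
        _, s_modes, _ = pnls_step(ds, basic_spec, true_params, designs=designs,
                                  options=opts)
        tau = math.sqrt(true_params.variance.tau2)
        grid = np.linspace(-4 * tau, 4 * tau, 241)
        resolution = grid[1] - grid[0]
        for i in [0, 7, 19, 33, 55]:
            subj = ds.subjects[i]
            vals = [
                nll_conditional(subj, s, true_params, designs.row(i))
                + 0.5 * s * s / tau**2
                for s in grid
            ]
            s_grid_best = grid[int(np.argmin(vals))]
            assert abs(s_modes[i] - s_grid_best) <= resolution

    def test_linear_family_reproduces_gls(self, rng):
        # without groups the linear-family mean is linear in (l, v): the
        # whitened least-squares update must equal closed-form GLS
        vp = VarianceParams(tau2=1e-8, sigma2_bm=0.1, sigma2_0=3.0,
                            sigma2_eps=2.0, rho=0.0)
        spec = ModelSpec(curve_family="linear",
                         group_levels=("cognitively normal",))
        subjects = []
        times = np.array([0.0, 6.0, 12.0, 24.0])
        for i in range(25):
            y = 10 + 0.3 * times + rng.normal(0, 2, times.size)
            subjects.append(Subject(f"s{i}", "cognitively normal", {},
                                    [Visit(t, v) for t, v in zip(times, y)]))
        ds = LongitudinalDataset(subjects, group_levels=("cognitively normal",))
        start = Parameters(l=0.0, g=0.0, v=0.0, beta_s=np.zeros(0), variance=vp)
        fitted, _, _ = pnls_step(ds, spec, start)
        cov = process_cov(times, vp) - 0.0  # tau2 ~ 0: shifts pinned at zero
        w = np.linalg.inv(cov)
        X = np.column_stack([times, np.ones(times.size)])
        A = X.T @ w @ X * len(subjects)
        b = sum(X.T @ w @ s.scores for s in subjects)
        gls = np.linalg.solve(A, b)
        assert fitted.l == pytest.approx(gls[0], rel=1e-6)
        assert fitted.v == pytest.approx(gls[1], rel=1e-6)


class TestLmeStep:
    def test_bm_variance_shrinks_to_boundary_without_bm(self):
        # individual draws can genuinely prefer a small positive rate, so
        # the boundary behavior is asserted on the replicate median
        gen = Parameters(l=1.0, g=math.log(45.0), v=9.0,
                         beta_s=np.array([29.0, 42.0, 88.0, 136.0]),
                         variance=VarianceParams(576.0, 0.0, 4.0, 6.25, 0.0))
        estimates = []
        for seed in (31, 131, 231):
            ds, _ = simulate_dataset(
                SimulationConfig(n_subjects=120, seed=seed, params=gen))
            fit = fit_ml(ds, ModelSpec())
            estimates.append(fit.params.variance.sigma2_bm)
        assert np.median(estimates) < 0.02

    def test_variance_update_improves_linearized_likelihood(self, small_cohort,
                                                            true_params, basic_spec):
        ds, _ = small_cohort
        params, s_modes, _ = pnls_step(ds, basic_spec, true_params)
        perturbed = Parameters(
            l=params.l, g=params.g, v=params.v, beta_s=params.beta_s,
            variance=params.variance.replace(sigma2_eps=30.0),
        )
        recovered, n2_bad = lme_step(ds, basic_spec, perturbed, s_modes)
        updated, n2_good = lme_step(ds, basic_spec, params, s_modes)
        # both starts reach the same optimum of the linearized likelihood,
        # and the inflated noise variance is pulled back down
        assert n2_good == pytest.approx(n2_bad, abs=0.01)
        assert recovered.variance.sigma2_eps < 15.0
        assert updated.variance.sigma2_eps < 15.0


# ---------------------------------------------------------------------------
# full fit

class TestFitMl:
    def test_basic_model_df_and_convergence(self, small_fit):
        assert small_fit.df == 12
        assert small_fit.converged
        assert small_fit.aic == pytest.approx(small_fit.neg2ll + 24)
        assert small_fit.bic == pytest.approx(
            small_fit.neg2ll + math.log(small_fit.n_obs) * 12)

    def test_trace_monotone_nonincreasing(self, small_fit):
        trace = np.asarray(small_fit.trace)
        assert np.all(np.diff(trace) <= 1e-8 * (np.abs(trace[:-1]) + 1.0))

    def test_flat_data_yields_flat_trajectory(self):
        # with l = 0 truth, (l, g, v) is ridge-degenerate (a huge-timescale
        # exponential is indistinguishable from a tiny linear trend), so
        # only the fitted trajectory's flatness over the observed range is
        # identified -- at the scale the cohort's sampling noise allows
        gen = Parameters(l=0.0, g=math.log(45.0), v=12.0,
                         beta_s=np.zeros(4),
                         variance=VarianceParams(576.0, 0.0, 3.0, 4.0, 0.0))
        ds, _ = simulate_dataset(SimulationConfig(n_subjects=400, seed=17, params=gen))
        fit = fit_ml(ds, ModelSpec())
        p = fit.params
        d_all = np.concatenate([
            t + d for t, d in zip(
                (s.times for s in ds.subjects),
                (build_designs(ds, ModelSpec()).X_s @ p.beta_s),
            )
        ])
        from latentshift.curves import CurveParams, theta

        curve = theta(d_all, CurveParams(p.l, p.g, p.v))
        data_sd = np.std(np.concatenate([s.scores for s in ds.subjects]))
        assert np.ptp(curve) < 0.5 * data_sd

    def test_laplace_close_to_quadrature_under_weak_nonlinearity(self):
        # a near-linear curve leaves (tau2, rho, sigma0) almost
        # unidentified; pinning the shift variance and correlation keeps
        # the fit in the identified subspace where the approximation
        # claim is meaningful
        gen = Parameters(l=8.0, g=math.log(400.0), v=10.0,
                         beta_s=np.array([20.0, 40.0, 80.0, 120.0]),
                         variance=VarianceParams(576.0, 0.05, 3.0, 4.0, 0.0))
        ds, _ = simulate_dataset(SimulationConfig(n_subjects=60, seed=23, params=gen))
        spec = ModelSpec()
        fit = fit_ml(ds, spec,
                     FitOptions(fix_variance={"tau2": 576.0, "rho": 0.0}))
        exact = exact_neg2ll(ds, spec, fit.params)
        assert abs(fit.neg2ll - exact) / fit.n_obs < 0.01

    def test_analytic_gradient_matches_finite_differences(self, small_cohort):
        ds, _ = small_cohort
        spec = ModelSpec(effects_on_v=("age",))
        designs = build_designs(ds, spec)
        work = _Work(ds, spec, designs)
        opts = FitOptions(s_grid_points=121, newton_iters=12)
        vec, vp = _initialize(work, spec)
        full = vp.to_unconstrained()
        full[4] = 0.15
        _, grad, _ = _laplace_value_grad(work, vec, full, opts, [0, 1, 2, 3, 4])
        x = np.concatenate([vec, full])
        nf = vec.size

        def value(xv):
            v, _ = _laplace_neg2ll(
                work, xv[:nf], VarianceParams.from_unconstrained(xv[nf:]),
                np.zeros(work.n), opts, use_incumbent=False)
            return v

        for j in range(x.size):
            h = 1e-5 * max(abs(x[j]), 1.0)
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (value(xp) - value(xm)) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=5e-2, abs=2e-2)

    def test_rate_covariate_rejected_for_linear_family(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(FitError, match="no rate parameter"):
            fit_ml(ds, ModelSpec(curve_family="linear", effects_on_g=("age",)))
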