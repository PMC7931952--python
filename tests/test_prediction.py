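import math

import numpy as np
import pytest

from latentshift import (
    ModelSpec,
    Parameters,
    Subject,
    SubjectDesign,
    Visit,
    build_designs,
    predict_disease_time,
    predict_random_effects,
    predict_stage_baseline,
    predict_trajectory,
    prediction_errors,
)
from latentshift.covariance import VarianceParams, conditional_given_shift
from latentshift.curves import CurveParams, theta
from latentshift.prediction import SubjectPosterior, holdout_prediction_errors
from latentshift.simulate import SimulationConfig, simulate_dataset


def _design(group_idx=None):
    x = np.zeros(4)
    if group_idx is not None:
        x[group_idx] = 1.0
    return SubjectDesign(x, np.zeros(0), np.zeros(0))


class TestPosteriorMode:
    def test_population_curve_subject_stays_at_origin(self, true_params):
        vp = true_params.variance.replace(rho=0.0)
        p = Parameters(l=true_params.l, g=true_params.g, v=true_params.v,
                       beta_s=true_params.beta_s, variance=vp)
        times = np.array([0.0, 6.0, 12.0, 24.0])
        scores = theta(times + 88.0, CurveParams(p.l, p.g, p.v))
        subj = Subject("x", "MCI (late)", {},
                       [Visit(t, y) for t, y in zip(times, scores)])
        post = predict_random_effects(subj, p, _design(2))
        assert abs(post.s_hat) < 0.5
        assert abs(post.x0_hat) < 0.1

    def test_mode_beats_every_grid_point(self, small_cohort, true_params, basic_spec):
        ds, _ = small_cohort
        designs = build_designs(ds, basic_spec)
        tau = math.sqrt(true_params.variance.tau2)
        grid = np.linspace(-4 * tau, 4 * tau, 200)
        from latentshift.prediction import _shift_objective_grid
        from latentshift.curves import get_family

        fam = get_family("exponential")
        for i, subj in enumerate(ds.subjects):
            post = predict_random_effects(subj, true_params, designs.row(i))
            l, gi, vi, d = true_params.effective(designs.row(i))
            h_grid, _ = _shift_objective_grid(
                subj.times, subj.scores, l, gi, vi, d,
                true_params.variance, fam, grid)
            assert post.objective <= h_grid.min() + 1e-9

    def test_no_visits_rejected(self, true_params):
        subj = Subject.__new__(Subject)
        subj.id, subj.group, subj.covariates, subj.visits = "z", "dementia", {}, []
        with pytest.raises(ValueError, match="no visits"):
            predict_random_effects(subj, true_params, _design(3))


class TestDiseaseTime:
    def test_reference_centering(self):
        post = SubjectPosterior("r", s_hat=0.0, x0_hat=0.0, bm_hat=np.zeros(1),
                                times=np.array([0.0]), d=0.0)
        subj = Subject("r", "cognitively normal", {}, [Visit(0.0, 10.0)])
        assert predict_disease_time(subj, post, 0.0) == 0.0

    def test_arithmetic(self):
        post = SubjectPosterior("x", s_hat=-10.0, x0_hat=0.0, bm_hat=np.zeros(1),
                                times=np.array([0.0]), d=88.0)
        subj = Subject("x", "MCI (late)", {}, [Visit(0.0, 17.0)])
        assert predict_disease_time(subj, post, 6.0) == pytest.approx(84.0)

    def test_unit_slope(self):
        post = SubjectPosterior("x", s_hat=3.0, x0_hat=0.0, bm_hat=np.zeros(1),
                                times=np.array([0.0]), d=42.0)
        subj = Subject("x", "MCI (early)", {}, [Visit(0.0, 12.0)])
        a = predict_disease_time(subj, post, 0.0)
        b = predict_disease_time(subj, post, 6.0)
        assert b - a == pytest.approx(6.0)


class TestTrajectory:
    def test_noiseless_limit_interpolates_observations(self, true_params):
        vp = VarianceParams(tau2=576.0, sigma2_bm=0.3, sigma2_0=4.0,
                            sigma2_eps=1e-8, rho=0.0)
        p = Parameters(l=true_params.l, g=true_params.g, v=true_params.v,
                       beta_s=true_params.beta_s, variance=vp)
        rng = np.random.default_rng(3)
        times = np.array([0.0, 6.0, 18.0, 36.0])
        scores = theta(times + 88.0, CurveParams(p.l, p.g, p.v)) + rng.normal(0, 2, 4)
        subj = Subject("x", "MCI (late)", {},
                       [Visit(t, y) for t, y in zip(times, scores)])
        post = predict_random_effects(subj, p, _design(2))
        pred = predict_trajectory(subj, post, p, times, _design(2))
        assert np.allclose(pred, scores, atol=1e-3)

    def test_zero_deviation_returns_population_curve(self, true_params):
        post = SubjectPosterior("x", s_hat=5.0, x0_hat=0.0, bm_hat=np.zeros(3),
                                times=np.array([0.0, 6.0, 12.0]), d=42.0)
        subj = Subject("x", "MCI (early)", {}, [Visit(0.0, 12.0)])
        t = np.array([0.0, 10.0, 30.0])
        pred = predict_trajectory(subj, post, true_params, t, _design(1))
        pop = theta(t + 47.0, CurveParams(true_params.l, true_params.g, true_params.v))
        assert np.allclose(pred, pop)

    def test_matches_gaussian_conditioning_oracle(self, true_params, rng):
        # E[x0 + BM(t*) | y, s_hat] by direct joint-Gaussian conditioning
        vp = true_params.variance
        p = true_params
        times = np.array([0.0, 6.0, 12.0, 24.0])
        scores = rng.normal(20, 5, times.size)
        subj = Subject("x", "MCI (late)", {},
                       [Visit(t, y) for t, y in zip(times, scores)])
        design = _design(2)
        post = predict_random_effects(subj, p, design)
        t_new = np.array([0.0, 6.0, 9.0, 24.0, 40.0])
        pred = predict_trajectory(subj, post, p, t_new, design)

        l, gi, vi, d = p.effective(design)
        s = post.s_hat
        a = vp.cov_shift_level / vp.tau2
        offset, cov = conditional_given_shift(s, times, vp)
        resid = scores - theta(times + d + s, CurveParams(l, gi, vi)) - offset
        r = vp.implied_corr
        s0c = vp.sigma2_0 * (1 - r * r)
        sol = np.linalg.solve(cov, resid)
        for j, t in enumerate(t_new):
            c_vec = s0c + vp.sigma2_bm * np.minimum(t, times)
            expected = (theta(np.array([t + d + s]), CurveParams(l, gi, vi))[0]
                        + a * s + c_vec @ sol)
            # beyond the last visit the BM conditional mean is constant,
            # which coincides with the covariance form for t >= t_m
            assert pred[j] == pytest.approx(expected, rel=1e-8, abs=1e-8)


class TestPredictionErrors:
    def test_simple_arithmetic(self):
        mse, mae = prediction_errors([1.0, 2.0], [1.0, 4.0])
        assert mse == 2.0 and mae == 1.0

    def test_identical_vectors(self):
        assert prediction_errors([3.0, 4.0], [3.0, 4.0]) == (0.0, 0.0)

    def test_matches_brute_force(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        mse, mae = prediction_errors(a, b)
        assert mse == pytest.approx(np.mean((a - b) ** 2))
        assert mae == pytest.approx(np.median(np.abs(a - b)))

    def test_baseline_exclusion(self):
        times = [0.0, 6.0, 0.0, 12.0]
        mse, _ = prediction_errors([1, 2, 3, 4], [0, 0, 0, 0],
                                   exclude_baseline=True, times=times)
        assert mse == pytest.approx((4 + 16) / 2)
        with pytest.raises(ValueError, match="times required"):
            prediction_errors([1], [0], exclude_baseline=True)
        with pytest.raises(ValueError, match="no observations"):
            prediction_errors([1], [0], exclude_baseline=True, times=[0.0])


def test_staging_sharpens_with_follow_up(true_params):
    """Mean absolute staging error is non-increasing in visits per subject."""
    maes = []
    for n_visits in (1, 3, 5, 9):
        schedule = tuple(np.linspace(0, 48, n_visits))
        cfg = SimulationConfig(n_subjects=250, seed=77, schedule=schedule,
                               retention=1.0)
        ds, truth = simulate_dataset(cfg)
        designs = build_designs(ds, ModelSpec())
        s_true = truth["subjects"]["s_true"].to_numpy()
        s_hat = np.array([
            predict_random_effects(subj, true_params, designs.row(i)).s_hat
            for i, subj in enumerate(ds.subjects)
        ])
        maes.append(np.mean(np.abs(s_hat - s_true)))
    for a, b in zip(maes, maes[1:]):
        assert b <= a * 1.05


def test_stage_informative_covariates_reduce_holdout_error(true_params):
    """Baseline-only staging with stage covariates beats the plain spec."""
    from latentshift import fit_ml, simulate_biomarkers

    cfg = SimulationConfig(n_subjects=220, seed=55)
    ds, truth = simulate_dataset(cfg)
    ds = simulate_biomarkers(ds, truth, loadings={"m1": 1.0},
                             noise_sds={"m1": 15.0}, seed=99)
    train = ds.subjects[:150]
    test = ds.subjects[150:]
    from latentshift.data import LongitudinalDataset

    ds_train = LongitudinalDataset(train, ds.group_levels, ds.reference_group,
                                   ds.covariate_names)
    ds_test = LongitudinalDataset(test, ds.group_levels, ds.reference_group,
                                  ds.covariate_names)
    basic = ModelSpec()
    marker = ModelSpec(effects_on_s=("m1",))
    fit_basic = fit_ml(ds_train, basic)
    fit_marker = fit_ml(ds_train, marker)
    mse_basic, _ = holdout_prediction_errors(ds_test, basic, fit_basic.params)
    mse_marker, _ = holdout_prediction_errors(ds_test, marker, fit_marker.params)
    assert mse_marker < mse_basic


def test_stage_baseline_with_score_uses_single_visit(true_params, small_cohort):
    ds, _ = small_cohort
    designs = build_designs(ds, ModelSpec())
    subj = ds.subjects[0]
    post = predict_stage_baseline(subj, true_params, designs.row(0),
                                  use_baseline_score=True)
    assert post.times.size == 1
    post0 = predict_stage_baseline(subj, true_params, designs.row(0))
    assert post0.s_hat == 0.0
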