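"""Empirical-Bayes prediction of subject-level random effects.

Random effects are predicted as posterior modes under the ML parameter
estimates.  The starting level and Brownian values are linear-Gaussian
given the time shift and are profiled in closed form, so the mode search
reduces to a one-dimensional problem in ``s_i`` solved by a dense grid
over +/- 4 tau followed by a bounded refinement.  A subject's predicted
disease month at study time ``t`` is ``t + d_i + s_hat`` (fixed stage
offset plus predicted shift); for a reference-group subject with zero
shift this equals study time, anchoring disease month 0 at the average
baseline stage of the reference group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .covariance import conditional_given_shift
from .curves import get_family
from .data import DesignMatrices, LongitudinalDataset, ModelSpec, Subject, SubjectDesign, build_designs
from .inference import Parameters

__all__ = [
    "SubjectPosterior",
    "predict_random_effects",
    "predict_disease_time",
    "predict_trajectory",
    "predict_cohort",
    "predict_stage_baseline",
    "prediction_errors",
    "holdout_prediction_errors",
]


@dataclass
class SubjectPosterior:
    """Posterior-mode random effects of one subject."""

    subject_id: str
    s_hat: float
    x0_hat: float
    bm_hat: np.ndarray
    times: np.ndarray
    d: float  # fixed stage offset X_s beta_s (months)
    objective: float = float("nan")

    def disease_month_at(self, t) -> np.ndarray:
        """Map study time (months) to predicted disease month; affine, unit slope."""
        return np.asarray(t, dtype=float) + self.d + self.s_hat


def _shift_objective_grid(t, y, l, gi, vi, d, vp, fam, s_values):
    """h(s) = 0.5 r' Sigma_c^-1 r + s^2/(2 tau^2) over a vector of shifts."""
    tau2 = max(vp.tau2, 1e-12)
    a = vp.cov_shift_level / vp.tau2 if vp.tau2 > 0 else 0.0
    _, cov = conditional_given_shift(0.0, t, vp)
    L = linalg.cholesky(cov, lower=True)
    Sinv = linalg.cho_solve((L, True), np.eye(t.size))
    s_values = np.asarray(s_values, dtype=float)
    tdis = t[None, :] + d + s_values[:, None]
    ev = fam.eval(tdis, l, gi, vi)
    r = y[None, :] - ev["value"] - a * s_values[:, None]
    q = np.einsum("gm,mn,gn->g", r, Sinv, r)
    return 0.5 * q + 0.5 * s_values**2 / tau2, Sinv


def predict_random_effects(subject: Subject, params: Parameters,
                           design: SubjectDesign | None = None,
                           family: str = "exponential",
                           grid_points: int = 201,
                           grid_width: float = 4.0) -> SubjectPosterior:
    """Jointly maximize the posterior of (s_i, x_{i,0}, BM values).

    The returned mode satisfies: objective at ``s_hat`` is no worse than
    at any of the search-grid points.
    """
    t, y = subject.times, subject.scores
    if t.size == 0:
        raise ValueError(f"subject {subject.id!r} has no visits")
    fam = get_family(family)
    l, gi, vi, d = params.effective(design)
    vp = params.variance
    tau = math.sqrt(max(vp.tau2, 1e-12))
    a = vp.cov_shift_level / vp.tau2 if vp.tau2 > 0 else 0.0

    grid = np.linspace(-grid_width * tau, grid_width * tau, grid_points)
    h_grid, Sinv = _shift_objective_grid(t, y, l, gi, vi, d, vp, fam, grid)
    j = int(np.argmin(h_grid))
    delta = grid[1] - grid[0] if grid_points > 1 else tau

    def h_scalar(s: float) -> float:
        return float(_shift_objective_grid(t, y, l, gi, vi, d, vp, fam, [s])[0][0])

    res = optimize.minimize_scalar(
        h_scalar,
        bounds=(grid[j] - delta, grid[j] + delta),
        method="bounded",
        options={"xatol": 1e-7 * max(tau, 1.0)},
    )
    s_hat = float(res.x) if res.fun <= h_grid[j] else float(grid[j])
    h_best = min(float(res.fun), float(h_grid[j]))

    # linear effects: Gaussian conditional mode given s_hat
    ev = fam.eval(t + d + s_hat, l, gi, vi)
    resid = y - ev["value"] - a * s_hat
    r = vp.implied_corr
    sigma2_0c = vp.sigma2_0 * (1.0 - r * r)
    k_bm = vp.sigma2_bm * np.minimum.outer(t, t)
    sr = Sinv @ resid
    x0_hat = a * s_hat + sigma2_0c * float(np.sum(sr))
    bm_hat = k_bm @ sr
    return SubjectPosterior(
        subject_id=subject.id, s_hat=s_hat, x0_hat=float(x0_hat), bm_hat=bm_hat,
        times=t.copy(), d=float(d), objective=h_best,
    )


def predict_disease_time(subject: Subject, posterior: SubjectPosterior, at_t) -> float:
    """Predicted disease month at study time ``at_t``: ``at_t + d_i + s_hat``."""
    return float(np.asarray(at_t, dtype=float) + posterior.d + posterior.s_hat)


def _bm_conditional_mean(posterior: SubjectPosterior, times) -> np.ndarray:
    """Brownian conditional mean: linear interpolation between visit-time
    modes (anchored at 0 at study time 0), constant beyond the last visit."""
    times = np.asarray(times, dtype=float)
    xp = posterior.times
    fp = posterior.bm_hat
    if xp.size == 0:
        return np.zeros_like(times)
    if xp[0] > 0:
        xp = np.concatenate([[0.0], xp])
        fp = np.concatenate([[0.0], fp])
    return np.interp(times, xp, fp)


def predict_trajectory(subject: Subject, posterior: SubjectPosterior,
                       params: Parameters, times,
                       design: SubjectDesign | None = None,
                       family: str = "exponential") -> np.ndarray:
    """Expected scores at the given study times given the predicted effects."""
    fam = get_family(family)
    l, gi, vi, _ = params.effective(design)
    times = np.asarray(times, dtype=float)
    ev = fam.eval(times + posterior.d + posterior.s_hat, l, gi, vi)
    return ev["value"] + posterior.x0_hat + _bm_conditional_mean(posterior, times)


def predict_cohort(dataset: LongitudinalDataset, spec: ModelSpec, params: Parameters,
                   designs: DesignMatrices | None = None) -> pd.DataFrame:
    """Posterior table for every complete-case subject.

    Columns: subject_id, s_hat_months, x0_hat,
    predicted_disease_month_at_baseline.
    """
    designs = designs or build_designs(dataset, spec)
    rows = []
    for i, subject in enumerate(dataset.subjects):
        if not designs.included[i]:
            continue
        post = predict_random_effects(subject, params, designs.row(i),
                                      family=spec.curve_family)
        rows.append({
            "subject_id": subject.id,
            "s_hat_months": post.s_hat,
            "x0_hat": post.x0_hat,
            "predicted_disease_month_at_baseline": predict_disease_time(
                subject, post, subject.times[0]
            ),
        })
    return pd.DataFrame(rows)


def predict_stage_baseline(subject: Subject, params: Parameters,
                           design: SubjectDesign | None = None,
                           family: str = "exponential",
                           use_baseline_score: bool = False) -> SubjectPosterior:
    """Stage a subject from baseline information only.

    With ``use_baseline_score=False`` the shift prediction uses fixed
    effects alone (group and any stage covariates; ``s_hat = 0``).  With
    ``use_baseline_score=True`` the posterior mode is computed from the
    baseline visit only.  This mirrors staging a newly enrolled patient
    from baseline data with or without the baseline cognitive score.
    """
    if use_baseline_score:
        baseline = Subject(
            subject.id, subject.group, dict(subject.covariates),
            [subject.visits[0]],
        )
        return predict_random_effects(baseline, params, design, family=family)
    _, _, _, d = params.effective(design)
    return SubjectPosterior(
        subject_id=subject.id, s_hat=0.0, x0_hat=0.0,
        bm_hat=np.zeros(0), times=np.zeros(0), d=float(d),
    )


def prediction_errors(predicted, observed, exclude_baseline: bool = False,
                      times=None) -> tuple[float, float]:
    """Mean squared error and median absolute error of score predictions.

    With ``exclude_baseline`` the entries at study time 0 are dropped
    before aggregation (``times`` must then be supplied).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if exclude_baseline:
        if times is None:
            raise ValueError("times required when excluding baseline visits")
        keep = np.asarray(times, dtype=float) > 0
        predicted, observed = predicted[keep], observed[keep]
    if predicted.size == 0:
        raise ValueError("no observations left after baseline exclusion")
    err = predicted - observed
    return float(np.mean(err**2)), float(np.median(np.abs(err)))


def holdout_prediction_errors(dataset: LongitudinalDataset, spec: ModelSpec,
                              params: Parameters,
                              designs: DesignMatrices | None = None,
                              use_baseline_score: bool = False,
                              exclude_baseline: bool = True) -> tuple[float, float]:
    """Score held-out trajectories staged from baseline information.

    Each subject is staged by :func:`predict_stage_baseline` and the full
    observed trajectory is compared with the population-curve forecast at
    the predicted stage (baseline visits excluded from the error
    aggregation by default, as baseline information was used for staging).
    """
    designs = designs or build_designs(dataset, spec)
    preds, obs, ts = [], [], []
    for i, subject in enumerate(dataset.subjects):
        if not designs.included[i]:
            continue
        post = predict_stage_baseline(
            subject, params, designs.row(i), family=spec.curve_family,
            use_baseline_score=use_baseline_score,
        )
        yhat = predict_trajectory(subject, post, params, subject.times,
                                  designs.row(i), family=spec.curve_family)
        preds.append(yhat)
        obs.append(subject.scores)
        ts.append(subject.times)
    predicted = np.concatenate(preds)
    observed = np.concatenate(obs)
    times = np.concatenate(ts)
    return prediction_errors(predicted, observed,
                             exclude_baseline=exclude_baseline, times=times)
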