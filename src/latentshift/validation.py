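"""Downstream validation of the fitted disease timeline.

Two procedures assess whether predicted disease time is a meaningful
scale beyond the score it was fitted on:

* regression of time since reported symptom onset (at baseline) on
  predicted disease time (OLS, t-test p-value), plus the slope-one
  least-squares intercept used when comparing onset age against age at
  predicted disease month 0;
* a comparison of two linear mixed models for a secondary longitudinal
  outcome — a cubic B-spline mean (3 df + intercept) per baseline group
  over study time versus a single cubic B-spline mean over predicted
  disease time — with subject-level random intercepts and slopes, ML
  estimation, and -2LL/AIC/BIC reported for both.  The fixed-effect df
  are 5x4 = 20 versus 4 for five groups; adding the four variance
  parameters (two random-effect variances, their covariance, residual)
  gives total df 24 versus 8.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline

from .inference import information_criteria

__all__ = [
    "onset_regression",
    "slope_one_intercept",
    "bspline_basis",
    "LMMFit",
    "fit_random_slope_lmm",
    "ModelCriteria",
    "TimescaleComparison",
    "timescale_comparison",
    "lrt_pvalue",
]


def onset_regression(onset_offsets, predicted_disease_months):
    """OLS of time since reported onset on predicted disease time.

    Returns ``(slope, intercept, p_value)`` with a two-sided t-test
    p-value for zero slope.
    """
    y = np.asarray(onset_offsets, dtype=float)
    x = np.asarray(predicted_disease_months, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if y.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def slope_one_intercept(onset_ages, ages_at_disease_time_zero) -> float:
    """Least-squares intercept under a fixed unit slope.

    Minimizing ``sum (onset_age - (age_at_zero + c))^2`` over ``c`` gives
    the mean difference.
    """
    a = np.asarray(onset_ages, dtype=float)
    b = np.asarray(ages_at_disease_time_zero, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors required")
    return float(np.mean(a - b))


def bspline_basis(x, df: int = 3) -> np.ndarray:
    """B-spline basis with ``df`` columns, intercept excluded.

    For ``df = 3`` this is a cubic basis with boundary knots at min/max
    and no interior knots (the first basis function, redundant with an
    intercept, is dropped).  Smaller ``df`` lowers the polynomial degree;
    ``df > 3`` adds interior knots at quantiles.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    degree = min(3, df)
    n_interior = df - degree
    a, b = float(np.min(x)), float(np.max(x))
    if b <= a:
        raise ValueError("x must have at least two distinct values")
    if n_interior:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([
        np.full(degree + 1, a), interior, np.full(degree + 1, b)
    ])
    design = BSpline.design_matrix(np.clip(x, a, b), knots, degree).toarray()
    return design[:, 1:]


# ---------------------------------------------------------------------------
# random intercept + slope linear mixed model, ML

@dataclass
class LMMFit:
    beta: np.ndarray
    cov_re: np.ndarray  # 2x2 covariance of (intercept, slope per year)
    sigma2: float
    neg2ll: float
    df: int
    n_obs: int
    n_subjects: int
    converged: bool


def _lmm_blocks(y, X, subject_ids, slope_time):
    order = {}
    for i, sid in enumerate(subject_ids):
        order.setdefault(sid, []).append(i)
    by_m: dict[int, list[list[int]]] = {}
    for sid, idx in order.items():
        by_m.setdefault(len(idx), []).append(idx)
    blocks = []
    for m, groups in sorted(by_m.items()):
        rows = np.array(groups)  # (k, m)
        blocks.append({
            "y": y[rows],
            "X": X[rows],
            # slope times in years: keeps the variance scales comparable
            "Z": np.stack([np.ones((rows.shape[0], m)), slope_time[rows] / 12.0], axis=2),
            "m": m,
            "k": rows.shape[0],
        })
    return blocks, len(order)


def fit_random_slope_lmm(y, X, subject_ids, slope_time) -> LMMFit:
    """ML fit of ``y = X beta + Z_i b_i + eps`` with random intercept+slope.

    ``b_i ~ N(0, D)`` (2x2, free covariance), ``eps ~ N(0, sigma2 I)``.
    The fixed effects are profiled out by GLS; the four covariance
    parameters are optimized on a log-Cholesky scale.  The slope random
    effect is taken per year of ``slope_time`` for numerical balance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    slope_time = np.asarray(slope_time, dtype=float)
    n, p = X.shape
    blocks, n_subjects = _lmm_blocks(y, X, np.asarray(subject_ids), slope_time)
    eyes = {blk["m"]: np.eye(blk["m"]) for blk in blocks}

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    v0 = max(float(np.var(resid)), 1e-6)

    def unpack(theta):
        L = np.array([[math.exp(theta[0]), 0.0],
                      [theta[1], math.exp(theta[2])]])
        return L @ L.T, math.exp(theta[3])

    def neg2ll_and_beta(theta):
        D, s2 = unpack(theta)
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        yVy = 0.0
        logdet = 0.0
        for blk in blocks:
            Z = blk["Z"]
            V = np.einsum("kma,ab,knb->kmn", Z, D, Z) + s2 * eyes[blk["m"]]
            try:
                C = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e13, None
            logdet += 2.0 * float(np.sum(np.log(np.diagonal(C, axis1=1, axis2=2))))
            rhs = np.concatenate([blk["X"], blk["y"][:, :, None]], axis=2)
            sol = np.linalg.solve(V, rhs)
            A += np.einsum("kmp,kmq->pq", blk["X"], sol[:, :, :p])
            bvec += np.einsum("kmp,km->p", blk["X"], sol[:, :, p])
            yVy += float(np.einsum("km,km->", blk["y"], sol[:, :, p]))
        beta = np.linalg.solve(A, bvec)
        quad = yVy - float(bvec @ beta)
        return n * math.log(2 * math.pi) + logdet + quad, beta

    theta0 = np.array([0.5 * math.log(v0 / 2), 0.0, 0.5 * math.log(v0 / 8 + 1e-8),
                       math.log(v0 / 2)])
    res = optimize.minimize(
        lambda t: neg2ll_and_beta(t)[0], theta0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
    )
    res2 = optimize.minimize(
        lambda t: neg2ll_and_beta(t)[0], res.x, method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    best = res2 if res2.fun <= res.fun else res
    neg2ll, beta = neg2ll_and_beta(best.x)
    D, s2 = unpack(best.x)
    return LMMFit(
        beta=beta, cov_re=D, sigma2=s2, neg2ll=float(neg2ll),
        df=p + 4, n_obs=n, n_subjects=n_subjects,
        converged=bool(res.success or res2.success),
    )


# ---------------------------------------------------------------------------
# timescale comparison

@dataclass
class ModelCriteria:
    neg2ll: float
    df: int
    aic: float
    bic: float


@dataclass
class TimescaleComparison:
    """Per-group-time versus disease-time spline models for one outcome."""

    group_model: ModelCriteria
    disease_model: ModelCriteria
    preferred: dict = field(default_factory=dict)
    n_obs: int = 0
    n_subjects: int = 0


def timescale_comparison(outcome, subject_ids, groups, study_times,
                         disease_months, group_levels=None) -> TimescaleComparison:
    """Compare two time scales for modeling a longitudinal outcome.

    Model (a): one cubic B-spline trajectory (3 df + intercept) per
    baseline group over study time.  Model (b): a single trajectory over
    predicted disease time.  Both use subject-level random intercepts and
    slopes and ML estimation, on the identical complete-case observation
    set, so the criteria are directly comparable.
    """
    outcome = np.asarray(outcome, dtype=float)
    subject_ids = np.asarray(subject_ids)
    groups = np.asarray(groups)
    study_times = np.asarray(study_times, dtype=float)
    disease_months = np.asarray(disease_months, dtype=float)

    keep = (np.isfinite(outcome) & np.isfinite(study_times)
            & np.isfinite(disease_months))
    outcome, subject_ids = outcome[keep], subject_ids[keep]
    groups, study_times = groups[keep], study_times[keep]
    disease_months = disease_months[keep]
    if group_levels is None:
        group_levels = list(dict.fromkeys(groups))

    # model (a): per-group intercept + spline block over study time
    cols = []
    for gname in group_levels:
        mask = groups == gname
        if not np.any(mask):
            continue
        n_distinct = np.unique(study_times[mask]).size
        df_g = 3
        if n_distinct < 4:
            df_g = max(n_distinct - 1, 1)
            warnings.warn(
                f"group {gname!r} has only {n_distinct} distinct study times; "
                f"spline basis reduced to {df_g} df", UserWarning, stacklevel=2,
            )
        block = np.zeros((outcome.size, df_g + 1))
        block[mask, 0] = 1.0
        block[mask, 1:] = bspline_basis(study_times[mask], df=df_g)
        cols.append(block)
    X_group = np.hstack(cols)
    fit_a = fit_random_slope_lmm(outcome, X_group, subject_ids, study_times)

    # model (b): single intercept + spline over disease time
    X_disease = np.column_stack([
        np.ones(outcome.size), bspline_basis(disease_months, df=3)
    ])
    fit_b = fit_random_slope_lmm(outcome, X_disease, subject_ids, disease_months)

    crits = []
    for fit in (fit_a, fit_b):
        aic, bic = information_criteria(fit.neg2ll, fit.df, fit.n_obs)
        crits.append(ModelCriteria(fit.neg2ll, fit.df, aic, bic))
    preferred = {
        "neg2ll": "disease" if crits[1].neg2ll < crits[0].neg2ll else "group",
        "aic": "disease" if crits[1].aic < crits[0].aic else "group",
        "bic": "disease" if crits[1].bic < crits[0].bic else "group",
    }
    return TimescaleComparison(
        group_model=crits[0], disease_model=crits[1], preferred=preferred,
        n_obs=int(outcome.size), n_subjects=fit_a.n_subjects,
    )


def lrt_pvalue(neg2ll_null: float, neg2ll_alt: float, df_diff: int) -> float:
    """Likelihood-ratio p-value on the chi-square reference (nested models)."""
    if df_diff <= 0:
        raise ValueError("df_diff must be positive")
    stat = max(neg2ll_null - neg2ll_alt, 0.0)
    return float(stats.chi2.sf(stat, df_diff))
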