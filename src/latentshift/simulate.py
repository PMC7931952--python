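"""Synthetic multi-group longitudinal cohorts from the generative model.

The simulator draws cohorts directly from the latent-shift model:
subjects are assigned to the five baseline strata at staggered fixed
stage offsets, receive a random shift and correlated starting level, a
Brownian-motion deviation, and i.i.d. measurement noise, and are observed
on an approximately six-monthly visit schedule with independent per-visit
thinning.  Defaults emulate the shape of a large observational AD cohort:
~2,000 subjects, an exponential decline unfolding over roughly 15 years
of disease time, group stagings of 29/42/88/136 months, a shift SD of 24
months, and about 4.6 visits per subject.  The default parameter values
are package choices shaped like that setting, not estimates from any real
cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import VarianceParams
from .curves import get_family
from .data import LongitudinalDataset, ModelSpec, Subject, Visit, build_designs
from .inference import Parameters

__all__ = [
    "SimulationConfig",
    "default_true_parameters",
    "simulate_dataset",
    "simulate_biomarkers",
    "empirical_moments_check",
]

#: scheduled visit months (semi-annual to 2 years, then annual)
DEFAULT_SCHEDULE = (0.0, 6.0, 12.0, 18.0, 24.0, 36.0, 48.0)

#: baseline-group mix, reference group first
DEFAULT_PROPORTIONS = {
    "cognitively normal": 0.25,
    "significant memory concern": 0.05,
    "MCI (early)": 0.20,
    "MCI (late)": 0.30,
    "dementia": 0.20,
}


def default_true_parameters() -> Parameters:
    """Generating parameters of the default synthetic cohort.

    Curve: v = 9 (pre-disease score level), l = 1, time scale exp(g) = 45
    months, which places the group baseline means near 10 / 11 / 11.5 / 16
    / 29.5 score points at stage offsets of 29, 42, 88 and 136 months.
    Variances: shift SD 24 months; stable level SD 2 points; Brownian
    wander reaching SD 2 points at 4 years; test-retest noise SD 2.5
    points; shift-level correlation 0.3 (rho = 3.6).
    """
    return Parameters(
        l=1.0,
        g=math.log(45.0),
        v=9.0,
        beta_s=np.array([29.0, 42.0, 88.0, 136.0]),
        beta_g=np.zeros(0),
        beta_v=np.zeros(0),
        variance=VarianceParams(
            tau2=576.0, sigma2_bm=0.08, sigma2_0=4.0, sigma2_eps=6.25, rho=3.6
        ),
    )


_DEFAULT_COVARIATES = {
    "age": ("normal", 73.0, 7.0),
    "sex": ("bernoulli", 0.45),
    "education": ("normal", 16.0, 2.6),
}


@dataclass
class SimulationConfig:
    """Configuration of one synthetic cohort.

    ``retention`` is the independent per-visit probability of observing
    each post-baseline scheduled visit (baseline is always observed); the
    default 0.6 yields about 4.6 visits per subject on the default
    schedule.  ``seed`` is mandatory for reproducibility.
    """

    n_subjects: int = 2000
    seed: int = 0
    group_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    params: Parameters = field(default_factory=default_true_parameters)
    spec: ModelSpec = field(default_factory=ModelSpec)
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    retention: float = 0.6
    covariate_generators: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))

    def __post_init__(self):
        total = sum(self.group_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"group proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.group_proportions.values()):
            raise ValueError("group proportions must be non-negative")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must lie in [0, 1]")
        unknown = set(self.group_proportions) - set(self.spec.group_levels)
        if unknown:
            raise ValueError(f"proportions name unknown groups: {sorted(unknown)}")


def _draw_covariate(rng: np.random.Generator, gen, n: int) -> np.ndarray:
    if callable(gen):
        return np.asarray(gen(rng, n), dtype=float)
    kind = gen[0]
    if kind == "normal":
        return rng.normal(gen[1], gen[2], size=n)
    if kind == "bernoulli":
        return rng.binomial(1, gen[1], size=n).astype(float)
    if kind == "uniform":
        return rng.uniform(gen[1], gen[2], size=n)
    raise ValueError(f"unknown covariate generator {gen!r}")


def simulate_dataset(cfg: SimulationConfig) -> tuple[LongitudinalDataset, dict]:
    """Draw a cohort and its latent truth from the generative model.

    Returns ``(dataset, truth)`` where ``truth`` holds a per-subject table
    (``subjects``: group, s_true, x0_true, d_true,
    disease_month_at_baseline) and a per-visit table (``visits``: the mean
    curve value, Brownian value, noise draw and score), consistent with
    the dataset bit-for-bit.
    """
    rng = np.random.default_rng(cfg.seed)
    vp = cfg.params.variance
    n = cfg.n_subjects
    levels = [g for g in cfg.spec.group_levels if cfg.group_proportions.get(g, 0) > 0]
    probs = np.array([cfg.group_proportions[g] for g in levels])
    covariate_names = tuple(cfg.covariate_generators)

    if n == 0:
        empty = LongitudinalDataset([], cfg.spec.group_levels,
                                    cfg.spec.reference_group, covariate_names)
        return empty, {"subjects": pd.DataFrame(), "visits": pd.DataFrame()}

    groups = rng.choice(levels, size=n, p=probs)
    cov_draws = {
        name: _draw_covariate(rng, gen, n)
        for name, gen in cfg.covariate_generators.items()
    }

    # bivariate (s_i, x_{i,0}) with Cov = rho * sigma0^2; an eigenvalue
    # factor keeps degenerate (zero-variance) components exactly zero
    cov_sx = vp.cov_shift_level
    joint = np.array([[vp.tau2, cov_sx], [cov_sx, vp.sigma2_0]])
    w, V = np.linalg.eigh(joint)
    factor = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, 2))
    draws = z @ factor.T
    s_true = draws[:, 0]
    x0_true = draws[:, 1]

    schedule = np.asarray(cfg.schedule, dtype=float)
    keep = np.ones((n, schedule.size), dtype=bool)
    if schedule.size > 1:
        keep[:, 1:] = rng.random((n, schedule.size - 1)) < cfg.retention

    # subjects without scores yet, to build design rows under the spec
    subjects = []
    for i in range(n):
        t_i = schedule[keep[i]]
        covs = {name: float(cov_draws[name][i]) for name in covariate_names}
        visits = [Visit(float(t), 0.0) for t in t_i]
        subjects.append(Subject(f"S{i:05d}", str(groups[i]), covs, visits))
    dataset = LongitudinalDataset(subjects, cfg.spec.group_levels,
                                  cfg.spec.reference_group, covariate_names)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # identifiability warnings are meaningless in the generative
        # direction (small cohorts may miss a group entirely)
        _warnings.simplefilter("ignore", UserWarning)
        designs = build_designs(dataset, cfg.spec)
    fam = get_family(cfg.spec.curve_family)

    subj_rows, visit_rows = [], []
    for i, subject in enumerate(dataset.subjects):
        l, gi, vi, d = cfg.params.effective(designs.row(i))
        t_i = subject.times
        m = t_i.size
        # Brownian motion sampled at the observed study times
        dt = np.diff(np.concatenate([[0.0], t_i]))
        bm = np.cumsum(rng.standard_normal(m) * np.sqrt(vp.sigma2_bm * dt))
        eps = rng.standard_normal(m) * math.sqrt(vp.sigma2_eps)
        mean = fam.eval(t_i + d + s_true[i], l, gi, vi)["value"]
        y = mean + x0_true[i] + bm + eps
        subject.visits = [Visit(float(t), float(val)) for t, val in zip(t_i, y)]
        subj_rows.append({
            "subject_id": subject.id, "group": subject.group,
            "s_true": float(s_true[i]), "x0_true": float(x0_true[i]),
            "d_true": float(d),
            "disease_month_at_baseline": float(t_i[0] + d + s_true[i]),
        })
        for j in range(m):
            visit_rows.append({
                "subject_id": subject.id, "t": float(t_i[j]),
                "mean": float(mean[j]), "bm": float(bm[j]),
                "eps": float(eps[j]), "y": float(y[j]),
            })
    truth = {
        "subjects": pd.DataFrame(subj_rows),
        "visits": pd.DataFrame(visit_rows),
    }
    return dataset, truth


def simulate_biomarkers(dataset: LongitudinalDataset, truth: dict,
                        loadings: dict, noise_sds: dict, seed: int,
                        intercepts: dict | None = None) -> LongitudinalDataset:
    """Add stage-informative baseline biomarkers as covariate columns.

    Marker m of subject i is
    ``intercept_m + loading_m * (true disease month at baseline) + noise``;
    zero loadings give markers independent of stage.
    """
    rng = np.random.default_rng(seed)
    intercepts = intercepts or {}
    stage = truth["subjects"].set_index("subject_id")["disease_month_at_baseline"]
    new_subjects = []
    marker_values = {
        name: {} for name in loadings
    }
    for name in loadings:
        noise = rng.standard_normal(dataset.n_subjects) * float(noise_sds.get(name, 0.0))
        for i, subject in enumerate(dataset.subjects):
            val = (intercepts.get(name, 0.0)
                   + loadings[name] * float(stage.loc[subject.id]) + noise[i])
            marker_values[name][subject.id] = float(val)
    for subject in dataset.subjects:
        covs = dict(subject.covariates)
        for name in loadings:
            covs[name] = marker_values[name][subject.id]
        new_subjects.append(Subject(subject.id, subject.group, covs,
                                    list(subject.visits)))
    return LongitudinalDataset(
        new_subjects, dataset.group_levels, dataset.reference_group,
        tuple(dataset.covariate_names) + tuple(loadings),
    )


def empirical_moments_check(cfg: SimulationConfig | None = None,
                            n_subjects: int = 5000) -> dict:
    """Validate the simulator's second moments against the analytic kernel.

    Simulates a cohort on the full schedule (no thinning), forms residuals
    of the scores about the population curve at the true disease time, and
    compares their empirical covariance with the process covariance.
    Returns the empirical and model covariance matrices and the maximum
    absolute z-score under the sampling standard error of a Gaussian
    covariance estimate.
    """
    import dataclasses

    from .covariance import process_cov

    cfg = cfg or SimulationConfig()
    cfg = dataclasses.replace(cfg, n_subjects=n_subjects, retention=1.0)
    dataset, truth = simulate_dataset(cfg)
    schedule = np.asarray(cfg.schedule, dtype=float)
    m = schedule.size

    visits = truth["visits"]
    resid = (visits["y"] - visits["mean"]).to_numpy().reshape(n_subjects, m)
    emp = np.cov(resid, rowvar=False, bias=False)
    model = process_cov(schedule, cfg.params.variance)
    se = np.sqrt(
        (np.outer(np.diag(model), np.diag(model)) + model**2) / n_subjects
    )
    z = (emp - model) / se
    return {
        "empirical_cov": emp,
        "model_cov": model,
        "z": z,
        "max_abs_z": float(np.max(np.abs(z))),
        "n_subjects": n_subjects,
    }
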