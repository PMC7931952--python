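"""Random-effects covariance structures.

The model decomposes subject-level deviations from the mean decline curve
into a random time shift ``s_i`` (months), a random starting level
``x_{i,0}`` (score units), a Brownian-motion process ``x_{i,BM}(t)``
indexed by study time, and i.i.d. measurement noise.  The observation
process ``x_{i,0} + x_{i,BM}(t) + eps`` has covariance

    C(t, t') = sigma2_bm * min(t, t') + sigma2_0  (+ sigma2_eps on the diagonal)

and the time shift is coupled to the starting level through
``Cov(s_i, x_{i,0}) = rho * sigma2_0``.

The Brownian motion is indexed by study time (t >= 0, so x_BM(0) = 0 and
the baseline level is carried entirely by x_{i,0}); indexing it by disease
time would make the covariance depend on the latent shift and destroy the
joint-normal formulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "VarianceParams",
    "process_cov",
    "joint_cov",
    "conditional_given_shift",
]

#: relative tolerance used when asserting positive semidefiniteness
PSD_TOL = 1e-10


@dataclass(frozen=True)
class VarianceParams:
    """Variance components of the progression model.

    Parameters
    ----------
    tau2 : float
        Variance of the random time shift ``s_i`` (months^2).
    sigma2_bm : float
        Variance rate of the Brownian-motion deviation (score^2 / month).
    sigma2_0 : float
        Variance of the random starting level ``x_{i,0}`` (score^2).
    sigma2_eps : float
        Measurement-noise variance (score^2).
    rho : float
        Shift-level coupling such that ``Cov(s_i, x_{i,0}) = rho * sigma2_0``.
        The implied correlation ``rho * sigma_0 / tau`` must lie in (-1, 1).
    """

    tau2: float
    sigma2_bm: float
    sigma2_0: float
    sigma2_eps: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau2", "sigma2_bm", "sigma2_0", "sigma2_eps"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value!r}")
        if not math.isfinite(self.rho):
            raise ValueError("rho must be finite")
        r = self.implied_corr
        if abs(r) >= 1.0:
            raise ValueError(
                f"implied shift-level correlation rho*sigma_0/tau = {r:.4g} "
                "must lie strictly inside (-1, 1)"
            )

    @property
    def implied_corr(self) -> float:
        """Correlation between ``s_i`` and ``x_{i,0}``: rho * sigma_0 / tau."""
        if self.tau2 == 0.0 or self.sigma2_0 == 0.0:
            return 0.0
        return self.rho * math.sqrt(self.sigma2_0) / math.sqrt(self.tau2)

    @property
    def cov_shift_level(self) -> float:
        """Cov(s_i, x_{i,0}) = rho * sigma2_0."""
        return self.rho * self.sigma2_0

    # -- unconstrained parameterization for optimization ------------------
    #
    # Internally the variances are estimated on the log scale and the
    # implied correlation r = rho*sigma_0/tau through atanh, which keeps
    # every iterate valid without explicit constraints.

    _LOG_FLOOR = -30.0

    def to_unconstrained(self) -> np.ndarray:
        logs = [
            math.log(max(v, math.exp(self._LOG_FLOOR)))
            for v in (self.tau2, self.sigma2_bm, self.sigma2_0, self.sigma2_eps)
        ]
        r = min(max(self.implied_corr, -0.999999), 0.999999)
        return np.array(logs + [math.atanh(r)], dtype=float)

    @classmethod
    def from_unconstrained(cls, x: np.ndarray) -> "VarianceParams":
        x = np.asarray(x, dtype=float)
        tau2, s_bm, s_0, s_eps = (math.exp(min(v, 50.0)) for v in x[:4])
        r = math.tanh(x[4])
        rho = r * math.sqrt(tau2) / math.sqrt(s_0) if s_0 > 0 else 0.0
        return cls(tau2=tau2, sigma2_bm=s_bm, sigma2_0=s_0, sigma2_eps=s_eps, rho=rho)

    def replace(self, **kwargs) -> "VarianceParams":
        return replace(self, **kwargs)


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be a 1-D vector")
    if t.size and np.min(t) < 0:
        raise ValueError(
            "negative observation time: the Brownian-motion deviation is "
            "indexed by study time, which must be >= 0"
        )
    return t


def process_cov(times: np.ndarray, vp: VarianceParams) -> np.ndarray:
    """Marginal covariance of the observation process at the given times.

    Entry (j, k) equals ``sigma2_bm * min(t_j, t_k) + sigma2_0`` plus
    ``sigma2_eps`` on the diagonal.
    """
    t = _check_times(times)
    m = np.minimum.outer(t, t)
    cov = vp.sigma2_bm * m + vp.sigma2_0
    cov[np.diag_indices_from(cov)] += vp.sigma2_eps
    return cov


def joint_cov(times: np.ndarray, vp: VarianceParams) -> np.ndarray:
    """Joint covariance of ``(s_i, x_{i,0}, y_1, ..., y_m)`` (mean-centered).

    The block layout is

    ========  =========  ============
    block     value      units
    ========  =========  ============
    Var(s)    tau2       months^2
    Cov(s,x0) rho*s0^2   months*score
    Cov(s,y)  rho*s0^2   months*score
    Cov(x0,y) s0^2       score^2
    y block   process    score^2
    ========  =========  ============
    """
    t = _check_times(times)
    m = t.size
    out = np.empty((m + 2, m + 2), dtype=float)
    c = vp.cov_shift_level
    out[0, 0] = vp.tau2
    out[0, 1] = out[1, 0] = c
    out[1, 1] = vp.sigma2_0
    out[0, 2:] = out[2:, 0] = c
    out[1, 2:] = out[2:, 1] = vp.sigma2_0
    out[2:, 2:] = process_cov(t, vp)
    return out


def conditional_given_shift(
    s: float, times: np.ndarray, vp: VarianceParams
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-condition the observation process on ``s_i = s``.

    Returns
    -------
    offset : ndarray, shape (m,)
        Mean offset added to every observation,
        ``(rho * sigma2_0 / tau2) * s``.
    cov : ndarray, shape (m, m)
        Conditional covariance,
        ``process_cov - (rho * sigma2_0)^2 / tau2 * J``.

    With ``tau2 = 0`` the shift is degenerate at zero and the unconditional
    process covariance is returned with a zero offset.
    """
    t = _check_times(times)
    base = process_cov(t, vp)
    if vp.tau2 == 0.0:
        return np.zeros(t.size), base
    c = vp.cov_shift_level
    offset = np.full(t.size, (c / vp.tau2) * s)
    cov = base - (c * c / vp.tau2)
    return offset, cov
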