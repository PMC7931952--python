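"""Parametric mean-trajectory families and their derivatives.

The default family is the shifted exponential

    theta(t) = l * exp((t + s) / exp(g)) + v

which has a stable left asymptote ``v`` (average pre-disease score), a
monotone course for ``l != 0``, a scale parameter ``l`` (score units) and a
log time-scale ``g`` (time scale exp(g) in months).  The family is
overparametrized in (l, s): multiplying ``l`` by ``exp(-a/exp(g))`` and
adding ``a`` to ``s`` leaves the curve unchanged, which is why fitted
models anchor the time scale by constraining the reference group's shift
to zero.

A linear-in-time family (``theta(t) = l*(t+s) + v``) is provided for
cross-checks against standard linear mixed models; in that family ``g`` is
not a free parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CurveParams",
    "CurveFamily",
    "EXP_CLIP",
    "get_family",
    "theta",
    "theta_grad",
]

logger = logging.getLogger(__name__)

#: bound on the argument of exp() before clipping (guards optimizer excursions)
EXP_CLIP = 50.0


@dataclass(frozen=True)
class CurveParams:
    """Parameters of a single mean curve.

    l : scale of the exponential (score units)
    g : log time-scale (exp(g) months); ignored by the linear family
    v : left asymptote / intercept (score units)
    s : time shift (months)
    """

    l: float
    g: float
    v: float
    s: float = 0.0


def _clipped_exp(z: np.ndarray, warn: bool = False) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if warn and np.any(np.abs(z) > EXP_CLIP):
        logger.warning(
            "exp argument clipped at +/-%g during curve evaluation", EXP_CLIP
        )
    return np.exp(np.clip(z, -EXP_CLIP, EXP_CLIP))


class CurveFamily:
    """Interface for mean-curve families.

    ``param_names`` lists the free curve-shape fixed effects (subset of
    ``l, g, v``); the time shift is handled outside the family by
    evaluating at disease time ``t + shift``.
    """

    name: str = ""
    param_names: tuple[str, ...] = ()

    def eval(self, tdis, l, g, v, order: int = 0) -> dict:
        """Evaluate value and requested derivatives at disease time ``tdis``.

        Returns a dict with key ``"value"`` and, for ``order >= 1``, keys
        ``"d_t"``, ``"d_l"``, ``"d_g"``, ``"d_v"``; for ``order >= 2`` also
        ``"d_tt"``; for ``order >= 3`` additionally ``"d_ttt"`` and the
        mixed parameter derivatives of the time slope and curvature
        (``"d_t_dl"``, ``"d_t_dg"``, ``"d_tt_dl"``, ``"d_tt_dg"``) used by
        analytic likelihood gradients.  All entries broadcast against
        ``tdis``.
        """
        raise NotImplementedError


class ExponentialCurve(CurveFamily):
    name = "exponential"
    param_names = ("l", "g", "v")

    def eval(self, tdis, l, g, v, order: int = 0) -> dict:
        eg = np.exp(np.clip(g, -EXP_CLIP, EXP_CLIP))
        z = np.asarray(tdis, dtype=float) / eg
        e = _clipped_exp(z)
        out = {"value": l * e + v}
        if order >= 1:
            out["d_t"] = l * e / eg
            out["d_l"] = e
            out["d_g"] = -l * z * e
            out["d_v"] = np.ones_like(e)
        if order >= 2:
            out["d_tt"] = l * e / (eg * eg)
        if order >= 3:
            out["d_ttt"] = l * e / (eg * eg * eg)
            out["d_t_dl"] = e / eg
            out["d_t_dg"] = -out["d_t"] * (z + 1.0)
            out["d_tt_dl"] = e / (eg * eg)
            out["d_tt_dg"] = -out["d_tt"] * (z + 2.0)
        return out


class LinearCurve(CurveFamily):
    """theta(t) = l*t + v; used for linear-mixed-model limits and checks."""

    name = "linear"
    param_names = ("l", "v")

    def eval(self, tdis, l, g, v, order: int = 0) -> dict:
        t = np.asarray(tdis, dtype=float)
        l_arr = np.broadcast_to(np.asarray(l, dtype=float), np.broadcast_shapes(np.shape(l), t.shape))
        out = {"value": l * t + v}
        if order >= 1:
            out["d_t"] = np.ones_like(t) * l_arr
            out["d_l"] = t.copy()
            out["d_g"] = np.zeros_like(t)
            out["d_v"] = np.ones_like(t)
        if order >= 2:
            out["d_tt"] = np.zeros_like(t)
        if order >= 3:
            out["d_ttt"] = np.zeros_like(t)
            out["d_t_dl"] = np.ones_like(t)
            out["d_t_dg"] = np.zeros_like(t)
            out["d_tt_dl"] = np.zeros_like(t)
            out["d_tt_dg"] = np.zeros_like(t)
        return out


_FAMILIES: dict[str, CurveFamily] = {
    "exponential": ExponentialCurve(),
    "linear": LinearCurve(),
}


def get_family(name: str) -> CurveFamily:
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown curve family {name!r}; available: {sorted(_FAMILIES)}"
        ) from None


def theta(t, p: CurveParams, family: str = "exponential"):
    """Mean curve value at time ``t`` (months on the aligned disease scale)."""
    fam = get_family(family)
    res = fam.eval(np.asarray(t, dtype=float) + p.s, p.l, p.g, p.v)
    return res["value"]


def theta_grad(t, p: CurveParams, family: str = "exponential") -> dict:
    """Analytic partials of the mean curve.

    Returns a dict with keys ``l``, ``g``, ``v``, ``s`` and ``t``; for the
    shift family used here ``d theta/d s = d theta/d t``.
    """
    fam = get_family(family)
    res = fam.eval(np.asarray(t, dtype=float) + p.s, p.l, p.g, p.v, order=1)
    return {
        "l": res["d_l"],
        "g": res["d_g"],
        "v": res["d_v"],
        "s": res["d_t"],
        "t": res["d_t"],
    }
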