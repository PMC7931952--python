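"""Forward selection of covariate effects on rate, stage and level.

The search evaluates, at each step, every (covariate, parameter) move not
yet in the model, accepts the move with the largest AIC improvement, and
continues while AIC improves; the final model is the minimum-BIC model
among the accepted chain (including the base model).  AIC drives the
continuation because it explores more freely; the more conservative BIC
makes the final choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalDataset, ModelSpec
from .inference import FitOptions, FitResult, fit_ml

__all__ = ["SelectionStep", "SelectionTrace", "candidate_moves", "forward_select"]

logger = logging.getLogger(__name__)

_TARGET_ORDER = {"g": 0, "s": 1, "v": 2}


@dataclass
class SelectionStep:
    """One evaluated candidate: the spec, its criteria, and the verdict."""

    spec: ModelSpec
    move: tuple[str, str] | None  # (covariate, target) or None for the base
    df: int
    neg2ll: float
    aic: float
    bic: float
    accepted: bool
    step_index: int
    error: str | None = None


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: FitResult | None = None

    @property
    def accepted_steps(self) -> list[SelectionStep]:
        return [s for s in self.steps if s.accepted]

    @property
    def criterion_path(self) -> list[float]:
        """AIC values along the accepted chain (base model first)."""
        return [s.aic for s in self.accepted_steps]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            rows.append({
                "step": s.step_index,
                "move": "base" if s.move is None else f"{s.move[1]}:{s.move[0]}",
                "df": s.df, "neg2ll": s.neg2ll, "aic": s.aic, "bic": s.bic,
                "accepted": s.accepted, "error": s.error or "",
            })
        return pd.DataFrame(rows)


def _normalize_pool(pool) -> list[tuple[str, str]]:
    """Expand a pool into (covariate, target) pairs.

    Entries may already be pairs; bare covariate names expand to all three
    targets in the deterministic order g, s, v.
    """
    moves: list[tuple[str, str]] = []
    for entry in pool:
        if isinstance(entry, str):
            expanded = [(entry, t) for t in ("g", "s", "v")]
        else:
            cov, target = entry
            expanded = [(cov, target)]
        for move in expanded:
            if move[1] not in _TARGET_ORDER:
                raise ValueError(f"unknown target parameter {move[1]!r} in pool")
            if move not in moves:
                moves.append(move)
    return moves


def candidate_moves(current: ModelSpec, pool) -> list[ModelSpec]:
    """One candidate spec per (covariate, parameter) move not in ``current``.

    Ordering is deterministic: pool order, expanding bare covariates as g
    before s before v.
    """
    specs = []
    for cov, target in _normalize_pool(pool):
        if not current.has_effect(cov, target):
            specs.append(current.with_effect(cov, target))
    return specs


def forward_select(dataset: LongitudinalDataset, base: ModelSpec, pool,
                   options: FitOptions | None = None,
                   fit_fn=None) -> SelectionTrace:
    """AIC-continued, BIC-chosen forward search over covariate effects.

    Each candidate fit warm-starts from the incumbent's parameters (new
    coefficients at zero).  Failed candidate fits are skipped with a
    warning and recorded in the trace.
    """
    options = options or FitOptions()
    fit = fit_fn or fit_ml
    moves = _normalize_pool(pool)

    trace = SelectionTrace()
    base_fit = fit(dataset, base, options)
    trace.steps.append(SelectionStep(
        spec=base, move=None, df=base_fit.df, neg2ll=base_fit.neg2ll,
        aic=base_fit.aic, bic=base_fit.bic, accepted=True, step_index=0,
    ))
    current_spec, current_fit = base, base_fit
    accepted_chain = [(base, base_fit)]

    step = 0
    while True:
        step += 1
        remaining = [m for m in moves if not current_spec.has_effect(*m)]
        if not remaining:
            break
        best = None
        for cov, target in remaining:
            cand = current_spec.with_effect(cov, target)
            try:
                opts = _warm_options(options, current_fit, target)
                cand_fit = fit(dataset, cand, opts)
            except Exception as exc:  # candidate failures are survivable
                logger.warning("candidate %s on %s failed: %s", cov, target, exc)
                trace.steps.append(SelectionStep(
                    spec=cand, move=(cov, target), df=0, neg2ll=float("nan"),
                    aic=float("inf"), bic=float("inf"), accepted=False,
                    step_index=step, error=str(exc),
                ))
                continue
            rec = SelectionStep(
                spec=cand, move=(cov, target), df=cand_fit.df,
                neg2ll=cand_fit.neg2ll, aic=cand_fit.aic, bic=cand_fit.bic,
                accepted=False, step_index=step,
            )
            trace.steps.append(rec)
            if best is None or cand_fit.aic < best[2].aic:
                best = (rec, cand, cand_fit)
        if best is None or best[2].aic >= current_fit.aic:
            break
        best[0].accepted = True
        current_spec, current_fit = best[1], best[2]
        accepted_chain.append((current_spec, current_fit))

    final_spec, final_fit = min(accepted_chain, key=lambda pair: pair[1].bic)
    trace.final_spec = final_spec
    trace.final_fit = final_fit
    return trace


def _warm_options(options: FitOptions, incumbent: FitResult, target: str) -> FitOptions:
    import dataclasses

    params = incumbent.params.copy()
    # appended effect coefficient starts at zero; the stage block appends
    # after group dummies and existing stage covariates
    if target == "s":
        params.beta_s = np.append(params.beta_s, 0.0)
    elif target == "g":
        params.beta_g = np.append(params.beta_g, 0.0)
    else:
        params.beta_v = np.append(params.beta_v, 0.0)
    opts = dataclasses.replace(options, init_params=params)
    return opts
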