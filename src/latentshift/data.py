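"""Long-format longitudinal data, model specifications and design matrices.

Data enter as one row per visit (subject id, months since baseline,
outcome score, baseline group label, optional covariates).  Times are in
months throughout; the identifiability convention is that disease month 0
is the average baseline stage of the reference group (by default the
cognitively normal group), enforced by giving the reference group an
all-zero stage design row.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GROUPS",
    "Visit",
    "Subject",
    "LongitudinalDataset",
    "ModelSpec",
    "SubjectDesign",
    "DesignMatrices",
    "SchemaError",
    "ValidationError",
    "read_long_csv",
    "write_long_csv",
    "build_designs",
    "write_fit",
    "read_fit",
]

logger = logging.getLogger(__name__)

#: the five baseline strata, reference level first
DEFAULT_GROUPS = (
    "cognitively normal",
    "significant memory concern",
    "MCI (early)",
    "MCI (late)",
    "dementia",
)


class SchemaError(ValueError):
    """A mandatory column is missing or mis-declared."""


class ValidationError(ValueError):
    """Row-level data violates the dataset contract."""


@dataclass(frozen=True)
class Visit:
    """A single assessment: months since study baseline and the score."""

    t: float
    y: float

    def __post_init__(self):
        if not np.isfinite(self.t) or self.t < 0:
            raise ValidationError(f"visit time must be finite and >= 0, got {self.t!r}")
        if not np.isfinite(self.y):
            raise ValidationError(f"score must be finite, got {self.y!r}")


@dataclass
class Subject:
    """One participant: group label, covariates, and time-ordered visits."""

    id: str
    group: str
    covariates: dict[str, float] = field(default_factory=dict)
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self):
        if not self.visits:
            raise ValidationError(f"subject {self.id!r} has no visits")
        self.visits = sorted(self.visits, key=lambda v: v.t)

    @property
    def times(self) -> np.ndarray:
        return np.array([v.t for v in self.visits], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.array([v.y for v in self.visits], dtype=float)

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class LongitudinalDataset:
    """A cohort of subjects plus its covariate schema and group levels."""

    subjects: list[Subject]
    group_levels: tuple[str, ...] = DEFAULT_GROUPS
    reference_group: str | None = None
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.reference_group is None:
            self.reference_group = self.group_levels[0]
        if self.reference_group not in self.group_levels:
            raise ValidationError(
                f"reference group {self.reference_group!r} not among levels {self.group_levels}"
            )
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes[:5]}")
        for s in self.subjects:
            if s.group not in self.group_levels:
                raise ValidationError(
                    f"subject {s.id!r} has unknown group label {s.group!r}; "
                    f"declared levels: {list(self.group_levels)}"
                )
            missing = [c for c in self.covariate_names if c not in s.covariates]
            for c in missing:
                s.covariates[c] = float("nan")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_visits for s in self.subjects)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for v in s.visits:
                row = {"id": s.id, "time": v.t, "score": v.y, "group": s.group}
                row.update({c: s.covariates.get(c, np.nan) for c in self.covariate_names})
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: tuple[str, ...] = (),
        group_levels: tuple[str, ...] = DEFAULT_GROUPS,
        reference_group: str | None = None,
    ) -> "LongitudinalDataset":
        subjects = []
        for sid, sub in df.groupby("id", sort=False):
            times = sub["time"].to_numpy(dtype=float)
            if np.any(times < 0):
                raise ValidationError(f"subject {sid!r} has a negative visit time")
            covs = {c: float(sub[c].iloc[0]) for c in covariates}
            visits = [
                Visit(float(t), float(y))
                for t, y in zip(times, sub["score"].to_numpy(dtype=float))
            ]
            subjects.append(Subject(str(sid), str(sub["group"].iloc[0]), covs, visits))
        return cls(subjects, tuple(group_levels), reference_group, tuple(covariates))


def read_long_csv(path, schema: dict | None = None) -> LongitudinalDataset:
    """Read a long-format longitudinal CSV into a validated dataset.

    Parameters
    ----------
    path : str or Path
        UTF-8 CSV with a header row.
    schema : dict, optional
        Column mapping with keys ``id``, ``time``, ``score``, ``group``
        (defaults to those literal names), plus optional ``covariates``
        (list of column names), ``group_levels`` and ``reference_group``.

    Rows with a missing score are dropped (count logged).  Visits are
    sorted by time within subject.
    """
    schema = dict(schema or {})
    colmap = {k: schema.get(k, k) for k in ("id", "time", "score", "group")}
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) {missing} not found in {path}")
    covariates = tuple(schema.get("covariates", ()))
    missing_cov = [c for c in covariates if c not in df.columns]
    if missing_cov:
        raise SchemaError(f"declared covariate column(s) {missing_cov} not found in {path}")

    df = df.rename(columns={v: k for k, v in colmap.items() if v != k})
    n_before = len(df)
    df = df[df["score"].notna()]
    if len(df) < n_before:
        logger.info("dropped %d row(s) with missing score", n_before - len(df))
    if df.empty:
        raise ValidationError(f"no rows with a valid score in {path}")
    bad_t = df[df["time"] < 0]
    if not bad_t.empty:
        raise ValidationError(
            f"negative time for subject(s) {sorted(bad_t['id'].astype(str).unique())[:5]}"
        )
    group_levels = tuple(schema.get("group_levels", DEFAULT_GROUPS))
    unknown = sorted(set(df["group"].astype(str)) - set(group_levels))
    if unknown:
        raise ValidationError(
            f"unknown group label(s) {unknown}; declared levels: {list(group_levels)}"
        )
    return LongitudinalDataset.from_dataframe(
        df,
        covariates=covariates,
        group_levels=group_levels,
        reference_group=schema.get("reference_group"),
    )


@dataclass(frozen=True)
class ModelSpec:
    """Declarative placement of covariate effects on the curve parameters.

    ``effects_on_g`` shift the log time-scale (rate of decline),
    ``effects_on_s`` the disease stage (months), and ``effects_on_v`` the
    pre-disease score level.  The baseline-group factor always acts on the
    stage (K-1 dummies, reference level all-zero) unless
    ``group_on_s=False``.
    """

    curve_family: str = "exponential"
    effects_on_g: tuple[str, ...] = ()
    effects_on_s: tuple[str, ...] = ()
    effects_on_v: tuple[str, ...] = ()
    group_on_s: bool = True
    group_levels: tuple[str, ...] = DEFAULT_GROUPS
    reference_group: str | None = None

    def __post_init__(self):
        for attr in ("effects_on_g", "effects_on_s", "effects_on_v"):
            effs = getattr(self, attr)
            object.__setattr__(self, attr, tuple(effs))
            if len(set(effs)) != len(effs):
                raise ValueError(f"duplicate covariate in {attr}: {effs}")
        object.__setattr__(self, "group_levels", tuple(self.group_levels))
        if self.reference_group is None:
            object.__setattr__(self, "reference_group", self.group_levels[0])
        if self.reference_group not in self.group_levels:
            raise ValueError(
                f"reference group {self.reference_group!r} not in {self.group_levels}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.group_levels)

    @property
    def nonreference_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.group_levels if g != self.reference_group)

    def with_effect(self, covariate: str, target: str) -> "ModelSpec":
        """Return a copy with ``covariate`` added to the effects on ``target``."""
        if target not in ("g", "s", "v"):
            raise ValueError(f"target must be one of g, s, v; got {target!r}")
        attr = f"effects_on_{target}"
        current = getattr(self, attr)
        if covariate in current:
            raise ValueError(f"{covariate!r} already acts on {target}")
        return dataclasses.replace(self, **{attr: current + (covariate,)})

    def has_effect(self, covariate: str, target: str) -> bool:
        return covariate in getattr(self, f"effects_on_{target}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for key in ("effects_on_g", "effects_on_s", "effects_on_v", "group_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SubjectDesign:
    """Design rows of one subject for the three covariate channels."""

    x_s: np.ndarray
    x_g: np.ndarray
    x_v: np.ndarray


@dataclass
class DesignMatrices:
    """Per-subject design rows for the stage, rate and level channels.

    ``X_s`` contains the K-1 group dummies (reference row all zeros)
    followed by the stage covariates; continuous stage covariates are
    mean-centered on reference-group values so that disease month 0 keeps
    its meaning as the average baseline stage of the reference group.
    ``included`` flags complete-case subjects.
    """

    X_s: np.ndarray
    X_g: np.ndarray
    X_v: np.ndarray
    names_s: tuple[str, ...]
    names_g: tuple[str, ...]
    names_v: tuple[str, ...]
    included: np.ndarray
    subject_ids: tuple[str, ...]
    centering: dict[str, float] = field(default_factory=dict)

    def row(self, i: int) -> SubjectDesign:
        return SubjectDesign(self.X_s[i], self.X_g[i], self.X_v[i])


def _is_indicator(values: np.ndarray) -> bool:
    vals = np.unique(values[np.isfinite(values)])
    return vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0)))


def build_designs(dataset: LongitudinalDataset, spec: ModelSpec) -> DesignMatrices:
    """Build the per-subject design rows implied by a model spec.

    Group dummies use the declaration order of the non-reference levels;
    covariate columns follow their declaration order in the spec, so
    coefficient meaning is independent of subject ordering.  Subjects with
    a missing value in any required covariate are flagged as excluded
    (complete-case per fitted model, count logged).  A rank check of the
    stacked design (with intercept) warns about non-identifiable columns.
    """
    needed = set(spec.effects_on_g) | set(spec.effects_on_s) | set(spec.effects_on_v)
    unknown = needed - set(dataset.covariate_names)
    if unknown:
        raise SchemaError(
            f"spec references covariate(s) {sorted(unknown)} absent from dataset schema "
            f"{list(dataset.covariate_names)}"
        )
    n = dataset.n_subjects
    nonref = spec.nonreference_groups if spec.group_on_s else ()
    names_s = tuple(f"group:{g}" for g in nonref) + spec.effects_on_s
    names_g = spec.effects_on_g
    names_v = spec.effects_on_v

    cov_values = {
        c: np.array([s.covariates.get(c, np.nan) for s in dataset.subjects], dtype=float)
        for c in needed
    }
    included = np.ones(n, dtype=bool)
    for c in needed:
        included &= np.isfinite(cov_values[c])
    n_excluded = int(n - included.sum())
    if n_excluded:
        logger.info(
            "excluding %d subject(s) with missing covariate values (complete case)",
            n_excluded,
        )

    # center continuous stage covariates on reference-group values so the
    # timeline origin stays anchored at the reference group's baseline stage
    ref_mask = np.array(
        [s.group == spec.reference_group for s in dataset.subjects], dtype=bool
    )
    centering: dict[str, float] = {}
    for c in spec.effects_on_s:
        vals = cov_values[c]
        if _is_indicator(vals):
            continue
        ref_vals = vals[ref_mask & np.isfinite(vals)]
        centering[c] = float(np.mean(ref_vals)) if ref_vals.size else float(
            np.nanmean(vals)
        )

    X_s = np.zeros((n, len(names_s)))
    for j, gname in enumerate(nonref):
        X_s[:, j] = [1.0 if s.group == gname else 0.0 for s in dataset.subjects]
    for j, c in enumerate(spec.effects_on_s):
        X_s[:, len(nonref) + j] = cov_values[c] - centering.get(c, 0.0)
    X_g = np.column_stack([cov_values[c] for c in names_g]) if names_g else np.zeros((n, 0))
    X_v = np.column_stack([cov_values[c] for c in names_v]) if names_v else np.zeros((n, 0))

    # within each channel the design (with intercept, since l/g/v carry
    # free intercepts) must have full column rank; a covariate may appear
    # in several channels without harming identifiability
    for channel, M, names in (("s", X_s, names_s), ("g", X_g, names_g), ("v", X_v, names_v)):
        if M.shape[1] == 0:
            continue
        stacked = np.column_stack([np.ones(int(included.sum())), M[included]])
        rank = np.linalg.matrix_rank(stacked)
        if rank < stacked.shape[1]:
            warnings.warn(
                f"design for effects on {channel} is rank deficient "
                f"(rank {rank} < {stacked.shape[1]} incl. intercept; columns "
                f"{list(names)}); some effects are not identifiable",
                UserWarning,
                stacklevel=2,
            )

    return DesignMatrices(
        X_s=X_s,
        X_g=X_g,
        X_v=X_v,
        names_s=names_s,
        names_g=names_g,
        names_v=names_v,
        included=included,
        subject_ids=tuple(s.id for s in dataset.subjects),
        centering=centering,
    )


def write_long_csv(dataset: LongitudinalDataset, path) -> None:
    """Write a dataset in long format with full float precision.

    ``read_long_csv`` of the result reproduces all times and scores
    exactly.
    """
    dataset.to_dataframe().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# fit serialization

def write_fit(result, path, posterior: pd.DataFrame | None = None) -> None:
    """Serialize a fit to JSON with a CSV parameter table alongside.

    ``path`` is the JSON path; the parameter table goes to
    ``<stem>.params.csv`` and the per-subject posterior table (possibly
    empty) to ``<stem>.posterior.csv``.
    """
    import pathlib

    path = pathlib.Path(path)
    payload = result.to_dict()
    path.write_text(json.dumps(payload, indent=2))

    table = pd.DataFrame(result.parameter_table())
    table.to_csv(path.with_suffix(".params.csv"), index=False)

    post_path = path.with_suffix(".posterior.csv")
    cols = ["subject_id", "s_hat_months", "x0_hat", "predicted_disease_month_at_baseline"]
    if posterior is None:
        posterior = pd.DataFrame(columns=cols)
    posterior.to_csv(post_path, index=False)


def read_fit(path) -> dict:
    """Read back a serialized fit (full stored precision)."""
    with open(path) as fh:
        return json.load(fh)
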