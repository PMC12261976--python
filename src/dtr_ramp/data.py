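"""Core containers and table I/O for multistage treatment cohorts.

A cohort is one row per subject with, for each decision stage ``t``:
feature columns (the history ``H_t``), a binary treatment ``A_t`` coded
{-1, +1}, an optional known assignment probability ``p_t = P(A_t = observed
| H_t)``, and a single terminal cumulative reward ``Y`` (sign-unrestricted).

Feature matrices never store an intercept column; the intercept is an
explicit scalar in :class:`DTRCoefficients`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrajectoryDataset",
    "StageDesign",
    "DTRCoefficients",
    "StandardizationState",
    "SchemaError",
    "ValidationError",
    "sign0",
    "read_cohort",
    "write_cohort",
    "stage_design_from_schema",
    "load_schema",
    "standardize",
]


class SchemaError(ValueError):
    """A column map does not match the table it describes."""


class ValidationError(ValueError):
    """Cohort values violate a structural invariant."""


def sign0(x):
    """Sign with the fixed tie-break sign(0) = +1.

    Used everywhere a decision rule or concordance indicator is evaluated,
    so that results are reproducible when a decision value is exactly zero.
    """
    return np.where(np.asarray(x, dtype=float) >= 0.0, 1.0, -1.0)


@dataclass
class TrajectoryDataset:
    """n subjects followed over T decision stages.

    Parameters
    ----------
    features : list of (n, d_t) float arrays
        Per-stage history matrices ``H_t`` (no intercept column).
    treatments : (n, T) array in {-1, +1}
        Observed assignments ``A_t``.
    reward : (n,) array
        Terminal cumulative reward ``Y``; larger is better.
    propensities : (n, T) array in (0, 1), optional
        ``P(A_t = observed | H_t)``; ``None`` when unknown (estimate with
        :mod:`dtr_ramp.nuisance`).
    column_names : list of list of str
        Per-stage feature column names, aligned with ``features``.
    """

    features: list
    treatments: np.ndarray
    reward: np.ndarray
    propensities: np.ndarray | None = None
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        self.features = [np.asarray(h, dtype=float) for h in self.features]
        self.treatments = np.asarray(self.treatments, dtype=float)
        if self.treatments.ndim == 1:
            self.treatments = self.treatments[:, None]
        self.reward = np.asarray(self.reward, dtype=float)
        if not self.column_names:
            self.column_names = [
                [f"h{t+1}_{j}" for j in range(h.shape[1])]
                for t, h in enumerate(self.features)
            ]
        n, T = self.n, self.T
        if self.treatments.shape != (n, T):
            raise ValidationError(
                f"treatments shape {self.treatments.shape} != ({n}, {T})"
            )
        if self.reward.shape != (n,):
            raise ValidationError("reward length does not match feature rows")
        if not np.isin(self.treatments, (-1.0, 1.0)).all():
            raise ValidationError("every treatment entry must be -1 or +1")
        if not np.isfinite(self.reward).all():
            raise ValidationError("reward contains non-finite values")
        for t, h in enumerate(self.features):
            if h.shape[0] != n:
                raise ValidationError("stage matrices must share row count")
            if not np.isfinite(h).all():
                raise ValidationError(f"stage {t+1} features contain non-finite values")
        if self.propensities is not None:
            self.propensities = np.asarray(self.propensities, dtype=float)
            if self.propensities.ndim == 1:
                self.propensities = self.propensities[:, None]
            if self.propensities.shape != (n, T):
                raise ValidationError("propensities shape mismatch")
            if not ((self.propensities > 0) & (self.propensities < 1)).all():
                raise ValidationError(
                    "assignment probabilities must lie strictly in (0, 1)"
                )

    @property
    def n(self) -> int:
        return self.features[0].shape[0]

    @property
    def T(self) -> int:
        return len(self.features)

    def subset(self, rows) -> "TrajectoryDataset":
        rows = np.asarray(rows)
        return TrajectoryDataset(
            features=[h[rows] for h in self.features],
            treatments=self.treatments[rows],
            reward=self.reward[rows],
            propensities=None if self.propensities is None else self.propensities[rows],
            column_names=[list(c) for c in self.column_names],
        )

    def with_reward(self, reward) -> "TrajectoryDataset":
        return replace(self, reward=np.asarray(reward, dtype=float))

    def with_propensities(self, p) -> "TrajectoryDataset":
        return replace(self, propensities=np.asarray(p, dtype=float))


@dataclass
class StageDesign:
    """Bookkeeping of which history columns enter variable selection.

    ``penalized[t]`` indexes the P candidate tailoring features ``O_t``
    (P identical across stages; candidates are aligned by position so a
    feature measured repeatedly forms one cross-stage group).
    ``unpenalized[t]`` indexes always-kept columns ``W_t`` such as earlier
    treatments. The intercept is implicit and never penalized.
    """

    penalized: list
    unpenalized: list
    intercept: bool = True

    def __post_init__(self):
        self.penalized = [np.asarray(o, dtype=int) for o in self.penalized]
        self.unpenalized = [np.asarray(w, dtype=int) for w in self.unpenalized]
        if len(self.penalized) != len(self.unpenalized):
            raise ValidationError("penalized/unpenalized must cover the same stages")
        sizes = {len(o) for o in self.penalized}
        if len(sizes) > 1:
            raise ValidationError("P must be identical across stages")
        for o, w in zip(self.penalized, self.unpenalized):
            if np.intersect1d(o, w).size:
                raise ValidationError("O_t and W_t must be disjoint")

    @property
    def T(self) -> int:
        return len(self.penalized)

    @property
    def P(self) -> int:
        return len(self.penalized[0])

    def validate_against(self, data: TrajectoryDataset) -> None:
        if self.T != data.T:
            raise ValidationError("design stage count does not match data")
        for t in range(self.T):
            d_t = data.features[t].shape[1]
            idx = np.concatenate([self.penalized[t], self.unpenalized[t]])
            if idx.size and (idx.min() < 0 or idx.max() >= d_t):
                raise ValidationError(f"stage {t+1} column index out of range")

    @classmethod
    def all_penalized(cls, data: TrajectoryDataset) -> "StageDesign":
        """Every feature column is a selection candidate (requires equal d_t)."""
        return cls(
            penalized=[np.arange(h.shape[1]) for h in data.features],
            unpenalized=[np.array([], dtype=int) for _ in data.features],
        )


@dataclass
class DTRCoefficients:
    """Per-stage linear decision rules g_t(H_t) = W_t'alpha_t + O_t'beta_t + gamma_t.

    The recommended treatment at stage t is sign(g_t) with sign(0) = +1.
    """

    beta: list
    alpha: list
    gamma: np.ndarray

    def __post_init__(self):
        self.beta = [np.asarray(b, dtype=float) for b in self.beta]
        self.alpha = [np.asarray(a, dtype=float) for a in self.alpha]
        self.gamma = np.asarray(self.gamma, dtype=float)

    @property
    def T(self) -> int:
        return len(self.beta)

    @classmethod
    def zeros(cls, design: StageDesign) -> "DTRCoefficients":
        return cls(
            beta=[np.zeros(len(o)) for o in design.penalized],
            alpha=[np.zeros(len(w)) for w in design.unpenalized],
            gamma=np.zeros(design.T),
        )

    def copy(self) -> "DTRCoefficients":
        return DTRCoefficients(
            [b.copy() for b in self.beta],
            [a.copy() for a in self.alpha],
            self.gamma.copy(),
        )

    def decision_values(self, data: TrajectoryDataset, design: StageDesign) -> np.ndarray:
        """(n, T) matrix of g_t(H_it)."""
        g = np.empty((data.n, self.T))
        for t in range(self.T):
            h = data.features[t]
            g[:, t] = (
                h[:, design.penalized[t]] @ self.beta[t]
                + h[:, design.unpenalized[t]] @ self.alpha[t]
                + self.gamma[t]
            )
        return g

    def recommend(self, data: TrajectoryDataset, design: StageDesign) -> np.ndarray:
        return sign0(self.decision_values(data, design))

    def selected(self, threshold: float = 1e-6) -> list:
        """Per-stage boolean masks of penalized features with |beta| > threshold."""
        return [np.abs(b) > threshold for b in self.beta]

    def count_nonzero(self, threshold: float = 1e-6) -> int:
        """Number of coefficients (all of theta) exceeding the threshold."""
        k = int(np.sum(np.abs(self.gamma) > threshold))
        for b in self.beta:
            k += int(np.sum(np.abs(b) > threshold))
        for a in self.alpha:
            k += int(np.sum(np.abs(a) > threshold))
        return k


@dataclass
class StandardizationState:
    """Per-stage, per-column centers and scales learned on training rows.

    Columns whose observed values lie in {-1, +1} (treatment codings) are
    passed through untouched. Constant columns get scale 1 with a warning.
    """

    centers: list
    scales: list

    def transform(self, data: TrajectoryDataset) -> TrajectoryDataset:
        feats = []
        for t, h in enumerate(data.features):
            feats.append((h - self.centers[t]) / self.scales[t])
        return replace(data, features=feats)

    def transform_stage(self, t: int, h: np.ndarray) -> np.ndarray:
        return (np.asarray(h, dtype=float) - self.centers[t]) / self.scales[t]


def standardize(data: TrajectoryDataset, fit_rows=None):
    """Center and scale feature columns; return (transformed data, state).

    Uses the population standard deviation (divide by n). The state is
    returned so held-out rows can reuse the training statistics.
    """
    if fit_rows is None:
        fit_rows = np.arange(data.n)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValidationError("fit_rows must be nonempty")
    centers, scales = [], []
    for t, h in enumerate(data.features):
        sub = h[fit_rows]
        center = sub.mean(axis=0)
        scale = sub.std(axis=0)  # population convention
        passthrough = np.array(
            [np.isin(np.unique(sub[:, j]), (-1.0, 1.0)).all() for j in range(h.shape[1])]
        )
        constant = scale == 0.0
        if (constant & ~passthrough).any():
            bad = [data.column_names[t][j] for j in np.where(constant & ~passthrough)[0]]
            warnings.warn(
                f"stage {t+1}: constant feature column(s) {bad}; scale set to 1",
                stacklevel=2,
            )
        center = np.where(passthrough | constant, 0.0, center)  # values untouched
        scale = np.where(passthrough | constant, 1.0, scale)
        centers.append(center)
        scales.append(scale)
    state = StandardizationState(centers=centers, scales=scales)
    return state.transform(data), state


# ---------------------------------------------------------------------------
# Table I/O


def load_schema(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _recode_treatment(col: pd.Series, name: str) -> np.ndarray:
    values = col.to_numpy()
    levels = sorted(pd.unique(values).tolist())
    if levels in ([-1, 1], [-1.0, 1.0]):
        return values.astype(float)
    if len(levels) != 2:
        raise SchemaError(
            f"treatment column {name!r} has {len(levels)} levels; exactly 2 required"
        )
    # deterministic coding: lexicographically smaller level -> -1
    return np.where(values == levels[0], -1.0, 1.0)


def read_cohort(path, schema) -> TrajectoryDataset:
    """Read a delimited cohort table guided by a role-mapping schema.

    ``schema`` is a mapping (or path to a YAML file) with keys::

        stages:
          - features: [Z1, Z2, X11]
            treatment: A1
            propensity: p1        # optional
            unpenalized: []       # optional subset of features
          - ...
        reward: Y

    Treatments in any declared 2-level coding are mapped to {-1, +1} with
    the lexicographically smaller level becoming -1.
    """
    if isinstance(schema, (str, bytes)) or hasattr(schema, "__fspath__"):
        schema = load_schema(schema)
    table = pd.read_csv(path, sep=None, engine="python")
    missing = []
    for st in schema["stages"]:
        missing += [c for c in st["features"] if c not in table.columns]
        if st["treatment"] not in table.columns:
            missing.append(st["treatment"])
        if st.get("propensity") and st["propensity"] not in table.columns:
            missing.append(st["propensity"])
    if schema["reward"] not in table.columns:
        missing.append(schema["reward"])
    if missing:
        raise SchemaError(f"columns missing from {path}: {sorted(set(missing))}")

    features, names, treats, props = [], [], [], []
    has_prop = all(st.get("propensity") for st in schema["stages"])
    for st in schema["stages"]:
        features.append(table[st["features"]].to_numpy(dtype=float))
        names.append(list(st["features"]))
        treats.append(_recode_treatment(table[st["treatment"]], st["treatment"]))
        if has_prop:
            props.append(table[st["propensity"]].to_numpy(dtype=float))
    reward = table[schema["reward"]].to_numpy(dtype=float)
    if not np.isfinite(reward).all():
        raise ValidationError("reward column contains non-finite values")
    return TrajectoryDataset(
        features=features,
        treatments=np.column_stack(treats),
        reward=reward,
        propensities=np.column_stack(props) if has_prop else None,
        column_names=names,
    )


def stage_design_from_schema(schema, data: TrajectoryDataset) -> StageDesign:
    """Build a StageDesign from the optional ``unpenalized`` schema keys."""
    if isinstance(schema, (str, bytes)) or hasattr(schema, "__fspath__"):
        schema = load_schema(schema)
    pen, unpen = [], []
    for t, st in enumerate(schema["stages"]):
        cols = list(st["features"])
        excluded = set(st.get("unpenalized", []))
        pen.append([j for j, c in enumerate(cols) if c not in excluded])
        unpen.append([j for j, c in enumerate(cols) if c in excluded])
    design = StageDesign(penalized=pen, unpenalized=unpen)
    design.validate_against(data)
    return design


def write_cohort(data: TrajectoryDataset, path, sep=",") -> pd.DataFrame:
    """Write the cohort as one flat delimited table; returns the frame."""
    frame = {}
    for t in range(data.T):
        for j, name in enumerate(data.column_names[t]):
            if name not in frame:  # stage-shared columns written once
                frame[name] = data.features[t][:, j]
        frame[f"A{t+1}"] = data.treatments[:, t].astype(int)
        if data.propensities is not None:
            frame[f"p{t+1}"] = data.propensities[:, t]
    frame["Y"] = data.reward
    df = pd.DataFrame(frame)
    if path is not None:
        df.to_csv(path, sep=sep, index=False)
    return df
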