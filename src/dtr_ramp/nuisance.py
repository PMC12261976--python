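"""Nuisance models: treatment-assignment probabilities.

When assignment probabilities are unknown (observational data, or SMART
records that did not store them) they are estimated per stage by
L1-penalized logistic regression of A_t on H_t, with the penalty strength
chosen by cross-validated deviance. Probability clipping is off by default
(positivity is assumed to hold); a clipping floor and the related
extreme-weight truncation are available for observational cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegressionCV

from .data import TrajectoryDataset

__all__ = [
    "PropensityModel",
    "estimate_propensity",
    "fit_propensity_models",
    "attach_propensities",
    "filter_extreme_weights",
]


@dataclass
class PropensityModel:
    """Fitted stage model; predicts P(A_t = observed | H_t)."""

    stage: int
    model: object
    clip: float | None = None

    def predict_observed(self, features: np.ndarray, treatments: np.ndarray) -> np.ndarray:
        p_plus = self.model.predict_proba(features)[:, list(self.model.classes_).index(1.0)]
        p = np.where(treatments > 0, p_plus, 1.0 - p_plus)
        if self.clip is not None:
            p = np.clip(p, self.clip, 1.0 - self.clip)
        return np.clip(p, 1e-12, 1.0 - 1e-12)


def estimate_propensity(
    data: TrajectoryDataset,
    stage: int,
    clip: float | None = None,
    cv: int = 3,
    Cs: int = 10,
    random_state: int | None = None,
):
    """Fit the stage-``stage`` (0-based) assignment model.

    Returns ``(p_hat, PropensityModel)`` with ``p_hat`` the predicted
    probability of each subject's observed arm.
    """
    a = data.treatments[:, stage]
    counts = [(a == v).sum() for v in (-1.0, 1.0)]
    if min(counts) < 2:
        raise ValueError(
            f"stage {stage + 1} has a nearly single-arm assignment "
            f"(counts {counts}); propensity model is degenerate"
        )
    h = data.features[stage]
    model = LogisticRegressionCV(
        penalty="l1",
        solver="liblinear",
        Cs=Cs,
        cv=min(cv, min(counts)),
        scoring="neg_log_loss",
        random_state=random_state,
        max_iter=200,
    ).fit(h, a)
    pm = PropensityModel(stage=stage, model=model, clip=clip)
    return pm.predict_observed(h, a), pm


def fit_propensity_models(
    data: TrajectoryDataset,
    clip: float | None = None,
    random_state: int | None = None,
):
    """Fit all stage models; returns (p matrix (n, T), list of models)."""
    p = np.empty((data.n, data.T))
    models = []
    for t in range(data.T):
        p[:, t], pm = estimate_propensity(
            data, t, clip=clip, random_state=random_state
        )
        models.append(pm)
    return p, models


def attach_propensities(data: TrajectoryDataset, models) -> TrajectoryDataset:
    """Predict observed-arm probabilities for ``data`` from fitted models."""
    p = np.empty((data.n, data.T))
    for t, pm in enumerate(models):
        p[:, t] = pm.predict_observed(data.features[t], data.treatments[:, t])
    return data.with_propensities(p)


def filter_extreme_weights(data: TrajectoryDataset, cap: float = 10.0):
    """Drop subjects whose |Y| / prod_t p_t exceeds ``cap``.

    An optional stabilization step for observational cohorts where a few
    near-positivity-violating subjects would dominate the weighted
    objective. Returns (filtered dataset, boolean keep mask).
    """
    if data.propensities is None:
        raise ValueError("propensities required before weight truncation")
    ratio = np.abs(data.reward) / np.prod(data.propensities, axis=1)
    keep = ratio <= cap
    return data.subset(np.where(keep)[0]), keep
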