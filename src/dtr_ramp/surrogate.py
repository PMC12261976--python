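"""Multistage ramp-loss surrogate of the inverse-probability-weighted value.

The value of a linear regime theta = (theta_1, ..., theta_T) is approximated
by

    V(theta) = sum_i [ w_i+ * min_t psi(A_it g_t(H_it) / eta)
                     + w_i- * sum_{a != A_i} min_t psi(a_t g_t(H_it) / eta) ]

with ramp psi(x) = max(min(x, 1), 0), positive/negative-part weights
w_i± = Y_i± / prod_t p(A_it | H_it), and the negative-part sum running over
all 2^T - 1 treatment sequences other than the observed one. The shifting
parameter eta in (0, 1] sharpens the ramp toward the 0-1 loss as it shrinks.
Enumerating alternative sequences is exact and costs O(n 2^T T), acceptable
for the small stage counts (T <= 4) this estimator targets.

``scale="mean"`` divides by n (the fitting objective); ``scale="sum"`` is
the raw sum used by the tuning criterion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LassoCV

from .data import DTRCoefficients, StageDesign, TrajectoryDataset

__all__ = [
    "psi",
    "multistage_surrogate",
    "SurrogateTerms",
    "build_surrogate_terms",
    "empirical_value_surrogate",
    "residualize_outcome",
]


def psi(x):
    """Ramp function max(min(x, 1), 0): nondecreasing, 1-Lipschitz, in [0, 1]."""
    return np.clip(x, 0.0, 1.0)


def multistage_surrogate(margins):
    """min over stages of the per-stage ramps; in [0, 1].

    Equals the product of correct-decision indicators whenever every
    |margin| >= 1.
    """
    return np.min(psi(np.asarray(margins, dtype=float)), axis=-1)


@dataclass
class SurrogateTerms:
    """Flattened weighted terms of the surrogate objective.

    Each row m is one (subject, treatment-sequence) pair: the observed
    sequence for subjects with Y > 0, every alternative sequence for
    subjects with Y < 0. Subjects with Y = 0 contribute nothing.
    """

    weights: np.ndarray  # (M,) nonnegative; Y±_i / prod_t p_it
    signs: np.ndarray  # (M, T) the treatment sequence of the term
    rows: np.ndarray  # (M,) subject index into the dataset

    @property
    def M(self) -> int:
        return self.weights.shape[0]


def build_surrogate_terms(data: TrajectoryDataset) -> SurrogateTerms:
    if data.propensities is None:
        raise ValueError("assignment probabilities are required; fit them first")
    T = data.T
    prodp = np.prod(data.propensities, axis=1)
    w_pos = np.maximum(data.reward, 0.0) / prodp
    w_neg = np.maximum(-data.reward, 0.0) / prodp

    weights, signs, rows = [], [], []
    pos_rows = np.where(w_pos > 0)[0]
    if pos_rows.size:
        weights.append(w_pos[pos_rows])
        signs.append(data.treatments[pos_rows])
        rows.append(pos_rows)
    neg_rows = np.where(w_neg > 0)[0]
    if neg_rows.size:
        for a in itertools.product((-1.0, 1.0), repeat=T):
            a = np.array(a)
            differs = (data.treatments[neg_rows] != a).any(axis=1)
            sel = neg_rows[differs]
            if sel.size:
                weights.append(w_neg[sel])
                signs.append(np.tile(a, (sel.size, 1)))
                rows.append(sel)
    if not weights:
        return SurrogateTerms(
            np.empty(0), np.empty((0, T)), np.empty(0, dtype=int)
        )
    return SurrogateTerms(
        weights=np.concatenate(weights),
        signs=np.vstack(signs),
        rows=np.concatenate(rows).astype(int),
    )


def _terms_value(terms: SurrogateTerms, g: np.ndarray, eta: float) -> float:
    if terms.M == 0:
        return 0.0
    margins = terms.signs * g[terms.rows] / eta
    return float(terms.weights @ multistage_surrogate(margins))


def empirical_value_surrogate(
    theta: DTRCoefficients,
    eta: float,
    data: TrajectoryDataset,
    design: StageDesign,
    scale: str = "mean",
    terms: SurrogateTerms | None = None,
) -> float:
    """Evaluate the surrogate value of ``theta`` on ``data``; higher is better."""
    if not 0.0 < eta <= 1.0 + 1e-12:
        # eta > 1 is allowed numerically but the method's range is (0, 1]
        if eta <= 0:
            raise ValueError("eta must be positive")
    if scale not in ("mean", "sum"):
        raise ValueError("scale must be 'mean' or 'sum'")
    if terms is None:
        terms = build_surrogate_terms(data)
    g = theta.decision_values(data, design)
    value = _terms_value(terms, g, eta)
    return value / data.n if scale == "mean" else value


def residualize_outcome(
    data: TrajectoryDataset,
    estimator: str = "lasso",
    random_state: int | None = None,
):
    """Replace Y by the residual Y - E_hat[Y | H_1].

    Subtracting any function of the stage-1 history leaves the population
    value objective unchanged while shrinking the weight magnitudes, which
    stabilizes the fit. Returns ``(dataset_with_residual_reward, model)``
    where ``model`` has ``predict(H1) -> conditional mean`` for applying the
    same correction to held-out rows.
    """
    h1 = data.features[0]
    if estimator == "linear":
        if np.linalg.matrix_rank(np.column_stack([np.ones(data.n), h1])) < h1.shape[1] + 1:
            warnings.warn(
                "singular stage-1 design for linear conditional mean; "
                "falling back to lasso",
                stacklevel=2,
            )
            estimator = "lasso"
    if estimator == "linear":
        from sklearn.linear_model import LinearRegression

        model = LinearRegression().fit(h1, data.reward)
    elif estimator == "lasso":
        model = LassoCV(cv=5, random_state=random_state).fit(h1, data.reward)
    else:
        raise ValueError("estimator must be 'linear' or 'lasso'")
    residual = data.reward - model.predict(h1)
    return data.with_reward(residual), model
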