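"""Sequential comparison learners: L1 Q-learning, L1 O-learning, AOWL.

All three fit the stages in backward order (stage T first); the stage-t fit
never reads earlier-stage coefficients. Q-learning is regression-based
(lasso Q-functions with backward pseudo-outcomes); O-learning maximizes an
inverse-probability-weighted classification value via exact weighted-hinge
linear programs with an L1 penalty; AOWL is O-learning on residualized
outcomes, with signed working weights absorbed by the standard
|weight| + flipped-label equivalence. The AOWL solution doubles as the
warm start and the adaptive-penalty pilot of the multistage ramp learner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from sklearn.base import BaseEstimator
from sklearn.linear_model import LassoCV

from .data import DTRCoefficients, StageDesign, TrajectoryDataset, sign0, standardize
from .nuisance import fit_propensity_models
from .policy import LinearPolicyMixin
from .surrogate import residualize_outcome

__all__ = [
    "BackwardFitResult",
    "QLearningLasso",
    "OLearningLP",
    "AOWLearner",
    "fit_l1_qlearning",
    "fit_l1_olearning",
    "fit_aowl",
]

DEFAULT_OLEARNING_GRID = tuple(10.0 ** np.arange(-5, 6))


@dataclass
class BackwardFitResult:
    """Coefficients, per-stage chosen penalties and stage weights used."""

    coef: DTRCoefficients
    lambdas: list
    stage_weights: list | None = None


def _resolve_rng(random_state):
    return np.random.default_rng(random_state)


# ---------------------------------------------------------------------------
# Q-learning with lasso


class QLearningLasso(LinearPolicyMixin, BaseEstimator):
    """Backward-inductive Q-learning with lasso-penalized linear Q-functions.

    Stage model Q_t(H_t, A_t) = c_t + H_t'w_t + A_t (theta_{t0} + H_t'theta_t);
    the stage rule is sign(theta_{t0} + H_t'theta_t), the stage-(t-1)
    pseudo-outcome is max_a of the fitted Q (ties resolved toward +1).
    The lasso strength is chosen by internal cross-validation.
    """

    def __init__(
        self,
        cv: int = 5,
        alphas=100,
        selection_threshold: float = 1e-6,
        random_state=None,
    ):
        self.cv = cv
        self.alphas = alphas
        self.selection_threshold = selection_threshold
        self.random_state = random_state

    def fit(self, data: TrajectoryDataset, design: StageDesign):
        design.validate_against(data)
        std, scaler = standardize(data)
        T = std.T
        beta = [None] * T
        alpha = [None] * T
        gamma = np.zeros(T)
        lambdas = [None] * T
        pseudo = std.reward.copy()
        seed = None if self.random_state is None else int(self.random_state) & 0x7FFFFFFF
        for t in range(T - 1, -1, -1):
            h = std.features[t]
            a = std.treatments[:, t]
            X = np.column_stack([h, a, a[:, None] * h])
            model = LassoCV(
                cv=self.cv, alphas=self.alphas, random_state=seed, n_jobs=1
            ).fit(X, pseudo)
            d_t = h.shape[1]
            omega = model.coef_[:d_t]
            a_main = model.coef_[d_t]
            theta = model.coef_[d_t + 1 :]
            beta[t] = theta[design.penalized[t]]
            alpha[t] = theta[design.unpenalized[t]]
            gamma[t] = a_main
            lambdas[t] = float(model.alpha_)
            if t > 0:
                contrast = a_main + h @ theta
                pseudo = model.intercept_ + h @ omega + np.abs(contrast)
        self.coef_ = DTRCoefficients(beta=beta, alpha=alpha, gamma=gamma)
        self.design_ = design
        self.scaler_ = scaler
        self.lambdas_ = lambdas
        return self


# ---------------------------------------------------------------------------
# O-learning via weighted-hinge linear programs


def _hinge_lp(h_int, labels, weights, lam, box):
    """Solve min_theta sum_i w_i (1 - lab_i x_i'theta)_+ + lam ||theta||_1.

    ``h_int`` includes the intercept column; the L1 penalty covers the full
    coefficient vector as written in the stagewise objective. Exact LP:
    theta = u - v with u, v >= 0, hinge slacks xi_i >= 0.
    """
    active = weights > 0
    d = h_int.shape[1]
    if not active.any():
        return np.zeros(d)
    X = h_int[active] * labels[active][:, None]
    w = weights[active]
    n = X.shape[0]
    c = np.concatenate([np.full(2 * d, lam), w])
    A_ub = sp.hstack([sp.csr_matrix(-X), sp.csr_matrix(X), -sp.eye(n)], format="csr")
    b_ub = -np.ones(n)
    bounds = [(0.0, box)] * (2 * d) + [(0.0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"weighted-hinge LP failed: {res.message}")
    u, v = res.x[:d], res.x[d : 2 * d]
    return u - v


class OLearningLP(LinearPolicyMixin, BaseEstimator):
    """Backward L1-penalized outcome-weighted learning, solved exactly by LP.

    Stage-t weights are [prod_{s>t} 1{A_s g_s(H_s) > 0}] * Y / prod_{s>=t} p_s.
    Since hinge weights must be nonnegative, a signed outcome is handled per
    ``negative_outcome``: "drop" keeps the positive part Y+ (default; the
    nonnegative mass the value identity assigns to the observed sequence),
    "shift" subtracts the (negative) minimum of Y once before fitting (the
    classical outcome-weighted-learning device, sensitive to heavy lower
    tails), "flip" uses weight |w| with pseudo-label -A, "error" refuses.
    The per-stage lambda is chosen by twofold cross-validation on the
    held-out inverse-probability-weighted value.
    """

    def __init__(
        self,
        lambda_grid=DEFAULT_OLEARNING_GRID,
        folds: int = 2,
        outcome: str = "raw",
        negative_outcome: str = "drop",
        box: float = 100.0,
        selection_threshold: float = 1e-6,
        random_state=None,
    ):
        self.lambda_grid = lambda_grid
        self.folds = folds
        self.outcome = outcome
        self.negative_outcome = negative_outcome
        self.box = box
        self.selection_threshold = selection_threshold
        self.random_state = random_state

    def _working_outcome(self, std: TrajectoryDataset, rng):
        if self.outcome == "residualized":
            seed = int(rng.integers(2**31 - 1))
            resid, model = residualize_outcome(std, "lasso", random_state=seed)
            self.residual_model_ = model
            return resid.reward
        if self.outcome != "raw":
            raise ValueError("outcome must be 'raw' or 'residualized'")
        y = std.reward
        if y.min() < 0:
            if self.negative_outcome == "shift":
                self.outcome_shift_ = float(y.min())
                return y - y.min()
            if self.negative_outcome == "flip":
                return y.copy()
            if self.negative_outcome == "drop":
                return np.maximum(y, 0.0)
            raise ValueError("raw O-learning requires nonnegative rewards")
        return y.copy()

    def fit(self, data: TrajectoryDataset, design: StageDesign):
        design.validate_against(data)
        rng = _resolve_rng(self.random_state)
        std, scaler = standardize(data)
        if std.propensities is None:
            seed = int(rng.integers(2**31 - 1))
            p, models = fit_propensity_models(std, random_state=seed)
            std = std.with_propensities(p)
            self.propensity_models_ = models
        y = self._working_outcome(std, rng)
        T, n = std.T, std.n
        lam_grid = sorted(float(l) for l in self.lambda_grid)
        beta, alpha, gamma, lambdas, stage_w = (
            [None] * T,
            [None] * T,
            np.zeros(T),
            [None] * T,
            [None] * T,
        )
        # prod_{s >= t} p_s
        tailp = np.ones((n, T + 1))
        for t in range(T - 1, -1, -1):
            tailp[:, t] = tailp[:, t + 1] * std.propensities[:, t]
        later_ok = np.ones(n, dtype=bool)
        for t in range(T - 1, -1, -1):
            h_int = np.column_stack([np.ones(n), std.features[t]])
            w_signed = later_ok * y / tailp[:, t]
            labels = std.treatments[:, t].copy()
            flip = w_signed < 0
            labels[flip] *= -1.0
            weights = np.abs(w_signed)
            lam_t = self._select_lambda(h_int, labels, weights, lam_grid, rng)
            theta = _hinge_lp(h_int, labels, weights, lam_t, self.box)
            gamma[t] = theta[0]
            coefs = theta[1:]
            beta[t] = coefs[design.penalized[t]]
            alpha[t] = coefs[design.unpenalized[t]]
            lambdas[t] = lam_t
            stage_w[t] = weights
            g = h_int @ theta
            later_ok &= std.treatments[:, t] == sign0(g)
        self.coef_ = DTRCoefficients(beta=beta, alpha=alpha, gamma=gamma)
        self.design_ = design
        self.scaler_ = scaler
        self.lambdas_ = lambdas
        self.result_ = BackwardFitResult(self.coef_, lambdas, stage_w)
        return self

    def _select_lambda(self, h_int, labels, weights, lam_grid, rng):
        if len(lam_grid) == 1:
            return lam_grid[0]
        n = h_int.shape[0]
        perm = rng.permutation(n)
        folds = np.array_split(perm, self.folds)
        scores = np.zeros(len(lam_grid))
        for hold in folds:
            train = np.setdiff1d(perm, hold)
            for j, lam in enumerate(lam_grid):
                theta = _hinge_lp(h_int[train], labels[train], weights[train], lam, self.box)
                concord = labels[hold] == sign0(h_int[hold] @ theta)
                scores[j] += float(weights[hold] @ concord)
        # ties broken toward the larger (sparser) lambda
        best = np.flatnonzero(scores >= scores.max() - 1e-12)[-1]
        return lam_grid[best]


class AOWLearner(OLearningLP):
    """Augmented outcome-weighted learning: O-learning on lasso residuals.

    Residualizing Y against the stage-1 history shrinks the weight spread;
    negative residuals become positive weights with flipped pseudo-labels.
    Used both as a learner and as the pilot/initializer of the multistage
    ramp estimator.
    """

    def __init__(
        self,
        lambda_grid=DEFAULT_OLEARNING_GRID,
        folds: int = 2,
        box: float = 100.0,
        selection_threshold: float = 1e-6,
        random_state=None,
    ):
        super().__init__(
            lambda_grid=lambda_grid,
            folds=folds,
            outcome="residualized",
            negative_outcome="flip",
            box=box,
            selection_threshold=selection_threshold,
            random_state=random_state,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_l1_qlearning(data, design, cv=5, random_state=None) -> BackwardFitResult:
    est = QLearningLasso(cv=cv, random_state=random_state).fit(data, design)
    return BackwardFitResult(est.coef_, est.lambdas_)


def fit_l1_olearning(
    data,
    design,
    lambda_grid=DEFAULT_OLEARNING_GRID,
    outcome="raw",
    random_state=None,
) -> BackwardFitResult:
    est = OLearningLP(
        lambda_grid=lambda_grid, outcome=outcome, random_state=random_state
    ).fit(data, design)
    return est.result_

def fit_aowl(
    data, design, lambda_grid=DEFAULT_OLEARNING_GRID, random_state=None
) -> BackwardFitResult:
    est = AOWLearner(lambda_grid=lambda_grid, random_state=random_state).fit(data, design)
    return est.result_
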