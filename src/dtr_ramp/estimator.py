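"""The penalized multistage ramp estimator (L1-MRL).

Learns all T stage rules of a dynamic treatment regimen in a single
optimization: the estimator maximizes the ramp-surrogate of the
inverse-probability-weighted value while an adaptive cross-stage
group-lasso penalty zeroes out features unimportant at *every* stage.
Tuning (lambda, eta), warm starts, the AOWL pilot and nuisance estimation
are orchestrated here; the numerical work lives in
:mod:`dtr_ramp.solver` and :mod:`dtr_ramp.tuning`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import StageDesign, TrajectoryDataset, standardize
from .policy import LinearPolicyMixin
from .baselines import DEFAULT_OLEARNING_GRID
from .tuning import DEFAULT_ETA_GRID, DEFAULT_LAMBDA_GRID, cross_validate

__all__ = ["MultistageRampDTR"]


class MultistageRampDTR(LinearPolicyMixin, BaseEstimator):
    """Simultaneous multistage rule learning with cross-stage selection.

    Parameters
    ----------
    lambda_grid, eta_grid : sequences
        Candidate penalty strengths (default powers of two up to 2^10) and
        ramp shifting parameters (default 1e-3, 1e-4, 1e-5); chosen by
        ``folds``-fold cross-validation of the AIC-type criterion.
    residualize : bool
        Replace Y by the residual against a stage-1 conditional-mean model
        (default); improves stability and leaves the target value unchanged.
    propensity_mode : {"auto", "per_fold", "given"}
        How assignment probabilities are obtained: estimate inside each
        training fold (default when absent from the data), or trust the
        ones stored on the dataset.
    gamma, weight_cap : float
        Adaptive-penalty exponent and the cap on adaptive weights.
    max_dc_iter, max_sweeps, tol, box : solver knobs (see FitConfig).

    Attributes
    ----------
    coef_ : DTRCoefficients — fitted stage rules (standardized scale).
    lambda_, eta_ : selected tuning pair.
    tuning_ : TuningResult with the full criterion grid.
    pilot_ : the AOWL coefficients used as warm start and penalty pilot.
    scaler_ : standardization state applied to inputs at prediction time.
    """

    def __init__(
        self,
        lambda_grid=DEFAULT_LAMBDA_GRID,
        eta_grid=DEFAULT_ETA_GRID,
        folds: int = 2,
        gamma: float = 1.0,
        weight_cap: float = 1e6,
        residualize: bool = True,
        residual_estimator: str = "lasso",
        propensity_mode: str = "auto",
        aowl_lambda_grid=DEFAULT_OLEARNING_GRID,
        max_dc_iter: int = 50,
        max_sweeps: int = 20,
        tol: float = 1e-6,
        box: float = 100.0,
        selection_threshold: float = 1e-6,
        random_state=None,
    ):
        self.lambda_grid = lambda_grid
        self.eta_grid = eta_grid
        self.folds = folds
        self.gamma = gamma
        self.weight_cap = weight_cap
        self.residualize = residualize
        self.residual_estimator = residual_estimator
        self.propensity_mode = propensity_mode
        self.aowl_lambda_grid = aowl_lambda_grid
        self.max_dc_iter = max_dc_iter
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.box = box
        self.selection_threshold = selection_threshold
        self.random_state = random_state

    def fit(self, data: TrajectoryDataset, design: StageDesign | None = None):
        if design is None:
            design = StageDesign.all_penalized(data)
        design.validate_against(data)
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        std, scaler = standardize(data)
        seed = (
            None
            if self.random_state is None
            else int(self.random_state) & 0x7FFFFFFF
        )
        tuning = cross_validate(
            std,
            design,
            lambda_grid=self.lambda_grid,
            eta_grid=self.eta_grid,
            folds=self.folds,
            seed=seed,
            residualize=self.residualize,
            residual_estimator=self.residual_estimator,
            propensity_mode=self.propensity_mode,
            gamma=self.gamma,
            weight_cap=self.weight_cap,
            aowl_lambda_grid=self.aowl_lambda_grid,
            threshold=self.selection_threshold,
            max_dc_iter=self.max_dc_iter,
            max_sweeps=self.max_sweeps,
            tol=self.tol,
            box=self.box,
        )
        self.coef_ = tuning.coef
        self.design_ = design
        self.scaler_ = scaler
        self.tuning_ = tuning
        self.lambda_, self.eta_ = tuning.best_pair
        self.pilot_ = tuning.pilot
        self.n_features_in_ = int(sum(h.shape[1] for h in data.features))
        return self
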