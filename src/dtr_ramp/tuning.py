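"""Tuning-parameter selection for the penalized multistage ramp learner.

The (lambda, eta) pair is chosen by k-fold (default twofold) cross-validation
of an AIC-type criterion evaluated on the held-out fold:

    n* log( R(theta_hat(lambda, eta)) / R(theta_hat(0, eta)) ) - k(lambda, eta)

where R is the sum-scale empirical surrogate value on the evaluation fold,
n* the evaluation-fold size, and k the number of coefficients with
magnitude above 1e-6. Within each training fold, the unpenalized fit at
(0, eta) is initialized from the AOWL solution (which also supplies the
adaptive penalty weights), and every lambda > 0 fit is warm-started from
the (0, eta) fit. Ties are broken toward larger lambda, then smaller eta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .baselines import DEFAULT_OLEARNING_GRID, AOWLearner
from .data import DTRCoefficients, StageDesign, TrajectoryDataset
from .nuisance import attach_propensities, fit_propensity_models
from .penalty import PenaltySpec
from .solver import FitConfig, dc_fit
from .surrogate import empirical_value_surrogate, residualize_outcome

log = logging.getLogger(__name__)

__all__ = ["TuningResult", "aic_criterion", "cross_validate"]

DEFAULT_LAMBDA_GRID = tuple(2.0 ** np.arange(0, 11))
DEFAULT_ETA_GRID = (1e-3, 1e-4, 1e-5)


@dataclass
class TuningResult:
    pairs: list  # list of (lambda, eta)
    mean_criteria: np.ndarray
    fold_criteria: np.ndarray  # (folds, n_pairs)
    best_pair: tuple
    coef: DTRCoefficients
    reference_coef: DTRCoefficients  # final (0, eta*) fit
    pilot: DTRCoefficients
    penalty: PenaltySpec
    nonzero_counts: dict = field(default_factory=dict)


def aic_criterion(
    theta_hat: DTRCoefficients,
    theta_ref: DTRCoefficients,
    eta: float,
    eval_data: TrajectoryDataset,
    design: StageDesign,
    threshold: float = 1e-6,
) -> float:
    """AIC-type held-out criterion; -inf when either value is nonpositive."""
    r_hat = empirical_value_surrogate(theta_hat, eta, eval_data, design, scale="sum")
    r_ref = empirical_value_surrogate(theta_ref, eta, eval_data, design, scale="sum")
    if r_hat <= 0 or r_ref <= 0:
        return -np.inf
    k = theta_hat.count_nonzero(threshold)
    return eval_data.n * np.log(r_hat / r_ref) - k


def _stratified_folds(data: TrajectoryDataset, folds: int, rng) -> list:
    """Deal subjects into folds, stratified by (A_1, sign of Y)."""
    labels = (data.treatments[:, 0] > 0).astype(int) * 2 + (data.reward >= 0).astype(int)
    assignment = np.empty(data.n, dtype=int)
    offset = 0
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        rng.shuffle(idx)
        assignment[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size  # balance fold sizes across strata
    return [np.where(assignment == f)[0] for f in range(folds)]


def _prepare_split(data, train_idx, eval_idx, residualize, residual_estimator,
                   propensity_mode, rng):
    """Fold-consistent nuisance handling: models fit on the training part
    are applied to the evaluation part."""
    tr = data.subset(train_idx)
    ev = data.subset(eval_idx) if eval_idx is not None else None
    if propensity_mode == "per_fold" or (
        propensity_mode == "auto" and data.propensities is None
    ):
        seed = int(rng.integers(2**31 - 1))
        p_tr, models = fit_propensity_models(tr, random_state=seed)
        tr = tr.with_propensities(p_tr)
        if ev is not None:
            ev = attach_propensities(ev, models)
    elif data.propensities is None:
        raise ValueError("propensities absent; use propensity_mode='per_fold'")
    pilot_input = tr  # AOWL residualizes internally from the raw reward
    if residualize:
        seed = int(rng.integers(2**31 - 1))
        tr, model = residualize_outcome(tr, residual_estimator, random_state=seed)
        if ev is not None:
            ev = ev.with_reward(ev.reward - model.predict(ev.features[0]))
    return tr, ev, pilot_input


def _fit_path(tr, design, eta, lambda_grid, pilot_coef, penalty0, fit_opts):
    """(0, eta) fit from the AOWL start, then warm-started lambda path."""
    cfg0 = FitConfig(eta=eta, penalty=penalty0.with_lam(0.0), init=pilot_coef, **fit_opts)
    theta0, _ = dc_fit(tr, design, cfg0)
    fits = {}
    for lam in lambda_grid:
        cfg = FitConfig(eta=eta, penalty=penalty0.with_lam(lam), init=theta0, **fit_opts)
        fits[lam], _ = dc_fit(tr, design, cfg)
    return theta0, fits


def cross_validate(
    data: TrajectoryDataset,
    design: StageDesign,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    eta_grid=DEFAULT_ETA_GRID,
    folds: int = 2,
    seed=None,
    residualize: bool = True,
    residual_estimator: str = "lasso",
    propensity_mode: str = "auto",
    gamma: float = 1.0,
    weight_cap: float = 1e6,
    aowl_lambda_grid=DEFAULT_OLEARNING_GRID,
    threshold: float = 1e-6,
    **fit_opts,
) -> TuningResult:
    """Grid search over (lambda, eta) with the warm-start scheme, then refit.

    ``data`` is expected standardized; propensities are refit inside each
    training fold by default (``propensity_mode='per_fold'``; ``'given'``
    reuses ``data.propensities`` everywhere, the all-samples mode used for
    observational cohorts).
    """
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    lambda_grid = [float(l) for l in lambda_grid]
    if len(set(lambda_grid)) != len(lambda_grid):
        log.info("duplicate lambda values in grid; deduplicated")
        lambda_grid = sorted(set(lambda_grid))
    eta_grid = [float(e) for e in eta_grid]
    pairs = [(lam, eta) for eta in eta_grid for lam in lambda_grid]
    rng = np.random.default_rng(seed)
    fold_sets = _stratified_folds(data, folds, rng)
    all_idx = np.arange(data.n)

    fold_criteria = np.full((folds, len(pairs)), -np.inf)
    for f, eval_idx in enumerate(fold_sets):
        train_idx = np.setdiff1d(all_idx, eval_idx)
        tr, ev, pilot_input = _prepare_split(
            data, train_idx, eval_idx, residualize, residual_estimator,
            propensity_mode, rng,
        )
        aowl = AOWLearner(
            lambda_grid=aowl_lambda_grid,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(pilot_input, design)
        penalty0 = PenaltySpec.from_pilot(aowl.coef_.beta, lam=0.0, gamma=gamma, cap=weight_cap)
        for eta in eta_grid:
            theta0, fits = _fit_path(
                tr, design, eta, lambda_grid, aowl.coef_, penalty0, fit_opts
            )
            for lam, theta in fits.items():
                crit = aic_criterion(theta, theta0, eta, ev, design, threshold)
                fold_criteria[f, pairs.index((lam, eta))] = crit

    mean_criteria = fold_criteria.mean(axis=0)
    if not np.isfinite(mean_criteria).any():
        raise RuntimeError(
            "tuning failed: every (lambda, eta) pair had nonpositive held-out "
            "surrogate value"
        )
    # ties -> larger lambda, then smaller eta
    order = sorted(
        range(len(pairs)),
        key=lambda i: (mean_criteria[i], pairs[i][0], -pairs[i][1]),
    )
    best = pairs[order[-1]]

    # refit on all data at the winner
    tr_all, _, pilot_input = _prepare_split(
        data, all_idx, None, residualize, residual_estimator, propensity_mode, rng
    )
    aowl = AOWLearner(
        lambda_grid=aowl_lambda_grid, random_state=int(rng.integers(2**31 - 1))
    ).fit(pilot_input, design)
    penalty0 = PenaltySpec.from_pilot(aowl.coef_.beta, lam=0.0, gamma=gamma, cap=weight_cap)
    lam_star, eta_star = best
    theta0, fits = _fit_path(
        tr_all, design, eta_star, [lam_star], aowl.coef_, penalty0, fit_opts
    )
    coef = fits[lam_star]
    return TuningResult(
        pairs=pairs,
        mean_criteria=mean_criteria,
        fold_criteria=fold_criteria,
        best_pair=best,
        coef=coef,
        reference_coef=theta0,
        pilot=aowl.coef_,
        penalty=penalty0.with_lam(lam_star),
        nonzero_counts={best: coef.count_nonzero(threshold)},
    )
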