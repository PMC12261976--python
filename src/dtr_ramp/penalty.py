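"""Adaptive cross-stage group-lasso-type penalty.

The sparsity term added to the (negated) surrogate objective is

    rho_{lambda,gamma}(theta) = lambda * sum_p omega_p * sum_t |beta_{t,p}|

with adaptive weights omega_p = (sum_t btilde_{t,p}^2)^(-gamma/2) built from
a pilot estimate whose per-stage coefficient vectors are normalized to unit
Euclidean norm. Pooling |beta_{t,p}| over stages inside one weighted group
makes the penalty hardest on features that the pilot finds unimportant at
every stage, which is what yields selection of the union of per-stage
important variables. gamma = 1 is the default exponent; alpha_t and the
intercepts are never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DTRCoefficients

__all__ = ["PenaltySpec", "pilot_normalize", "adaptive_weights", "penalty_value"]


def pilot_normalize(beta_pilot):
    """Scale each stage's pilot P-vector to unit Euclidean norm.

    An all-zero stage vector is left at zero; the weight cap deals with
    features that are zero across every stage.
    """
    out = []
    for b in beta_pilot:
        b = np.asarray(b, dtype=float)
        nrm = np.linalg.norm(b)
        out.append(b / nrm if nrm > 0 else b.copy())
    return out


def adaptive_weights(beta_tilde, gamma: float = 1.0, cap: float = 1e6) -> np.ndarray:
    """omega_p = (sum_t btilde_{t,p}^2)^(-gamma/2), truncated at ``cap``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if cap <= 0:
        raise ValueError("cap must be positive")
    stacked = np.vstack([np.asarray(b, dtype=float) for b in beta_tilde])
    col_norm_sq = (stacked**2).sum(axis=0)
    with np.errstate(divide="ignore"):
        omega = np.where(col_norm_sq > 0, col_norm_sq ** (-gamma / 2.0), np.inf)
    return np.minimum(omega, cap)


@dataclass
class PenaltySpec:
    """lambda, exponent gamma and the P adaptive weights."""

    lam: float
    weights: np.ndarray
    gamma: float = 1.0
    weight_cap: float = 1e6

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        self.weights = np.minimum(np.asarray(self.weights, dtype=float), self.weight_cap)
        if not (self.weights > 0).all():
            raise ValueError("adaptive weights must be strictly positive")

    @classmethod
    def from_pilot(cls, beta_pilot, lam: float, gamma: float = 1.0, cap: float = 1e6):
        """Normalize a pilot fit per stage and derive the adaptive weights.

        Any root-n-consistent pilot works in theory; in practice the AOWL
        solution is used (see :mod:`dtr_ramp.baselines`).
        """
        btilde = pilot_normalize(beta_pilot)
        return cls(lam=lam, weights=adaptive_weights(btilde, gamma, cap), gamma=gamma, weight_cap=cap)

    @classmethod
    def uniform(cls, P: int, lam: float):
        return cls(lam=lam, weights=np.ones(P))

    def with_lam(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(lam=lam, weights=self.weights, gamma=self.gamma, weight_cap=self.weight_cap)


def penalty_value(theta: DTRCoefficients, spec: PenaltySpec) -> float:
    """lambda * sum_p omega_p sum_t |beta_{t,p}|; alpha and intercepts exempt."""
    total = np.zeros_like(spec.weights)
    for b in theta.beta:
        total += np.abs(b)
    return float(spec.lam * (spec.weights @ total))
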