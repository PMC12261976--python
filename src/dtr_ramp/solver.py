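"""Difference-of-convex fitting of the penalized multistage ramp objective.

Minimization form of the problem:

    F(theta) = -V_n(theta; eta) + rho_lambda(beta),

where V_n is the empirical surrogate value (mean scale) and rho the adaptive
cross-stage L1 penalty. Writing the ramp as psi = phi1 - phi2 with
phi1(u) = max(u, 0) and phi2(u) = max(u - 1, 0), each weighted term
-w * min_t psi(u_t) (w >= 0, margins u affine in theta) decomposes as

    w * max_t [ phi2(u_t) + sum_{s != t} phi1(u_s) ]  -  w * sum_s phi1(u_s),

so F = G - H + rho with G, H convex piecewise-linear. The DC algorithm
linearizes H at the current iterate and minimizes the convex surrogate
G - <grad H, theta> + rho by cyclic coordinate descent, each coordinate
solved *exactly*.

Key reduction used by the coordinate solver: fixing all coordinates except
one in stage t, the per-term max collapses to a single hinge,

    max_t'[...] = const + phi1(u_t - delta),   delta = min_{s != t} psi(u_s)

(delta = 1 when T = 1), so the one-dimensional subproblem is a weighted sum
of hinges plus a linear and an absolute-value term, minimized exactly by a
breakpoint sort. Subgradient convention at the kinks: slope 0 at u = 0 for
phi1 and at u = 1 for phi2 (fixed for reproducibility).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data import DTRCoefficients, StageDesign, TrajectoryDataset
from .penalty import PenaltySpec, penalty_value
from .surrogate import SurrogateTerms, build_surrogate_terms

__all__ = [
    "FitConfig",
    "DCState",
    "CoefficientLayout",
    "dc_fit",
    "dc_linearize",
    "coordinate_minimize",
]


@dataclass
class FitConfig:
    """Knobs of one DC fit.

    ``box`` bounds every coefficient in [-B, B]: the piecewise-linear
    subproblem can be unbounded along flat directions, and after
    standardization useful coefficients are far smaller than the default
    B = 100 (a warning is raised if the bound is ever active).
    """

    eta: float
    penalty: PenaltySpec
    init: DTRCoefficients | None = None
    max_dc_iter: int = 50
    max_sweeps: int = 100
    tol: float = 1e-6
    coord_tol: float = 1e-8
    box: float = 100.0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.tol <= 0 or self.coord_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.box <= 0:
            raise ValueError("box bound must be positive")


@dataclass
class DCState:
    objective: float
    history: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


class CoefficientLayout:
    """Flat ordering of theta: per stage [intercept, alpha..., beta...]."""

    def __init__(self, design: StageDesign):
        stage_of, col_of, pen_index = [], [], []
        for t in range(design.T):
            stage_of.append(t)
            col_of.append(-1)
            pen_index.append(-1)
            for j in design.unpenalized[t]:
                stage_of.append(t)
                col_of.append(int(j))
                pen_index.append(-1)
            for p, j in enumerate(design.penalized[t]):
                stage_of.append(t)
                col_of.append(int(j))
                pen_index.append(p)
        self.design = design
        self.stage_of = np.array(stage_of, dtype=np.int64)
        self.col_of = np.array(col_of, dtype=np.int64)
        self.pen_index = np.array(pen_index, dtype=np.int64)
        self.D = len(stage_of)

    def to_vector(self, coef: DTRCoefficients) -> np.ndarray:
        vec = np.empty(self.D)
        i = 0
        for t in range(self.design.T):
            vec[i] = coef.gamma[t]
            i += 1
            nw = len(self.design.unpenalized[t])
            vec[i : i + nw] = coef.alpha[t]
            i += nw
            npn = len(self.design.penalized[t])
            vec[i : i + npn] = coef.beta[t]
            i += npn
        return vec

    def from_vector(self, vec: np.ndarray) -> DTRCoefficients:
        beta, alpha, gamma = [], [], []
        i = 0
        for t in range(self.design.T):
            gamma.append(vec[i])
            i += 1
            nw = len(self.design.unpenalized[t])
            alpha.append(vec[i : i + nw].copy())
            i += nw
            npn = len(self.design.penalized[t])
            beta.append(vec[i : i + npn].copy())
            i += npn
        return DTRCoefficients(beta=beta, alpha=alpha, gamma=np.array(gamma))

    def penalty_per_coordinate(self, spec: PenaltySpec) -> np.ndarray:
        pen = np.zeros(self.D)
        mask = self.pen_index >= 0
        pen[mask] = spec.lam * spec.weights[self.pen_index[mask]]
        return pen

    def term_design(self, data: TrajectoryDataset, terms: SurrogateTerms, eta: float):
        """K[m, c] = d u_{m, stage(c)} / d theta_c = sign_{m,t} x_{row, col} / eta."""
        M = terms.M
        K = np.empty((M, self.D))
        for c in range(self.D):
            t = self.stage_of[c]
            j = self.col_of[c]
            x = 1.0 if j < 0 else data.features[t][terms.rows, j]
            K[:, c] = terms.signs[:, t] * x / eta
        return K


@njit(cache=True)
def _solve_1d(base, xs, ds, ne, x_old, box):
    """Exact minimizer of a convex piecewise-linear function on [-box, box].

    Slope is ``base`` left of every breakpoint and increases by ds[j] when
    crossing xs[j]. The minimizer set is the closed segment between the
    first point where the subgradient reaches 0 and the first where it
    turns positive; the point of that segment closest to ``x_old`` is
    returned (stability on flat plateaus), clipped to the box.
    """
    if ne == 0:
        if base > 0.0:
            return -box
        if base < 0.0:
            return box
        return x_old
    order = np.argsort(xs[:ne])
    # lo: first x with subgradient >= 0 to its right (-box if base >= 0)
    # hi: first x with subgradient > 0 to its right (box if never)
    s = base
    lo = -box if s >= 0.0 else box
    hi = box
    if s > 0.0:
        hi = -box
    else:
        for oi in range(ne):
            x_ev = xs[order[oi]]
            s += ds[order[oi]]
            if s >= 0.0 and lo == box:
                lo = x_ev
            if s > 0.0:
                hi = x_ev
                break
    if lo > hi:
        lo = hi
    x = x_old
    if x < lo:
        x = lo
    elif x > hi:
        x = hi
    if x > box:
        x = box
    elif x < -box:
        x = -box
    return x


@njit(cache=True)
def _cd_sweeps(theta, U, K, w, stage_of, pen, dlin, box, coord_tol, max_sweeps):
    """Cyclic coordinate descent on the convex DC subproblem (in place)."""
    D = theta.shape[0]
    M, T = U.shape
    xs = np.empty(M + 1)
    ds = np.empty(M + 1)
    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        max_delta = 0.0
        for c in range(D):
            t = stage_of[c]
            x_old = theta[c]
            base = -dlin[c]
            ne = 0
            pc = pen[c]
            if pc > 0.0:
                base -= pc
                xs[ne] = 0.0
                ds[ne] = 2.0 * pc
                ne += 1
            for m in range(M):
                k = K[m, c]
                if k == 0.0:
                    continue
                dmin = 1.0
                for s in range(T):
                    if s == t:
                        continue
                    v = U[m, s]
                    if v < 0.0:
                        v = 0.0
                    elif v > 1.0:
                        v = 1.0
                    if v < dmin:
                        dmin = v
                b = U[m, t] - k * x_old
                wk = w[m] * k
                xs[ne] = (dmin - b) / k
                if wk < 0.0:
                    base += wk
                    ds[ne] = -wk
                else:
                    ds[ne] = wk
                ne += 1
            x_new = _solve_1d(base, xs, ds, ne, x_old, box)
            if x_new != x_old:
                dlt = x_new - x_old
                theta[c] = x_new
                for m in range(M):
                    k = K[m, c]
                    if k != 0.0:
                        U[m, t] += k * dlt
                if abs(dlt) > max_delta:
                    max_delta = abs(dlt)
        if max_delta < coord_tol:
            break
    return sweeps


def _margins(K, theta, stage_of, T):
    U = np.empty((K.shape[0], T))
    for t in range(T):
        cols = np.where(stage_of == t)[0]
        U[:, t] = K[:, cols] @ theta[cols]
    return U


def _objective_from_margins(U, w, theta, pen):
    data_part = float(w @ np.min(np.clip(U, 0.0, 1.0), axis=1)) if U.shape[0] else 0.0
    return -data_part + float(pen @ np.abs(theta))


def _grad_h(U, K, w, stage_of):
    """Subgradient of the concave-part majorant H at the current margins."""
    D = K.shape[1]
    dlin = np.empty(D)
    for t in range(U.shape[1]):
        mw = w * (U[:, t] > 0.0)
        cols = np.where(stage_of == t)[0]
        dlin[cols] = K[:, cols].T @ mw
    return dlin


def dc_fit(
    data: TrajectoryDataset,
    design: StageDesign,
    config: FitConfig,
    terms: SurrogateTerms | None = None,
):
    """Fit the penalized multistage ramp objective; returns (coef, DCState).

    The returned coefficients are a DC stationary point: the linearized
    convex subproblem at the solution admits no coordinate improvement
    beyond tolerance. The recorded objective history is nonincreasing.
    """
    design.validate_against(data)
    if terms is None:
        terms = build_surrogate_terms(data)
    layout = CoefficientLayout(design)
    theta = (
        layout.to_vector(config.init)
        if config.init is not None
        else np.zeros(layout.D)
    )
    if not np.isfinite(theta).all():
        raise FloatingPointError("non-finite initial coefficients")
    K = layout.term_design(data, terms, config.eta)
    w = terms.weights / data.n  # mean scale
    if not np.isfinite(w).all():
        raise FloatingPointError("non-finite surrogate weights (check propensities)")
    pen = layout.penalty_per_coordinate(config.penalty)
    U = _margins(K, theta, layout.stage_of, data.T)

    obj = _objective_from_margins(U, w, theta, pen)
    state = DCState(objective=obj, history=[obj])
    for it in range(config.max_dc_iter):
        dlin = _grad_h(U, K, w, layout.stage_of)
        _cd_sweeps(
            theta,
            U,
            K,
            w,
            layout.stage_of,
            pen,
            dlin,
            config.box,
            config.coord_tol,
            config.max_sweeps,
        )
        U = _margins(K, theta, layout.stage_of, data.T)  # refresh against drift
        new_obj = _objective_from_margins(U, w, theta, pen)
        if not np.isfinite(new_obj):
            raise FloatingPointError("non-finite objective during DC iteration")
        state.history.append(new_obj)
        state.n_iter = it + 1
        decrease = obj - new_obj
        obj = new_obj
        if decrease < config.tol * max(1.0, abs(new_obj)):
            state.converged = True
            break
    state.objective = obj
    if np.any(np.abs(theta) >= config.box - 1e-9):
        warnings.warn(
            "coefficient hit the box bound B; consider enlarging FitConfig.box",
            stacklevel=2,
        )
    return layout.from_vector(theta), state


def dc_linearize(
    theta: DTRCoefficients,
    data: TrajectoryDataset,
    design: StageDesign,
    eta: float,
    terms: SurrogateTerms | None = None,
) -> DTRCoefficients:
    """Subgradient of the convex part H(theta) that each DC step linearizes.

    Where every margin is away from the phi1 kink this is the exact
    gradient of H; at a kink the fixed lower (slope-0) choice is taken.
    """
    if terms is None:
        terms = build_surrogate_terms(data)
    layout = CoefficientLayout(design)
    K = layout.term_design(data, terms, eta)
    vec = layout.to_vector(theta)
    U = _margins(K, vec, layout.stage_of, data.T)
    return layout.from_vector(_grad_h(U, K, terms.weights / data.n, layout.stage_of))


def coordinate_minimize(
    breakpoints,
    slope_changes,
    base_slope: float,
    l1_weight: float = 0.0,
    box: float = 100.0,
    x_current: float = 0.0,
) -> float:
    """Exact global minimizer of f(x) + l1_weight * |x| on [-box, box].

    ``f`` is a convex piecewise-linear function given by its breakpoints and
    the (nonnegative) slope increase at each one, with slope ``base_slope``
    left of all breakpoints. The minimizer lies in the breakpoint set,
    at 0, or at +-box.
    """
    breakpoints = np.asarray(breakpoints, dtype=float)
    slope_changes = np.asarray(slope_changes, dtype=float)
    if breakpoints.shape != slope_changes.shape:
        raise ValueError("breakpoints and slope_changes must align")
    if np.any(slope_changes < 0):
        raise ValueError("negative slope change: function is not convex")
    if l1_weight < 0:
        raise ValueError("l1_weight must be nonnegative")
    xs = breakpoints
    ds = slope_changes
    base = base_slope
    if l1_weight > 0:
        xs = np.append(xs, 0.0)
        ds = np.append(ds, 2.0 * l1_weight)
        base = base - l1_weight
    return float(_solve_1d(base, xs, ds, len(xs), x_current, box))
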