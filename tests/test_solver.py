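import numpy as np
import pytest

from dtr_ramp.data import DTRCoefficients
from dtr_ramp.penalty import PenaltySpec, penalty_value
from dtr_ramp.solver import FitConfig, coordinate_minimize, dc_fit, dc_linearize
from dtr_ramp.surrogate import empirical_value_surrogate

from conftest import make_random_instance


def minimization_objective(coef, eta, data, design, spec):
    return -empirical_value_surrogate(coef, eta, data, design, "mean") + penalty_value(
        coef, spec
    )


class TestCoordinateMinimize:
    def test_pure_absolute_value(self):
        assert coordinate_minimize([], [], base_slope=0.0, l1_weight=1.0) == 0.0

    def test_single_kink(self):
        # f(x) = |x - 2|: slope -1 then +1
        assert coordinate_minimize([2.0], [2.0], base_slope=-1.0) == 2.0

    def test_scaled_hinge_plus_l1(self):
        # f(x) = 3 max(0, 1 - x): slopes -3 then 0; adding |x| puts the min at 1
        assert coordinate_minimize([1.0], [3.0], base_slope=-3.0, l1_weight=1.0) == 1.0

    def test_box_respected(self):
        assert coordinate_minimize([], [], base_slope=-2.0, box=5.0) == 5.0
        assert coordinate_minimize([], [], base_slope=2.0, box=5.0) == -5.0

    def test_nonconvex_rejected(self):
        with pytest.raises(ValueError, match="convex"):
            coordinate_minimize([0.0], [-1.0], base_slope=0.0)


def random_pl_instance(rng, box=2.0):
    k = rng.integers(1, 12)
    breaks = np.sort(rng.uniform(-box, box, k))
    deltas = rng.uniform(0.0, 3.0, k)
    base = -rng.uniform(0.0, 1.0) * deltas.sum()
    l1 = rng.choice([0.0, rng.uniform(0, 2)])
    return breaks, deltas, base, l1


def eval_pl(x, breaks, deltas, base, l1):
    """Value of the piecewise-linear function, up to one common constant."""
    out = base * x + l1 * np.abs(x)
    for b, d in zip(breaks, deltas):
        out = out + d * np.maximum(0.0, x - b)
    return out


@pytest.mark.parametrize("seed", [0, 1])
def test_coordinate_minimize_matches_dense_grid(seed):
    rng = np.random.default_rng(seed)
    box = 2.0
    grid = np.arange(-box, box + 1e-9, 1e-4)
    for _ in range(100):
        breaks, deltas, base, l1 = random_pl_instance(rng, box)
        x_star = coordinate_minimize(breaks, deltas, base, l1, box=box)
        vals = eval_pl(grid, breaks, deltas, base, l1)
        assert eval_pl(np.array([x_star]), breaks, deltas, base, l1)[0] <= vals.min() + 1e-9


class TestDCFit:
    def test_huge_lambda_zeroes_all_penalized_coefficients(self, tiny_two_stage):
        data, design = tiny_two_stage
        spec = PenaltySpec(lam=1e8, weights=[1.0])
        init = DTRCoefficients(beta=[[0.7], [-0.4]], alpha=[[], []], gamma=[0.3, 0.1])
        coef, _ = dc_fit(data, design, FitConfig(eta=1.0, penalty=spec, init=init))
        assert coef.beta[0][0] == 0.0 and coef.beta[1][0] == 0.0

    def test_stationary_init_returns_after_one_iteration(self, tiny_two_stage):
        data, design = tiny_two_stage
        spec = PenaltySpec.uniform(1, 0.3)
        cfg = FitConfig(eta=1.0, penalty=spec, init=None)  # theta = 0 is DC-stationary
        coef, state = dc_fit(data, design, cfg)
        assert state.converged and state.n_iter == 1
        assert coef.beta[0][0] == 0.0 and coef.gamma[0] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_history_monotone(self, seed):
        data, design = make_random_instance(seed)
        rng = np.random.default_rng(seed + 1000)
        spec = PenaltySpec(lam=rng.uniform(0, 1), weights=rng.uniform(0.5, 2, 2))
        init = DTRCoefficients(
            beta=[rng.standard_normal(2), rng.standard_normal(2)],
            alpha=[[], []],
            gamma=rng.standard_normal(2),
        )
        eta = rng.choice([1.0, 0.3, 1e-2])
        _, state = dc_fit(data, design, FitConfig(eta=eta, penalty=spec, init=init))
        h = np.array(state.history)
        assert np.all(np.diff(h) <= 1e-9)

    def test_reported_objective_matches_recomputation(self, tiny_two_stage):
        data, design = tiny_two_stage
        spec = PenaltySpec.uniform(1, 0.2)
        init = DTRCoefficients(beta=[[0.5], [0.5]], alpha=[[], []], gamma=[0.1, -0.2])
        coef, state = dc_fit(data, design, FitConfig(eta=0.5, penalty=spec, init=init))
        assert state.objective == pytest.approx(
            minimization_objective(coef, 0.5, data, design, spec), abs=1e-10
        )

    def test_scaling_rewards_scales_objective_and_keeps_rules(self, tiny_two_stage):
        data, design = tiny_two_stage
        spec = PenaltySpec.uniform(1, 0.0)
        init = DTRCoefficients(beta=[[0.4], [-0.3]], alpha=[[], []], gamma=[0.2, 0.6])
        cfg = FitConfig(eta=1.0, penalty=spec, init=init)
        coef1, st1 = dc_fit(data, design, cfg)
        scaled = data.with_reward(data.reward * 7.0)
        coef2, st2 = dc_fit(scaled, design, cfg)
        assert st2.objective == pytest.approx(7.0 * st1.objective, rel=1e-9)
        np.testing.assert_allclose(
            coef1.recommend(data, design), coef2.recommend(data, design)
        )


class TestDCLinearize:
    def test_matches_finite_difference_in_smooth_region(self):
        # margins placed strictly inside (0, 1): concave-part subgradient is
        # the exact gradient there
        data, design = make_random_instance(7, n=4, d1=1, d2=1)
        coef = DTRCoefficients(beta=[[1e-3], [-2e-3]], alpha=[[], []], gamma=[0.5, 0.5])
        g = coef.decision_values(data, design)
        eta = 2.0 * np.abs(g).max()  # all |margins| < 1/2 of the ramp width
        grad = dc_linearize(coef, data, design, eta)

        def h_value(c):
            # H(theta) = (1/n) sum_terms w sum_s phi1(u_s)
            from dtr_ramp.surrogate import build_surrogate_terms

            terms = build_surrogate_terms(data)
            gg = c.decision_values(data, design)
            u = terms.signs * gg[terms.rows] / eta
            return float(terms.weights @ np.maximum(u, 0.0).sum(axis=1)) / data.n

        eps = 1e-7
        bumped = DTRCoefficients(
            beta=[coef.beta[0] + eps, coef.beta[1]], alpha=coef.alpha, gamma=coef.gamma
        )
        fd = (h_value(bumped) - h_value(coef)) / eps
        assert grad.beta[0][0] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_finite_at_kinks_and_zero(self, tiny_two_stage):
        data, design = tiny_two_stage
        zero = DTRCoefficients(beta=[[0.0], [0.0]], alpha=[[], []], gamma=[0.0, 0.0])
        grad = dc_linearize(zero, data, design, 1.0)
        assert np.isfinite(grad.gamma).all()
        # slope-0 convention at the phi1 kink: all margins are exactly 0
        assert np.all(grad.gamma == 0.0) and np.all(grad.beta[0] == 0.0)


def test_config_validation(tiny_two_stage):
    with pytest.raises(ValueError):
        FitConfig(eta=0.0, penalty=PenaltySpec.uniform(1, 0.0))
    with pytest.raises(ValueError):
        FitConfig(eta=1.0, penalty=PenaltySpec.uniform(1, 0.0), tol=-1.0)
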