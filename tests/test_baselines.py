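import numpy as np
import pytest

from dtr_ramp.baselines import (
    AOWLearner,
    OLearningLP,
    QLearningLasso,
    _hinge_lp,
    fit_l1_qlearning,
)
from dtr_ramp.data import StageDesign, TrajectoryDataset


def _two_stage_cohort(seed, n=300, noise=0.0):
    """Y = A2 * Z1 exactly (plus optional noise); Z2 is irrelevant."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    a = rng.choice([-1.0, 1.0], (n, 2))
    y = a[:, 1] * z[:, 0] + noise * rng.standard_normal(n)
    data = TrajectoryDataset(
        features=[z.copy(), z.copy()],
        treatments=a,
        reward=y,
        propensities=np.full((n, 2), 0.5),
        column_names=[["Z1", "Z2"], ["Z1", "Z2"]],
    )
    design = StageDesign(penalized=[[0, 1], [0, 1]], unpenalized=[[], []])
    return data, design


class TestQLearning:
    def test_noiseless_recovery_of_single_tailoring_variable(self):
        data, design = _two_stage_cohort(0)
        est = QLearningLasso(random_state=0).fit(data, design)
        sel2 = est.selected_[1]
        assert sel2[0] and not sel2[1]  # Z1 in, Z2 out at stage 2
        # stage-2 rule reproduces sign(Z1)
        dec = est.stage_decision(1, data.features[1])
        np.testing.assert_array_equal(dec, np.sign(data.features[1][:, 0]))

    def test_huge_penalty_gives_constant_plus_one_rule(self):
        data, design = _two_stage_cohort(1)
        est = QLearningLasso(alphas=[1e6], random_state=0).fit(data, design)
        for t in range(2):
            assert np.all(np.abs(est.coef_.beta[t]) == 0.0)
            np.testing.assert_array_equal(est.stage_decision(t, data.features[t]), 1.0)

    def test_backward_stage_fit_ignores_stage1_features(self):
        data, design = _two_stage_cohort(2)
        est1 = QLearningLasso(random_state=0).fit(data, design)
        tampered = TrajectoryDataset(
            features=[data.features[0] * 3.0 + 1.0, data.features[1]],
            treatments=data.treatments,
            reward=data.reward,
            propensities=data.propensities,
            column_names=data.column_names,
        )
        est2 = QLearningLasso(random_state=0).fit(tampered, design)
        np.testing.assert_allclose(est1.coef_.beta[1], est2.coef_.beta[1], atol=1e-10)

    def test_functional_wrapper_returns_backward_result(self):
        data, design = _two_stage_cohort(3)
        res = fit_l1_qlearning(data, design, random_state=0)
        assert len(res.lambdas) == 2 and res.coef.T == 2


class TestHingeLP:
    def test_all_zero_weights_give_zero_coefficients(self):
        h = np.column_stack([np.ones(5), np.arange(5.0)])
        theta = _hinge_lp(h, np.ones(5), np.zeros(5), lam=1.0, box=100.0)
        np.testing.assert_array_equal(theta, 0.0)

    def test_single_separable_subject_attains_zero_hinge(self):
        h = np.array([[1.0]])  # intercept only
        theta = _hinge_lp(h, np.array([1.0]), np.array([1.0]), lam=0.0, box=100.0)
        assert theta[0] >= 1.0 - 1e-9

    def test_solution_slacks_satisfy_complementarity(self):
        rng = np.random.default_rng(4)
        h = np.column_stack([np.ones(30), rng.standard_normal(30)])
        labels = rng.choice([-1.0, 1.0], 30)
        weights = rng.uniform(0, 2, 30)
        lam = 0.5
        theta = _hinge_lp(h, labels, weights, lam, box=100.0)
        hinge = np.maximum(0.0, 1.0 - labels * (h @ theta))
        # LP objective computed from theta alone must match the optimum the
        # slack variables attained (xi_i = hinge_i at the optimum)
        obj = weights @ hinge + lam * np.abs(theta).sum()
        grid_best = _lp_grid_oracle(h, labels, weights, lam)
        assert obj <= grid_best + 1e-6

    def test_lp_matches_dense_grid_on_toy(self):
        rng = np.random.default_rng(5)
        n = 10
        h = np.column_stack([np.ones(n), rng.standard_normal(n)])
        labels = rng.choice([-1.0, 1.0], n)
        weights = rng.uniform(0.2, 1.5, n)
        lam = 0.7
        theta = _hinge_lp(h, labels, weights, lam, box=100.0)
        obj = weights @ np.maximum(0, 1 - labels * (h @ theta)) + lam * np.abs(theta).sum()
        assert obj <= _lp_grid_oracle(h, labels, weights, lam) + 1e-6


def _lp_grid_oracle(h, labels, weights, lam, lo=-3.0, hi=3.0, step=0.01):
    g = np.arange(lo, hi + 1e-12, step)
    t0, t1 = np.meshgrid(g, g, indexing="ij")
    margins = labels[:, None, None] * (
        h[:, 0][:, None, None] * t0 + h[:, 1][:, None, None] * t1
    )
    hinge = np.maximum(0.0, 1.0 - margins)
    obj = np.tensordot(weights, hinge, axes=1) + lam * (np.abs(t0) + np.abs(t1))
    return obj.min()


class TestOLearning:
    def test_raw_nonnegative_outcome_runs_and_is_backward(self):
        data, design = _two_stage_cohort(6)
        data = data.with_reward(np.abs(data.reward))
        est = OLearningLP(random_state=0).fit(data, design)
        assert est.coef_.T == 2 and len(est.lambdas_) == 2

    def test_negative_outcome_error_mode(self):
        data, design = _two_stage_cohort(7)
        est = OLearningLP(negative_outcome="error", random_state=0)
        with pytest.raises(ValueError, match="nonnegative"):
            est.fit(data, design)

    def test_stage2_fit_unaffected_by_stage1_features(self):
        data, design = _two_stage_cohort(8)
        data = data.with_reward(np.abs(data.reward))
        est1 = OLearningLP(random_state=0).fit(data, design)
        tampered = TrajectoryDataset(
            features=[data.features[0] * 2.0, data.features[1]],
            treatments=data.treatments,
            reward=data.reward,
            propensities=data.propensities,
            column_names=data.column_names,
        )
        est2 = OLearningLP(random_state=0).fit(tampered, design)
        np.testing.assert_allclose(est1.coef_.beta[1], est2.coef_.beta[1], atol=1e-8)


class TestAOWL:
    def test_sign_symmetry_single_stage(self):
        # negating Y and flipping the labels leaves the fitted rule unchanged
        rng = np.random.default_rng(9)
        n = 120
        z = rng.standard_normal((n, 2))
        a = rng.choice([-1.0, 1.0], n)
        y = a * z[:, 0] + 0.2 * rng.standard_normal(n)
        design = StageDesign(penalized=[[0, 1]], unpenalized=[[]])
        d1 = TrajectoryDataset([z], a[:, None], y, np.full((n, 1), 0.5))
        d2 = TrajectoryDataset([z], -a[:, None], -y, np.full((n, 1), 0.5))
        e1 = AOWLearner(random_state=0).fit(d1, design)
        e2 = AOWLearner(random_state=0).fit(d2, design)
        np.testing.assert_allclose(e1.coef_.beta[0], e2.coef_.beta[0], atol=1e-8)
        np.testing.assert_allclose(e1.coef_.gamma, e2.coef_.gamma, atol=1e-8)

    def test_pilot_favours_true_tailoring_variables(self):
        from dtr_ramp.penalty import pilot_normalize

        data, design = _two_stage_cohort(10, n=400, noise=0.3)
        est = AOWLearner(random_state=0).fit(data, design)
        btilde = pilot_normalize(est.coef_.beta)
        stacked = np.vstack(btilde)
        # Z1 drives the stage-2 reward; its pooled pilot magnitude dominates
        assert np.abs(stacked[:, 0]).max() > np.abs(stacked[:, 1]).max()
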