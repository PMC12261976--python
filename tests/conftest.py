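import numpy as np
import pytest

from dtr_ramp.data import StageDesign, TrajectoryDataset


@pytest.fixture
def tiny_two_stage():
    """n=4, T=2, one feature per stage, known propensities."""
    rng = np.random.default_rng(3)
    n = 4
    h1 = rng.standard_normal((n, 1))
    h2 = rng.standard_normal((n, 1))
    a = rng.choice([-1.0, 1.0], size=(n, 2))
    y = rng.standard_normal(n) * 2
    data = TrajectoryDataset(
        features=[h1, h2],
        treatments=a,
        reward=y,
        propensities=np.full((n, 2), 0.5),
        column_names=[["Z"], ["Z"]],
    )
    design = StageDesign(penalized=[[0], [0]], unpenalized=[[], []])
    return data, design


def make_random_instance(seed, n=6, d1=2, d2=2, with_propensities=True):
    """Small random two-stage cohort for solver property tests."""
    rng = np.random.default_rng(seed)
    h1 = rng.standard_normal((n, d1))
    h2 = rng.standard_normal((n, d2))
    a = rng.choice([-1.0, 1.0], size=(n, 2))
    y = rng.standard_normal(n) * 3
    p = rng.uniform(0.25, 0.75, (n, 2)) if with_propensities else None
    data = TrajectoryDataset([h1, h2], a, y, p)
    design = StageDesign(
        penalized=[np.arange(d1), np.arange(d2)],
        unpenalized=[[], []],
    )
    return data, design
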