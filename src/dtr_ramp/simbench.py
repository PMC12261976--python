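"""Two-stage SMART simulation benchmark, metrics, and value estimators.

The generator emulates a two-stage trial with 12 baseline covariates
Z1..Z12 ~ MVN(0, Sigma) (unit variances; covariance 0.2 among Z1..Z6, 0
elsewhere) and three repeatedly measured covariates per subject,

    X_{i1} = Z1 w_i + a_i + e_{i1},
    X_{i2} = Z1 w_i + a_i (1 + A1 / 2) + e_{i2},    i = 1, 2, 3,

with w_i ~ Unif[0,1], a_i ~ N(0,1), e ~ N(0,1) drawn per subject and
covariate index. Treatments are randomized with logits X_{11}/3 at stage 1
and X_{12}/3 + A1/2 at stage 2. Two reward models are provided: a linear
one (setting 1) and a nonlinear one with quadratic treatment contrasts
(setting 2); in both, the important tailoring variables are
(Z1, Z2, Z7, Z8, X1) at each stage, out of P = 15 candidates.

``true_value`` scores a regime by Monte Carlo from the structural model,
propagating the stage-1 decision into the stage-2 covariates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import StageDesign, TrajectoryDataset, sign0

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "SelectionMetrics",
    "generate_cohort",
    "true_value",
    "selection_metrics",
    "jaccard_summary",
    "sipwe",
    "run_replications",
    "TRUE_IMPORTANT",
]

Z_NAMES = [f"Z{j}" for j in range(1, 13)]
H1_NAMES = Z_NAMES + ["X11", "X21", "X31"]
H2_NAMES = Z_NAMES + ["X12", "X22", "X32", "A1"]
CANDIDATE_NAMES = [Z_NAMES + ["X11", "X21", "X31"], Z_NAMES + ["X12", "X22", "X32"]]
TRUE_IMPORTANT = [
    {"Z1", "Z2", "Z7", "Z8", "X11"},
    {"Z1", "Z2", "Z7", "Z8", "X12"},
]


@dataclass
class SimulationConfig:
    setting: int
    n: int
    seed: int = 0
    n_test: int = 5000
    reps: int = 1

    def __post_init__(self):
        if self.setting not in (1, 2):
            raise ValueError("setting must be 1 or 2")
        if self.n < 20:
            raise ValueError("training size must be at least 20")
        if self.reps < 1:
            raise ValueError("replication count must be positive")


@dataclass
class SimTruth:
    """Hidden structural state of a generated cohort."""

    Z: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    propensities: np.ndarray  # true P(A_t = observed | H_t), (n, 2)
    important: list = field(default_factory=lambda: [set(s) for s in TRUE_IMPORTANT])


def _z_cov() -> np.ndarray:
    sigma = np.eye(12)
    sigma[:6, :6] = 0.2
    np.fill_diagonal(sigma, 1.0)
    return sigma


_Z_CHOL = np.linalg.cholesky(_z_cov())


def _draw_baseline(rng, n):
    Z = rng.standard_normal((n, 12)) @ _Z_CHOL.T
    omega = rng.uniform(0.0, 1.0, (n, 3))
    alpha = rng.standard_normal((n, 3))
    return Z, omega, alpha


def _reward(setting, Z, X1, X2, A1, A2, eps):
    if setting == 1:
        c1 = 3 * Z[:, 0] + 3 * Z[:, 1] - 2 * Z[:, 6] - 2 * Z[:, 7] - 2 * X1[:, 0]
        c2 = 3 * Z[:, 0] + 3 * Z[:, 1] - 2 * Z[:, 6] - 2 * Z[:, 7] - 2 * X2[:, 0]
        return 1 + Z[:, 0] + Z[:, 2] + A1 * c1 + A2 * c2 + eps
    b1 = (
        (Z[:, 0] + 3) ** 2
        + (Z[:, 1] + 3) ** 2
        + (Z[:, 6] - 3) ** 2
        + (Z[:, 7] - 3) ** 2
        + (2.0 / 3.0) * (X1[:, 0] - 5) ** 2
        - 60.0
    )
    b2 = (
        (Z[:, 0] + 3) ** 2
        + (Z[:, 1] + 3) ** 2
        + (Z[:, 6] - 3) ** 2
        + (Z[:, 7] - 3) ** 2
        + (2.0 / 3.0) * (X2[:, 0] - 5) ** 2
        - 60.0
    )
    baseline = 1 + Z[:, 0] + Z[:, 1] + 0.5 * (Z[:, 2] ** 2 + Z[:, 3] ** 2)
    return baseline + A1 * b1 + A2 * b2 + eps


def generate_cohort(config: SimulationConfig, attach_propensities: bool = False):
    """Draw one training cohort; returns (dataset, design, truth).

    True assignment probabilities live on the truth handle; they are only
    attached to the dataset when ``attach_propensities`` (benchmarks follow
    the convention that they must be estimated).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    Z, omega, alpha = _draw_baseline(rng, n)
    X1 = Z[:, [0]] * omega + alpha + rng.standard_normal((n, 3))
    p1_plus = expit(X1[:, 0] / 3.0)
    A1 = np.where(rng.random(n) < p1_plus, 1.0, -1.0)
    X2 = Z[:, [0]] * omega + alpha * (1 + A1[:, None] / 2.0) + rng.standard_normal((n, 3))
    p2_plus = expit(X2[:, 0] / 3.0 + A1 / 2.0)
    A2 = np.where(rng.random(n) < p2_plus, 1.0, -1.0)
    Y = _reward(config.setting, Z, X1, X2, A1, A2, rng.standard_normal(n))

    p_obs = np.column_stack(
        [
            np.where(A1 > 0, p1_plus, 1 - p1_plus),
            np.where(A2 > 0, p2_plus, 1 - p2_plus),
        ]
    )
    data = TrajectoryDataset(
        features=[np.column_stack([Z, X1]), np.column_stack([Z, X2, A1])],
        treatments=np.column_stack([A1, A2]),
        reward=Y,
        propensities=p_obs if attach_propensities else None,
        column_names=[list(H1_NAMES), list(H2_NAMES)],
    )
    design = StageDesign(
        penalized=[np.arange(15), np.arange(15)],
        unpenalized=[np.array([], dtype=int), np.array([15])],  # A1 kept, unselected
    )
    truth = SimTruth(Z=Z, omega=omega, alpha=alpha, propensities=p_obs)
    return data, design, truth


def _as_policy(policy):
    if callable(policy) and not hasattr(policy, "stage_decision"):
        return policy
    return lambda t, h: policy.stage_decision(t, h)


def true_value(policy, setting: int, n_test: int = 5000, seed=None) -> float:
    """Monte-Carlo expected reward of a regime under the structural model.

    ``policy(t, H_raw) -> array in {-1, +1}`` receives the raw stage
    feature matrix in generator layout (stage 2 includes the assigned A1
    column). The stage-1 decision feeds the stage-2 covariate model before
    the stage-2 decision is requested.
    """
    decide = _as_policy(policy)
    rng = np.random.default_rng(seed)
    Z, omega, alpha = _draw_baseline(rng, n_test)
    X1 = Z[:, [0]] * omega + alpha + rng.standard_normal((n_test, 3))
    eps2 = rng.standard_normal((n_test, 3))
    epsY = rng.standard_normal(n_test)
    a1 = np.asarray(decide(0, np.column_stack([Z, X1])), dtype=float)
    X2 = Z[:, [0]] * omega + alpha * (1 + a1[:, None] / 2.0) + eps2
    a2 = np.asarray(decide(1, np.column_stack([Z, X2, a1])), dtype=float)
    return float(np.mean(_reward(setting, Z, X1, X2, a1, a2, epsY)))


@dataclass
class SelectionMetrics:
    """Per-stage false negatives/positives among the P candidates."""

    fn: np.ndarray
    fp: np.ndarray
    P: int

    @property
    def fdr(self) -> np.ndarray:
        return (self.fn + self.fp) / self.P


def selection_metrics(
    theta_hat,
    important=TRUE_IMPORTANT,
    candidate_names=CANDIDATE_NAMES,
    threshold: float = 1e-6,
) -> SelectionMetrics:
    """FN/FP/FDR of a fit against the per-stage truly important variables.

    ``theta_hat`` is a DTRCoefficients (its |beta| > threshold masks are
    used) or a list of per-stage selected-name sets.
    """
    if hasattr(theta_hat, "beta"):
        selected = [
            {candidate_names[t][j] for j in np.where(mask)[0]}
            for t, mask in enumerate(theta_hat.selected(threshold))
        ]
    else:
        selected = [set(s) for s in theta_hat]
    fn, fp = [], []
    for t, sel in enumerate(selected):
        truth = set(important[t])
        fn.append(len(truth - sel))
        fp.append(len(sel - truth))
    return SelectionMetrics(
        fn=np.array(fn), fp=np.array(fp), P=len(candidate_names[0])
    )


def jaccard_summary(selected_sets) -> float:
    """Mean pairwise Jaccard index across replications; J(empty, empty) = 1."""
    sets = [set(s) for s in selected_sets]
    if len(sets) < 2:
        raise ValueError("need at least two replications")
    vals = []
    for s1, s2 in itertools.combinations(sets, 2):
        if not s1 and not s2:
            vals.append(1.0)
        else:
            vals.append(len(s1 & s2) / len(s1 | s2))
    return float(np.mean(vals))


def sipwe(rules, data: TrajectoryDataset) -> float:
    """Stabilized inverse-probability-weighted value of a regime.

    ``rules`` is an (n, T) matrix of recommended treatments, a fitted
    linear-policy estimator, or a DTRCoefficients paired with the data via
    an estimator. Weights are concordance indicators over all stages
    divided by the product of assignment probabilities.
    """
    if data.propensities is None:
        raise ValueError("sipwe needs assignment probabilities on the dataset")
    if hasattr(rules, "predict"):
        D = rules.predict(data)
    else:
        D = np.asarray(rules, dtype=float)
    concord = (data.treatments == sign0(D)).all(axis=1)
    if not concord.any():
        raise ValueError("no subject is concordant with the rules at all stages")
    w = concord / np.prod(data.propensities, axis=1)
    return float((data.reward @ w) / w.sum())


# ---------------------------------------------------------------------------
# replication harness

METHODS = ("l1mrl", "l1_qlearning", "l1_olearning", "aowl")


def _make_estimator(method: str, seed: int, **overrides):
    from .baselines import AOWLearner, OLearningLP, QLearningLasso
    from .estimator import MultistageRampDTR

    if method == "l1mrl":
        return MultistageRampDTR(random_state=seed, **overrides)
    if method == "l1_qlearning":
        return QLearningLasso(random_state=seed, **overrides)
    if method == "l1_olearning":
        return OLearningLP(random_state=seed, **overrides)
    if method == "aowl":
        return AOWLearner(random_state=seed, **overrides)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


@dataclass
class ReplicationResult:
    method: str
    config: SimulationConfig
    table: pd.DataFrame  # one row per successful replication
    jaccard: np.ndarray  # per-stage mean pairwise JI
    failures: list

    def aggregate(self) -> pd.DataFrame:
        """Mean (SD) summary mirroring the benchmark-table layout."""
        numeric = self.table.drop(columns=["rep"]).select_dtypes("number")
        agg = numeric.agg(["mean", "std"])
        agg.loc["mean", [f"ji{t+1}" for t in range(len(self.jaccard))]] = self.jaccard
        return agg


def run_replications(
    method: str,
    config: SimulationConfig,
    estimator_overrides: dict | None = None,
    progress: bool = False,
) -> ReplicationResult:
    """Seeded generate -> fit -> evaluate pipeline, repeated ``config.reps`` times.

    Each replication draws a fresh training cohort, fits the learner
    (nuisance models estimated inside), scores the fitted regime by Monte
    Carlo on ``config.n_test`` fresh subjects, and records the selection
    metrics. Failures are recorded and excluded from the aggregate.
    """
    overrides = estimator_overrides or {}
    rows, failures = [], []
    sel_sets = [[] for _ in range(2)]
    children = np.random.SeedSequence(config.seed).spawn(config.reps)
    for r in range(config.reps):
        s_gen, s_fit, s_eval = (children[r].generate_state(3) & 0x7FFFFFFF).tolist()
        rep_cfg = SimulationConfig(
            setting=config.setting, n=config.n, seed=s_gen, n_test=config.n_test
        )
        data, design, truth = generate_cohort(rep_cfg)
        est = _make_estimator(method, s_fit, **overrides)
        try:
            est.fit(data, design)
        except Exception as exc:  # noqa: BLE001 - recorded, excluded, reported
            failures.append((r, repr(exc)))
            continue
        reward = true_value(est, config.setting, config.n_test, seed=s_eval)
        met = selection_metrics(est.coef_)
        names = est.selected_names(CANDIDATE_NAMES)
        for t in range(2):
            sel_sets[t].append(set(names[t]))
        rows.append(
            {
                "rep": r,
                "reward": reward,
                "fn1": met.fn[0],
                "fp1": met.fp[0],
                "fdr1": met.fdr[0],
                "fn2": met.fn[1],
                "fp2": met.fp[1],
                "fdr2": met.fdr[1],
                "lambda": getattr(est, "lambda_", np.nan),
                "eta": getattr(est, "eta_", np.nan),
                "sel1": ";".join(sorted(names[0])),
                "sel2": ";".join(sorted(names[1])),
            }
        )
        if progress:
            print(f"[{method}] rep {r + 1}/{config.reps}: reward={reward:.3f}")
    table = pd.DataFrame(rows)
    ji = np.array(
        [
            jaccard_summary(s) if len(s) >= 2 else np.nan
            for s in sel_sets
        ]
    )
    return ReplicationResult(
        method=method, config=config, table=table, jaccard=ji, failures=failures
    )
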