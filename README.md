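# dtr-ramp

Optimal **dynamic treatment regimens** (DTRs) with **simultaneous
cross-stage variable selection**, for biostatisticians working with
SMART-style or observational longitudinal cohorts: one row per subject,
per-stage histories `H_t`, binary treatments `A_t ∈ {−1,+1}`, and a
terminal cumulative reward `Y`.

Backward-sequential learners (Q-learning, O-learning) select variables one
stage at a time and accumulate false discoveries across stages. This
package implements **L1-MRL** — learning all stage rules in a *single*
optimization by maximizing the multistage ramp-loss surrogate of the
inverse-probability-weighted value,

    (1/n) Σᵢ [ Yᵢ⁺ · min_t ψ(A_it g_t(H_it)/η) / Π_t p(A_it|H_it)
             + Yᵢ⁻ · Σ_{a≠Aᵢ} min_t ψ(a_t g_t(H_it)/η) / Π_t p(A_it|H_it) ]
             − λ Σ_p ω_p Σ_t |β_tp| ,

with ramp `ψ(x) = max(min(x,1),0)`, linear rules
`g_t = W_t'α_t + O_t'β_t + γ_t`, and an **adaptive cross-stage group-lasso
penalty** whose weights `ω_p = (Σ_t β̃_tp²)^{−γ/2}` come from an AOWL pilot
fit — so a feature is dropped exactly when it matters at *no* stage. The
nonconvex objective is minimized by a difference-of-convex (DC) algorithm
whose convex subproblems are solved by exact piecewise-linear coordinate
descent; `(λ, η)` are tuned by twofold cross-validation of an AIC-type
criterion. The field-standard baselines (lasso Q-learning, L1-penalized
O-learning via exact linear programs, AOWL) and a two-stage SMART
simulation benchmark with Monte-Carlo value evaluation, FN/FP/FDR and
Jaccard selection metrics, and a stabilized IPW value estimator (SIPWE)
are included. See `docs/methods.md` for the full model and numerics.

## Worked example

```python
import numpy as np
from dtr_ramp import (
    MultistageRampDTR, SimulationConfig, generate_cohort,
    true_value, selection_metrics,
)

# two-stage SMART cohort, linear reward setting, N = 400 subjects
data, design, truth = generate_cohort(SimulationConfig(setting=1, n=400, seed=11))

est = MultistageRampDTR(random_state=5).fit(data, design)
print("selected (lambda, eta):", est.tuning_.best_pair)
print("stage-1 variables:", est.selected_names(data)[0])
print("stage-2 variables:", est.selected_names(data)[1])

reward = true_value(est, setting=1, n_test=5000, seed=123)
met = selection_metrics(est.coef_)
print(f"Monte-Carlo value of the fitted regimen: {reward:.3f}")
print(f"per-stage FN {met.fn}, FP {met.fp}, FDR {np.round(met.fdr, 3)}")
```

prints

```
selected (lambda, eta): (64.0, 0.001)
stage-1 variables: ['Z1', 'Z2', 'Z7', 'Z8', 'X11']
stage-2 variables: ['Z1', 'Z2', 'Z7', 'Z8', 'X12']
Monte-Carlo value of the fitted regimen: 9.397
per-stage FN [0 0], FP [0 0], FDR [0. 0.]
```

The truly tailoring variables at each stage are `(Z1, Z2, Z7, Z8, X1t)`;
here the fit recovers exactly those five at both stages, and the fitted
regimen's expected reward (9.40) sits near the regime ceiling for this
setting (an uninformed constant rule scores about 1). The same pipeline is
available from the shell:

```bash
dtr-ramp simulate --setting 1 --n 400 --seed 11 --output-dir out/
dtr-ramp fit --cohort out/cohort_setting1_n400_seed11.csv \
             --schema examples/smart_schema.yaml --seed 5 --output-dir out/
dtr-ramp benchmark --method l1mrl --setting 1 --n 200 --reps 10 --seed 42
```

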