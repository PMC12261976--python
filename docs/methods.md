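# Methods

`dtr-ramp` estimates optimal multistage dynamic treatment regimens (DTRs)
with *simultaneous* cross-stage variable selection. This note records the
model, the numerical procedure, the synthetic benchmark, and the design
choices that were genuinely open.

## Model and estimand

A cohort follows T decision stages. At stage t the history `H_t` is
observed, a binary treatment `A_t ∈ {−1, +1}` is assigned with probability
`p(A_t | H_t)`, and a terminal cumulative reward `Y` (larger = better) is
recorded. Under the standard causal assumptions (SUTVA, no unmeasured
confounders, positivity — all satisfied by design in a SMART), the value of
a regimen `D = (D_1, …, D_T)` is identified by inverse-probability
weighting:

    E_D[Y] = E[ Y · Π_t 1{A_t = D_t(H_t)} / Π_t p(A_t | H_t) ].

We restrict to linear rules `D_t = sign(g_t(H_t))`,
`g_t = W_t'α_t + O_t'β_t + γ_t`, where the `O_t` are the P candidate
tailoring features (aligned across stages so a repeatedly measured feature
forms one cross-stage group) and `W_t` holds always-kept columns such as
earlier treatments. Maximizing the identified value is NP-hard (product of
indicators), so the indicator product is replaced by the multistage ramp
surrogate

    min_t ψ(A_t g_t(H_t) / η),      ψ(x) = max(min(x, 1), 0),

for the positive part of Y, plus a correction term that sums the same
surrogate over all `2^T − 1` counterfactual treatment sequences weighted by
the negative part of Y. The shifting parameter `η ∈ (0, 1]` sharpens the
ramp toward the 0–1 loss; it is treated as a tuning parameter. Enumerating
the alternative sequences is exact and costs `O(n·2^T·T)`; the method
targets small stage counts (T ≤ 4).

Selection is induced by an adaptive cross-stage group-lasso penalty

    ρ_{λ,γ}(θ) = λ Σ_p ω_p Σ_t |β_{t,p}|,
    ω_p = (Σ_t β̃_{t,p}²)^(−γ/2),

where the pilot coefficients β̃ are a consistent preliminary estimate,
normalized to unit norm per stage. Pooling a feature's coefficients across
stages inside one weight makes the penalty hardest on features unimportant
at *every* stage — the estimator removes exactly those, rather than
accumulating stagewise false discoveries the way backward-sequential
methods do. `γ = 1` by default; intercepts and `W_t` columns are never
penalized. Weights are capped at `1e6` so a pilot feature that is zero at
every stage yields a finite objective while still being forced to zero at
any practical λ. The pilot is the AOWL solution (below); any root-n
consistent pilot can be substituted.

Because subtracting any function of `H_1` from Y leaves the population
value ordering unchanged, the default fitting path replaces Y by the
residual `Y − Ê[Y | H_1]` (lasso, CV-chosen strength). This shrinks weight
magnitudes and stabilizes the fit; raw-Y fitting is available via
`residualize=False`.

## The DC solver

In minimization form the objective is `F = −V_n(θ; η) + ρ_λ(β)` with `V_n`
the empirical surrogate value (mean scale). Writing `ψ = φ₁ − φ₂`,
`φ₁(u) = max(u, 0)`, `φ₂(u) = max(u − 1, 0)`, each weighted term satisfies

    −w·min_t ψ(u_t) = w·max_t[φ₂(u_t) + Σ_{s≠t} φ₁(u_s)] − w·Σ_s φ₁(u_s),

so `F = G − H + ρ` with G, H convex piecewise-linear (margins are affine in
θ). Each DC step linearizes H at the current iterate (subgradient
convention: slope 0 at the φ₁ kink u = 0 and the φ₂ kink u = 1, fixed for
reproducibility) and minimizes `G − ⟨∇H, θ⟩ + ρ` by cyclic coordinate
descent (stage order 1..T; within a stage: intercept, unpenalized,
penalized).

The coordinate subproblem is solved *exactly*. For a coordinate in stage t,
the per-term max collapses to a single hinge: with
`δ = min_{s≠t} ψ(u_s)` (δ = 1 when T = 1),

    max_t'[φ₂(u_t') + Σ_{s≠t'} φ₁(u_s)] = const + φ₁(u_t − δ),

so the one-dimensional function is a weighted sum of hinges plus a linear
term and `λω|x|` — minimized by sorting breakpoints and walking the
subgradient. On flat minimizing segments the point closest to the current
value is returned (stability); coefficients live in a box `[−B, B]`
(default B = 100; a warning is raised if the bound activates, which on
standardized data indicates a degenerate direction). Note that θ = 0 is
always a DC fixed point of this objective (all margins sit at the ψ kink),
which is why warm starts matter.

Stopping: the DC loop ends when the relative objective decrease falls below
`tol` (default 1e-6) or after `max_dc_iter` (50) iterations; coordinate
sweeps stop at `max_sweeps` per DC step or when the largest coordinate move
is below 1e-8. The estimator default is `max_sweeps = 20`: subproblems are
then solved approximately, which leaves DC monotonicity intact (any descent
of the convex majorant descends F) and changes the benchmark results only
within replication noise, at roughly half the cost of fully converged
sweeps. The low-level `FitConfig` default remains 100. The objective
history is checked nonincreasing (tolerance 1e-9) in the test suite, and
the solver is validated against a dense-grid oracle on tiny instances.

A practical consequence of the piecewise-linear geometry worth recording:
at small η the data part of the objective is locally flat between
decision-boundary breakpoints whose slope jumps scale like `w/η`. The ℓ1
term therefore shrinks a redundant coefficient only until it reaches the
first breakpoint that would flip a training decision, where it can "park"
at a small nonzero value instead of reaching 0 exactly. Selection
(|coef| > 1e-6) consequently errs toward keeping a few small stage-1
coefficients; see Limitations.

## Warm starts, pilot, and tuning

`(λ, η)` are chosen by twofold cross-validation of an AIC-type criterion.
On each training fold: nuisance models (lasso-logistic propensities per
stage, lasso conditional mean for residualization) are fit on that fold and
applied to the held-out fold; the AOWL solution on the fold initializes the
unpenalized `(0, η)` fit, whose solution warm-starts every `λ > 0` fit and
supplies the adaptive weights. The held-out criterion is

    n* · log( R̂(θ̂(λ,η)) / R̂(θ̂(0,η)) ) − k(λ,η),

with R̂ the sum-scale surrogate value on the evaluation fold, `n*` the
evaluation-fold size, and k the number of coefficients with magnitude above
1e-6. A pair with nonpositive R̂ in numerator or denominator is invalid
(−∞); if every pair is invalid the fit fails loudly. Ties break toward
larger λ, then smaller η. The winner is refit on all data with an all-data
pilot. R̂ is evaluated with the working (residualized) outcome so that both
ratio terms refer to the objective actually optimized; the criterion is
insensitive to this choice in practice (checked numerically).

Defaults: `λ ∈ {2⁰, …, 2¹⁰}`, `η ∈ {1e-3, 1e-4, 1e-5}`; fold split
stratified by `(A_1, sign Y)`; `n*` read as the evaluation-fold size.

## Baselines

*Q-learning with lasso* fits `Q_t = c + H_t'w + A_t(θ₀ + H_t'θ)` backward
with CV-chosen lasso strength; the stage-(t−1) pseudo-outcome is the
fitted max over arms (ties toward +1); the rule is `sign(θ₀ + H_t'θ)`.

*O-learning with L1 penalty* solves, backward,
`min_θ Σ_i w_it ϕ(A_it H_it'θ) + λ‖θ‖₁` with hinge
`ϕ(x) = (1−x)₊` and weights
`w_it = [Π_{s>t} 1{A_is g_s > 0}] · Y_i / Π_{s≥t} p_s`, as an exact linear
program (positive/negative coefficient split, hinge slacks; HiGHS via
scipy). The L1 norm covers the full coefficient vector including the
intercept, as in the stagewise objective. λ is selected per stage from the
decade grid `1e-5 … 1e5` by twofold CV on the held-out weighted
concordance value. Hinge weights must be nonnegative; a signed Y is
handled by `negative_outcome`: `"drop"` (default) uses the positive part
Y⁺, `"shift"` subtracts the training minimum (the classical
outcome-weighted-learning device — sensitive to heavy lower tails, which
it has in these benchmarks), `"flip"` uses |w| with flipped pseudo-label.

*AOWL* residualizes Y against `H_1` first and then runs the same backward
LPs with the |residual| + flipped-label equivalence for negative residuals.
It serves as a learner, as the DC warm start, and as the adaptive-weight
pilot.

## Synthetic benchmark

The generator emulates a two-stage SMART: twelve baseline covariates
`Z ~ MVN(0, Σ)` (unit variances, covariance 0.2 among Z1..Z6, 0 elsewhere)
plus three repeatedly measured covariates per subject,

    X_{i1} = Z1·w_i + a_i + e_{i1},
    X_{i2} = Z1·w_i + a_i(1 + A1/2) + e_{i2},   i = 1, 2, 3,

with `w_i ~ U[0,1]`, `a_i ~ N(0,1)`, `e ~ N(0,1)` drawn per subject and
index i (so `a_i` induces within-subject correlation between the two
measurements, and stage-1 treatment structurally shifts the stage-2
measurement). Treatments are assigned with logits `X_{11}/3` (stage 1) and
`X_{12}/3 + A1/2` (stage 2). Setting 1 has a linear reward with stage
contrasts `3Z1 + 3Z2 − 2Z7 − 2Z8 − 2X_{1t}`; setting 2 replaces them with
the quadratic bracket
`(Z1+3)² + (Z2+3)² + (Z7−3)² + (Z8−3)² + (2/3)(X_{1t}−5)² − 60` over the
nonlinear baseline `1 + Z1 + Z2 + (Z3² + Z4²)/2`, so linear decision rules
are misspecified there by construction. In both settings the important
tailoring variables are `(Z1, Z2, Z7, Z8, X1)` at each stage out of P = 15
candidates (`A1` is excluded from selection at stage 2).

Fitted regimens are scored by Monte Carlo from the structural model
(`true_value`): fresh subjects are drawn, the stage-1 decision is fed into
the stage-2 covariate model before the stage-2 decision is requested, and
the mean simulated reward is returned (test size 5000). Selection is scored
by per-stage FN/FP over the candidates ((FN+FP)/P = FDR, threshold 1e-6)
and by the mean pairwise Jaccard index across replications (J(∅,∅) = 1).
The stabilized IPW estimator (SIPWE) and the extreme-weight filter
(truncating |Y|/Πp at 10) are provided for observational cohorts; note
that SIPWE's `1/Πp` weights renormalize to the *uniform* assignment
measure, so for the observed-assignment-matching rule it estimates the
mean of the constant-regime values, not the observed-data mean.

What the generator does not emulate: missing data, more than two arms,
measurement error in propensities beyond estimation, or the irregular
visit timing of real EHR cohorts — passing benchmarks here shows
correctness of the machinery under the stated model, not field readiness.

## Problem sizes

Replication studies in the test suite and the acceptance script run 25
seeded replications per configuration (the reference tables were built
from 500) with training sizes N ∈ {200, 400} and Monte-Carlo test size
5000; agreement is judged within two standard errors of the reference
means. At these sizes one tuned fit takes a few seconds on one CPU.

## Known limitations

- Stage-1 false positives run above the reference tables (FDR₁ ≈ 0.1–0.2
  at N = 400 versus ≈ 0.05): the exact coordinate solver parks small
  redundant stage-1 coefficients at decision-boundary breakpoints (see
  above), and the held-out criterion tolerates them because they barely
  move the surrogate value. Rewards and stage-2 selection are unaffected;
  fitted regimens score at or slightly above the reference values.
- The O-learning baseline, solved as an exact LP, recovers the true
  tailoring variables and scores near the ramp learner — substantially
  better than the reference implementation of the same objective. The
  displayed objective does not pin down negative-weight handling or solver
  details, and none of the standard choices (drop/shift/flip) reproduces
  the reference's partially informative rules.
- DC descent guarantees a stationary point, not a global optimum; quality
  depends on the AOWL warm start. θ = 0 is always a fixed point.
- Propensities enter as plug-ins; no augmentation beyond stage-1
  residualization, and positivity violations (tiny Πp) inflate weights —
  use the extreme-weight filter on observational data.
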