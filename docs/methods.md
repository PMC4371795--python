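# Methods

## Model and assumptions

The startle response is modelled as a one-dimensional decision: choose the
response magnitude `r` in `[0, r_max]` minimising the total expected cost

```
C_TOT(r) = C_R,d(r) + η·C_R,f(r) + P(B|X)·[C_B,d(r) + η·C_B,f(r)]
```

All costs combine additively and are known to the agent; the blow is
Bernoulli in the discrete model (probability `P(B|X)`, independent of `r`);
opportunity costs scale jointly and linearly with the utility `η` of the
interrupted behaviour.  The behavioural constraints are slope conditions:
the blow cost `C_B,d + η·C_B,f` is strictly decreasing in `r` (a more
vigorous startle protects better), the startle opportunity cost is strictly
increasing, the blow opportunity cost strictly decreasing, and the former's
slope is smaller in magnitude than the latter's.

These constraints are not tied to functional forms, and no canonical forms
exist for startle costs; the package therefore ships three parametric
families — `quadratic-exponential` (default: convex quadratic startle cost,
exponentially decaying blow cost, linear opportunity costs), `linear`, and
`logistic` — and audits any family numerically (`audit_assumptions`: central
differences on a lattice, step `r_span/(10·n_grid)`, strict inequalities
enforced with a 1e−10 margin).  Construction and audit are deliberately
separate: building a family never guarantees the assumptions.

### Applicability range of the opportunity-slope condition

The η-monotonicity result compares `C_R,f(r) + P(B|X)·C_B,f(r)` at candidate
minimisers, so the condition it actually needs is the expectation-weighted
one, `|C′_R,f| < P(B|X)·|C′_B,f|`.  With a raw slope ratio below 1 but a
small blow probability, raising η can strictly *lower* the minimiser (the
opportunity sum is then increasing in `r`).  This is an applicability-range
statement, not a defect: the slope relation must hold over the range of
startle magnitudes and expected blow costs the model is applied to.  The
audit therefore checks the raw condition by default and accepts an optional
`p_blow` for the weighted check; the property harnesses draw startle-side
opportunity slopes in `[0.02, 0.07]`, blow-side slopes in `[0.6, 1.2]`, and
blow probabilities of at least 0.15, so the weighted condition holds for
every draw (0.07 < 0.15·0.6).

## Solver

`optimal_startle` evaluates the objective on a 1 024-point grid over the
domain and refines inside the one-grid-step bracket with bounded scalar
minimisation (`xatol = 1e−8`).  Grid-first avoids local-minimum traps in
non-convex (e.g. logistic) families; the theorems concern *global*
minimisers.  Ties — flat valleys, plateaus reaching the domain floor —
resolve to the smallest `r`, consistent with the non-strict `r0* ≥ r0` in
the monotonicity results.  Every shipped family is regression-checked
against an exhaustive 10⁴-point grid search to within one grid step.

## Bayesian inference

Posteriors are likelihood-ratio-scaled associations under the simplifying
independence assumption `p(S, CS+) = p(S)·p(CS+)`:
`P(B|{S,CS+}) = P(S|B)·P(B|CS+)/P(S)`.  The expression can exceed 1 for
extreme factor combinations; it is clamped to `[0, 1]` with a logged
warning rather than renormalised, and no shipped scenario reaches the
clamp.  The CS-alone posterior `P(¬S|B)·P(B|CS+)/P(¬S)` is below 1e−3
whenever `P(¬S|B) ≤ 1e−3` *and* `P(B|CS+) ≤ P(¬S)`; the randomised
forward-model distributions used in the tests draw occasional probes
(`P(S) ≤ 0.5`) and moderate associations (`≤ 0.5`), the regime experimental
paradigms occupy.  "No startle elicited" means the probe posterior is below
a configurable epsilon (default 1e−3); the underlying prediction is
qualitative.

## Continuous blow magnitude

The continuous model holds mass on a grid of blow magnitudes `b > 0`
(missing mass is the no-blow outcome, `b = 0`, zero cost — a Bernoulli ×
conditional-magnitude belief is expressed by scaling the conditional mass
to the occurrence probability) and a bivariate cost `c_b(r, b)` with
`c_b(r, 0) = 0`.  Total cost is `C_R(r) + Σ_b p(B=b)·c_b(r, b)`; the
expectation-coded approximation is `p_blow·c_b(r, E[b|blow])`.  The two
coincide exactly for `c_b` linear in `b`, and a point-mass belief recovers
the discrete model verbatim (same solver, same objective).

The shipped `saturating-protection` form is
`c_b(r, b) = b·(1 − g(r)·h(b))` with protection `g(r) = g_max·r/r_max`
(`g_max = 0.9`) and effectiveness `h(b) = clip((b_crit − b)/ramp, 0, 1)`
(`b_crit = 2`, `ramp = 0.6`, in the same arbitrary units as `b`): full
protection below `b_crit − ramp`, none at or above `b_crit`.  It is the
minimal form exhibiting both the compliant regime (startle always helps)
and the violation regime (`∂c_b/∂r ≥ 0` for `b ≥ b_crit`) that
`effectiveness_violation_ranges` detects by a numeric derivative sign scan
(`b = 0` lattice points are excluded: a zero derivative there reflects the
no-blow outcome, not a protection failure).

## Conditioning simulations

Protocols are ordered trials (CS+, CS− or context; US flag and magnitude;
probe flag).  Two learning rules update, per stimulus, the association
`P(B|CS)` and a magnitude trace: the default conjugate beta-bernoulli
(posterior-mean counts; magnitude as a pseudo-count mean under the prior's
weight) and Rescorla–Wagner (`V ← V + α(λ − V)`, `λ ∈ {0, 1}`; the
magnitude trace follows the same recursion on the observed US magnitude,
0 on omission).  The decision on each trial uses the state *before* that
trial's outcome — the CS precedes the US — so the first probe after
acquisition is already potentiated.  Extinction is pure association decay
from non-reinforced trials; no separate inhibitory process is modelled.
Trajectories record, per trial, the association, magnitude estimate, probe
posterior, and the optimal startle under both codings; `cost_full` and
`cost_exp` are the full-distribution (true) total cost at `r0_full` and
`r0_exp`, so expectation coding's suboptimality is read directly off the
CSV.  Reported startle "magnitude" is `r0` itself; no mapping to EMG or
whole-body units is attempted.  An optional seeded log-normal response
noise exists for realistic-looking output and is off by default and in all
tests.

In the full-coding route the belief over magnitudes is the empirical
distribution of magnitudes observed on reinforced trials, scaled to the
current probe posterior; in the expectation-coding route the learner's
decaying magnitude trace enters the cost directly.  The trace blends
occurrence and magnitude (it decays on omission trials), which is exactly
the sparseness that generates the high-US rise-then-fall: during extinction
the trace falls back through the effective range while the association is
still appreciable, transiently restoring the incentive to startle.

### Davis–Astrachan configuration

The shipped comparison conditions with a medium (`b = 1.0`) versus high
(`b = 2.5`) US — below and inside the ineffectiveness range of the default
blow cost — over 10 reinforced trials followed by 30 extinction trials,
probed throughout, with Rescorla–Wagner learning at `α = 0.2`.  RW is used
here (the module default elsewhere is beta-bernoulli) because its flat-prior
conjugate counterpart starts at association ½ before any training and its
1/n decay stretches extinction; the geometric RW decay traverses the
effectiveness ramp in a few trials, which is what the shape classifier needs
to label cleanly.  `α = 0.2` puts the trained magnitude estimate
(2.5·(1−0.8¹⁰) ≈ 2.23) above `b_crit`, so the high-US group ends acquisition
with no protective value to a startle.  Extinction-segment shapes are
classified by the run-length sequence of signed trial-to-trial changes
(changes below 1e−6 collapse to no-change): `monotone-decreasing`,
`rise-then-fall`, `flat`, `monotone-increasing`, `other`.

## Scenario catalogue

Each paradigm is a single-axis manipulation with an expected direction;
directions are classified from `r0` differences with tolerance 1e−6 (the
solver floor).  Defaults: forward model `P(S|B) = 0.95`, `P(S) = 0.5`;
associations 0.4 (CS+) and 0.02 (CS−); context priors 0.05 (baseline) and
0.2 (threat); η = 2 for reward anticipation and 1.5 for instructed
attention at a fixed blow probability 0.3 (large enough that the weighted
slope condition holds for the default family).  The food-deprivation
scenario lowers the prior 0.2 → 0.15 for both arms and raises η to 4 in the
deprived arm only, yielding the observed dissociation; the
`reward_with_safety` scenario (prior ↓ and η ↑ with neither dominating) is
reported descriptively without a verdict, as the net direction is genuinely
indeterminate.  Instructed attention is modelled through η only;
modality-specific attentional gain is out of scope.

## What the synthetic conditions do and do not show

There are no empirical startle data in the package: cost families, forward
models and protocols are synthetic study conditions.  Passing tests show
that the *model* has the claimed properties (monotonicity, discrete-model
recovery, the coding dissociation, the directional predictions) under
assumption-satisfying families and realistic parameter regimes; they do not
show that any particular family fits measured startle magnitudes, that real
learning follows either rule, or that the chosen `b_crit` matches a real
footshock scale.  Fitting to empirical data is an explicit non-goal.

## Problem sizes and numerical choices

Property harnesses use 200 randomised families per theorem with a
10⁴-point oracle; continuous-model recovery uses 50 families; conditioning
runs are 40 trials per group.  Solver: 1 024-point grid + `xatol = 1e−8`
refinement; audit margin 1e−10; direction tolerance 1e−6; belief grids
default to 256 points when discretising a density.  Degenerate inputs:
a single-point `r_domain` yields no derivative and no violation intervals;
zero-mass beliefs cost nothing under either coding (expectation coding logs
the undefined-expectation case); `η = 0` removes opportunity terms and
fails the strict-slope audit, as it should.
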