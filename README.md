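# startleopt

A normative model of startle reflex modulation: the vigour of the startle
response is the solution of a cost-minimisation problem, and its well-known
context sensitivity — fear-potentiated startle, potentiation by context
conditioning, by reward anticipation and instructed attention, suppression by
positive pictures, and the puzzling non-monotonic extinction after
very-high-magnitude footshock conditioning — follows from Bayesian decision
theory rather than from a descriptive motivational state.

The package is for computational-neuroscience and behavioural-modelling work:
it provides the cost model and solver, the Bayesian blow-probability
inference, a continuous blow-magnitude extension with a sparse
"expectation-coding" approximation, trial-level conditioning/extinction
simulations, and a scenario catalogue that checks each experimental paradigm's
qualitative prediction.

## The model

An organism suspecting an imminent blow *B* chooses a startle magnitude *r*
minimising

```
C_TOT(r) = C_R,d(r) + η·C_R,f(r) + P(B|X) · [ C_B,d(r) + η·C_B,f(r) ]
```

where `C_R,d` is the direct (metabolic) cost of the response, `C_B,d` the
direct cost of the blow (reduced by a more vigorous startle), `C_R,f`/`C_B,f`
the opportunity costs of the interruption caused by the startle and by the
blow, and `η ≥ 0` scales the utility of the interrupted behaviour.  Under
mild slope assumptions (blow cost strictly decreasing in *r*; startle
opportunity cost rising more slowly than blow opportunity cost falls), the
global minimiser `r0` is non-decreasing in the blow probability `P(B|X)` and
in `η` — the two monotonicity theorems the property tests exercise against a
dense grid-search oracle.

`P(B|X)` is not fixed or learned directly: it is inferred by Bayes' theorem
from a forward model, `P(B|{S,CS+}) = P(S|B)·P(B|CS+)/P(S)`, so conditioning
the association `P(B|CS+)` potentiates startle on the very first probe, and a
CS presented without the startle probe *S* yields a near-zero posterior (no
startle).  The continuous extension replaces the Bernoulli blow with a
distribution over scalar blow magnitudes *b* and a bivariate cost
`c_b(r, b)`; coding only the *expectation* of *b* instead of the full
distribution is cheaper but provably suboptimal when startle loses
effectiveness above a critical blow magnitude — which reproduces the
Davis–Astrachan rise-then-fall extinction pattern after high-magnitude
footshock.

## Worked example

```python
import startleopt as so

family = so.make_cost_family()          # audited default cost family
fm_plus  = so.ForwardModel(p_s_given_b=0.95, p_s=0.5, p_b_given_cs=0.4)
fm_minus = so.ForwardModel(p_s_given_b=0.95, p_s=0.5, p_b_given_cs=0.02)

for label, fm in [("CS+", fm_plus), ("CS-", fm_minus)]:
    post = so.posterior_with_probe(fm)
    opt = so.optimal_startle(family, post)
    print(f"{label}: P(B|X) = {post.p_blow:.3f}, optimal startle r0 = {opt.r0:.3f}")
```

prints

```
CS+: P(B|X) = 0.760, optimal startle r0 = 0.809
CS-: P(B|X) = 0.038, optimal startle r0 = 0.006
```

The learned CS+→US association raises the blow posterior from 0.038 to 0.760
and the cost-minimising startle magnitude from ≈0 to 0.81 (arbitrary vigour
units on [0, 1]): fear-potentiated startle as optimal behaviour.  The
conditioning simulator shows the same end to end:

```python
result = so.davis_astrachan_scenario()   # medium (b=1.0) vs high (b=2.5) US
print(result.shapes)
```

```
{'medium': 'monotone-decreasing', 'high': 'rise-then-fall',
 'medium_full': 'monotone-decreasing', 'high_full': 'flat'}
```

Under expectation coding, the high-US group's startle *rises* early in
extinction before falling — suboptimal behaviour that disappears under
full-distribution coding.

A CLI wraps the catalogue: `startleopt all` runs every scenario and writes a
JSON prediction report, `startleopt panels` regenerates the four cost-curve
panels with minimiser markers, `startleopt protocol FILE` simulates a YAML
trial protocol to CSV.

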