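# homingcues

Cue-combination analysis of triangle-completion homing in cluttered virtual
environments.

## The problem

How do human navigators combine **path integration** (PI — the continuous
tracking of self-motion) with **landmark cues** when the environment ranges
from an open steppe to a dense forest of identical trees?  In a
triangle-completion task the navigator walks two legs of a triangle
(35.4 vm and 25 vm with a 45° inner angle; vm = virtual metre) and must
return unguided to the start.  Varying the number of identical objects
around the goal (0, 1, 2, 3, 10, 99) manipulates *clutter*: with three
objects at 10 vm from the goal the location is fully triangulated, while
beyond three, objects become ambiguous and may mislead.

`homingcues` provides the complete analysis stack for this paradigm:

* **geometry** — the outbound course, ideal home vector, polar
  decomposition of endpoints, position error;
* **environment** — procedural, nested clutter environments honouring the
  task's placement constraints;
* **synthetic** — endpoint generators under PI-only, cue-*integration* and
  cue-*alternation* strategies, and a multi-participant study composer;
* **metrics** — accuracy (median position error) and precision (SD of
  position error), clutter-effect deltas, bootstrap median CIs, and
  rank-sum classification of participants;
* **mle** — the maximum-likelihood cue-combination model family (below);
* **stats** — forward-difference condition coding, mixed-model comparisons,
  the quadratic local-minimum check, and power analysis;
* **io / cli** — CSV trial tables, a YAML-configured pipeline, and
  `simulate / report / fit / compare / surface / power / pipeline`
  subcommands.

## The model

A goal estimate is decomposed into a distance and a direction component.
Distance information relative to a reference point (the release point for
PI, an object for a landmark) is a Gaussian **ring**

$$g(d) = \frac{1}{\sigma\sqrt{2\pi}}\, e^{-(d-\mu_d)^2 / 2\sigma^2},$$

and direction information is a von Mises **fan** over the signed homing
angle $x \in [-\pi, \pi]$,

$$f(x) = \frac{1}{2\pi I_0(\kappa)}\, e^{\kappa \cos(x - \mu_x)},$$

with $I_0$ the modified Bessel function of order zero.  Landmark rings are
fixed at the true goal distance of 10 vm; only the four PI parameters
$(\mu_d, \sigma, \mu_x, \kappa)$ are fitted (closed form).  Several
distance estimates combine either multiplicatively — **integration**
($\prod_i g_i$), which sharpens the estimate — or additively —
**alternation** ($\tfrac1n \sum_i g_i$), a mixture that models trial-wise
commitment to a single, possibly misidentified, tree.  The combined
distance term is always multiplied with the single direction term,
$L = f(x)\, g_{\text{combined}}(d)$, and variants are ranked by
$\ell = \sum \log L$ (with AIC/BIC agreeing), with bootstrap CIs for all
estimates and exportable 2-D likelihood surfaces.

## Worked example

```python
import math
from homingcues.geometry import standard_course
from homingcues.environment import build_environment
from homingcues.synthetic import default_cohort, simulate_study
from homingcues.metrics import summarize_performance, classify_participants
from homingcues.mle import (fit_pi_model, landmark_rings, CombinedModel,
                            compare_models)

course = standard_course()
trials = simulate_study(default_cohort(23, seed=1), seed=1)   # 3312 trials
summary = summarize_performance(trials)
print(summary.groupby("condition")[["median_error", "sd_error"]].median().round(2))
```

```
           median_error  sd_error
condition
0                  9.80      8.34
1                  6.77      4.88
2                  3.89      3.91
3                  1.93      1.06
10                 2.48     10.50
99                 2.68     14.82
```

Accuracy and precision are worst with no objects (PI alone, median error
~10 vm), best with three objects around the goal (~2 vm), and precision
collapses again in dense clutter — driven by the participants who confuse
trees.  The rank-sum classification separates them:

```python
print(classify_participants(trials)["label"].value_counts().to_dict())
# {'unchanged': 13, 'worse': 10}
```

Fitting the PI model on the three-object condition and comparing
cue-combination variants:

```python
cond3 = trials[trials["condition"] == 3][["x", "y"]].to_numpy(float)
fit = fit_pi_model(cond3, course.release, course.release_heading)
print(round(math.degrees(fit.params["mu_x"]), 1))   # 89.9 (ideal turn: 90 deg)

env = build_environment(3, seed=1)
rings = landmark_rings(env, sigma=2.0)
pi = fit.model
candidates = {
    "pi_only": pi,
    "integration": CombinedModel(fan=pi.fan, ring_pi=pi.ring_pi,
                                 rings_lm=rings, mode="integration"),
    "alternation": CombinedModel(fan=pi.fan, ring_pi=pi.ring_pi,
                                 rings_lm=rings, mode="alternation"),
}
print(compare_models(candidates, cond3).round(1))
```

```
             loglik     aic     bic  n_obs  rank
integration -2205.2  4418.5  4435.7    552     1
alternation -2369.8  4747.6  4764.8    552     2
pi_only     -2629.0  5265.9  5283.2    552     3
```

With three identifiable landmarks, integration of all cues explains the
endpoints best — the hallmark of Bayesian cue combination.

The same analyses are available from the shell, e.g.

```bash
homingcues simulate --participants 23 --seed 1 --out trials.csv
homingcues report --trials trials.csv --out-dir results/
homingcues power --sd 2.78 --n 24
```

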