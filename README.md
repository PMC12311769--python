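# npbddm

Nonparametric-bound drift-diffusion modelling of choice and reaction-time
data.

## What this is for

In reaction-time perceptual decisions (for example, random-dot motion
discrimination), the observer trades speed against accuracy by choosing
*when* to stop accumulating evidence. The standard bounded drift-diffusion
model (DDM) describes the evidence as a Wiener process with drift
`kappa * coh` (coherence `coh` as a signed proportion, unit diffusion)
that terminates at the first crossing of symmetric bounds `+-B(t)`;
reaction time is the crossing time plus a Gaussian non-decision time
`N(mu_nd, sigma_nd^2)`. Most fitting pipelines assume a parametric shape
for `B(t)` (flat, exponential collapse, ...). This package instead infers
the bound *nonparametrically*: given `kappa` and `mu_nd`, the distribution
of decision times determines `B(t)` uniquely, so the bound can be read off
the data by alternating density **propagation** (a Fokker-Planck step per
coherence) with a **match** step that places the bound where the model's
absorbed probability equals the empirically observed termination
probability. The three scalar parameters `theta = (kappa, mu_nd,
sigma_nd)` are then estimated by maximum likelihood, each candidate theta
carrying its own recovered bound.

Around that estimator the package provides, for students of
speed-accuracy policy:

* forward simulators (continuous-time and discretely monitored semantics),
* a dynamic-programming solver for the reward-rate-optimal stopping
  policy, with coherence-posterior beliefs and shifted-Rayleigh deadline
  hazards, plus an earning-rate evaluator for arbitrary bounds,
* bound-scaling cross-fits (`B'(t) = s_m B(t/s_t)`) with an exact
  diagonal-rank permutation test,
* a synthetic three-phase experiment generator (baseline / provisional
  deadlines / washout) and the accompanying behavioral statistics.

## Worked example

Simulate choice/RT data from a known sinusoidally modulated bound, then
recover the bound and parameters:

```python
import numpy as np
from npbddm import (DDMParams, canonical_bound, simulate_dataset,
                    fit_npb_ddm)

truth = DDMParams(kappa=15.0, mu_nd=0.3, sigma_nd=0.01)
trials = simulate_dataset(truth, canonical_bound("sinusoidal"), 200, seed=7)
fit = fit_npb_ddm(trials, n_restarts=2, seed=1, maxfev=110)

print(f"kappa    = {fit.params.kappa:.2f}")
print(f"mu_nd    = {fit.params.mu_nd:.3f}")
print(f"sigma_nd = {fit.params.sigma_nd:.4f}")
ts = np.array([0.4, 0.8, 1.2])
print("B(t) recovered:", np.round(fit.bound(ts), 3))
print("B(t) true:     ", np.round(canonical_bound("sinusoidal")(ts), 3))
```

prints (2,400 trials, about a minute):

```
kappa    = 15.30
mu_nd    = 0.332
sigma_nd = 0.0011
B(t) recovered: [0.986 0.725 0.611]
B(t) true:      [0.999 0.758 0.61 ]
```

The signal-to-noise scale is recovered within 2% and the bound's
modulation is tracked across the decision-time range. Two biases are
expected and documented in `docs/methods.md`: `sigma_nd` is systematically
underestimated and `mu_nd` slightly overestimated, both consequences of
the fixed-width kernel used to turn discrete decision times into a
density.

The reward-rate-optimal policy for a fitted observer:

```python
from npbddm import DDMParams, TaskEconomics, optimal_earning_rate
from npbddm.types import Grid

sol = optimal_earning_rate(DDMParams(16.19, 0.27, 0.001), TaskEconomics(),
                           None, Grid.coarse(t_max=6.0))
print(f"rho* = {sol.rho:.3f} points/s, B(0.5 s) = {float(sol.bound(0.5)):.2f} a.u.")
```

```
rho* = 0.202 points/s, B(0.5 s) = 0.93 a.u.
```

The optimal bound declines over time (mixed difficulties make prolonged
deliberation progressively less promising), and adding provisional
deadlines lowers it further.

A command-line interface mirrors the library:

```
npbddm synth --n-per-coh 200 --bound-shape sinusoidal --seed 7 --out trials.csv
npbddm fit --trials trials.csv --out fit.json --restarts 10 --seed 1
npbddm policy --kappa 16.19 --mu-nd 0.27 --out policy.json
npbddm stats --trials trials.csv --analysis sliding --out sliding.csv
```

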