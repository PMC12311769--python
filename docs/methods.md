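# Methods

## The model

Decisions about noisy evidence are modelled as a bounded drift-diffusion
process. The decision variable x(t) starts at 0 and accumulates momentary
evidence,

    dx = kappa * coh * dt + dW,

with unit diffusion, where `coh` is the signed stimulus coherence (a
proportion; positive = rightward) and `kappa` (1/(coherence s^(1/2)) under
the unit-diffusion convention) is the signal-to-noise scale. The trial
terminates at the first time x(t) leaves the open interval (-B(t), +B(t));
the sign of the crossed bound gives the choice, the crossing time the
decision time Td. The reaction time adds a Gaussian non-decision time,
RT = Td + Tnd, Tnd ~ N(mu_nd, sigma_nd^2), truncated at zero in simulation
(redraw; the likelihood uses the untruncated normal, as sigma_nd is tiny
relative to mu_nd over the fitted range).

The bound B(t) is symmetric about zero and is *not* given a parametric
form. It is the object of inference.

## Nonparametric bound recovery (propagate/match)

Given kappa and mu_nd, the distribution of decision times uniquely
determines B(t), and the map can be inverted:

1. Estimate per-trial decision times Td_i = RT_i - mu_nd and smooth them
   with an Epanechnikov kernel of standard deviation 0.1 s (half-support
   0.1*sqrt(5) ~ 0.224 s) into a density p_Td(t) on the solver's time grid.
   Kernel mass falling at t <= 0 is truncated and the density renormalised.
   (We also evaluated per-kernel cut-and-normalise and reflection boundary
   corrections; both worsened the location bias discussed below, so the
   simple truncation is kept.)
2. Maintain one decision-variable density per coherence (a delta at x = 0
   initially). For each step t -> t + dt: advance every density with a
   fully implicit (backward-Euler) finite-volume step of the Fokker-Planck
   equation du/dt = d/dx[-mu u + (1/2) du/dx]; then find, by root
   bracketing on the piecewise-linear absorbed-mass function, the single
   symmetric bound height at which the absorbed probability mass —
   aggregated over coherences with their empirical frequencies in the
   dataset — equals the empirical termination mass p_Td(t) dt; absorb
   (clip) and continue. If the required mass exceeds what is available at
   a bound of zero, the bound is clamped to zero and a warning recorded.
   Before the first positive empirical mass the bound is held at the
   domain ceiling (no absorption).

Mirror symmetry (the density at -coh is the reflection of the density at
+coh) lets the solver propagate only the six coherence magnitudes.

## Likelihood and fitting

For a candidate theta = (kappa, mu_nd, sigma_nd), the recovered bound's
per-coherence, per-side absorption fluxes define P(Td, choice | coh). The
RT/choice density is the convolution with N(mu_nd, sigma_nd^2), evaluated
per trial as a Gaussian-CDF difference that treats each flux bin as
uniform over its dt interval — this remains exact in the sigma_nd -> 0
limit, which matters because fitted sigma_nd values can be an order of
magnitude below dt. Per-trial densities are floored at 1e-10. The total
log-likelihood is maximised by Nelder-Mead in box-normalised coordinates
(kappa in [5, 40], mu_nd in [0.01, 0.6], sigma_nd in [0.001, 0.08]) with
uniformly drawn restarts (10 by default).

### Numerical semantics

The clip-after-propagate scheme is exactly the law of the diffusion
*monitored only at multiples of dt* (an effective-barrier offset of about
0.583 sqrt(dt) relative to continuous monitoring). The package therefore
carries both semantics explicitly:

* Monte-Carlo simulation uses within-step Brownian-bridge crossing
  probabilities by default (continuous-time first passages; exact for the
  linear segments of the stored bound); `bridge=False` gives the
  dt-monitored process.
* `first_passage` offers `implicit_clip` (the estimator's scheme),
  `gaussian_clip` (exact one-step transition + clip; identical in law to
  the plain Euler simulator), and `absorbing_fd` (Dirichlet conditions at
  the bound; converges to the continuous-time problem, hit probabilities
  and mean passage times agree with the flat-bound closed forms to ~1e-4
  at dt = 0.5 ms, dx = 0.02). Clip fluxes absorb at end-of-step instants;
  for moments of the Dirichlet scheme the midpoint convention applies.

### Grids

The reference lattice is dt = 0.5 ms, dx = 0.02 a.u., |x| <= 4. Fitting
and validation use dt = 2.5 ms, dx = 0.025, |x| <= 3 (`Grid.fitting()`),
for which one likelihood evaluation costs ~0.3 s and a two-restart fit one
to two minutes; refinement checks (dt 5 -> 2.5 -> 1.25 ms) move recovered
bounds by < 0.02 a.u. and the mu_nd likelihood peak by ~0.01 s. Test-suite
studies use the coarser dt = 5 ms lattice where only signs or coarse
magnitudes are asserted.

### Known estimator biases

Simulation studies at the validation conditions (kappa = 15, mu_nd = 0.3 s,
sigma_nd = 0.01 s, bounds near 1 a.u.) show three systematic effects, all
traceable to the fixed-width kernel smoothing:

* sigma_nd is underestimated (the kernel and the neglect of sigma_nd when
  estimating decision times both inflate the decision-time variance, which
  the fit offsets by shrinking non-decision variability).
* mu_nd is overestimated by roughly +0.02 to +0.035 s. With the exact
  (unsmoothed) decision-time density substituted for the KDE, the
  likelihood peaks at the true mu_nd; the bias comes from the smoothed
  model density's blurred left flank at the fastest coherence's narrow RT
  cluster, which the zero-truncation progressively sharpens as mu_nd
  grows.
* The recovered bound shows a dip-then-overshoot artifact of one to two
  tenths of an a.u. within ~0.2 s of the earliest decision times, because
  the kernel smears termination mass to times before any true decision
  occurs; mid-range deviations are 0.02-0.07 a.u. Bounds are therefore
  reported over the 1st-99th percentile window of decision times, and
  deviations quoted there should be read with the edge artifact in mind.

## Canonical validation bounds

`canonical_bound` provides the three profiles used in recovery studies, in
accumulated-evidence units chosen so that with kappa ~ 15 decision times
span the usual sub-second to few-second range: stationary B = 1.0;
exponential 0.35 + 0.65 exp(-t / 0.9 s); sinusoidal
0.8 + 0.2 sin(2 pi t / 1.5 s).

## Optimal stopping policy

The task is formalised as a goal MDP over states <x, t> with actions
left/right (terminate) and fix (accumulate for another dt). The decision-
maker does not know the coherence; transitions marginalise over the
posterior p(coh | x, t) ∝ N(x | kappa coh t, t) p(coh), which is
independent of the bound shape and of deadline hazards (the bound- and
deadline-dependent path factors cancel in the normalisation — verified
numerically against brute-force Monte-Carlo conditioning). Terminating
right earns the posterior probability of rightward motion (0% coherence
counts half) times R_c plus the complement times R_e, minus the
opportunity cost rho * (mu_ITI + mu_misc + mu_nd); fixation costs rho dt
and, in deadline phases, risks cancelation with the state-dependent hazard
mixing the shifted-Rayleigh hazard with the posterior probability that the
trial carries a deadline given survival. The earning rate rho* solves
V(s0; rho) = 0 by bisection (V is monotone in rho).

Defaults: horizon 6 s with forced termination at the end. Near x = 0 the
value function is kinked, so a sliver of the fix region one or two cells
wide survives to *any* horizon (in continuous time the optimal bound
reaches zero only asymptotically once a zero-coherence stimulus has prior
mass); forced termination there is harmless because almost no probability
mass survives that long — rho* moves by < 1e-6 when the horizon is
extended from 6 s to 9 s. A genuinely short horizon (a still-wide fix
region at the final step) raises `HorizonError` and the bisection driver
extends the horizon automatically.

The bound is extracted from the action lattice as the smallest terminating
|x| minus half a cell. `earning_rate_of_bounds` evaluates an arbitrary
bound policy by forward-propagating the *same* chain the Bellman recursion
uses (posterior-mixed, edge-renormalised kernels; the inverse frontier
rule |x| >= B + dx/2, with a bound below half a cell terminating
everything), so the extracted optimal bound reproduces rho* to the
bisection tolerance, and by the tower property the subjective evaluation
equals the objective per-coherence earning rate.

One structural caveat: with deadlines the optimal bound is lower than
without throughout the window where decisions actually happen, but at very
late times (beyond the 99th percentile of decision times) it can sit one
lattice cell *higher*, because the deadline hazard vanishes for survivors
(they almost surely carry no deadline) while the lower rho* reduces the
opportunity cost of waiting.

## Bound-scaling cross-fit

The transform B'(t) = s_m B(t / s_t) stretches a donor bound in magnitude
and time; (s_t, s_m) are fit by Nelder-Mead on log-scale coordinates in
[0.2, 5], with the bound given (not re-derived) and theta fixed to the
recipient's own fit. Donor bounds are held at their last value beyond
their support. Fit quality is the per-trial log-likelihood difference to
the recipient's own nonparametric fit; per-recipient donor ranks (ties
broken by donor index and flagged) feed an exact permutation test that
enumerates all 4^4 = 256 diagonal rank vectors under the i.i.d.-uniform
null.

## Synthetic experiments

`task_synth` emulates the three-phase design: a static agent (fixed theta
and per-phase bound) plays 13-minute sessions; phase 2 assigns provisional
deadlines T_DL = t0 + Rayleigh(sigma_dl) to half of the trials and cancels
a trial when the decision completes after the deadline (Td + mu_nd > T_DL;
an RT-based comparison is available via `cancel_on="rt"`). Deadline
parameters are calibrated to cancel a target fraction (10% in the study)
under the phase-1 RT distribution, by pinning t0 at the 20th RT percentile
and bisecting sigma_dl — the joint selection of (t0, sigma_dl) is otherwise
under-determined, so a fixed, reproducible search path was chosen. Session
trial counts derive from the session time budget and mean trial duration
rather than wall-clock simulation; this preserves every statistic the
analyses consume.

What the generator does not emulate: trial-to-trial bound adaptation
(learning), eye-movement aborts beyond an optional i.i.d. rate, stimulus
rendering, and any RT autocorrelation beyond what the static policy
induces. Passing recovery tests on these data therefore demonstrate the
estimator's internal consistency under the model's own assumptions, not
robustness to the richer structure of human data.

## Behavioral statistics

Plain OLS and logistic fits (statsmodels): session regression with the
study's session index convention (phase 1: -10..-1, phase 2: 0..19),
motion-strength indicators and a phase-2 step plus phase-by-session
interaction; per-participant and pooled logistic accuracy models with the
phase indicator scaled by |coh|; z-scored RT comparisons pooling phases
within signed-coherence cells; sliding-window (100-trial) time-dependent
accuracy; and peri-cancelation z-scored RT profiles over +-5 trial lags,
truncated at session boundaries, with unsigned motion-strength cells.

## Problem sizes used in the shipped studies

Recovery studies run 1,000 trials per unit of prior weight (12,000 trials)
per bound shape with two optimiser restarts, and ten replicates of the
200-trials-per-coherence protocol for the sigma_nd bias; oracle
comparisons use 1e5-1e6 Monte-Carlo paths; the miniature dynamic program
enumerated exhaustively has 5 evidence cells, 8 time steps and 4^8
threshold policies. These sizes are the package's choices for routine
verification; all entry points accept larger values.
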