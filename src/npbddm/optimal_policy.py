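"""Reward-rate-optimal stopping policies by average-reward dynamic programming.

The decision problem is cast as a goal Markov decision process over states
s = <x, t> (accumulated evidence, elapsed decision time).  Actions are
``fix`` (accumulate for another dt) or terminating with a left/right
choice.  Because the coherence of the current stimulus is unknown, the
transition kernel marginalises over coherences with the Bayesian posterior
p(coh | x, t); remarkably, that posterior is independent of the bound shape
and of any deadline hazard, so it can be computed from the unbounded
Gaussian likelihoods alone (an invariant verified numerically in the test
suite).

The earning rate rho (points per second) enters as an opportunity cost per
unit time; the optimal rho* is the root of V(s0; rho) = 0, located by
bisection.  Provisional deadlines (phase 2) add a state-dependent
cancelation hazard to the ``fix`` action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .types import BoundFunction, CoherencePrior, DDMParams, Grid

__all__ = [
    "TaskEconomics",
    "DeadlineSpec",
    "PolicySolution",
    "coherence_posterior",
    "transition_kernel",
    "cancel_hazard",
    "solve_bellman",
    "optimal_earning_rate",
    "earning_rate_of_bounds",
    "HorizonError",
]

ACT_FIX, ACT_LEFT, ACT_RIGHT = 0, 1, 2


class HorizonError(RuntimeError):
    """Fixation is still optimal at the final pre-terminal step."""


@dataclass(frozen=True)
class TaskEconomics:
    """Point rewards and mean latencies of the experimental task.

    Defaults are the study values: +1/-1/0 points for correct/error/
    canceled outcomes, 2.0 s inter-trial interval, 0.7 s of miscellaneous
    latencies (fixation acquisition, motion-onset delay, saccade
    validation) and 0.4 s of miscellaneous latencies on canceled trials
    (no saccade validation).
    """

    r_correct: float = 1.0
    r_error: float = -1.0
    r_cancel: float = 0.0
    mu_iti: float = 2.0
    mu_misc: float = 0.7
    mu_misc_cancel: float = 0.4

    def __post_init__(self) -> None:
        if min(self.mu_iti, self.mu_misc, self.mu_misc_cancel) < 0:
            raise ValueError("latencies must be non-negative")


@dataclass(frozen=True)
class DeadlineSpec:
    """Shifted-Rayleigh provisional-deadline distribution.

    The deadline is ``t0 + Rayleigh(sigma_dl)`` on the reaction-time clock;
    ``p_deadline`` is the fraction of trials carrying a deadline (0.5 in
    phase 2 of the study).
    """

    t0: float
    sigma_dl: float
    p_deadline: float = 0.5

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.sigma_dl <= 0:
            raise ValueError("t0 and sigma_dl must be positive")
        if not 0.0 <= self.p_deadline <= 1.0:
            raise ValueError("p_deadline must be a proportion")


@dataclass
class PolicySolution:
    """Value/action surfaces, earning rate, and the extracted optimal bound."""

    value: np.ndarray  # (n_t + 1, n_x), time index 0 = t = 0
    action: np.ndarray  # same shape, entries in {ACT_FIX, ACT_LEFT, ACT_RIGHT}
    rho: float
    bound: BoundFunction
    grid: Grid

    @property
    def value_at_start(self) -> float:
        return float(self.value[0, self.grid.n_x // 2])


def coherence_posterior(
    x, t, params: DDMParams, prior: CoherencePrior | None = None
) -> np.ndarray:
    """Posterior p(coh_i | x, t) over signed coherences.

    Proportional to ``N(x | kappa coh_i t, t) * prior_i``.  Valid inside
    termination bounds and under deadline hazards because the bound- and
    deadline-dependent factors are coherence-independent and cancel in the
    normalisation.  At t = 0 the prior is returned.
    """
    prior = prior or CoherencePrior.study_default()
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if t <= 0:
        out = np.tile(prior.probs, (x.size, 1))
    else:
        means = params.kappa * prior.levels * t
        logw = -0.5 * (x[:, None] - means[None, :]) ** 2 / t + np.log(prior.probs)[None, :]
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        out = w / w.sum(axis=1, keepdims=True)
    return out[0] if scalar else out


def _step_kernels(params: DDMParams, prior: CoherencePrior, grid: Grid) -> np.ndarray:
    """Cell-integrated one-step displacement kernels, one per coherence."""
    sd = math.sqrt(grid.dt)
    shifts = params.kappa * prior.levels * grid.dt
    m = int(np.ceil((5.0 * sd + np.abs(shifts).max()) / grid.dx)) + 1
    m = min(m, (grid.n_x - 1) // 2)  # kernel cannot exceed the lattice
    centers = np.arange(-m, m + 1) * grid.dx
    kers = norm.cdf((centers[None, :] + grid.dx / 2 - shifts[:, None]) / sd) - norm.cdf(
        (centers[None, :] - grid.dx / 2 - shifts[:, None]) / sd
    )
    return kers / kers.sum(axis=1, keepdims=True)


def transition_kernel(
    x: float, t: float, params: DDMParams, prior: CoherencePrior, grid: Grid
) -> np.ndarray:
    """Distribution over x' on the lattice after one dt of fixation at (x, t).

    Mixture over coherences of cell-integrated Gaussian increments,
    weighted by the coherence posterior; renormalised onto the lattice.
    """
    post = coherence_posterior(x, t, params, prior)
    kers = _step_kernels(params, prior, grid)
    m = (kers.shape[1] - 1) // 2
    j0 = int(round((x + grid.x_max) / grid.dx))
    out = np.zeros(grid.n_x)
    for i in range(prior.n_levels):
        lo = max(j0 - m, 0)
        hi = min(j0 + m + 1, grid.n_x)
        out[lo:hi] += post[i] * kers[i, (lo - j0 + m) : (hi - j0 + m)]
    return out / out.sum()


def cancel_hazard(
    t, dl: DeadlineSpec, mu_nd: float, dt: float, p_deadline: float | None = None
) -> np.ndarray:
    """Probability that the trial is canceled in (t, t + dt] while fixating.

    Works on the decision-time clock, so the deadline shift is reduced by
    the mean non-decision time.  The hazard mixes the Rayleigh hazard with
    the posterior probability that this trial carries a deadline given
    survival to t: ``p(d+|t) = S(t) q / (S(t) q + (1 - q))`` with the
    Rayleigh survival S and deadline fraction q.
    """
    t = np.asarray(t, dtype=float)
    q = dl.p_deadline if p_deadline is None else p_deadline
    shift = dl.t0 - mu_nd
    z = np.maximum(t - shift, 0.0)
    s = np.exp(-0.5 * (z / dl.sigma_dl) ** 2)
    p_dplus = s * q / (s * q + (1.0 - q))
    return p_dplus * dt * z / dl.sigma_dl**2


def _terminal_values(params: DDMParams, econ: TaskEconomics, prior: CoherencePrior,
                     grid: Grid, t: float, rho: float):
    """Q-values of the two terminal actions at every lattice x for time t."""
    post = coherence_posterior(grid.x_grid, t, params, prior)
    p0 = post[:, prior.levels == 0].sum(axis=1)
    p_right_correct = post[:, prior.levels > 0].sum(axis=1) + 0.5 * p0
    cost = rho * (econ.mu_iti + econ.mu_misc + params.mu_nd)
    q_right = (
        p_right_correct * econ.r_correct + (1.0 - p_right_correct) * econ.r_error - cost
    )
    q_left = (
        (1.0 - p_right_correct) * econ.r_correct + p_right_correct * econ.r_error - cost
    )
    return q_left, q_right


def solve_bellman(
    params: DDMParams,
    econ: TaskEconomics,
    dl: DeadlineSpec | None,
    rho: float,
    grid: Grid,
    prior: CoherencePrior | None = None,
) -> PolicySolution:
    """Backward induction of the average-reward Bellman equation for fixed rho.

    At the terminal horizon fixation is disallowed.  The ``fix`` value is
    ``E[V(s') | s] - rho dt``; with deadlines it becomes the mixture of the
    continuation term (probability ``1 - p_cancel(s)``) and the cancelation
    outcome ``R_cancel - rho (mu_ITI + mu_misc_cancel + mu_nd)``.

    Raises :class:`HorizonError` when fixating is still optimal somewhere at
    the final pre-terminal step (the horizon is too short to be harmless).
    """
    prior = prior or CoherencePrior.study_default()
    n_x, n_t = grid.n_x, grid.n_t
    kers = _step_kernels(params, prior, grid)
    t_nodes = np.arange(n_t + 1) * grid.dt

    value = np.empty((n_t + 1, n_x))
    action = np.empty((n_t + 1, n_x), dtype=np.int8)

    if dl is not None:
        p_cancel = cancel_hazard(t_nodes, dl, params.mu_nd, grid.dt)
        cancel_val = econ.r_cancel - rho * (econ.mu_iti + econ.mu_misc_cancel + params.mu_nd)

    # terminal slice: must choose left or right
    q_left, q_right = _terminal_values(params, econ, prior, grid, t_nodes[-1], rho)
    value[-1] = np.maximum(q_left, q_right)
    action[-1] = np.where(q_right >= q_left, ACT_RIGHT, ACT_LEFT)

    ones = np.ones(n_x)
    edge_mass = [np.convolve(ones, kers[i][::-1], mode="same") for i in range(prior.n_levels)]
    for k in range(n_t - 1, -1, -1):
        t = t_nodes[k]
        post = coherence_posterior(grid.x_grid, t, params, prior)
        ev = np.zeros(n_x)
        for i in range(prior.n_levels):
            conv = np.convolve(value[k + 1], kers[i][::-1], mode="same")
            ev += post[:, i] * (conv / edge_mass[i])
        q_fix = ev - rho * grid.dt
        if dl is not None:
            q_fix = (1.0 - p_cancel[k]) * q_fix + p_cancel[k] * cancel_val
        q_left, q_right = _terminal_values(params, econ, prior, grid, t, rho)
        v = np.maximum(q_fix, np.maximum(q_left, q_right))
        a = np.full(n_x, ACT_FIX, dtype=np.int8)
        term = np.maximum(q_left, q_right) >= q_fix
        a[term] = np.where(q_right[term] >= q_left[term], ACT_RIGHT, ACT_LEFT)
        value[k] = v
        action[k] = a

    bound = _extract_bound(action, grid)
    # Near x = 0 the value function is kinked, so a sliver of the fix
    # region (a cell or two wide) survives to any horizon; forced terminal
    # termination there is harmless.  Signal only a grossly short horizon,
    # i.e. a still-wide fix region at the last pre-terminal step.
    if bound.heights[-2] > max(3 * grid.dx, 0.1):
        raise HorizonError("fix region still wide at the last pre-terminal step")
    return PolicySolution(value=value, action=action, rho=rho, bound=bound, grid=grid)


def _extract_bound(action: np.ndarray, grid: Grid) -> BoundFunction:
    """Fix/terminate frontier: smallest terminating |x| minus half a cell."""
    centre = grid.n_x // 2
    heights = np.empty(action.shape[0])
    for k in range(action.shape[0]):
        upper = action[k, centre:]
        idx = np.nonzero(upper != ACT_FIX)[0]
        if idx.size == 0:
            heights[k] = grid.x_max
        else:
            heights[k] = max(idx[0] * grid.dx - grid.dx / 2.0, 0.0)
    times = np.arange(action.shape[0]) * grid.dt
    return BoundFunction(times, heights)


def optimal_earning_rate(
    params: DDMParams,
    econ: TaskEconomics,
    dl: DeadlineSpec | None = None,
    grid: Grid | None = None,
    prior: CoherencePrior | None = None,
    tol: float = 1e-6,
    max_horizon: float = 12.0,
) -> PolicySolution:
    """Optimal policy and earning rate rho* with V(s0; rho*) = 0, by bisection.

    V(s0; rho) decreases monotonically in rho, so rho* is bracketed by
    ``[r_error / tau, r_correct / tau]`` with tau the per-trial overhead
    ``mu_ITI + mu_misc + mu_nd``.  The horizon is extended automatically if
    fixation is still optimal at its end.
    """
    grid = grid or Grid.coarse(t_max=6.0)
    tau = econ.mu_iti + econ.mu_misc + params.mu_nd
    lo = econ.r_error / tau
    hi = econ.r_correct / tau

    def value_at(rho: float) -> PolicySolution | None:
        """None signals that fixation never stops paying: rho is below rho*."""
        g = grid
        while True:
            try:
                return solve_bellman(params, econ, dl, rho, g, prior)
            except HorizonError:
                if g.t_max >= max_horizon:
                    return None
                g = g.with_t_max(min(g.t_max * 1.5, max_horizon))

    sol = None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        cand = value_at(mid)
        if cand is None:
            lo = mid
            continue
        sol = cand
        v0 = sol.value_at_start
        if abs(v0) < tol:
            break
        if v0 > 0:
            lo = mid
        else:
            hi = mid
    if sol is None:
        raise HorizonError("no terminating policy found within the maximum horizon")
    return sol


def earning_rate_of_bounds(
    bound: BoundFunction,
    params: DDMParams,
    econ: TaskEconomics,
    dl: DeadlineSpec | None = None,
    prior: CoherencePrior | None = None,
    grid: Grid | None = None,
) -> float:
    """Expected points per second of a *given* bound policy.

    The bound policy is evaluated by forward propagation of the belief-MDP
    chain itself: the state distribution over x is advanced with the same
    posterior-mixed, edge-renormalised transition kernels as the Bellman
    recursion, states beyond the frontier (|x| >= B(t) + dx/2, the inverse
    of the bound-extraction rule) terminate with the posterior-expected
    reward, and the cancelation lottery precedes propagation.  By the tower
    property this equals the objective per-coherence evaluation, and it
    reproduces rho* exactly (up to bisection tolerance) when handed the
    extracted optimal bound.  Returns expected points per expected trial
    duration (points/s).
    """
    prior = prior or CoherencePrior.study_default()
    grid = grid or Grid.coarse(t_max=6.0)
    if bound.t_max + 1e-9 < grid.t_max:
        raise ValueError("bound must cover the evaluation horizon")
    kers = _step_kernels(params, prior, grid)
    n_x, n_t = grid.n_x, grid.n_t
    xg = grid.x_grid
    t_nodes = np.arange(n_t + 1) * grid.dt
    if dl is not None:
        p_cancel = cancel_hazard(t_nodes, dl, params.mu_nd, grid.dt)
    ones = np.ones(n_x)
    edge_mass = [np.convolve(ones, kers[i][::-1], mode="same") for i in range(prior.n_levels)]

    mass = np.zeros(n_x)
    mass[n_x // 2] = 1.0
    exp_points = 0.0
    exp_time = 0.0
    tau_done = econ.mu_iti + econ.mu_misc + params.mu_nd
    tau_cancel = econ.mu_iti + econ.mu_misc_cancel + params.mu_nd

    def settle(m: np.ndarray, sel: np.ndarray, t: float):
        """Terminate the selected states: choice toward sign(x)."""
        nonlocal exp_points, exp_time
        if not np.any(sel):
            return
        post = coherence_posterior(xg[sel], t, params, prior)
        p0 = post[:, prior.levels == 0].sum(axis=1)
        p_rc = post[:, prior.levels > 0].sum(axis=1) + 0.5 * p0
        p_correct = np.where(xg[sel] > 0, p_rc, np.where(xg[sel] < 0, 1.0 - p_rc, 0.5))
        pts = p_correct * econ.r_correct + (1.0 - p_correct) * econ.r_error
        exp_points += float(m[sel] @ pts)
        exp_time += float(m[sel].sum()) * (t + tau_done)

    def terminate_region(t: float) -> np.ndarray:
        """Inverse of the bound-extraction rule.  A bound below half a cell
        means even the centre node terminates (an extracted B of exactly 0)."""
        b = float(bound(t))
        if b < grid.dx / 2.0:
            return np.ones(n_x, dtype=bool)
        return np.abs(xg) >= b + grid.dx / 2.0 - 1e-12

    for k in range(n_t):
        t = t_nodes[k]
        outside = terminate_region(t)
        settle(mass, outside, t)
        mass[outside] = 0.0
        if mass.sum() < 1e-12:
            break
        if dl is not None and p_cancel[k] > 0:
            lost = mass.sum() * p_cancel[k]
            exp_points += lost * econ.r_cancel
            exp_time += lost * (t + tau_cancel)
            mass = mass * (1.0 - p_cancel[k])
        post = coherence_posterior(xg, t, params, prior)
        new = np.zeros(n_x)
        for i in range(prior.n_levels):
            new += np.convolve(mass * post[:, i] / edge_mass[i], kers[i], mode="same")
        mass = new
    # force termination of residual mass at the horizon
    settle(mass, np.ones(n_x, dtype=bool), t_nodes[-1])
    return exp_points / exp_time
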