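"""MDP solver: posterior oracles, hazard identities, enumeration oracle."""

import numpy as np
import pytest

from npbddm.optimal_policy import (
    ACT_FIX,
    DeadlineSpec,
    TaskEconomics,
    _step_kernels,
    cancel_hazard,
    coherence_posterior,
    earning_rate_of_bounds,
    optimal_earning_rate,
    solve_bellman,
    transition_kernel,
)
from npbddm.types import BoundFunction, CoherencePrior, DDMParams, Grid


class TestCoherencePosterior:
    def test_prior_at_time_zero(self, study_prior, truth_params):
        post = coherence_posterior(0.7, 0.0, truth_params, study_prior)
        np.testing.assert_allclose(post, study_prior.probs)

    def test_symmetric_at_zero_evidence(self, study_prior, truth_params):
        post = coherence_posterior(0.0, 0.8, truth_params, study_prior)
        np.testing.assert_allclose(post, post[::-1], atol=1e-14)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_normalised_on_a_lattice(self, study_prior, truth_params):
        xs = np.linspace(-2.5, 2.5, 101)
        post = coherence_posterior(xs, 0.5, truth_params, study_prior)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_monte_carlo_conditioning_inside_bounds(self, truth_params):
        """Bound-independence: conditioning surviving discrete paths on (x, t)
        reproduces the unbounded-likelihood posterior."""
        prior = CoherencePrior(
            np.array([-0.256, 0.0, 0.256]), np.array([1, 1, 1]) / 3.0
        )
        dt, t_star, b = 0.005, 0.3, 1.0
        n = 200_000
        rng = np.random.default_rng(17)
        coh_idx = rng.integers(0, 3, size=n)
        drift = truth_params.kappa * prior.levels[coh_idx]
        x = np.zeros(n)
        alive = np.ones(n, dtype=bool)
        for _ in range(int(round(t_star / dt))):
            x = x + drift * dt + rng.standard_normal(n) * np.sqrt(dt)
            alive &= np.abs(x) < b
        for x_star in (0.0, 0.4):
            sel = alive & (np.abs(x - x_star) < 0.05)
            freq = np.bincount(coh_idx[sel], minlength=3) / sel.sum()
            post = coherence_posterior(x_star, t_star, truth_params, prior)
            assert np.max(np.abs(freq - post)) < 0.03


class TestTransitionKernel:
    def test_rows_sum_to_one(self, study_prior, truth_params):
        g = Grid.coarse(t_max=1.0)
        for x in (-1.0, 0.0, 0.85):
            k = transition_kernel(x, 0.4, truth_params, study_prior, g)
            assert k.sum() == pytest.approx(1.0, abs=1e-9)
            assert (k >= 0).all()

    def test_symmetric_at_the_start_state(self, study_prior, truth_params):
        g = Grid.coarse(t_max=1.0)
        k = transition_kernel(0.0, 0.0, truth_params, study_prior, g)
        np.testing.assert_allclose(k, k[::-1], atol=1e-12)

    def test_mean_displacement_matches_posterior_drift(self, study_prior, truth_params):
        g = Grid(dt=0.005, dx=0.01, x_max=3.0, t_max=1.0)
        x, t = 1.2, 0.6
        k = transition_kernel(x, t, truth_params, study_prior, g)
        post = coherence_posterior(x, t, truth_params, study_prior)
        expected = truth_params.kappa * (post @ study_prior.levels) * g.dt
        assert (k @ g.x_grid) - x == pytest.approx(expected, abs=g.dx / 4)


class TestCancelHazard:
    DL = DeadlineSpec(t0=0.6, sigma_dl=0.7, p_deadline=0.5)

    def test_zero_before_the_shift(self):
        h = cancel_hazard(np.array([0.0, 0.1, 0.3299]), self.DL, 0.27, 0.005)
        np.testing.assert_array_equal(h, 0.0)

    def test_equal_prior_mixing_at_the_shift(self):
        """Just past t0 - mu_nd the deadline posterior is 1/2 (S = 1)."""
        eps = 1e-4
        shift = self.DL.t0 - 0.27
        h = cancel_hazard(shift + eps, self.DL, 0.27, 0.005)
        pure = 0.005 * eps / self.DL.sigma_dl**2  # hazard if all trials had deadlines
        assert float(h) == pytest.approx(0.5 * pure, rel=1e-3)

    def test_hazard_integrates_to_the_rayleigh_cdf(self):
        """On deadline-carrying trials, survival from the hazard chain matches
        the shifted-Rayleigh distribution function."""
        dl = DeadlineSpec(t0=0.6, sigma_dl=0.7, p_deadline=1.0)
        dt = 0.001
        t = np.arange(0, 4.0, dt)
        h = cancel_hazard(t, dl, 0.0, dt)
        surv = np.cumprod(1.0 - h)
        model_cdf = 1.0 - surv
        z = np.maximum(t + dt - dl.t0, 0.0)
        true_cdf = 1.0 - np.exp(-0.5 * (z / dl.sigma_dl) ** 2)
        assert np.max(np.abs(model_cdf - true_cdf)) < 1e-3


def _mini_setup():
    """A deliberately tiny MDP: one magnitude, 5 evidence cells, 8 steps."""
    prior = CoherencePrior(np.array([-0.256, 0.256]), np.array([0.5, 0.5]))
    params = DDMParams(15.0, 0.1, 0.01)
    grid = Grid(dt=0.05, dx=0.5, x_max=1.0, t_max=0.4)
    econ = TaskEconomics()
    return params, econ, prior, grid


def _all_threshold_policy_values(params, econ, prior, grid, rho):
    """Values of *every* node-threshold policy, evaluated on the DP's chain.

    A policy is a per-step termination threshold h_k in {0, 1, 2, 3}: stop
    when |x| >= h_k * dx (3 = beyond the lattice = never stop).  All 4^n_t
    policies are propagated simultaneously as a batch of state
    distributions, using the same posterior-mixed, edge-renormalised
    transition matrix as the Bellman recursion.
    """
    n_x, n_t = grid.n_x, grid.n_t
    xg = grid.x_grid
    kers = _step_kernels(params, prior, grid)
    edge = [np.convolve(np.ones(n_x), kers[i][::-1], mode="same") for i in range(prior.n_levels)]
    tau = econ.mu_iti + econ.mu_misc + params.mu_nd

    def term_reward(t):
        post = coherence_posterior(xg, t, params, prior)
        p_rc = post[:, prior.levels > 0].sum(axis=1)
        best = np.maximum(p_rc, 1.0 - p_rc)
        return best * econ.r_correct + (1.0 - best) * econ.r_error - rho * tau

    def transition_matrix(t):
        post = coherence_posterior(xg, t, params, prior)
        T = np.zeros((n_x, n_x))
        for j in range(n_x):
            e = np.zeros(n_x)
            e[j] = 1.0
            for i in range(prior.n_levels):
                T[j] += np.convolve(e * post[j, i] / edge[i][j], kers[i], mode="same")
        return T

    n_pol = 4**n_t
    codes = np.arange(n_pol)
    h = (codes[:, None] // 4 ** np.arange(n_t)[None, :]) % 4  # (P, n_t)
    stop_lut = np.stack(
        [np.abs(xg) >= v * grid.dx - 1e-12 if v < 3 else np.zeros(n_x, bool) for v in range(4)]
    )
    mass = np.zeros((n_pol, n_x))
    mass[:, n_x // 2] = 1.0
    value = np.zeros(n_pol)
    for k in range(n_t):
        t = k * grid.dt
        r = term_reward(t)
        S = stop_lut[h[:, k]]  # (P, n_x) termination masks
        value += (mass * S) @ r
        mass = mass * ~S
        value -= rho * grid.dt * mass.sum(axis=1)
        mass = mass @ transition_matrix(t)
    value += mass @ term_reward(n_t * grid.dt)
    return value


class TestBellman:
    def test_equal_rewards_make_waiting_pointless(self):
        """With Rc = Re every choice earns the same, so terminate at once."""
        params, _, prior, grid = _mini_setup()
        econ = TaskEconomics(r_correct=1.0, r_error=1.0)
        sol = solve_bellman(params, econ, None, rho=0.2, grid=grid, prior=prior)
        assert sol.action[0, grid.n_x // 2] != ACT_FIX

    def test_certain_states_terminate_toward_the_evidence(self, truth_params):
        econ = TaskEconomics()
        grid = Grid.coarse(t_max=3.0)
        sol = solve_bellman(truth_params, econ, None, rho=0.2, grid=grid)
        far = grid.x_grid >= 2.0
        k = int(0.5 / grid.dt)
        assert (sol.action[k, far] == 2).all()  # ACT_RIGHT
        assert (sol.action[k, grid.x_grid <= -2.0] == 1).all()  # ACT_LEFT

    def test_dp_value_equals_best_enumerated_threshold_policy(self):
        """Exhaustive enumeration over all 4^8 node-threshold sequences."""
        params, econ, prior, grid = _mini_setup()
        rho = 0.15
        sol = solve_bellman(params, econ, None, rho=rho, grid=grid, prior=prior)
        v_dp = sol.value_at_start
        values = _all_threshold_policy_values(params, econ, prior, grid, rho)
        assert v_dp == pytest.approx(values.max(), abs=1e-9)
        assert (values <= v_dp + 1e-9).all()


@pytest.fixture(scope="module")
def solution():
    params = DDMParams(16.19, 0.27, 0.001)
    grid = Grid.coarse(t_max=6.0)
    return params, TaskEconomics(), grid, optimal_earning_rate(
        params, TaskEconomics(), None, grid
    )


class TestEarningRate:

    def test_rho_bounded_by_instant_perfection(self, solution):
        params, econ, _, sol = solution
        assert sol.rho <= econ.r_correct / (econ.mu_iti + econ.mu_misc + params.mu_nd)

    def test_optimal_bound_declines_over_time(self, solution):
        """Mixed difficulties make later deliberation less promising."""
        _, _, _, sol = solution
        b = sol.bound
        ts = np.array([0.3, 1.0, 2.0, 3.5, 5.0])
        heights = b(ts)
        assert (np.diff(heights) <= 1e-9).all()
        assert heights[0] > heights[-1]

    def test_evaluator_reproduces_rho_star(self, solution):
        params, econ, grid, sol = solution
        r = earning_rate_of_bounds(sol.bound, params, econ, None, grid=grid)
        assert r == pytest.approx(sol.rho, abs=1e-3)

    def test_scaled_bounds_never_beat_the_optimum(self, solution):
        params, econ, grid, sol = solution
        for s in (0.5, 2.0):
            scaled = BoundFunction(
                sol.bound.times, np.clip(sol.bound.heights * s, 0, grid.x_max)
            )
            assert earning_rate_of_bounds(scaled, params, econ, None, grid=grid) <= sol.rho + 1e-6

    def test_zero_bound_earns_zero(self, solution):
        """Immediate random guessing: expected points are exactly zero."""
        params, econ, grid, _ = solution
        zero = BoundFunction.flat(1e-9, grid.t_max, dt=grid.dt)
        assert earning_rate_of_bounds(zero, params, econ, None, grid=grid) == pytest.approx(
            0.0, abs=1e-12
        )
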