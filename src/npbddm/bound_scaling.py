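"""Cross-fitting of scaled bounds: is the bound shape an individual trait?

A donor bound B_j from phase 1 is stretched in time and magnitude,
``B'(t) = s_m * B_j(t / s_t)``, and the two scale factors are fit by
maximum likelihood to a recipient's phase 2 data with the recipient's own
DDM parameters held fixed.  Fit quality is the per-trial log-likelihood
difference to the recipient's own nonparametric phase 2 fit; ranking the
donors for each recipient yields a rank matrix whose diagonal is tested
against a uniform null by exact enumeration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize

from . import ddm_core
from .fokker_planck import first_passage
from .npb_estimator import NpbFit, _loglik_from_fluxes, _prepare
from .types import BoundFunction, CoherencePrior, DDMParams, Grid

__all__ = [
    "ScalingParams",
    "CrossFitMatrix",
    "scale_bounds",
    "fit_scaling",
    "likelihood_with_fixed_bound",
    "crossfit_matrix",
    "rank_permutation_test",
]

#: Search box for the two scale factors.
SCALE_RANGE = (0.2, 5.0)


@dataclass(frozen=True)
class ScalingParams:
    """Time (s_t) and magnitude (s_m) scale factors, both positive."""

    s_t: float
    s_m: float

    def __post_init__(self) -> None:
        if self.s_t <= 0 or self.s_m <= 0:
            raise ValueError("scale factors must be positive")


@dataclass
class CrossFitMatrix:
    """Per-trial log-likelihood differences and their per-row ranks.

    Row i = data recipient, column j = bound donor.  ``ranks[i, j]`` is the
    rank (1 = best) of donor j for recipient i; ties are broken by donor
    index and flagged.
    """

    participants: list
    delta_loglik_per_trial: np.ndarray
    ranks: np.ndarray
    scales: np.ndarray
    had_ties: bool = False

    @property
    def diagonal_ranks(self) -> np.ndarray:
        return np.diag(self.ranks)


def scale_bounds(base: BoundFunction, s: ScalingParams, grid: Grid | None = None) -> BoundFunction:
    """``B'(t) = s_m * base(t / s_t)`` resampled on the working time grid.

    Beyond the donor's support the last height is held constant (the
    donor's shape carries no information there).
    """
    dt = grid.dt if grid is not None else base.dt
    t_max = grid.t_max if grid is not None else base.t_max * s.s_t
    times = np.arange(0.0, t_max + dt / 2, dt)
    return BoundFunction(times, s.s_m * base(times / s.s_t))


def likelihood_with_fixed_bound(
    trials: pd.DataFrame,
    params: DDMParams,
    bound: BoundFunction,
    prior: CoherencePrior | None = None,
    grid: Grid | None = None,
) -> float:
    """Log-likelihood of (RT, choice) data under a *given* bound.

    Unlike the nonparametric fit, the bound is not re-derived from the
    data; first-passage fluxes are computed directly under ``bound``.
    """
    done, weights, idx = _prepare(trials, prior)
    base = grid or Grid.fitting()
    rts = done["rt"].to_numpy(dtype=float)
    t_need = max(float(rts.max()) - params.mu_nd + 0.1, 20 * base.dt)
    g = base.with_t_max(math.ceil(t_need / base.dt) * base.dt)
    if bound.t_max < g.t_max:
        ext_t = np.arange(0.0, g.t_max + g.dt / 2, g.dt)
        bound = BoundFunction(ext_t, bound(ext_t))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fluxes = first_passage(params, bound, weights, g, method="implicit_clip")
    return _loglik_from_fluxes(done, fluxes, params, idx)


def fit_scaling(
    trials_p2: pd.DataFrame,
    theta_p2: DDMParams,
    base_bound: BoundFunction,
    prior: CoherencePrior | None = None,
    grid: Grid | None = None,
    n_restarts: int = 2,
    seed: int | np.random.Generator = 0,
    maxfev: int = 60,
) -> tuple[ScalingParams, float]:
    """Maximum-likelihood fit of (s_t, s_m), theta held fixed.

    Nelder-Mead over log-scale coordinates within the ``SCALE_RANGE`` box;
    the first restart starts at the identity transform.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = np.log(SCALE_RANGE)

    def objective(z: np.ndarray) -> float:
        s = ScalingParams(float(np.exp(z[0])), float(np.exp(z[1])))
        return -likelihood_with_fixed_bound(
            trials_p2, theta_p2, scale_bounds(base_bound, s), prior, grid
        )

    best = None
    for r in range(max(n_restarts, 1)):
        z0 = np.zeros(2) if r == 0 else rng.uniform(math.log(0.5), math.log(2.0), 2)
        res = optimize.minimize(
            objective,
            z0,
            method="Nelder-Mead",
            bounds=[(lo, hi)] * 2,
            options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-3},
        )
        if best is None or res.fun < best.fun:
            best = res
    s = ScalingParams(float(np.exp(best.x[0])), float(np.exp(best.x[1])))
    return s, -float(best.fun)


def crossfit_matrix(
    fits_p1: dict[str, NpbFit],
    fits_p2: dict[str, NpbFit],
    data_p2: dict[str, pd.DataFrame],
    prior: CoherencePrior | None = None,
    grid: Grid | None = None,
    seed: int = 0,
) -> CrossFitMatrix:
    """All recipient x donor scaled-bound cross-fits, per-trial normalised.

    ``delta[i, j] = (logP_ij - logP(D_i | theta_i, B_i)) / N_i`` where
    logP_ij is the best scaled-bound likelihood of recipient i's phase 2
    data using donor j's phase 1 bound.
    """
    names = list(data_p2)
    if set(fits_p1) < set(names) or set(fits_p2) < set(names):
        raise ValueError("missing participant in fits")
    n = len(names)
    delta = np.zeros((n, n))
    scales = np.empty((n, n), dtype=object)
    for i, name_i in enumerate(names):
        theta_i = fits_p2[name_i].params
        trials_i = data_p2[name_i]
        done = ddm_core.completed(trials_i)
        ref = likelihood_with_fixed_bound(trials_i, theta_i, fits_p2[name_i].bound, prior, grid)
        for j, name_j in enumerate(names):
            s, ll = fit_scaling(
                trials_i, theta_i, fits_p1[name_j].bound, prior, grid, seed=seed + 97 * i + j
            )
            delta[i, j] = (ll - ref) / len(done)
            scales[i, j] = s
    # per-row ranks by descending delta; ties broken by donor index
    order = np.lexsort((np.arange(n)[None, :].repeat(n, 0), -delta), axis=1)
    ranks = np.empty((n, n), dtype=int)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]
    had_ties = bool(np.any([len(np.unique(row)) < n for row in delta]))
    return CrossFitMatrix(names, delta, ranks, scales, had_ties)


def rank_permutation_test(diagonal_ranks) -> float:
    """Exact test of the diagonal ranks against an i.i.d. uniform null.

    Under H0 each diagonal rank is independently uniform on {1, ..., 4};
    all 4^4 = 256 rank vectors are enumerated and the p-value is the
    fraction whose sum does not exceed the observed sum.
    """
    ranks = np.asarray(diagonal_ranks, dtype=int)
    if ranks.size != 4 or np.any(ranks < 1) or np.any(ranks > 4):
        raise ValueError("expected four ranks, each in {1, 2, 3, 4}")
    observed = int(ranks.sum())
    count = sum(1 for combo in product(range(1, 5), repeat=4) if sum(combo) <= observed)
    return count / 256.0
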