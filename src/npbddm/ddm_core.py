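"""Monte-Carlo forward simulation of the bounded drift-diffusion decision process.

A trial is a Wiener process with drift ``kappa * coh`` and unit diffusion,
started at x = 0, terminated at the first crossing of the symmetric,
possibly time-varying bounds ``+/-B(t)``.  The first passage sets the choice
(upper bound = rightward) and the decision time Td; the reaction time adds a
Gaussian non-decision time truncated at zero.

Two termination semantics are supported:

* ``bridge=True`` (default): within-step Brownian-bridge crossing
  probabilities are applied, so simulated first passages converge to the
  continuous-time process.
* ``bridge=False``: the walk is only monitored at multiples of ``dt``
  (plain Euler-Maruyama), which is exactly the discrete-time process the
  density-propagation-with-clipping solver and the dynamic-programming
  lattice describe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import BoundFunction, CoherencePrior, DDMParams

__all__ = [
    "TrialRecord",
    "TRIAL_COLUMNS",
    "simulate_trial",
    "simulate_dataset",
    "flat_bound_oracle",
    "canonical_bound",
]

#: Column order of the on-disk trial table.
TRIAL_COLUMNS = [
    "participant",
    "phase",
    "session",
    "trial_index",
    "signed_coh",
    "choice",
    "correct",
    "rt",
    "has_deadline",
    "canceled",
]


@dataclass
class TrialRecord:
    """One behavioral trial.

    ``choice``/``rt`` are None/NaN when the trial was canceled or the walk
    never reached a bound within the simulated horizon (``terminated`` is
    False in the latter case; the caller decides the truncation policy).
    """

    signed_coh: float
    choice: str | None
    correct: bool | None
    rt: float
    phase: int = 1
    session: int = 1
    trial_index: int = 0
    has_deadline: bool = False
    canceled: bool = False
    terminated: bool = True


def flat_bound_oracle(drift: float, bound_height: float) -> tuple[float, float]:
    """Closed-form hit probability and mean decision time for a flat bound.

    For unit diffusion, symmetric bounds at ``+/-B`` and a start at zero,

    ``P(upper) = 1 / (1 + exp(-2 mu B))`` and
    ``E[Td] = (B / mu) * tanh(mu B)``; the zero-drift limits are 0.5 and B^2.
    """
    if not bound_height > 0:
        raise ValueError("bound_height must be positive")
    mu = float(drift)
    b = float(bound_height)
    if mu == 0.0:
        return 0.5, b * b
    p_upper = 1.0 / (1.0 + math.exp(-2.0 * mu * b))
    mean_td = (b / mu) * math.tanh(mu * b)
    return p_upper, mean_td


def canonical_bound(shape: str, t_max: float = 6.0, dt: float = 0.0005) -> BoundFunction:
    """Reference bound profiles used throughout validation studies.

    ``stationary``: B = 1.0; ``exponential``: 0.35 + 0.65 exp(-t/0.9);
    ``sinusoidal``: 0.8 + 0.2 sin(2 pi t / 1.5).  Magnitudes are in
    accumulated-evidence units and chosen so that, with kappa around 15,
    decision times span the sub-second to few-second range typical of
    reaction-time motion discrimination.
    """
    shapes = {
        "stationary": lambda t: np.full_like(t, 1.0),
        "exponential": lambda t: 0.35 + 0.65 * np.exp(-t / 0.9),
        "sinusoidal": lambda t: 0.8 + 0.2 * np.sin(2 * np.pi * t / 1.5),
    }
    if shape not in shapes:
        raise ValueError(f"unknown bound shape {shape!r}; pick one of {sorted(shapes)}")
    return BoundFunction.from_callable(shapes[shape], t_max=t_max, dt=dt)


def _simulate_paths(
    drift: float,
    bound: BoundFunction,
    n: int,
    rng: np.random.Generator,
    dt: float,
    bridge: bool,
):
    """Vectorised first-passage simulation for ``n`` paths at one drift.

    Returns (decision_time, hit_upper, terminated) arrays.  Decision times
    are end-of-step times; non-terminated paths carry NaN.
    """
    n_steps = int(round(bound.t_max / dt))
    t_end = (np.arange(n_steps) + 1) * dt
    b_hi = bound(t_end)  # bound at end of each step
    b_lo = bound(t_end - dt)  # bound at start of each step

    x = np.zeros(n)
    alive = np.arange(n)
    td = np.full(n, np.nan)
    hit_upper = np.zeros(n, dtype=bool)
    sqrt_dt = math.sqrt(dt)

    for k in range(n_steps):
        if alive.size == 0:
            break
        x_old = x
        x_new = x_old + drift * dt + rng.standard_normal(alive.size) * sqrt_dt
        up = x_new >= b_hi[k]
        dn = x_new <= -b_hi[k]
        absorbed = up | dn
        if bridge:
            inside = ~absorbed
            if np.any(inside):
                xo, xn = x_old[inside], x_new[inside]
                # Brownian-bridge crossing of the linear barrier segment
                # between (t, B(t)) and (t+dt, B(t+dt)); exact for linear B.
                gap_u = (b_lo[k] - xo) * (b_hi[k] - xn)
                gap_l = (b_lo[k] + xo) * (b_hi[k] + xn)
                p_up = np.exp(-2.0 * np.maximum(gap_u, 0.0) / dt)
                p_dn = np.exp(-2.0 * np.maximum(gap_l, 0.0) / dt)
                u = rng.random(xo.size)
                cross_u = u < p_up
                cross_d = (~cross_u) & (u < p_up + p_dn)
                sub_up = np.zeros_like(inside)
                sub_dn = np.zeros_like(inside)
                sub_up[inside] = cross_u
                sub_dn[inside] = cross_d
                up = up | sub_up
                dn = dn | sub_dn
                absorbed = up | dn
        if np.any(absorbed):
            idx = alive[absorbed]
            td[idx] = t_end[k]
            hit_upper[idx] = up[absorbed]
            keep = ~absorbed
            x = x_new[keep]
            alive = alive[keep]
        else:
            x = x_new
    terminated = ~np.isnan(td)
    return td, hit_upper, terminated


def _draw_nondecision(n: int, params: DDMParams, rng: np.random.Generator) -> np.ndarray:
    """Normal(mu_nd, sigma_nd^2) truncated at zero by redraw."""
    if params.sigma_nd == 0:
        return np.full(n, params.mu_nd)
    out = rng.normal(params.mu_nd, params.sigma_nd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(params.mu_nd, params.sigma_nd, size=int(bad.sum()))
        bad = out <= 0
    return out


def simulate_trial(
    params: DDMParams,
    bound: BoundFunction,
    signed_coh: float,
    seed: int | np.random.Generator,
    dt: float = 0.0005,
    bridge: bool = True,
) -> TrialRecord:
    """Simulate a single trial; see module docstring for the model."""
    if abs(signed_coh) > 1:
        raise ValueError("signed coherence must be a proportion in [-1, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    td, hit_upper, terminated = _simulate_paths(
        params.drift(signed_coh), bound, 1, rng, dt, bridge
    )
    if not terminated[0]:
        return TrialRecord(signed_coh, None, None, float("nan"), terminated=False)
    choice = "right" if hit_upper[0] else "left"
    if signed_coh == 0:
        correct = bool(rng.random() < 0.5)
    else:
        correct = (signed_coh > 0) == hit_upper[0]
    rt = float(td[0] + _draw_nondecision(1, params, rng)[0])
    return TrialRecord(signed_coh, choice, correct, rt)


def simulate_dataset(
    params: DDMParams,
    bound: BoundFunction,
    n_per_coh: int,
    prior: CoherencePrior | None = None,
    seed: int | np.random.Generator = 0,
    dt: float = 0.0005,
    bridge: bool = True,
    phase: int = 1,
    session: int = 1,
    participant: str = "sim",
) -> pd.DataFrame:
    """Simulate a balanced dataset: ``n_per_coh`` trials per unit of prior weight.

    With the study's default prior the merged 0% level receives twice
    ``n_per_coh`` (it stands for the +0 and -0 stimuli).  Trials are
    returned in randomised order with sequential trial indices.
    """
    if n_per_coh < 1:
        raise ValueError("n_per_coh must be >= 1")
    prior = prior or CoherencePrior.study_default()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    base_w = prior.probs.min()
    counts = np.rint(prior.probs / base_w * n_per_coh).astype(int)

    rows = []
    for coh, n in zip(prior.levels, counts):
        td, hit_upper, terminated = _simulate_paths(
            params.drift(coh), bound, int(n), rng, dt, bridge
        )
        tnd = _draw_nondecision(int(n), params, rng)
        rt = td + tnd
        choice = np.where(hit_upper, "right", "left").astype(object)
        if coh == 0:
            correct = rng.random(int(n)) < 0.5
        else:
            correct = (coh > 0) == hit_upper
        choice[~terminated] = None
        rt[~terminated] = np.nan
        rows.append(
            pd.DataFrame(
                {
                    "signed_coh": coh,
                    "choice": choice,
                    "correct": np.where(terminated, correct, None),
                    "rt": rt,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table.insert(0, "participant", participant)
    table.insert(1, "phase", phase)
    table.insert(2, "session", session)
    table.insert(3, "trial_index", np.arange(len(table)))
    table["has_deadline"] = False
    table["canceled"] = False
    return table[TRIAL_COLUMNS]


def completed(trials: pd.DataFrame) -> pd.DataFrame:
    """Completed (terminated, non-canceled) trials of a table."""
    ok = trials["rt"].notna() & ~trials["canceled"].astype(bool)
    return trials[ok]
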