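"""Synthetic-experiment generator: deadlines, schedules, scoring.

Generates trial tables emulating the three-phase reaction-time motion
discrimination study: phase 1 (baseline, 10 sessions), phase 2 (20
sessions, half of trials carry provisional deadlines drawn from a
shifted-Rayleigh distribution, calibrated to cancel roughly 10% of
trials), phase 3 (washout, 10 sessions).  The simulated agent is static
within a phase: it applies the phase's bound without trial-to-trial
adaptation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ddm_core
from .optimal_policy import DeadlineSpec
from .types import BoundFunction, CoherencePrior, DDMParams

__all__ = [
    "ExperimentSchedule",
    "PhaseSpec",
    "STUDY_DEADLINES",
    "sample_deadline",
    "deadline_moments",
    "calibrate_deadline",
    "simulate_experiment",
    "earning_rate_trace",
]

#: Per-participant provisional-deadline parameters (t0 s, sigma_dl s).
STUDY_DEADLINES = {
    "A": DeadlineSpec(t0=0.6, sigma_dl=0.7),
    "B": DeadlineSpec(t0=0.3, sigma_dl=0.6),
    "C": DeadlineSpec(t0=0.6, sigma_dl=1.0),
    "D": DeadlineSpec(t0=0.6, sigma_dl=0.6),
}


@dataclass(frozen=True)
class PhaseSpec:
    """One experimental phase: session count and optional deadlines."""

    phase: int
    n_sessions: int
    deadline: DeadlineSpec | None = None
    session_minutes: float = 13.0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


@dataclass
class ExperimentSchedule:
    """Ordered phases plus the between-trial latencies used for timing."""

    phases: list[PhaseSpec] = field(
        default_factory=lambda: [
            PhaseSpec(1, 10),
            PhaseSpec(2, 20, STUDY_DEADLINES["A"]),
            PhaseSpec(3, 10),
        ]
    )
    iti: float = 2.0
    misc_latency: float = 0.7


def sample_deadline(dl: DeadlineSpec, seed: int | np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw provisional deadlines ``t0 + Rayleigh(sigma_dl)`` (seconds)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return dl.t0 + rng.rayleigh(dl.sigma_dl, size=size)


def deadline_moments(dl: DeadlineSpec) -> tuple[float, float]:
    """Mean and SD of the shifted-Rayleigh deadline distribution.

    ``mean = t0 + sigma sqrt(pi/2)``, ``sd = sigma sqrt((4 - pi)/2)``;
    the shift moves only the mean.
    """
    mean = dl.t0 + dl.sigma_dl * math.sqrt(math.pi / 2.0)
    sd = dl.sigma_dl * math.sqrt((4.0 - math.pi) / 2.0)
    return mean, sd


def calibrate_deadline(
    rt_sample: np.ndarray,
    target_cancel_frac: float = 0.10,
    p_deadline: float = 0.5,
    t0_quantile: float = 0.20,
) -> DeadlineSpec:
    """Deadline parameters canceling a target fraction of upcoming trials.

    Assuming the agent keeps its current policy, a trial with a deadline is
    canceled when the deadline beats its reaction time, so the overall
    cancelation fraction is ``p_deadline * P(T_DL < RT)`` under the
    supplied RT sample.  The search path is fixed for reproducibility:
    ``t0`` is pinned to a low quantile of the RT sample and ``sigma_dl`` is
    solved by bisection.
    """
    rts = np.asarray(rt_sample, dtype=float)
    rts = rts[~np.isnan(rts)]
    if rts.size == 0:
        raise ValueError("rt_sample is empty")
    if not 0.0 < target_cancel_frac < p_deadline:
        raise ValueError("need 0 < target_cancel_frac < p_deadline")
    t0 = float(np.quantile(rts, t0_quantile))

    def cancel_frac(sigma: float) -> float:
        # P(T_DL < rt) per trial = Rayleigh CDF at (rt - t0)
        z = np.maximum(rts - t0, 0.0)
        return p_deadline * float(np.mean(1.0 - np.exp(-0.5 * (z / sigma) ** 2)))

    lo, hi = 1e-3, 20.0
    if cancel_frac(lo) < target_cancel_frac:
        raise ValueError("target cancelation fraction unattainable with t0 at this quantile")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cancel_frac(mid) > target_cancel_frac:
            lo = mid
        else:
            hi = mid
    return DeadlineSpec(t0=t0, sigma_dl=0.5 * (lo + hi), p_deadline=p_deadline)


def _session_trial_count(
    params: DDMParams, bound: BoundFunction, prior: CoherencePrior,
    schedule: ExperimentSchedule, session_minutes: float, mean_rt: float
) -> int:
    """Trials per session from the time budget and the mean trial duration."""
    per_trial = mean_rt + schedule.iti + schedule.misc_latency
    return max(int(session_minutes * 60.0 / per_trial), 1)


def simulate_experiment(
    params: DDMParams,
    bounds_by_phase: dict[int, BoundFunction],
    schedule: ExperimentSchedule | None = None,
    seed: int | np.random.Generator = 0,
    participant: str = "sim",
    dt: float = 0.0005,
    cancel_on: str = "decision",
) -> pd.DataFrame:
    """Simulate the full multi-phase experiment for a static agent.

    Coherences are drawn i.i.d. from the study prior.  In deadline phases
    each trial carries a provisional deadline with probability
    ``p_deadline``; the trial is canceled (choice and RT withheld, zero
    points) when the decision completes after the deadline, i.e. when
    ``Td + mu_nd > T_DL``.  Session lengths are derived from the phase's
    session minutes and the mean trial duration.
    """
    schedule = schedule or ExperimentSchedule()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    prior = CoherencePrior.study_default()
    frames = []
    for spec in schedule.phases:
        bound = bounds_by_phase[spec.phase]
        # estimate mean RT for the session budget from a pilot batch
        pilot = ddm_core.simulate_dataset(
            params, bound, 20, prior, seed=rng, dt=dt, phase=spec.phase
        )
        mean_rt = float(np.nanmean(pilot["rt"]))
        n_trials = _session_trial_count(
            params, bound, prior, schedule, spec.session_minutes, mean_rt
        )
        for sess in range(1, spec.n_sessions + 1):
            coh_idx = rng.choice(prior.n_levels, size=n_trials, p=prior.probs)
            td = np.full(n_trials, np.nan)
            hit_upper = np.zeros(n_trials, dtype=bool)
            terminated = np.zeros(n_trials, dtype=bool)
            for ci in np.unique(coh_idx):
                sel = np.nonzero(coh_idx == ci)[0]
                t, h, ok = ddm_core._simulate_paths(
                    params.drift(prior.levels[ci]), bound, sel.size, rng, dt, bridge=True
                )
                td[sel], hit_upper[sel], terminated[sel] = t, h, ok
            tnd = ddm_core._draw_nondecision(n_trials, params, rng)
            rt = td + tnd
            coh = prior.levels[coh_idx]
            choice = np.where(hit_upper, "right", "left").astype(object)
            correct = np.where(coh == 0, rng.random(n_trials) < 0.5, (coh > 0) == hit_upper)
            if spec.deadline is not None:
                has_dl = rng.random(n_trials) < spec.deadline.p_deadline
                t_dl = sample_deadline(spec.deadline, rng, size=n_trials)
                # canceled when the decision completes after the deadline;
                # completion is Td + mu_nd by default, the realised RT with
                # cancel_on="rt"
                done_at = td + params.mu_nd if cancel_on == "decision" else rt
                canceled = has_dl & terminated & (done_at > t_dl)
            else:
                has_dl = np.zeros(n_trials, dtype=bool)
                canceled = np.zeros(n_trials, dtype=bool)
            dead = canceled | ~terminated
            choice[dead] = None
            rt = np.where(dead, np.nan, rt)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": participant,
                        "phase": spec.phase,
                        "session": sess,
                        "trial_index": np.arange(n_trials),
                        "signed_coh": coh,
                        "choice": choice,
                        "correct": np.where(dead, None, correct),
                        "rt": rt,
                        "has_deadline": has_dl,
                        "canceled": canceled,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[ddm_core.TRIAL_COLUMNS]


def earning_rate_trace(
    trials: pd.DataFrame,
    window_minutes: float = 2.0,
    iti: float = 2.0,
    misc_latency: float = 0.7,
) -> pd.DataFrame:
    """Windowed points-per-minute series, reconstructed from trial timing.

    Cumulative session time is rebuilt as RT (or 0 for canceled/aborted
    trials' missing RT) plus the inter-trial and miscellaneous latencies.
    Returns one row per window with columns ``t_minutes`` and
    ``points_per_minute``.
    """
    points = np.where(
        trials["canceled"].astype(bool) | trials["rt"].isna(),
        0.0,
        np.where(trials["correct"].astype(bool), 1.0, -1.0),
    )
    dur = trials["rt"].fillna(0.0).to_numpy(dtype=float) + iti + misc_latency
    t_end = np.cumsum(dur) / 60.0
    out = []
    w = window_minutes
    n_win = int(math.ceil(t_end[-1] / w)) if len(trials) else 0
    for k in range(n_win):
        sel = (t_end > k * w) & (t_end <= (k + 1) * w)
        out.append(((k + 0.5) * w, points[sel].sum() / w))
    return pd.DataFrame(out, columns=["t_minutes", "points_per_minute"])
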