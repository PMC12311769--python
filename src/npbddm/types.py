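"""Shared domain types for bounded drift-diffusion modelling.

The conventions used throughout the package:

* Evidence (the decision variable) is in arbitrary accumulation units
  (a.u.) with unit diffusion coefficient, so the drift for a stimulus of
  signed coherence ``coh`` is ``kappa * coh`` per second.
* Coherence is a signed proportion in [-1, 1] (0.512, not 51.2%).
* All times are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DDMParams",
    "BoundFunction",
    "CoherencePrior",
    "Grid",
    "STUDY_COHERENCE_MAGNITUDES",
    "FIT_RANGES",
]

#: Unsigned motion strengths used in the random-dot task, as proportions.
STUDY_COHERENCE_MAGNITUDES = (0.0, 0.032, 0.064, 0.128, 0.256, 0.512)

#: Box constraints for maximum-likelihood search over (kappa, mu_nd, sigma_nd).
FIT_RANGES = {
    "kappa": (5.0, 40.0),
    "mu_nd": (0.01, 0.6),
    "sigma_nd": (0.001, 0.08),
}


@dataclass(frozen=True)
class DDMParams:
    """Free parameters of the bounded drift-diffusion model.

    Parameters
    ----------
    kappa
        Signal-to-noise scale; the drift rate for coherence ``coh`` is
        ``kappa * coh`` (1/s for unit-variance diffusion).
    mu_nd
        Mean non-decision time in seconds (sensory + motor latencies).
    sigma_nd
        Standard deviation of the non-decision time in seconds.
    """

    kappa: float
    mu_nd: float
    sigma_nd: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.mu_nd < 0:
            raise ValueError(f"mu_nd must be non-negative, got {self.mu_nd}")
        if self.sigma_nd < 0:
            raise ValueError(f"sigma_nd must be non-negative, got {self.sigma_nd}")

    def drift(self, signed_coh: float) -> float:
        """Drift rate ``kappa * coh`` for a signed coherence."""
        return self.kappa * signed_coh

    def as_array(self) -> np.ndarray:
        return np.array([self.kappa, self.mu_nd, self.sigma_nd])


@dataclass
class BoundFunction:
    """Symmetric decision-termination bound B(t) on a uniform time grid.

    Only the magnitude is stored; the process terminates when the decision
    variable leaves the open interval (-B(t), +B(t)).  Beyond the last grid
    time the bound is held at its final value.
    """

    times: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.heights.shape:
            raise ValueError("times and heights must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a bound needs at least two grid points")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
        if np.any(self.heights < 0):
            raise ValueError("bound heights must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def __call__(self, t) -> np.ndarray:
        """Interpolated bound magnitude; held constant beyond the support."""
        return np.interp(t, self.times, self.heights)

    @classmethod
    def from_callable(cls, fn, t_max: float, dt: float) -> "BoundFunction":
        times = np.arange(0.0, t_max + dt / 2, dt)
        return cls(times, np.asarray(fn(times), dtype=float) * np.ones_like(times))

    @classmethod
    def flat(cls, height: float, t_max: float, dt: float = 0.0005) -> "BoundFunction":
        return cls.from_callable(lambda t: np.full_like(t, float(height)), t_max, dt)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "B": self.heights})


@dataclass
class CoherencePrior:
    """Prior over signed coherence levels.

    The study's stimulus set lists a +0% and a -0% condition; these are
    indistinguishable and are represented here as a single level 0 with
    doubled prior weight.
    """

    levels: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.levels.shape != self.probs.shape or self.levels.ndim != 1:
            raise ValueError("levels and probs must be matching 1-D arrays")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError("probabilities must sum to 1")
        if not np.allclose(np.sort(self.levels), np.sort(-self.levels)):
            raise ValueError("coherence levels must be symmetric about 0")

    @classmethod
    def study_default(cls) -> "CoherencePrior":
        """Uniform prior over the task's 12 signed stimuli (0 merged, weight 2/12)."""
        mags = np.asarray(STUDY_COHERENCE_MAGNITUDES)
        levels = np.concatenate([-mags[:0:-1], mags])  # -0.512 ... 0 ... 0.512
        probs = np.ones_like(levels)
        probs[levels == 0.0] = 2.0
        return cls(levels, probs / probs.sum())

    @property
    def n_levels(self) -> int:
        return int(self.levels.size)

    def reweighted(self, counts) -> "CoherencePrior":
        """Empirical re-weighting of the same levels by observed counts."""
        counts = np.asarray(counts, dtype=float)
        return CoherencePrior(self.levels, counts / counts.sum())


@dataclass(frozen=True)
class Grid:
    """Discretisation of the (evidence, time) space.

    Defaults are the reference lattice (dt = 0.5 ms, dx = 0.02 a.u.).
    ``coarse()`` provides the resolution used for desk-scale fitting and
    tests; a refinement check guards its adequacy.
    """

    dt: float = 0.0005
    dx: float = 0.02
    x_max: float = 4.0
    t_max: float = 5.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dt and dx must be positive")
        if self.x_max <= 0 or self.t_max <= 0:
            raise ValueError("x_max and t_max must be positive")

    @classmethod
    def coarse(cls, t_max: float = 5.0, x_max: float = 3.0) -> "Grid":
        return cls(dt=0.005, dx=0.05, x_max=x_max, t_max=t_max)

    @classmethod
    def fitting(cls, t_max: float = 5.0, x_max: float = 3.0) -> "Grid":
        """Default resolution for likelihood fitting (dt 2.5 ms, dx 0.025)."""
        return cls(dt=0.0025, dx=0.025, x_max=x_max, t_max=t_max)

    @property
    def x_grid(self) -> np.ndarray:
        n = int(round(self.x_max / self.dx))
        return np.arange(-n, n + 1) * self.dx

    @property
    def n_x(self) -> int:
        return int(round(self.x_max / self.dx)) * 2 + 1

    @property
    def t_grid(self) -> np.ndarray:
        """Decision-time grid (end-of-step times dt, 2dt, ..., t_max)."""
        n = int(round(self.t_max / self.dt))
        return np.arange(1, n + 1) * self.dt

    @property
    def n_t(self) -> int:
        return int(round(self.t_max / self.dt))

    def with_t_max(self, t_max: float) -> "Grid":
        return Grid(dt=self.dt, dx=self.dx, x_max=self.x_max, t_max=t_max)
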