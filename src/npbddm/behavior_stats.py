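"""Descriptive and inferential analyses of trial tables.

Implements the study's behavioral statistics: z-scored RT comparisons
between phases, the session-wise RT regression (step change vs gradual
drift), logistic accuracy models with a phase indicator, sliding-window
time-dependent accuracy, and peri-cancelation RT profiles.  All models are
plain OLS/logistic fits via statsmodels; nothing here is stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import ddm_core

__all__ = [
    "RegressionResult",
    "zscore_rt_by_coherence",
    "rt_phase_ttest",
    "rt_session_regression",
    "accuracy_logistic",
    "sliding_accuracy",
    "peri_cancel_rt",
]


@dataclass
class RegressionResult:
    """Named coefficients with standard errors and p-values."""

    names: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    n: int

    def __getitem__(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])


def _standard_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Completed trials without provisional deadlines."""
    done = ddm_core.completed(trials)
    return done[~done["has_deadline"].astype(bool)]


def zscore_rt_by_coherence(
    trials: pd.DataFrame, phases: tuple[int, int] = (1, 2), signed: bool = True
) -> pd.DataFrame:
    """Pool the two phases and z-score RT within each coherence cell.

    Returns the pooled standard trials with an added ``z_rt`` column.  With
    ``signed=False`` cells are unsigned motion strengths.
    """
    pooled = _standard_trials(trials)
    pooled = pooled[pooled["phase"].isin(phases)].copy()
    key = pooled["signed_coh"] if signed else pooled["signed_coh"].abs()
    def _z(x):
        sd = x.std(ddof=0)
        if sd == 0 or len(x) < 2:
            raise ValueError("zero-variance or singleton coherence cell")
        return (x - x.mean()) / sd
    pooled["z_rt"] = pooled.groupby(key)["rt"].transform(_z)
    return pooled


def rt_phase_ttest(trials: pd.DataFrame, phases: tuple[int, int] = (1, 2)):
    """Welch t-test on pooled z-scored RTs between two phases."""
    from scipy import stats

    pooled = zscore_rt_by_coherence(trials, phases)
    a = pooled.loc[pooled["phase"] == phases[0], "z_rt"]
    b = pooled.loc[pooled["phase"] == phases[1], "z_rt"]
    return stats.ttest_ind(a, b, equal_var=False)


def rt_session_regression(trials: pd.DataFrame) -> RegressionResult:
    """OLS test of a phase-2 step change in RT against a session drift.

    ``RT = sum_c beta_c I_c + beta_session k + beta_phase I_P2 +
    beta_phase_x_session k I_P2`` with the study's session index convention
    (phase 1 sessions -10..-1, phase 2 sessions 0..19) and one indicator
    per unsigned motion strength (no intercept).
    """
    data = _standard_trials(trials)
    data = data[data["phase"].isin([1, 2])]
    mags = np.sort(data["signed_coh"].abs().unique())
    n_sess_p1 = data.loc[data["phase"] == 1, "session"].nunique()
    k_session = np.where(
        data["phase"] == 1,
        data["session"] - n_sess_p1 - 1,  # ..., -2, -1
        data["session"] - 1,  # 0, 1, ...
    )
    i_phase = (data["phase"] == 2).astype(float).to_numpy()
    cols = {f"coh_{m:.3f}": (data["signed_coh"].abs() == m).astype(float).to_numpy() for m in mags}
    cols["session"] = k_session.astype(float)
    cols["phase"] = i_phase
    cols["phase_x_session"] = i_phase * k_session
    X = pd.DataFrame(cols)
    fit = sm.OLS(data["rt"].to_numpy(dtype=float), X).fit()
    return RegressionResult(
        list(X.columns), fit.params.to_numpy(), fit.bse.to_numpy(), fit.pvalues.to_numpy(), len(data)
    )


def accuracy_logistic(trials: pd.DataFrame, pooled: bool = False) -> RegressionResult:
    """Logistic accuracy model ``logit p_correct = b_coh |coh| + b_phase I_P2 |coh|``.

    With ``pooled=True`` the motion-strength slope is fit per participant
    (one ``I_s |coh|`` regressor each) while ``b_phase`` is shared.  The 0%
    coherence trials enter with their randomly designated correctness.
    Raises a warning-carrying flag on (quasi-)separation via statsmodels.
    """
    data = _standard_trials(trials)
    data = data[data["phase"].isin([1, 2])]
    acoh = data["signed_coh"].abs().to_numpy(dtype=float)
    i_phase = (data["phase"] == 2).astype(float).to_numpy()
    if pooled:
        cols = {}
        for s in sorted(data["participant"].unique()):
            ind = (data["participant"] == s).astype(float).to_numpy()
            cols[f"coh_{s}"] = ind * acoh
        cols["phase"] = i_phase * acoh
    else:
        cols = {"coh": acoh, "phase": i_phase * acoh}
    X = pd.DataFrame(cols)
    y = data["correct"].astype(bool).astype(float).to_numpy()
    fit = sm.Logit(y, X).fit(disp=0)
    return RegressionResult(
        list(X.columns), fit.params.to_numpy(), fit.bse.to_numpy(), fit.pvalues.to_numpy(), len(data)
    )


def sliding_accuracy(trials: pd.DataFrame, window: int = 100) -> pd.DataFrame:
    """Proportion correct vs RT in sliding windows, per motion strength.

    Trials are sorted by RT within each unsigned motion strength; the
    proportion correct over ``window`` consecutive trials is plotted at the
    window's centre RT.  Strengths with fewer trials than the window yield
    a single aggregate point.
    """
    data = ddm_core.completed(trials)
    out = []
    for mag, grp in data.groupby(data["signed_coh"].abs()):
        grp = grp.sort_values("rt")
        rt = grp["rt"].to_numpy(dtype=float)
        corr = grp["correct"].astype(bool).to_numpy(dtype=float)
        if len(grp) < window:
            out.append((mag, float(np.median(rt)), float(corr.mean()), len(grp)))
            continue
        c = np.convolve(corr, np.ones(window), mode="valid") / window
        centers = np.convolve(rt, np.ones(window), mode="valid") / window
        for t, p in zip(centers, c):
            out.append((mag, float(t), float(p), window))
    return pd.DataFrame(out, columns=["motion_strength", "rt", "p_correct", "n"])


def peri_cancel_rt(trials: pd.DataFrame, n_lags: int = 5) -> pd.DataFrame:
    """Mean z-scored RT around cancelation events (lags -n..-1, +1..+n).

    Uses all phase-2 trials (deadline trials included; this is the one
    analysis where they are).  RTs are z-scored within unsigned motion
    strength; each completed trial contributes once per nearby cancelation
    event, and windows are truncated at session boundaries.
    """
    p2 = trials[trials["phase"] == 2].copy()
    if not p2["canceled"].astype(bool).any():
        raise ValueError("no canceled trials in phase 2")
    done = p2["rt"].notna()
    key = p2["signed_coh"].abs()
    z = pd.Series(np.nan, index=p2.index)
    for mag, grp in p2[done].groupby(key[done]):
        sd = grp["rt"].std(ddof=0)
        z.loc[grp.index] = (grp["rt"] - grp["rt"].mean()) / (sd if sd > 0 else 1.0)
    p2["z_rt"] = z

    records = {lag: [] for lag in range(-n_lags, n_lags + 1) if lag != 0}
    for (_, sess), grp in p2.groupby(["participant", "session"]):
        grp = grp.sort_values("trial_index").reset_index(drop=True)
        cancel_pos = np.nonzero(grp["canceled"].to_numpy(dtype=bool))[0]
        zr = grp["z_rt"].to_numpy()
        for c in cancel_pos:
            for lag in records:
                j = c + lag
                if 0 <= j < len(grp) and np.isfinite(zr[j]):
                    records[lag].append(zr[j])
    rows = []
    for lag in sorted(records):
        vals = np.asarray(records[lag])
        if vals.size:
            rows.append((lag, vals.mean(), vals.std(ddof=1) / np.sqrt(vals.size), vals.size))
        else:
            rows.append((lag, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["lag", "mean_z_rt", "sem", "n"])
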