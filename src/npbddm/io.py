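"""Readers and writers for trial tables, fits, and bound curves.

Trial tables are CSV with the header ``participant,phase,session,
trial_index,signed_coh,choice,correct,rt,has_deadline,canceled``; missing
choice/RT (canceled or aborted trials) are empty fields.  Fits are JSON
with a CSV sidecar for the bound curve.  All times are stored in seconds;
coherence may be declared as percent or proportion at read time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ddm_core import TRIAL_COLUMNS
from .npb_estimator import NpbFit
from .types import BoundFunction, DDMParams

__all__ = ["read_trials", "write_trials", "write_fit", "read_fit", "TrialValidationError"]


class TrialValidationError(ValueError):
    """A trial table failed validation; the message lists offending lines."""


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_trials(path, coherence_units: str = "proportion") -> pd.DataFrame:
    """Load and validate a trial table.

    ``coherence_units='percent'`` divides signed coherences by 100 on the
    way in.  Malformed rows (negative or zero RT on completed trials,
    cancelation without a deadline) are reported with their line numbers.
    """
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {', '.join(missing)}")
    table = table[TRIAL_COLUMNS].copy()
    for col in ("has_deadline", "canceled"):
        table[col] = table[col].astype(bool)
    table["rt"] = pd.to_numeric(table["rt"], errors="coerce")
    if coherence_units == "percent":
        table["signed_coh"] = table["signed_coh"] / 100.0
    elif coherence_units != "proportion":
        raise ValueError("coherence_units must be 'percent' or 'proportion'")

    completed = table["choice"].notna() & ~table["canceled"]
    bad_rt = completed & ~(table["rt"] > 0)
    bad_cancel = table["canceled"] & ~table["has_deadline"]
    problems = []
    for idx in table.index[bad_rt]:
        problems.append(f"line {idx + 2}: non-positive rt on a completed trial")
    for idx in table.index[bad_cancel]:
        problems.append(f"line {idx + 2}: canceled trial without a deadline")
    if np.any(table["signed_coh"].abs() > 1):
        problems.append("coherences exceed 1; did you mean coherence_units='percent'?")
    if problems:
        raise TrialValidationError("; ".join(problems))
    return table


def write_fit(fit: NpbFit, path, seed: int | None = None, grid: dict | None = None) -> None:
    """JSON fit summary plus a ``<stem>_bound.csv`` sidecar with B(t)."""
    path = Path(path)
    payload = {
        "kappa": fit.params.kappa,
        "mu_nd": fit.params.mu_nd,
        "sigma_nd": fit.params.sigma_nd,
        "loglik": fit.loglik,
        "n_trials": fit.n_trials,
        "percentile_window": list(fit.percentile_window),
        "converged": fit.converged,
        "seed": seed,
        "grid": grid,
        "bound_csv": path.stem + "_bound.csv",
    }
    path.write_text(json.dumps(payload, indent=2))
    fit.bound.to_frame().to_csv(path.with_name(payload["bound_csv"]), index=False)


def read_fit(path) -> NpbFit:
    path = Path(path)
    payload = json.loads(path.read_text())
    bound_df = pd.read_csv(path.with_name(payload["bound_csv"]))
    return NpbFit(
        params=DDMParams(payload["kappa"], payload["mu_nd"], payload["sigma_nd"]),
        bound=BoundFunction(bound_df["t"].to_numpy(), bound_df["B"].to_numpy()),
        loglik=payload["loglik"],
        n_trials=payload["n_trials"],
        percentile_window=tuple(payload["percentile_window"]),
        converged=payload.get("converged", True),
    )
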