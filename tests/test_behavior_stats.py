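"""Behavioral statistics: standardisation, regressions, sliding accuracy."""

import numpy as np
import pandas as pd
import pytest

from npbddm.behavior_stats import (
    accuracy_logistic,
    peri_cancel_rt,
    rt_session_regression,
    sliding_accuracy,
    zscore_rt_by_coherence,
)
from npbddm.ddm_core import TRIAL_COLUMNS, canonical_bound, simulate_dataset
from npbddm.types import BoundFunction, DDMParams


def _table(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "participant": ["s1"] * n,
        "phase": [1] * n,
        "session": [1] * n,
        "trial_index": list(range(n)),
        "signed_coh": [0.064] * n,
        "choice": ["right"] * n,
        "correct": [True] * n,
        "rt": [0.5] * n,
        "has_deadline": [False] * n,
        "canceled": [False] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)[TRIAL_COLUMNS]


class TestZscore:
    def test_standardised_cells_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        tab = _table(
            rt=rng.gamma(5, 0.1, 300) + 0.3,
            signed_coh=rng.choice([0.0, 0.064, 0.256], 300),
            phase=rng.choice([1, 2], 300),
        )
        z = zscore_rt_by_coherence(tab)
        for _, grp in z.groupby("signed_coh"):
            assert grp["z_rt"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["z_rt"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_six_trial_hand_calculation(self):
        rts = [0.4, 0.6, 0.8, 0.5, 0.7, 0.9]
        tab = _table(rt=rts, phase=[1, 1, 1, 2, 2, 2])
        z = zscore_rt_by_coherence(tab)
        mu, sd = np.mean(rts), np.std(rts)
        np.testing.assert_allclose(z["z_rt"], (np.array(rts) - mu) / sd, atol=1e-12)

    def test_destandardising_recovers_the_rts(self):
        rng = np.random.default_rng(4)
        rts = rng.gamma(5, 0.1, 200) + 0.3
        tab = _table(rt=rts, phase=rng.choice([1, 2], 200))
        z = zscore_rt_by_coherence(tab)
        mu, sd = rts.mean(), rts.std()
        np.testing.assert_allclose(z["z_rt"] * sd + mu, z["rt"], atol=1e-12)

    def test_zero_variance_cell_rejected(self):
        tab = _table(rt=[0.5] * 6, phase=[1, 1, 1, 2, 2, 2])
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_rt_by_coherence(tab)


def _two_phase_rts(step=0.0, drift=0.0, n_per_sess=60, seed=0):
    """RT data with an optional phase-2 step and/or per-session linear drift."""
    rng = np.random.default_rng(seed)
    rows = []
    mags = [0.0, 0.064, 0.256]
    base = {0.0: 0.9, 0.064: 0.8, 0.256: 0.6}
    k = 0
    for phase, sessions in [(1, range(1, 11)), (2, range(1, 21))]:
        for s in sessions:
            k_sess = (s - 11) if phase == 1 else (s - 1)
            for _ in range(n_per_sess):
                m = rng.choice(mags)
                rt = base[m] + drift * k_sess + (step if phase == 2 else 0.0)
                rt += rng.normal(0, 0.05)
                rows.append(("s1", phase, s, 0, m, "right", True, rt, False, False))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


class TestSessionRegression:
    def test_detects_a_pure_step_change(self):
        res = rt_session_regression(_two_phase_rts(step=-0.15, seed=1))
        assert res["phase"] < -0.10
        assert res.p_value("phase") < 1e-6
        assert abs(res["session"]) < 0.01

    def test_pure_drift_shows_no_step(self):
        res = rt_session_regression(_two_phase_rts(drift=-0.004, seed=2))
        assert res["session"] == pytest.approx(-0.004, abs=0.002)
        assert res.p_value("phase") > 0.01


class TestAccuracyLogistic:
    def test_lower_phase2_bound_gives_negative_phase_coefficient(self):
        params = DDMParams(15, 0.3, 0.01)
        p1 = simulate_dataset(params, canonical_bound("stationary"), 150,
                              seed=5, dt=0.002, phase=1)
        low = BoundFunction.flat(0.55, 6.0, dt=0.002)
        p2 = simulate_dataset(params, low, 150, seed=6, dt=0.002, phase=2)
        res = accuracy_logistic(pd.concat([p1, p2], ignore_index=True))
        assert res["phase"] < 0
        assert res.p_value("phase") < 0.05

    def test_identical_phases_show_no_effect(self):
        params = DDMParams(15, 0.3, 0.01)
        p1 = simulate_dataset(params, canonical_bound("stationary"), 120,
                              seed=7, dt=0.002, phase=1)
        p2 = simulate_dataset(params, canonical_bound("stationary"), 120,
                              seed=8, dt=0.002, phase=2)
        res = accuracy_logistic(pd.concat([p1, p2], ignore_index=True))
        assert res.p_value("phase") > 0.01

    def test_pooled_single_participant_nests_the_plain_model(self):
        params = DDMParams(15, 0.3, 0.01)
        tab = simulate_dataset(params, canonical_bound("stationary"), 100, seed=9, dt=0.002)
        tab2 = simulate_dataset(params, BoundFunction.flat(0.7, 6.0, dt=0.002), 100,
                                seed=10, dt=0.002, phase=2)
        both = pd.concat([tab, tab2], ignore_index=True)
        plain = accuracy_logistic(both, pooled=False)
        pooled = accuracy_logistic(both, pooled=True)
        assert pooled["phase"] == pytest.approx(plain["phase"], rel=1e-6)


class TestSlidingAccuracy:
    def test_all_correct_is_flat_at_one(self):
        tab = _table(rt=np.linspace(0.3, 2.0, 250))
        out = sliding_accuracy(tab, window=100)
        assert (out["p_correct"] == 1.0).all()

    def test_collapsing_bounds_produce_declining_accuracy(self):
        """Flat bounds give a flat time-accuracy curve; collapsing bounds a
        declining one, at an intermediate motion strength."""
        params = DDMParams(15, 0.3, 0.01)
        flat = simulate_dataset(params, canonical_bound("stationary"), 400, seed=11, dt=0.002)
        coll = simulate_dataset(params, canonical_bound("exponential"), 400, seed=12, dt=0.002)
        slopes = {}
        for name, tab in [("flat", flat), ("coll", coll)]:
            sub = tab[tab["signed_coh"].abs() == 0.064]
            out = sliding_accuracy(sub, window=150)
            slopes[name] = np.polyfit(out["rt"], out["p_correct"], 1)[0]
        assert slopes["coll"] < slopes["flat"]
        assert slopes["coll"] < -0.02
        assert abs(slopes["flat"]) < 0.06

    def test_fewer_trials_than_window_gives_single_point(self):
        tab = _table(rt=np.linspace(0.3, 1.0, 30))
        out = sliding_accuracy(tab, window=100)
        assert len(out) == 1


class TestPeriCancelRt:
    def _phase2_table(self, rts, canceled, seed=0):
        n = len(rts)
        return _table(
            rt=rts, phase=[2] * n, has_deadline=list(canceled),
            canceled=list(canceled),
            choice=[None if c else "right" for c in canceled],
        )

    def test_requires_cancelations(self):
        with pytest.raises(ValueError, match="no canceled"):
            peri_cancel_rt(_table(rt=[0.5] * 10, phase=[2] * 10))

    def test_shuffled_cancelations_give_a_flat_profile(self):
        rng = np.random.default_rng(13)
        n = 8000
        rts = rng.gamma(6, 0.1, n) + 0.3
        canceled = np.zeros(n, dtype=bool)
        canceled[rng.choice(n, 400, replace=False)] = True
        rts = np.where(canceled, np.nan, rts)
        out = peri_cancel_rt(self._phase2_table(rts, canceled))
        # 400 events per lag: 4 standard errors of the mean z-score
        assert np.nanmax(np.abs(out["mean_z_rt"])) < 4 / np.sqrt(400)

    def test_bound_dropping_agent_speeds_up_after_cancelation(self):
        """An agent that responds faster right after each cancelation."""
        rng = np.random.default_rng(14)
        n = 4000
        rts = rng.normal(0.8, 0.08, n)
        canceled = np.zeros(n, dtype=bool)
        canceled[rng.choice(np.arange(5, n - 5), 150, replace=False)] = True
        pos = np.nonzero(canceled)[0]
        for p in pos:
            rts[p + 1 : p + 3] -= 0.25
        rts = np.where(canceled, np.nan, rts)
        out = peri_cancel_rt(self._phase2_table(rts, canceled)).set_index("lag")
        assert out.loc[1, "mean_z_rt"] < out.loc[-1, "mean_z_rt"] - 0.3

    def test_cancelations_after_slow_responses_show_positive_pre_event_rt(self):
        """When deadlines catch slow trials, the trials *before* a cancelation
        tend to be slower than average (positive mean z)."""
        rng = np.random.default_rng(15)
        n = 4000
        slow_block = rng.random(n) < 0.1
        rts = np.where(slow_block, 1.2, 0.8) + rng.normal(0, 0.05, n)
        # cancelations occur within slow stretches
        canceled = slow_block & (rng.random(n) < 0.3)
        # make slowness persist around the cancelation
        for p in np.nonzero(canceled)[0]:
            rts[max(p - 2, 0) : p + 3] += 0.2
        rts = np.where(canceled, np.nan, rts)
        out = peri_cancel_rt(self._phase2_table(rts, canceled)).set_index("lag")
        assert out.loc[-1, "mean_z_rt"] > 0.1
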