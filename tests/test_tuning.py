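"""Task-epoch activity tables, tuning vectors, and CN statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from photoplast import tuning
from photoplast.bci import TrialEvents
from photoplast.session import SessionRecord


def make_session(dff, frame_rate, starts, rewards, cn=0):
    """Toy session from a dF/F matrix and event times (NaN reward = miss)."""
    dff = np.asarray(dff, float)
    raw = 100.0 * (1.0 + dff)
    outcomes = np.array(
        ["miss" if np.isnan(r) else "hit" for r in rewards], object
    )
    durations = np.array(
        [10.0 if np.isnan(r) else r - s for s, r in zip(starts, rewards)]
    )
    ev = TrialEvents(np.asarray(starts, float), np.asarray(rewards, float),
                     outcomes, durations)
    return SessionRecord(raw=raw, dff=dff, frame_rate=frame_rate, events=ev,
                         cn_index=cn)


@pytest.fixture
def ramp_session():
    """3-trial toy session with linear-ramp traces; all windows hand-checkable.

    20 Hz, trials start at 10, 30, 50 s; rewards at 14, 35, NaN (miss).
    Neuron 0: dff = t / 100; neuron 1: constant 0.3.
    """
    fr = 20.0
    T = int(60 * fr)
    t = np.arange(T) / fr
    dff = np.vstack([t / 100.0, np.full(T, 0.3)])
    return make_session(dff, fr, starts=[10.0, 30.0, 50.0],
                        rewards=[14.0, 35.0, np.nan])


class TestEpochActivity:
    def test_hand_computed_window_means(self, ramp_session):
        table = tuning.epoch_activity(ramp_session)
        ramp = table[table.neuron == 0].set_index(["trial", "epoch"])["value"]
        # late of trial 1: (13, 14] s -> frames at 13.05..14.0, mean t = 13.525
        assert ramp.loc[(1, "late")] == pytest.approx(13.525 / 100)
        # early of trial 1: (10, 13] s -> mean t = 11.525
        assert ramp.loc[(1, "early")] == pytest.approx(11.525 / 100)
        # reward of trial 1: (14, 17] s -> mean t = 15.525
        assert ramp.loc[(1, "rew")] == pytest.approx(15.525 / 100)
        # pretrial of trial 2 (follows hit): (28, 29] s -> mean t = 28.525
        assert ramp.loc[(2, "pre")] == pytest.approx(28.525 / 100)

    def test_constant_trace_gives_constant_entries(self, ramp_session):
        table = tuning.epoch_activity(ramp_session)
        const = table[table.neuron == 1]
        assert np.allclose(const["value"], 0.3)

    def test_availability_rules(self, ramp_session):
        table = tuning.epoch_activity(ramp_session)
        t0 = table[table.neuron == 0].set_index(["trial", "epoch"])
        # trial 1 has no pretrial (no preceding hit trial)
        assert (1, "pre") not in t0.index
        # trial 3 is a miss: no early/late/reward
        for epoch in ("early", "late", "rew"):
            assert (3, epoch) not in t0.index
        # trial 3 follows a hit: pretrial present
        assert (3, "pre") in t0.index

    def test_short_hit_trial_has_no_early_entry(self):
        fr = 20.0
        dff = np.zeros((1, int(30 * fr)))
        ses = make_session(dff, fr, starts=[10.0], rewards=[10.8])
        table = tuning.epoch_activity(ses)
        epochs = set(table[table.trial == 1]["epoch"])
        assert "early" not in epochs and "late" in epochs

    def test_first_40_trials_only(self):
        fr = 20.0
        starts = np.arange(50) * 10.0 + 5.0
        rewards = starts + 3.0
        dff = np.zeros((1, int(fr * 600)))
        ses = make_session(dff, fr, starts, rewards)
        table = tuning.epoch_activity(ses)
        assert table["trial"].max() == 40


class TestTuningAndDelta:
    @pytest.mark.parametrize(
        "values, base, slope",
        [
            ([1, 1, 1, 1], 1.0, 0.0),
            ([1, 2, 3, 4], 2.5, 1.0),
            ([0.2, 0.1, 0.5, 0.6], 0.35, 0.16),  # closed-form OLS slope
        ],
    )
    def test_base_and_slope(self, values, base, slope):
        table = pd.DataFrame(
            {"neuron": 0, "trial": [1, 2, 3, 4], "epoch": "late", "value": values}
        )
        tv = tuning.tuning_and_delta(table, n_neurons=1)
        assert tv.loc[0, "late"] == pytest.approx(base)
        assert tv.loc[0, "d_late"] == pytest.approx(slope)

    def test_single_trial_base_defined_delta_absent(self):
        table = pd.DataFrame(
            {"neuron": [0], "trial": [1], "epoch": ["rew"], "value": [0.7]}
        )
        tv = tuning.tuning_and_delta(table, n_neurons=1)
        assert tv.loc[0, "rew"] == pytest.approx(0.7)
        assert np.isnan(tv.loc[0, "d_rew"])

    def test_delta_invariant_to_constant_shift(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=6)
        t1 = pd.DataFrame({"neuron": 0, "trial": np.arange(1, 7),
                           "epoch": "early", "value": vals})
        t2 = t1.assign(value=vals + 5.0)
        tv1 = tuning.tuning_and_delta(t1, 1)
        tv2 = tuning.tuning_and_delta(t2, 1)
        assert tv2.loc[0, "d_early"] == pytest.approx(tv1.loc[0, "d_early"])
        assert tv2.loc[0, "early"] == pytest.approx(tv1.loc[0, "early"] + 5.0)


class TestCNBootstrap:
    def test_exchangeable_null_centered(self):
        deltas = [np.full(10, 0.5) for _ in range(4)]
        pct, p, _ = tuning.cn_sparsity_bootstrap(deltas, [0, 0, 0, 0],
                                                 n_draws=500, seed=0)
        assert pct == pytest.approx(0.5)
        assert p == pytest.approx(1.0)  # all ties count as >= CN median

    def test_extreme_cn(self):
        rng = np.random.default_rng(1)
        deltas = [np.concatenate([rng.normal(size=9), [10.0]]) for _ in range(3)]
        pct, p, null = tuning.cn_sparsity_bootstrap(deltas, [9, 9, 9],
                                                    n_draws=1000, seed=2)
        assert pct == pytest.approx(1.0)
        assert p <= 1 / 1000

    def test_matches_exhaustive_enumeration(self):
        """Bootstrap percentile converges to the exact enumeration value."""
        rng = np.random.default_rng(3)
        deltas = [rng.normal(size=6) for _ in range(3)]
        cn_ids = [2, 4, 1]
        cn_median = np.median([d[c] for d, c in zip(deltas, cn_ids)])
        pools = [np.delete(d, c) for d, c in zip(deltas, cn_ids)]
        null_exact = [
            np.median(combo)
            for combo in itertools.product(*[list(d) for d in pools])
        ]
        null_exact = np.asarray(null_exact)
        exact_pct = np.mean(null_exact < cn_median) + 0.5 * np.mean(
            null_exact == cn_median
        )
        pct, _, _ = tuning.cn_sparsity_bootstrap(deltas, cn_ids,
                                                 n_draws=40_000, seed=4)
        assert pct == pytest.approx(exact_pct, abs=0.01)

    def test_null_percentile_uniform_for_random_neuron(self):
        """Percentile of a random non-CN neuron is U[0, 1] under
        exchangeability (KS over repeated seeds at reduced draws)."""
        rng = np.random.default_rng(5)
        pcts = []
        for rep in range(120):
            deltas = [rng.normal(size=8) for _ in range(5)]
            cn_ids = [int(rng.integers(8)) for _ in range(5)]
            pct, _, _ = tuning.cn_sparsity_bootstrap(deltas, cn_ids,
                                                     n_draws=400, seed=rep)
            pcts.append(pct)
        assert stats.kstest(pcts, "uniform").pvalue > 0.01

    def test_empty_candidate_mask_names_session(self):
        deltas = [np.ones(5), np.ones(5)]
        masks = [np.ones(5, bool), np.zeros(5, bool)]
        with pytest.raises(ValueError, match="session 1"):
            tuning.cn_sparsity_bootstrap(deltas, [0, 0], 100, 0,
                                         candidate_masks=masks)


class TestCandidateCNMask:
    def _session(self, dff):
        fr = 20.0
        return make_session(dff, fr, starts=[5.0, 15.0], rewards=[8.0, 18.0])

    def test_reference_always_included_silent_excluded(self):
        rng = np.random.default_rng(6)
        n, T = 60, 600
        dff = 0.2 * np.abs(rng.standard_normal((n, T)))
        dff[1] = 0.0  # silent neuron
        dff[1, ::97] = 1e-6
        ses = self._session(dff)
        mask = tuning.candidate_cn_mask(ses, reference=0)
        assert mask[0]
        assert not mask[1]
        assert mask.sum() == int(np.ceil(0.05 * n))

    def test_matches_rank_distance_oracle(self):
        rng = np.random.default_rng(7)
        n, T = 100, 800
        dff = 0.3 * np.abs(rng.standard_normal((n, T))) * rng.uniform(
            0.2, 2.0, size=(n, 1)
        )
        ses = self._session(dff)
        mask = tuning.candidate_cn_mask(ses, reference=3)
        # oracle: recompute both statistics and the rank-space selection
        sd = dff.std(axis=1)
        modulation = np.mean(dff > sd[:, None], axis=1)
        tun = tuning._trial_start_tuning(ses, tuning.EpochWindows())
        r1, r2 = stats.rankdata(modulation), stats.rankdata(tun)
        d2 = (r1 - r1[3]) ** 2 + (r2 - r2[3]) ** 2
        expect = np.zeros(n, bool)
        expect[np.argsort(d2, kind="stable")[: int(np.ceil(0.05 * n))]] = True
        np.testing.assert_array_equal(mask, expect)


class TestEpochWeightedAverage:
    def test_single_neuron_identity(self, ramp_session):
        tv = pd.DataFrame({"late": [1.0, np.nan]})
        out = tuning.epoch_weighted_average(ramp_session, tv, "late")
        np.testing.assert_allclose(out, ramp_session.dff[0])

    def test_identical_traces_idempotent(self):
        fr = 20.0
        trace = np.sin(np.arange(200) / 10)
        dff = np.vstack([trace, trace])
        ses = make_session(dff, fr, starts=[2.0], rewards=[5.0])
        tv = pd.DataFrame({"rew": [1.0, 1.0]})
        out = tuning.epoch_weighted_average(ses, tv, "rew")
        np.testing.assert_allclose(out, trace)

    def test_three_neuron_weighted_mean(self):
        fr = 20.0
        dff = np.vstack([np.full(100, 1.0), np.full(100, 2.0), np.full(100, 4.0)])
        ses = make_session(dff, fr, starts=[1.0], rewards=[3.0])
        tv = pd.DataFrame({"pre": [1.0, -2.0, 1.0]})
        out = tuning.epoch_weighted_average(ses, tv, "pre")
        np.testing.assert_allclose(out, (1 - 4 + 4) / 4.0)

    def test_zero_weights_rejected(self, ramp_session):
        tv = pd.DataFrame({"early": [0.0, 0.0]})
        with pytest.raises(ValueError):
            tuning.epoch_weighted_average(ramp_session, tv, "early")


class TestPretrialPerformance:
    def _session_with_durations(self, slope, n_trials=60, seed=0):
        rng = np.random.default_rng(seed)
        fr = 20.0
        gap = 15.0
        starts = np.arange(n_trials) * gap + 5.0
        pre_level = rng.uniform(0.1, 1.0, size=n_trials)
        durations = np.clip(5.0 + slope * pre_level + 0.3 * rng.standard_normal(n_trials), 1.0, 9.0)
        rewards = starts + durations
        T = int((starts[-1] + 12) * fr)
        t = np.arange(T) / fr
        dff = np.zeros((3, T))
        for k in range(n_trials):
            sel = (t > starts[k] - 2.0) & (t <= starts[k] - 1.0)
            dff[:, sel] = pre_level[k]
        return make_session(dff, fr, starts, rewards)

    def test_planted_negative_slope_detected(self):
        ses = self._session_with_durations(slope=-4.0, seed=1)
        slope, p = tuning.pretrial_performance_regression(ses, max_trials=60)
        assert slope < 0
        assert p < 0.01

    def test_constant_durations_zero_slope(self):
        ses = self._session_with_durations(slope=0.0, seed=2)
        # overwrite durations to a constant by rebuilding rewards
        ev = ses.events
        ev.reward_times[:] = ev.trial_start_times + 5.0
        ev.durations[:] = 5.0
        slope, p = tuning.pretrial_performance_regression(ses, max_trials=60)
        assert slope == pytest.approx(0.0)

    def test_too_few_trials_rejected(self, ramp_session):
        with pytest.raises(ValueError):
            tuning.pretrial_performance_regression(ramp_session)


class TestSplitHalfControl:
    def test_odd_even_tuning_consistency(self, small_session, small_circuit):
        """Tuning on odd trials predicts even-trial tuning (split-half)."""
        table = tuning.epoch_activity(small_session)
        odd = table[table.trial % 2 == 1]
        even = table[table.trial % 2 == 0]
        n = small_session.n_neurons
        tv_odd = tuning.tuning_and_delta(odd, n)
        tv_even = tuning.tuning_and_delta(even, n)
        for epoch in ("pre", "early", "late", "rew"):
            a, b = tv_odd[epoch], tv_even[epoch]
            ok = a.notna() & b.notna()
            rho = stats.spearmanr(a[ok], b[ok]).statistic
            assert rho > 0.5, epoch


def test_session_record_roundtrip(tmp_path, small_session):
    path = tmp_path / "session.h5"
    small_session.save(path)
    back = SessionRecord.load(path)
    np.testing.assert_allclose(back.raw, small_session.raw)
    np.testing.assert_allclose(back.dff, small_session.dff)
    assert back.cn_index == small_session.cn_index
    assert list(back.events.outcomes) == list(small_session.events.outcomes)
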