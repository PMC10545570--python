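import numpy as np
import pandas as pd
import pytest

from denseior.preprocess import (FilterRules, apply_screening, cell_means,
                                 condition_timecourses, difference_course,
                                 filter_trials, preprocess,
                                 screen_participants, zscore_rts)
from denseior.simulate import EffectParams, difference_curve


def _trials(pid, rows):
    df = pd.DataFrame(rows)
    df["participant_id"] = pid
    for col, default in (("block", 1), ("trial", 0), ("ctoa_ms", pd.NA),
                         ("validity", pd.NA), ("is_catch", False),
                         ("responded", True), ("rt", 0.5)):
        if col not in df:
            df[col] = default
    df.loc[~df["responded"], "rt"] = np.nan
    return df


def _catch_trials(pid, n_catch, n_fa):
    return _trials(pid, [{"is_catch": True, "responded": i < n_fa,
                          "rt": 0.4 if i < n_fa else np.nan}
                         for i in range(n_catch)])


class TestScreening:
    def test_exactly_20_percent_is_retained(self):
        s, = screen_participants(_catch_trials("a", 60, 12))
        assert s.false_alarm_rate == pytest.approx(0.20)
        assert not s.excluded

    def test_above_20_percent_is_excluded(self):
        s, = screen_participants(_catch_trials("a", 60, 13))
        assert s.excluded and "false-alarm" in s.reason

    def test_zero_false_alarms_retained(self):
        s, = screen_participants(_catch_trials("a", 60, 0))
        assert s.false_alarm_rate == 0.0 and not s.excluded

    def test_no_catch_trials_flagged_undefined(self):
        s, = screen_participants(_trials("a", [{"rt": 0.3}] * 5))
        assert s.excluded and np.isnan(s.false_alarm_rate)

    def test_screening_is_per_participant(self, small_cohort):
        _, trials = small_cohort
        summaries = screen_participants(trials)
        kept = apply_screening(trials, summaries)
        # removing one participant's rows leaves all others untouched
        pid = summaries[0].participant_id
        rest = kept[kept["participant_id"] != pid]
        again = apply_screening(
            trials[trials["participant_id"] != pid], summaries)
        pd.testing.assert_frame_equal(rest.reset_index(drop=True), again)


class TestFilters:
    def test_deadline_and_anticipation_cutoffs(self):
        df = _trials("a", [{"rt": 2.4, "ctoa_ms": 42, "validity": "valid"},
                           {"rt": 0.10, "ctoa_ms": 42, "validity": "valid"},
                           {"rt": 0.30, "ctoa_ms": 42, "validity": "valid"}])
        out, log = filter_trials(df, FilterRules())
        assert len(out) == 1 and out["rt"].iloc[0] == 0.30
        assert log["dropped_above_max_rt"] == 1
        assert log["dropped_below_min_rt"] == 1

    def test_empty_rule_set_is_identity(self, small_cohort):
        _, trials = small_cohort
        rules = FilterRules(drop_catch=False, drop_misses=False,
                            min_rt=None, max_rt=None)
        out, log = filter_trials(trials, rules)
        pd.testing.assert_frame_equal(out, trials.reset_index(drop=True))
        assert log["retained"] == log["input"]


class TestZScore:
    def test_three_point_example(self):
        df = _trials("a", [{"rt": 1.0}, {"rt": 2.0}, {"rt": 3.0}])
        z = zscore_rts(df)["z_rt"]
        assert np.allclose(z, [-1.0, 0.0, 1.0])  # sample SD

    def test_mean_zero_sd_one_per_participant(self, small_cohort):
        _, trials = small_cohort
        filtered, _ = filter_trials(trials)
        z = zscore_rts(filtered)
        for _, grp in z.groupby("participant_id"):
            assert abs(grp["z_rt"].mean()) < 1e-12
            assert abs(grp["z_rt"].std(ddof=1) - 1) < 1e-12

    def test_scale_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        rts = rng.uniform(0.2, 0.9, 40)
        a = zscore_rts(_trials("a", [{"rt": r} for r in rts]))
        b = zscore_rts(_trials("b", [{"rt": 0.2 + 3.0 * r} for r in rts]))
        assert np.allclose(a["z_rt"].to_numpy(), b["z_rt"].to_numpy())

    def test_idempotent_up_to_machine_precision(self):
        rng = np.random.default_rng(1)
        df = _trials("a", [{"rt": r} for r in rng.uniform(0.2, 1.0, 30)])
        once = zscore_rts(df)
        twice = zscore_rts(once.assign(rt=once["z_rt"]))
        assert np.allclose(once["z_rt"], twice["z_rt"], atol=1e-12)

    def test_degenerate_participants_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            zscore_rts(_trials("a", [{"rt": 0.5}]))
        with pytest.raises(ValueError, match="zero RT variance"):
            zscore_rts(_trials("a", [{"rt": 0.5}] * 5))


class TestCellMeansAndCourses:
    def test_missing_cell_aborts(self, noisefree_cohort):
        _, _, trials = noisefree_cohort
        filtered, _ = filter_trials(trials)
        z = zscore_rts(filtered)
        broken = z[~((z["ctoa_ms"] == 84) & (z["validity"] == "valid")
                     & (z["participant_id"] == z["participant_id"].iloc[0]))]
        with pytest.raises(ValueError, match="empty design cells"):
            cell_means(broken)

    def test_single_participant_se_is_zero(self, noisefree_cohort):
        _, _, trials = noisefree_cohort
        one = trials[trials["participant_id"]
                     == trials["participant_id"].iloc[0]]
        filtered, _ = filter_trials(one)
        cm = cell_means(zscore_rts(filtered))
        tcs = condition_timecourses(cm)
        assert np.all(tcs["valid"].within_subject_se == 0)

    def test_morey_se_ignores_additive_participant_offsets(self, small_cohort):
        _, trials = small_cohort
        *_, cm, tcs, _ = preprocess(trials)
        shifted = cm.__class__(
            ctoa=cm.ctoa, participants=cm.participants,
            valid=cm.valid + np.arange(len(cm.participants))[:, None],
            invalid=cm.invalid + np.arange(len(cm.participants))[:, None])
        tcs2 = condition_timecourses(shifted)
        for cond in ("valid", "invalid"):
            assert np.allclose(tcs[cond].within_subject_se,
                               tcs2[cond].within_subject_se, atol=1e-10)

    def test_difference_is_mean_of_per_participant_differences(self, small_cohort):
        _, trials = small_cohort
        *_, cm, tcs, diff = preprocess(trials)
        assert np.allclose(diff.diff, diff.per_participant_diff.mean(axis=0))
        assert np.allclose(diff.diff,
                           tcs["invalid"].mean_z_rt - tcs["valid"].mean_z_rt)

    def test_identical_conditions_give_zero_difference(self, small_cohort):
        _, trials = small_cohort
        *_, cm, _, _ = preprocess(trials)
        same = cm.__class__(ctoa=cm.ctoa, participants=cm.participants,
                            valid=cm.valid, invalid=cm.valid)
        assert np.allclose(difference_course(same).diff, 0)


class TestNoiseFreeRecovery:
    def test_pipeline_recovers_generative_curve_up_to_normalization(
            self, noisefree_cohort):
        cfg, noise, trials = noisefree_cohort
        *_, diff = preprocess(trials)
        d_true = difference_curve(diff.ctoa, EffectParams())
        # z-scaling divides each participant's values by the SD of their
        # trial RTs; noise-free, that constant is identical across
        # participants and computable from the retained trials
        filtered, _ = filter_trials(trials)
        one = filtered[filtered["participant_id"]
                       == filtered["participant_id"].iloc[0]]
        c = one["rt"].std(ddof=1)
        assert np.allclose(diff.diff, d_true / c, atol=1e-12)
        # facilitation at the shortest CTOA: positive difference
        assert diff.diff[0] > 0 > diff.diff[-1]
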