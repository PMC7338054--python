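"""Behavioural statistics: classification, d', baselining, MCC, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from seqmem.behaviour import (ConfusionCounts, baseline_and_trim,
                              bootstrap_advantage, classify_responses,
                              dprime, dprime_by_block, exclude_participants,
                              mcc, mcc_from_responses, rt_advantage)


def _trial(cond, trans, press, participant=0, block=0, third=0, idx=0,
           pres=None, duration=7.0):
    return {"participant": participant, "block": block, "third": third,
            "trial_index": idx, "condition": cond, "pattern_id": None,
            "presentation_index": pres, "transition_time_s": trans,
            "duration_s": duration, "press_time_s": press}


class TestClassification:
    def test_labels(self):
        df = pd.DataFrame([
            _trial("RANREG", 3.5, 3.9, idx=0),    # hit, RT 0.4
            _trial("RANREG", 3.5, 3.0, idx=1),    # pre-transition press
            _trial("RANREG", 3.5, np.nan, idx=2),  # miss
            _trial("RAN", np.nan, 4.0, idx=3),     # false alarm
            _trial("RAN", np.nan, np.nan, idx=4),  # correct rejection
            _trial("STEP", 3.2, 3.5, idx=5),       # STEP hit, RT 0.3
        ])
        out = classify_responses(df)
        assert out["label"].tolist() == [
            "hit", "pre_transition_excluded", "miss", "false_alarm",
            "correct_rejection", "hit"]
        assert out["raw_rt_s"].iloc[0] == pytest.approx(0.4)
        assert out["raw_rt_s"].iloc[5] == pytest.approx(0.3)

    def test_second_cycle_reference(self):
        df = pd.DataFrame([_trial("RANREG", 3.45, 5.0),
                           _trial("PATinRAN", 6.0, 6.5, idx=1)])
        out = classify_responses(df, rt_reference="second_cycle_onset")
        # adjacent-cycle conditions shift the reference by one cycle (1 s);
        # for PATinRAN the transition already is the second occurrence
        assert out["raw_rt_s"].iloc[0] == pytest.approx(5.0 - 4.45)
        assert out["raw_rt_s"].iloc[1] == pytest.approx(0.5)

    def test_press_outside_trial_rejected(self):
        df = pd.DataFrame([_trial("RANREG", 3.5, 7.5)])
        with pytest.raises(ValueError):
            classify_responses(df)

    def test_unknown_condition_rejected(self):
        df = pd.DataFrame([_trial("RANREGX", 3.5, 4.0)])
        with pytest.raises(ValueError):
            classify_responses(df)


class TestDprime:
    def test_equal_rates_give_zero(self):
        assert dprime(10, 10, 10, 10) == pytest.approx(0.0)

    def test_ceiling_with_loglinear_correction(self):
        # 20/20 hits, 0/20 FAs: z(20.5/21) - z(0.5/21)
        assert dprime(20, 0, 0, 20) == pytest.approx(3.9615, abs=1e-3)

    def test_uncorrected_is_infinite_at_ceiling(self):
        assert np.isinf(dprime(20, 0, 0, 20, correction="none"))

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 5, 5)

    def test_exclusion_rule_depends_on_threshold(self):
        table = pd.DataFrame([{"participant": "p1", "block": 0, "dprime": 1.5},
                              {"participant": "p2", "block": 0, "dprime": 2.5}])
        assert exclude_participants(table, threshold=2.0) == ["p1"]
        assert exclude_participants(table, threshold=1.0) == []  # lenient rule

    def test_dprime_by_block_counts(self):
        trials = []
        for i in range(20):
            trials.append(_trial("RANREG", 3.5, 4.0, idx=i))       # hits
        for i in range(20):
            trials.append(_trial("RAN", np.nan, np.nan, idx=20 + i))
        out = classify_responses(pd.DataFrame(trials))
        dp = dprime_by_block(out)
        assert dp["dprime"].iloc[0] == pytest.approx(3.9615, abs=1e-3)


class TestBaselineTrim:
    def test_baseline_subtracts_step_mean(self):
        trials = [_trial("STEP", 3.0, 3.3, idx=0),
                  _trial("RANREG", 3.5, 4.5, idx=1),
                  _trial("RANREG", 3.5, 4.6, idx=2)]
        out = baseline_and_trim(classify_responses(pd.DataFrame(trials)),
                                trim=False)
        vals = out["baselined_rt_s"].dropna().tolist()
        assert vals == pytest.approx([0.7, 0.8])

    def test_two_sd_trim_discards_outlier(self):
        # {0.5 x 9, 5.0}: mean 0.95, sd 1.423; only 5.0 exceeds 2 SD
        trials = [_trial("STEP", 3.0, 3.0, idx=99)]
        for i in range(9):
            trials.append(_trial("RANREG", 1.0, 1.5, idx=i))
        trials.append(_trial("RANREG", 1.0, 6.0, idx=9))
        out = baseline_and_trim(classify_responses(pd.DataFrame(trials)))
        kept = out["baselined_rt_s"].dropna()
        assert len(kept) == 9
        assert out["trimmed"].sum() == 1

    def test_identical_rts_nothing_trimmed(self):
        trials = [_trial("STEP", 3.0, 3.2, idx=99)]
        trials += [_trial("RANREG", 3.5, 4.0, idx=i) for i in range(5)]
        out = baseline_and_trim(classify_responses(pd.DataFrame(trials)))
        assert out["trimmed"].sum() == 0
        assert out["baselined_rt_s"].dropna().nunique() == 1

    def test_missing_step_baseline_warns(self):
        trials = [_trial("RANREG", 3.5, 4.0)]
        with pytest.warns(UserWarning):
            out = baseline_and_trim(classify_responses(pd.DataFrame(trials)))
        assert out["baselined_rt_s"].isna().all()


class TestRtAdvantage:
    def _classified(self, novel_rts, regr_rts):
        trials = [_trial("STEP", 3.0, 3.0, idx=99)]
        idx = 0
        for third, rt in novel_rts:
            trials.append(_trial("RANREG", 3.5, 3.5 + rt, third=third,
                                 idx=idx)); idx += 1
        for pres, rt in regr_rts:
            trials.append(_trial("RANREGr", 3.5, 3.5 + rt, third=pres - 1,
                                 idx=idx, pres=pres)); idx += 1
        return baseline_and_trim(classify_responses(pd.DataFrame(trials)),
                                 trim=False)

    def test_per_block_zero_for_equal_means(self):
        out = self._classified([(0, 1.0), (1, 1.0)], [(1, 1.0), (2, 1.0)])
        adv = rt_advantage(out, "per_block")
        assert adv["advantage_s"].iloc[0] == pytest.approx(0.0)

    def test_intra_block_pairing_and_tone_units(self):
        out = self._classified([(0, 1.0), (1, 1.0), (2, 1.0)],
                               [(1, 0.9), (2, 0.8), (3, 0.7)])
        adv = rt_advantage(out, "per_intra_block_presentation", block=0)
        assert adv["advantage_s"].tolist() == pytest.approx([0.1, 0.2, 0.3])
        # 0.233 s equals 4.66 tones at 50 ms per tone
        assert 0.233 / 0.05 == pytest.approx(4.66)

    def test_empty_cell_warns(self):
        out = self._classified([(0, 1.0)], [])
        with pytest.warns(UserWarning):
            adv = rt_advantage(out, "per_block")
        assert adv["advantage_s"].isna().all()

    def test_pipeline_invariant_to_trial_order(self):
        out = self._classified([(0, 1.1), (1, 0.9), (2, 1.3)],
                               [(1, 0.9), (2, 0.7), (3, 1.0)])
        shuffled = out.sample(frac=1.0, random_state=4)
        a = rt_advantage(out, "per_block")["advantage_s"]
        b = rt_advantage(shuffled, "per_block")["advantage_s"]
        assert a.tolist() == pytest.approx(b.tolist())


class TestMcc:
    def test_worked_examples(self):
        assert mcc(ConfusionCounts(3, 18, 0, 0)) == pytest.approx(1.0)
        assert mcc(ConfusionCounts(0, 0, 18, 3)) == pytest.approx(-1.0)
        # (2*16 - 2*1)/sqrt(4*3*18*17) = 30/sqrt(3672)
        assert mcc(ConfusionCounts(2, 16, 2, 1)) == pytest.approx(
            30 / np.sqrt(3672), abs=1e-9)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(0, 10, 0, 0)) == 0.0

    @pytest.mark.parametrize("c", [(3, 15, 2, 1), (5, 5, 5, 5), (1, 20, 0, 2)])
    def test_symmetries(self, c):
        tp, tn, fp, fn = c
        base = mcc(ConfusionCounts(tp, tn, fp, fn))
        # swapping the class labels leaves MCC unchanged
        assert mcc(ConfusionCounts(tn, tp, fn, fp)) == pytest.approx(base)
        # negating the classifier negates it
        assert mcc(ConfusionCounts(fn, fp, tn, tp)) == pytest.approx(-base)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_mcc_from_responses(self):
        rows = ([{"participant": 0, "is_reoccurring": True,
                  "tagged_familiar": True}] * 3
                + [{"participant": 0, "is_reoccurring": False,
                    "tagged_familiar": False}] * 18)
        out = mcc_from_responses(pd.DataFrame(rows))
        assert out["mcc"].iloc[0] == pytest.approx(1.0)


class TestBootstrap:
    def test_degenerate_pool(self):
        means, p = bootstrap_advantage(np.full(10, 0.2), 5, iters=200,
                                       rng=0, observed=0.3)
        assert (means == 0.2).all()
        assert p == 0.0

    def test_symmetric_pool_centre(self):
        rng = np.random.default_rng(1)
        pool = rng.normal(0.1, 0.05, 200)
        _, p = bootstrap_advantage(pool, 20, iters=4000, rng=2,
                                   observed=float(pool.mean()))
        assert p == pytest.approx(0.5, abs=0.03)

    def test_far_observation_is_significant(self):
        # pool ~ N(0.03, 0.05^2), n_draw 20, observed 0.157
        rng = np.random.default_rng(3)
        pool = rng.normal(0.03, 0.05, 147)
        _, p = bootstrap_advantage(pool, 20, iters=5000, rng=4,
                                   observed=0.157)
        assert p < 0.01

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bootstrap_advantage(np.array([]), 5)
        with pytest.raises(ValueError):
            bootstrap_advantage(np.ones(5), 0)
        with pytest.raises(ValueError):
            bootstrap_advantage(np.ones(5), 3, iters=0)


# ---------------------------------------------------------------------------
# property-based checks

from hypothesis import given, settings, strategies as st  # noqa: E402

counts = st.integers(min_value=0, max_value=60)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(tp=counts, tn=counts, fp=counts, fn=counts)
def test_mcc_bounded_and_antisymmetric(tp, tn, fp, fn):
    """MCC lies in [-1, 1]; label swap preserves it, negation flips it."""
    v = mcc(ConfusionCounts(tp, tn, fp, fn))
    assert -1.0 <= v <= 1.0
    assert mcc(ConfusionCounts(tn, tp, fn, fp)) == pytest.approx(v)
    assert mcc(ConfusionCounts(fn, fp, tn, tp)) == pytest.approx(-v)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(hits=st.integers(0, 40), fas=st.integers(0, 40),
       n_sig=st.integers(1, 40), n_noise=st.integers(1, 40))
def test_dprime_monotone_in_hits(hits, fas, n_sig, n_noise):
    """With misses/CRs fixed, more hits never lowers corrected d'."""
    d1 = dprime(hits, n_sig, fas, n_noise)
    d2 = dprime(hits + 1, n_sig, fas, n_noise)
    assert d2 >= d1
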