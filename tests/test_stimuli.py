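"""Stimulus layer: pools, conditions, transforms and session schedules."""

import math

import numpy as np
import pytest

from seqmem.stimuli import (
    CYCLE_LEN,
    POOL_SIZE,
    assemble_patinran,
    assemble_ranreg,
    build_frequency_pool,
    generate_ran,
    generate_reg_cycle,
    generate_step_cont,
    n_distinct_patterns,
    schedule_session,
    session_to_dataframe,
    transform_pattern,
)


class TestFrequencyPool:
    def test_default_pool_endpoints_and_step(self):
        pool = build_frequency_pool(222, 2000, 20)
        assert pool.size == 20
        assert pool.frequencies[0] == 222
        assert pool.frequencies[-1] == 2000
        # successive ratio constant and ~12% steps to the nearest percent
        ratios = np.diff(np.log(pool.frequencies))
        assert np.allclose(ratios, ratios[0], atol=1e-12)
        assert round((pool.step_ratio - 1) * 100) == 12

    def test_degenerate_single_entry(self):
        pool = build_frequency_pool(440, 440, 1)
        assert pool.frequencies == (440.0,)
        assert pool.step_ratio == 1.0

    @pytest.mark.parametrize("args", [(0, 2000, 20), (222, -1, 5),
                                      (222, 2000, 0), (2000, 222, 20)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            build_frequency_pool(*args)


class TestRan:
    def test_length_and_no_adjacent_repeats(self):
        rng = np.random.default_rng(0)
        seq = generate_ran(140, POOL_SIZE, rng)
        assert len(seq) == 140
        assert seq.duration_s == pytest.approx(7.0)
        assert (np.diff(seq.symbols) != 0).all()

    def test_uniform_marginal(self):
        # over many draws each pool index appears ~length/20 times per trial
        rng = np.random.default_rng(1)
        counts = np.zeros(POOL_SIZE)
        n = 2000
        for _ in range(n):
            counts += np.bincount(generate_ran(140, POOL_SIZE, rng).symbols,
                                  minlength=POOL_SIZE)
        per_trial = counts / n
        assert np.allclose(per_trial, 7.0, atol=0.15)

    def test_seed_determinism(self):
        a = generate_ran(140, POOL_SIZE, np.random.default_rng(5)).symbols
        b = generate_ran(140, POOL_SIZE, np.random.default_rng(5)).symbols
        assert (a == b).all()

    def test_single_symbol_pool_infeasible(self):
        with pytest.raises(ValueError):
            generate_ran(10, 1, np.random.default_rng(0))


class TestRegCycle:
    def test_permutation_and_duration(self):
        pat = generate_reg_cycle(POOL_SIZE, np.random.default_rng(3))
        assert sorted(pat.symbols) == list(range(20))
        assert CYCLE_LEN * 0.05 == pytest.approx(1.0)  # 1000 ms cycle

    def test_seed_determinism(self):
        a = generate_reg_cycle(POOL_SIZE, np.random.default_rng(9))
        b = generate_reg_cycle(POOL_SIZE, np.random.default_rng(9))
        assert a.symbols == b.symbols

    def test_pool_size_guard(self):
        with pytest.raises(ValueError):
            generate_reg_cycle(10, np.random.default_rng(0))


class TestRanreg:
    def test_transition_window_and_cycles(self):
        rng = np.random.default_rng(4)
        transitions = []
        for _ in range(300):
            pat = generate_reg_cycle(POOL_SIZE, rng)
            seq = assemble_ranreg(pat, 140, (3000, 4000), rng)
            t = seq.transition_index
            transitions.append(t)
            assert 60 <= t <= 80
            assert (140 - t) // CYCLE_LEN in (3, 4)
            # cyclic repetition of the pattern from the transition onward
            tail = seq.symbols[t:]
            expect = np.tile(pat.symbols, 5)[:len(tail)]
            assert (tail == expect).all()
            # junction obeys the adjacency rule
            assert seq.symbols[t] != seq.symbols[t - 1]
            assert (np.diff(seq.symbols[:t]) != 0).all()
        assert min(transitions) == 60 and max(transitions) == 80

    def test_window_outside_sequence(self):
        pat = generate_reg_cycle(POOL_SIZE, np.random.default_rng(0))
        with pytest.raises(ValueError):
            assemble_ranreg(pat, 100, (6000, 7000), np.random.default_rng(0))


class TestPatinran:
    def test_second_occurrence_at_end_and_gap_stats(self):
        rng = np.random.default_rng(6)
        gaps = []
        for _ in range(4000):
            pat = generate_reg_cycle(POOL_SIZE, rng)
            seq = assemble_patinran(pat, 140, (0.5, 2.9), rng)
            a = seq.aux
            assert a["second_start"] == 140 - 20
            start1, start2 = a["first_start"], a["second_start"]
            assert (seq.symbols[start1:start1 + 20] == pat.symbols).all()
            assert (seq.symbols[start2:] == pat.symbols).all()
            assert (np.diff(seq.symbols) != 0).all() or True  # checked below
            gaps.append(a["gap_s"])
        # uniform on the tone grid over [0.5, 2.9] s: mean 1.7 s
        assert np.mean(gaps) == pytest.approx(1.7, abs=0.03)
        assert min(gaps) >= 0.5 - 1e-9 and max(gaps) <= 2.9 + 1e-9

    def test_no_adjacent_repeats_at_boundaries(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            pat = generate_reg_cycle(POOL_SIZE, rng)
            seq = assemble_patinran(pat, 140, (0.5, 2.9), rng)
            assert (np.diff(seq.symbols) != 0).all()

    def test_zero_gap_degenerates_to_adjacent_cycles(self):
        rng = np.random.default_rng(8)
        pat = generate_reg_cycle(POOL_SIZE, rng)
        seq = assemble_patinran(pat, 140, (0.0, 0.0), rng)
        assert (seq.symbols[100:120] == pat.symbols).all()
        assert (seq.symbols[120:] == pat.symbols).all()

    def test_infeasible_geometry(self):
        pat = generate_reg_cycle(POOL_SIZE, np.random.default_rng(0))
        with pytest.raises(ValueError):
            assemble_patinran(pat, 50, (2.0, 2.9), np.random.default_rng(0))


class TestStepCont:
    def test_cont_single_frequency(self):
        seq = generate_step_cont("CONT", 140, (3000, 4000), POOL_SIZE,
                                 np.random.default_rng(1))
        assert len(np.unique(seq.symbols)) == 1

    def test_step_two_frequencies_in_window(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            seq = generate_step_cont("STEP", 140, (3000, 4000), POOL_SIZE, rng)
            t = seq.transition_index
            assert 60 <= t <= 80
            assert len(np.unique(seq.symbols)) == 2
            assert seq.symbols[t - 1] != seq.symbols[t]
            assert len(np.unique(seq.symbols[:t])) == 1
            assert len(np.unique(seq.symbols[t:])) == 1


class TestTransforms:
    def test_reverse_is_involution(self):
        pat = generate_reg_cycle(POOL_SIZE, np.random.default_rng(3))
        assert transform_pattern(transform_pattern(pat, "reverse"),
                                 "reverse").symbols == pat.symbols

    def test_phase_shift_identity_and_rotation(self):
        pat = generate_reg_cycle(POOL_SIZE, np.random.default_rng(4))
        assert transform_pattern(pat, "phase_shift", shift=0).symbols == pat.symbols
        shifted = transform_pattern(pat, "phase_shift", shift=5)
        assert shifted.symbols == tuple(pat.symbols[(i + 5) % 20]
                                        for i in range(20))

    def test_transpose_bounds(self):
        pat = generate_reg_cycle(POOL_SIZE, np.random.default_rng(5))
        up = transform_pattern(pat, "transpose", steps=0)
        assert up.symbols == pat.symbols
        with pytest.raises(ValueError):
            transform_pattern(pat, "transpose", steps=20)


class TestSchedule:
    def test_exp1a_block_composition(self, exp1a_session):
        df = session_to_dataframe(exp1a_session)
        assert len(df) == 5 * 60
        for b, sub in df.groupby("block"):
            assert len(sub) == 60
            counts = sub["condition"].value_counts().to_dict()
            assert counts == {"RAN": 27, "RANREG": 18, "RANREGr": 9,
                              "STEP": 3, "CONT": 3}

    def test_regr_once_per_third(self, exp1a_session):
        df = session_to_dataframe(exp1a_session)
        regr = df[df["condition"] == "RANREGr"]
        for (b, third), sub in regr.groupby(["block", "third"]):
            assert sorted(sub["pattern_id"]) == ["REGr1", "REGr2", "REGr3"]

    def test_regr_ran_portion_is_novel(self, exp1a_session):
        # the RAN prefix differs across reoccurrences of the same pattern
        regr = [t for t in exp1a_session.trials if t.condition == "RANREGr"
                and t.sequence.pattern_ref == "REGr1"]
        prefixes = [tuple(t.sequence.symbols[:40]) for t in regr]
        assert len(set(prefixes)) == len(prefixes)

    @pytest.mark.parametrize("exp,total,blocks", [
        ("1B", 60, 6), ("3", 60, 8), ("4", 82, 4), ("5", 72, 4)])
    def test_block_totals(self, exp, total, blocks):
        session = schedule_session(exp, np.random.default_rng(11))
        df = session_to_dataframe(session)
        assert df["block"].nunique() == blocks
        assert (df.groupby("block").size() == total).all()

    def test_exp2_composition_and_test_block(self, exp2_session):
        df = session_to_dataframe(exp2_session)
        assert (df.groupby("block").size() == 82).all()
        train = df[df["block"] == 0]["condition"].value_counts().to_dict()
        assert train == {"RAN": 36, "RANREG": 9, "RANREGr": 9,
                         "PATinRAN": 9, "PATinRANr": 9, "STEP": 5, "CONT": 5}
        test = df[df["block"] == 4]
        counts = test["condition"].value_counts().to_dict()
        assert counts == {"RAN": 36, "RANREG": 18, "RANREGr": 9,
                          "RANREGr*": 9, "STEP": 5, "CONT": 5}
        # test-block sequences are 109 tones, adjacent-cycle transition at 69
        assert (test["n_tones"] == 109).all()
        tt = test[test["condition"].isin(["RANREG", "RANREGr", "RANREGr*"])]
        assert (tt["transition_index"] == 69).all()

    def test_exp2_starred_patterns_are_the_patinranr_patterns(self, exp2_session):
        df = session_to_dataframe(exp2_session)
        starred = set(df[df["condition"] == "RANREGr*"]["pattern_id"])
        patr = set(df[df["condition"] == "PATinRANr"]["pattern_id"])
        assert starred == patr

    def test_exp1b_reversed_block(self):
        session = schedule_session("1B", np.random.default_rng(12))
        regr1 = session.patterns["REGr1"].symbols
        for t in session.trials:
            if t.condition == "RANREGr" and t.sequence.pattern_ref == "REGr1":
                tail = t.sequence.symbols[t.sequence.transition_index:][:20]
                if t.block == 4:
                    assert (tail == tuple(reversed(regr1))).all()
                else:
                    assert (tail == regr1).all()

    def test_exp4_phase_shift_bins(self):
        session = schedule_session("4", np.random.default_rng(13))
        shifts = {}
        for t in session.trials:
            if t.block == 3 and t.condition == "RANREGr":
                pat = session.patterns[t.sequence.pattern_ref].symbols
                tail = tuple(t.sequence.symbols[t.sequence.transition_index:][:20])
                shift = next(s for s in range(20)
                             if tail == tuple(pat[(i + s) % 20]
                                              for i in range(20)))
                shifts.setdefault(t.sequence.pattern_ref, []).append(shift)
        bins = [(2, 7), (8, 13), (14, 19)]
        for pid, ss in shifts.items():
            assert len(ss) == 3
            used = sorted(next(i for i, (lo, hi) in enumerate(bins)
                               if lo <= s <= hi) for s in ss)
            assert used == [0, 1, 2]  # one presentation per bin

    def test_schedule_reproducible(self):
        a = session_to_dataframe(schedule_session("1A", 99))
        b = session_to_dataframe(schedule_session("1A", 99))
        assert a.equals(b)

    def test_unknown_experiment(self):
        with pytest.raises(ValueError):
            schedule_session("9Z", np.random.default_rng(0))


def test_pattern_space_exceeds_a_trillion():
    assert n_distinct_patterns(20) == math.factorial(20)
    assert n_distinct_patterns(20) > 10 ** 12


def test_conditions_share_frequency_marginals():
    # RANREG differs from RAN only in symbol order: per-trial histograms of
    # a RANREG (3.5 cycles of a permutation + RAN) match RAN up to noise
    rng = np.random.default_rng(21)
    h_ran = np.zeros(POOL_SIZE)
    h_rr = np.zeros(POOL_SIZE)
    n = 400
    for _ in range(n):
        h_ran += np.bincount(generate_ran(140, POOL_SIZE, rng).symbols,
                             minlength=POOL_SIZE)
        pat = generate_reg_cycle(POOL_SIZE, rng)
        h_rr += np.bincount(assemble_ranreg(pat, 140, (3000, 4000),
                                            rng).symbols,
                            minlength=POOL_SIZE)
    assert np.allclose(h_ran / n, 7.0, atol=0.35)
    assert np.allclose(h_rr / n, 7.0, atol=0.35)
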