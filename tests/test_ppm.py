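"""PPM model: bookkeeping, smoothing, information content, oracle parity."""

import math

import numpy as np
import pytest

from seqmem.decay import DecayParams
from seqmem.ppm import PPMModel
from seqmem.ppm_oracle import OraclePPM


class TestBookkeeping:
    def test_unigram_records_count_symbols(self):
        m = PPMModel(alphabet_size=5, order_bound=2)
        syms = np.array([0, 1, 2, 3, 4, 0, 1, 2], dtype=np.int64)
        m.information_content(syms)
        assert m.n_unigram_records == 8

    def test_no_ngram_beyond_order_bound(self):
        m = PPMModel(alphabet_size=3, order_bound=2)
        m.information_content(np.array([0, 1, 2, 0, 1, 2], dtype=np.int64))
        assert m.ngram_record_count((0, 1, 2)) == 2          # length 3 ok
        with pytest.raises(ValueError):
            m.ngram_record_count((0, 1, 2, 0))               # length 4 > bound

    def test_trial_boundary_resets_context(self):
        # first symbol after a boundary contributes only a length-1 record
        m = PPMModel(alphabet_size=3, order_bound=2)
        m.information_content(np.array([0, 1], dtype=np.int64))
        m.information_content(np.array([2], dtype=np.int64))
        assert m.ngram_record_count((1, 2)) == 0
        assert m.ngram_record_count((2,)) == 1
        # within-trial bigram was stored
        assert m.ngram_record_count((0, 1)) == 1

    def test_out_of_alphabet_symbol_rejected(self):
        m = PPMModel(alphabet_size=3)
        with pytest.raises(ValueError):
            m.information_content(np.array([0, 5], dtype=np.int64))

    def test_oracle_rejects_bad_inputs(self):
        o = OraclePPM(alphabet_size=3)
        with pytest.raises(ValueError):
            o.observe(7, 0.0)
        o.observe(1, 1.0)
        with pytest.raises(ValueError):
            o.observe(1, 0.5)  # time must be non-decreasing


class TestPrediction:
    def test_empty_store_is_uniform(self):
        m = PPMModel(alphabet_size=20)
        p = m.predict(())
        assert np.allclose(p, 1 / 20, atol=1e-12)

    def test_abab_prefers_continuation(self):
        # hand-evaluated smoothing recursion: after "a b a b", context "b"
        # gives P = (31/36, 4/36, 1/36)
        m = PPMModel(alphabet_size=3, order_bound=4)
        probs = m.predictive_matrix(np.array([0, 1, 0, 1, 0], dtype=np.int64))
        assert probs[4] == pytest.approx([31 / 36, 4 / 36, 1 / 36], abs=1e-12)
        assert probs[4][0] > probs[4][1] > probs[4][2]

    def test_distributions_normalise(self):
        rng = np.random.default_rng(3)
        m = PPMModel(alphabet_size=6, order_bound=3)
        for _ in range(5):
            probs = m.predictive_matrix(rng.integers(0, 6, 50))
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
            assert (probs > 0).all()

    def test_alphabet_relabelling_symmetry(self):
        # permuting symbol labels permutes predictions identically
        rng = np.random.default_rng(4)
        seq = rng.integers(0, 4, 60)
        perm = np.array([2, 0, 3, 1])
        m1 = PPMModel(alphabet_size=4, order_bound=3)
        m2 = PPMModel(alphabet_size=4, order_bound=3)
        p1 = m1.predictive_matrix(seq)
        p2 = m2.predictive_matrix(perm[seq])
        # P2(perm[x] | relabelled context) == P1(x | context)
        assert np.allclose(p1, p2[:, perm], atol=1e-12)


class TestInformationContent:
    def test_first_tone_of_session_is_log2_alphabet(self):
        m = PPMModel(alphabet_size=20)
        ic = m.information_content(np.array([7], dtype=np.int64))
        assert ic.values[0] == pytest.approx(math.log2(20), abs=1e-12)

    def test_repeated_symbol_ic_strictly_decreasing(self):
        m = PPMModel(alphabet_size=2, order_bound=4)
        ic = m.information_content(np.zeros(10, dtype=np.int64)).values
        assert (np.diff(ic) < 0).all()
        # oracle agrees exactly
        o = OraclePPM(alphabet_size=2, order_bound=4)
        ic_o = o.information_content(np.zeros(10, dtype=int),
                                     np.arange(10) * 0.05)
        assert np.allclose(ic, ic_o, atol=1e-12)

    def test_ic_additivity(self):
        # total IC equals -log2 of the product of per-tone probabilities
        rng = np.random.default_rng(5)
        m = PPMModel(alphabet_size=5, order_bound=3)
        seq = rng.integers(0, 5, 40)
        probs = m.predictive_matrix(seq)
        m2 = PPMModel(alphabet_size=5, order_bound=3)
        ic = m2.information_content(seq).values
        assert ic.sum() == pytest.approx(
            -np.log2(probs[np.arange(40), seq]).sum(), abs=1e-6)

    def test_unconstrained_ranreg_second_cycle_drop(self, exp1a_session):
        # with perfect memory the second regularity cycle is predictable
        m = PPMModel()
        for tr in exp1a_session.trials[:80]:
            ic = m.information_content(tr.sequence, gap_after=1.0)
            if tr.condition == "RANREG" and tr.trial_index > 20:
                t = tr.sequence.transition_index
                ran = ic.values[20:t].mean()
                cyc2 = ic.values[t + 20:t + 40].mean()
                assert cyc2 < ran


class TestOracleParity:
    """The fast engine against the brute-force reference implementation."""

    def test_unconstrained_multi_trial(self):
        rng = np.random.default_rng(11)
        m = PPMModel(alphabet_size=4, order_bound=3)
        o = OraclePPM(alphabet_size=4, order_bound=3)
        t = 0.0
        for _ in range(6):
            seq = rng.integers(0, 4, 30)
            ic_m = m.information_content(seq, gap_after=1.0).values
            ic_o = o.information_content(seq, t + np.arange(30) * 0.05)
            t += 30 * 0.05 + 1.0
            assert np.allclose(ic_m, ic_o, atol=1e-9)

    def test_decay_noise_free_multi_trial(self):
        par = DecayParams(noise=0.0, buffer_capacity=5, stm_duration=2.0,
                          ltm_half_life=30.0, order_bound=3)
        rng = np.random.default_rng(12)
        m = PPMModel(alphabet_size=4, decay=par)
        o = OraclePPM(alphabet_size=4, order_bound=3, decay=par)
        t = 0.0
        for _ in range(8):
            seq = rng.integers(0, 4, 25)
            ic_m = m.information_content(seq, gap_after=2.0).values
            ic_o = o.information_content(seq, t + np.arange(25) * 0.05)
            t += 25 * 0.05 + 2.0
            assert np.allclose(ic_m, ic_o, atol=1e-8)

    def test_degenerate_decay_reproduces_unconstrained(self):
        # all phase weights 1, no decay, no noise == perfect memory
        rng = np.random.default_rng(13)
        m_flat = PPMModel(alphabet_size=5,
                          decay=DecayParams.unconstrained())
        m_none = PPMModel(alphabet_size=5, order_bound=4)
        for _ in range(4):
            seq = rng.integers(0, 5, 40)
            a = m_flat.information_content(seq, gap_after=1.0).values
            b = m_none.information_content(seq, gap_after=1.0).values
            assert (a == b).all()

    def test_noisy_retrieval_is_seeded_and_reproducible(self):
        par = DecayParams()  # noise 1.3
        seq = np.arange(20, dtype=np.int64) % 20
        a = PPMModel(decay=par, seed=42).information_content(seq).values
        b = PPMModel(decay=par, seed=42).information_content(seq).values
        c = PPMModel(decay=par, seed=43).information_content(seq).values
        assert (a == b).all()
        assert not (a == c).all()

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError):
            PPMModel(decay=DecayParams())
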