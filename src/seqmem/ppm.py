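"""Variable-order PPM sequence model with optional memory decay.

`PPMModel` wraps the numba engine: a timestamped n-gram store (n = 1 to
order_bound + 1), interpolated-smoothing prediction, and per-tone
information content IC = -log2 P(tone | context).  In the unconstrained
mode every historic observation counts fully (perfect memory); with a
`DecayParams` the counts are weighted by the three-phase decay kernel and
perturbed by retrieval noise.  The prediction context resets at trial
boundaries while the store persists across trials -- this is what carries
cross-trial memory for reoccurring patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from seqmem import _engine
from seqmem.decay import DecayParams
from seqmem.stimuli import TONE_DURATION_S, ToneSequence

DEFAULT_ALPHABET = 20
DEFAULT_ORDER_BOUND = 4


@dataclass
class ICTrace:
    """Per-tone information content (bits) for one trial."""

    values: np.ndarray
    condition: str = "RAN"
    transition_index: int | None = None
    trial_index: int | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


class PPMModel:
    """Online PPM model over a fixed symbol alphabet.

    Parameters
    ----------
    alphabet_size:
        Number of distinct symbols (20 tone frequencies by default).
    order_bound:
        Maximum Markov order (4: n-grams up to length 5).
    decay:
        Memory-decay parameters; ``None`` gives the unconstrained
        (perfect-memory) model.
    seed:
        Seed for the retrieval-noise stream (required only when
        ``decay.noise > 0``).
    """

    def __init__(self, alphabet_size: int = DEFAULT_ALPHABET,
                 order_bound: int | None = None,
                 decay: DecayParams | None = None,
                 seed: int | None = None):
        if alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if order_bound is None:
            order_bound = (decay.order_bound if decay is not None
                           else DEFAULT_ORDER_BOUND)
        self.A = alphabet_size
        self.B = order_bound
        self.decay = decay
        size = _engine.store_size(alphabet_size, order_bound)
        self._bases = _engine.store_bases(alphabet_size, order_bound)
        self._nrec = np.zeros(size, dtype=np.int64)
        self.time = 0.0          # next available clock time (s)
        self.items = 0           # global tone counter
        self._trials_seen = 0

        decay_on = decay is not None and not _is_unconstrained(decay)
        self._decay_on = decay_on
        if decay_on:
            self._buf_cnt = np.zeros(size, dtype=np.int64)
            self._stm_val = np.zeros(size)
            self._stm_t = np.zeros(size)
            self._ltm_val = np.zeros(size)
            self._ltm_t = np.zeros(size)
            self._ltm_cnt = np.zeros(size, dtype=np.int64)
            cap0 = 1 << 14
            self._item_times = np.zeros(cap0)
            self._bq_bucket = np.zeros(cap0 * (order_bound + 1), dtype=np.int64)
            self._bq_iobs = np.zeros(cap0 * (order_bound + 1), dtype=np.int64)
            self._sq_bucket = np.zeros(cap0 * (order_bound + 1), dtype=np.int64)
            self._sq_texit = np.zeros(cap0 * (order_bound + 1))
            self._bq_state = np.zeros(2, dtype=np.int64)
            self._sq_state = np.zeros(2, dtype=np.int64)
            if decay.noise > 0.0:
                if seed is None:
                    raise ValueError("retrieval noise requires a seed")
                _engine.seed_engine_rng(seed)
        else:
            one = np.zeros(1)
            onei = np.zeros(1, dtype=np.int64)
            self._buf_cnt = onei
            self._stm_val = self._stm_t = one
            self._ltm_val = self._ltm_t = one
            self._ltm_cnt = onei
            self._item_times = np.zeros(1)
            self._bq_bucket = self._bq_iobs = onei.copy()
            self._sq_bucket = onei.copy()
            self._sq_texit = one.copy()
            self._bq_state = np.zeros(2, dtype=np.int64)
            self._sq_state = np.zeros(2, dtype=np.int64)

        self._fparams = np.zeros(_engine.N_FPARAMS)
        self._iparams = np.zeros(_engine.N_IPARAMS, dtype=np.int64)
        p = decay if decay is not None else DecayParams.unconstrained()
        k_stm = p.stm_rate
        if not np.isfinite(k_stm):
            k_stm = 1e30
        k_ltm = 0.0 if not np.isfinite(p.ltm_half_life) else np.log(2.0) / p.ltm_half_life
        self._fparams[:] = [p.buffer_weight, p.stm_weight, k_stm,
                            p.stm_duration, p.ltm_weight, k_ltm,
                            p.ltm_asymptote, p.noise, TONE_DURATION_S]
        self._iparams[:] = [alphabet_size, order_bound,
                            p.buffer_capacity, int(decay_on)]

    # -- capacity management ------------------------------------------------

    def _ensure_capacity(self, n_new: int) -> None:
        if not self._decay_on:
            return
        need_items = self.items + n_new + 2
        if need_items > len(self._item_times):
            grown = np.zeros(max(need_items, 2 * len(self._item_times)))
            grown[:len(self._item_times)] = self._item_times
            self._item_times = grown
        need_q = self._bq_state[1] + n_new * (self.B + 1) + 2
        if need_q > len(self._bq_bucket):
            for name in ("_bq_bucket", "_bq_iobs"):
                old = getattr(self, name)
                grown = np.zeros(max(need_q, 2 * len(old)), dtype=old.dtype)
                grown[:len(old)] = old
                setattr(self, name, grown)
        need_q = self._sq_state[1] + n_new * (self.B + 1) + 2
        if need_q > len(self._sq_bucket):
            for name in ("_sq_bucket", "_sq_texit"):
                old = getattr(self, name)
                grown = np.zeros(max(need_q, 2 * len(old)), dtype=old.dtype)
                grown[:len(old)] = old
                setattr(self, name, grown)

    # -- the public surface -------------------------------------------------

    def information_content(self, trial: ToneSequence | np.ndarray,
                            t0: float | None = None,
                            gap_after: float = 0.0) -> ICTrace:
        """Feed one trial through the model and return its IC trace.

        Each tone is predicted from the within-trial context, scored
        (IC = -log2 P), then observed.  `t0` defaults to the model clock;
        `gap_after` advances the clock beyond the trial end (silent
        inter-trial interval).
        """
        if isinstance(trial, ToneSequence):
            symbols = trial.symbols
            condition = trial.condition
            transition = trial.transition_index
        else:
            symbols = np.asarray(trial, dtype=np.int64)
            condition, transition = "RAN", None
        if symbols.min(initial=0) < 0 or symbols.max(initial=0) >= self.A:
            raise ValueError("symbol outside the alphabet")
        if t0 is None:
            t0 = self.time
        elif t0 < self.time:
            raise ValueError("t0 precedes the model clock")
        self._ensure_capacity(len(symbols))
        ic = np.empty(len(symbols))
        self.items = _engine.run_trial(
            symbols, float(t0), self.items, self._bases, self._nrec,
            self._buf_cnt, self._stm_val, self._stm_t,
            self._ltm_val, self._ltm_t, self._ltm_cnt,
            self._item_times, self._bq_bucket, self._bq_iobs, self._bq_state,
            self._sq_bucket, self._sq_texit, self._sq_state,
            self._fparams, self._iparams, ic)
        self.time = t0 + len(symbols) * TONE_DURATION_S + gap_after
        self._trials_seen += 1
        return ICTrace(ic, condition, transition,
                       trial_index=self._trials_seen - 1, t0=float(t0))

    def reset(self) -> None:
        """Forget everything: empty store, clock and counters at zero."""
        self._nrec[:] = 0
        if self._decay_on:
            self._buf_cnt[:] = 0
            self._stm_val[:] = 0.0
            self._stm_t[:] = 0.0
            self._ltm_val[:] = 0.0
            self._ltm_t[:] = 0.0
            self._ltm_cnt[:] = 0
            self._bq_state[:] = 0
            self._sq_state[:] = 0
        self.time = 0.0
        self.items = 0
        self._trials_seen = 0

    def predictive_matrix(self, trial: ToneSequence | np.ndarray,
                          t0: float | None = None,
                          gap_after: float = 0.0) -> np.ndarray:
        """Feed one trial and return the (n_tones, A) predictive matrix.

        Row i is the full distribution P(. | context_i) used to score tone
        i, before observing it.
        """
        symbols = (trial.symbols if isinstance(trial, ToneSequence)
                   else np.asarray(trial, dtype=np.int64))
        if t0 is None:
            t0 = self.time
        self._ensure_capacity(len(symbols))
        probs = np.empty((len(symbols), self.A))
        self.items = _engine.run_trial_probs(
            symbols, float(t0), self.items, self._bases, self._nrec,
            self._buf_cnt, self._stm_val, self._stm_t,
            self._ltm_val, self._ltm_t, self._ltm_cnt,
            self._item_times, self._bq_bucket, self._bq_iobs, self._bq_state,
            self._sq_bucket, self._sq_texit, self._sq_state,
            self._fparams, self._iparams, probs)
        self.time = t0 + len(symbols) * TONE_DURATION_S + gap_after
        self._trials_seen += 1
        return probs

    def predict(self, context=()) -> np.ndarray:
        """Predictive distribution given a within-trial context (no update)."""
        context = np.asarray(list(context) + [0], dtype=np.int64)
        i = len(context) - 1
        self._ensure_capacity(1)
        return _engine.predict_only(
            context, i, self.time, self.items, self._item_times,
            self._bases, self._nrec,
            self._buf_cnt, self._stm_val, self._stm_t,
            self._ltm_val, self._ltm_t, self._ltm_cnt,
            self._bq_bucket, self._bq_iobs, self._bq_state,
            self._sq_bucket, self._sq_texit, self._sq_state,
            self._fparams, self._iparams)

    @property
    def n_unigram_records(self) -> int:
        return int(self._nrec[:self.A].sum())

    def ngram_record_count(self, gram) -> int:
        """Raw (undecayed) record count of one n-gram."""
        gram = tuple(int(x) for x in gram)
        o = len(gram) - 1
        if not 0 <= o <= self.B:
            raise ValueError("n-gram length outside 1..order_bound+1")
        # context code: matches the engine's incremental encoding
        code = 0
        mult = 1
        for k in range(1, o + 1):
            code += gram[o - k] * mult
            mult *= self.A
        b = int(self._bases[o]) + code * self.A + gram[-1]
        return int(self._nrec[b])


def _is_unconstrained(p: DecayParams) -> bool:
    """True when the kernel degenerates to weight-1 everywhere, no noise."""
    return (p.noise == 0.0 and p.buffer_weight == 1.0 and p.stm_weight == 1.0
            and p.ltm_weight == 1.0 and not np.isfinite(p.ltm_half_life))


def ic_trace_dataframe(traces: list[ICTrace]):
    """Long-format per-tone IC table for CSV export."""
    import pandas as pd

    rows = []
    for tr in traces:
        for i, v in enumerate(tr.values):
            rows.append({"trial_index": tr.trial_index, "tone_index": i,
                         "time_s": tr.t0 + i * TONE_DURATION_S,
                         "condition": tr.condition, "ic_bits": v})
    return pd.DataFrame(rows)
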