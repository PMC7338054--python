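"""Brute-force reference PPM: the independent oracle for the fast engine.

This implementation keeps every n-gram observation as an explicit
timestamped record in a dictionary and evaluates the interpolated-smoothing
recursion and the decay kernel directly from first principles, with no
aggregation tricks.  It is deliberately simple and slow; the test suite
uses it to pin the numba engine on small alphabets and short sessions.
"""

from __future__ import annotations

import math

import numpy as np

from seqmem.decay import DecayParams, observation_weight


class OraclePPM:
    """Dictionary-based variable-order PPM with optional memory decay."""

    def __init__(self, alphabet_size: int = 20, order_bound: int = 4,
                 decay: DecayParams | None = None,
                 rng: np.random.Generator | None = None):
        self.A = alphabet_size
        self.B = order_bound
        self.decay = decay
        self.rng = rng
        self.records: dict[tuple[int, ...], list[tuple[float, int]]] = {}
        self.item_times: list[float] = []
        self.items = 0
        self._trial: list[int] = []

    # -- bookkeeping --------------------------------------------------------

    def new_trial(self) -> None:
        """Reset the prediction context; the record store persists."""
        self._trial = []

    def observe(self, symbol: int, time: float) -> None:
        if not 0 <= symbol < self.A:
            raise ValueError("symbol outside the alphabet")
        if self.item_times and time < self.item_times[-1]:
            raise ValueError("time must be non-decreasing")
        self.item_times.append(time)
        ctx = self._trial
        for L in range(1, min(len(ctx), self.B) + 2):
            gram = tuple(ctx[len(ctx) - (L - 1):]) + (symbol,)
            self.records.setdefault(gram, []).append((time, self.items))
        self._trial.append(symbol)
        self.items += 1

    def _count(self, gram: tuple[int, ...], t_now: float) -> float:
        recs = self.records.get(gram, [])
        if self.decay is None:
            return float(len(recs))
        p = self.decay
        if not recs and p.noise == 0.0:
            return 0.0
        i_now = self.items
        total = 0.0
        for t_obs, i_obs in recs:
            j = i_obs + p.buffer_capacity + 1
            if j < i_now:
                t_exit = self.item_times[j]
            elif j == i_now:
                # the evicting item is the tone about to be presented
                t_exit = t_now
            else:
                t_exit = None  # still inside the buffer
            total += observation_weight(t_obs, i_obs, t_now, i_now, p, t_exit)
        if p.noise > 0.0:
            if self.rng is None:
                raise ValueError("retrieval noise requires an rng")
            total += p.noise * self.rng.standard_normal()
        return max(total, 0.0)

    # -- prediction ---------------------------------------------------------

    def predict(self, t_now: float | None = None) -> np.ndarray:
        """Predictive distribution for the next tone of the current trial.

        Interpolated smoothing: starting from the uniform 1/A distribution
        (order -1), each order o = 0..min(|context|, order_bound) blends in
        its maximum-likelihood estimate with weight N/(N + t), where N is
        the total (weighted) count after the order-o context and t the
        number of distinct continuations observed.
        """
        if t_now is None:
            t_now = self.item_times[-1] + 0.05 if self.item_times else 0.0
        p = np.full(self.A, 1.0 / self.A)
        ctx = self._trial
        for o in range(min(len(ctx), self.B) + 1):
            suffix = tuple(ctx[len(ctx) - o:])
            counts = np.array([self._count(suffix + (x,), t_now)
                               for x in range(self.A)])
            total = counts.sum()
            if total > 0.0:
                t_distinct = float((counts > 0).sum())
                p = (counts + t_distinct * p) / (total + t_distinct)
        return p

    def information_content(self, symbols, times) -> np.ndarray:
        """Per-tone IC (bits) of one trial, updating the model as it goes."""
        self.new_trial()
        ic = np.empty(len(symbols))
        for i, (s, t) in enumerate(zip(symbols, times)):
            p = self.predict(t_now=t)
            ic[i] = -math.log2(p[s])
            self.observe(int(s), float(t))
        return ic


def max_mw_statistic(x: np.ndarray, two_sided: bool = False) -> float:
    """Max standardised Mann-Whitney rank statistic over all splits.

    Direct O(n^2) evaluation with midranks and tie-corrected variance;
    oracle for the sequential detector kernel.  Positive values indicate
    the later segment lies below the earlier one.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    n = len(x)
    r = rankdata(x)
    _, counts = np.unique(x, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie <= 0.0:
        return 0.0
    best = -np.inf
    w = 0.0
    for k in range(1, n):
        w += r[k - 1]
        var = k * (n - k) * (n + 1.0) / 12.0 * tie
        z = (w - k * (n + 1.0) / 2.0) / math.sqrt(var)
        if two_sided:
            z = abs(z)
        best = max(best, z)
    return best
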