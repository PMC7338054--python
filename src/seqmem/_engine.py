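"""Numba kernels for the PPM sequence model and its memory-decay store.

The store is a flat array indexed by n-gram: bucket ``base[o] + code(ctx)*A
+ sym`` holds the aggregate state of all observations of the n-gram
``ctx + (sym,)`` (order ``o = len(ctx)``, contexts encoded base-A with the
oldest symbol most significant).  Rather than keeping per-record
timestamps, each bucket carries phase aggregates that are updated lazily:

* ``buf_cnt``       -- records still inside the echoic buffer (weight
                       ``buffer_weight`` each);
* ``stm_val/stm_t`` -- summed STM weights, valid at time ``stm_t`` and
                       decayed forward on touch with rate ``k_stm``;
* ``ltm_val/ltm_t`` -- summed decaying LTM parts (above the asymptote),
                       rate ``k_ltm``; ``ltm_cnt`` counts records at the
                       asymptote.

Two global FIFO queues move records between phases: records leave the
buffer when ``buffer_capacity`` further items have been presented (the exit
time is the onset of the item that evicts them) and leave STM
``stm_duration`` seconds after buffer exit.  Queues are drained eagerly at
every tone onset, so the aggregates track the closed-form kernel exactly up
to one processing step.

This organisation makes both prediction and update O(alphabet x order) per
tone independent of history length, which is what lets full multi-block
sessions run in seconds.  The pure-Python reference implementation in
``ppm_oracle`` computes the same quantities directly from per-record
timestamps and pins these kernels in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# float-parameter vector layout
FP_BUFFER_WEIGHT = 0
FP_STM_WEIGHT = 1
FP_K_STM = 2
FP_STM_DURATION = 3
FP_LTM_WEIGHT = 4
FP_K_LTM = 5
FP_LTM_ASYM = 6
FP_NOISE = 7
FP_DT = 8
N_FPARAMS = 9

# int-parameter vector layout
IP_ALPHABET = 0
IP_ORDER_BOUND = 1
IP_BUFFER_CAP = 2
IP_DECAY = 3            # 0 = unconstrained (counts are plain tallies)
N_IPARAMS = 4


def store_size(alphabet_size: int, order_bound: int) -> int:
    """Number of n-gram buckets for n-grams of length 1..order_bound+1."""
    return sum(alphabet_size ** (o + 1) for o in range(order_bound + 1))


def store_bases(alphabet_size: int, order_bound: int) -> np.ndarray:
    bases = np.zeros(order_bound + 1, dtype=np.int64)
    for o in range(1, order_bound + 1):
        bases[o] = bases[o - 1] + alphabet_size ** o
    return bases


@njit(cache=True)
def seed_engine_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _sync_bucket(b, t, stm_val, stm_t, ltm_val, ltm_t, k_stm, k_ltm):
    dt = t - stm_t[b]
    if dt > 0.0:
        stm_val[b] *= np.exp(-k_stm * dt)
        stm_t[b] = t
    dt = t - ltm_t[b]
    if dt > 0.0:
        ltm_val[b] *= np.exp(-k_ltm * dt)
        ltm_t[b] = t


@njit(cache=True)
def _drain_queues(t_now, i_now, item_times,
                  buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
                  bq_bucket, bq_iobs, bq_state,
                  sq_bucket, sq_texit, sq_state,
                  fparams, iparams):
    cap = iparams[IP_BUFFER_CAP]
    stm_w = fparams[FP_STM_WEIGHT]
    k_stm = fparams[FP_K_STM]
    k_ltm = fparams[FP_K_LTM]
    stm_dur = fparams[FP_STM_DURATION]
    ltm_w = fparams[FP_LTM_WEIGHT]
    asym = fparams[FP_LTM_ASYM]

    # buffer -> STM: a record observed at item i leaves the buffer at the
    # onset of item i + cap + 1
    while bq_state[0] < bq_state[1]:
        i_obs = bq_iobs[bq_state[0]]
        exit_item = i_obs + cap + 1
        if exit_item > i_now:
            break
        b = bq_bucket[bq_state[0]]
        bq_state[0] += 1
        t_exit = item_times[exit_item]
        buf_cnt[b] -= 1
        if t_exit >= stm_t[b]:
            _sync_bucket(b, t_exit, stm_val, stm_t, ltm_val, ltm_t,
                         k_stm, k_ltm)
            stm_val[b] += stm_w
        else:
            # bucket already synced past the exit time: add the record at
            # its decayed value
            stm_val[b] += stm_w * np.exp(-k_stm * (stm_t[b] - t_exit))
        sq_bucket[sq_state[1]] = b
        sq_texit[sq_state[1]] = t_exit
        sq_state[1] += 1

    # STM -> LTM: stm_duration seconds after buffer exit
    while sq_state[0] < sq_state[1]:
        t_exit = sq_texit[sq_state[0]]
        t_dead = t_exit + stm_dur
        if t_dead > t_now:
            break
        b = sq_bucket[sq_state[0]]
        sq_state[0] += 1
        _sync_bucket(b, t_now, stm_val, stm_t, ltm_val, ltm_t, k_stm, k_ltm)
        stm_val[b] -= stm_w * np.exp(-k_stm * (t_now - t_exit))
        if stm_val[b] < 0.0:
            stm_val[b] = 0.0
        # LTM entry value, back-dated to the true phase boundary
        ltm_val[b] += (ltm_w - asym) * np.exp(-k_ltm * (t_now - t_dead))
        ltm_cnt[b] += 1


@njit(cache=True)
def _bucket_count(b, t_now, nrec,
                  buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
                  fparams, iparams):
    if iparams[IP_DECAY] == 0:
        return float(nrec[b])
    k_stm = fparams[FP_K_STM]
    k_ltm = fparams[FP_K_LTM]
    _sync_bucket(b, t_now, stm_val, stm_t, ltm_val, ltm_t, k_stm, k_ltm)
    return (buf_cnt[b] * fparams[FP_BUFFER_WEIGHT] + stm_val[b] +
            ltm_val[b] + ltm_cnt[b] * fparams[FP_LTM_ASYM])


@njit(cache=True)
def _predict(symbols, i, t_now, bases, nrec,
             buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
             fparams, iparams, p):
    """Interpolated-smoothing predictive distribution for tone i.

    Blends maximum-likelihood n-gram estimates from order 0 up to
    min(i, order_bound), starting from the uniform 1/A base distribution;
    escape weight at each order is t/(N + t) with N the total (possibly
    decayed, noise-perturbed) count after the context and t the number of
    distinct continuations.
    """
    A = iparams[IP_ALPHABET]
    B = iparams[IP_ORDER_BOUND]
    noise = fparams[FP_NOISE]
    for x in range(A):
        p[x] = 1.0 / A
    o_max = i if i < B else B
    c = np.empty(A)
    code = 0
    mult = 1
    for o in range(o_max + 1):
        if o > 0:
            code = code + symbols[i - o] * mult
            mult *= A
        base_idx = bases[o] + code * A
        N = 0.0
        tdis = 0.0
        for x in range(A):
            b = base_idx + x
            if nrec[b] > 0:
                cnt = _bucket_count(b, t_now, nrec, buf_cnt, stm_val, stm_t,
                                    ltm_val, ltm_t, ltm_cnt, fparams, iparams)
            else:
                cnt = 0.0
            # retrieval noise perturbs every candidate count, stored or
            # not: phantom counts are what swamp weak memory traces
            if noise > 0.0:
                cnt += noise * np.random.normal(0.0, 1.0)
                if cnt < 0.0:
                    cnt = 0.0
            c[x] = cnt
            N += cnt
            if cnt > 0.0:
                tdis += 1.0
        if N > 0.0:
            denom = N + tdis
            for x in range(A):
                p[x] = (c[x] + tdis * p[x]) / denom


@njit(cache=True)
def _observe(symbols, i, t_now, i_now, bases, nrec, buf_cnt,
             item_times, bq_bucket, bq_iobs, bq_state, iparams):
    A = iparams[IP_ALPHABET]
    B = iparams[IP_ORDER_BOUND]
    if iparams[IP_DECAY] != 0:
        item_times[i_now] = t_now
    sym = symbols[i]
    o_max = i if i < B else B
    code = 0
    mult = 1
    for o in range(o_max + 1):
        if o > 0:
            code = code + symbols[i - o] * mult
            mult *= A
        b = bases[o] + code * A + sym
        nrec[b] += 1
        if iparams[IP_DECAY] != 0:
            buf_cnt[b] += 1
            bq_bucket[bq_state[1]] = b
            bq_iobs[bq_state[1]] = i_now
            bq_state[1] += 1


@njit(cache=True)
def run_trial(symbols, t0, i_start, bases, nrec,
              buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
              item_times, bq_bucket, bq_iobs, bq_state,
              sq_bucket, sq_texit, sq_state,
              fparams, iparams, ic_out):
    """Feed one trial through the model: predict-then-observe per tone.

    Context resets at the trial boundary (predictions near the trial start
    use shorter contexts) while the store persists.  Returns the global
    item counter after the trial.
    """
    dt = fparams[FP_DT]
    n = symbols.shape[0]
    A = iparams[IP_ALPHABET]
    p = np.empty(A)
    i_now = i_start
    for i in range(n):
        t_now = t0 + i * dt
        if iparams[IP_DECAY] != 0:
            # records whose buffer-exit item is the tone about to be
            # presented exit at its onset
            item_times[i_now] = t_now
            _drain_queues(t_now, i_now, item_times,
                          buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
                          bq_bucket, bq_iobs, bq_state,
                          sq_bucket, sq_texit, sq_state, fparams, iparams)
        _predict(symbols, i, t_now, bases, nrec, buf_cnt, stm_val, stm_t,
                 ltm_val, ltm_t, ltm_cnt, fparams, iparams, p)
        ic_out[i] = -np.log2(p[symbols[i]])
        _observe(symbols, i, t_now, i_now, bases, nrec, buf_cnt,
                 item_times, bq_bucket, bq_iobs, bq_state, iparams)
        i_now += 1
    return i_now


@njit(cache=True)
def run_trial_probs(symbols, t0, i_start, bases, nrec,
                    buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
                    item_times, bq_bucket, bq_iobs, bq_state,
                    sq_bucket, sq_texit, sq_state,
                    fparams, iparams, p_out):
    """As `run_trial` but storing the full predictive distribution per tone."""
    dt = fparams[FP_DT]
    n = symbols.shape[0]
    A = iparams[IP_ALPHABET]
    p = np.empty(A)
    i_now = i_start
    for i in range(n):
        t_now = t0 + i * dt
        if iparams[IP_DECAY] != 0:
            item_times[i_now] = t_now
            _drain_queues(t_now, i_now, item_times,
                          buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
                          bq_bucket, bq_iobs, bq_state,
                          sq_bucket, sq_texit, sq_state, fparams, iparams)
        _predict(symbols, i, t_now, bases, nrec, buf_cnt, stm_val, stm_t,
                 ltm_val, ltm_t, ltm_cnt, fparams, iparams, p)
        for x in range(A):
            p_out[i, x] = p[x]
        _observe(symbols, i, t_now, i_now, bases, nrec, buf_cnt,
                 item_times, bq_bucket, bq_iobs, bq_state, iparams)
        i_now += 1
    return i_now


@njit(cache=True)
def predict_only(symbols, i, t_now, i_now, item_times, bases, nrec,
                 buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
                 bq_bucket, bq_iobs, bq_state,
                 sq_bucket, sq_texit, sq_state,
                 fparams, iparams):
    """One predictive distribution (context = symbols[:i]) without update."""
    A = iparams[IP_ALPHABET]
    p = np.empty(A)
    if iparams[IP_DECAY] != 0:
        item_times[i_now] = t_now
        _drain_queues(t_now, i_now, item_times,
                      buf_cnt, stm_val, stm_t, ltm_val, ltm_t, ltm_cnt,
                      bq_bucket, bq_iobs, bq_state,
                      sq_bucket, sq_texit, sq_state, fparams, iparams)
    _predict(symbols, i, t_now, bases, nrec, buf_cnt, stm_val, stm_t,
             ltm_val, ltm_t, ltm_cnt, fparams, iparams, p)
    return p


# ---------------------------------------------------------------------------
# sequential Mann-Whitney changepoint kernels


@njit(cache=True)
def _tie_factor(x, m, scratch):
    """Variance correction 1 - sum(t^3 - t)/(m^3 - m) from midrank ties."""
    for i in range(m):
        scratch[i] = x[i]
    sub = scratch[:m]
    sub.sort()
    tie_sum = 0.0
    run = 1
    for i in range(1, m):
        if sub[i] == sub[i - 1]:
            run += 1
        else:
            if run > 1:
                tie_sum += run ** 3 - run
            run = 1
    if run > 1:
        tie_sum += run ** 3 - run
    denom = float(m) ** 3 - m
    if denom <= 0.0:
        return 0.0
    return 1.0 - tie_sum / denom


@njit(cache=True)
def mw_detect(x, burn_in, thresholds, two_sided, handle_ties):
    """Sequential max-standardised Mann-Whitney monitoring of one trace.

    At each observation m >= burn_in, the trace so far is split at every
    k in [1, m-1]; the rank-sum statistic of the first segment is
    standardised and the maximum over k (signed: positive when the later
    segment sits lower, i.e. an information-content drop) is compared with
    thresholds[m].  Returns (alarm index or -1, per-tone statistic trace).
    Midranks handle ties; windows with zero rank variance are skipped.
    """
    n = x.shape[0]
    r = np.zeros(n)
    stat = np.zeros(n)
    scratch = np.empty(n)
    alarm = -1
    for m in range(1, n + 1):
        xm = x[m - 1]
        less = 0.0
        eq = 0.0
        for i in range(m - 1):
            if x[i] > xm:
                r[i] += 1.0
            elif x[i] == xm:
                r[i] += 0.5
                eq += 1.0
            else:
                less += 1.0
        r[m - 1] = 1.0 + less + 0.5 * eq
        if m < burn_in or m < 4:
            continue
        tie = 1.0
        if handle_ties:
            tie = _tie_factor(x, m, scratch)
            if tie <= 0.0:
                stat[m - 1] = 0.0
                continue
        best = -np.inf
        w = 0.0
        for k in range(1, m):
            w += r[k - 1]
            var = k * (m - k) * (m + 1.0) / 12.0 * tie
            z = (w - k * (m + 1.0) / 2.0) / np.sqrt(var)
            if two_sided:
                z = abs(z)
            if z > best:
                best = z
        stat[m - 1] = best
        if best > thresholds[m]:
            alarm = m - 1
            break
    return alarm, stat


@njit(cache=True)
def calibrate_kernel(streams, burn_in, arl0, two_sided):
    """Per-length critical values h_m controlling the conditional per-
    observation false-alarm probability at 1/arl0.

    `streams` is (n_streams, max_len) of IID draws from any continuous
    null.  At each monitored length the (1 - 1/arl0) quantile of the
    max-statistic over surviving streams becomes h_m, and streams exceeding
    it are retired -- the conditional-quantile calibration of sequential
    changepoint monitoring.
    """
    n_streams, max_len = streams.shape
    thresholds = np.full(max_len + 1, np.inf)
    ranks = np.zeros((n_streams, max_len))
    alive = np.ones(n_streams, dtype=np.bool_)
    dvals = np.empty(n_streams)
    d = np.empty(n_streams)
    for m in range(1, max_len + 1):
        nd = 0
        for s in range(n_streams):
            if not alive[s]:
                continue
            xm = streams[s, m - 1]
            less = 0.0
            for i in range(m - 1):
                if streams[s, i] > xm:
                    ranks[s, i] += 1.0
                else:
                    less += 1.0
            ranks[s, m - 1] = 1.0 + less
            if m < burn_in or m < 4:
                continue
            best = -np.inf
            w = 0.0
            for k in range(1, m):
                w += ranks[s, k - 1]
                var = k * (m - k) * (m + 1.0) / 12.0
                z = (w - k * (m + 1.0) / 2.0) / np.sqrt(var)
                if two_sided:
                    z = abs(z)
                if z > best:
                    best = z
            dvals[s] = best
            d[nd] = best
            nd += 1
        if m < burn_in or m < 4 or nd == 0:
            continue
        ds = np.sort(d[:nd])
        # order-statistic threshold: the k-th largest of n draws is
        # exceeded by a fresh draw with probability k/(n+1), so target
        # k* = (n+1)/arl0 (interpolating between adjacent order stats)
        k_star = (nd + 1.0) / arl0
        if k_star <= 1.0:
            h = ds[nd - 1]
        else:
            k = int(np.floor(k_star))
            frac = k_star - k
            h = ds[nd - k]
            if k + 1 <= nd and frac > 0.0:
                h = h - frac * (h - ds[nd - k - 1])
        thresholds[m] = h
        for s in range(n_streams):
            if alive[s] and dvals[s] > h:
                alive[s] = False
    return thresholds
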