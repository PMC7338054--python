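"""Stimulus generation: tone-pip sequences and session schedules.

All stimuli are symbol streams indexing a fixed pool of 20 log-spaced
frequencies (222-2000 Hz, 12% steps), presented at 20 Hz (50 ms tone-pips).
Conditions:

* RAN       -- random order, no adjacent repeats, each frequency equiprobable
* RANREG    -- RAN prefix, then cyclic repeats of a novel 20-tone permutation
* RANREGr   -- as RANREG but the cycle reoccurs identically across trials
* RANREGr*  -- a previously non-adjacent reoccurring pattern presented with
               its two cycles adjacent (Exp 2 test block)
* PATinRAN  -- two identical 20-tone patterns embedded non-adjacently in
               random tones; the second ends at the final tone
* PATinRANr -- as PATinRAN with a reoccurring pattern
* STEP/CONT -- single-frequency controls (STEP carries one frequency change
               partway through; its RT gives the motor-latency baseline)

`schedule_session` realises the per-experiment block compositions and the
placement rule for reoccurring patterns (once per block third).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TONE_DURATION_S = 0.05
POOL_SIZE = 20
F_MIN_HZ = 222.0
F_MAX_HZ = 2000.0
CYCLE_LEN = 20

CONDITIONS = (
    "RAN", "RANREG", "RANREGr", "RANREGr*", "PATinRAN", "PATinRANr",
    "STEP", "CONT",
)
#: conditions whose sequences contain a nominal transition to detect
TRANSITION_CONDITIONS = ("RANREG", "RANREGr", "RANREGr*", "PATinRAN",
                         "PATinRANr", "STEP")
#: conditions entering the regularity-detection analysis (d', RT advantage)
REGULARITY_CONDITIONS = ("RANREG", "RANREGr", "RANREGr*", "PATinRAN",
                         "PATinRANr")


@dataclass(frozen=True)
class FrequencyPool:
    """Ordered pool of tone frequencies (Hz), logarithmically spaced."""

    frequencies: tuple[float, ...]

    @property
    def size(self) -> int:
        return len(self.frequencies)

    @property
    def step_ratio(self) -> float:
        """Ratio between successive pool entries (1.0 for a single entry)."""
        if self.size < 2:
            return 1.0
        return self.frequencies[1] / self.frequencies[0]

    def __post_init__(self) -> None:
        f = self.frequencies
        if any(x <= 0 for x in f):
            raise ValueError("frequencies must be positive")
        if list(f) != sorted(f) or len(set(f)) != len(f):
            raise ValueError("frequencies must be strictly increasing")
        if len(f) >= 3:
            ratios = [f[i + 1] / f[i] for i in range(len(f) - 1)]
            if max(ratios) - min(ratios) > 1e-9 * max(ratios):
                raise ValueError("pool must be log-spaced (constant ratio)")


def build_frequency_pool(f_min: float = F_MIN_HZ, f_max: float = F_MAX_HZ,
                         n: int = POOL_SIZE) -> FrequencyPool:
    """Log-spaced frequency pool from `f_min` to `f_max` (inclusive)."""
    if n < 1:
        raise ValueError("pool size must be >= 1")
    if f_min <= 0 or f_max <= 0:
        raise ValueError("frequencies must be positive")
    if n == 1:
        if f_min != f_max:
            raise ValueError("n = 1 requires f_min == f_max")
        return FrequencyPool((float(f_min),))
    if f_max <= f_min:
        raise ValueError("f_max must exceed f_min")
    freqs = np.geomspace(f_min, f_max, n)
    freqs[0], freqs[-1] = f_min, f_max
    return FrequencyPool(tuple(float(x) for x in freqs))


@dataclass(frozen=True)
class Pattern:
    """A 20-tone regular cycle: a permutation of all pool indices."""

    symbols: tuple[int, ...]
    pattern_id: str
    provenance: str = "novel"  # novel | reoccurring | reversed | phase_shifted | transposed

    def __post_init__(self) -> None:
        if sorted(self.symbols) != list(range(len(self.symbols))):
            raise ValueError("pattern must be a permutation of the pool indices")


@dataclass
class ToneSequence:
    """One trial's symbol stream plus condition metadata.

    `transition_index` is the tone index of the nominal transition (first
    regular tone for RANREG-type trials, frequency change for STEP, onset of
    the second pattern occurrence for PATinRAN); None for RAN and CONT.
    """

    symbols: np.ndarray
    condition: str
    transition_index: int | None = None
    pattern_ref: str | None = None
    tone_duration: float = TONE_DURATION_S
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def duration_s(self) -> float:
        return len(self.symbols) * self.tone_duration

    @property
    def transition_time_s(self) -> float | None:
        if self.transition_index is None:
            return None
        return self.transition_index * self.tone_duration

    def onset_times(self, t0: float = 0.0) -> np.ndarray:
        return t0 + np.arange(len(self.symbols)) * self.tone_duration


@dataclass
class BlockSpec:
    """Composition and geometry of one block."""

    counts: dict[str, int]
    sequence_length: int = 140
    transition_window_ms: tuple[float, float] = (3000.0, 4000.0)
    transform: str | None = None      # None | "reverse" | "phase_shift" | "transpose"
    iti_ms: tuple[float, float] = (1400.0, 1800.0)
    regr_set: str = "set1"            # which reoccurring-pattern set this block uses
    is_test_block: bool = False       # Exp 2 test-block geometry

    @property
    def n_trials(self) -> int:
        return sum(self.counts.values())


@dataclass
class SessionSpec:
    """Declarative description of an experimental session."""

    experiment_id: str
    blocks: list[BlockSpec]
    n_regr_per_set: int = 3
    pattern_sets: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class ScheduledTrial:
    """One scheduled trial: the stimulus plus its place in the session."""

    trial_index: int
    block: int
    third: int                       # 0, 1, 2 within the block
    sequence: ToneSequence
    presentation_index: int | None = None  # 1..3 for reoccurring patterns

    @property
    def condition(self) -> str:
        return self.sequence.condition


@dataclass
class Session:
    """A fully materialised session: spec, reoccurring patterns, trials."""

    spec: SessionSpec
    patterns: dict[str, Pattern]
    trials: list[ScheduledTrial]


# ---------------------------------------------------------------------------
# elementary generators


def _ran_symbols(length: int, pool_size: int, rng: np.random.Generator,
                 prev: int | None = None) -> np.ndarray:
    """Random symbols, uniform conditional on no adjacent repeats.

    `prev` constrains the first symbol (chaining into preceding material).
    """
    if pool_size < 2 and (length > 1 or (length == 1 and prev is not None)):
        raise ValueError("pool of size 1 cannot satisfy the adjacency rule")
    out = np.empty(length, dtype=np.int64)
    for i in range(length):
        if prev is None:
            out[i] = rng.integers(pool_size)
        else:
            # uniform over the pool minus the previous symbol
            s = int(rng.integers(pool_size - 1))
            if s >= prev:
                s += 1
            out[i] = s
        prev = int(out[i])
    return out


def generate_ran(length: int, pool: FrequencyPool | int = POOL_SIZE,
                 rng: np.random.Generator | None = None) -> ToneSequence:
    """A RAN trial: `length` random tones, no two adjacent tones equal."""
    pool_size = pool if isinstance(pool, int) else pool.size
    rng = np.random.default_rng() if rng is None else rng
    return ToneSequence(_ran_symbols(length, pool_size, rng), "RAN")


def generate_reg_cycle(pool: FrequencyPool | int = POOL_SIZE,
                       rng: np.random.Generator | None = None,
                       pattern_id: str = "REG",
                       provenance: str = "novel") -> Pattern:
    """A regular cycle: uniformly random permutation of the 20 pool indices."""
    pool_size = pool if isinstance(pool, int) else pool.size
    if pool_size != CYCLE_LEN:
        raise ValueError(f"regular cycles are permutations of {CYCLE_LEN} "
                         f"pool indices (got pool of {pool_size})")
    rng = np.random.default_rng() if rng is None else rng
    perm = tuple(int(x) for x in rng.permutation(pool_size))
    return Pattern(perm, pattern_id, provenance)


def _window_to_tone_range(window_ms: tuple[float, float]) -> tuple[int, int]:
    lo = int(round(window_ms[0] / 1000.0 / TONE_DURATION_S))
    hi = int(round(window_ms[1] / 1000.0 / TONE_DURATION_S))
    return lo, hi


def assemble_ranreg(pattern: Pattern, length: int = 140,
                    transition_window_ms: tuple[float, float] = (3000.0, 4000.0),
                    rng: np.random.Generator | None = None,
                    condition: str = "RANREG",
                    transition_index: int | None = None) -> ToneSequence:
    """RAN prefix followed by cyclic repeats of `pattern` to the end.

    The transition tone index is uniform over the tone grid inside
    `transition_window_ms` unless given explicitly.  The junction obeys the
    no-adjacent-repeat rule by regenerating the final RAN tone if it equals
    the first cycle tone (the cycle itself is never altered, preserving
    reoccurring-pattern identity).
    """
    rng = np.random.default_rng() if rng is None else rng
    if transition_index is None:
        lo, hi = _window_to_tone_range(transition_window_ms)
        if not (0 < lo <= hi < length):
            raise ValueError("transition window outside the sequence")
        t = int(rng.integers(lo, hi + 1))
    else:
        t = int(transition_index)
        if not 0 < t < length:
            raise ValueError("transition index outside the sequence")
    prefix = _ran_symbols(t, CYCLE_LEN, rng)
    if prefix[-1] == pattern.symbols[0]:
        forbidden = {int(prefix[-2]) if t >= 2 else -1, pattern.symbols[0]}
        choices = [s for s in range(CYCLE_LEN) if s not in forbidden]
        prefix[-1] = rng.choice(choices)
    n_reg = length - t
    cycle = np.array(pattern.symbols, dtype=np.int64)
    tail = np.tile(cycle, n_reg // CYCLE_LEN + 1)[:n_reg]
    return ToneSequence(np.concatenate([prefix, tail]), condition,
                        transition_index=t, pattern_ref=pattern.pattern_id)


def assemble_patinran(pattern: Pattern, length: int = 140,
                      gap_range_s: tuple[float, float] = (0.5, 2.9),
                      rng: np.random.Generator | None = None,
                      condition: str = "PATinRAN") -> ToneSequence:
    """Two identical pattern occurrences embedded in random tones.

    The second occurrence always ends at the final tone; the gap between the
    end of the first and the start of the second is uniform on the tone grid
    over `gap_range_s`.  Embedding RAN tones are fresh on every call.
    """
    rng = np.random.default_rng() if rng is None else rng
    gap_lo = int(round(gap_range_s[0] / TONE_DURATION_S))
    gap_hi = int(round(gap_range_s[1] / TONE_DURATION_S))
    gap = int(rng.integers(gap_lo, gap_hi + 1))
    second_start = length - CYCLE_LEN
    first_start = second_start - gap - CYCLE_LEN
    if first_start < 0:
        raise ValueError("sequence too short for two occurrences plus gap")
    cycle = np.array(pattern.symbols, dtype=np.int64)
    head = _ran_symbols(first_start, CYCLE_LEN, rng)
    if first_start and head[-1] == cycle[0]:
        forbidden = {int(head[-2]) if first_start >= 2 else -1, int(cycle[0])}
        head[-1] = rng.choice([s for s in range(CYCLE_LEN) if s not in forbidden])
    mid = _ran_symbols(gap, CYCLE_LEN, rng, prev=int(cycle[-1]))
    if gap and mid[-1] == cycle[0]:
        forbidden = {int(mid[-2]) if gap >= 2 else int(cycle[-1]), int(cycle[0])}
        mid[-1] = rng.choice([s for s in range(CYCLE_LEN) if s not in forbidden])
    symbols = np.concatenate([head, cycle, mid, cycle])
    return ToneSequence(
        symbols, condition, transition_index=second_start,
        pattern_ref=pattern.pattern_id,
        aux={"first_start": int(first_start), "gap_s": gap * TONE_DURATION_S,
             "second_start": int(second_start)})


def generate_step_cont(kind: str, length: int = 140,
                       change_window_ms: tuple[float, float] = (3000.0, 4000.0),
                       pool: FrequencyPool | int = POOL_SIZE,
                       rng: np.random.Generator | None = None) -> ToneSequence:
    """Control trials: constant frequency (CONT) or one step change (STEP)."""
    pool_size = pool if isinstance(pool, int) else pool.size
    rng = np.random.default_rng() if rng is None else rng
    if kind == "CONT":
        f = int(rng.integers(pool_size))
        return ToneSequence(np.full(length, f, dtype=np.int64), "CONT")
    if kind != "STEP":
        raise ValueError("kind must be 'STEP' or 'CONT'")
    lo, hi = _window_to_tone_range(change_window_ms)
    if not (0 < lo <= hi < length):
        raise ValueError("change window outside the sequence")
    t = int(rng.integers(lo, hi + 1))
    f1 = int(rng.integers(pool_size))
    f2 = int(rng.integers(pool_size - 1))
    if f2 >= f1:
        f2 += 1
    symbols = np.concatenate([np.full(t, f1, dtype=np.int64),
                              np.full(length - t, f2, dtype=np.int64)])
    return ToneSequence(symbols, "STEP", transition_index=t)


def transform_pattern(pattern: Pattern, transform: str,
                      shift: int = 0, steps: int = 0) -> Pattern:
    """Return a transformed copy of a regular cycle.

    * ``reverse``            -- symbol order reversed (time reversal)
    * ``phase_shift``        -- out[i] = in[(i + shift) mod 20]
    * ``transpose``          -- every pool index shifted by `steps`
    """
    n = len(pattern.symbols)
    if transform == "reverse":
        return Pattern(tuple(reversed(pattern.symbols)),
                       pattern.pattern_id, "reversed")
    if transform == "phase_shift":
        if not 0 <= shift < n:
            raise ValueError("phase shift must be in [0, cycle length)")
        sym = tuple(pattern.symbols[(i + shift) % n] for i in range(n))
        prov = "phase_shifted" if shift else pattern.provenance
        return Pattern(sym, pattern.pattern_id, prov)
    if transform == "transpose":
        sym = tuple(s + steps for s in pattern.symbols)
        if min(sym) < 0 or max(sym) >= n:
            raise ValueError("transposition leaves the frequency pool")
        return Pattern(sym, pattern.pattern_id, "transposed")
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# session scheduling

#: per-experiment block composition and geometry (counts sum to the block total)
_EXPERIMENTS: dict[str, dict] = {
    "1A": dict(n_blocks=5,
               counts={"RANREGr": 9, "RANREG": 18, "RAN": 27,
                       "STEP": 3, "CONT": 3},
               n_regr=3, seq_len=140, window=(3000.0, 4000.0),
               iti=(1400.0, 1800.0)),
    "1B": dict(n_blocks=6,
               counts={"RANREGr": 9, "RANREG": 18, "RAN": 27,
                       "STEP": 3, "CONT": 3},
               n_regr=3, seq_len=140, window=(3000.0, 4000.0),
               iti=(1400.0, 1800.0), reverse_block=4),
    "2":  dict(n_blocks=5, n_regr=3, iti=(2400.0, 2800.0)),  # built specially
    "3":  dict(n_blocks=8,
               counts={"RANREGr": 9, "RANREG": 18, "RAN": 27,
                       "STEP": 3, "CONT": 3},
               n_regr=3, seq_len=140, window=(3000.0, 4000.0),
               iti=(1400.0, 1800.0)),
    "4":  dict(n_blocks=4,
               counts={"RANREGr": 18, "RANREG": 18, "RAN": 36,
                       "STEP": 5, "CONT": 5},
               n_regr=6, seq_len=130, window=(3000.0, 3500.0),
               iti=(1400.0, 1800.0), phase_shift_block=3),
    "5":  dict(n_blocks=4,
               counts={"RANREGr": 9, "RANREG": 18, "RAN": 27,
                       "STEP": 9, "CONT": 9},
               n_regr=3, seq_len=140, window=(3000.0, 4000.0),
               iti=(900.0, 1300.0)),
}

PHASE_SHIFT_BINS = ((2, 7), (8, 13), (14, 19))


def _split_counts_by_third(counts: dict[str, int], regr_conditions: set[str],
                           n_regr: int, rng: np.random.Generator) -> list[dict[str, int]]:
    """Distribute a block's composition over its three thirds.

    Reoccurring conditions contribute exactly one occurrence of each pattern
    per third; other conditions are split as evenly as possible with the
    remainder assigned to random thirds.
    """
    thirds: list[dict[str, int]] = [dict(), dict(), dict()]
    for cond, cnt in counts.items():
        if cond in regr_conditions:
            assert cnt == 3 * n_regr, f"{cond}: {cnt} != 3 x {n_regr}"
            for th in thirds:
                th[cond] = n_regr
        else:
            base, rem = divmod(cnt, 3)
            extra = rng.permutation(3)[:rem]
            for i, th in enumerate(thirds):
                th[cond] = base + (1 if i in extra else 0)
    return thirds


def _make_regr_patterns(set_name: str, n: int, rng: np.random.Generator,
                        prefix: str) -> dict[str, Pattern]:
    out = {}
    for i in range(n):
        pid = f"{prefix}{i + 1}"
        out[pid] = generate_reg_cycle(POOL_SIZE, rng, pid, "reoccurring")
    return out


def _schedule_standard(experiment_id: str, cfg: dict,
                       rng: np.random.Generator) -> Session:
    n_regr = cfg["n_regr"]
    seq_len = cfg["seq_len"]
    window = cfg["window"]
    counts = cfg["counts"]

    if experiment_id == "3":
        sets = {"set1": _make_regr_patterns("set1", n_regr, rng, "REGr1-"),
                "set2": _make_regr_patterns("set2", n_regr, rng, "REGr2-")}
        block_sets = ["set1"] * 3 + ["set2"] * 3 + ["set1", "set2"]
    else:
        sets = {"set1": _make_regr_patterns("set1", n_regr, rng, "REGr")}
        block_sets = ["set1"] * cfg["n_blocks"]

    patterns = {pid: p for s in sets.values() for pid, p in s.items()}
    blocks, trials = [], []
    regr_seen: dict[str, int] = {pid: 0 for pid in patterns}
    trial_index = 0
    for b in range(cfg["n_blocks"]):
        transform = None
        if cfg.get("reverse_block") == b:
            transform = "reverse"
        if cfg.get("phase_shift_block") == b:
            transform = "phase_shift"
        block = BlockSpec(counts=dict(counts), sequence_length=seq_len,
                          transition_window_ms=window, transform=transform,
                          iti_ms=cfg["iti"], regr_set=block_sets[b])
        blocks.append(block)
        set_ids = list(sets[block_sets[b]].keys())
        thirds = _split_counts_by_third(counts, {"RANREGr"}, n_regr, rng)
        # Exp 4 block 4: assign one phase-shift bin per intra-block presentation
        shift_bins = {}
        if transform == "phase_shift":
            for pid in set_ids:
                shift_bins[pid] = rng.permutation(3)
        for third_i, third_counts in enumerate(thirds):
            entries: list[tuple[str, str | None]] = []
            for cond, cnt in third_counts.items():
                if cond == "RANREGr":
                    entries += [(cond, pid) for pid in set_ids]
                else:
                    entries += [(cond, None)] * cnt
            order = rng.permutation(len(entries))
            for k in order:
                cond, pid = entries[k]
                seq = _realise_trial(cond, pid, patterns, seq_len, window,
                                     transform, shift_bins, third_i, rng)
                pres = None
                if pid is not None:
                    regr_seen[pid] += 1
                    pres = third_i + 1
                trials.append(ScheduledTrial(trial_index, b, third_i, seq, pres))
                trial_index += 1
    spec = SessionSpec(experiment_id, blocks, n_regr,
                       {name: list(s.keys()) for name, s in sets.items()})
    return Session(spec, patterns, trials)


def _realise_trial(cond: str, pid: str | None, patterns: dict[str, Pattern],
                   seq_len: int, window: tuple[float, float],
                   transform: str | None, shift_bins: dict, third_i: int,
                   rng: np.random.Generator) -> ToneSequence:
    if cond == "RAN":
        return generate_ran(seq_len, POOL_SIZE, rng)
    if cond == "STEP" or cond == "CONT":
        return generate_step_cont(cond, seq_len, window, POOL_SIZE, rng)
    if cond == "RANREG":
        pat = generate_reg_cycle(POOL_SIZE, rng, f"novel-{rng.integers(1 << 30)}")
        return assemble_ranreg(pat, seq_len, window, rng)
    if cond == "RANREGr":
        pat = patterns[pid]
        if transform == "reverse":
            pat = transform_pattern(pat, "reverse")
        elif transform == "phase_shift":
            lo, hi = PHASE_SHIFT_BINS[shift_bins[pid][third_i]]
            pat = transform_pattern(pat, "phase_shift",
                                    shift=int(rng.integers(lo, hi + 1)))
        return assemble_ranreg(pat, seq_len, window, rng, condition="RANREGr")
    raise ValueError(f"cannot realise condition {cond!r}")


def _schedule_exp2(rng: np.random.Generator) -> Session:
    """Exp 2: non-adjacent pattern pairs (PATinRAN) plus a test block.

    Blocks 1-4 RANREG(r) trials carry exactly two cycles after a transition
    drawn from the 3-4 s window (sequence length transition + 40 tones);
    PATinRAN trials are 140 tones with the second occurrence at the end.
    Test-block sequences are 109 tones with two adjacent cycles at the end
    (transition at tone 69); RANREGr* presents the former PATinRANr patterns
    adjacently.
    """
    window = (3000.0, 4000.0)
    iti = (2400.0, 2800.0)
    n_regr = 3
    regr = _make_regr_patterns("set1", n_regr, rng, "REGr")
    patr = _make_regr_patterns("set2", n_regr, rng, "PATr")
    patterns = {**regr, **patr}
    train_counts = {"RAN": 36, "RANREG": 9, "RANREGr": 9,
                    "PATinRAN": 9, "PATinRANr": 9, "STEP": 5, "CONT": 5}
    test_counts = {"RAN": 36, "RANREG": 18, "RANREGr": 9, "RANREGr*": 9,
                   "STEP": 5, "CONT": 5}
    test_len, test_transition = 109, 69

    blocks, trials = [], []
    trial_index = 0
    for b in range(5):
        is_test = b == 4
        counts = test_counts if is_test else train_counts
        blocks.append(BlockSpec(counts=dict(counts),
                                sequence_length=test_len if is_test else 140,
                                transition_window_ms=window, iti_ms=iti,
                                is_test_block=is_test))
        thirds = _split_counts_by_third(
            counts, {"RANREGr", "PATinRANr", "RANREGr*"}, n_regr, rng)
        for third_i, third_counts in enumerate(thirds):
            entries: list[tuple[str, str | None]] = []
            for cond, cnt in third_counts.items():
                if cond == "RANREGr":
                    entries += [(cond, pid) for pid in regr]
                elif cond in ("PATinRANr", "RANREGr*"):
                    entries += [(cond, pid) for pid in patr]
                else:
                    entries += [(cond, None)] * cnt
            for k in rng.permutation(len(entries)):
                cond, pid = entries[k]
                if cond == "RAN":
                    length = test_len if is_test else int(rng.integers(60, 81)) + 40
                    seq = generate_ran(length, POOL_SIZE, rng)
                elif cond in ("STEP", "CONT"):
                    length = test_len if is_test else int(rng.integers(60, 81)) + 40
                    seq = generate_step_cont(cond, length, window, POOL_SIZE, rng)
                elif cond in ("RANREG", "RANREGr", "RANREGr*"):
                    if cond == "RANREG":
                        pat = generate_reg_cycle(
                            POOL_SIZE, rng, f"novel-{rng.integers(1 << 30)}")
                    else:
                        pat = patterns[pid]
                    if is_test:
                        seq = assemble_ranreg(pat, test_len, window, rng,
                                              condition=cond,
                                              transition_index=test_transition)
                    else:
                        t = int(rng.integers(60, 81))
                        seq = assemble_ranreg(pat, t + 40, window, rng,
                                              condition=cond,
                                              transition_index=t)
                elif cond in ("PATinRAN", "PATinRANr"):
                    pat = (patterns[pid] if pid is not None else
                           generate_reg_cycle(POOL_SIZE, rng,
                                              f"novel-{rng.integers(1 << 30)}"))
                    seq = assemble_patinran(pat, 140, (0.5, 2.9), rng,
                                            condition=cond)
                else:  # pragma: no cover
                    raise ValueError(cond)
                pres = third_i + 1 if pid is not None else None
                trials.append(ScheduledTrial(trial_index, b, third_i, seq, pres))
                trial_index += 1
    spec = SessionSpec("2", blocks, n_regr,
                       {"set1": list(regr), "set2": list(patr)})
    return Session(spec, patterns, trials)


def schedule_session(experiment_id: str,
                     rng: np.random.Generator | int | None = None,
                     n_blocks: int | None = None) -> Session:
    """Materialise a full session for one experiment.

    Reoccurring patterns appear exactly once per block third (order within
    each third randomised); the RAN portion of every RANREGr trial is fresh.
    `n_blocks` truncates or extends the default block count (same
    composition per block) for reduced-scale simulation.
    """
    if experiment_id not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment_id!r}; "
                         f"choose from {sorted(_EXPERIMENTS)}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cfg = dict(_EXPERIMENTS[experiment_id])
    if n_blocks is not None:
        cfg["n_blocks"] = n_blocks
    if experiment_id == "2":
        session = _schedule_exp2(rng)
        if n_blocks is not None and n_blocks != 5:
            raise ValueError("Exp 2 schedule is fixed at 4 training blocks + test")
        return session
    return _schedule_standard(experiment_id, cfg, rng)


def session_to_dataframe(session: Session):
    """Tidy trial table (one row per trial) for CSV export."""
    import pandas as pd

    rows = []
    for tr in session.trials:
        seq = tr.sequence
        rows.append({
            "trial_index": tr.trial_index,
            "block": tr.block,
            "third": tr.third,
            "condition": seq.condition,
            "pattern_id": seq.pattern_ref,
            "presentation_index": tr.presentation_index,
            "transition_index": seq.transition_index,
            "transition_time_s": seq.transition_time_s,
            "n_tones": len(seq),
            "symbols": " ".join(str(s) for s in seq.symbols),
        })
    return pd.DataFrame(rows)


def n_distinct_patterns(cycle_len: int = CYCLE_LEN) -> int:
    """Number of distinct regular cycles (permutations of the pool)."""
    return math.factorial(cycle_len)
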