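"""Three-phase memory-decay kernel and noisy retrieval.

Every stored n-gram observation carries a weight that evolves through three
phases as the session unfolds:

a) *echoic buffer* -- full weight while at most `buffer_capacity` further
   tones have been presented (item-count based, matching a fixed 20 Hz
   presentation rate);
b) *short-term memory* -- exponential interpolation from `stm_weight` down
   to `ltm_weight`, reaching it exactly at `stm_duration` seconds after
   buffer exit;
c) *long-term memory* -- slow exponential decay from `ltm_weight` toward
   `ltm_asymptote` with half-life `ltm_half_life`.

Retrieval sums the current weights of all records of an n-gram and perturbs
the sum with zero-mean Gaussian noise (SD `noise`), truncated below at zero
-- the model's account of imperfect memory retrieval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from seqmem.stimuli import TONE_DURATION_S


@dataclass(frozen=True)
class DecayParams:
    """Decay-kernel parameters (defaults: the constrained model)."""

    buffer_capacity: int = 15       # items
    buffer_weight: float = 1.0
    stm_weight: float = 1.0
    stm_duration: float = 15.0      # s, from buffer exit to LTM entry
    ltm_weight: float = 0.02
    ltm_half_life: float = 500.0    # s
    ltm_asymptote: float = 0.0
    noise: float = 1.3              # SD of retrieval noise, count units
    order_bound: int = 4

    def __post_init__(self) -> None:
        if self.buffer_capacity < 0 or self.buffer_capacity != int(self.buffer_capacity):
            raise ValueError("buffer_capacity must be a non-negative integer")
        for name in ("buffer_weight", "stm_weight", "ltm_weight",
                     "ltm_asymptote", "noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ltm_half_life <= 0 or self.stm_duration <= 0:
            raise ValueError("durations and half-lives must be positive")
        if self.order_bound < 0:
            raise ValueError("order_bound must be >= 0")

    @property
    def stm_rate(self) -> float:
        """Exponential rate (1/s) of the STM phase."""
        if self.ltm_weight == 0:
            return math.inf
        if self.ltm_weight >= self.stm_weight:
            return 0.0
        return math.log(self.stm_weight / self.ltm_weight) / self.stm_duration

    @property
    def stm_half_life(self) -> float:
        """Half-life (s) implied by the STM weight drop over its duration."""
        rate = self.stm_rate
        if rate == 0.0:
            return math.inf
        return math.log(2.0) / rate

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DecayParams":
        return cls(**d)

    @classmethod
    def unconstrained(cls) -> "DecayParams":
        """Degenerate kernel: every phase weight 1, no decay, no noise.

        With these parameters every stored observation keeps weight one
        forever, so predictions coincide with the perfect-memory model.
        """
        return cls(buffer_capacity=15, buffer_weight=1.0, stm_weight=1.0,
                   stm_duration=15.0, ltm_weight=1.0, ltm_half_life=math.inf,
                   ltm_asymptote=0.0, noise=0.0)


def observation_weight(t_obs: float, i_obs: int, t_now: float, i_now: int,
                       params: DecayParams,
                       t_exit: float | None = None) -> float:
    """Current memory weight of one n-gram observation.

    `t_exit` is the clock time at which the observation left the echoic
    buffer (the onset of the ``buffer_capacity + 1``-th subsequent item).
    When not supplied it is inferred from a constant 20 Hz presentation
    rate: ``t_obs + (buffer_capacity + 1) * 0.05``.
    """
    if t_now < t_obs or i_now < i_obs:
        raise ValueError("negative elapsed time")
    if i_now - i_obs <= params.buffer_capacity:
        return params.buffer_weight
    if t_exit is None:
        t_exit = t_obs + (params.buffer_capacity + 1) * TONE_DURATION_S
    tau = max(t_now - t_exit, 0.0)
    if tau < params.stm_duration:
        if params.ltm_weight == 0.0:
            frac = tau / params.stm_duration
            return params.stm_weight * (0.0 if frac >= 1 else
                                        math.exp(-params.stm_rate * tau)
                                        if math.isfinite(params.stm_rate) else 0.0)
        return params.stm_weight * (params.ltm_weight / params.stm_weight) ** (
            tau / params.stm_duration)
    tau_ltm = tau - params.stm_duration
    half = 0.0 if math.isinf(params.ltm_half_life) else tau_ltm / params.ltm_half_life
    return (params.ltm_asymptote +
            (params.ltm_weight - params.ltm_asymptote) * 2.0 ** (-half))


def effective_count(records: list[tuple[float, int]], t_now: float, i_now: int,
                    params: DecayParams,
                    rng: np.random.Generator | None = None,
                    item_times: np.ndarray | None = None) -> float:
    """Noisy weighted count of an n-gram's observation records.

    `records` are ``(t_obs, i_obs)`` pairs.  The weighted sum is perturbed
    by one zero-mean Gaussian draw (SD ``params.noise``) and truncated below
    at zero.  Noise applies per aggregated retrieval, not per record, and
    also to empty record sets: retrieving an unstored n-gram yields a
    truncated pure-noise "phantom" count, which is what masks weak memory
    traces.  `item_times` (onset time per global item index) refines each
    record's buffer-exit time; without it a constant 20 Hz rate is assumed.
    """
    if not records and params.noise == 0.0:
        return 0.0
    total = 0.0
    for t_obs, i_obs in records:
        if t_obs > t_now:
            raise ValueError("record observed after retrieval time")
        t_exit = None
        if item_times is not None:
            j = i_obs + params.buffer_capacity + 1
            if j <= i_now:
                t_exit = float(item_times[j])
        total += observation_weight(t_obs, i_obs, t_now, i_now, params, t_exit)
    if params.noise > 0.0:
        rng = np.random.default_rng() if rng is None else rng
        total += params.noise * rng.standard_normal()
    return max(total, 0.0)


def kernel_curve(params: DecayParams, n_tones: int = 2000,
                 rate_hz: float = 20.0) -> "np.ndarray":
    """Weight of a single observation as a function of subsequent tones.

    Mirrors the decay-profile figure convention: item `k` on the x-axis is
    the number of consequent tones presented at a constant `rate_hz`.
    Returns an (n_tones, 2) array of (tones elapsed, weight).
    """
    dt = 1.0 / rate_hz
    out = np.empty((n_tones, 2))
    for k in range(n_tones):
        out[k, 0] = k
        out[k, 1] = observation_weight(0.0, 0, k * dt, k, params)
    return out
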