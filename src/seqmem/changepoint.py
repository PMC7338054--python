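"""Sequential nonparametric changepoint detection on IC traces.

At each new observation the trace so far is split at every candidate point
and the standardised Mann-Whitney rank statistic of the split is computed;
the maximum over splits is compared with a length-dependent critical value
h_n.  Critical values are Monte-Carlo calibrated so that the conditional
probability of a false alarm at each monitored observation is 1/ARL0
(target Type-I error: one false alarm per `arl0` tones under a regularity-
free stream).  Because the statistic is rank-based, thresholds calibrated
on any continuous null apply to any other continuous distribution --
including the model's information-content output.

The detector monitors for a *drop* in level by default (the model's
signature of emerging regularity); its first alarm plays the role of the
participant's button press.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seqmem import _engine
from seqmem.ppm import ICTrace

DEFAULT_ARL0 = 10_000.0
DEFAULT_BURN_IN = 20
DEFAULT_MAX_LENGTH = 140


@dataclass
class DetectorConfig:
    """Configuration plus calibrated per-length critical values."""

    arl0: float = DEFAULT_ARL0
    burn_in: int = DEFAULT_BURN_IN
    side: str = "decrease_only"          # or "two_sided"
    thresholds: np.ndarray | None = None  # h_n, indexed by window length n

    def __post_init__(self) -> None:
        if self.arl0 <= 0:
            raise ValueError("arl0 must be positive")
        if self.side not in ("decrease_only", "two_sided"):
            raise ValueError("side must be 'decrease_only' or 'two_sided'")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            finite = self.thresholds[np.isfinite(self.thresholds)]
            if finite.size and (finite <= 0).any():
                raise ValueError("thresholds must be positive")

    @property
    def max_length(self) -> int:
        if self.thresholds is None:
            raise ValueError("detector not calibrated")
        return len(self.thresholds) - 1


@dataclass
class DetectionResult:
    """Outcome of monitoring one trace."""

    alarm_index: int | None
    statistic_trace: np.ndarray = field(repr=False, default=None)


def calibrate_thresholds(arl0: float = DEFAULT_ARL0,
                         max_length: int = DEFAULT_MAX_LENGTH,
                         n_sims: int = 100_000,
                         rng: np.random.Generator | int | None = None,
                         burn_in: int = DEFAULT_BURN_IN,
                         side: str = "decrease_only",
                         streams: np.ndarray | None = None) -> DetectorConfig:
    """Monte-Carlo calibration of the per-length critical values.

    At each monitored length the (1 - 1/arl0) conditional quantile of the
    max statistic over surviving streams becomes h_n and the streams above
    it are retired.  For a stable estimate of the tail quantile, `n_sims`
    should be a respectable multiple of arl0.

    Without `streams`, calibration uses IID standard-normal draws; the
    rank statistic makes the result valid for any IID continuous null.
    Model IC traces are *not* IID (a short low-IC warm-up while the
    prediction context grows, and negative serial correlation), which
    makes IID thresholds conservative on them -- pass per-trial null
    streams (rows of shape (n_sims, max_length), e.g. from
    `harness.ran_ic_streams`) to calibrate against the actual monitored
    process so the achieved Type-I rate matches the target.
    """
    if arl0 <= 0:
        raise ValueError("arl0 must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if streams is None:
        if n_sims < 100:
            raise ValueError("n_sims too small for any quantile estimate")
        streams = rng.standard_normal((n_sims, max_length))
    else:
        streams = np.ascontiguousarray(np.asarray(streams, dtype=float))
        if streams.shape[1] < max_length:
            raise ValueError("null streams shorter than max_length")
        streams = streams[:, :max_length]
    thresholds = _engine.calibrate_kernel(streams, burn_in, float(arl0),
                                          side == "two_sided")
    return DetectorConfig(arl0=arl0, burn_in=burn_in, side=side,
                          thresholds=thresholds)


def detect(trace: ICTrace | np.ndarray, config: DetectorConfig) -> DetectionResult:
    """Monitor one trace; return the first alarm (or none).

    Ties are handled with midranks and a tie-corrected variance; windows
    with zero rank variance are skipped.  Traces longer than the
    calibrated range reuse the last available threshold.
    """
    x = trace.values if isinstance(trace, ICTrace) else np.asarray(trace, dtype=float)
    if config.thresholds is None:
        raise ValueError("detector not calibrated: no thresholds")
    thr = config.thresholds
    if len(x) + 1 > len(thr):
        last = thr[np.isfinite(thr)][-1]
        pad = np.full(len(x) + 1 - len(thr), last)
        thr = np.concatenate([thr, pad])
    alarm, stat = _engine.mw_detect(x, config.burn_in, thr,
                                    config.side == "two_sided", True)
    return DetectionResult(alarm_index=None if alarm < 0 else int(alarm),
                           statistic_trace=stat)


# ---------------------------------------------------------------------------
# threshold cache (text CSV so calibrations can be reused across runs)


def save_thresholds(config: DetectorConfig, path: str | Path,
                    n_sims: int | None = None, seed: int | None = None) -> None:
    df = pd.DataFrame({"n": np.arange(len(config.thresholds)),
                       "h_n": config.thresholds})
    df["arl0"] = config.arl0
    df["burn_in"] = config.burn_in
    if n_sims is not None:
        df["n_sims"] = n_sims
    if seed is not None:
        df["seed"] = seed
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_thresholds(path: str | Path) -> DetectorConfig:
    df = pd.read_csv(path)
    return DetectorConfig(arl0=float(df["arl0"].iloc[0]),
                          burn_in=int(df["burn_in"].iloc[0]),
                          thresholds=df["h_n"].to_numpy())
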