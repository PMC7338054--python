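"""End-to-end model harness: stimuli -> PPM -> changepoint -> simulated RTs.

`run_session` feeds every scheduled trial of a session through one model
(unconstrained or memory-constrained) on a continuous clock -- 20 Hz tones
with fixed 1 s silent gaps between trials and blocks -- then runs the
changepoint detector on each trial's IC trace.  The detector's first alarm
is the model's "button press"; the model RT is the alarm latency from the
nominal transition (no STEP-motor baselining, which corrects a human motor
latency the model does not have).

`summarize_rt_advantage` reproduces the behavioural summary used for
humans: mean RT to novel regularities minus mean RT to reoccurring ones,
per block or per intra-block presentation (matching presentations 1/2/3 to
novel trials in the corresponding block third).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seqmem.changepoint import DetectorConfig, calibrate_thresholds, detect
from seqmem.decay import DecayParams
from seqmem.ppm import PPMModel
from seqmem.stimuli import (REGULARITY_CONDITIONS, TONE_DURATION_S, Session,
                            schedule_session)

#: conditions whose IC traces are monitored by the detector
_MONITORED = ("RAN",) + REGULARITY_CONDITIONS


@dataclass
class HarnessConfig:
    """Model-side session configuration."""

    model_mode: str = "constrained"          # or "unconstrained"
    decay: DecayParams = field(default_factory=DecayParams)
    detector: DetectorConfig | None = None
    inter_trial_gap: float = 1.0             # s
    inter_block_gap: float = 1.0             # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model_mode not in ("constrained", "unconstrained"):
            raise ValueError("model_mode must be 'constrained' or 'unconstrained'")
        if self.inter_trial_gap < 0 or self.inter_block_gap < 0:
            raise ValueError("gaps must be >= 0")


#: trials per regularity-free calibration session -- the session-length
#: regime of the simulated experiments (300-420 trials)
NULL_SESSION_TRIALS = 400


def ran_ic_streams(n_streams: int, trial_len: int = 140,
                   decay: DecayParams | None = None, seed: int = 0,
                   gap: float = 1.0,
                   session_trials: int = NULL_SESSION_TRIALS) -> np.ndarray:
    """Per-trial IC traces of the model under regularity-free sessions.

    Runs as many independent RAN-only sessions of `session_trials` trials
    (20 Hz tones, `gap`-second intervals, fresh model each) as needed and
    returns all per-trial IC traces.  These are the detector's null
    streams: they carry the monitored process's actual within-trial
    structure (context warm-up, serial anticorrelation) and its
    session-position mixture, neither of which IID surrogates reproduce.
    The model's null statistics drift as its store matures, so streams are
    drawn from whole sessions matching the experiments' length regime
    rather than from one endless run.
    """
    from seqmem.stimuli import generate_ran

    out = np.empty((n_streams, trial_len))
    made = 0
    root = np.random.SeedSequence(seed)
    while made < n_streams:
        stim_seed, noise_seed = root.spawn(1)[0].generate_state(2)
        rng = np.random.default_rng(stim_seed)
        model = PPMModel(decay=decay, seed=int(noise_seed % (2 ** 31)))
        for _ in range(min(session_trials, n_streams - made)):
            out[made] = model.information_content(
                generate_ran(trial_len, model.A, rng), gap_after=gap).values
            made += 1
    return out


def calibrate_matched(arl0: float = 10_000.0, max_length: int = 140,
                      n_sims: int = 30_000,
                      decay: DecayParams | None = None, seed: int = 0,
                      burn_in: int = 20,
                      session_trials: int = NULL_SESSION_TRIALS) -> DetectorConfig:
    """Detector thresholds calibrated on the model's own null IC streams.

    This is the pipeline's default Type-I configuration: the conditional
    per-tone false-alarm probability equals 1/arl0 under the very process
    the detector monitors (RAN-only trials through the given model mode,
    in the experiments' session-length regime).
    """
    streams = ran_ic_streams(n_sims, max_length, decay=decay, seed=seed,
                             session_trials=session_trials)
    return calibrate_thresholds(arl0, max_length, n_sims, burn_in=burn_in,
                                streams=streams)


def run_session(session: Session, cfg: HarnessConfig,
                collect_ic: bool = False) -> pd.DataFrame:
    """Simulate one full session with one model.

    Returns one row per trial: scheduling metadata, the detector's alarm
    tone index (NaN if none), the model RT in seconds from the nominal
    transition (defined only for alarms at or after it), and flags for
    pre-transition alarms (model false positives) and RAN-trial alarms
    (false alarms).  With ``collect_ic`` the per-trial IC traces are
    attached as ``df.attrs['ic_traces']``.
    """
    if cfg.detector is None or cfg.detector.thresholds is None:
        raise ValueError("run_session requires a calibrated detector")
    decay = cfg.decay if cfg.model_mode == "constrained" else None
    model = PPMModel(decay=decay, seed=cfg.seed)
    rows = []
    traces = []
    prev_block = None
    for tr in session.trials:
        if prev_block is not None and tr.block != prev_block:
            model.time += cfg.inter_block_gap
        prev_block = tr.block
        ic = model.information_content(tr.sequence,
                                       gap_after=cfg.inter_trial_gap)
        if collect_ic:
            traces.append(ic)
        seq = tr.sequence
        alarm = np.nan
        model_rt = np.nan
        pre_alarm = False
        false_alarm = False
        if seq.condition in _MONITORED:
            res = detect(ic, cfg.detector)
            if res.alarm_index is not None:
                alarm = res.alarm_index
                if seq.condition == "RAN":
                    false_alarm = True
                elif seq.transition_index is not None:
                    if res.alarm_index >= seq.transition_index:
                        model_rt = (res.alarm_index -
                                    seq.transition_index) * TONE_DURATION_S
                    else:
                        pre_alarm = True
        rows.append({
            "trial_index": tr.trial_index,
            "block": tr.block,
            "third": tr.third,
            "condition": seq.condition,
            "pattern_id": seq.pattern_ref,
            "presentation_index": tr.presentation_index,
            "transition_index": seq.transition_index,
            "alarm_index": alarm,
            "model_rt": model_rt,
            "pre_transition_alarm": pre_alarm,
            "false_alarm": false_alarm,
        })
    df = pd.DataFrame(rows)
    df.attrs["model_mode"] = cfg.model_mode
    if collect_ic:
        df.attrs["ic_traces"] = traces
    return df


def run_replicates(experiment_id: str, cfg: HarnessConfig, n_replicates: int,
                   seed: int, n_blocks: int | None = None) -> pd.DataFrame:
    """Independent virtual subjects: fresh stimuli and noise per replicate."""
    out = []
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(n_replicates)):
        stim_seed, noise_seed = child.generate_state(2)
        session = schedule_session(experiment_id,
                                   np.random.default_rng(stim_seed),
                                   n_blocks=n_blocks)
        rep_cfg = HarnessConfig(model_mode=cfg.model_mode, decay=cfg.decay,
                                detector=cfg.detector,
                                inter_trial_gap=cfg.inter_trial_gap,
                                inter_block_gap=cfg.inter_block_gap,
                                seed=int(noise_seed % (2 ** 31)))
        df = run_session(session, rep_cfg)
        df["replicate"] = rep
        out.append(df)
    return pd.concat(out, ignore_index=True)


def summarize_rt_advantage(results: pd.DataFrame, grouping: str = "per_block",
                           novel: str = "RANREG",
                           reoccurring: str = "RANREGr",
                           block: int | None = None,
                           rt_col: str = "model_rt") -> pd.DataFrame:
    """RT advantage = mean(novel RT) - mean(reoccurring RT).

    ``per_block``: one advantage per block (novel and reoccurring trials of
    that block).  ``per_intra_block_presentation``: within one block
    (default: the last), presentation p of the reoccurring condition is
    matched against novel trials of block third p.  Empty cells yield NaN
    with a warning rather than a silent zero.  With a ``replicate`` column
    the advantage is computed per replicate and averaged (sem across
    replicates).
    """
    if grouping not in ("per_block", "per_intra_block_presentation"):
        raise ValueError("unknown grouping")
    df = results[results[rt_col].notna()]
    reps = sorted(results["replicate"].unique()) if "replicate" in results else [None]

    def _cell(sub: pd.DataFrame, cond: str, sel) -> float:
        vals = sub[(sub["condition"] == cond) & sel(sub)][rt_col]
        if len(vals) == 0:
            return np.nan
        return float(vals.mean())

    rows = []
    if grouping == "per_block":
        blocks = sorted(results["block"].unique())
        for b in blocks:
            per_rep = []
            for rep in reps:
                sub = df if rep is None else df[df["replicate"] == rep]
                sub = sub[sub["block"] == b]
                a = _cell(sub, novel, lambda s: np.ones(len(s), dtype=bool))
                r = _cell(sub, reoccurring, lambda s: np.ones(len(s), dtype=bool))
                per_rep.append(a - r)
            per_rep = np.asarray(per_rep, dtype=float)
            if np.isnan(per_rep).all():
                warnings.warn(f"block {b}: empty cell for "
                              f"{novel} vs {reoccurring}")
            rows.append(_agg_row({"block": b}, per_rep))
    else:
        b = int(results["block"].max()) if block is None else block
        sub_b = df[df["block"] == b]
        for p in (1, 2, 3):
            per_rep = []
            for rep in reps:
                sub = sub_b if rep is None else sub_b[sub_b["replicate"] == rep]
                a = _cell(sub, novel, lambda s, p=p: s["third"] == p - 1)
                r = _cell(sub, reoccurring,
                          lambda s, p=p: s["presentation_index"] == p)
                per_rep.append(a - r)
            per_rep = np.asarray(per_rep, dtype=float)
            if np.isnan(per_rep).all():
                warnings.warn(f"presentation {p}: empty cell for "
                              f"{novel} vs {reoccurring}")
            rows.append(_agg_row({"block": b, "presentation": p}, per_rep))
    return pd.DataFrame(rows)


def _agg_row(meta: dict, per_rep: np.ndarray) -> dict:
    ok = per_rep[~np.isnan(per_rep)]
    out = dict(meta)
    out["advantage_s"] = float(ok.mean()) if ok.size else np.nan
    out["sem_s"] = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else np.nan
    out["n"] = int(ok.size)
    out["advantage_tones"] = out["advantage_s"] / TONE_DURATION_S
    return out
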