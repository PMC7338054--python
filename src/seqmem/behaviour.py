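"""Behavioural statistics for the transition-detection paradigm.

Implements the study-side analysis chain: response classification
(hit / miss / false alarm / correct rejection, with presses before the
nominal transition excluded as false positives), signal-detection d'
(collapsed over novel and reoccurring regularities), STEP-baselined RTs
with per-participant-and-block 2-SD trimming, the RT advantage (per block
and per intra-block presentation), the Matthews correlation coefficient for
the explicit familiarity task, and the pooled bootstrap benchmark used to
situate an observed RT advantage within a reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from seqmem.stimuli import TONE_DURATION_S

REGULARITY_SIGNAL = ("RANREG", "RANREGr", "RANREGr*", "PATinRAN", "PATinRANr")

#: trial-response schema (one row per trial)
RESPONSE_COLUMNS = ("participant", "block", "third", "trial_index",
                    "condition", "pattern_id", "presentation_index",
                    "transition_time_s", "duration_s", "press_time_s")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification cells of the familiarity task."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")


def classify_responses(trials: pd.DataFrame,
                       rt_reference: str = "transition_onset") -> pd.DataFrame:
    """Label every trial and derive its raw RT.

    Signal trials (any regularity condition) with a press at or after the
    nominal transition are hits; presses before it are excluded as false
    positives (``pre_transition_excluded``); no press is a miss.  Presses
    on RAN trials are false alarms, silence a correct rejection.  STEP
    trials are classified like signal trials against their step-change
    time (their hits supply the motor-RT baseline).

    ``rt_reference`` selects the zero point of the raw RT: the nominal
    transition, or the onset of the second regularity cycle (transition +
    1 s for adjacent-cycle conditions; for the non-adjacent PATinRAN
    conditions the nominal transition already is the second occurrence's
    onset).
    """
    if rt_reference not in ("transition_onset", "second_cycle_onset"):
        raise ValueError("unknown rt_reference")
    df = trials.copy()
    cond = df["condition"]
    unknown = set(cond) - set(REGULARITY_SIGNAL) - {"STEP", "RAN", "CONT"}
    if unknown:
        raise ValueError(f"unknown condition(s) {sorted(unknown)}")
    press = pd.to_numeric(df["press_time_s"], errors="coerce")
    pressed = press.notna()
    if "duration_s" in df.columns:
        bad = pressed & (press > pd.to_numeric(df["duration_s"]))
        if bad.any():
            raise ValueError(
                f"press outside the trial window (trials "
                f"{df.loc[bad, 'trial_index'].tolist()[:5]} ...)")
    is_signal = cond.isin(REGULARITY_SIGNAL) | (cond == "STEP")
    t_trans = pd.to_numeric(df["transition_time_s"], errors="coerce")
    if (is_signal & t_trans.isna()).any():
        raise ValueError("signal trial without a transition time")
    labels = np.select(
        [is_signal & ~pressed,
         is_signal & pressed & (press >= t_trans),
         is_signal & pressed,
         ~is_signal & pressed],
        ["miss", "hit", "pre_transition_excluded", "false_alarm"],
        default="correct_rejection")
    ref = t_trans.to_numpy(dtype=float, copy=True)
    if rt_reference == "second_cycle_onset":
        adjacent = cond.isin(["RANREG", "RANREGr", "RANREGr*"]).to_numpy()
        ref[adjacent] += 20 * TONE_DURATION_S
    raw_rt = np.where(labels == "hit", press.to_numpy(dtype=float) - ref,
                      np.nan)
    df["label"] = labels
    df["raw_rt_s"] = raw_rt
    return df


# ---------------------------------------------------------------------------
# signal detection


def _z(rate: float) -> float:
    return float(norm.ppf(rate))


def dprime(hits: int, misses: int, fas: int, crs: int,
           correction: str = "loglinear") -> float:
    """Sensitivity d' = z(hit rate) - z(false-alarm rate).

    ``loglinear`` adds 0.5 to each cell and 1 to each trial count before
    taking rates, keeping d' finite at ceiling; ``none`` uses raw rates
    (infinite at 0 or 1).
    """
    n_sig = hits + misses
    n_noise = fas + crs
    if n_sig <= 0 or n_noise <= 0:
        raise ValueError("need at least one signal and one noise trial")
    if correction == "loglinear":
        hr = (hits + 0.5) / (n_sig + 1)
        fr = (fas + 0.5) / (n_noise + 1)
    elif correction == "none":
        hr = hits / n_sig
        fr = fas / n_noise
    else:
        raise ValueError("correction must be 'loglinear' or 'none'")
    return _z(hr) - _z(fr)


def dprime_by_block(classified: pd.DataFrame,
                    correction: str = "loglinear") -> pd.DataFrame:
    """Per participant x block d' (signal = regularity trials, noise = RAN)."""
    rows = []
    for (p, b), sub in classified.groupby(["participant", "block"]):
        sig = sub[sub["condition"].isin(REGULARITY_SIGNAL)]
        noise = sub[sub["condition"] == "RAN"]
        hits = int((sig["label"] == "hit").sum())
        # pre-transition presses count against the hit rate
        misses = int(sig["label"].isin(["miss", "pre_transition_excluded"]).sum())
        fas = int((noise["label"] == "false_alarm").sum())
        crs = int((noise["label"] == "correct_rejection").sum())
        rows.append({"participant": p, "block": b,
                     "dprime": dprime(hits, misses, fas, crs, correction),
                     "hit_rate": hits / max(hits + misses, 1),
                     "fa_rate": fas / max(fas + crs, 1)})
    return pd.DataFrame(rows)


def exclude_participants(dprime_table: pd.DataFrame, threshold: float = 2.0,
                         block: int = 0) -> list:
    """Participants whose first-block d' falls below the exclusion bound."""
    first = dprime_table[dprime_table["block"] == block]
    return sorted(first.loc[first["dprime"] < threshold, "participant"])


# ---------------------------------------------------------------------------
# RT baselining, trimming, advantage


def baseline_and_trim(classified: pd.DataFrame, sd_limit: float = 2.0,
                      trim: bool = True,
                      per_condition: bool = True) -> pd.DataFrame:
    """STEP-baselined RTs with per-participant x block outlier trimming.

    Subtracts each participant's mean STEP hit RT from every regularity-hit
    RT, then discards baselined RTs beyond ``sd_limit`` SDs of their mean
    within participant x block x condition (``per_condition=False`` pools
    the regularity conditions instead).  Per-condition trimming is the
    default because pooled trimming is a biased estimator of the RT
    advantage whenever the condition means differ by an amount comparable
    to the RT spread: the cut then removes the slow tail of the novel
    condition and the fast tail of the reoccurring one, compressing their
    difference (about 25% at realistic effect sizes in the package's own
    synthetic cohorts).  Trimming each condition around its own mean makes
    the skew-induced shrinkage identical across conditions, so it cancels
    in the advantage.  Participants without any STEP hit are flagged with
    a warning and keep NaN baselined RTs rather than being dropped.
    """
    df = classified.copy()
    df["baselined_rt_s"] = np.nan
    step = df[(df["condition"] == "STEP") & (df["label"] == "hit")]
    step_mean = step.groupby("participant")["raw_rt_s"].mean()
    missing = set(df["participant"]) - set(step_mean.index)
    if missing:
        warnings.warn(f"no STEP hits for participants {sorted(missing)}; "
                      "their RTs cannot be baselined")
    is_sig_hit = df["condition"].isin(REGULARITY_SIGNAL) & (df["label"] == "hit")
    df.loc[is_sig_hit, "baselined_rt_s"] = (
        df.loc[is_sig_hit, "raw_rt_s"]
        - df.loc[is_sig_hit, "participant"].map(step_mean))
    if not trim:
        return df
    df["trimmed"] = False
    group_cols = ["participant", "block"]
    if per_condition:
        group_cols.append("condition")
    for _, idx in df[is_sig_hit].groupby(group_cols).groups.items():
        vals = df.loc[idx, "baselined_rt_s"]
        if vals.notna().sum() < 2:
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        out = (vals - mu).abs() > sd_limit * sd
        df.loc[idx[out], "trimmed"] = True
        df.loc[idx[out], "baselined_rt_s"] = np.nan
    return df


def rt_advantage(classified: pd.DataFrame, grouping: str = "per_block",
                 novel: str = "RANREG", reoccurring: str = "RANREGr",
                 block: int | None = None,
                 rt_col: str = "baselined_rt_s") -> pd.DataFrame:
    """Mean RT advantage (novel minus reoccurring), per participant.

    ``per_block``: within each block, mean novel RT minus mean reoccurring
    RT.  ``per_intra_block_presentation``: the reoccurring condition's
    1st/2nd/3rd intra-block presentation (averaged across patterns) against
    novel trials of the corresponding block third.  Empty cells give NaN
    with a warning.
    """
    if grouping not in ("per_block", "per_intra_block_presentation"):
        raise ValueError("unknown grouping")
    df = classified[classified[rt_col].notna()]
    rows = []
    for p, sub_p in df.groupby("participant"):
        if grouping == "per_block":
            for b in sorted(classified["block"].unique()):
                sub = sub_p[sub_p["block"] == b]
                a = sub[sub["condition"] == novel][rt_col]
                r = sub[sub["condition"] == reoccurring][rt_col]
                if len(a) == 0 or len(r) == 0:
                    warnings.warn(f"participant {p} block {b}: empty RT cell")
                    adv = np.nan
                else:
                    adv = float(a.mean() - r.mean())
                rows.append({"participant": p, "block": b, "advantage_s": adv})
        else:
            b = int(classified["block"].max()) if block is None else block
            sub = sub_p[sub_p["block"] == b]
            for pres in (1, 2, 3):
                a = sub[(sub["condition"] == novel) & (sub["third"] == pres - 1)][rt_col]
                r = sub[(sub["condition"] == reoccurring)
                        & (sub["presentation_index"] == pres)][rt_col]
                if len(a) == 0 or len(r) == 0:
                    warnings.warn(f"participant {p} presentation {pres}: "
                                  "empty RT cell")
                    adv = np.nan
                else:
                    adv = float(a.mean() - r.mean())
                rows.append({"participant": p, "block": b,
                             "presentation": pres, "advantage_s": adv})
    out = pd.DataFrame(rows)
    out["advantage_tones"] = out["advantage_s"] / TONE_DURATION_S
    return out


# ---------------------------------------------------------------------------
# familiarity (explicit memory) and benchmark bootstrap


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, in [-1, 1].

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor in the denominator yields 0 (the conventional limit, reachable
    here because the familiar set holds only a handful of patterns).
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def mcc_from_responses(familiarity: pd.DataFrame) -> pd.DataFrame:
    """Per-participant MCC from a familiarity-response table.

    Expects columns participant, is_reoccurring (bool), tagged_familiar
    (bool): reoccurring patterns are the positive class.
    """
    rows = []
    for p, sub in familiarity.groupby("participant"):
        pos = sub["is_reoccurring"].astype(bool)
        tag = sub["tagged_familiar"].astype(bool)
        c = ConfusionCounts(tp=int((pos & tag).sum()),
                            tn=int((~pos & ~tag).sum()),
                            fp=int((~pos & tag).sum()),
                            fn=int((pos & ~tag).sum()))
        rows.append({"participant": p, "mcc": mcc(c)})
    return pd.DataFrame(rows)


def bootstrap_advantage(pool: np.ndarray, n_draw: int, iters: int = 1000,
                        rng: np.random.Generator | int | None = None,
                        observed: float | None = None):
    """Bootstrap distribution of the mean RT advantage of `n_draw` subjects.

    Resamples `n_draw` participant-level advantages with replacement from
    `pool`, `iters` times; returns the bootstrap means and, if an observed
    value is given, the one-tailed p: the proportion of bootstrap means at
    or beyond it (direction: larger advantage = pre-exposed faster).
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty advantage pool")
    if n_draw <= 0:
        raise ValueError("n_draw must be positive")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = rng.choice(pool, size=(iters, n_draw), replace=True)
    means = draws.mean(axis=1)
    if observed is None:
        return means, None
    p = float((means >= observed).mean())
    return means, p
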