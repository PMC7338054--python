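"""Synthetic participant cohorts for end-to-end analysis testing.

Generates trial-level button-press data with the statistical structure the
behavioural analysis assumes: a STEP motor baseline, log-normal detection
latencies for novel regularities, a learning curve that shortens latencies
for reoccurring patterns as they accrue presentations (exponential
approach to a plateau advantage), miss and false-alarm rates, and binary
familiarity judgements with configurable sensitivity.  Because every
generator parameter maps to an analysis output (plateau advantage -> RT
advantage, rates -> d', familiarity sensitivity -> MCC), the whole chain
is testable by parameter recovery without any human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seqmem.stimuli import REGULARITY_CONDITIONS, Session, schedule_session


@dataclass
class CohortSpec:
    """Generator settings for one simulated cohort.

    Detection latency is log-normal (median ``exp(latency_mu)`` s after the
    RT reference, spread ``latency_sigma`` in log units); reoccurring
    patterns earn a latency reduction Δ(k) = plateau_advantage x
    (1 - exp(-k / learning_rate_occurrences)) after k prior presentations,
    so the plateau advantage (default 0.233 s, the magnitude the analysis
    should recover) is approached exponentially.
    """

    n_participants: int = 20
    latency_mu: float = np.log(1.0)      # log s, novel-regularity median
    latency_sigma: float = 0.25
    plateau_advantage_s: float = 0.233
    learning_rate_occurrences: float = 1.5
    step_rt_mean_s: float = 0.35
    step_rt_sd_s: float = 0.08
    miss_rate: float = 0.05
    fa_rate: float = 0.02
    familiarity_hit_rate: float = 0.8
    familiarity_false_rate: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("miss_rate", "fa_rate", "familiarity_hit_rate",
                     "familiarity_false_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.latency_sigma <= 0 or self.step_rt_sd_s < 0:
            raise ValueError("scales must be positive")
        if self.plateau_advantage_s < 0:
            raise ValueError("plateau advantage must be >= 0")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


def _advantage(k_prior: int, spec: CohortSpec) -> float:
    if spec.learning_rate_occurrences <= 0:
        return spec.plateau_advantage_s if k_prior > 0 else 0.0
    return spec.plateau_advantage_s * (
        1.0 - np.exp(-k_prior / spec.learning_rate_occurrences))


def simulate_cohort(session: Session | str, spec: CohortSpec,
                    rng: np.random.Generator | int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every participant's presses for one session design.

    Each participant gets an independently scheduled session (fresh stimuli,
    same design).  Returns (trial responses, familiarity responses) in the
    schemas `behaviour.classify_responses` and `behaviour.mcc_from_responses`
    consume.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    trial_rows = []
    fam_rows = []
    for p in range(spec.n_participants):
        sess = (schedule_session(session, rng) if isinstance(session, str)
                else session)
        seen: dict[str, int] = {}
        for tr in sess.trials:
            seq = tr.sequence
            cond = seq.condition
            duration = seq.duration_s
            t_trans = seq.transition_time_s
            press = np.nan
            if cond == "STEP":
                if rng.random() >= spec.miss_rate:
                    press = t_trans + max(
                        rng.normal(spec.step_rt_mean_s, spec.step_rt_sd_s),
                        0.01)
            elif cond in REGULARITY_CONDITIONS:
                pid = seq.pattern_ref
                k_prior = 0
                if cond in ("RANREGr", "RANREGr*", "PATinRANr"):
                    k_prior = seen.get(pid, 0)
                    seen[pid] = k_prior + 1
                if rng.random() >= spec.miss_rate:
                    motor = max(rng.normal(spec.step_rt_mean_s,
                                           spec.step_rt_sd_s), 0.01)
                    latency = rng.lognormal(spec.latency_mu,
                                            spec.latency_sigma)
                    latency = max(latency - _advantage(k_prior, spec), 0.02)
                    press = t_trans + motor + latency
            elif cond == "RAN":
                if rng.random() < spec.fa_rate:
                    press = rng.uniform(0.2, duration)
            if not np.isnan(press) and press > duration:
                press = np.nan  # too slow: the trial ends first
            trial_rows.append({
                "participant": p,
                "block": tr.block,
                "third": tr.third,
                "trial_index": tr.trial_index,
                "condition": cond,
                "pattern_id": seq.pattern_ref,
                "presentation_index": tr.presentation_index,
                "transition_time_s": t_trans if t_trans is not None else np.nan,
                "duration_s": duration,
                "press_time_s": press,
            })
        # familiarity test: each reoccurring pattern once among novel foils
        regr_ids = [pid for ids in sess.spec.pattern_sets.values()
                    for pid in ids]
        for pid in regr_ids:
            fam_rows.append({"participant": p, "pattern_id": pid,
                             "is_reoccurring": True,
                             "tagged_familiar":
                                 rng.random() < spec.familiarity_hit_rate})
        for i in range(6 * max(len(regr_ids), 1)):
            fam_rows.append({"participant": p, "pattern_id": f"foil-{i}",
                             "is_reoccurring": False,
                             "tagged_familiar":
                                 rng.random() < spec.familiarity_false_rate})
    return pd.DataFrame(trial_rows), pd.DataFrame(fam_rows)
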