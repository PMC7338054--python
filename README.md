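# seqmem

Modelling and analysis machinery for **long-term implicit memory of tone
sequences**.  In the underlying paradigm, listeners hear rapid (20 Hz)
sequences of tone-pips drawn from a fixed pool of 20 frequencies and press
a button when a random stream (RAN) turns into a regularly repeating cycle
(RANREG).  Unbeknownst to them, a few cycles reoccur sparsely across the
session (RANREGr); memory for these patterns shows up as a **reaction-time
advantage** — reoccurring regularities are detected progressively faster
than novel ones, while explicit recognition stays near chance.

`seqmem` implements the full computational side of that paradigm for
researchers in auditory statistical learning and computational cognitive
neuroscience:

- **stimuli** — all conditions (RAN, RANREG(r), RANREGr\*, PATinRAN(r),
  STEP, CONT) as symbol sequences, plus declarative multi-block session
  schedules for six experiment designs;
- **ppm / decay** — a variable-order PPM sequence model (order bound 4,
  interpolated smoothing) whose n-gram counts can be filtered through a
  three-phase memory kernel: a 15-item echoic buffer, an exponential
  short-term phase (1 → 0.02 over 15 s), a slow long-term phase
  (half-life 500 s), and Gaussian retrieval noise (SD 1.3);
- **changepoint** — sequential Mann–Whitney monitoring of the model's
  per-tone information content IC = −log₂ P(tone | context), calibrated so
  false alarms occur once per 10⁴ tones; its alarm is the model's button
  press;
- **harness** — full-session simulations (stimuli → model → detector) for
  the unconstrained (perfect-memory) and memory-constrained models;
- **behaviour** — the human-side statistics: hit/false-alarm
  classification, d′ with ceiling correction, STEP-baselined and 2-SD
  trimmed RTs, block-wise and per-presentation RT advantage, Matthews
  correlation for the familiarity task, bootstrap benchmark distributions;
- **cohort** — a synthetic-participant generator with a programmable
  learning curve, so the whole analysis chain is testable by parameter
  recovery without human data.

## Worked example

Simulate the base experiment (5 blocks × 60 trials) with both models and
summarise the RT advantage for reoccurring patterns:

```python
from seqmem.decay import DecayParams
from seqmem.harness import (HarnessConfig, calibrate_matched,
                            run_replicates, summarize_rt_advantage)

det = calibrate_matched(arl0=10_000, n_sims=30_000, seed=0)   # ~1 min
cfg = HarnessConfig(model_mode="unconstrained", detector=det, seed=1)
df = run_replicates("1A", cfg, n_replicates=2, seed=42)
print(df[df.condition == "RANREG"].model_rt.mean())
# 1.309  -> novel regularities are detected ~1.3 s (one 1 s cycle plus
#           ~6 tones) after the transition

det_c = calibrate_matched(arl0=10_000, n_sims=20_000, seed=0,
                          decay=DecayParams())
cfg = HarnessConfig(model_mode="constrained", decay=DecayParams(),
                    detector=det_c, seed=11)
adv = summarize_rt_advantage(run_replicates("1A", cfg, 8, seed=42),
                             "per_block")
print(adv[["block", "advantage_s"]].round(3).to_string(index=False))
#  block  advantage_s
#      0        0.050
#      1        0.166
#      2        0.213
#      3        0.165
#      4        0.297
```

The two outputs are the package's central contrast: with perfect memory
the advantage for reoccurring patterns is immediate and large (~1 s from
block 2), whereas the memory-decay kernel makes it start near zero and
grow over blocks to ~0.2–0.3 s — the slow formation of an implicit memory
trace.  The numbers above are what the code prints for these seeds.

The numbered drivers under `analysis/` run the same pipeline as a
narrative: `01_generate_stimuli.py` (stimulus sets), `02_decay_kernel.py`
(the memory profile), `03_calibrate_detector.py` (Type-I calibration),
`04_simulate_models.py` (the paired model simulations above),
`05_synthetic_behaviour.py` (cohort parameter recovery).  Each writes its
tables under `results/`.  A `seqmem` CLI wraps the same stages
(`seqmem generate|calibrate|simulate|synth|analyze|plot-kernel|reproduce-fig5`).

## Documentation

`docs/methods.md` documents the models and their assumptions: the
smoothing recursion, the decay kernel's closed forms, why retrieval noise
applies to unstored n-grams, why detector calibration uses matched null
streams rather than IID surrogates, what the synthetic cohorts do and do
not emulate, and the package's known limitations.
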