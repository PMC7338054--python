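# Methods

This package simulates and analyses a transition-detection paradigm for
long-term implicit auditory sequence memory: listeners (or a model) monitor
rapid tone sequences for the emergence of a regularly repeating pattern,
and memory for sporadically reoccurring patterns reveals itself as a
reaction-time (RT) advantage that grows with exposure.  This note records
the models implemented, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## Stimuli

All stimuli index a pool of 20 frequencies log-spaced from 222 to 2000 Hz
(12% steps), presented as 50 ms tone-pips (20 Hz).  Conditions:

- **RAN** — random draws, no adjacent repeats (uniform conditional on the
  constraint, implemented by a draw over the 19 non-predecessor symbols);
- **RANREG** — a RAN prefix, then cyclic repeats of a fresh random
  permutation of all 20 pool indices (cycle = 1000 ms); the transition is
  uniform on the tone grid in the 3–4 s window, leaving 3–4 full cycles;
- **RANREGr** — as RANREG with a pattern that reoccurs identically across
  trials (the RAN portion is always fresh).  Each reoccurring pattern
  appears exactly once per block third;
- **PATinRAN(r)** — two identical 20-tone patterns embedded in random
  tones; the second always ends at the final tone, and the gap between
  them is uniform on the tone grid over 0.5–2.9 s (mean 1.7 s);
- **RANREGr\*** — a previously non-adjacent reoccurring pattern presented
  with its two cycles adjacent (test-block condition);
- **STEP / CONT** — single-frequency controls; STEP's frequency change
  supplies the human motor-RT baseline.

At the RAN→REG junction the final RAN tone is regenerated if it equals the
first cycle tone, so the adjacency rule holds while the reoccurring
pattern's identity is never altered.

Session schedules are declarative: per-experiment block compositions
(60 trials for the base experiment, 82 for the non-adjacency and
phase-shift experiments, 72 for the incidental-listening one), block-level
pattern transforms (time reversal in block 5 of experiment 1B; phase
shifts drawn one-per-presentation from the bins 2–7, 8–13, 14–19 tones in
block 4 of experiment 4), and reoccurrence placement one-per-third.  For
the non-adjacency experiment the paper's printed test-block duration
("about 5.45 ms") is read as 5.45 s = 109 tones; training-block RANREG(r)
trials carry exactly two cycles (length = transition + 40 tones), and all
test-block sequences are 109 tones with the two adjacent cycles ending at
the final tone (transition at tone 69, inside the 3–4 s window).  The
training-block sequence lengths are not stated in the source description;
these choices keep every regularity detectable while preserving the
printed cycle counts.

## The PPM model

Prediction is by a variable-order Markov model (PPM) over the 20-symbol
alphabet with order bound 4 (n-grams of length 1–5).  Each tone is
predicted from its within-trial context, scored as information content
IC = −log₂ P(tone | context), then added to the store.  The prediction
context resets at trial boundaries; the n-gram store persists — that
persistence is the only channel through which cross-trial memory exists.

**Interpolated smoothing.**  Orders are blended from the uniform 1/A base
upward: at each order with context count N > 0 and t distinct observed
continuations,

    P_o(x) = (c(x) + t · P_{o−1}(x)) / (N + t),

equivalently an escape weight λ = N/(N+t) on the order-o maximum-
likelihood estimate.  No update exclusion is used.  The literature offers
several escape conventions; this one is the standard interpolated-
smoothing construction, and an independent brute-force implementation of
the same recursion (dictionary counts, direct evaluation) pins the fast
engine exhaustively over all 3-symbol sequences of length ≤ 10 at 1e-9.
The smoothing choice does change exact IC values; the unconstrained-model
detection-latency benchmark (below) is the external anchor showing the
chosen variant reproduces the reference behaviour.

**Memory decay.**  In the constrained mode every stored observation
carries a three-phase weight:

| phase  | form | parameters (defaults) |
|--------|------|------------------------|
| echoic buffer | weight 1 while ≤ 15 further tones have been presented | capacity 15 items, weight 1 |
| short-term memory | exponential from 1 down to 0.02, reaching it exactly 15 s after buffer exit | weight 1, duration 15 s |
| long-term memory | exponential from 0.02 toward 0 with half-life 500 s | weight 0.02, half-life 500 s, asymptote 0 |

Buffer exit is item-count based (the evicting item's onset time starts the
STM clock), since the capacity is specified in items at a fixed 20 Hz
rate.  The STM form w(τ) = 1 · (0.02/1)^(τ/15) uses exactly the three
parameters that determine the phase; it implies an STM half-life of
15·ln2/ln50 ≈ 2.66 s, which the package reports rather than hard-coding
any other figure.  A nonzero LTM asymptote is supported in the kernel but
defaults to zero: consolidation ("fixing") of memory traces is explicitly
out of scope.

**Retrieval noise.**  At prediction time, every candidate n-gram count is
retrieved with one zero-mean Gaussian perturbation (SD 1.3), truncated at
zero — including n-grams with *no* stored records, which therefore
retrieve truncated pure-noise "phantom" counts (mean ≈ 0.52).  This
choice is load-bearing: if noise touched only stored n-grams, a single
long-decayed trace (weight 0.02) would remain perfectly discriminable
against exact-zero competitors and the constrained model would behave
almost like the perfect-memory one.  With phantom noise, weak LTM traces
are masked until they have accumulated over many reoccurrences, which is
precisely the slow memory-formation dynamic the constrained model exists
to produce.

**Engine.**  The store is a flat array of per-n-gram phase aggregates
updated lazily (buffer counts; STM/LTM sums decayed on touch), with two
global FIFO queues moving records between phases at their exact boundary
times.  This makes prediction O(alphabet × order) per tone regardless of
history length.  The pure-Python reference implementation evaluates the
same quantities record-by-record from the closed-form kernel; engine and
reference agree to 1e-8 over multi-trial sessions in both modes.

## Changepoint detection

A drop in IC marks emerging regularity.  The detector sequentially applies
the Mann–Whitney rank test: at each observation the trial's trace so far
is split at every point, the rank-sum statistic is standardised (midranks
and tie-corrected variance), and the maximum over splits is compared with
a length-dependent critical value h_n.  Monitoring is one-sided for
decreases, starts after a burn-in of 20 observations, and restarts at each
trial onset.  The first alarm is the model's "button press"; model RT =
(alarm tone − transition tone) × 0.05 s, with no STEP baselining (that
correction removes a human motor latency the model does not have).

**Calibration.**  Critical values are Monte-Carlo calibrated so the
conditional false-alarm probability at each monitored observation is
1/ARL₀ with ARL₀ = 10⁴ tones.  Two facts shaped the procedure:

1. *The model's null IC traces are not IID.*  They carry a deterministic
   warm-up (the first ~4 tones of each trial are predicted from short
   contexts), negative lag-1 autocorrelation (≈ −0.19), and a slow drift
   of the null statistic with store maturity.  IID-calibrated thresholds,
   though distribution-free over IID nulls, achieved only ~1 false alarm
   per 170 000 tones on these traces.  Default calibration therefore uses
   *matched* null streams: per-trial IC traces of the same model fed
   RAN-only sessions of 400 trials (the experiments' session-length
   regime), pooled over independent sessions.  Each model mode gets its
   own calibration (the constrained model's noisy traces have a
   heavier-tailed null statistic and correspondingly higher thresholds).
   The IID-Gaussian path is retained and unit-tested as the
   distribution-free reference.
2. *Tail-quantile estimation.*  Per-step thresholds use the k-th-largest
   order statistic with k* = (n+1)/ARL₀ (interpolated), whose expected
   out-of-sample exceedance is exactly 1/ARL₀; naive empirical quantiles
   at this depth were measurably anti-conservative.  Calibration sizes of
   2–3 × ARL₀ streams give a ~5% standard error on the achieved rate.

Zero-variance windows (constant traces) yield a zero statistic and can
never alarm.  Calibration streams are continuous, so the calibration
kernel omits the tie correction that `detect` applies to real traces.

## Simulated experiments

`run_session` presents every scheduled trial to one model on a continuous
clock — 20 Hz tones, fixed 1 s silent gaps between trials and between
blocks (calendar gaps between sessions are deliberately not modelled; the
observed persistence of human memory across days is exactly what the decay
model does not capture).  The detector monitors RAN, RANREG-family and
PATinRAN trials; STEP/CONT trials advance the clock and the store only.
Alarms before the nominal transition are tabulated as model false
positives, alarms on RAN trials as false alarms; both run at rates
consistent with the ARL₀ calibration.  Virtual subjects (`run_replicates`)
get fresh stimuli, schedules and noise streams.

With the Table-defaults kernel this machinery reproduces most of the
reference behaviour: the unconstrained model detects novel RANREG about
1.3 s after the transition (one cycle plus ~6 tones; reference value
≈ 1.4 s) and shows an immediate ~1 s advantage for reoccurring patterns
from block 2; the constrained model starts near zero advantage in block 1
and grows to ~0.2–0.3 s by block 5.  In the non-adjacency experiment's
test block, the unconstrained model is indifferent to how a pattern was
learned (equal large advantages for RANREGr and RANREGr*) and the
constrained model retains no usable trace of the non-adjacent patterns
(RANREGr* first-presentation advantage ≈ 0.02 ± 0.01 s at 320 virtual
subjects) — both as in the reference.  One reference property does *not*
emerge under this smoothing variant: the constrained RANREGr
first-presentation advantage is equally small (0.017 ± 0.011 s) rather
than clearly positive.  The structural reason is that with n-grams up to
length 5, adjacent-cycle training differs from non-adjacent training only
in the four cycle-junction n-grams (long-term mass ~0.1 count against
retrieval noise of SD 1.3), and the 109-tone test-block geometry leaves
just 40 post-transition tones, so the constrained model's ~1.7 s novel
latency presses against the trial end and compresses all condition
differences.  Noise regimes that make single stored traces sharply
discriminable restore a large advantage — but for both conditions at
once, mimicking the unconstrained model instead.  The corresponding
acceptance test asserts the reference property and is expected to flag
this divergence.

## Behavioural statistics

The analysis chain mirrors the human pipeline: presses after the nominal
transition on regularity trials are hits (pre-transition presses are
excluded as false positives, not misses), RAN-trial presses are false
alarms.  d′ = z(hit) − z(FA) collapses RANREG and RANREGr, with a
log-linear ceiling correction (0.5 added per cell, 1 per count) as a
swappable policy — the source reports near-ceiling rates but no rule.
Participant exclusion applies the configurable first-block d′ bound
(default 2, lenient variant 1).  RTs are baselined by each participant's
mean STEP RT and trimmed at 2 SD within participant × block × condition.
Per-condition trimming is the default because the package's own cohort
simulations show pooled trimming biases the advantage downward by ~25%
whenever the condition means differ by an amount comparable to the RT
spread (the pooled cut removes the novel condition's slow tail and the
reoccurring condition's fast tail); a pooled switch exists.  Even
per-condition, SD-based trimming carries a small (~−0.01 s) bias from
unequal cell sizes — the 9-trial reoccurring cell retains more of its
slow tail than the 18-trial novel cell — which the recovery tests
quantify and document.  The RT advantage is novel minus reoccurring,
per block or per intra-block presentation with presentations 1/2/3 matched
to novel trials of the corresponding block third.  For the non-adjacency
experiment RTs are referenced to the second-cycle onset.  Familiarity
judgements are scored with the Matthews correlation coefficient (zero
denominator → 0, the standard convention, reachable because only three
patterns are "familiar").  The pooled benchmark distribution is a
participant-level bootstrap (draw N with replacement, 1000 iterations)
with a one-tailed p.

## Synthetic cohorts

The generator emulates the trial-level structure the analysis assumes:
STEP presses at the change plus Gaussian motor RT (0.35 ± 0.08 s);
regularity hits at transition + motor + log-normal detection latency
(median 1 s, σ = 0.25 log-units); misses at 5%, RAN false alarms at 2%;
familiarity tagging at 80%/20% hit/false rates.  Reoccurring patterns earn
a latency reduction Δ(k) = 0.233 · (1 − e^(−k/1.5)) s after k prior
presentations — an exponential approach that plateaus within the first
blocks, with the plateau set to the reference effect magnitude (0.233 s =
4.66 tones).  What the generator does *not* emulate: individual-difference
covariance, fatigue or attention drift, consolidation across days, and any
dependence of latency on the specific pattern.  Passing recovery tests
therefore show the *analysis chain* is unbiased at realistic effect sizes
and noise, not that real listeners behave this simply.

## Problem sizes and numerical choices

Default simulation sizes were chosen as the smallest that leave
Monte-Carlo error well under each effect of interest: detector calibration
at 20–30 k streams (≈5% SE on the achieved rate), 2 virtual sessions
(180 trials) for the latency benchmark (trial-to-trial SD 0.035 s), 10–48
virtual subjects for the advantage signatures, 50 cohorts for parameter
recovery.  All randomness flows from one root seed through named
substreams (stimuli / retrieval noise / calibration / cohort); repeated
runs with the same configuration are byte-identical.  Weighted counts are
real-valued throughout; retrieval noise draws come from the engine's own
seeded generator, one draw per candidate count per prediction.

## Known limitations

- The smoothing variant and noise granularity are reconstructions of an
  incompletely specified reference; exact IC values (and hence exact RTs)
  inherit that uncertainty even where qualitative behaviour matches.
- The detector is calibrated per model mode on 400-trial RAN sessions;
  substantially longer sessions would need recalibration because the
  unconstrained null drifts with store maturity.
- Human-data-only phenomena — 24 h and 7-week retention, the consolidation
  "fixing" effect, explicit-familiarity MCC magnitudes — are outside what
  model simulations or synthetic cohorts can establish.
- Audio rendering, on-screen feedback, and inferential ANOVA machinery are
  intentionally absent; tidy CSV exports feed external statistics tools.
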