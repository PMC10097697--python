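# Methods

## Task model

A session is three 80-trial blocks. Appetitive and aversive blocks run
first in seeded random order; the bivalent block is always last, so the
single-valence blocks provide the value reference for the bivalent one.
Each block draws a seeded uniform permutation of the fixed trial multiset
(20 cued trials per CS probability 1.0/0.5/0.0, plus 10 per uncued type).
"Pseudorandom" presentation is implemented as exactly this permutation,
with no run-length constraints — the simplest reproducible reading.

Trial timing (integer ms from trial start): a 1,000-ms pre-TC pad, TC onset
at 1,000, CS onset at 2,200 (TC lasts 1,200 ms), trace onset at 3,200,
outcome at 4,200 for 100 ms, and a 500-ms post-outcome pad (trial end
4,800 ms). The pads exist so that the 1,000-ms pre-TC baseline window and
the post-outcome test window are defined on every trial. Inter-trial
intervals are drawn uniformly on [3,000, 5,000] ms and recorded but not
simulated as spiking epochs.

Uncued trials display the TC but no CS, and their outcome falls at the same
absolute time as cued outcomes (TC + CS + trace durations after TC onset).
Whether the animals saw a TC on uncued trials is a convention here — it
keeps a pre-TC baseline defined for every trial and puts the free outcome
exactly where a cued outcome would fall.

Outcome draws follow the context matrix: appetitive — reward with
probability *p*, else tone; aversive — airpuff with *p*, else tone;
bivalent — reward with *p*, else airpuff. In the bivalent context the
airpuff probability of a cued trial is therefore 1 − *p*.

## Synthetic neurons

Spike trains are inhomogeneous Poisson processes with piecewise-constant
intensity: a per-context baseline plus rectangular response kernels.
Because the intensity is piecewise constant, generation is exact (Poisson
segment counts + uniform times), and spike counts inside any
constant-intensity window are exactly Poisson — which the dispersion test
in the suite verifies. Spike times are floored to integer ms (1-kHz
sampling of the emulated recordings).

Archetype families and their driving variables:

| family | epoch | drive |
|---|---|---|
| `cs_value_pos` / `cs_value_neg` | post-CS kernel | reward probability *p* / 1 − *p* |
| `pred_reward_pref` / `unpred_reward_pref` | post-outcome kernel, delivered rewards | predictability level / its complement |
| `uncertainty_50_highest` / `_lowest` | whole trace, 50% trials | +gain / −gain |
| `punishment_value` | post-CS kernel | airpuff probability |
| `context_baseline_shift` | whole trial | ±gain in gated contexts |
| `nonselective` | — | baseline only |

A context gate (`appetitive_only`, `bivalent_only`, `shared`,
`aversive_only`, `aversive_bivalent`) multiplies the kernel gain by 1 in
gated contexts and 0 elsewhere. Reward-value families are silent to
airpuff-predicting CSs in the aversive block. Intended intensities below
zero are clamped to zero and counted in the log — never an exception.

Defaults: baseline 5 Hz and response gain 12 Hz per unit drive — a
modulation depth typical of robustly task-modulated LH neurons, chosen once
as the study condition; CS/US kernels start 100 ms after their driving
event and last 400 ms, aligning their energy with the [201, 401) ms test
windows; uncertainty kernels span the whole trace. The context baseline
shift defaults to ±3–5 Hz. The built-in 240-neuron mix mirrors the observed
taxonomy qualitatively (every family in shared and context-dependent
variants, a smaller punishment contingent, a large untuned remainder) and
is fully configurable via an archetype-mix file.

## Synthetic behaviour

Licks and blinks are Poisson point events. In the 2-s anticipatory epoch
before the outcome the lick rate is `1 + 6·P(reward)` Hz and the blink rate
`0.5 + 4·P(airpuff)` Hz; in the bivalent context blink rates are multiplied
by the attenuation factor κ (default 0.6 — the weaker avoidance observed
when reward is also possible; κ = 1 disables the effect and is the null
used for calibration tests). A 0.2-Hz background rate runs outside the
epoch. At 15 sessions (~1,800 cued trials entering the probability ×
context ANOVA) the κ = 0.6 condition produces a context main effect of
roughly F ≈ 60, which is the scale of effect the analysis is meant to
detect.

## Analysis conventions

- **Windows.** All windows are half-open `[start, end)` in integer ms.
  Printed bounds such as "201–400 ms" denote 200 ms of 1-kHz data and are
  encoded `[201, 401)`; the same convention gives the TC window
  `[101, 501)`. The catalog: behaviour `[-250, 0)` before outcome; z
  baseline `[-500, 0)` and context baseline `[-1000, 0)` before TC; CS and
  US test `[201, 401)` after CS onset / outcome; trace-uncertainty
  `[-500, 0)` and trace-late `[-400, 0)` before outcome.
- **z-scoring.** Per neuron per block: `(rate − μ)/σ` where μ, σ are the
  mean and *across-trial* SD of the 500-ms pre-TC baseline rate (the
  across-trial reading of the baseline statistic; an across-time-bin SD
  would be the alternative). If σ = 0, bins equal to μ get z = 0 and any
  departure flags the neuron "degenerate-baseline"; such neurons are
  excluded from z-based population analyses with a logged warning rather
  than producing infinities.
- **Per-neuron statistic.** OLS slope t-test on trial-level rates,
  reported as (r, p) — identical to the Pearson correlation test with one
  predictor. Trial-level (not condition-mean) regression is required for
  meaningful per-neuron p-values with only three condition levels. The
  classification criterion is α = 0.05 per family per block (surfaced in
  config; the observed-by-chance rate of ~5% uncertainty coders in the
  aversive block is consistent with this choice). Bonferroni correction is
  applied only where a specific battery states it (behaviour ladder /3,
  group AUC conditions /3, pairwise Welch tests /3).
- **Predictability coding scale.** Levels enter on the probability scale
  (1.0/0.5/0.0) rather than as ranks; with three equally spaced levels the
  OLS test on ranks is identical up to sign, so the choice is innocuous.
  Free-US trials enter as level 0.
- **ROC-AUC.** Normalised Mann–Whitney U (ties ½) of test-window versus
  pre-TC baseline rates; validated in the suite against exhaustive
  pair-counting and the complement identity AUC(a,b) + AUC(b,a) = 1.
- **Sliding series.** Per 200-ms window (10-ms steps), each neuron's
  within-block sensitivity is recomputed on that window's rates, then the
  two blocks' sensitivity vectors are correlated across all neurons
  (Spearman). CS-value series run from CS onset over the 2-s CS+trace
  epoch (181 windows); predictability series run from outcome delivery
  over the 600-ms post-outcome epoch. In the aversive block the
  predictability ladder is the airpuff's (that block's own US).
- **PCA.** Fit on condition-averaged population vectors: non-overlapping
  100-ms bins from CS onset to trace end (20 bins) for the 100% and 0%
  trial types in all three blocks, raw averaged rates with per-neuron mean
  centering only (no per-bin z-scoring; switchable). Held-out vectors
  (uncued outcomes, US responses) are projected with the training centering
  and loadings. The bin span/step is configurable; one published caption's
  bin arithmetic (90 bins per condition) is inconsistent with non-overlapping
  100-ms bins over a 2-s epoch and is not used as a correctness target.
- **Behaviour.** X/Max normalisation per session and measure; the ladder
  tests pair *session-level condition means* (the signed-rank test needs a
  pairing unit, and sessions are the natural one), while the blink
  probability × context ANOVA uses trial-level observations (matching the
  published degrees of freedom, which imply trials). The blink ladder runs
  over airpuff probability, which in bivalent blocks is the complement of
  the stated reward probability. Identical paired samples give p = 1 by
  convention. An all-zero measure is marked unavailable rather than
  dividing by zero.

## Validation experiments and problem sizes

The suite validates the pipeline by parameter recovery and calibration, at
sizes chosen to make Monte-Carlo error small relative to each tolerance:

- null calibration of the uncertainty classifier: 10,000 constant-rate
  neurons on one aversive block (labelled fraction within 1.5 points of
  the 5% criterion);
- archetype recovery: 40 neurons per (family × gate) plus 3,000 null
  neurons on a full session — sensitivity ≥ 0.9 per family, 100% sign
  agreement among detected, pooled false-positive rate within 1.5 points
  of α, context-gate accuracy ≥ 0.85;
- cross-block series: a 60-neuron population with heterogeneous gains
  shared between appetitive and bivalent blocks (sustained value kernels)
  gives significantly positive ρ across CS-period windows; populations
  with independently drawn per-block gains are pooled over 12 runs, since
  overlapping sliding windows within one population are strongly
  correlated and a single run has very few effective independent tests;
- PCA identities (orthonormality, ordered variance, exact reconstruction,
  block-offset separation) and the behaviour battery (κ = 0.6 power at 15
  sessions, κ = 1 chance-rate detection over 12 replicates).

## What the generator does and does not emulate

It reproduces the task structure exactly, graded behaviour including the
bivalent blink attenuation, and the response taxonomy with context gating.
It does **not** model: biophysics (neurons are Poisson, so no refractory
periods or bursting), inter-neuron correlations or simultaneous-recording
covariance (neurons are conditionally independent given the schedule),
temporally structured kernels (all rectangular), eye-position or video
signals (blinks are emitted as point events directly), or slow
nonstationarities within a session. Passing recovery tests therefore shows
the *analysis* is correct and calibrated under its stated assumptions — it
does not show that real LH populations satisfy those assumptions, and
headline counts obtained on real recordings are not reproducible from
synthetic data.

## Known limitations

- The per-cell classification α and the z-SD convention are assumptions
  surfaced in configuration, as noted above.
- Degenerate-baseline handling discards information from silent-baseline
  neurons in z-based analyses.
- The sliding-series significance flags are pointwise; no correction for
  the strong dependence between overlapping windows is applied (the
  published series are presented the same way).
- Multi-session datasets are supported by the data model, but the
  classifier treats each neuron's session as its entire world; there is no
  across-session alignment of neurons.
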