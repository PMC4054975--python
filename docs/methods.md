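# Methods

`cogload` implements a subject-specific two-class mental-workload decoder
for EEG and the evaluation machinery needed to ask one specific question:
how much accuracy does such a decoder lose when the affective context
(relaxed vs. psychosocially stressed) changes between calibration and use,
and how much of that loss does cross-context calibration recover?  Because
no public dataset carries this protocol, the package ships a synthetic
study generator whose event schedule reproduces the protocol exactly and
whose signal model plants controllable class effects and context
nonstationarities.

## Protocol geometry

One session = two affective contexts x 12 two-minute n-back blocks.
Within a context, 0-back (low workload) and 2-back (high workload) blocks
alternate, six of each.  Every block presents 60 letters for 500 ms at a
2-s onset pitch (1500 ms inter-stimulus interval); 25% of letters are
targets (exactly 15 per block).  Trials are 2-s epochs locked to letter
onset; target trials are discarded to keep target-evoked P300 components
out of the workload contrast.  The arithmetic that follows from this:
60 trials/block, 720 trials per workload level, 540 per level after target
exclusion (270 per context per level), 45 surviving trials per block.
Context order and the starting workload level are counterbalanced over
four scenarios when a multi-subject study is generated.

## Signal model of the generator

The generator is deliberately the simplest model whose class and context
structure lives exactly in the feature spaces the decoder probes:

* **Oscillatory sources.** One stationary Gaussian source per classical
  band (delta 1-4, theta 4-8, alpha 8-12, beta 12-30, gamma 30-47, high
  gamma 53-90 Hz), produced by band-pass filtering white noise, spatially
  mixed through a seeded random orthonormal 28 x 6 forward matrix.
  Resting source amplitudes are 6/5/8/4/2/1.5 uV RMS.  Workload multiplies
  source power by `band_power_effects` (defaults: delta 1.2, theta 1.3,
  alpha 0.7 — load raises frontal low-band power and suppresses alpha);
  the stress context multiplies power by `context_shift` (defaults 1.25 /
  1.25 / 0.8 on delta/theta/alpha), independent of workload.  The shift is
  confined to low bands, mirroring where context effects concentrate in
  real recordings.
* **ERP.** A biphasic template (small negativity near 170 ms, ~400 ms-wide
  positive deflection peaking near 300 ms, confined to the first second)
  on a fixed centro-parietal channel subset; peak amplitude 2 uV for low
  workload plus `erp_amplitude_effect` (default 1 uV) for high workload.
* **Artifacts and noise.** Blink-like EOG transients (Poisson, 6/min,
  60-120 uV) on four EOG channels, leaking into frontal EEG channels with
  fixed known coefficients so regression cleaning is exactly verifiable,
  plus 2 uV white sensor noise.

The effect magnitudes are not identifiable from any published numbers;
they were chosen once so that the frequency-domain pipeline operates in
the accuracy regime reported for comparable 2-s-trial workload studies
(~70-75%), and frozen.  A 20-subject run under these defaults gives mean
within-context accuracy ~73%, across-context ~71%, combined-training
~73% for the frequency variety.

What the generator does **not** emulate: 1/f broadband structure,
volume-conduction realism, fatigue and time-on-task drifts, behavioral
responses, or any interaction between stress and the workload effect.
Passing tests therefore demonstrate that the pipeline recovers the kinds
of structure it is designed for and that the evaluation schemes measure
what they claim — not that the decoder would reach these numbers on real
EEG.

## Decoding pipeline

* **Cleaning.** Every EEG channel has the least-squares combination of the
  four EOG channels subtracted; coefficients come from cross-covariances
  over the full recording.  This is applied before any train/test split —
  deliberate, as only artifact statistics (never class labels) cross fold
  boundaries.
* **Oscillatory branch.** Per band (4th-order Butterworth, zero-phase,
  applied per epoch), CSP filters solve `C_high w = lambda (C_high +
  C_low) w` on class-averaged, per-trial trace-normalized covariances;
  6 largest + 6 smallest eigenvalue filters per band; features are
  log-variances of the filtered trials: 72 features.  Log-power rather
  than raw power is used as the standard variance-stabilizing choice for
  LDA; `log_variance_features` exposes the primitive directly.
* **ERP branch.** 0.5-16 Hz zero-phase band-pass, polyphase resampling to
  exactly 36 Hz (the 16 Hz low-pass acting as anti-alias filter),
  truncation to the first second: 36 samples/channel.  Regularized Fisher
  spatial filters treat every time sample as a channel-space observation;
  one pooled scatter pair is built from per-sample class means and
  residuals, the within-class scatter shrunk as `(1-lambda) S_w + lambda
  (tr S_w / C) I` with lambda = 0.4.  Six filters x 36 samples = 216
  features.  The per-sample-filters alternative was rejected because the
  216-feature count implies a single 6 x C projection.
* **Selection and classification.** Per branch, greedy mRMR (difference
  scheme, mutual information after equal-frequency discretization into 8
  bins, lowest-index tie-break) keeps 18 features; the combined variety
  concatenates 18 + 18.  Shrinkage LDA uses the pooled within-class
  covariance blended toward `(tr S / d) I` with the analytic Ledoit-Wolf
  intensity; the bias puts the boundary at the midpoint of the projected
  class means; exact zero scores resolve to the high class.

## Evaluation schemes

All folds partition whole blocks and balance workload per fold (and
context, where both appear).  `general`: sixfold over 24 blocks (900
train / 180 test trials).  `within`: sixfold over one context (450 / 90).
`across`: the within training folds of one context tested on two-block
folds of the other.  `combined`: six random training blocks per context,
all trials of four plus every other trial of the remaining two (alternating
start parity, so 23 + 22 trials), matching the within scheme's 450 (+-2)
training trials; tested on two held-out blocks of a single context;
six independent seeded repetitions.  `halves_within` / `halves_across`:
threefold inside six-block context halves (180 / 90), separating the cost
of time passing from the cost of the context change.  When fewer complete
blocks exist, fold counts fall back with a warning.

Per fold, spatial filters, mRMR and LDA see training trials only.  Block
decisions fuse the 45 trial labels by majority vote (odd count — no tie;
even counts resolve by mean signed score).  The chance level for n test
trials is `100 * ceil(n/2 + z sqrt(n/4)) / n` with z = 1.96 at alpha =
0.05 — the two-sided normal approximation with ceiling to the next
achievable correct count (53.1% at n = 1080, 71% at n = 24); an exact
binomial variant is available via `method="binomial"`.  The behavioral
block statistic is `(TP + TN) / (TP + TN + FP + FN)`.

Statistical comparison across subjects (repeated-measures ANOVA) is out
of scope; `evaluate_study` exports the tidy per-subject/per-scheme/per-fold
table for external tools.

## Numerical choices and conventions

* Trial indexing is 0-based and half-open: `[onset, onset + 2 s)`, so
  trials tile the block exactly at the 2-s pitch.
* Eigenvector rows are unit-norm with the largest-magnitude coefficient
  positive, for reproducible serialization.  Generalized eigenproblems use
  `scipy.linalg.eigh`; singular pooled covariances / scatters raise with a
  pointer to regularization rather than produce garbage.
* Per-trial trace normalization (CSP) trades exact mixing-invariance of
  the eigenvalue spectrum for robustness to high-variance trials:
  invariance remains exact for trace-preserving (orthogonal) mixings and
  for `normalize="none"`.
* mRMR mutual information is computed from contingency tables in nats;
  constant features discretize to a single bin and get zero relevance.
* The EDF writer emits plain 16-bit EDF with one-second records and a
  symmetric physical range per channel (quantization error < 0.01 uV at
  typical amplitudes); events travel in a TSV sidecar keyed by onset
  seconds.  Epoch sets serialize to a compressed array container with a
  JSON header.

## Problem sizes used in the shipped tests

Structural and oracle tests run on toy instances (3-28 channels, tens of
trials).  Calibration tests use one full default session each (1080
trials).  The cross-context pattern is established on a 20-subject
default-configuration study, frequency-domain variety, schemes within /
across / combined — about 320 s of compute on one core.

## Known limitations

* The generator's block-constant gain steps create small spectral edge
  artifacts at block boundaries; epochs never straddle blocks, so the
  pipeline does not see them.
* EOG regression estimated on the full recording slightly deflates
  across-fold independence; only artifact statistics, never class labels,
  cross fold boundaries.
* With only two contexts per session, context is confounded with time by
  design; the halves schemes exist precisely to bound that confound, not
  to remove it.
* Chance-level conventions differ across the BCI literature; the default
  here reproduces the normal-approximation convention, and exact-binomial
  values can differ by a few tenths of a point.
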