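# Methods

`gradedbci` simulates, end to end, a brain-computer-interface (BCI) system
in which 96-channel intracortical recordings from primary motor cortex are
decoded into a continuously graded wrist-flexion command that drives
functional electrical stimulation (FES) of the forearm. No public
recordings exist for this paradigm, so every input is synthetic; the point
of the package is that the *analysis chain* — artifact excision,
mean-wavelet-power features, beta-regression and SVR decoders, the
closed-loop stimulation/plant/fatigue dynamics, and the scoring
statistics — is implemented faithfully and testable.

## Task structure

Both experiments are organized in 24-cue blocks: three repetitions of four
target angles in seeded random order, each 5 s cue followed by a 5 s rest
cue (120 s per block). The virtual (imagined) experiment uses targets
{52.5°, 90°, 127.5°, 165°} with rest at 0° over seven blocks. The FES
experiment uses the physical wrist range — rest 36°, maximum flexion
128° — with targets {60°, 82°, 105°, 128°} for eleven blocks: one
open-loop block (stimulation follows the cue), one first volitional block,
three training blocks, four test blocks (stimulation recalibrated between
the third and fourth), and two generalization blocks whose intermediate
targets move to {57°, 76°, 111°} and {71°, 90°, 114°}. Inter-block breaks
are treated as zero-length; the only modeled pause is the recalibration
break (120 s, see below).

## Synthetic neural signals

Channels carry one of four tuning classes seen on real arrays: monotone
increasing with angle, a step up from rest followed by an affine decrease
over non-zero angles (the classic non-monotone shape), non-linear
(unimodal Gaussian bump by default, saturating optionally), and flat.
By default 56 of 96 channels are informative, drawn from the three
responsive classes with weights (0.40, 0.25, 0.35); per-channel gains are
uniform on [0.8, 2.0] and response latencies uniform on [0.2 s, 0.4 s]
(mean 0.3 s, consistent with sub-500 ms cortical responses; the latency
spread is also what makes similarly tuned electrodes statistically
separable).

Two generation levels share these tuning curves:

- **Raw voltage** (30 kHz, µV): per channel, broadband Gaussian noise
  (σ = 20 µV) plus an independent band-limited carrier (234.375–1875 Hz,
  4th-order Butterworth) whose instantaneous power is
  `baseline * (1 + gain * shape(x))` with baseline 100 µV², evaluated at
  the delayed normalized angle. Total power is therefore exactly
  broadband + band power (verified against a Parseval oracle within 1%).
  Stimulation artifacts are injected as biphasic exponentially decaying
  transients (3 ms support, configurable peak) on all channels at the
  20 Hz pulse grid.
- **Feature level** (10 Hz): per-frame channel values
  `gain * shape(x)` plus unit-variance white noise, smoothed by the same
  trailing 1 s boxcar the raw pipeline applies. This level is used for
  session-scale and many-seed experiments; the raw level exercises the
  full signal path.

The per-frame feature noise (σ = 1 before smoothing) was fixed once so
that the simulated virtual experiment lands near the published operating
point: closed-loop FES success near 90% and roughly 45–55 of 96 channels
significant in the pooled beta regression.

What the generator does *not* emulate: spike waveforms, electrode drift,
non-stationary baselines, cross-channel noise correlations, or any neural
phenomenon beyond angle-tuned band power. Passing tests therefore show
that the pipeline recovers what this model encodes — not that it would
decode arbitrary real recordings.

## Preprocessing

Raw data are processed in 100 ms frames (3000 samples). Stimulation
artifacts are detected when at least 4 of 12 fixed, seeded sentinel
channels exceed |500 µV| within a 0.5 ms coincidence tolerance; detections
closer than 3.5 ms are merged. A 3.5 ms window starting at each detection
is excised and the remainder rejoined; at most five excisions are honored
per frame, so every frame keeps at least 82.5% of its samples (20 Hz
stimulation removes exactly 2 × 105 samples, retaining 93%).

Mean wavelet power (MWP) per channel and frame: a db4 discrete wavelet
decomposition; the mean absolute detail coefficient at levels 4–6, whose
dyadic bands at 30 kHz tile 234.375–1875 Hz (the multiunit band); a
trailing 1 s boxcar; an optional trailing 15 s boxcar baseline
subtraction (enabled only in the virtual experiment); z-standardization
per channel and level against training-block statistics; and an average
over levels. "Mean of the coefficients" is implemented as the mean of
absolute values — raw means cancel to ≈0. Boxcars are causal because the
online system updated every 100 ms.

Two numerical details matter. First, boundary-padding coefficients are
trimmed (one filter length per end, per level): their leakage depends on
the frame length, which would otherwise bias the mean by ~7% at level 6
whenever excision shortens a frame. Second, coefficients whose support
straddles a rejoin splice are excluded. With both, artifact injection
followed by excision changes the per-scale means by <1% on average; the
residual per-frame scatter (~7–14% at level 6) is the irreducible cost of
discarding 7% of the coefficients, and is what limits how "invisible"
excision can be on channels with no tuning signal.

## Decoding

Angles are scaled to the open unit interval — virtual: `a/180`; FES:
`(a − 36)/92` — and clamped to [1e-3, 1 − 1e-3] because the beta
likelihood is undefined at the endpoints.

**Beta regression** models the scaled angle with a beta density whose mean
follows `logit(mu) = b0 + sum_j b_j MWP_j` and constant precision φ.
Maximum likelihood uses Fisher scoring on (β, log φ) with step halving, so
the log-likelihood is non-decreasing by construction; initialization is
slope coefficients at zero, intercept at `logit(mean y)` and φ from the
method of moments. Standard errors and two-sided Wald p-values per channel
come from the inverse expected information at the MLE; no multiple-testing
correction is applied, matching how raw significant-channel counts are
usually reported. The fit agrees with `statsmodels`' independent
implementation to ~1e-4 on shared problems. One caveat the tests encode:
on the smoothed 10 Hz stream consecutive frames are autocorrelated, so
full-resolution Wald tests are anti-conservative; calibrated inference
requires thinning to roughly one frame per smoothing window.

**SVR** is ε-insensitive support vector regression (libsvm via
scikit-learn) with an RBF kernel on the same standardized features;
defaults C = 10, γ = 1/96, ε = 0.01. ε was chosen small because a wide
tube (0.05 ≈ 4.6° of slack) leaves the decoded rest state biased upward
enough to destabilize the rest cues in the closed loop.

**Training protocol.** Online decoders are retrained after each block on
the ≤3 most recent blocks, with standardization statistics recomputed on
the same window. In FES mode the decoder trained after the third training
block (blocks 3–5) is frozen for all test and generalization blocks.
Training labels are the cue lagged by 0.7 s — the known channel latency
plus the smoothing boxcar's group delay — so that transition frames pair
features with the cue that generated them; without this alignment the
~15% of frames inside transitions compress the decoder's output range by
roughly a third. SVR training frames are thinned by a stride of 2 to keep
session-scale refits fast; beta regression uses every frame.

## Stimulation encoding and the wrist plant

The decoded force command F ∈ [0, 1] maps to a stimulation amplitude
through a monotone piecewise-linear calibration (five anchors, fitted at
session start by sweeping amplitudes and recording achieved angles),
clipped to [0, 20] mA, at 20 Hz / 500 µs pulses updated every 100 ms.
Commanded amplitudes pass through a first-order slew filter (EMA
coefficient 0.35 per frame) — FES amplitudes are ramped, not stepped.

The plant integrates: a recruitment curve with a 2 mA motor threshold and
exponential saturation reaching full flexion at 14 mA when fresh; wrist
angle relaxing toward the recruited target with τ = 0.3 s over 36–128°;
load-cell force 0.3–0.7 lb affine in angle (σ = 0.02 lb noise, zero at
rest, giving angle–force correlation >0.93 as in the physical rig); and a
charge-integrating leaky fatigue accumulator (rate 0.0046/s at full
amplitude, recovery 0.0016/s). Fatigue scales the *suprathreshold* drive
by `1 − min(0.6, 6 · max(0, fatigue − 0.30))`: functionally silent early,
then an abrupt decline, bounded by a fatigue-resistant fraction. These
constants were chosen, once, to reproduce the qualitative published
narrative — training blocks unaffected, a marked mismatch between decoded
and achieved angles across the later test blocks, restoration after
recalibration — not any particular numeric value.

Recalibration (between test blocks 3 and 4) models the experimental
break: 120 s of rest (partial fatigue recovery), then a fresh amplitude
sweep whose (amplitude, achieved angle) pairs are inverted into a new
anchor set by binned medians with monotonicity enforcement. Under
accumulated fatigue the refit map drives harder at the top, up to the
20 mA ceiling.

## The closed loop and the subject model

In the feature-level FES session the loop closes twice per 100 ms frame:
decoded force → amplitude → plant, and plant → subject. The subject model
is leaky integral compensation of the visually observed error: the
imagined force is `cue + b`, with `b ← 0.9 b + 0.08 (cue − observed)`
(reset at each cue onset, intent clipped to [0, 1.15]). A cue-driven
open-loop generator cannot reproduce closed-loop success rates: the real
participant watched his wrist and corrected; the small gain and leak are
what keep the loop stable given the ~1 s sensorimotor latency of the
pipeline. In raw-signal mode the neural stream stays cue-driven and the
session instead exercises artifact injection, excision and the wavelet
path.

## Scoring and statistics

A cue is successful if the trajectory stays within 15° of the target
(inclusive) continuously for ≥2 s inside the scoring window: 6.5 s for
movement cues (5 s cue + 1.5 s grace), 3.5 s for rest cues (5 s minus the
preceding grace). Dwell is measured on the linearly interpolated
trajectory, so band crossings between samples count fractionally and the
verdict is invariant to the sampling rate between 10 and 30 Hz.

Block accuracy is pooled counts k/n with the binomial standard error
100·√(p(1−p)/n) — this, and not the between-block SE, reproduces the
published ±-figures from the printed counts. The calibration difference
distribution (CDD) is decoded-minus-achieved angle over movement windows,
summarized per block by median and IQR (linear-interpolation quantiles).
Channel-level condition contrasts use a two-sided permutation test on the
difference of trial-mean MWP (trials averaged 0.5–2.5 s post-cue),
exhaustive when the assignment count permits and otherwise Monte Carlo
with the add-one estimator.

## Problem sizes used by the test suite

Session-scale experiments run at the feature level: full 7-block virtual
and 11-block FES sessions; the fatigue/recalibration comparison uses 20
paired seeds; the beta-vs-SVR ordering uses 50 replicates of a 3-block
design (2 train, 1 test) with tuning dominated by the non-monotone and
unimodal classes (mixture 0.0/0.8/0.2), which is the regime where a
logit-linear readout is genuinely handicapped. Raw-voltage tests use
single blocks or shorter streams. Parameter recovery uses n = 2000 frames
with 5 active of 96 channels at φ = 50.

## Known limitations

- The subject model is a fixed-gain controller; real volitional
  compensation is adaptive and faster, so absolute accuracies are only
  qualitatively comparable to the published ones.
- Fatigue parameters are narrative-calibrated; the published IQR values
  (8.6°, 26.6°, 10.0°) and human accuracy tables depend on the
  participant and are not reproduction targets.
- Wald p-values at full frame resolution inherit the smoothing
  autocorrelation (as do analogous counts computed on real data).
- The published "scales 3–6" conflicts with the published band
  (234–1875 Hz) under any consistent dyadic indexing at 30 kHz; the band
  is treated as authoritative, selecting levels 4–6.
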