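# Methods

This note documents the models implemented in `physioaffect`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic benchmark can and cannot show.

## The modeling problem

Twelve music excerpts, three per valence-arousal quadrant, are each
described by a 5-vector of physiological features (SCL, HR, Resp, Zyg,
Corr) and a pair of mean felt-emotion ratings on 1–9 scales, all collapsed
across participants. Two model families map features to ratings: stepwise
linear regression, and a 5-5-2 sigmoid network trained on 8 excerpts (two
per quadrant: M1, M2, M4, M5, M7, M8, M10, M11) and tested on the held-out
four (M3, M6, M9, M12). A signed connection-weight decomposition then
attributes each output to the inputs.

## Signal processing

- **Filters.** Channel defaults: SCL and Resp unfiltered; the cardiac pulse
  band-passed 0.5–3 Hz; EMG band-passed 1–500 Hz. The filter family and
  order are not dictated by the feature definition, so a zero-phase
  (forward-backward) 2nd-order Butterworth is used — standard
  psychophysiology practice with a testable contract (≥ 20 dB stop-band
  attenuation on out-of-band tones, exact pass-through when both cutoffs
  are disabled). A low-pass at or above Nyquist (e.g. the 500 Hz EMG cutoff
  at a 100 Hz sampling rate) is clamped to 0.45 × sample rate with a
  warning.
- **Rate conversion.** Local maxima with a minimum separation of
  60/max-rate seconds and a prominence floor; inter-event intervals
  implying rates outside the physiological bounds (HR 40–180/min, Resp
  5–180/min) are rejected and the events/min series is linearly
  interpolated across them (interval rates placed at interval midpoints,
  held constant at the edges). Rate conversion precedes z-scoring: z-scores
  of a raw pulse waveform would not measure heart rate. Interpolation
  rather than sample-dropping keeps the feature windows fully populated.
- **EMG rectification.** The feature is a windowed mean, but a band-passed
  EMG signal has mean ≈ 0 regardless of activity, so the filtered EMG is
  full-wave rectified (absolute value) before z-scoring. This is an
  assumption the source feature definition leaves open; it is the choice
  that makes an amplitude effect visible to a mean-based feature.
- **Standardization.** Per participant and channel, the mean/SD pool over
  *all* of that participant's trials (baselines included), after rate
  conversion/rectification. A zero pooled SD is an error, not a silent
  NaN.
- **Feature windows.** Baseline mean over the final 20 s of the 30 s
  white-noise baseline; music mean over seconds 10–40 of the excerpt (the
  first 10 s of each segment are excluded as a startle guard). Exactly 20 s
  and 30 s of samples enter every feature; a window extending past its
  segment is an error.
- Features are averaged over participants after baseline subtraction; for
  unweighted means the order is irrelevant, but the order is fixed for
  transparency. Only participants with a complete trial set enter the
  average.

## Linear stage

Pearson r with two-tailed t-based p-values on n − 2 df. Stepwise forward
entry: at each step every remaining candidate is added to the current OLS
model and the one with the smallest coefficient p-value (equivalent to the
partial F test) enters while p < α_enter; after each entry, members whose
p-value has drifted above α_keep are removed (never the one just entered).
Defaults α_enter = 0.10, α_keep = 0.15: the benchmark arousal model retains
respiration at p = 0.07, so a 0.05 entry threshold would be inconsistent
with the procedure being reproduced; removal can be disabled (α_keep = 1)
for pure forward entry. Ties break on the fixed column order (scl, hr,
resp, zyg, corr). An empty model is legitimate and predicts the training
mean. A warning (not an error) is logged when n/candidates < 5 — twelve
excerpts against five predictors is below usual regression norms and the
fits are read as descriptive.

## Network and training protocol

Architecture 5-5-2, logistic activations everywhere, hidden units kept
equal to inputs as the overfitting guard. Protocol details and the
reasoning where the source protocol is silent:

- **Input squashing.** The stated procedure passes inputs through a sigmoid
  before the first weight layer; this is implemented literally behind
  `input_sigmoid` (default on), with the conventional variant available.
  Fidelity first: the squashing compresses [0, 1] inputs to [0.5, 0.73] and
  measurably slows early training but does not prevent convergence.
- **Biases.** Not mentioned in the source protocol; included by default and
  initialized like weights, because a sigmoid-output network with
  all-positive initial weights and no biases cannot express targets below
  0.5. A no-bias mode exists for strict-literal runs.
- **Scaling.** Features are min-max scaled to [0, 1] on the *training*
  excerpts; test inputs use the training scaling and are not clipped, so
  distribution shift remains visible. Ratings map by r ↦ (r − 1)/8 (exact
  inverse 8o + 1), the affine map matching sigmoidal outputs to the 1–9
  scale.
- **Updates.** Per epoch, all 8 patterns are presented in a randomized
  order, per-pattern deltas of E_p = ½‖o − t‖² are accumulated, and the sum
  is applied once with learning rate 0.1 (full-batch gradient descent).
  Presentation order provably cannot affect a summed update; it is retained
  for protocol fidelity, with one permutation drawn per epoch. Gradients
  are verified against central finite differences (tolerance 1e-6).
- **Stopping.** Fixed 80,000 epochs; convergence (final MSE < 0.02 on the
  scaled targets, MSE averaged over patterns and both outputs — the
  per-pair-mean convention, documented because the summing convention is
  not dictated) is *reported*, not used for early stopping. Non-finite loss
  raises with the epoch index; at this scale (37 parameters, 8 patterns,
  lr 0.1) training is monotone-stable in practice and a loss increase from
  epoch 0 to the end is treated as a defect, not tolerated noise.
- **Ensemble.** 20 trials, independent U(0, 0.05) re-initializations from
  spawned RNG substreams; per-excerpt predictions are trial means. The
  trainer carries a leading trial axis so one numpy path trains one network
  or twenty; a single trial is numerically identical to a direct `train()`
  call.

## Contribution analysis

For hidden unit j and input i, the signed share w_ji / Σ_i′ |w_ji′| is
scaled by the hidden-to-output weight w_oj, summed over j, and normalized
so that Σ_i |c_io| = 1 per output. Biases are excluded: the decomposition
partitions influence carried by input-connected weights. The method is
scale-invariant (positive rescaling of an output's weights changes nothing;
negative rescaling flips all of that output's signs) and equivariant under
input permutation — both are property-tested, and a hand-derived two-input
case (weights (3, 1) into one hidden unit: contributions (0.75, 0.25))
pins the exact form.

Contribution *sizes* (|c|) across the 20 trials are compared with a one-way
repeated-measures ANOVA, trials as subjects, uncorrected degrees of freedom
((k − 1), (k − 1)(n − 1)) = (4, 76) at the default geometry. Whether signed
values or sizes feed the ANOVA was an open choice; sizes are used, matching
the "relative size" framing. The null threshold 1/5 = 0.2 (equal sharing)
is applied to the trial-mean |c|; features at exactly the threshold are not
reported (strict inequality). Note that a feature far below the threshold
has a sign that is essentially noise — sign interpretation is only
meaningful above threshold.

## Evaluation conventions

"Distance" between predicted and observed ratings is computed per dimension
(|ŷ − y|, a 1-D Euclidean distance): separate valence and arousal errors
are reported, and error % uses the 8-unit span (mean error 0.82 → 10.25 %
→ accuracy 89.75 %), the only convention under which the published
arithmetic is self-consistent. The combined 2-D distance is available as a
supplementary quantity. RMSE is computed on the (r − 1)/8 scaled space,
which is what makes values near 0.1 commensurate with rating-unit errors
near 0.8. Accuracy + error % = 100 exactly. Pearson r between predicted
and observed means is reported as unavailable (None) when either series is
constant.

## Synthetic-data generator

The generator exists so the whole pipeline is testable without the
unreleased recordings. What it emulates, per trial (30 s baseline + 40 s
music, 100 Hz default; 1000 Hz reproduces the original sampling):

- **Cardiac pulse:** an asymmetric raised-cosine pulse per beat (peak at
  ~37 % of the interbeat interval), rate 70 bpm at baseline rising by
  2 bpm per arousal unit above the scale midpoint during music, with 3 %
  CV interbeat jitter. Planted rates outside 40–180 bpm raise a generation
  error naming the channel.
- **Respiration:** a quasi-sinusoidal belt signal, 15 breaths/min baseline,
  +0.8/min per arousal unit and +0.5/min per valence unit, 5 % CV breath
  jitter, bounds 5–60/min.
- **SCL:** a tonic level with a slow intrinsic oscillation plus low-pass
  drift noise; the music window shifts by −0.10 conductance units per
  valence unit (higher for negative valence).
- **EMG:** band-limited noise whose *music-window amplitude* carries the
  valence effect (+0.05 relative units per valence unit for zygomaticus,
  −0.08 for corrugator) — amplitude modulation, not a mean shift, because
  the feature stage rectifies EMG.
- **Ratings:** round(clip(latent + N(0, 1.8), 1, 9)); the 1.8 SD reproduces
  the reported inter-subject rating variability (clipped-sample SD ≈ 1.78
  at mid-scale, verified by Monte-Carlo).
- **Participants:** random per-participant offsets on each channel's effect
  level (0.5 × the channel noise SD; 1.0 bpm HR and 0.5 bpm Resp for the
  rate channels, whose effect units differ from waveform noise units).
  There is no published anchor for inter-subject physiological variance;
  these are modest, documented choices.
- **Latent excerpt values** default to the benchmark study's published
  per-excerpt mean ratings, so synthetic studies cover the valence-arousal
  grid the same way.
- **Determinism:** every trial draws from an RNG substream keyed by
  (participant, excerpt) under the study seed, so output is bit-identical
  across runs and independent of generation order.

The effect sizes were fixed once, at values a psychophysiologist would call
realistic for musical emotion induction (a few bpm of HR range across the
arousal scale, fractions of a microsiemens of SCL, tens of percent of EMG
amplitude), and produce feature-rating correlations comparable in strength
to those reported for real recordings.

**Interaction mode** (`valence_interaction=True`) multiplies every valence
drive by (arousal − 5)/2.5. Each feature then carries (nearly) zero linear
valence information across the excerpt grid, but valence remains
recoverable from the joint pattern (the sign of the SCL/Corr response
flips between high- and low-arousal excerpts, and arousal itself is
readable from HR). This is the regime in which a non-linear model should
outperform stepwise regression on valence, and the benchmark property test
uses it.

**What it does not emulate:** biophysically realistic hemodynamics or
electrodermal kinetics, motion/electrode artifacts, missing channels,
habituation across the session, or correlated channel noise. Passing the
synthetic benchmark therefore shows that the *pipeline* recovers planted
structure of realistic size under honest noise — it does not certify the
accuracy figures attainable on real recordings.

## Numerical choices and degenerate inputs

- Zero-variance inputs raise errors (undefined correlation, zero pooled SD,
  degenerate min-max range, zero ANOVA error SS, all-zero hidden-unit input
  weights) rather than propagating NaNs.
- Collinearity in a selected regression set (design condition number
  > 1e10) is an error.
- Peak detection requires at least two accepted events per window and names
  the channel when it fails.
- Stepwise ties and candidate order are deterministic; all stochastic
  stages (generation, initialization, presentation order) are seeded, and
  the end-to-end report is byte-reproducible for a fixed configuration.

## Problem sizes used in tests and the acceptance script

Tests and the acceptance script run the full design (20 participants × 12
excerpts, 100 Hz, 20 network trials × 80,000 epochs). Replicate-based
properties use 20 fixed seeds. The 100 Hz default (the original recordings
used 1000 Hz) is the one deliberate scale reduction; the EMG synthesis is
band-limited so the default remains meaningful, and the sampling rate is
configurable where the 500 Hz EMG low-pass is itself under test.

## Known limitations

- With 8 training excerpts and 37 free parameters the network interpolates
  its training set; test accuracy rests entirely on the smoothness of the
  planted (or real) feature-rating relation.
- The stepwise procedure's p-values are nominal, not selection-adjusted;
  under the null it enters at least one spurious predictor in roughly
  1 − 0.9⁵ ≈ 41 % of datasets at α_enter = 0.10, which the null-recovery
  test checks as a rate, not as an impossibility.
- Contribution signs below the null threshold are noise; only
  above-threshold directions are interpreted.
- The repeated-measures ANOVA applies no sphericity correction, matching
  the convention of the analysis being reproduced.
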