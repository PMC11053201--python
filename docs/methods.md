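# Methods

This note documents the models implemented in `fusefall`, the conventions
chosen where the underlying method leaves details open, the synthetic data
the package trains and validates on, and the limits of what the included
experiments demonstrate.

## Problem setting

The package detects human falls in 3-second clips from two non-invasive
modalities: a skeleton keypoint track extracted from video by a pose
estimator (consumed as data — pose estimation itself is out of scope), and
the clip's mono audio. Each modality gets its own classifier; their
per-clip fall probabilities are combined by decision-level fusion. "Fall"
is the positive class throughout.

## Video branch: two-stream ST-GCN

**Input.** Per frame, a 57-element pose prediction vector: box center,
width/height, box and class confidences, then 17 COCO-ordered keypoint
triples (x, y, score). Coordinates are image pixels, origin top-left, y
down. Frames whose keypoint scores are all below 0.05 are treated as blank
and eliminated (the threshold is configurable; the source procedure states
only that blank frames are removed).

**Skeleton graph.** The 17 COCO joints with the standard natural-connection
edge set:

```
nose—eyes—ears chain: (0,1) (0,2) (1,2) (1,3) (2,4)
ears—shoulders:       (3,5) (4,6)
arms:                 (5,7) (7,9) (6,8) (8,10)
trunk:                (5,6) (5,11) (6,12) (11,12)
legs:                 (11,13) (13,15) (12,14) (14,16)
```

The method never enumerates its edges; this list is the package's
convention. Spatial graph convolution sums over the 1-hop neighborhood of
each joint with one weight block per partition subset and a normalization
term balancing subset contributions. Three partition strategies are
implemented: *uni-label* (one subset), *distance* (self vs. neighbors), and
*spatial configuration* (same hop distance to the body root — the hips —
vs. closer vs. farther); spatial configuration is the default. The
normalization divides by the total 1-hop neighborhood size, so the
partition stack is jointly row-stochastic: a constant node signal is
preserved exactly (this contract is property-tested).

**Normalization.** Each frame is translated so the hip midpoint is at the
origin, and all coordinates are divided by the median torso length
(hip-midpoint to shoulder-midpoint distance) over the clip. The result is
invariant to global translation and uniform scaling (asserted to 1e-9).
Occluded keypoints (score 0) keep their coordinate value; no interpolation
is performed. The source states only that joint coordinates are
normalized; this recipe is the package's documented choice and is recorded
in the output metadata so alternatives stay pluggable.

**Motion stream.** Frame-to-frame differences of the normalized
coordinates, frame 0 all zeros, shape preserved. Both streams feed
identical (separately parameterized) nine-layer ST-GCN stacks.

**Network.** Each ST-GCN layer is a graph-convolution sub-block (1x1
convolution over partition-stacked propagated features, batch norm, ReLU)
followed by a temporal convolution (kernel Γ over time per joint, batch
norm, dropout) with a residual connection. Temporal strides are 2 at
layers 4 and 7 and 1 elsewhere, so 75 input frames reach the head at
ceil(ceil(75/2)/2) = 19 frames. Global average pooling per stream,
concatenation, and a fully connected two-way softmax head give the clip
probability. Binary cross entropy is the training loss (identical to
two-class categorical cross entropy).

Defaults: channel plan 64,64,64,128,128,128,256,256,256 (the canonical
progression for this architecture; the source fixes only the layer count
and stride positions), Γ = 9, dropout 0.5, Adam at lr 1e-3. The
desk-scale preset (`TwoStreamConfig.tiny()`) keeps the topology and stride
plan but narrows channels to 8…32, uses Γ = 5, dropout 0.1, 12 epochs,
batch 32, and trains in about a minute on one CPU at 260 clips.

**Label smoothing (0.05 in the desk preset, 0.1 for the audio branch)**
bounds the attainable logit scale so the trained classifiers keep *graded*
confidence on borderline content instead of saturating at 0/1. This is a
deliberate calibration choice: decision fusion can only outperform the
better single modality when the erring classifier is also the less
confident one, and the fusion experiments below depend on it.

**Frame-level inference.** A clip classifier yields per-frame scores via a
sliding window (default 45 frames, inference stride configurable); each
frame inherits the probability of the window whose center is nearest. The
source does not describe its frame-level mechanism; this is the package's
convention.

**Video-level aggregation.** A clip is a fall when at least 15 consecutive
frames are classified fall (frame threshold 0.5); the fall confidence is
the maximum over qualifying maximal runs of the mean frame probability in
the run. For non-fall clips — where the rule defines no confidence — the
reported fall probability is the maximum sliding-window mean of length 15,
so fusion always receives a probability. Run detection is property-tested
against an exhaustive window scan.

## Audio branch: log-mel + MobileNetV2

**Preprocessing.** An automatic energy-gate trim removes leading/trailing
regions more than 40 dB below the clip peak (100 ms pads, never returns
empty audio); it replaces any manual clip clean-up in the original
procedure.

**Augmentation.** Five label-preserving waveform methods — white noise at
20 dB SNR, time-domain lengthening (x1.2) and shortening (x0.8), volume
+6 dB and −6 dB — expand a corpus exactly sixfold (260 clips → 1560). The
training protocol augments the training split only.

**Features.** Log-scaled mel spectrogram: Hann-windowed power STFT
(n_fft 1024, hop 512, no center padding, so a length-L clip yields
1 + (L − n_fft)//hop frames), a 64-band triangular mel filterbank, and
log10 with a 1e-10 power floor. The spectrogram is bilinearly resized to
the classifier's square single-channel grid and standardized per image.
All DSP parameters are package choices (none are stated in the source) and
are configurable.

**Classifier.** MobileNetV2: stem convolution (32 channels, stride 2),
seven inverted-residual bottleneck stages with (expansion, channels,
repeats, stride) schedule (1,16,1,1), (6,24,2,2), (6,32,3,2), (6,64,4,2),
(6,96,3,1), (6,160,3,2), (6,320,1,1), a 1x1 convolution to 1280 features,
global average pooling, dropout, and a two-way head. At the reference
224x224 single-channel input the stage feature sizes are
112,112,56,28,14,14,7,7 and the parameter count is 2,225,858 (width 1.0,
1 input channel, 2 classes; verified against a closed-form sum over the
schedule). A width multiplier scales every channel count, rounded to
multiples of 8 (minimum 8).

The desk-scale preset (`MobileNetV2Config.tiny()`) uses width 0.25 on a
48x48 input and keeps only the first three bottleneck stages. The reason
is empirical and structural: at desk-scale input sizes the deep tail of
the schedule operates on 2x2 and 1x1 feature maps, where it memorizes the
training set instead of generalizing (observed directly on a trivially
separable bright-patch control task: full schedule ~0.75 held-out, first
three stages ~0.99). The full schedule remains the default architecture
and all architecture contract tests run on it.

Training: Adam with classic L2 weight decay (1e-4), lr 1e-3, label
smoothing 0.1, 12 epochs. Stratified 5-fold cross-validation is available
(`kfold_evaluate`) with every sample tested exactly once.

## Decision fusion

Let a and b be the video and audio fall probabilities for a clip.

**Linear weighting:** c = α·a + (1−α)·b with α the video weight. Video is
the primary modality, so the recommended operating band is α ∈ [0.6, 0.9]
(values outside warn but do not fail); the pipeline sweeps
α ∈ {0.6, 0.7, 0.8, 0.9} and reports each.

**Dempster–Shafer:** over the frame of discernment Θ = {fall, not-fall},
each probability becomes a basic probability assignment m({fall}) =
(1−d)·p, m({not-fall}) = (1−d)·(1−p), m(Θ) = d with discount d (default 0;
the source never states its assignment construction). Dempster's rule
combines the two assignments with conflict renormalization:

    (m1 ⊕ m2)(A) = 1/(1−K) · Σ_{B∩C=A≠∅} m1(B)·m2(C),
    K = Σ_{B∩C=∅} m1(B)·m2(C).

The printed form of the conflict coefficient in the source contradicts
itself (both sums range over non-empty intersections); the standard
empty-intersection definition above is implemented, consistent with the
1/(1−K) normalization. K = 1 (contradictory certainties) raises an
explicit error. With d = 0 the combination reduces exactly to the Bayesian
product rule a·b/(a·b + (1−a)(1−b)), which serves as a closed-form test
oracle. Belief and plausibility functions provide the [bel, pl]
credibility interval; decisions use the pignistic probability
m({fall}) + m(Θ)/2 by default. Ties at the 0.5 threshold resolve to
not-fall everywhere (conservative for specificity).

## Evaluation

TP/FP/TN/FN with fall positive; sensitivity, specificity, accuracy,
precision and F1 as percentages, full precision internally, half-up
rounding to two decimals for display (required to reproduce printed
reference values exactly), explicit undefined markers for zero
denominators. Identity properties (accuracy as the prevalence-weighted mix
of sensitivity and specificity; F1 as the harmonic mean of precision and
sensitivity) are property-tested.

## Synthetic data

The generator emulates 3-second paired clips at the reference recording
conditions: 75-frame (25 fps) 17-joint tracks in 320x240 pixel coordinates
and 16 kHz mono audio, 130 clips per class by default, exact balance,
bijective skeleton/audio pairing, fully seed-deterministic.

A scalar *severity* drives both modalities monotonically from daily
activity toward a fall. Video: the hip descends 15 + 75·s px over
28 − 18·s frames (smoothstep), the body axis rotates toward horizontal by
up to 80°; daily activities are walking (gait oscillation, no descent),
sitting down and squatting (slow modest descent, upright torso). Audio: a
damped broadband impact transient time-locked to the end of the skeletal
descent (falls) or soft periodic footsteps (daily activity) over ambient
noise, amplitude rising with severity (25 dB peak SNR at s = 1). Normal
clips draw s from U(0.75, 1) for falls and U(0.05, 0.25) for daily
activity, far from the s = 0.5 midpoint, which makes the classes linearly
separable in the two hand-crafted oracle features: maximum hip descent
rate (threshold 4.2 px/frame, the mid-severity value) and waveform crest
factor (threshold 19, likewise). Keypoint scores are high with a 3%
dropout rate; coordinates carry 1.5 px Gaussian noise.

**Modality error injection** replaces a clip's content in one modality,
independently per modality with the configured probability, by
opposite-class content drawn near (but across) the severity midpoint
(s ∈ (0.30, 0.44) or (0.56, 0.70)). The injected content is deliberately
placed in the *classifier's* uncertainty zone while staying on the wrong
side of the oracle threshold: flipped daily-activity video is a slumping
sit-down with a 32–46° torso lean (hop-distance features near the
boundary, descent rate still below the oracle threshold); flipped fall
audio is a low-pass "muffled thud" (spectrally unlike training falls,
crest factor preserved); flipped daily-activity audio gains one faint
sharp stumble. A classifier of the injected modality then errs at
approximately the injection rate — with moderate confidence — while the
other modality stays correct and confident. This is the independent-error
regime that decision-level fusion exploits, mirroring the motivating
study's situation where video misses falls that audio catches.

**What the generator does not emulate:** real pose-estimator failure modes
(identity switches, long occlusions, background-person detections),
reverberant or polyphonic acoustics, camera motion, and any correlation
between lighting and pose quality. Passing the included experiments shows
the pipeline's machinery is correct and that fusion behaves as designed in
a controlled independent-error regime; it does not certify performance on
real recordings.

## Experiment protocol and problem sizes

The pipeline trains on a clean corpus (130 clips/class by default, 8:2
stratified clip-level split, one root seed driving every stage) and
evaluates on a *separately generated* inference corpus (120 clips/class)
carrying the configured modality error rates — training on originals and
validating on independently degraded data, as in the motivating protocol.

The desk-scale benchmark runs used throughout the tests and the acceptance
script: video branch, 260 clips, ~75 s to 100% held-out accuracy; audio
branch, 260 clips with sixfold train-split augmentation, ~65 s to 100%;
fusion experiment, 5 replicate seeds at 80 train-clips/class and 120
inference-clips/class with 18%/5% injected video/audio errors (~90 s per
replicate). In a 5-seed pilot at these sizes: video 91.0%, audio 93.1%,
linear fusion (α = 0.7) 94.7%, Dempster fusion 97.2% mean accuracy.
Linear fusion is evaluated at the best swept α (the motivating study
likewise sweeps the video weight and reports its optimum); its mean gain
over the better single modality is small and seed-sensitive (about ±2
points), while the Dempster gain is consistently positive.

## Numerical choices

- The neural-network engine is a compact in-repo reverse-mode autodiff on
  numpy arrays (float32 working precision; float64 context for gradient
  verification). Convolution forwards are verified against
  `scipy.signal.correlate2d`; all backwards against central differences
  (1e-4 relative on a two-layer network, typically far better).
- BCE predictions are clipped to (1e-7, 1 − 1e-7).
- Dempster combination renormalizes by the surviving mass so the unit-sum
  contract holds to 1e-12 even near total conflict.
- Batch norm uses momentum 0.1 running statistics; eval mode is used for
  all reported predictions.
- All randomness flows through `numpy.random.SeedSequence` trees from one
  root seed per run; same seed, same report, bit for bit.

## Known limitations

- Figure-level details of the original network (exact per-layer channel
  numbers, weight sharing between streams) are not recoverable from the
  source; the canonical ST-GCN choices used here are conventions.
- The frame-level inference mechanism and the non-fall confidence are
  package conventions (see above).
- Desk-scale accuracies on synthetic data say nothing quantitative about
  the published accuracies on real recordings, which require the original
  dataset and trained weights.
- The audio branch trains from random initialization; no pretraining is
  used or supported.
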