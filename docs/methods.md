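# Methods

`oculemo` re-implements an eye-movement-based emotion perception pipeline:
synchronous electrooculography (EOG) and eye-video recordings are reduced to
time-frequency and oculomotor time-domain features, which are fused at the
feature level (FLF) or the decision level (DLF) and classified into three
valence classes (positive / neutral / negative) with polynomial-kernel SVMs.
Because no paired EOG + eye-video emotion dataset is publicly available, the
package ships a synthetic trial generator with exhaustive ground truth; all
quantitative claims made by the test suite are claims about that generator.

## Signal model and preprocessing

Four monopolar electrodes are assumed: HEOR/HEOL lateral to the eyes and
VEOU/VEOD above/below one eye, sampled at 250 Hz in microvolts.  Bipolar
derivations isolate the two movement axes: `h = HEOR − HEOL`,
`v = VEOU − VEOD`.

The band-pass keeps 0.01–10 Hz: oculomotor potentials live below 10 Hz,
while electrode drift and polarization sit near DC.  The filter is an
order-32 Butterworth band-pass (16th-order prototype, second-order
sections) applied forward–backward, hence zero-phase — event timing feeds
the duration features downstream, so phase delay would bias them.  Two
numerical points matter at such an extreme corner (0.01 Hz at 250 Hz
sampling, a relative frequency of 4·10⁻⁵):

* an FIR realisation of the same order is impossible: 33 taps at 250 Hz
  have a frequency resolution of several hertz and cannot separate DC from
  the 1–10 Hz passband (the windowed design has DC gain 1.16; forcing a DC
  null destroys the passband).  The IIR band-pass places exact zeros at DC.
* `sosfiltfilt` is called with `padlen=0`.  The default odd-reflection
  padding scales the step-matched initial filter state by the *pad*
  endpoint rather than the true first sample; the mismatch excites the
  ~0.01 Hz poles and leaves a decaying mode (time constant tens of
  seconds) with amplitude of the order of the signal itself.  With
  `padlen=0` the measured responses are: DC gain < 10⁻⁸, 5 Hz gain 1.0006,
  50 Hz residual < 0.08, linearity error < 10⁻¹⁰.

Amplitude normalization rescales the rectified trace,
`(|s| − min|s|) / (max|s| − min|s|)`, to exactly [0, 1]; constant-magnitude
traces are rejected rather than silently mapped.

## Time-frequency features

Each bipolar trace is cut into 1-s windows hopping by 0.5 s
(`M = floor((T − 1)/0.5) + 1` frames; 119 for a 60-s trial).  Every window
is linearly resampled to L = 64 samples, tapered with a 64-point Hamming
window and transformed with a 64-point DFT; magnitudes of bins 0–31 (DC
included, Nyquist excluded) are retained.  Resampling is the bridge between
a 1-s window and a 64-point transform at an arbitrary sampling rate: the
effective in-window rate becomes 64 Hz, so bin *l* sits at *l* Hz and the
0.01–10 Hz band occupies the lower third of the retained bins.  The two
channel spectrograms (horizontal, vertical) are averaged element-wise and
flattened bin-major, giving a 32 × 119 = 3808-dimensional observation
vector for a 60-s trial.  Features are magnitudes, not powers: they stay on
the amplitude scale the SVM standardization expects.

Averaging the two bipolar channels (rather than concatenating them, which
would double the dimension) is the symmetric way to reconcile per-channel
spectrograms with a single fixed-length vector.

## Saccade detection (EOG)

Saccades appear as step-like transitions on the horizontal bipolar trace.
The detector correlates the trace with a Haar wavelet at a single fixed
scale (default 20 samples = 80 ms at 250 Hz):
`C[b] = (1/√a) Σ_t x(b+t) ψ(t/a)`, ψ = +1 on the first half of its support
and −1 on the second.  |C| peaks where a step bisects the support.  The
threshold is *adaptive per recording*: 1/3 of the recording's maximum |C|.
Supra-threshold runs become events (rising edge = start, falling edge =
end), and events outside the physiological 10–100 ms saccade band are
discarded.  The supra-threshold run of an ideal step spans roughly
(2/3)·(scale + rise time) samples, i.e. ≈ 53–90 ms for rises up to ~20 ms —
inside the gate.  This also means the *generator's* saccade-duration ranges
must stay below ≈ 65 ms for the detector to be able to score perfect recall
on clean trials; the class defaults respect that (see below).

Detection runs on the horizontal trace only (vertical optionally unioned
via `include_vertical_saccades`), because the vertical channel is dominated
by blink transients.

## Pupil measurement and fixation detection (video)

Frames are grayscaled with ITU-R 601 luma weights (0.299/0.587/0.114),
then binarized with a threshold driven by the frame's minimum pixel value
(MPV): `4·MPV` when MPV ≤ 20, `3·MPV` when 20 < MPV ≤ 30, else 75.  The
pupil is the darkest structure, so the threshold hugs it adaptively in dark
frames and falls back to a fixed level in bright ones.

The pupil circle is recovered with a circle Hough transform implemented
from first principles because its exact semantics are contractual: edge
pixels are black pixels with at least one white 4-neighbor; each edge pixel
votes, for every candidate radius and every 1° angle, for the center it
implies (`a = x₀ − r cos θ`, `b = y₀ − r sin θ`, rounded); the accumulator
cell with the most votes wins, ties broken toward the smallest radius and
then the smallest (row, column); a best cell with fewer than 3 votes means
"no circle" (`found = False`).  On noiselessly rasterised disks the
recovery is exact over a 3×3×3 grid of centers and radii.  Per-frame
extraction optionally *tracks*: after the first confident detection the
radius search narrows to ±2 px around the previous estimate (the vote
space over centers is never restricted, so saccadic jumps are not lost);
this follows the slow pupil dynamics at a fraction of the full search cost.

Fixations are detected from per-frame pupil centers with a two-pass rule:
(1) maximal runs of frames whose consecutive centers move ≤ 1 px on each
axis; (2) a run is kept only if its duration (frames/fps, bounds inclusive)
lies in [0.1, 0.2] s *and* its total dispersion (max − min) is ≤ 3 px on
both axes.  The rule is implemented literally, including its rejection of
stable segments longer than 200 ms; frames without a valid pupil are
bridged with the most recent valid center.

## Time-domain features

Eleven scalars per segment: max/mean/SD of saccade duration plus saccade
frequency (count / segment duration); the same four for fixations;
max/mean/SD of pupil diameter (2 × radius over frames with a valid
measurement).  Event SDs are population SDs (a single event has SD 0).
Empty event lists yield zeros; a segment with no valid pupil yields zero
pupil features with a warning.

## Fusion and evaluation

FLF concatenates the TF vector with the 11 time-domain values (3808 + 11 =
3819 under 60-s defaults) and trains one SVM.  DLF trains four SVMs — TF
vector, saccade 4-vector, fixation 4-vector, pupil 3-vector — each
producing calibrated posteriors (pairwise-coupled sigmoid fit on the
training fold), and fuses them with the maximal rule: predict the class
whose maximum posterior across classifiers is largest, ties toward the
lowest class index.

All SVMs use the inhomogeneous polynomial kernel `(γ x·y + 1)³` with
C = 1 and per-feature standardization fitted on training data only.  The
kernel offset matters: the homogeneous variant (`coef0 = 0`) collapses on
the high-dimensional standardized TF block (near-chance accuracy), while
the textbook inhomogeneous form is well behaved.  Degree, C and the offset
are exposed as parameters.

Evaluation is repeated k-fold cross-validation, default 10 repetitions × 6
folds: each repetition freshly shuffles the samples into equal segments
(remainder round-robin), and every segment serves once as test.  Reported:
mean accuracy over repetitions, the pooled confusion matrix (rows = actual
class), and macro-F1 — the unweighted mean over classes of
`2PR/(P+R)` with precision from column sums and recall from row sums;
degenerate classes contribute 0.  The stimulus-score utility
(mean / sample SD of ratings) is included for ranking emotion-induction
material by rater agreement-weighted intensity.

## Synthetic data generator

One latent "scan path" per trial drives both modalities, so EOG and video
of the same (profile, duration, seed) are mutually consistent.  The
schedule alternates saccade → fixation → pause cycles, with independent
blink scheduling; event durations are drawn uniformly from per-class
ranges inside the physiological bands (saccades 10–100 ms, fixations
100–200 ms, blinks 100–400 ms).

* **EOG rendering.**  A saccade is a raised-cosine step of amplitude *A*
  on HEOR and −*A* on HEOL (bipolar step 2*A*); amplitudes are drawn from
  N(mean, 0.08·mean) clipped to ±20%, which keeps every event above the
  1/3-of-maximum detection threshold on clean trials.  Blinks are positive
  raised-cosine bumps on VEOU (with a −30% counterpart on VEOD) and touch
  the horizontal channels not at all.  Per channel, white Gaussian noise
  (default 5 µV) and a slow sinusoidal drift (default 20 µV at
  0.002–0.005 Hz, i.e. below the filter's 0.01 Hz corner, hence removable)
  are added.
* **Video rendering.**  Frames are 8-bit grayscale: background 160, a dark
  disk (value 15) whose mask is `d² ≤ (r + 0.5)²` — the +0.5 px rasterise
  convention makes the drawn boundary straddle radius *r*, which is what
  lets the Hough transform recover *r* exactly on clean frames.  The disk
  center follows the EOG-implied horizontal gaze (scaled so the excursion
  stays in-frame), frozen during fixations and augmented with a ±2 px
  random wander between events so that center-stability runs coincide
  exactly with ground-truth fixations.  The wander stands in for small eye
  movements below the EOG noise floor and is not mirrored in the EOG
  channels.  With nonzero noise the radius also carries a slow
  hippus-like ±0.75 px oscillation and pixels get Gaussian noise (SD 2
  gray levels); a fully noise-free profile renders deterministically.
* **Class conditioning.**  Positive: frequent, fast, large saccades
  (2.2 /s, 20–45 ms, 110 µV), short fixations (100–140 ms), dilated pupil
  (radius 22 px).  Negative: sparse slow saccades (0.7 /s, 35–65 ms,
  80 µV), long fixations (155–200 ms), moderately dilated pupil (20 px).
  Neutral sits between on dynamics with the smallest pupil (16 px) —
  arousal of either valence dilates the pupil.  All magnitudes are plain
  profile fields and can be overridden.
* **Determinism.**  Every generator is a pure function of (parameters,
  seed); trial *i* of a dataset uses seed `base + i`.  Dataset manifests
  are byte-identical across runs of the same (config, seed).

### What the generator does *not* emulate

No eyelid/iris/eyelash structure, no photorealistic shading, no vertical
saccades, no head movement, no micro-saccades, nystagmus or smooth
pursuit, no EOG crosstalk between axes, and class differences are imposed
directly on oculomotor statistics rather than emerging from scene content.
Consequently, passing tests demonstrate that the *pipeline* recovers the
structure the generator encodes (event timing, pupil geometry,
class-conditional statistics); they say nothing about how well these
features separate human emotional states.

## Benchmark scale and runtime choices

The default labelled benchmark is 60 trials per class (180 trials), 10-s
trials at 250 Hz EOG and 30 fps video on 160×120 frames, seed 42.  Ten
seconds per trial keeps the per-frame Hough voting for 54 000 frames at
desk scale while leaving ≈ 20 events per positive trial; the canonical
60-s / 3808-dimensional geometry is exercised separately where dimensions
are asserted.  On this benchmark the FLF reaches ≈ 0.95 repeated-CV mean
accuracy and the DLF ≈ 0.99; with permuted labels the accuracy averaged
over five independent permutations is statistically indistinguishable from
the 1/3 chance level.  (A *single* permutation's repeated-CV accuracy has
extra variance beyond binomial sampling — fold-wise class imbalances
anti-correlate between train and test — which is why the chance-level
check averages over permutations.)

## Numerical conventions

Image x = column, y = row, 0-based; times in seconds; event intervals
half-open `[start, end)`; fixation duration = frame count / fps, bounds
inclusive; duration-gate comparisons carry a 10⁻¹² tolerance; Hough ties
break smallest-radius-then-smallest-(row, column); empty feature groups
produce zeros, never NaNs.  EDF input is read through `mne` when
installed; all other formats are plain text or PNG.

## Known limitations

* The saccade detector's supra-threshold run length is set by the wavelet
  scale, so detected saccade durations cluster around (2/3)·scale/fs
  rather than tracking the true duration closely; duration *statistics*
  still separate classes because rise time enters the run length.
* The adaptive 1/3-of-maximum threshold assumes at least one strong
  saccade per recording; a recording with a single artifactual spike would
  mask genuine smaller saccades.
* The literal fixation rule rejects stable gaze longer than 200 ms, so
  long calm fixations are invisible to the fixation features.
* The Hough vote threshold of 3 is permissive; on nearly empty binary
  images a spurious circle can be "found".  The MPV-driven binarization
  assumes the pupil is the darkest image structure.
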