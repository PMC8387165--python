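# Methods

## Model

The classifier is a dual-stream spatiotemporal network. Each stream maps a
fixed-length stack of frames to a sequence-level feature and class
probabilities; the streams differ only in their input modality and in how
the frame-level descriptor is assembled.

**Spatial model.** Five blocks of [zero-padded 3×3 convolution → batch
normalisation → ReLU → 2×2 max-pooling, stride 2]. A frame of size H×W
therefore needs H, W divisible by 32 and ends as an (H/32)×(W/32) map.
Default widths are (32, 64, 128, 256, 512) at 224×224; the bundled
benchmark uses (8, 16, 32, 64, 64) at 64×64.

- *Motion stream (STMN-A):* input is the 2-channel flow field. The block-3
  map is refined in place by multiscale-kernel spatial attention and the
  block-5 map by global dual-pool channel attention; global average pooling
  of the refined block-5 map is the frame feature (dimension = width 5).
- *Appearance stream (STAN-A):* input is the grayscale frame. The backbone
  runs unmodified; a low/high fusion path (LHFN) taps the block-3 map
  (refined by spatial attention → 1×1 conv → GAP, the "texture" vector) and
  the block-5 map (refined by channel attention → 1×1 conv → GAP, the
  "semantic" vector) and concatenates them. The backbone deliberately
  continues from the *unrefined* block-3 map, so spatial attention shapes
  only the fused descriptor; this keeps the two attention sites independent
  and mirrors the refine-in-place variant used in the motion stream.

**Attention.** Three sigmoid-gated mechanisms, all strictly in (0, 1), none
softmax-normalised:

1. spatial: SA = σ(Conv¹ˣ¹(concat(Conv¹ˣ¹, Conv³ˣ³, Conv⁵ˣ⁵ applied to the
   low-level map))), broadcast over channels;
2. channel: CA = σ(MLP(GAP) + MLP(GMP)) with one shared two-layer MLP
   (bottleneck C/r, ReLU in between, r = 16 by default), broadcast over
   pixels;
3. temporal: rᵢ = σ(u·Sᵢ + b), one scalar per frame. The affine-projection
   form is the minimal learnable map consistent with a per-frame sigmoid
   weight; each stream owns an independent (u, b).

**Temporal model.** The gated frame features feed a single-layer LSTM; the
sequence feature f is the arithmetic mean of the hidden states (temporal
average pooling), and an affine layer + softmax gives class probabilities.
The motion stream consumes t−1 flow steps for t appearance frames — no
padding; the recurrent model accepts either length.

**Fusion.** DSTAN-SVM concatenates the two streams' sequence features f
(pre-classifier, the default; logits or probabilities are a config switch)
and fits a linear-kernel SVC, one-vs-rest, C = 1, on features standardised
with training-fold statistics only. DSTAN-Average takes the argmax of the
unweighted mean of the two softmax vectors; ties break to the lowest class
index.

## Preprocessing

Frames are loaded from per-sample directories (lexicographic order) or video
files, rescaled to [0, 1]. Face detection/alignment is a pass-through hook:
inputs are assumed pre-cropped and aligned. Spatial normalisation is
bilinear resampling; temporal normalisation interpolates each pixel
trajectory piecewise-linearly at uniform fractional positions — an
endpoint-preserving, idempotent, bounds-preserving fixed-length resampler
(the graph-embedding interpolation models in the literature can be swapped
in behind the same interface; the pipeline's contract is only the fixed
length). Optical flow is computed *after* spatial normalisation so both
streams share geometry, and on the *temporally normalised* sequence, giving
t−1 fields. The default estimator is scikit-image's iterative Lucas–Kanade
(deterministic, fast, accurate for sub-pixel-to-few-pixel motion); TV-L1 or
any callable `(gray0, gray1) -> (H, W, 2)` can be substituted. Flow is
encoded for the network by clipping to ±8 px and rescaling linearly to
[0, 1] (micro-expression motion is far inside that bound; clipping only
guards outliers).

Conventions: row-major arrays, origin top-left, 0-based indices; flow
channel 0 is horizontal (x), channel 1 vertical (y), in pixels at the
normalised size.

## Training

Cross-entropy minimised by Adam (β = 0.9/0.999); every source of randomness
(weight init, batch shuffling, corpus generation) derives from one master
seed, and two runs with the same seed are bitwise identical. Defaults follow
the reference setting (batch 32, t = 9, 224×224, r = 16); learning rate and
epochs are deliberately configurable since no canonical values exist. The
numerical engine is NumPy with explicit backprop; convolutions are im2col +
one large GEMM, and the patch gather/scatter and pooling inner loops have
numba-compiled versions that produce bitwise-identical results (the NumPy
path remains as reference and fallback). Batch-norm uses batch statistics in
training and running averages (momentum 0.1, ε = 1e-5) in evaluation;
statistics are re-estimated inside every LOSOCV fold, never shared across
folds.

## Evaluation protocol

Leave-one-subject-out: one fold per subject, ordered by subject id; the
fold's test set is exactly that subject's samples, and a leakage assertion
checks the partition every fold. Metrics are pooled over the concatenated
test predictions of all folds (per-fold accuracies are reported separately);
precision/recall/F1 are one-vs-rest per class and macro-averaged, F1 being
the per-class harmonic mean 2PR/(P+R) averaged over classes. Zero
denominators contribute 0 with a logged warning. Accuracy equals
trace(confusion)/total by construction.

## Synthetic corpus

The generator emulates the structure of spontaneous micro-expression
corpora: per-subject identity templates (smooth elliptical head with
eye/brow/nose/mouth blobs, geometry jittered per identity seed) and short
clips in which one facial region deforms along an onset–apex–offset arc.
The deformation is a Gaussian-windowed translation warp (backward mapping,
bilinear sampling, window σ = 6 px) whose amplitude follows a triangular
profile with the apex at the middle frame — not a muscle model, but the
minimal machinery that produces localized, low-amplitude, temporally peaked
motion. Amplitude jitter (10% relative), additive pixel noise (σ = 0.01),
and a random global drift of up to 0.5 px per sequence supply nuisance
variation.

The three default classes are complementary on purpose: "positive" is a
2.5 px horizontal motion cue at the mouth, "negative" a 2.5 px vertical cue
at the brows, and "surprise" mainly a static appearance cue (brightness
+0.30 at the eyes with only 0.4 px of motion) — so the appearance and motion
streams genuinely carry different information and fusion is exercised, not
just averaged. Two controls bracket the benchmark: a nearest-centroid
classifier on handcrafted per-region flow means must solve it (≥ 0.9;
positive control — the task is learnable), and the identical pipeline on a
zero-amplitude corpus must sit at chance (negative control — nothing but
the injected deformations is informative).

What the generator does **not** emulate: photorealistic texture, 3-D head
pose, illumination changes, FACS action-unit geometry, class imbalance, and
inter-subject variation in expression style. Passing the benchmark therefore
demonstrates that the architecture, training loop, fusion and protocol are
correct and that the streams capture the cue types they were designed for —
it does not predict accuracy on spontaneous human data.

## Benchmark scale and defaults

The bundled benchmark uses 8 subjects × 3 classes × 6 sequences (144 clips,
matching the subject count of the smallest real corpus and its 3-class
arity), 9 frames at 64×64, widths (8, 16, 32, 64, 64), LSTM 64, batch 16,
learning rate 2e-3 with 10 epochs for the appearance stream and 6 for the
faster-converging motion stream. These sizes keep a full 8-fold run (two
streams trained from scratch per fold) in the ten-minute range on a single
CPU while leaving clear headroom over chance. The negative control trains 3
epochs per stream: with no signal to fit, longer schedules only move the
model between chance-level solutions.

## Numerical and design notes

- Sigmoid weights are mathematically in (0, 1); float32 saturates for
  |logit| ≳ 17, which is irrelevant at trained magnitudes but worth knowing
  when probing with extreme inputs.
- Max-pool gradient routes to the first maximal element of each 2×2 window
  (scan order row-major); argmax ties in probabilities resolve to the lowest
  class index everywhere.
- Conv biases ahead of batch norm are redundant (BN removes any constant
  offset); they are kept for interface uniformity and initialise to zero.
- The temporal-attention placement is before the recurrent layer (the gated
  features are what the LSTM consumes).
- Eq-level contracts (attention formulas, temporal pooling, metrics) are
  enforced in the test suite against independently coded loop-based oracles,
  and the whole forward pass against a layer-by-layer re-evaluation; the
  training path is validated by central-difference gradient checks in
  float64.

## Known limitations

- No pretrained backbone, no augmentation: with real corpora of ~150–250
  clips, accuracy will hinge on training-schedule tuning the synthetic
  benchmark does not probe.
- The NumPy engine is single-device and trains the benchmark scale
  comfortably, but 224×224 with full widths is substantially slower than a
  GPU framework; the architecture is configured, not hard-coded, precisely
  so desk-scale runs stay cheap.
- Video-container input requires an imageio backend with the corresponding
  codec; frame directories are the first-class path.
- Labels are assumed to be contiguous integers 0..K−1 (the generator and
  CSV layout guarantee this).
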