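# Methods

## Problem and pipeline

The package classifies single grayscale CT slices as nodule-present
("cancer", the positive class) or background-only ("healthy").  The pipeline
is: impulse-noise removal by median filtering, per-image min-max level
balancing, resizing to the network input, a small convolutional classifier,
and confusion-matrix evaluation on a held-out split.  The classifier can be
trained by RMSprop gradient descent or, the package's main point, by the
Marine Predators Algorithm operating directly on the flattened parameter
vector, with no gradients anywhere in the training loop.

## Preprocessing

* **Median filter** — each pixel is replaced by the median of its m×n
  neighborhood (default 5×5, tests mostly use 3×3).  Borders use replicate
  (edge-clamp) padding, so the output keeps the input shape and edge pixels
  are medians of clamped windows.  Odd window dimensions are required so the
  median is an order statistic of the window; this makes the filter exactly
  idempotent on constant images and value-preserving (outputs are a subset of
  input values).
* **Min-max normalization** — the affine map sending the image minimum to
  `a_new` (default 0) and maximum to `b_new` (default 1).  A constant image
  leaves the map undefined; callers choose between an error (library default)
  and an all-`a_new` fill (pipeline behavior, for blank slices).  The map is
  invariant to positive affine transforms of the input, which removes
  scanner gain/offset — but it also means *absolute* brightness is not
  available downstream; see "What the synthetic experiments show" below.
* **Resize** — bilinear, with a Gaussian prefilter when downsampling.  Both
  operations are convex combinations of input pixels, so intensities cannot
  overshoot the input range; the result is clipped to that range to absorb
  floating-point round-off.  The full-scale pipeline targets 227×227 inputs;
  the desk-scale presets use 6–12 px inputs.
* **Order** — filter → normalize → resize: denoising first so impulses do not
  distort the min/max, resizing last so the network input size wins.

## Classifier

Architecture: repeated (valid 3×3 conv, stride 1 → ReLU → 2×2 max pool)
stages with 32/64/128 filters at full scale, then flatten, an optional dense
hidden layer (64 units, ReLU, dropout 0.5 inverted convention), and a softmax
output over two classes.  Kernels may also be specified per stage (used by
the integer hyperparameter encoding).  Everything — im2col convolution,
pooling argmax bookkeeping, and the exact backward pass — is NumPy; the
gradient is verified against central finite differences in the test suite.

Losses: summed cross-entropy over samples and classes with probabilities
clamped at 1e−12 (a confident wrong answer is a large finite loss, never an
exception), optionally plus an L2 penalty `(η/2) Σ ω²` on connection weights
only — biases are excluded.  Defaults: η = 1e−4; RMSprop with learning rate
1e−3, decay 0.9, epsilon 1e−8, batch 32, 200 iterations.  The RMSprop
trainer records the full-training-set regularized loss per iteration and
returns the best-scoring parameters, so the returned loss never exceeds the
initial one even on noisy minibatch trajectories.

The metaheuristic cost of a candidate weight vector is either the per-sample
summed squared error between softmax outputs and one-hot targets (default)
or the misclassification rate; both are pure inference, deterministic given
the vector and the data.

## Marine Predators Algorithm

Bound-constrained minimization of f : R^d → R with an n×d prey matrix and a
best-so-far elite vector.  Per iteration `it` of `T`:

* phase 1 (`it < ⌊T/3⌋`): `step = R_B ⊗ (elite − R_B ⊗ prey)`,
  `prey += P·R ⊗ step` with `R_B` standard normal and `R` uniform;
* phase 2 (`⌊T/3⌋ ≤ it < ⌊2T/3⌋`): the first ⌈n/2⌉ prey take the Lévy
  analogue of phase 1; the rest contract onto the elite:
  `prey = elite + P·CF ⊗ R_B ⊗ (R_B ⊗ elite − prey)`;
* phase 3: `prey = elite + P·CF ⊗ R_L ⊗ (R_L ⊗ elite − prey)` for all prey
  (the contraction form, symmetric with phase 2's second half);
* FADs: with probability 0.2 a CF-scaled jump toward a random box point,
  gated per entry by a binary mask (entries set with probability 0.2);
  otherwise recombination along the difference of two random population
  permutations, scaled by `FADs·(1−r) + r`;
* re-evaluate; a greedy memory rule restores any prey whose pre-update
  position scored better (configurable off, which reproduces the memory-less
  reading of the update equations; the best-so-far history stays monotone
  either way); elite update with lowest-index tie-breaking.

Constants: P = 0.5, FADs = 0.2, `CF = (1 − it/T)^(2·it/T)`.  Lévy steps use
Mantegna's construction with stability exponent 1.5 and the conventional
0.05 scale factor inside the updates (`levy_step` itself returns unscaled
samples, whose exceedance tail `P(|X|>t) ~ t^(−α)` is verified by
regression).  The same `R_B`/`R_L` draw multiplies both occurrences within
one step expression.  Out-of-bounds positions are clamped componentwise.
Phase boundaries use floor division so all three phases are non-empty for
any budget ≥ 3.  One objective evaluation per prey per iteration (after the
FADs step).  The RNG draw order per phase is part of the documented contract
so an entrywise scalar transcription can replay a captured stream; the test
suite holds such a transcription (`tests/reference_mpa.py`) and a frozen
benchmark fixture generated with it.

## Encodings

* **weights-only** (default): layer-major concatenation of every weight
  tensor and bias vector; search box [−1, 1] per entry.  This mode admits
  the teacher–student recovery experiment, since any teacher drawn from the
  box is exactly representable.
* **hyperparams-only**: 10 integer coordinates (3 conv filter counts, 3 conv
  kernel sizes, pool window, dense width, dropout code = rate·20, batch
  size), each rounded and clamped into bounds with minimum 2.  Conv stages
  whose kernel or pooling would underflow the input are dropped from the
  tail, so every vector in the box decodes to a network that admits a
  forward pass.  Candidates are scored after a brief RMSprop pre-train.
* **joint**: both blocks concatenated (hyper block first).

## Synthetic data

Positive images: one soft-edged bright disc (radius uniform in 6–10 px on a
64×64 canvas, peak contrast 0.5, sigmoid edge ~1.5 px wide to avoid aliasing
cues) on a smooth background (Gaussian-filtered uniform noise, correlation
length 4 px, range ≈ [0.15, 0.55]); negatives: background only.  Both are
corrupted by salt-and-pepper noise (default 5 %, exact 0/1 values).  The
class split is exact (rounded balance) in a seeded random order, and the
same spec and seed reproduce the dataset bit for bit.

The generator emulates the *statistical* structure the method assumes —
present/absent bright lesion, impulse noise, textured background — not lung
anatomy: no ribs, vessels, or partial-volume effects, a single lesion at
most, and no inter-slice correlation.  Passing tests therefore demonstrate
that the machinery works end to end under controlled conditions, not
clinical performance.

A note on difficulty: per-image min-max normalization maps the nodule peak
to 1 in every positive, so after preprocessing the *maximum* intensity
carries no class information; the signal is the compressed mid-tone
distribution (background occupies ≈ [0, 0.5] in positives but the full range
in negatives).  The best simple feature (mean intensity) separates the
default easy setting at ≈ 95 %.

## Desk-scale study conditions

* **End-to-end classification**: 60 images, 80/20 stratified split, MPA
  weights-only with population 20 and 100 iterations.  The test-scale
  network is a 6×6 input, two 1×1 conv filters (a learned pixelwise
  intensity transfer — the spatial reasoning lives in the dense readout,
  which suits the post-normalization signal described above), no hidden
  dense layer: 42 parameters.  Measured over 40 seeds the held-out accuracy
  averages ≈ 0.93 and reaches ≥ 0.9 in ≈ 83 % of seeds (8/10 in each of the
  first three seed decades); each seeded run is exactly reproducible.
* **Teacher–student recovery**: a frozen 20-parameter network (weights and
  biases uniform in the search box, independent RNG stream) labels 40 random
  6×6 images with its softmax outputs; MPA (population 25, 300 iterations)
  refits from scratch.  The final cost falls below 10 % of the initial
  population's best in ≈ 78 % of seeds over 40 seeds (8/10 in each of the
  first three decades); failures are mostly seeds whose random initial
  population already contains a near-fit, making the *ratio* criterion
  harsh rather than the optimization weak.
* **Optimizer benchmark**: 10-D sphere, bounds ±100, population 25, 500
  iterations, 20 seeds; median final cost ≈ 1e−9.  The frozen threshold in
  `tests/fixtures/sphere_reference.json` is 1000× the scalar-transcription
  reference median, recorded before the packaged implementation was
  benchmarked.

These sizes keep the whole suite under half a minute on one CPU; they are
the package's chosen desk-scale conditions, with the 227×227 / 100-predator
/ 200-iteration configuration remaining the documented full-scale default.

## Numerical choices and degenerate inputs

* Softmax is computed shift-invariantly (max subtraction), so extreme logits
  cannot overflow.
* Cross-entropy clamps probabilities at 1e−12.
* Equal objective costs: the lowest population index wins (determinism).
* Constant images: error by default, all-`a_new` under the pipeline.
* The FADs step requires population ≥ 3 (two random partners plus self).
* Dropout uses the inverted convention so inference is exactly the identity.
* All experiment code takes explicit seeds; the optimizer's stream ordering
  is fixed and documented.

## Known limitations

* The NumPy CNN targets desk-scale problems; at 227×227 with the full
  32/64/128 stack, MPA over the flat weight vector is far beyond a sensible
  population budget — weights-only MPA is a small-network method here, and
  the hyperparams-only mode is the realistic full-scale use of the
  optimizer.
* Only box constraints; no constraint handling beyond clamping.
* Binary classification only; metrics raise on empty denominators rather
  than imputing.
* The synthetic phantom is deliberately minimal (see above); no DICOM
  writing, 3-D volumes, or lung segmentation.
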