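# Methods

## Problem setting

A minirhizotron (MR) system photographs soil through a buried transparent
tube at fixed depth increments. For each frame `i` an annotator marks each
visible root as an ordered chain of points; chains are connected into
polylines whose pixel length, multiplied by the camera's mm-per-pixel pitch,
gives each root's length, and the frame's total root length (TRL) `y_i` is
the sum over roots. The package estimates `ŷ_i` directly from the raw frame
with compact CNNs, without segmentation masks, and evaluates the estimates
with the five-metric suite below.

## Camera geometry

Two acquisition systems are modelled as `CameraProfile`s:

| profile | field of view | sensor | stored frame | depth step |
|---|---|---|---|---|
| `manual` | 18 × 13.5 mm | 640 × 480 px | 624 × 450 px (border crop) | 13.5 mm |
| `automated` | 25 × 19 mm | 2952 × 1944 px | 2952 × 1944 px | 18.75 mm |
| `automated_sim` | 25 × 19 mm | 738 × 486 px | 738 × 486 px | 18.75 mm |

Design choices:

- **Scalar pitch = width pitch.** Root lengths are scalar mm values, so one
  pitch must be chosen. The manual profile is exactly isotropic
  (18/640 = 13.5/480 = 0.028125 mm/px). The automated profile's printed
  numbers are ~15% anisotropic (25/2952 vs 19/1944); the width-axis pitch is
  used and profile construction emits an `AnisotropicPitchWarning` rather
  than failing, since rejecting the printed specification of a real
  instrument would be worse than flagging it.
- **Cropping does not rescale.** The manual system's stored 624 × 450 frame
  is a border crop of the 640 × 480 sensor, so its pitch stays 18/640.
  Annotation bounds are checked against the stored frame.
- **RLD uses the nominal window.** Root length density divides by the
  nominal imaged area (18 × 13.5 mm → 2.43 cm²; 25 × 19 mm → 4.75 cm²), not
  the cropped one: the nominal window is what field protocols quote.
- `automated_sim` is the automated optics rendered at quarter resolution —
  the synthetic generator's default for that system, keeping desk-scale
  training tractable; full resolution remains available as `automated`.

Coordinates are 0-based pixels, x = column, y = row, origin top-left of the
stored frame. Depth below the tube top is
`depth_index × depth_step_mm + top_offset`, with a configurable offset
because tube insertion depth varies between installations; importers of
external data must normalize scan direction to increasing depth index.

## Gaussian point-density supervision

The points estimator is supervised by a map with a unit-peak Gaussian
`exp(−d²/(2σ²))` centred at every annotated point, rendered at `scale` times
the image resolution (default 1/4; map size is the floor of image size ×
scale, annotated coordinates are scaled, never re-annotated).

- **σ = 2 px at map scale (default).** The click positions along a root are
  annotator-dependent, so sub-pixel supervision would be meaningless; a
  2-px kernel makes near misses partial successes and keeps adjacent-click
  kernels merged into a ridge along the root.
- **Overlap rule: element-wise max (default), clipped sum optional.** Two
  annotators click with different density along the same root; max keeps the
  map magnitude independent of click density, whereas summation would make
  densely clicked roots "hotter". Both conventions are defensible for a
  density-style map, so `mode="sum"` (clipped to 1) is exposed.
- Kernels are evaluated over the whole grid (no truncation), so rendering is
  exactly the per-pixel max.

`decode_peaks` (threshold + non-maximum suppression via local-maximum
search) exists for overlay-style visual inspection; TRL never comes from
decoded peaks (see below).

## Estimator architectures

Both models are built on an in-repo NumPy engine (`rhizolen._nn`): im2col
convolutions on BLAS matmuls, manual backward passes verified against
numeric differentiation, and Adam. Arrays are float32, NCHW; the
architecture is deliberately small (≈ 17k parameters at the default width)
so a 400-image, 30-epoch run completes in about a minute on one CPU core.

Shared encoder: three strided stages (5×5 s2, 3×3 s2, 3×3 s2; default
channels 12/24/32), ReLU. Input frames are resized to a common training grid
(default 144 × 96) and standardized per image; the mm label always comes
from the original camera pitch, so resizing cannot corrupt it.

- **Regression model** ("multiple-scale direct regression"): global average
  pooling of *each* stage, concatenated → hidden layer (32) → scalar →
  softplus × `output_scale_mm`. Softplus enforces TRL ≥ 0 by construction;
  the output scale (default 10 mm) keeps the head working in O(1) units.
- **Points model** (detection + regression): the same encoder, plus a
  decoder (nearest ×2 upsample → 3×3 conv → 1×1 conv → sigmoid) emitting the
  point heatmap at map scale (output cropped to `floor(in_size × map_scale)`
  when stride arithmetic overshoots). The scalar head reads the pooled
  encoder stages *and* the mean of the predicted heatmap, so the length
  estimate is informed by the detected points. TRL is produced by this
  learned head, not by geometrically summing decoded peak positions: decoded
  point sets are annotator-convention-dependent and their pairwise
  connectivity is unknown, so a learned readout of the detection map is the
  robust choice; geometric decoding stays available for visualization only.

The head bias is initialized at the training-set mean TRL
(softplus-inverse), the standard trick that spares the optimizer hundreds of
steps of drift toward the label scale.

## Training protocol

Loss: `w_h · MSE(predicted map, GT map) + w_t · smoothL1(ŷ/s − y/s)` with
`w_h = w_t = 1`, `s = output_scale_mm`, smooth-L1 transition at 1 (i.e.
10 mm). The heatmap term is dropped for the regression model. Optimizer
Adam, lr 3·10⁻³, batch 8. Defaults were fixed during development on
generator output before the evaluation corpora were drawn.

- **Model selection by validation MRD**: after every epoch the mean relative
  deviation on validation images with roots is recorded; the returned
  checkpoint is the epoch minimizing it (earliest on ties). If a validation
  set contains no root-bearing images (degenerate but legal, e.g. sanity
  runs on empty-frame corpora), selection falls back to mean absolute error.
- **Augmentation: flips only.** Horizontal/vertical flips preserve root
  length; any scaling augmentation would silently corrupt the mm label and
  is therefore not offered.
- **Epochs default to 300** (the full protocol); the scaled-down runs used
  by the test suite and the acceptance script train for 30 epochs on 400
  images, which this architecture needs to converge on the synthetic task.
- **Joint training** concatenates datasets from different cameras; each
  image's label is already in mm via its own pitch, so mixing is safe.
- **Fine-tuning** continues optimization of a trained model on k randomly
  chosen *root-bearing* images from the target system (zero-root frames
  transfer nearly for free, so budget goes to rooted frames), with the
  target system's validation split driving best-epoch selection.
- Determinism: initialization is a function of `ModelConfig.init_seed`,
  data order and augmentation of `TrainConfig.seed`; identical seeds
  reproduce logs and weights exactly (single-threaded numpy arithmetic).

## Evaluation

For pairs `(y_i, ŷ_i)`, `ȳ` the GT mean, `n` the count:

- `|ΔRL| = (1/n) Σ |y_i − ŷ_i|` (mm);
- `MRD = (1/n') Σ_{y_i>0} |y_i − ŷ_i| / y_i` — relative error is undefined
  on zero-root frames, so they are excluded; requesting MRD of a set with no
  rooted frame is an error, not 0;
- `NRMSE = RMSE / (y_max − y_min)` over the evaluated set's GT extrema;
- `1 − FVU = 1 − Σ(y_i − ŷ_i)² / Σ(y_i − ȳ)²` — the model against the
  constant-mean predictor (exactly 0 for the mean predictor, 1 for the
  perfect one);
- `R²` = squared Pearson correlation of `y` and `ŷ`. R² and 1−FVU are
  deliberately distinct statistics (they coincide only for least-squares-
  calibrated predictions) and are reported side by side.

**Binary root presence.** The threshold is the 80th percentile of the
model's estimates on zero-GT validation frames, with linear interpolation in
the exclusive (n+1)/Weibull convention — chosen because it reproduces the
documented behaviour that estimates (0, 0, 0, 0, 1) yield a threshold of
0.8; the convention is configurable and results may shift in the third
decimal under the inclusive alternative. A frame is "no roots" iff its
estimate is *strictly* below the threshold (an estimate equal to the
threshold counts as rooted), and a no-roots frame's reported TRL is set
to 0.

## Synthetic scenes

The generator exists so every stage — training, evaluation, classification,
RLD, transfer — is exercisable without external data, with labels exact by
construction (the generating polylines are the annotation; no estimation is
involved in the ground truth).

What it emulates: multiple curved roots per frame (random-heading walks,
5–15 clicks at 1.5–3 mm spacing — click density mimicking how annotators
space points along curvature) including zero-root frames (30% by default);
low root/soil contrast; correlated soil texture at two granularity scales;
a directional illumination gradient with mild vignetting; water-bubble rings
and long thin scratches that resemble roots; additive sensor noise. The
manual-profile conditions are harsher (contrast 0.14, illumination amplitude
0.25, noise 0.045) than the automated ones (0.30 / 0.08 / 0.02), mirroring
the incandescent-vs-LED, low-vs-high-resolution gap between the systems.

Root geometry is sampled in *physical mm* inside a fixed 18 × 13.5 mm world
window and projected through whichever camera renders the scene. Two
`SceneSpec`s differing only in camera therefore image the same root
population at different quality and resolution — the property that makes
cross-system transfer experiments meaningful rather than a comparison of
two unrelated distributions.

What it does not emulate: real soil morphology, root branching topology,
root diameter variation along a root, moisture films, condensation, or
growth over time. Passing tests on synthetic data therefore demonstrate
that the pipeline's mechanics (geometry, supervision, optimization,
selection, thresholding, profiling) are correct and that the estimators can
learn the image-to-length mapping under MR-like nuisance factors — not that
a given accuracy will transfer to any particular field dataset.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the protocol at desk scale,
chosen as the package's own standard small-corpus configuration: 400/50/100
train/val/test frames per profile, 30 epochs, three seeds for medians in the
stochastic checks; the transfer sweep uses k ∈ {10, 50, 200} fine-tuning
images from a 210-frame rooted pool. Tolerances: geometric and metric
oracles agree to 1e-9; heatmap rendering matches a naive per-pixel loop to
1e-6; RLD conservation (Σ depths rld × window area = total length per
tube/date) holds to 1e-9; round-trip decoding recovers points separated by
> 4σ within 1 px/scale.

Degenerate inputs: single-point polylines have length 0 and contribute 0 mm;
empty images render an all-zero heatmap; MRD/NRMSE/R²/1−FVU raise
`UndefinedMetricError` when their preconditions fail (the bundled
`EvalReport` NaN-fills instead, for batch reporting); fine-tuning with k = 0
returns the input model unchanged.

## Known limitations

- The NumPy engine is CPU-only and single-threaded by design; it is sized
  for the desk-scale corpora, not for thousands of full-resolution frames.
- The architecture is a compact realization of the two estimator *contracts*
  (multi-scale direct regression; detection branch + learned length head),
  not a parameter-for-parameter reproduction of any published network.
- The Rootfly importer (`import-zenodo`) is best-effort by design: the
  native project format is undocumented, so it matches loose column names
  and skips unparseable records with warnings. Imported mm values should be
  spot-checked against the source tool, particularly the width-vs-height
  pitch convention and crop handling.
- The binary classifier uses a single fixed percentile; no ROC analysis is
  provided.
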