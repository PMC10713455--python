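# Methods

This note documents the models, conventions and numerical choices behind
`emcaps`: what the simulator states about the world, how the reference
segmentation engine works, the exact semantics of every filter and
metric, and what a green test on synthetic data does and does not
establish.

## Contrast model and shell geometry

Each barcode class is modeled by a radial intensity template
`I(r) ∈ [0, 1]` (1 = local background brightness). The dark metal band
covers `[r_lumen, r_outer]`:

```
I(r) = 1 − depth · rise(r) · fall(r)
rise(r) = Φ((r − r_lumen)/σ)   if r_lumen > σ, else 1
fall(r) = Φ((r_outer − r)/σ)
```

with `Φ` the normal CDF, contrast `depth` = 0.5 and edge smoothing
`σ` = 1.5 nm by default. When the lumen radius does not exceed `σ` the
bright central plateau vanishes and the band extends to `r = 0` — this
reproduces the vanishing central spot of the three-layer Qt variant, and
means the intensity minimum of such classes sits at the center rather
than inside the nominal `[r_lumen, r_outer]` band.

The lumen radius follows from the shell geometry:

```
r_lumen = r_outer − shell_thickness − n_layers · ring_width
```

Defaults (config-overridable, shipped as `emcaps/data/geometry.yaml`):
outer diameters Qt 40 nm and Tm 25 nm as reported, Mx 32 nm as an
editorial intermediate (only the ordering Qt > Mx > Tm is documented);
shell thickness 3.5 nm and ring width 5.5 nm per metallothionein layer.
The thickness/ring-width pair is a rendering choice fixed by two
qualitative constraints: the three-layer Qt lumen must vanish
(20 − 3.5 − 3·5.5 = 0) and the single-layer Mx bright center must be
comparable to the two-layer Qt center (7.0 vs 5.5 nm). These two
parameters are *not* measured values.

Closed-form helpers: `min_area_pixels` rounds `π(d/2p)²` half-up (20 nm
at p = 1.81 nm/px → 96 px); `monomer_count` is the icosahedral rule 60·T;
`expected_surface_copies` rounds 60·T·fraction to the nearest ten because
surface stoichiometry under translational read-through is only ever
quoted to that precision.

## Simulator

A scene is `background × Π_i template_i(‖x − c_i‖) + noise`:

- **Background**: mean 0.85 of full scale, multiplied by a Gaussian
  random field (σ = 3 %, correlation length 8 px) emulating cytosolic
  texture.
- **Particles** attenuate multiplicatively — stain density attenuates
  transmitted electrons — rather than adding; rendered with 5σ edge
  support so truncation error is < 1e-6.
- **Noise**: additive Gaussian, σ = 5 % of full scale.
- **Section-thickness effects** (70 nm sections vs ≤ 40 nm particles) are
  approximated by a uniform ±5 % radius jitter per particle; full
  slab-projection geometry is out of scope.
- **Placement** is rejection sampling with pairwise center distance
  ≥ r_i + r_j + 5 nm; pattern satellites sit at the linker distance with
  Gaussian angular (0.15 rad) and radial (1.5 nm) jitter around a regular
  polygon. Placement fails loudly (naming the class) if the requested
  particles would cover > 50 % of the frame.
- **Ground truth**: the annotation footprint is the full disk of the
  (jittered) outer radius. Class labels live in a 0..6 raster; pattern
  membership is a separate mask plane because pattern regions spatially
  overlap class footprints.
- **Determinism**: one `numpy` PCG64 generator per scene, consumed in a
  fixed order; identical seeds give bit-identical rasters and manifests.
- **Datasets**: each image gets a random vertical-stripe train/validation
  split whose validation share is exactly `round(0.3 · width)` columns.

Coordinates are row-major, 0-based, pixel centers at integer positions;
centers are stored in float pixels and in nm (default scale 1.81 nm/px,
0.5525 px/nm).

What the simulator does **not** contain: membranes, organelles, synaptic
vesicles or any non-barcode clutter; spatially correlated stain
artifacts; partial particles from glancing sections. Green synthetic
benchmarks therefore establish the correctness and internal consistency
of the pipeline — not its accuracy on real tissue micrographs, which in
the original setting required a trained network and reached mean Dice
scores in the 0.6–0.7 range rather than the ≈ 0.96 seen here.

## Matched-filter reference engine

The deterministic engine replaces a trained network with template
matching:

1. percentile normalization (0.5/99.5 by default) to [0, 1];
2. normalized cross-correlation (NCC) of the raster with the 2D rotation
   of each class template;
3. candidate centers = local maxima of the per-pixel best NCC above 0.35,
   with a minimum spacing of the smallest class radius;
4. each accepted center paints a disk of its winning class's outer
   radius, carrying the NCC score, into that class channel;
5. background = 1 − max class evidence; the pattern channel marks
   co-occurrence of Qt and Tm detections within 80 nm; the 8 channels are
   normalized to sum to 1.

Step 4 is a deliberate design choice: the raw per-pixel NCC field decays
away from particle centers and cannot by itself label a particle's full
footprint; painting the class disk at each detection makes the argmax
map match the annotation convention (filled disks) to within a ~2 px
boundary band on clean scenes. The flip-equivariance of the rotationally
symmetric kernels makes flip test-time augmentation exactly neutral for
this engine (a useful invariance check).

Sliding-window inference tiles with stride `window·(1 − overlap)`
(overlap 0.5 by default), averages overlapping predictions uniformly,
and under TTA averages the four flip variants plus one seeded
Gaussian-noise pass (σ = 1 % of dynamic range — the magnitude is a
package default, not a documented value).

**Argmax semantics**: labels 1..6 are the argmax over the six class
channels; the background label is assigned wherever the background
channel is at least as large as every class channel, so a fully uniform
stack maps to background. Class ties resolve to the lowest channel
index. The pattern channel never participates and is retained as stack
plane 7. `--argmax-mode eight` includes the background channel in the
argmax directly; with the tie rule above the two modes coincide for this
engine.

## Postprocessing

Applied to the argmax label map, strictly in order:

1. binarize labels 1..6 into a foreground mask;
2. 8-connected component analysis (the paper's tooling was a
   connected-components library; 8-connectivity is required so diagonal
   ring pixels merge);
3. remove components with **fewer than 42 px** (41 px dies, 42 survives);
4. conditional majority voting per component: reassign all pixels to the
   majority class only if area **< 500 px** *and* circularity **> 0.2**
   *and* the majority is unique (ties leave the component untouched);
5. fill background holes whose entire 8-neighborhood boundary belongs to
   a single class (holes are 4-connected background components not
   touching the image border, the topological complement of 8-connected
   foreground).

The procedure is idempotent and never introduces a class absent from the
component it modifies. Foreground pixel count can only shrink in step 3
and only grow in step 5.

## Circularity and the perimeter estimator

Circularity is `4πA/P²`, clamped to ≤ 1. The choice of perimeter
estimator is functional, not cosmetic: a raw pixel-edge count scores
digitized disks near `π²/16 ≈ 0.62` and would break the 0.8
classification gate. `P` is therefore the 8-connected Moore boundary
chain through pixel centers (axial steps 1, diagonal steps √2) plus 4
for the half-pixel band between pixel centers and the pixel-footprint
boundary (exact for convex shapes). Consequences: an a×a square scores
exactly `4a` (circularity π/4), a single pixel scores `P = 4`
(circularity ≈ 0.785), digitized disks of radius ≥ 10 px score
0.86–0.90. The estimator is stable under re-digitization at a different
magnification (< 0.05 shift for convex shapes) but *not* under
nearest-neighbor raster upscaling, which converts diagonal boundary
steps into staircases; circularities should always be computed at the
native pixel grid.

## Instance pipeline

Connected components of the label map approximate instances, so touching
particles merge — an accepted, deliberately pessimistic convention
(correct detections of merged neighbors count as false positives in the
instance metrics). Gates, checked in order with the first match
recorded: area < 60 px (`too_small`), area > 2304 px (`too_large`), bbox
touching any image edge (`border`), circularity < 0.8
(`low_circularity`); equality always keeps the instance. Excluded
records are reset to class 0.

Classification extracts a 49 px square patch centered on the component
centroid (89.2 nm at the default scale, matching the patch-averaging
convention), zeroes everything outside the component mask, computes the
radial mean-intensity profile about the mask centroid in 1 px bins, and
assigns the class whose template maximizes the Pearson correlation over
the radial support with ≥ 8 mask pixels per annulus (tiny masks fall
back to all populated bins). Pearson correlation makes the classifier
exactly invariant to affine brightness rescaling. Condition calls sample
`n` classified instances without replacement and return the modal class,
or a no-call sentinel on ties. A balancing utility undersamples
overrepresented classes to the minimum per-class count for any learned
classifier.

## Geometry analysis

Radial profiles bin pixel intensities by Euclidean distance (on pixel
centers, honoring sub-pixel particle centers) in 1 px bins; averages over
multiple centers are pixel-count-weighted. The outer diameter estimate
is `2 ·` the outermost radius where the profile crosses the half-depth
level between its deepest minimum and the asymptotic background (mean of
the outermost 20 % of populated bins), linearly interpolated between
bins. The estimator is invariant to affine intensity rescaling; strictly
rising profiles (gradients, no particle) and profiles whose minimum is
less than 5 % of background below it raise an estimation error rather
than returning a number. The half-depth criterion itself is a package
convention — the raw profile is always exported so other edge
definitions can be applied.

In pattern scenes, the average profile from Qt centers shows the Tm
satellites as *two* dips straddling the linker distance (the satellite's
own bright lumen sits exactly at the linker radius); pattern distances
are therefore measured between instance centroids, not read off the
profile, and recover configured 40/50/60 nm linkers to well within 1 nm
in the mean.

## Evaluation

Pixel metrics per class k: DSC = 2TP/(2TP+FP+FN), sensitivity =
TP/(TP+FN), precision = TP/(TP+FP), all derived from one confusion
matrix **summed globally over all images** — likewise the instance
counts — so every particle weighs equally regardless of scene density.
This is deliberately *not* the mean of per-image scores, and the test
suite contains a constructed dense/sparse pair where the two differ.

Instance matching pairs same-class components with IoU strictly > 0.5;
above that threshold each instance can have at most one such
counterpart, so the matching is unique without an assignment search
(verified against exhaustive assignment in tests). Panoptic metrics:
RQ = TP/(TP + ½FP + ½FN) (identical to the F1 score), SQ = mean IoU over
matched pairs only, PQ = SQ·RQ (exact identity wherever TP > 0). A class
with no instances anywhere is reported absent (NaN) and excluded from
macro means; macro means run over classes, with per-image means also
derivable from the per-pair reports.

## Optional trainable engine

`emcaps.train` provides a deliberately small trainable stand-in for an
encoder-decoder network: multinomial logistic regression (SGD) over
per-pixel features (normalized intensity, two Gaussian blurs, six NCC
maps), trained on pixels sampled from the training stripes, with the
epoch achieving the lowest validation loss (equally weighted soft Dice +
binary cross-entropy on foreground) kept as the checkpoint. A desk-scale
profile caps training at 50 epochs / 256 px crops unless explicitly
overridden. It satisfies the same predict contract as the matched-filter
engine and exists to make the training recipe concrete without a GPU
dependency; the reference pipeline and all acceptance checks use the
matched-filter engine only.

## Numerical conventions

- Rounding: `min_area_pixels` half-up; `expected_surface_copies` to the
  nearest ten; `pixels_per_nm` to 4 decimals.
- Threshold strictness, taken literally: "fewer than 42" (< 42 removed),
  "below a maximum of 500" (< 500 eligible), "below an area of 60"
  (< 60 excluded, 60 kept), "above 2,304" (> 2304 excluded, 2304 kept),
  "circularity below 0.8" (< 0.8 excluded, 0.8 kept), IoU > 0.5 strict.
- Probability stacks sum to 1 per pixel to within 1e-6.
- Constant rasters normalize to all-zeros.
- Config hashes are SHA-256 of canonicalized (sorted-key) YAML; every
  pipeline artifact embeds the hash and seed.
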