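# Methods

## Problem

Stomata on a leaf epidermis are elongated pores at arbitrary orientations.
Axis-aligned detection boxes cannot be read off as anatomical measurements;
a rotated box aligned with the guard-cell pair gives stomatal length and
width directly.  stomakit detects stomata as rotated boxes with an
anchor-free keypoint detector and converts the boxes into traits: length
(µm), width (µm), count, stomatal density SD (mm⁻²) and the anatomical
maximum stomatal conductance g_smax.

## Conductance model

For one image with mean stomatal length SL (µm), mean guard-cell width l
(µm, used as the proxy for pore depth) and density SD (mm⁻²):

    α_max  = π·SL²/4                            (maximum pore area)
    g_smax = d·SD·α_max / ( v·(l + (π/2)·√(α_max/π)) )

with d = 24.9×10⁻⁶ m² s⁻¹ (diffusivity of water vapour in air) and
v = 22.4×10⁻³ m³ mol⁻¹ (molar volume of air) at 25 °C and 101.3 kPa.  All
unit conversions to SI happen inside `measure.gsmax_formula`; note
(π/2)·√(α_max/π) = (π/4)·SL, so the denominator is smooth in SL and the
expression is differentiable (the training loss reuses the same code path
on autodiff tensors).  g_smax is strictly increasing in SL and SD and
strictly decreasing in l; SL = l = 0 is the defined limit 0.  Reported
traits are rounded half-away-from-zero to 2 decimals.

## Detector

Anchor-free keypoint detection at output stride R = 4: the network predicts
a center heatmap (sigmoid, clamped to (10⁻⁴, 1−10⁻⁴)), a 2-channel size map
(softplus, grid units), a 2-channel sub-cell offset map and an angle map
(sigmoid × 180°).  Peaks are cells equal to their 3×3 neighbourhood maximum
(plateau ties all survive; deterministic row-major tie-break in the
ordering); the top 100 peaks are kept and thresholded at score 0.3.  No
IoU-based NMS is applied anywhere.  A decoded box is
center ((x̂+δx)·R, (ŷ+δy)·R), sides (size·R), angle from the angle map,
canonicalized so length ≥ width and angle ∈ [0°, 180°).

The backbone is a deep-layer-aggregation design: residual-block stages
fused hierarchically within a stage (a tree whose branches meet in
aggregation nodes) and iteratively across stages (deep/coarse features
projected, bilinearly up-sampled ×2 and aggregated into shallower/finer
ones).  An aggregation node computes `relu(BN(conv1×1(concat)) + x_n)` —
the residual always runs from its last input.  Bilinear (not nearest)
up-sampling is used in the across-stage path because nearest-neighbour
blocks produce spurious local maxima in the heatmap, which surface directly
as duplicate detections under 3×3 peak extraction.  CBAM attention
(channel gate from pooled statistics through a shared MLP, then a spatial
gate from channel-pooled maps) weighs the final fused feature.  The
up-sampling projections can optionally be 3×3 deformable convolutions
(learned sampling offsets, bilinear interpolation, zero-initialized so the
layer starts as a plain convolution); the default uses plain convolutions,
which keeps CPU passes fast and changes no shapes.

Two presets: `dla_lite` — a three-stage backbone (stage channels 16/32/64,
tree depth 1 per stage, ~230k parameters) sized so a 256×256 forward pass
takes well under a second on one CPU core and a full desk-scale training
run takes minutes; `dla34` mirrors the published DLA-34 stage layout
(channels 64/128/256/512, tree depths 1/2/2/1) and is impractical without
GPU hardware — it exists as configuration, not as a tested operating
point.  Capacity in `dla_lite` is deliberately concentrated in the coarse
stages: telling a stoma's center cell from a cell two grid units away along
its long axis requires mid-range context, and the stride-8/16 features are
cheap to widen.

## Targets and losses

Each annotated box becomes a keypoint at grid cell floor(center/R).  A
Gaussian bump is splatted around it with σ = (2r+1)/6, where r comes from
the standard minimum-overlap-0.7 radius rule evaluated on the grid-unit box
sides.  For thin elongated stomata that rule degenerates (r < 1 cell), so r
is floored at 2 cells: a sub-cell-wide bump is unlearnable at R = 4 and
empirically produces broad multi-peaked heatmaps instead of sharp modes.
The center cell is set to exactly 1.

Losses (summed, unit weights by default):

* heatmap: penalty-reduced focal loss with α = 2, β = 4 — positives
  −(1−p)^α·log p, negatives −(1−q)^β·p^α·log(1−p) — normalized by the
  keypoint count (floored at 1), not the pixel count.
* offset, size: mean |Δ| over instances and components, read at the
  ground-truth center cells only.
* angle: mean |Δθ| in degrees.  The literal form is the default; a wrapped
  mode min(|Δθ|, 180−|Δθ|) removes the 0°/180° seam.  The desk-scale
  generator preset keeps orientations in [10°, 170°] so both forms agree.
* conductance: mean |Ĝ−G| per instance, Ĝ from the predicted sizes and G
  from the true box, both evaluated at the image's ground-truth density —
  predicted counts are not differentiable, and fixing the density isolates
  the trait-size error this term supervises.  Non-positive predicted sizes
  are clamped to 10⁻³ µm and counted in `targets.clamp_warnings`.

## Training

AdamW (β = 0.9/0.999), initial learning rate 1.25×10⁻³ decayed per epoch by
gamma = 0.95 (lr = lr₀·γ^epoch), 20 epochs, weight decay 5×10⁻³ applied to
convolution/linear kernels only (norm scales and biases are exempt — the
usual decoupled-decay practice), batch size 4, global gradient-norm clip at
10.  The small batch is intentional: at a fixed epoch budget the number of
optimizer updates is what sharpens the center heatmap, and batch 4 doubles
it relative to batch 8 at identical cost per epoch.  Model weights, data order and the synthetic data itself all derive
from explicit seeds; two runs with the same seed produce identical losses.
Each epoch logs the per-term loss breakdown and validation
precision/recall/F1 at rotated IoU 0.5 plus the validation g_smax MSE; the
best-validation-F1 weights are kept.  The validation conductance comparison
runs the full measurement path — decoded detections → predicted count →
predicted density → g_smax — against the same measurement on the ground
truth, so it includes count errors, not only size errors.

## Synthetic data

The generator emulates bright-field nail-polish imprints of a maize upper
epidermis.  Defaults are the production-frame conditions: 1000×667 px at
0.625 µm/px, 9–16 stomata per image (34.5–61.4 mm⁻², the range of the
reference measurements), length 30–47 µm, width 12–18 µm, uniform
orientation.  A stoma is two concentric ellipses — guard-cell rim darker
than the background, pore slit lighter — so its tight rotated bounding box
equals the sampled traits exactly, which is what makes every downstream
tolerance checkable.  Backgrounds: flat, two-octave smoothed gradient noise
("perlin"), or a periodic cell-wall grid; additive Gaussian noise
(σ = 6 gray levels); Poisson-distributed circular bubble distractors are
rendered but never annotated.  Placement is bounded rejection sampling
(≤ 100 retries per stoma, rotated-IoU overlap ≤ 0.05), raising
`PlacementError` when the frame cannot hold the requested count.  Boxes
with more than one third of their area outside the frame are rendered but
not annotated (the two-thirds visibility labeling rule).

What the generator does not emulate: uneven illumination and focus drift,
partially open/closed pore states, touching or occluded stomata, epidermal
pavement-cell texture that mimics guard cells, and imprint artifacts other
than round bubbles.  Passing tests therefore demonstrate that the pipeline
is correct and learnable end to end, not that the detector transfers to
real micrographs.

The desk-scale preset (`SynthConfig.test_scale()`) uses 256×256 px frames
with 2–6 stomata — per-image counts scaled to keep the frame similarly
occupied — and orientations in [10°, 170°] (see the angle-loss seam above).

Desk-scale study runs train on 200 such images (150 train / 50 validation,
the 3:1 split) for the standard 20 epochs, after expanding the training
split with the 30°/45°/90° rotation augmentation (600 training images) —
the same dataset-expansion step a real imprint corpus goes through before
training.  The expansion matters at this scale: it multiplies the
optimizer updates per epoch by four and supplies the orientation diversity
that a fixed 20-epoch schedule on 150 images otherwise lacks.

The conductance-loss ablation compares training with the conductance
weight at 1 versus 0: 3 seeds per arm, 10 epochs, validation at the final
epoch, on a separate 80-image dataset without the rotation expansion so
that six runs stay desk-sized.  The compared quantity is the median
validation g_smax MSE computed through the full measurement path (decoded
detections → predicted count → predicted density → g_smax).  At this
operating point that MSE responds to detection quality at least as much as
to the trait-size accuracy the conductance term directly supervises — a
single spurious detection shifts the predicted density, which enters
g_smax linearly — so the comparison measures the term's net effect on the
whole pipeline, not size error in isolation; see Known limitations.

## Numerical choices and degenerate inputs

* Angles live in [0°, 180°) on the long axis; `canonicalize` swaps sides
  and rotates by 90° when given width > length.  Equal sides are accepted
  (angle then ambiguous by 90°; tests avoid near-squares).
* Serialization rounds to 6 decimals; annotation readers ignore unknown
  JSON keys and canonicalize on load.
* `gray_stretch` maps the input band [210, 255] onto [0, 255] by default —
  the contrast-maximizing reading; the compressive alternative (output band
  [210, 255]) is available through `out_range`.
* Rotation augmentation expands the canvas (never crops) and re-applies the
  visibility rule on the new frame.
* Matching is greedy in descending score (ties: lower index), one ground
  truth per detection; precision/recall/F1 use the 0-convention for empty
  denominators.  TN is identically 0 in detection.
* R² is reported as NaN with a warning when the truth is constant.
* Division-free guards: zero imaged area raises; a heatmap prediction not
  strictly inside (0, 1) raises (the network clamps its sigmoid).

## Known limitations

* The numpy autodiff engine is single-threaded and keeps im2col buffers
  alive for the backward pass; it is sized for desk-scale experiments, not
  production training.
* The `dla34` preset is untested beyond construction and shape checks.
* Greedy matching is not optimal assignment (a detection may claim a ground
  truth that a later detection overlaps better); at the densities used here
  the difference is negligible.
* Per-stoma conductance inside the loss uses the image-level density, so
  the loss does not penalize count errors — the validation MSE does.
  Consequently, in undertrained regimes where false positives inflate the
  predicted density, the validation conductance MSE moves with detection
  quality as much as with the size accuracy the conductance term
  supervises; the measured sign and size of the ablation contrast should
  be expected to vary with the data budget and training length, and
  desk-scale outcomes do not quantify the term's benefit on a converged
  detector.
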