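# Methods

`satpose` reimplements, end to end, a fully automated pipeline for
estimating 13 postural point-features from sagittal images of seated
children and deriving the two per-frame classifications used by the
Segmental Assessment of Trunk Control (SATCo): segment **alignment**
(deviation from a per-child reference posture) and upper-limb **contact**
(arm support detected relative to the pelvis). Because the clinical videos
this class of pipeline is built on are ethics-restricted, the package ships
a first-class synthetic generator; everything downstream of the camera is
real, tested code.

## Point-features, segments and angle convention

Thirteen landmarks are tracked: temporal fossa, ear tragus, C7, T3, T7,
T11, L3, S1, ASIS, greater trochanter, shoulder, elbow, wrist (fixed order;
the network output is the 26-vector x1, y1, …, x13, y13). Ten segments are
each defined by a (proximal, distal) landmark pair — head, neck, UT, MT,
LT, UL, LL (the spinal chain), pelvis (ASIS–greater trochanter), upper arm
and forearm.

Image coordinates are 0-based, origin at the top-left pixel center, x
rightward, y downward, sub-pixel floats; landmarks may lie outside the
frame (annotators infer occluded points). The segment angle is

    angle = atan2(dx, −dy),  (dx, dy) = proximal − distal,

in degrees: 0° means the proximal point is vertically above the distal one,
positive angles lean toward image-right. No published convention exists for
these segments in pixel space; since every clinical quantity in the
pipeline is an angle *difference*, any consistent convention gives
identical classifications. Differences are always taken circularly (wrapped
to (−180°, 180°]); the per-child reference posture uses arithmetic means,
legitimate because seated postures live far from the ±180° wrap.

## Labels

Manual annotation marks every 4th frame; `data_io.densify_labels` fills the
gaps by per-coordinate linear interpolation between the bracketing manual
rows (exact at annotated frames, monotone between them). Label CSVs are
comma-separated with a `frame_index` column, 26 coordinate columns
`<feature>_x/_y` in canonical order, and an optional `source` column
(`manual` / `interpolated` / `predicted`).

## Preprocessing

- **Crop + resize**: a static per-video ROI is cropped and bilinearly
  resampled to the square network input (256 px full scale, 64 px desk
  scale). The coordinate map is a pure scale about the ROI origin,
  `x_net = (x_orig − x0)·target/width`, and the image is sampled on exactly
  that grid, so transported labels and pixel content match exactly and the
  map inverts to machine precision.
- **Translation augmentation** (training only): per learning iteration,
  (dx, dy) ~ Uniform[−16, 16] px (single precision, real-valued, scaled
  with input size) shifts the image by bilinear resampling with
  edge-replicated borders and shifts every keypoint by exactly the same
  amount.
- **Local contrast normalization** (always): per pixel and channel,
  `(v − μ)/(σ + ε)` with μ, σ over a 19×19 box neighbourhood (reflected
  borders) and ε = 1e-4. The operation is scale-invariant in intensity,
  which removes brightness/contrast/skin-tone variation. Note the output's
  *local* mean is only approximately zero: the divisive step uses a
  spatially varying σ, so exact zero-mean is impossible; tests assert
  approximate standardization instead.

## Network

Five convolutional stages — convolution (filters 9×9×3, 5×5, 5×5, 3×3,
3×3; channels 64, 64, 128, 128, 256; stride 2×2 in the first layer only;
"same" zero padding), ELU, then 2×2 **mean pooling** — followed by three
fully connected ELU layers of 512 units and a linear 26-unit output. With a
256×256×3 input the final feature map is 4×4×256 (3 402 074 trainable
parameters). Mean pooling is the deliberate architectural choice: unlike
max pooling it is differentiable in the *position* of features, so precise
localization can survive five levels of down-sampling via interpolation
between adjacent patches. A max-pooling comparator is one flag away
(`pool="max"`).

Weights are drawn from uniform distributions with bound `sqrt(6/fan_in)`
for ELU units and `sqrt(3/fan_in)` for the linear output (`fan_in` counts
spatial×feature inputs for convolutional units, feature inputs for fully
connected ones); biases start at zero. The printed source ranges omit the
radical signs; the square-root forms are the standard schemes the
description paraphrases.

"Same" padding is an inference: the end-to-end 64× spatial reduction that
yields the stated 4×4 map is exactly stride 2 plus five 2×2 pools, which
requires padding that preserves size elsewhere.

The engine is pure numpy (float32, im2col + BLAS); no deep-learning
framework is available in the target environment, and the architecture *is*
the contribution, so it is authored here with explicit forward/backward
passes verified against finite differences and brute-force pooling oracles.

### Desk-scale preset

`ArchitectureSpec.small()`: 64×64 input, channels [16, 16, 32, 32, 64],
same filters, FC sizes [128, 128, 128], ~120k parameters. The first conv
uses stride 1 — stride 2 plus five pools would terminate at 1×1 and destroy
the spatial information the design exists to preserve; the final map is
2×2×64. This preset is for CPU-scale experiments and CI; the full preset
matches the publication.

## Training protocol

Online learning (batch size 1) minimizing the MAE over the 26 outputs with
ADAM (α = 1e-4 — deliberately below the usual 2e-3 to stabilize
single-sample updates — β1 = 0.9, β2 = 0.999). One source sentence says
"MSE" inside the early-stopping description while defining MAE everywhere
else; MAE is used throughout. Every quarter pass through the training set
(`floor(n_train/4)` iterations; the published "≈7000" is specific to their
~28 000-frame folds) both held-out test sets are evaluated without
augmentation, in loss space; a checkpoint is stored whenever a set improves
its own best, and training stops after 32 consecutive evaluations that
improve neither. Final reporting swaps the checkpoints: test set 2 is
scored with the checkpoint best on set 1 and vice versa, so model selection
never sees the set it reports on.

Cross-validation is leave-one-subject-out: each fold trains on all frames
of the other subjects (asserted by subject ID — no leakage), and the
held-out subject's trials split ~50/50 into the two test sets (odd trial to
set 1; a single-trial subject is split by frames, with a warning). Sample
order is uniform with replacement per iteration. Everything is
deterministic given the data, net seed and training seed.

Optionally targets can be standardized internally (affine, inverted on
prediction); default off, matching delivery of labels in pixel space.

## Synthetic world

The generator renders a side-profile seated child as filled capsules with
coloured square marker blocks on the 10 head/trunk/pelvis landmarks — the
arm carries none, as in the clinical protocol, so the network must learn
arm landmarks from limb shape alone. Pose is articulated by the same 10
segments the kinematics module measures; forward kinematics places the
landmarks, and the returned ground truth is the exact float geometry
(occluders and photometric jitter affect pixels only). Per-frame nuisances:
skin-toned rectangles over a random landmark (therapist hands; default
probability 0.15/frame), a far-side-arm confuser at an offset pose (the
documented wrist-ambiguity failure mode), brightness (±12/255) and contrast
(±15%) jitter. Rendering is 4× supersampled and box-downsampled so marker
edges carry sub-pixel position. Byte-identical output for identical
configuration.

Angles follow independent per-segment bounded random walks about a
near-vertical base pose: Gaussian steps of SD 1.2°/frame (≈30°/s at 25 Hz),
hard-capped at 4°/frame, clipped to per-segment bounds (head 25°, neck 20°,
trunk 18°, pelvis 12°, arm 30°) — magnitudes chosen once as plausible for
seated children with limited trunk control. Contact truth is computed by
forward kinematics through the *same* rule the assessment module applies;
misalignment truth uses the same deviation rule against the trajectory's
own mean at a stated threshold (default 15°). Subject variants perturb
anthropometry by ±10%.

What the generator does **not** emulate: photorealistic appearance,
clothing, 3-D out-of-plane motion, camera optics, correlated inter-segment
coordination, and real annotator noise. A green synthetic test therefore
establishes correctness of the machinery and desk-scale learnability of
this rendering — not clinical-grade performance.

## Classifications

- **Alignment**: a segment is misaligned (positive) when its absolute
  circular deviation from the child's reference posture strictly exceeds
  the threshold (clinically ±20°; a ±1–40° integer sweep is provided). The
  reference posture is the per-child mean of *label-derived* angles over
  all sessions.
- **Contact**: per frame, relative to the *label-derived* ASIS position
  (a dynamic, pelvis-linked threshold): elbow contact iff the elbow is
  strictly on the front side of the ASIS in x (camera on the child's right,
  child facing image-left by default; a facing flag mirrors the rule),
  wrist contact iff strictly below in y. Ties are negative for both rules,
  matching the "more than" wording of the alignment rule.
- **Metrics**: the confusion summary reports counts plus accuracy, TPR/
  recall, FPR, TNR, FNR, precision and F1 as percentages, with machine-
  checked identities; undefined precision (no positive predictions) is
  reported as 0 with an explicit flag rather than dropped.

## Numerical choices

- float32 throughout the network; evaluation MAE in loss space.
- Non-finite activations raise naming the layer; a non-finite loss aborts
  with the iteration index and last good checkpoint.
- Max-pool backward splits gradient equally among tied maxima.
- Strict `<` defines checkpoint improvement, so an identical evaluation
  counts as a strike (this makes the early-stopping trace exact).
- Coincident segment endpoints raise naming the segment.

## Known limitations and the one red check

Desk-scale feasibility (64-px preset, ~4000 synthetic frames, 10 000
iterations, held-out subject variant) achieves ≈0.9 px mean Euclidean
keypoint error — comfortably under the 5%-of-width bar (3.2 px). The
companion expectation that network-derived alignment classification reach
F1 > 0.8 at a 15° threshold does **not** hold, and cannot at this scale:
with ~7-px trunk segments, keypoint error e propagates to angle noise of
roughly √2·e/L radians ≈ 10°, and random-walk misalignment events cluster
marginally past the threshold, so near-threshold flips dominate the
confusion table. The published analysis shows the same physics at full
scale — trunk-segment F1 of 0.2–49% at its clinical threshold despite
4.4-px accuracy. The corresponding acceptance test is kept faithful and
fails by design rather than being weakened; treat alignment F1 at wide
thresholds as a property of the angle-noise-to-excursion ratio, not of the
estimator alone.

Other limitations: no video decoding (callers pre-extract frames); no 3-D
reconstruction or joint angles; the full 256-px preset trains in hours on
CPU (the numpy engine is single-threaded apart from BLAS); reproducing the
paper's exact trained weights is impossible without its restricted data.
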