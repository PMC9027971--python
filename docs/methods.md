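# Methods

`kneeplan` implements a three-stage pipeline for (semi-)automatic 2D
surgical planning in knee ligament reconstruction on lateral radiographs:

* **Stage A** — a multi-task hourglass network detects all anatomical
  features relevant to a planning blueprint in parallel: bone regions as
  multi-label segmentation masks, point landmarks as Gaussian heatmaps, and
  elongated structures as line-symmetric heatmaps.
* **Stage B** — the spatial encodings are converted to geometric objects:
  sub-pixel keypoints (argmax or least-squares Gaussian fit), polylines
  (thresholded weighted point cloud → principal-axis ordering → smoothing
  parametric spline → equidistant arc-length resampling), closed bone
  polygons (largest connected component of each mask channel), and contour
  subsections (a structure's contour weighted by a line heatmap, e.g. the
  posterior femoral cortex).
* **Stage C** — a parameterized blueprint interrelates the named features
  into a plan: MPFL (Schoettle point), ACL femur (Bernard quadrant), ACL
  tibia (AP-diameter fractions), PCL (metric offset + guidewire
  angulation). Plans are pure functions of the features, so user edits
  re-execute in real time, and missing features yield a typed `cancelled`
  status rather than an error.

## Coordinate conventions

Coordinates are continuous, 0-based, x rightwards, y downwards, origin at
the center of the top-left pixel; an `(H, W)` image covers
`[0, W) x [0, H)`. Angles are degrees from the +x axis; undirected line
orientations are folded into `(-90, 90]`. A positive rotation maps
`(1, 0)` toward `(0, 1)`.

## Spatial encodings

Keypoints are encoded as unnormalized bivariate Gaussians with peak value 1
at the continuous landmark coordinate and standard deviation `sigma`
(default **6 px** at the 256×256 network resolution). Line heatmaps apply
the same Gaussian to the point-to-segment distance inside a hull of
line-orthogonal width `6 sigma`; segment ends are capped with half-disks of
radius `3 sigma`, which keeps the field continuous (the hull cap shape is
otherwise immaterial). Both encodings are truncated at `±3 sigma`: the
value at exactly `3 sigma` distance is kept, everything beyond is exactly
zero. Masks are rasterized by pixel-center inclusion (holes subtracted) and
channels may overlap — transmissive imaging superimposes structures
additively, so bones are deliberately *not* modelled as a disjoint
partition.

Encoding happens at network resolution after geometric preprocessing:
augmentation and resizing act on the numeric coordinates, never on already
rasterized labels, so no label information is lost to interpolation.

Decoding thresholds are expressed in sigma units of the unit-peak Gaussian:
"1 sigma" = `exp(-1/2) ≈ 0.6065` (line point selection, contour
subsections) and "2 sigma" = `exp(-2) ≈ 0.1353` (moment-based line
evaluation). This is the only self-consistent mapping from sigma-units to
likelihood for unit-peak heatmaps.

## Network

The detection network is a single (non-stacked) hourglass built entirely
from residual pre-activation bottleneck units (BN → ReLU → 1×1 compress to
half width → BN → ReLU → 3×3 → BN → ReLU → 1×1 expand, identity shortcut)
with a **constant channel count** at every scale, 2× max-pool
downsampling, nearest-neighbour upsampling and parameterized (1×1-convolved)
skip connections. Defaults: 128 features, depth 4, 256×256 input. Three
parameter-sharing topologies are available: `single_task` (independent
towers), `multi_head` (shared encoder *and* decoder, per-task 1×1 heads)
and `multi_decoder` (shared encoder, per-task decoders). Segmentation heads
end in a per-channel sigmoid (multi-label); heatmap heads are linear and
their decoded values are clamped to [0, 1] only at decoding time.

The network and its backpropagation are implemented directly in NumPy
(`kneeplan.nn`): im2col convolutions over BLAS, hand-derived backward
passes, Nesterov-momentum SGD and RMSProp. The backward implementation is
verified against finite differences in the test suite.

## Optimization

The composite objective is `sum_t w_t L_t` with `L_seg = (1 − softDice) +
BCE` (Dice smoothing ε = 1 in numerator and denominator; Dice and BCE each
averaged over channels) and `L_kpt/line = MSE` over all pixels. Training
uses batch size 2, L2 weight penalty `d = 5e-5`, and a triangular cyclical
schedule: learning rate 0.001 → 0.1 → 0.001 over a full cycle of 360
iterations with momentum annealed inversely between 0.9 and 0.8 (momentum
high when the learning rate is low — the conventional coupling; the phase
relation is otherwise a free choice). An RMSProp variant (lr 0.001, single
×0.1 decay at epoch 350) is available for harder intra-operative-style
data. Default budgets are 400 epochs (500 for the RMSProp variant).

Model selection is the epoch minimizing the **unweighted** composite
validation loss `sum_t L_t`, evaluated in encoded space after every epoch
(selection deliberately uses the losses, not decoded-space errors).

### Task weighting

`uniform` sets all `w_t = 1`. `gradnorm` adapts the weights online to
level the tasks' training rates: with `G_t` the gradient norm of the
weighted task loss at the last shared convolution (after the decoder for
`multi_head`, after the encoder bottleneck for `multi_decoder`) and
`r_t` the relative inverse training rate `(L_t / L_t(0)) / mean(·)`, each
step descends `sum_t |G_t − mean(G) · r_t^α|` with asymmetry `α = 1`,
then renormalizes so `sum_t w_t = T`. Reference losses `L_t(0)` are
recorded after the first optimization step (before it they are untrained
noise); this is config-exposed. The weight step size is a dedicated
constant (`gradnorm_lr = 0.025`, the value used in the original GradNorm
formulation) rather than the network's cyclical learning rate: the weight
gradient `sign(G_t − target) · G_t / w_t` lives on a scale unrelated to
the network parameters, and driving it with learning rates up to 0.1 makes
the weights oscillate. Weights are floored at 1e-3 and renormalized after
every update, so they remain positive with `sum w = T` throughout.

## Phantom generator

Clinical cohorts are replaced by schematic lateral-knee phantoms. Each
phantom composes a femur (two overlapping condyle discs + a shaft capsule)
and a tibia (rounded-rectangle plateau + shaft capsule), posed by a random
similarity (rotation ±10°, scale 0.9–1.1, translation ±3%); the joint
fills most of the frame, as on a collimated lateral view. Landmarks carry
the visual evidence they have on real radiographs: the Blumensaat segment
(K1–K2) is rendered as a notch-roof sclerosis line, the plateau corners
are the AP-diameter endpoints (K4/K5) under a subchondral density line,
and K3 sits at the posterior condylar extreme. Two unannotated chirality
cues — a patella-like ellipse anterior to the condyles and a fibula-like
capsule posterior to the tibial shaft — are rendered into the image only:
real lateral knees are chiral, and without such cues the projection would
be nearly left–right symmetric, making anterior/posterior landmarks
ill-posed under horizontal-flip augmentation. The image is an additive
attenuation model (overlap regions are brighter), with optional bright
implant-like bars, optional bilateral exposure (a shifted faint copy),
shaft truncation at the frame border, Gaussian noise, and min–max
normalization. The joint gap is drawn in [-3%, +1%] of the frame so a
majority of samples have genuinely overlapping bone masks. Every sample
stores a synthetic `mm_per_px` drawn uniformly from [0.2, 0.5], emulating
the 30 mm calibration-sphere pathway.

Ground truth is computed analytically from the generating parameters — no
annotation step: bone polygons S1/S2; Blumensaat endpoints K1/K2; MPFL
femoral surface keypoints K3/K7 (snapped onto the femur contour); tibial
AP-diameter endpoints K4/K5 and champagne drop-off K6 (on the tibia
contour); posterior cortex edge L1, plateau AP line L2, shaft axis L3; and
the plan each blueprint produces from those features. Samples are
deterministic in `(seed, index)`.

What the phantom does *not* emulate: real radiographic texture, soft
tissue, anatomical shape variation beyond pose/size jitter, genuine
projective (3D→2D) ambiguity of the tibial plateau, or fracture patterns.
Passing tests therefore demonstrate that the pipeline's machinery —
encodings, optimization, decoding, planning geometry — is correct and
learnable, not that the network reaches clinical accuracy on real
radiographs.

## Blueprint constants

The construction constants are configuration values with non-normative
defaults taken from the cited clinical planning literature: Bernard-quadrant
fractions AM (0.217, 0.332) and PL (0.351, 0.553); tibial AP-diameter
fractions AM 0.36 and PL 0.52; PCL insertion offset 6 mm with a 50°
guidewire angulation; Schoettle anterior offset 0 mm and tolerance radius
2.5 mm. They parameterize the geometry and are validated (fractions in
[0, 1]) at blueprint load; none of them is claimed to reproduce a specific
clinical protocol. "Anterior" for the Schoettle offset is resolved as the
side of the cortex line containing the two keypoints' centroid. The cortex
extension line is fitted by total least squares (orthogonal regression),
which is robust to near-vertical shafts.

## Evaluation

Segmentation is scored with the Dice coefficient averaged over foreground
and background (a channel empty in both prediction and truth scores 1) and
the Average Symmetric Surface Distance between contours densely resampled
at ≤ 0.5 px. Keypoints use the Euclidean distance in px (and mm when
calibrated). Lines are compared via raw image moments after truncating the
heatmap at the 2-sigma likelihood: centroid `(M10/M00, M01/M00)` and
orientation `γ = ½·atan2(2µ′11, µ′20 − µ′02)` folded into `(-90°, 90°]`
(the standard second-moment form; validated by rotation-recovery tests).
Test-set aggregation reports the median with a seeded percentile-bootstrap
95% CI (10,000 resamples); cancelled plans are counted separately.

## Reduced-scale study protocol

The package's end-to-end learning check runs at desk scale: 200 phantoms at
64×64 (split 120/40/40), a multi-head model with 24 features and depth 3,
heatmap sigma 3 px at that resolution, 20 epochs with batch 2 and the
cyclical schedule above, one run per weighting (uniform, GradNorm) on the
same seed set. Held-out quality is measured as fg/bg-averaged Dice and the
median keypoint localization error of the argmax decoder.

At this scale the augmentation ranges are narrowed to the phantom's own
pose variability (rotation ±10°, scale 0.9–1.1, no flip or shear; the
config-exposed `augment_*` fields). The full clinical-scale protocol draws
a fresh ±45° rotation for every one of only ~1200 updates, so the network
never sees a comparable view twice and the MSE-optimal keypoint response
degenerates to the marginal average heatmap — a pure underfitting regime
that the full-scale budget (hundreds of epochs) does not have. Narrowed
augmentation keeps the tasks competing for shared capacity (the regime in
which task weighting matters) while remaining learnable in 20 epochs.
These sizes and ranges are the package's own scaled-down protocol; the
defaults above remain the full-scale configuration.

## Numerical choices and degenerate inputs

* Heatmap truncation boundary: strict `<=` (kept at exactly 3σ).
* Argmax ties break to the lowest y, then lowest x; peaks below 0.05
  signal "not detected".
* The Gaussian-fit decoder falls back to the argmax when the fit diverges
  or moves more than the window radius.
* Line decoding orders points by projection onto the cloud's principal
  axis; curves that double back along that axis are out of scope (none of
  the supported reference structures do).
* Constant images min–max-normalize to all zeros with a warning.
* Degenerate plans (coincident keypoints, flat contours, missing scale)
  cancel with machine-readable reasons; planning never raises on missing
  features.

## Known limitations

* No registration of a plan onto subsequent live images.
* Single-hourglass supervision only (no stacked intermediate supervision),
  no attention, no uncertainty estimation.
* The NumPy training loop is single-threaded BLAS-bound; it is sized for
  the reduced-scale protocol, not for 256×256/400-epoch production runs.
* The phantom's schematic realism bounds what can be claimed about
  clinical data (see above).
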