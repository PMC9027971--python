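# kneeplan

Multi-stage 2D surgical planning for knee ligament reconstruction on
lateral radiographs.

Reconstructive surgery of the knee ligaments (MPFL, ACL, PCL) is planned on
2D X-ray images by interrelating salient anatomical features — bone
outlines, point landmarks, reference lines — through clinically established
geometric constructions: the Schoettle point for the femoral MPFL
insertion, the Bernard quadrant method for the femoral ACL tunnel,
AP-diameter fractions for the tibial ACL attachment, and a metric
offset-plus-angulation rule for the transtibial PCL guidewire. `kneeplan`
automates this workflow in three stages while keeping every step
user-correctable:

* **Stage A — detection.** A multi-task hourglass network (constant channel
  count, residual pre-activation bottlenecks) predicts all features in
  parallel: multi-label bone masks `S_k` (overlap allowed — transmissive
  imaging superimposes structures additively), unit-peak Gaussian keypoint
  heatmaps (`σ = 6 px`, truncated at `±3σ`) and line-symmetric heatmaps of
  hull width `6σ`. Parameter sharing is configurable: `single_task`,
  `multi_head` (shared encoder+decoder, 1×1 heads) or `multi_decoder`.
  The multi-task objective `Σ_t w_t L_t` uses Soft-Dice+BCE for
  segmentation and MSE for heatmaps, with uniform or GradNorm (`α = 1`)
  task weights, Nesterov momentum under a triangular cyclical schedule
  (lr 0.001–0.1, momentum 0.9–0.8, cycle 360 iterations), and selection by
  minimum unweighted composite validation loss.
* **Stage B — geometric decoding.** Heatmaps become sub-pixel keypoints
  (spatial argmax or least-squares Gaussian fit), B-spline polylines, bone
  polygons, and heatmap-weighted contour subsections (e.g. the posterior
  femoral cortex). Weak evidence yields a typed *not-detected* result.
* **Stage C — plan construction.** Parameterized blueprints map named
  features to drill targets and guidewires; plans are pure functions of
  their inputs, so user edits re-execute in real time, and missing features
  cancel the plan gracefully. PCL planning refuses to run without a
  pixel-to-mm calibration (e.g. from a 30 mm reference sphere:
  `mm_per_px = 30 / diameter_px`).

Because the clinical cohorts behind this methodology are not available, the
package ships a **synthetic phantom generator**: schematic lateral-knee
projections with additive intensities, bone overlap, shaft truncation,
implant overlays, bilateral exposure, and *exact* analytic ground truth
(masks S1/S2, keypoints K1–K7, lines L1–L3, per-application plan truth).
Every stage is trainable and testable end to end without downloads. See
`docs/methods.md` for the model details and what phantom results do and do
not demonstrate.

The network and its backpropagation are implemented directly in NumPy
(`kneeplan.nn`), verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from kneeplan import (
    PhantomConfig, generate_phantom, PlanBlueprint, execute_plan, keypoint_ed,
)
from kneeplan.planning import Application

sample = generate_phantom(PhantomConfig(image_size=(256, 256), seed=7), 0)
plan = execute_plan(
    sample.features, PlanBlueprint.default(Application.MPFL), cal=sample.calibration
)
t = plan.targets["schoettle"]
print(f"status={plan.status} schoettle=({t.x:.2f}, {t.y:.2f}) px "
      f"tolerance={plan.tolerance_radius_px:.2f} px")

edited = execute_plan(
    sample.features, PlanBlueprint.default(Application.MPFL),
    edits={"kp_a": sample.features.keypoints["K3"]}, cal=sample.calibration,
)
moved, _ = keypoint_ed(edited.targets["schoettle"], t)
print(f"after identity edit the target moved {moved:.6f} px")
```

Output:

```
status=ok schoettle=(157.65, 130.92) px tolerance=7.00 px
after identity edit the target moved 0.000000 px
```

The plan is `ok`; the Schoettle point lies on the posterior-cortex
extension line midway between the perpendicular feet of the two distal
femoral keypoints, and the 2.5 mm clinical tolerance circle is 7.0 px at
this phantom's 0.36 mm/px calibration. Re-executing with an edit that
replaces a keypoint by itself reproduces the target bit for bit — the plan
is a deterministic function of its features.

A command-line interface wraps the same library:

```bash
kneeplan phantom --n 50 --seed 0 --out data/
kneeplan train --data data/ --topology multi_head --weighting gradnorm --out model.npz
kneeplan infer --model model.npz --image data/test/phantom_00045.png --out pred.json
kneeplan plan --app mpfl --features pred.json --out plan_overlay
kneeplan eval --pred preds/ --gt data/test/ --out report.json
```

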