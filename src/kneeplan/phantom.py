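"""Synthetic lateral-knee phantoms with exact ground truth.

The phantom is schematic, not anatomically realistic: its purpose is to
reproduce the *structural* properties the detection and planning stages
consume — two bone outlines that may superimpose (femoral condyles over the
tibial plateau, as in an additive transmissive projection), landmarks that
lie exactly on the generating contours, elongated reference structures
(posterior cortex, plateau diameter, shaft axis), shaft truncation at the
frame border, optional implant-like overlays and bilateral exposure, plus a
stored pixel-to-mm scale emulating the calibration-sphere pathway.

Every sample is a deterministic function of ``(seed, index)`` and carries
its complete ground truth computed analytically from the generating
parameters: bone polygons S1/S2, keypoints K1-K7, lines L1-L3 and the plan
each blueprint produces from those features.

Feature registry (see also :mod:`kneeplan.planning`):

====== =====================================================
K1, K2 Blumensaat-line endpoints (femoral notch roof)
K3, K7 distal femoral MPFL keypoints (posterior / distal condyle surface)
K4, K5 anterior / posterior tibial plateau AP-diameter endpoints
K6     champagne drop-off (posterior tibial PCL reference)
L1     posterior femoral cortex edge
L2     tibial plateau AP-diameter line
L3     tibial shaft axis
S1, S2 femur / tibia outline
====== =====================================================
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from shapely import affinity
from shapely.geometry import LineString, Point, box
from shapely.ops import nearest_points, unary_union

from .decoding import FeatureSet
from .encoding import rasterize_mask
from .geometry import Calibration, CalibrationSource, Keypoint, PolygonRegion, Polyline
from .planning import Application, PlanBlueprint, PlanResult, execute_plan
from .training import normalize_intensity

KEYPOINT_LABELS = ("K1", "K2", "K3", "K4", "K5", "K6", "K7")
LINE_LABELS = ("L1", "L2", "L3")
REGION_LABELS = ("S1", "S2")


class CohortPreset(str, Enum):
    diagnostic = "diagnostic"
    intraoperative = "intraoperative"


@dataclass(frozen=True)
class PhantomConfig:
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0
    rotation_deg: float = 10.0
    translation_frac: float = 0.03
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_implant: float = 0.25
    p_bilateral: float = 0.05
    noise: float = 0.02
    mm_per_px_range: tuple[float, float] = (0.2, 0.5)
    preset: CohortPreset = CohortPreset.diagnostic

    def __post_init__(self) -> None:
        object.__setattr__(self, "preset", CohortPreset(self.preset))
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("phantom images must be at least 32x32")
        if not (0 <= self.p_implant <= 1 and 0 <= self.p_bilateral <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.scale_range[0] >= self.scale_range[1] or self.mm_per_px_range[0] >= self.mm_per_px_range[1]:
            raise ValueError("ranges must be non-degenerate (lo < hi)")

    @classmethod
    def for_preset(cls, preset: CohortPreset | str, **kwargs) -> "PhantomConfig":
        preset = CohortPreset(preset)
        if preset == CohortPreset.intraoperative:
            defaults = dict(p_implant=0.7, p_bilateral=0.35, noise=0.04, rotation_deg=14.0)
        else:
            defaults = {}
        defaults.update(kwargs)
        return cls(preset=preset, **defaults)


@dataclass
class PhantomSample:
    index: int
    image: np.ndarray  # (H, W) float in [0, 1]
    features: FeatureSet  # S1/S2 regions, K1-K7, L1-L3
    calibration: Calibration
    plan_truth: dict[str, PlanResult]
    params: dict = field(default_factory=dict)


def _snap_to_contour(poly, p: np.ndarray) -> np.ndarray:
    """Project a point onto a polygon's exterior ring."""
    nearest = nearest_points(poly.exterior, Point(p))[0]
    return np.array([nearest.x, nearest.y])


def _shapely_to_region(poly, label: str) -> PolygonRegion:
    shell = np.asarray(poly.exterior.coords)[:-1]
    holes = tuple(np.asarray(r.coords)[:-1] for r in poly.interiors)
    return PolygonRegion(shell=shell, holes=holes, label=label)


def generate_phantom(cfg: PhantomConfig, index: int) -> PhantomSample:
    """Generate one phantom; deterministic in ``(cfg.seed, index)``."""
    rng = np.random.default_rng([cfg.seed, index])
    h, w = cfg.image_size
    s = float(min(h, w))
    params: dict = {"index": index}

    # -- canonical anatomy (the joint fills most of the frame, as on a
    # collimated lateral view) --------------------------------------------
    c_f = np.array([0.52 * w, 0.38 * h]) + rng.uniform(-0.015, 0.015, 2) * s
    r1 = s * rng.uniform(0.20, 0.24)
    r2 = 0.85 * r1
    c_f2 = c_f + np.array([0.05, 0.02]) * s
    tilt_f = np.radians(rng.uniform(-8.0, 8.0))
    u_up = np.array([np.sin(tilt_f), -np.cos(tilt_f)])  # unit vector up the femoral shaft
    n_post = np.array([np.cos(tilt_f), np.sin(tilt_f)])  # posterior (right) shaft normal
    w_f = 0.16 * s
    shaft_f = LineString([c_f - 0.02 * s * u_up, c_f + 0.8 * s * u_up]).buffer(w_f / 2.0, quad_segs=12)
    femur = unary_union(
        [Point(c_f).buffer(r1, quad_segs=24), Point(c_f2).buffer(r2, quad_segs=24), shaft_f]
    )

    tilt_t = np.radians(rng.uniform(-6.0, 6.0))
    u_dn = np.array([np.sin(tilt_t), np.cos(tilt_t)])
    joint_gap = rng.uniform(-0.03, 0.01) * s  # negative gap -> bone overlap
    c_t = c_f + np.array([0.03 * s, r1 + 0.06 * s + joint_gap])
    # plateau as a rounded rectangle: real tibial plateaus have distinct
    # anterior/posterior corners at the articular surface, which is what
    # makes the AP-diameter endpoints identifiable landmarks
    rr = 0.02 * s
    half_ap, half_th = 0.26 * s, 0.07 * s
    plateau = box(
        c_t[0] - half_ap + rr, c_t[1] - half_th + rr, c_t[0] + half_ap - rr, c_t[1] + half_th - rr
    ).buffer(rr, quad_segs=8)
    shaft_t = LineString([c_t, c_t + 0.8 * s * u_dn]).buffer(0.10 * s, quad_segs=12)
    tibia = unary_union([plateau, shaft_t])

    # chirality cues rendered into the image but not annotated (as in real
    # lateral views): patella anterior to the condyles, fibula posterior to
    # the tibial shaft. Without them the projection would be nearly
    # left-right symmetric and anterior/posterior landmarks ill-posed under
    # horizontal-flip augmentation.
    patella = affinity.scale(
        Point(c_f + np.array([-1.45 * r1, -0.25 * r1])).buffer(1.0, quad_segs=16),
        0.4 * r1,
        0.7 * r1,
    )
    fib_start = c_t + np.array([0.20 * s, 0.12 * s])
    fibula = LineString([fib_start, fib_start + 0.6 * s * u_dn]).buffer(0.04 * s, quad_segs=8)

    # landmarks (canonical frame; snapped to the generating contours)
    blu_center = c_f + np.array([0.0, 0.015 * s])
    blu_angle = np.radians(rng.uniform(-40.0, -25.0))
    blu_dir = np.array([np.cos(blu_angle), np.sin(blu_angle)])
    k1 = blu_center - 0.6 * r1 * blu_dir
    k2 = blu_center + 0.6 * r1 * blu_dir
    # K3 at the posterior condylar extreme (a curvature landmark), K7 on the
    # distal condyle surface; K4/K5 at the plateau's anterior/posterior
    # articular-surface corners
    k3 = _snap_to_contour(femur, c_f + r1 * np.array([1.0, 0.0]))
    k7 = _snap_to_contour(femur, c_f + r1 * np.array([np.cos(np.radians(80)), np.sin(np.radians(80))]))
    k4 = _snap_to_contour(tibia, c_t + np.array([-half_ap, -half_th]))
    k5 = _snap_to_contour(tibia, c_t + np.array([half_ap, -half_th]))
    k6 = _snap_to_contour(tibia, c_t + 0.08 * s * u_dn + np.array([0.12 * s, 0.0]))
    cortex_a = c_f + 0.18 * s * u_up + (w_f / 2.0) * n_post
    cortex_b = c_f + 0.55 * s * u_up + (w_f / 2.0) * n_post
    l3_a, l3_b = c_t + 0.12 * s * u_dn, c_t + 0.50 * s * u_dn

    # -- global pose (redraw until all keypoints stay inside the frame) ----
    for _ in range(10):
        rot = np.radians(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
        scale = rng.uniform(*cfg.scale_range)
        trans = rng.uniform(-cfg.translation_frac, cfg.translation_frac, 2) * s
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        lin = scale * np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        t = center - lin @ center + trans
        kps = {
            name: lin @ p + t
            for name, p in zip(KEYPOINT_LABELS, (k1, k2, k3, k4, k5, k6, k7))
        }
        margin = 2.0
        if all(
            margin <= p[0] < w - margin and margin <= p[1] < h - margin for p in kps.values()
        ):
            break
    params.update(rotation_deg=np.degrees(rot), scale=scale)

    def warp_pts(pts):
        return np.asarray(pts, dtype=float) @ lin.T + t

    mat = [lin[0, 0], lin[0, 1], lin[1, 0], lin[1, 1], t[0], t[1]]
    femur_p = affinity.affine_transform(femur, mat)
    tibia_p = affinity.affine_transform(tibia, mat)

    features = FeatureSet()
    features.add(_shapely_to_region(femur_p, "S1"), provenance="ground_truth")
    features.add(_shapely_to_region(tibia_p, "S2"), provenance="ground_truth")
    for name, p in kps.items():
        if name in ("K3", "K7"):
            p = _snap_to_contour(femur_p, p)
        elif name in ("K4", "K5", "K6"):
            p = _snap_to_contour(tibia_p, p)
        features.add(Keypoint(x=float(p[0]), y=float(p[1]), label=name), provenance="ground_truth")
    features.add(
        Polyline(points=warp_pts([cortex_a, cortex_b]), label="L1"), provenance="ground_truth"
    )
    features.add(
        Polyline(
            points=np.vstack([features.keypoints["K4"].xy, features.keypoints["K5"].xy]), label="L2"
        ),
        provenance="ground_truth",
    )
    features.add(Polyline(points=warp_pts([l3_a, l3_b]), label="L3"), provenance="ground_truth")

    # -- image formation (additive attenuation) ----------------------------
    masks = rasterize_mask([features.regions["S1"], features.regions["S2"]], (h, w))
    img = 0.35 * masks.data[0].astype(float) + 0.35 * masks.data[1].astype(float)
    # radiographic density lines — the visual evidence behind the interior
    # landmarks: notch-roof sclerosis along the Blumensaat segment (K1-K2)
    # and the subchondral plateau surface (K4-K5)
    blu_line = LineString(
        [features.keypoints["K1"].xy, features.keypoints["K2"].xy]
    ).buffer(0.018 * s, quad_segs=6)
    plateau_line = LineString(
        [features.keypoints["K4"].xy, features.keypoints["K5"].xy]
    ).buffer(0.014 * s, quad_segs=6)
    cues = [
        (affinity.affine_transform(patella, mat), 0.30),
        (affinity.affine_transform(fibula, mat), 0.25),
        (blu_line, 0.22),
        (plateau_line, 0.18),
    ]
    for cue_p, intensity in cues:
        if not cue_p.is_empty:
            cue_mask = rasterize_mask([_shapely_to_region(cue_p, "cue")], (h, w)).data[0]
            img += intensity * cue_mask.astype(float)
    p_implant = cfg.p_implant
    p_bilateral = cfg.p_bilateral
    if rng.random() < p_implant:
        n_bars = rng.integers(1, 3)
        for _ in range(n_bars):
            angle = rng.uniform(0, np.pi)
            length, width = rng.uniform(0.3, 0.6) * s, rng.uniform(0.02, 0.04) * s
            cb = rng.uniform(0.3, 0.7, 2) * np.array([w, h])
            d = np.array([np.cos(angle), np.sin(angle)])
            bar = LineString([cb - length / 2 * d, cb + length / 2 * d]).buffer(width / 2.0)
            bar_mask = rasterize_mask([_shapely_to_region(bar, "implant")], (h, w)).data[0]
            img += 0.85 * bar_mask.astype(float)
        params["implant"] = True
    if rng.random() < p_bilateral:
        shift = int(0.45 * w) * (1 if rng.random() < 0.5 else -1)
        img = img + 0.5 * np.roll(img, shift, axis=1)
        params["bilateral"] = True
    img = ndimage.gaussian_filter(img, sigma=0.8)
    img = img + rng.normal(0.0, cfg.noise, size=img.shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        img = normalize_intensity(img)

    calibration = Calibration(
        mm_per_px=float(rng.uniform(*cfg.mm_per_px_range)), source=CalibrationSource.sphere
    )

    plan_truth = {
        app.value: execute_plan(features, PlanBlueprint.default(app), cal=calibration)
        for app in Application
    }
    return PhantomSample(
        index=index,
        image=img,
        features=features,
        calibration=calibration,
        plan_truth=plan_truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def split_indices(n: int, fractions: tuple[float, float, float]) -> dict[str, list[int]]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    if n < 3:
        raise ValueError("need at least 3 samples for a 3-way split")
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    n_val = max(1, min(n_val, n - n_train - 1))
    n_train = max(1, min(n_train, n - n_val - 1))
    return {
        "train": list(range(0, n_train)),
        "val": list(range(n_train, n_train + n_val)),
        "test": list(range(n_train + n_val, n)),
    }


def generate_samples(cfg: PhantomConfig, indices) -> list[PhantomSample]:
    return [generate_phantom(cfg, i) for i in indices]


def generate_dataset(
    cfg: PhantomConfig,
    n: int,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    out_dir: Optional[Path] = None,
) -> dict:
    """Generate ``n`` phantoms with a disjoint train/val/test split.

    When ``out_dir`` is given, images (PNG), annotations (labelme-style
    JSON), plan truth (JSON) and a manifest CSV are written to disk;
    regenerating with the same config reproduces the manifest byte for byte.
    """
    from .annotations import write_annotation  # deferred to avoid cycle

    splits = split_indices(n, split)
    manifest_rows = []
    samples: dict[str, list[PhantomSample]] = {}
    for split_name, idxs in splits.items():
        samples[split_name] = []
        for i in idxs:
            sample = generate_phantom(cfg, i)
            samples[split_name].append(sample)
            row = {
                "index": i,
                "split": split_name,
                "mm_per_px": round(sample.calibration.mm_per_px, 6),
                "implant": bool(sample.params.get("implant", False)),
                "bilateral": bool(sample.params.get("bilateral", False)),
            }
            manifest_rows.append(row)
            if out_dir is not None:
                out_dir = Path(out_dir)
                (out_dir / split_name).mkdir(parents=True, exist_ok=True)
                stem = out_dir / split_name / f"phantom_{i:05d}"
                Image.fromarray((sample.image * 255).round().astype(np.uint8)).save(
                    stem.with_suffix(".png")
                )
                write_annotation(
                    stem.with_suffix(".json"),
                    sample.features,
                    image_path=stem.with_suffix(".png").name,
                    image_size=cfg.image_size,
                )
                plan_json = {
                    app: _plan_to_json(plan) for app, plan in sample.plan_truth.items()
                }
                plan_json["calibration_mm_per_px"] = sample.calibration.mm_per_px
                with open(stem.with_suffix(".plan.json"), "w") as f:
                    json.dump(plan_json, f, indent=1, sort_keys=True)
    manifest = pd.DataFrame(manifest_rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return {"samples": samples, "manifest": manifest, "splits": splits}


def _plan_to_json(plan: PlanResult) -> dict:
    out: dict = {"status": plan.status, "reason": plan.reason}
    out["targets"] = {k: [kp.x, kp.y] for k, kp in plan.targets.items()}
    if plan.wire_angle_deg is not None:
        out["wire_angle_deg"] = plan.wire_angle_deg
    return out
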