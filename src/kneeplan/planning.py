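"""Stage C: blueprint-driven geometric construction of surgical plans.

Each supported application maps named anatomical features to a drill target
and/or a guidewire line through a deterministic sequence of elementary
constructions (orthogonal line fit, perpendicular feet, fractional points,
metric offsets):

* **MPFL** (Schoettle): a total-least-squares extension line through the
  posterior femoral cortex subsection, perpendicular feet of two distal
  femoral keypoints on that line, target at the midpoint of the feet
  (optionally offset anteriorly), with a 2.5 mm tolerance circle when the
  image is calibrated.
* **ACL femur** (Bernard quadrant): a rectangle aligned to the Blumensaat
  segment (K1 -> K2) and sized by the condyle contour's extents; bundle
  targets at configured fractional coordinates of that rectangle.
* **ACL tibia** (Staeubli/Rauschning): bundle targets at configured
  fractions of the anterior-posterior plateau diameter.
* **PCL** (Johannsen): insertion point displaced a metric distance from a
  tibial reference keypoint along the reference line, with a guidewire at a
  configured angulation; refuses to run without pixel-to-mm calibration.

Every step is similarity-equivariant, and any missing input feature yields
a ``cancelled`` plan with a machine-readable reason instead of an error.

The numeric blueprint constants are configuration with documented,
non-normative defaults drawn from the cited clinical literature; they are
not claimed to reproduce any particular clinical protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Union

import numpy as np

from .decoding import FeatureSet, NotDetected
from .geometry import (
    Calibration,
    Keypoint,
    PolygonRegion,
    Polyline,
    UNCALIBRATED,
    normalize_orientation_deg,
)


class Application(str, Enum):
    MPFL = "mpfl"
    ACL_FEMUR = "acl_femur"
    ACL_TIBIA = "acl_tibia"
    PCL = "pcl"


#: Default binding of blueprint roles to registry feature labels. K1/K2 are
#: the Blumensaat endpoints, K3/K7 the distal femoral (MPFL) keypoints,
#: K4/K5 the tibial AP-diameter endpoints, K6 the champagne drop-off
#: reference; L1 is the posterior femoral cortex, L3 the tibial shaft axis.
DEFAULT_ROLES: dict[Application, dict[str, str]] = {
    Application.MPFL: {"kp_a": "K3", "kp_b": "K7", "cortex_line": "L1"},
    Application.ACL_FEMUR: {"kp_blumensaat_a": "K1", "kp_blumensaat_b": "K2", "condyle_region": "S1"},
    Application.ACL_TIBIA: {"kp_anterior": "K4", "kp_posterior": "K5"},
    Application.PCL: {"kp_reference": "K6", "reference_line": "L3"},
}

DEFAULT_CONSTANTS: dict[Application, dict[str, float]] = {
    Application.MPFL: {"anterior_offset_mm": 0.0, "tolerance_radius_mm": 2.5},
    Application.ACL_FEMUR: {
        "am_frac_u": 0.217,
        "am_frac_v": 0.332,
        "pl_frac_u": 0.351,
        "pl_frac_v": 0.553,
    },
    Application.ACL_TIBIA: {"am_frac": 0.36, "pl_frac": 0.52},
    Application.PCL: {"offset_mm": 6.0, "wire_angle_deg": 50.0},
}

_FRACTION_KEYS = {"am_frac_u", "am_frac_v", "pl_frac_u", "pl_frac_v", "am_frac", "pl_frac"}


@dataclass(frozen=True)
class PlanBlueprint:
    """Parameterized construction recipe for one application."""

    application: Application
    constants: dict[str, float] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        app = Application(self.application)
        object.__setattr__(self, "application", app)
        constants = {**DEFAULT_CONSTANTS[app], **self.constants}
        roles = {**DEFAULT_ROLES[app], **self.roles}
        for key, value in constants.items():
            if key in _FRACTION_KEYS and not 0.0 <= value <= 1.0:
                raise ValueError(f"blueprint fraction {key}={value} outside [0, 1]")
        object.__setattr__(self, "constants", constants)
        object.__setattr__(self, "roles", roles)

    @classmethod
    def default(cls, application: Union[Application, str]) -> "PlanBlueprint":
        return cls(application=Application(application))


@dataclass(frozen=True)
class PlanResult:
    application: Application
    status: str  # "ok" or "cancelled"
    reason: str = ""
    targets: dict[str, Keypoint] = field(default_factory=dict)
    wires: dict[str, Polyline] = field(default_factory=dict)
    intermediates: dict[str, object] = field(default_factory=dict)
    targets_mm: dict[str, tuple[float, float]] = field(default_factory=dict)
    wire_angle_deg: Optional[float] = None
    tolerance_radius_px: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _cancelled(app: Application, reason: str) -> PlanResult:
    return PlanResult(application=app, status="cancelled", reason=reason)


def _get_role(features: FeatureSet, bp: PlanBlueprint, role: str):
    label = bp.roles[role]
    feat = features.get(label)
    return feat


def _tls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares (orthogonal) line fit: returns (centroid, unit direction)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    # principal direction of the scatter; robust to near-vertical lines
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    return centroid, direction / np.linalg.norm(direction)


def _project_onto_line(p: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    return origin + float((p - origin) @ direction) * direction


def _mm_to_px(cal: Optional[Calibration], mm: float) -> Optional[float]:
    if cal is None or not cal.is_calibrated:
        return None
    return cal.mm_to_px(mm)


def _report_mm(cal: Optional[Calibration], kp: Keypoint) -> Optional[tuple[float, float]]:
    if cal is None or not cal.is_calibrated:
        return None
    return (kp.x * cal.mm_per_px, kp.y * cal.mm_per_px)


# ---------------------------------------------------------------------------
# MPFL (Schoettle)
# ---------------------------------------------------------------------------


def plan_mpfl(
    features: FeatureSet, bp: Optional[PlanBlueprint] = None, cal: Calibration = UNCALIBRATED
) -> PlanResult:
    """Locate the femoral MPFL insertion (Schoettle point)."""
    bp = bp or PlanBlueprint.default(Application.MPFL)
    app = Application.MPFL
    kp_a = _get_role(features, bp, "kp_a")
    kp_b = _get_role(features, bp, "kp_b")
    cortex = _get_role(features, bp, "cortex_line")
    for feat, name in ((kp_a, "kp_a"), (kp_b, "kp_b"), (cortex, "cortex_line")):
        if isinstance(feat, NotDetected):
            return _cancelled(app, f"missing-feature:{name}")
    if not isinstance(cortex, Polyline):
        return _cancelled(app, "cortex_line-not-a-line")
    pa, pb = kp_a.xy, kp_b.xy
    if np.allclose(pa, pb):
        return _cancelled(app, "degenerate:keypoints-coincident")
    origin, direction = _tls_line(cortex.points)
    foot_a = _project_onto_line(pa, origin, direction)
    foot_b = _project_onto_line(pb, origin, direction)
    target = 0.5 * (foot_a + foot_b)
    normal = np.array([-direction[1], direction[0]])
    # "anterior" = the side of the cortex line holding the keypoints' centroid
    centroid = 0.5 * (pa + pb)
    if (centroid - target) @ normal < 0:
        normal = -normal
    offset_mm = bp.constants["anterior_offset_mm"]
    if offset_mm:
        offset_px = _mm_to_px(cal, offset_mm)
        if offset_px is None:
            return _cancelled(app, "no-scale:anterior-offset-requires-calibration")
        target = target + offset_px * normal
    target_kp = Keypoint(x=float(target[0]), y=float(target[1]), label="schoettle")
    tol_px = _mm_to_px(cal, bp.constants["tolerance_radius_mm"])
    line_len = max(np.linalg.norm(cortex.points[-1] - cortex.points[0]), 1.0)
    cortex_line = Polyline(
        points=np.vstack([origin - line_len * direction, origin + line_len * direction]),
        label="cortex_extension",
    )
    result = PlanResult(
        application=app,
        status="ok",
        targets={"schoettle": target_kp},
        intermediates={
            "cortex_extension": cortex_line,
            "foot_a": Keypoint(*foot_a, label="foot_a"),
            "foot_b": Keypoint(*foot_b, label="foot_b"),
            "perpendicular_a": Polyline(points=np.vstack([pa, foot_a]), label="perpendicular_a"),
            "perpendicular_b": Polyline(points=np.vstack([pb, foot_b]), label="perpendicular_b"),
        },
        tolerance_radius_px=tol_px,
    )
    mm = _report_mm(cal, target_kp)
    if mm is not None:
        result.targets_mm["schoettle"] = mm
    return result


# ---------------------------------------------------------------------------
# ACL femur (Bernard quadrant)
# ---------------------------------------------------------------------------


def plan_acl_femur(
    features: FeatureSet, bp: Optional[PlanBlueprint] = None, cal: Calibration = UNCALIBRATED
) -> PlanResult:
    """Place the AM/PL femoral bundle targets on the Bernard quadrant frame."""
    bp = bp or PlanBlueprint.default(Application.ACL_FEMUR)
    app = Application.ACL_FEMUR
    k1 = _get_role(features, bp, "kp_blumensaat_a")
    k2 = _get_role(features, bp, "kp_blumensaat_b")
    region = _get_role(features, bp, "condyle_region")
    for feat, name in ((k1, "kp_blumensaat_a"), (k2, "kp_blumensaat_b"), (region, "condyle_region")):
        if isinstance(feat, NotDetected):
            return _cancelled(app, f"missing-feature:{name}")
    if not isinstance(region, PolygonRegion):
        return _cancelled(app, "condyle_region-not-a-region")
    p1, p2 = k1.xy, k2.xy
    if np.allclose(p1, p2):
        return _cancelled(app, "degenerate:blumensaat-keypoints-coincident")
    u = (p2 - p1) / np.linalg.norm(p2 - p1)
    v = np.array([-u[1], u[0]])
    contour = region.shell
    centroid = contour.mean(axis=0)
    # v points from the Blumensaat line towards the condyle body
    if (centroid - p1) @ v < 0:
        v = -v
    pu = (contour - p1) @ u
    pv = (contour - p1) @ v
    u0, u1 = float(pu.min()), float(pu.max())
    v0, v1 = float(pv.min()), float(pv.max())
    width, height = u1 - u0, v1 - v0
    if width <= 0 or height <= 0:
        return _cancelled(app, "degenerate:flat-contour")
    origin = p1 + u0 * u + v0 * v
    c = bp.constants

    def frame_point(fu: float, fv: float, label: str) -> Keypoint:
        p = origin + fu * width * u + fv * height * v
        return Keypoint(x=float(p[0]), y=float(p[1]), label=label)

    am = frame_point(c["am_frac_u"], c["am_frac_v"], "acl_am_femur")
    pl = frame_point(c["pl_frac_u"], c["pl_frac_v"], "acl_pl_femur")
    corners = np.array(
        [origin, origin + width * u, origin + width * u + height * v, origin + height * v]
    )
    result = PlanResult(
        application=app,
        status="ok",
        targets={"am": am, "pl": pl},
        intermediates={
            "frame": Polyline(points=corners, label="bernard_frame", closed=True),
            "blumensaat": Polyline(points=np.vstack([p1, p2]), label="blumensaat"),
        },
    )
    for name, kp in result.targets.items():
        mm = _report_mm(cal, kp)
        if mm is not None:
            result.targets_mm[name] = mm
    return result


# ---------------------------------------------------------------------------
# ACL tibia (Staeubli/Rauschning AP-diameter fractions)
# ---------------------------------------------------------------------------


def plan_acl_tibia(
    features: FeatureSet, bp: Optional[PlanBlueprint] = None, cal: Calibration = UNCALIBRATED
) -> PlanResult:
    """Place the AM/PL tibial bundle targets on the AP plateau diameter."""
    bp = bp or PlanBlueprint.default(Application.ACL_TIBIA)
    app = Application.ACL_TIBIA
    ant = _get_role(features, bp, "kp_anterior")
    post = _get_role(features, bp, "kp_posterior")
    for feat, name in ((ant, "kp_anterior"), (post, "kp_posterior")):
        if isinstance(feat, NotDetected):
            return _cancelled(app, f"missing-feature:{name}")
    pa, pp = ant.xy, post.xy
    if np.allclose(pa, pp):
        return _cancelled(app, "degenerate:endpoints-coincident")
    c = bp.constants

    def frac_point(f: float, label: str) -> Keypoint:
        p = pa + f * (pp - pa)
        return Keypoint(x=float(p[0]), y=float(p[1]), label=label)

    am = frac_point(c["am_frac"], "acl_am_tibia")
    pl = frac_point(c["pl_frac"], "acl_pl_tibia")
    result = PlanResult(
        application=app,
        status="ok",
        targets={"am": am, "pl": pl},
        intermediates={"ap_diameter": Polyline(points=np.vstack([pa, pp]), label="ap_diameter")},
    )
    for name, kp in result.targets.items():
        mm = _report_mm(cal, kp)
        if mm is not None:
            result.targets_mm[name] = mm
    return result


# ---------------------------------------------------------------------------
# PCL (Johannsen, transtibial)
# ---------------------------------------------------------------------------


def plan_pcl(
    features: FeatureSet, bp: Optional[PlanBlueprint] = None, cal: Calibration = UNCALIBRATED
) -> PlanResult:
    """Locate the transtibial PCL insertion target and guidewire.

    Requires pixel-to-mm calibration: the insertion offset is a metric
    distance, so the plan refuses to run uncalibrated.
    """
    bp = bp or PlanBlueprint.default(Application.PCL)
    app = Application.PCL
    if not cal.is_calibrated:
        return _cancelled(app, "no-scale")
    ref_kp = _get_role(features, bp, "kp_reference")
    ref_line = _get_role(features, bp, "reference_line")
    for feat, name in ((ref_kp, "kp_reference"), (ref_line, "reference_line")):
        if isinstance(feat, NotDetected):
            return _cancelled(app, f"missing-feature:{name}")
    if not isinstance(ref_line, Polyline):
        return _cancelled(app, "reference_line-not-a-line")
    origin, direction = _tls_line(ref_line.points)
    # orient the fitted direction along the annotated polyline
    chord = ref_line.points[-1] - ref_line.points[0]
    if chord @ direction < 0:
        direction = -direction
    offset_px = cal.mm_to_px(bp.constants["offset_mm"])
    target = ref_kp.xy + offset_px * direction
    target_kp = Keypoint(x=float(target[0]), y=float(target[1]), label="pcl_insertion")
    wire_angle = bp.constants["wire_angle_deg"]
    a = math.radians(wire_angle)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    wire_dir = rot @ direction
    half = max(float(np.linalg.norm(chord)), 1.0)
    wire = Polyline(
        points=np.vstack([target - half * wire_dir, target + half * wire_dir]), label="guidewire"
    )
    result = PlanResult(
        application=app,
        status="ok",
        targets={"insertion": target_kp},
        wires={"guidewire": wire},
        intermediates={
            "reference_line": Polyline(
                points=np.vstack([origin - half * direction, origin + half * direction]),
                label="reference_extension",
            )
        },
        wire_angle_deg=normalize_orientation_deg(
            math.degrees(math.atan2(wire_dir[1], wire_dir[0]))
        ),
    )
    result.targets_mm["insertion"] = _report_mm(cal, target_kp)
    return result


# ---------------------------------------------------------------------------
# Dispatch and real-time re-execution
# ---------------------------------------------------------------------------

_PLANNERS = {
    Application.MPFL: plan_mpfl,
    Application.ACL_FEMUR: plan_acl_femur,
    Application.ACL_TIBIA: plan_acl_tibia,
    Application.PCL: plan_pcl,
}


def execute_plan(
    features: FeatureSet,
    bp: PlanBlueprint,
    edits: Optional[Mapping[str, object]] = None,
    cal: Calibration = UNCALIBRATED,
) -> PlanResult:
    """Re-run a blueprint with optional user edits.

    ``edits`` maps blueprint role names to replacement geometry. The call is
    a pure function of its inputs: identical inputs give identical results,
    and only construction steps downstream of an edited feature change.
    """
    edits = dict(edits or {})
    unknown = set(edits) - set(bp.roles)
    if unknown:
        raise KeyError(f"unknown blueprint roles in edits: {sorted(unknown)}")
    if edits:
        fs = FeatureSet(
            keypoints=dict(features.keypoints),
            lines=dict(features.lines),
            regions=dict(features.regions),
            missing=dict(features.missing),
            provenance=dict(features.provenance),
        )
        for role, geometry in edits.items():
            label = bp.roles[role]
            relabeled = _relabel(geometry, label)
            fs.missing.pop(label, None)
            fs.add(relabeled, provenance="user_edited")
        features = fs
    return _PLANNERS[bp.application](features, bp, cal)


def _relabel(feature, label: str):
    from dataclasses import replace as _replace

    if isinstance(feature, (Keypoint, Polyline)):
        return _replace(feature, label=label)
    if isinstance(feature, PolygonRegion):
        return PolygonRegion(shell=feature.shell, holes=feature.holes, label=label)
    raise TypeError(f"cannot use {type(feature).__name__} as an edit")
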