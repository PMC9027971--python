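"""Labelme-compatible annotation I/O.

One JSON dialect serves both manual ground truth and automatic predictions,
so evaluation and planning are agnostic to the feature source. Shapes map
as ``polygon`` <-> :class:`PolygonRegion`, ``point`` <-> :class:`Keypoint`
and ``linestrip`` <-> :class:`Polyline`.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .decoding import FeatureSet
from .geometry import Keypoint, PolygonRegion, Polyline

FORMAT_VERSION = "5.0.1"

#: Registry of admissible labels: bone structures, keypoints, lines.
REGISTRY_LABELS = frozenset(
    {"S1", "S2", "K1", "K2", "K3", "K4", "K5", "K6", "K7", "L1", "L2", "L3"}
)


class AnnotationError(ValueError):
    """Raised for malformed or out-of-registry annotation documents."""


def write_annotation(
    path,
    features: FeatureSet,
    image_path: str = "",
    image_size: tuple[int, int] = (256, 256),
) -> None:
    """Write a feature set as a labelme-style JSON document."""
    shapes = []
    for label in sorted(features.keypoints):
        kp = features.keypoints[label]
        shapes.append({"label": label, "shape_type": "point", "points": [[kp.x, kp.y]]})
    for label in sorted(features.lines):
        line = features.lines[label]
        shapes.append(
            {"label": label, "shape_type": "linestrip", "points": line.points.tolist()}
        )
    for label in sorted(features.regions):
        region = features.regions[label]
        shapes.append(
            {"label": label, "shape_type": "polygon", "points": region.shell.tolist()}
        )
    doc = {
        "version": FORMAT_VERSION,
        "imagePath": image_path,
        "imageHeight": image_size[0],
        "imageWidth": image_size[1],
        "shapes": shapes,
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=1, sort_keys=True)


def read_annotation(path, strict: bool = False) -> tuple[FeatureSet, tuple[int, int]]:
    """Read a labelme-style document into a feature set.

    Unknown labels warn in lenient mode and raise in ``strict`` mode.
    Returns the features and the recorded image size ``(H, W)``.
    """
    path = Path(path)
    try:
        with open(path) as f:
            doc = json.load(f)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed JSON in {path}: {exc}") from exc
    if "imageHeight" not in doc or "imageWidth" not in doc:
        raise AnnotationError(f"{path}: missing image size fields")
    size = (int(doc["imageHeight"]), int(doc["imageWidth"]))
    features = FeatureSet()
    for shape in doc.get("shapes", []):
        label = shape.get("label", "")
        if label not in REGISTRY_LABELS:
            if strict:
                raise AnnotationError(f"unknown label {label!r} in strict mode")
            warnings.warn(f"unknown annotation label {label!r}", stacklevel=2)
        stype = shape.get("shape_type")
        pts = np.asarray(shape.get("points", []), dtype=float)
        if stype == "point":
            features.add(Keypoint(x=float(pts[0, 0]), y=float(pts[0, 1]), label=label), "manual")
        elif stype == "linestrip":
            features.add(Polyline(points=pts, label=label), "manual")
        elif stype == "polygon":
            features.add(PolygonRegion(shell=pts, label=label), "manual")
        else:
            raise AnnotationError(f"unsupported shape type {stype!r}")
    return features, size
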