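"""Plan overlay rendering: layered SVG plus a flattened PNG.

Each construction step becomes its own SVG group (``<g id="...">``) so a
viewer can toggle intermediates individually; the PNG flattens the same
primitives onto the radiograph for quick inspection. Output is
deterministic for fixed inputs. Cancelled plans render a status banner and
no target marker.
"""

from __future__ import annotations

from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
from PIL import Image, ImageDraw

from .geometry import Keypoint, Polyline
from .planning import PlanResult

_COLORS = ["#00a0ff", "#ffa000", "#00c060", "#e040a0", "#a0a000", "#40c0c0"]
_TARGET_COLOR = "#ff2020"


def _svg_for_feature(feature, color: str) -> str:
    if isinstance(feature, Keypoint):
        return (
            f'<circle cx="{feature.x:.3f}" cy="{feature.y:.3f}" r="3" '
            f'fill="none" stroke="{color}" stroke-width="1.5"/>'
        )
    if isinstance(feature, Polyline):
        pts = " ".join(f"{x:.3f},{y:.3f}" for x, y in feature.points)
        tag = "polygon" if feature.closed else "polyline"
        return f'<{tag} points="{pts}" fill="none" stroke="{color}" stroke-width="1.5"/>'
    return ""


def render_plan_svg(plan: PlanResult, image_size: tuple[int, int]) -> str:
    h, w = image_size
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">'
    ]
    if plan.ok:
        for i, (name, feature) in enumerate(sorted(plan.intermediates.items())):
            color = _COLORS[i % len(_COLORS)]
            parts.append(f'<g id="step_{escape(name)}">{_svg_for_feature(feature, color)}</g>')
        for name, wire in sorted(plan.wires.items()):
            parts.append(f'<g id="wire_{escape(name)}">{_svg_for_feature(wire, _TARGET_COLOR)}</g>')
        for name, kp in sorted(plan.targets.items()):
            parts.append(
                f'<g id="target_{escape(name)}">'
                f'<circle cx="{kp.x:.3f}" cy="{kp.y:.3f}" r="2" fill="{_TARGET_COLOR}"/>'
                + (
                    f'<circle cx="{kp.x:.3f}" cy="{kp.y:.3f}" r="{plan.tolerance_radius_px:.3f}" '
                    f'fill="none" stroke="{_TARGET_COLOR}" stroke-dasharray="3,2"/>'
                    if plan.tolerance_radius_px
                    else ""
                )
                + "</g>"
            )
    else:
        parts.append(
            f'<g id="status_banner"><rect x="0" y="0" width="{w}" height="14" fill="#802020"/>'
            f'<text x="4" y="11" fill="#ffffff" font-size="10">'
            f"planning cancelled: {escape(plan.reason)}</text></g>"
        )
    parts.append("</svg>")
    return "".join(parts)


def write_plan_overlay(image: np.ndarray, plan: PlanResult, path) -> tuple[Path, Path]:
    """Write ``<path>.svg`` (layered) and ``<path>.png`` (flattened)."""
    path = Path(path)
    svg_path = path.with_suffix(".svg")
    png_path = path.with_suffix(".png")
    h, w = image.shape
    svg_path.write_text(render_plan_svg(plan, (h, w)))

    base = Image.fromarray((np.clip(image, 0, 1) * 255).round().astype(np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(base)
    if plan.ok:
        for i, (name, feature) in enumerate(sorted(plan.intermediates.items())):
            _draw_feature(draw, feature, _COLORS[i % len(_COLORS)])
        for wire in plan.wires.values():
            _draw_feature(draw, wire, _TARGET_COLOR)
        for kp in plan.targets.values():
            draw.ellipse([kp.x - 2, kp.y - 2, kp.x + 2, kp.y + 2], outline=_TARGET_COLOR, width=2)
            if plan.tolerance_radius_px:
                r = plan.tolerance_radius_px
                draw.ellipse([kp.x - r, kp.y - r, kp.x + r, kp.y + r], outline=_TARGET_COLOR)
    else:
        draw.rectangle([0, 0, w, 14], fill="#802020")
        draw.text((4, 2), f"cancelled: {plan.reason}", fill="#ffffff")
    base.save(png_path)
    return svg_path, png_path


def _draw_feature(draw: ImageDraw.ImageDraw, feature, color: str) -> None:
    if isinstance(feature, Keypoint):
        draw.ellipse([feature.x - 3, feature.y - 3, feature.x + 3, feature.y + 3], outline=color)
    elif isinstance(feature, Polyline):
        pts = [tuple(p) for p in feature.points]
        if feature.closed:
            pts.append(pts[0])
        draw.line(pts, fill=color, width=1)
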