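"""Rotated-box geometry and annotation file I/O.

A stoma is annotated by the tight rotated rectangle around its guard-cell
pair.  The universal geometry record is :class:`RotatedBox`: center ``(cx,
cy)`` in 0-based pixel coordinates (x rightward, y downward), the long-axis
``length``, the short-axis ``width``, and ``angle_deg`` — the angle from the
+x axis to the long axis, counter-clockwise in the (x, y) frame, reduced
modulo 180 because a rectangle is symmetric under a half turn.

Annotations are stored in a small JSON dialect::

    {"image_id": str, "width": int, "height": int,
     "pixel_scale_um_per_px": float,
     "stomata": [{"cx": f, "cy": f, "length": f, "width": f,
                  "angle_deg": f}, ...]}

Unknown keys are ignored on read; boxes with swapped sides are canonicalized
on load.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np


class AnnotationError(ValueError):
    """Malformed annotation record or file."""


@dataclass(frozen=True)
class RotatedBox:
    """Oriented rectangle: long axis ``length``, short axis ``width``.

    Invariants (enforced): ``length >= width > 0``, ``0 <= angle_deg < 180``,
    finite center.  Use :func:`canonicalize` to build a box from unordered
    side lengths or an out-of-range angle.
    """

    cx: float
    cy: float
    length: float
    width: float
    angle_deg: float

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "length", "width", "angle_deg"):
            if not math.isfinite(getattr(self, name)):
                raise AnnotationError(f"non-finite field {name!r} in {self}")
        if not self.width > 0:
            raise AnnotationError(f"non-positive width in {self}")
        if self.length < self.width:
            raise AnnotationError(
                f"length < width in {self}; use canonicalize() to fix side order"
            )
        if not 0.0 <= self.angle_deg < 180.0:
            raise AnnotationError(
                f"angle_deg {self.angle_deg} outside [0, 180) in {self}"
            )

    @property
    def area(self) -> float:
        return self.length * self.width


def canonicalize(cx: float, cy: float, a_side: float, b_side: float,
                 angle_deg: float) -> RotatedBox:
    """Build a canonical :class:`RotatedBox` from unordered sides.

    ``a_side`` is the extent along ``angle_deg``, ``b_side`` across it.  If
    ``b_side`` is the longer one the sides are swapped and the angle rotated
    by 90°; the angle is then reduced modulo 180 into [0, 180).
    """
    if not (a_side > 0 and b_side > 0):
        raise AnnotationError(
            f"sides must be positive, got ({a_side}, {b_side})"
        )
    if b_side > a_side:
        a_side, b_side = b_side, a_side
        angle_deg += 90.0
    angle_deg %= 180.0
    if angle_deg == 180.0:  # -1e-14 % 180 can land on 180.0
        angle_deg = 0.0
    return RotatedBox(cx, cy, a_side, b_side, angle_deg)


def corners(box: RotatedBox) -> np.ndarray:
    """Vertices of the rotated rectangle, shape (4, 2), in (x, y).

    Ordered counter-clockwise in the (x, y) frame (visually clockwise when y
    points down).  At angle 0 the corners are ``(cx ± length/2, cy ± width/2)``.
    """
    t = math.radians(box.angle_deg)
    u = np.array([math.cos(t), math.sin(t)])       # long-axis direction
    v = np.array([-math.sin(t), math.cos(t)])      # short-axis direction
    c = np.array([box.cx, box.cy])
    hl, hw = box.length / 2.0, box.width / 2.0
    return np.array([
        c - u * hl - v * hw,
        c + u * hl - v * hw,
        c + u * hl + v * hw,
        c - u * hl + v * hw,
    ])


def box_from_points(points: np.ndarray) -> RotatedBox:
    """Minimum-area rotated rectangle around a point set, as a canonical box.

    Thin wrapper over shapely's rotating-calipers fit; used for refitting
    rendered ellipses and for the corners→box round-trip property.
    """
    from shapely import MultiPoint
    from shapely.geometry import Polygon

    hull = MultiPoint([tuple(p) for p in np.asarray(points, float)]).convex_hull
    rect = hull.minimum_rotated_rectangle
    if not isinstance(rect, Polygon):  # degenerate (collinear) input
        raise AnnotationError("point set is degenerate, no area to fit")
    xy = np.asarray(rect.exterior.coords)[:4]
    c = xy.mean(axis=0)
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    a, b = np.hypot(*e1), np.hypot(*e2)
    angle = math.degrees(math.atan2(*(e1[::-1] if a >= b else e2[::-1])))
    return canonicalize(c[0], c[1], max(a, b), min(a, b), angle)


@dataclass
class AnnotationSet:
    """All rotated-box labels for one image plus its geometry metadata."""

    image_id: str
    image_width_px: int
    image_height_px: int
    pixel_scale: float  # micrometres per pixel
    boxes: list[RotatedBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise AnnotationError(
                f"non-positive image dimensions in {self.image_id!r}"
            )
        if not self.pixel_scale > 0:
            raise AnnotationError(f"pixel_scale must be > 0 in {self.image_id!r}")


_MANDATORY = ("image_id", "width", "height", "pixel_scale_um_per_px", "stomata")
_BOX_KEYS = ("cx", "cy", "length", "width", "angle_deg")


def write_annotations(ann: AnnotationSet, path: str | os.PathLike) -> None:
    """Serialize an :class:`AnnotationSet` to the JSON dialect (6 dp)."""
    payload = {
        "image_id": ann.image_id,
        "width": int(ann.image_width_px),
        "height": int(ann.image_height_px),
        "pixel_scale_um_per_px": round(float(ann.pixel_scale), 6),
        "stomata": [
            {k: round(float(getattr(b, bk)), 6)
             for k, bk in zip(_BOX_KEYS, _BOX_KEYS)}
            for b in ann.boxes
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_annotations(path: str | os.PathLike) -> AnnotationSet:
    """Parse the JSON dialect; canonicalizes each box, ignores unknown keys."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed JSON in {path}: {exc}") from exc
    for key in _MANDATORY:
        if key not in payload:
            raise AnnotationError(f"missing mandatory key {key!r} in {path}")
    boxes = []
    for i, rec in enumerate(payload["stomata"]):
        missing = [k for k in _BOX_KEYS if k not in rec]
        if missing:
            raise AnnotationError(
                f"stoma record {i} in {path} missing keys {missing}"
            )
        try:
            boxes.append(canonicalize(rec["cx"], rec["cy"], rec["length"],
                                      rec["width"], rec["angle_deg"]))
        except AnnotationError as exc:
            raise AnnotationError(
                f"invalid stoma record {i} in {path}: {exc}"
            ) from exc
    return AnnotationSet(
        image_id=str(payload["image_id"]),
        image_width_px=int(payload["width"]),
        image_height_px=int(payload["height"]),
        pixel_scale=float(payload["pixel_scale_um_per_px"]),
        boxes=boxes,
    )
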