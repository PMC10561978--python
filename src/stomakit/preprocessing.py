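"""Image preprocessing and label-aware augmentation.

Covers the steps applied to raw epidermis micrographs before training:

* ``pad_border`` — a black border so stomata touching the frame edge can be
  enclosed by a full rotated box (default 30 px);
* ``gray_stretch`` — linear contrast stretch mapping an input gray band
  (default 210–255, the band nail-polish imprints occupy) onto a target band
  (default the full 0–255 range), maximizing stoma/background contrast;
* ``rotate_augment`` — rotation about the image center with an expanded
  canvas, transforming every box with the same rotation;
* ``visibility_fraction`` — exact polygon-clipped fraction of a box inside
  the frame.  A box is a valid label iff the fraction exceeds 2/3.

All functions take 8-bit grayscale arrays (H×W) and lists of
:class:`~stomakit.annotations.RotatedBox`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box as shapely_box

from .annotations import RotatedBox, canonicalize, corners

#: a box is kept as a training label iff visibility_fraction > this
VISIBILITY_RULE = 2.0 / 3.0


@dataclass(frozen=True)
class StretchParams:
    """Input gray band mapped onto the output band by ``gray_stretch``."""

    lo: int = 210
    hi: int = 255

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi <= 255:
            raise ValueError(f"need 0 <= lo < hi <= 255, got ({self.lo}, {self.hi})")


def gray_stretch(image: np.ndarray, params: StretchParams = StretchParams(),
                 out_range: tuple[int, int] = (0, 255)) -> np.ndarray:
    """Linear gray-level stretch of ``[lo, hi]`` onto ``out_range``.

    ``g' = round(out_lo + (out_hi - out_lo) * clip((g - lo)/(hi - lo), 0, 1))``.
    Monotone non-decreasing in g; with the defaults, 210 maps to 0 and 255
    to 255.  ``out_range=(210, 255)`` gives the compressive reading instead.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("gray_stretch expects an 8-bit grayscale image")
    out_lo, out_hi = out_range
    frac = np.clip((image.astype(np.float64) - params.lo) / (params.hi - params.lo),
                   0.0, 1.0)
    return np.rint(out_lo + (out_hi - out_lo) * frac).astype(np.uint8)


def pad_border(image: np.ndarray, boxes: list[RotatedBox],
               border_px: int = 30) -> tuple[np.ndarray, list[RotatedBox]]:
    """Add a black border of ``border_px`` on every side; shift box centers."""
    if border_px < 0:
        raise ValueError("border_px must be >= 0")
    if border_px == 0:
        return image, list(boxes)
    padded = np.pad(image, border_px, mode="constant", constant_values=0)
    shifted = [RotatedBox(b.cx + border_px, b.cy + border_px,
                          b.length, b.width, b.angle_deg) for b in boxes]
    return padded, shifted


def visibility_fraction(box: RotatedBox, frame_w: float, frame_h: float) -> float:
    """area(box ∩ frame) / area(box) by exact convex polygon clipping."""
    poly = Polygon(corners(box))
    frame = shapely_box(0.0, 0.0, float(frame_w), float(frame_h))
    return poly.intersection(frame).area / poly.area


def center_crop(image: np.ndarray, boxes: list[RotatedBox], target_w: int,
                target_h: int, visibility_threshold: float = VISIBILITY_RULE,
                ) -> tuple[np.ndarray, list[RotatedBox]]:
    """Crop the central ``target_w``×``target_h`` window; shift boxes and
    re-apply the visibility rule on the cropped frame."""
    h, w = image.shape
    if target_w > w or target_h > h:
        raise ValueError("crop larger than image")
    x0 = (w - target_w) // 2
    y0 = (h - target_h) // 2
    cropped = image[y0:y0 + target_h, x0:x0 + target_w]
    kept = []
    for b in boxes:
        cand = RotatedBox(b.cx - x0, b.cy - y0, b.length, b.width, b.angle_deg)
        if visibility_fraction(cand, target_w, target_h) > visibility_threshold:
            kept.append(cand)
    return cropped, kept


def augment_dataset(data_dir, angles: tuple[float, ...] = (30.0, 45.0, 90.0),
                    crop_to_original: bool = True) -> dict:
    """Expand a generated dataset's training split with rotated copies.

    For every training image, writes one rotated copy per angle (image +
    annotation JSON with the image_id suffixed ``_rotNN``) and appends the
    new entries to the manifest.  Rotations expand the canvas; with
    ``crop_to_original`` the result is cropped back to the source frame so
    all images share one size (boxes failing the visibility rule on the
    crop are dropped).  The validation split is left untouched.  Calling
    this on an already-augmented dataset is a no-op.
    """
    import json
    import os

    import imageio.v3 as iio

    from .annotations import AnnotationSet, read_annotations, write_annotations

    data_dir = os.fspath(data_dir)
    manifest_path = os.path.join(data_dir, "manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("augmented"):
        return manifest

    new_entries = []
    for entry in manifest["images"]:
        if entry["split"] != "train":
            continue
        image = iio.imread(os.path.join(data_dir, entry["image"]))
        ann = read_annotations(os.path.join(data_dir, entry["annotations"]))
        for angle in angles:
            rotated, boxes = rotate_augment(image, ann.boxes, angle)
            if crop_to_original:
                rotated, boxes = center_crop(rotated, boxes,
                                             ann.image_width_px,
                                             ann.image_height_px)
            stem = entry["image"].rsplit(".", 1)[0] + f"_rot{int(angle):02d}"
            iio.imwrite(os.path.join(data_dir, stem + ".png"), rotated)
            write_annotations(
                AnnotationSet(stem, rotated.shape[1], rotated.shape[0],
                              ann.pixel_scale, boxes),
                os.path.join(data_dir, stem + ".json"))
            new_entries.append({"image": stem + ".png",
                                "annotations": stem + ".json",
                                "seed": entry["seed"], "split": "train"})
    manifest["images"].extend(new_entries)
    manifest["n_train"] += len(new_entries)
    manifest["augmented"] = True
    manifest["augment_angles"] = list(angles)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    return np.array([[math.cos(t), -math.sin(t)],
                     [math.sin(t), math.cos(t)]])


def rotate_augment(image: np.ndarray, boxes: list[RotatedBox], angle_deg: float,
                   visibility_threshold: float = VISIBILITY_RULE,
                   ) -> tuple[np.ndarray, list[RotatedBox]]:
    """Rotate image and labels by ``angle_deg`` about the image center.

    The canvas is expanded to contain the whole rotated frame (fill 0), so
    no content is cropped away.  Box centers follow the same rotation, box
    angles advance by ``angle_deg`` modulo 180, and boxes whose visible area
    fraction on the new canvas drops to ``visibility_threshold`` or below
    are removed.  The default angles used for dataset expansion are 30°,
    45° and 90°, but any angle is accepted.
    """
    image = np.asarray(image)
    h, w = image.shape
    t = math.radians(angle_deg)
    new_w = int(math.ceil(round(abs(w * math.cos(t)) + abs(h * math.sin(t)), 6)))
    new_h = int(math.ceil(round(abs(w * math.sin(t)) + abs(h * math.cos(t)), 6)))

    rot = _rotation_matrix(angle_deg)
    c_in = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    c_out = np.array([(new_w - 1) / 2.0, (new_h - 1) / 2.0])

    # ndimage maps output index (y, x) -> input index; invert the forward map
    # p_out = R (p_in - c_in) + c_out.
    inv_xy = rot.T
    inv_yx = inv_xy[::-1, ::-1]
    offset_xy = c_in - inv_xy @ c_out
    rotated = ndimage.affine_transform(
        image.astype(np.float32), inv_yx, offset=offset_xy[::-1],
        output_shape=(new_h, new_w), order=1, mode="constant", cval=0.0)
    rotated = np.clip(np.rint(rotated), 0, 255).astype(np.uint8)

    kept: list[RotatedBox] = []
    for b in boxes:
        cx, cy = rot @ (np.array([b.cx, b.cy]) - c_in) + c_out
        cand = canonicalize(float(cx), float(cy), b.length, b.width,
                            b.angle_deg + angle_deg)
        if visibility_fraction(cand, new_w, new_h) > visibility_threshold:
            kept.append(cand)
    return rotated, kept
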