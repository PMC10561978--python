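"""Decode head outputs into detections and physical stomatal traits.

Decoding follows the keypoint-heatmap recipe: cells that equal their 3×3
neighbourhood maximum are peak candidates (this replaces IoU-based NMS),
the best ``top_k = 100`` are kept, and each surviving peak is turned into a
rotated box from the size/offset/angle heads at that cell.

Traits follow from the boxes and the imaged area: lengths and widths in
micrometres, stomatal density SD in mm⁻², and the anatomical maximum
stomatal conductance to water vapour

    g_smax = d · SD · α_max / ( v · (l + (π/2)·√(α_max/π)) ),

with α_max = π·SL²/4 the maximum pore area estimated from stomatal length
SL, l the pore depth (taken equal to the guard-cell width), d the
diffusivity of water vapour in air and v the molar volume of air.  Note
(π/2)·√(α_max/π) = (π/4)·SL.  Defaults d = 24.9×10⁻⁶ m² s⁻¹ and
v = 22.4×10⁻³ m³ mol⁻¹ hold at 25 °C and 101.3 kPa.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import RotatedBox, canonicalize
from .network import HeadOutputs


@dataclass(frozen=True)
class ConductanceParams:
    """Physical constants of the conductance model (SI units)."""

    d: float = 24.9e-6   # diffusivity of water vapour in air, m² s⁻¹
    v: float = 22.4e-3   # molar volume of air, m³ mol⁻¹

    def __post_init__(self) -> None:
        if not (self.d > 0 and self.v > 0):
            raise ValueError("d and v must be positive")


@dataclass(frozen=True)
class Detection:
    """A decoded rotated box plus its keypoint confidence."""

    box: RotatedBox
    score: float

    def __post_init__(self) -> None:
        if not 0.0 < self.score < 1.0:
            raise ValueError(f"score must lie in (0, 1), got {self.score}")


@dataclass
class TraitRecord:
    """Per-image stomatal traits; reported values rounded to 2 decimals."""

    image_id: str
    lengths_um: list[float]
    widths_um: list[float]
    count: int
    density_per_mm2: float
    gsmax_mol_m2_s: float


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals (the reporting convention)."""
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5) / 100.0, x)


# -- peak extraction and box decoding ---------------------------------------


def extract_peaks(heatmap: np.ndarray, top_k: int = 100,
                  score_threshold: float = 0.0) -> list[tuple[tuple[int, int], float]]:
    """Local maxima of the heatmap by 3×3 max-pool comparison.

    A cell survives iff its value equals the maximum over its 3×3
    neighbourhood (plateau ties all survive).  Survivors are ordered by
    descending score (row-major index breaks ties), truncated to ``top_k``
    and filtered by ``score_threshold``.  Returns ``[((x, y), score), ...]``.
    """
    hm = np.asarray(heatmap, dtype=np.float64)
    if hm.ndim != 2:
        raise ValueError("extract_peaks expects a 2-D heatmap")
    pooled = ndimage.maximum_filter(hm, size=3, mode="constant", cval=-np.inf)
    ys, xs = np.nonzero(hm >= pooled)
    scores = hm[ys, xs]
    order = np.lexsort((ys * hm.shape[1] + xs, -scores))[:top_k]
    return [((int(xs[i]), int(ys[i])), float(scores[i]))
            for i in order if scores[i] >= score_threshold]


def decode_detections(heads: HeadOutputs, stride: int | None = None,
                      top_k: int = 100,
                      score_threshold: float = 0.3) -> list[Detection]:
    """Turn head outputs for one image into rotated-box detections.

    For each surviving peak at grid cell (x̂, ŷ): center = ((x̂+δx)·R,
    (ŷ+δy)·R) with (δx, δy) from the offset head, box sides from the size
    head ×R, angle from the angle head; the box is canonicalized.  No
    IoU-based NMS is applied — the 3×3 peak rule is the whole suppression.
    """
    r = heads.stride if stride is None else stride
    heat = np.asarray(heads.heatmap.data)[0, 0]
    size = np.asarray(heads.size.data)[0]
    offset = np.asarray(heads.offset.data)[0]
    angle = np.asarray(heads.angle.data)[0, 0]
    detections = []
    for (x, y), score in extract_peaks(heat, top_k, score_threshold):
        cx = (x + float(offset[0, y, x])) * r
        cy = (y + float(offset[1, y, x])) * r
        a_side = max(float(size[0, y, x]) * r, 1e-3)
        b_side = max(float(size[1, y, x]) * r, 1e-3)
        box = canonicalize(cx, cy, a_side, b_side, float(angle[y, x]))
        detections.append(Detection(box, min(score, 1.0 - 1e-9)))
    return detections


# -- trait computation ------------------------------------------------------


def stomatal_density(count: int, image_w_px: float, image_h_px: float,
                     pixel_scale: float) -> float:
    """Stomata per mm² of imaged area (border padding must be excluded)."""
    area_mm2 = image_w_px * image_h_px * pixel_scale ** 2 * 1e-6
    if area_mm2 <= 0:
        raise ValueError("imaged area must be positive")
    return count / area_mm2


def alpha_max(sl_um: float) -> float:
    """Maximum pore area π·SL²/4 (µm²) from stomatal length SL (µm)."""
    if sl_um < 0:
        raise ValueError("stomatal length must be >= 0")
    return math.pi * float(sl_um) ** 2 / 4.0


def gsmax_formula(sl_um, l_um, sd_per_mm2,
                  params: ConductanceParams = ConductanceParams()):
    """The conductance closed form on any arithmetic type (floats, arrays,
    autodiff tensors).  Inputs in µm / mm⁻²; output in mol m⁻² s⁻¹.

    Uses (π/2)·√(α_max/π) = (π/4)·SL, so the expression is smooth in SL.
    """
    quarter_pi = math.pi / 4.0
    alpha_m2 = quarter_pi * sl_um * sl_um * 1e-12
    depth_m = (l_um + quarter_pi * sl_um) * 1e-6
    return params.d * (sd_per_mm2 * 1e6) * alpha_m2 / (params.v * depth_m)


def gsmax(sl_um: float, l_um: float, sd_per_mm2: float,
          params: ConductanceParams = ConductanceParams()) -> float:
    """Anatomical maximum stomatal conductance (mol m⁻² s⁻¹).

    ``SL = l = 0`` is the defined limit 0 (no pore, no conductance), not an
    error; any negative input is rejected.
    """
    if sl_um < 0 or l_um < 0 or sd_per_mm2 < 0:
        raise ValueError("conductance inputs must be non-negative")
    if sl_um == 0.0:
        return 0.0
    return float(gsmax_formula(sl_um, l_um, sd_per_mm2, params))


def measure_image(detections: list[Detection], image_w_px: float,
                  image_h_px: float, pixel_scale: float,
                  params: ConductanceParams = ConductanceParams(),
                  image_id: str = "image") -> TraitRecord:
    """Aggregate detections of one (un-padded) image into a trait record.

    g_smax uses the per-image MEAN length and MEAN width (as pore depth)
    together with the image's detection density — one conductance value per
    image, matching how measured trait tables report it.  Reported density
    and conductance are rounded half-away-from-zero to 2 decimals.
    """
    lengths = [det.box.length * pixel_scale for det in detections]
    widths = [det.box.width * pixel_scale for det in detections]
    count = len(detections)
    density = stomatal_density(count, image_w_px, image_h_px, pixel_scale)
    g = gsmax(float(np.mean(lengths)), float(np.mean(widths)), density,
              params) if count else 0.0
    return TraitRecord(image_id, lengths, widths, count,
                       round2(density), round2(g))


def write_traits_csv(records: list[TraitRecord], path: str | os.PathLike) -> None:
    """Trait table CSV: image_id, avg_length_um, avg_width_um, count,
    density_per_mm2, gsmax."""
    with open(path, "w") as fh:
        fh.write("image_id,avg_length_um,avg_width_um,count,"
                 "density_per_mm2,gsmax\n")
        for r in records:
            avg_l = round2(float(np.mean(r.lengths_um))) if r.count else 0.0
            avg_w = round2(float(np.mean(r.widths_um))) if r.count else 0.0
            fh.write(f"{r.image_id},{avg_l},{avg_w},{r.count},"
                     f"{r.density_per_mm2},{r.gsmax_mol_m2_s}\n")


# -- detection I/O (same JSON dialect as annotations, plus "score") ---------


def write_detections(detections: list[Detection], image_id: str,
                     image_w_px: int, image_h_px: int, pixel_scale: float,
                     path: str | os.PathLike) -> None:
    payload = {
        "image_id": image_id,
        "width": int(image_w_px),
        "height": int(image_h_px),
        "pixel_scale_um_per_px": round(float(pixel_scale), 6),
        "stomata": [
            {"cx": round(d.box.cx, 6), "cy": round(d.box.cy, 6),
             "length": round(d.box.length, 6), "width": round(d.box.width, 6),
             "angle_deg": round(d.box.angle_deg, 6),
             "score": round(float(d.score), 6)}
            for d in detections
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_detections(path: str | os.PathLike) -> list[Detection]:
    from .annotations import read_annotations
    ann = read_annotations(path)
    with open(path) as fh:
        payload = json.load(fh)
    scores = [rec.get("score", 0.5) for rec in payload["stomata"]]
    return [Detection(box, float(s)) for box, s in zip(ann.boxes, scores)]
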