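"""Ground-truth target encoding and the five training losses.

Each annotated box becomes a keypoint at output-grid cell
``floor(center/R)`` with a Gaussian bump splatted around it (σ from the
standard min-overlap-0.7 radius rule, radius floored at one cell, the
center cell set to exactly 1); sub-cell offsets, grid-unit sizes, angles
and a per-stoma conductance value are stored per instance.

The losses:

* heatmap — penalty-reduced focal loss: positives (q=1) contribute
  ``−(1−p)^α·log p``; negatives ``−(1−q)^β·p^α·log(1−p)``, the Gaussian
  bump (1−q)^β softening the penalty near true centers; sum normalized by
  the number of keypoints (≥ 1);
* offset / size / angle — mean absolute error at the ground-truth center
  cells only (the angle loss optionally wraps |Δθ| modulo 180°);
* conductance — mean absolute difference between the conductance computed
  from the predicted sizes and from the true boxes, both evaluated at the
  image's ground-truth density, keeping the term differentiable and focused
  on trait-size error;
* total — the plain (optionally re-weighted) sum of the five.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationSet
from .measure import ConductanceParams, gsmax_formula, stomatal_density
from .nn import Tensor, astensor

#: clamp for non-positive predicted sizes inside the conductance loss (µm)
_SIZE_EPS_UM = 1e-3

#: how many times the conductance loss had to clamp a non-positive size
clamp_warnings = 0


@dataclass
class HeadTargets:
    """Training targets for one image at output stride R."""

    heatmap_q: np.ndarray       # 1×Hg×Wg in [0, 1], exactly 1 at centers
    size: np.ndarray            # K×2 (length, width) in grid units
    offset: np.ndarray          # K×2 in [0, 1)
    angle: np.ndarray           # K degrees in [0, 180)
    centers: np.ndarray         # K×2 integer grid coords (x, y)
    gsmax: np.ndarray           # K per-stoma conductance, mol m⁻² s⁻¹
    density_per_mm2: float = 0.0


@dataclass(frozen=True)
class LossWeights:
    """Focal exponents and per-term weights (all 1 reproduces the plain sum)."""

    alpha: float = 2.0
    beta: float = 4.0
    heatmap: float = 1.0
    offset: float = 1.0
    size: float = 1.0
    angle: float = 1.0
    conductance: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("focal exponents must be positive")
        if min(self.heatmap, self.offset, self.size, self.angle,
               self.conductance) < 0:
            raise ValueError("loss weights must be >= 0")


def gaussian_radius(height: float, width: float,
                    min_overlap: float = 0.7) -> float:
    """Largest center shift keeping IoU ≥ ``min_overlap`` with an
    axis-aligned h×w box (the CornerNet radius rule, three quadratic cases)."""
    a1 = 1.0
    b1 = height + width
    c1 = width * height * (1 - min_overlap) / (1 + min_overlap)
    r1 = (b1 - math.sqrt(b1 ** 2 - 4 * a1 * c1)) / (2 * a1)

    a2 = 4.0
    b2 = 2 * (height + width)
    c2 = (1 - min_overlap) * width * height
    r2 = (b2 - math.sqrt(b2 ** 2 - 4 * a2 * c2)) / (2 * a2)

    a3 = 4.0 * min_overlap
    b3 = -2 * min_overlap * (height + width)
    c3 = (min_overlap - 1) * width * height
    r3 = (-b3 + math.sqrt(b3 ** 2 - 4 * a3 * c3)) / (2 * a3)
    return min(r1, r2, r3)


def _splat_gaussian(heatmap: np.ndarray, cx: int, cy: int, radius: int) -> None:
    sigma = (2 * radius + 1) / 6.0
    h, w = heatmap.shape
    y0, y1 = max(0, cy - radius), min(h, cy + radius + 1)
    x0, x1 = max(0, cx - radius), min(w, cx + radius + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    bump = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma ** 2))
    np.maximum(heatmap[y0:y1, x0:x1], bump, out=heatmap[y0:y1, x0:x1])


def encode_targets(annotations: AnnotationSet, stride: int = 4,
                   gsmax_params: ConductanceParams = ConductanceParams(),
                   ) -> HeadTargets:
    """Encode one image's boxes into head-aligned targets.

    Raises if any box center lies outside the image (such boxes must be
    filtered by the visibility rule beforehand).
    """
    w_img, h_img = annotations.image_width_px, annotations.image_height_px
    wg = math.ceil(w_img / stride)
    hg = math.ceil(h_img / stride)
    heat = np.zeros((hg, wg), dtype=np.float32)
    k = len(annotations.boxes)
    size = np.zeros((k, 2), dtype=np.float32)
    offset = np.zeros((k, 2), dtype=np.float32)
    angle = np.zeros(k, dtype=np.float32)
    centers = np.zeros((k, 2), dtype=np.int64)
    density = stomatal_density(k, w_img, h_img, annotations.pixel_scale)
    gs = np.zeros(k, dtype=np.float32)

    for i, b in enumerate(annotations.boxes):
        if not (0 <= b.cx < w_img and 0 <= b.cy < h_img):
            raise ValueError(
                f"box center ({b.cx}, {b.cy}) outside {w_img}×{h_img} image")
        gx, gy = b.cx / stride, b.cy / stride
        cx, cy = int(gx), int(gy)
        centers[i] = (cx, cy)
        offset[i] = (gx - cx, gy - cy)
        size[i] = (b.length / stride, b.width / stride)
        angle[i] = b.angle_deg
        ps = annotations.pixel_scale
        gs[i] = gsmax_formula(b.length * ps, b.width * ps, density,
                              gsmax_params)
        # the min-overlap radius rule degenerates (< 1 cell) for thin
        # elongated boxes; a 2-cell floor keeps the bump learnable at R=4
        radius = max(2, int(gaussian_radius(b.width / stride,
                                            b.length / stride)))
        _splat_gaussian(heat, cx, cy, radius)

    for cx, cy in centers:
        heat[cy, cx] = 1.0
    return HeadTargets(heat[None], size, offset, angle, centers, gs, density)


# -- losses -----------------------------------------------------------------


def heatmap_loss(p, q, alpha: float = 2.0, beta: float = 4.0,
                 n_norm: int | None = None) -> Tensor:
    """Penalty-reduced focal loss between predicted ``p`` and target ``q``.

    ``p`` must lie strictly inside (0, 1) (activate and clamp upstream);
    ``q`` in [0, 1] with exact 1 marking keypoints.  Normalized by the
    keypoint count (at least 1), not the pixel count.
    """
    p = astensor(p)
    q = np.asarray(q, dtype=np.float32)
    if p.data.min() <= 0.0 or p.data.max() >= 1.0:
        raise ValueError("heatmap predictions must lie strictly in (0, 1)")
    if q.min() < 0.0 or q.max() > 1.0:
        raise ValueError("heatmap targets must lie in [0, 1]")
    pos = (q == 1.0).astype(np.float32)
    neg = 1.0 - pos
    if n_norm is None:
        n_norm = max(1, int(pos.sum()))
    pos_term = ((1.0 - p) ** alpha * p.log() * pos).sum()
    neg_term = (np.power(1.0 - q, beta) * p ** alpha * (1.0 - p).log()
                * neg).sum()
    return -(pos_term + neg_term) * (1.0 / n_norm)


def _mae(pred, target) -> Tensor:
    pred = astensor(pred)
    target = np.asarray(target, dtype=np.float32)
    if pred.data.size == 0:
        return astensor(0.0)
    return (pred - target).abs().mean()


def offset_loss(pred_offsets, true_offsets) -> Tensor:
    """Mean |Δ| over the K instances and both components; 0 when K = 0."""
    return _mae(pred_offsets, true_offsets)


def size_loss(pred_sizes, true_sizes) -> Tensor:
    """Mean |Δ| of grid-unit (length, width) at ground-truth centers."""
    return _mae(pred_sizes, true_sizes)


def angle_loss(pred_angles, true_angles, wrap: bool = False) -> Tensor:
    """Mean |Δθ| in degrees; ``wrap=True`` uses min(|Δθ|, 180−|Δθ|).

    The literal (non-wrapped) form is the default; the wrapped form removes
    the 0°/180° label discontinuity.
    """
    pred = astensor(pred_angles)
    true = np.asarray(true_angles, dtype=np.float32)
    if pred.data.size == 0:
        return astensor(0.0)
    diff = (pred - true).abs()
    if wrap:
        need_wrap = (diff.data > 90.0).astype(np.float32)
        diff = diff * (1.0 - need_wrap) + (180.0 - diff) * need_wrap
    return diff.mean()


def conductance_loss(pred_sizes, true_sizes_um: np.ndarray,
                     image_density: float, pixel_scale: float,
                     stride: int = 4,
                     params: ConductanceParams = ConductanceParams()) -> Tensor:
    """Mean |Ĝ − G| between conductances from predicted and true sizes.

    ``pred_sizes`` are grid-unit (length, width) at the true center cells;
    ``true_sizes_um`` is the K×2 array of true (length, width) in µm.  Both
    conductances use the image's ground-truth density, so the term
    isolates the trait-size error and stays differentiable.  Non-positive
    predicted sizes are clamped to a small ε (counted in
    ``targets.clamp_warnings``).
    """
    global clamp_warnings
    pred = astensor(pred_sizes)
    true = np.asarray(true_sizes_um, dtype=np.float32)
    if pred.data.size == 0:
        return astensor(0.0)
    scale = pixel_scale * stride
    if np.any(pred.data * scale <= 0.0):
        clamp_warnings += int(np.sum(pred.data * scale <= 0.0))
    pred_um = (pred * scale).clip(_SIZE_EPS_UM, None)
    g_pred = gsmax_formula(pred_um[:, 0], pred_um[:, 1], image_density, params)
    g_true = gsmax_formula(true[:, 0], true[:, 1], image_density, params)
    return (g_pred - g_true).abs().mean()


def total_loss(components: dict[str, Tensor],
               weights: LossWeights = LossWeights(),
               ) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of the five terms plus a float breakdown for logging.

    Default unit weights give the plain sum
    ``L = LH + Loff + Lsize + Lang + Lcon``; a zero weight removes a term's
    gradient entirely (used for the conductance-loss ablation).
    """
    w = {"heatmap": weights.heatmap, "offset": weights.offset,
         "size": weights.size, "angle": weights.angle,
         "conductance": weights.conductance}
    total = astensor(0.0)
    breakdown = {}
    for name, term in components.items():
        term = astensor(term)
        breakdown[name] = float(term.data)
        total = total + w[name] * term
    breakdown["total"] = float(total.data)
    return total, breakdown
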