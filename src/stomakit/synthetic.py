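"""Synthetic epidermis micrographs with exact rotated-box ground truth.

Every downstream stage (target encoding, training, decoding, trait
measurement, evaluation) is exercised against images from this module, so
real microscope data is never required for testing.  A sample emulates a
nail-polish imprint of a maize upper epidermis viewed in bright field:

* elliptical stomata, long axis 30–47 µm, short axis 12–18 µm, uniformly
  random orientation — rendered as a dark guard-cell rim around a lighter
  pore slit, so the detector has a learnable signature;
* densities in the tens per mm² (the default frame of 1000×667 px at
  0.625 µm/px with 9–16 stomata gives 34.5–61.4 mm⁻²);
* a textured background (flat, smoothed gradient noise, or a periodic
  cell-grid pattern), additive Gaussian noise, and occasional circular
  bubble/droplet distractors that are rendered but never annotated — the
  classic false-positive source in imprint imagery.

The ground-truth box of a stoma is the tight rotated bounding box of its
rendered outer ellipse, so box length/width equal the sampled trait values
divided by the pixel scale, exactly.  Stomata whose box sticks out of the
frame are annotated only if more than two thirds of the box area is inside
(the same visibility rule the labeling protocol uses).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .annotations import (AnnotationSet, RotatedBox, canonicalize, corners,
                          write_annotations)
from .preprocessing import VISIBILITY_RULE, visibility_fraction

BACKGROUNDS = ("flat", "perlin", "cell-grid")


class PlacementError(RuntimeError):
    """Stomata could not be placed without exceeding the overlap budget."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the production-frame conditions.

    The default frame is 1000×667 px at 0.625 µm/px with 9–16 stomata per
    image; trait ranges follow measured maize values (length 30–47 µm,
    width 12–18 µm).  For fast desk-scale work use
    ``SynthConfig.test_scale()`` (256×256 px, 2–6 stomata).
    """

    image_width_px: int = 1000
    image_height_px: int = 667
    pixel_scale: float = 0.625          # µm per pixel
    n_stomata_range: tuple[int, int] = (9, 16)
    length_range_um: tuple[float, float] = (30.0, 47.0)
    width_range_um: tuple[float, float] = (12.0, 18.0)
    angle_range_deg: tuple[float, float] = (0.0, 180.0)
    background_texture: str = "perlin"
    noise_sd: float = 6.0               # gray levels
    distractor_rate: float = 1.0        # expected distractors per image
    seed: int = 0
    # free contrast parameters (the source imagery's intensity statistics
    # are not prescribed anywhere, so these are exposed):
    background_level: float = 190.0
    rim_level: float = 95.0
    pore_level: float = 235.0
    max_overlap_iou: float = 0.05
    max_place_retries: int = 100

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0")
        for name in ("n_stomata_range", "length_range_um", "width_range_um",
                     "angle_range_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is degenerate: ({lo}, {hi})")
        if self.background_texture not in BACKGROUNDS:
            raise ValueError(f"unknown background_texture "
                             f"{self.background_texture!r}; one of {BACKGROUNDS}")

    @staticmethod
    def test_scale(**overrides) -> "SynthConfig":
        """A 256×256 frame with 2–6 stomata, for desk-scale experiments.

        Orientations stay in [10°, 170°]: the literal (non-wrapped) angle
        loss has a seam at 0°/180°, and the desk-scale conditions keep the
        wrapped and literal losses in agreement.
        """
        base = dict(image_width_px=256, image_height_px=256,
                    n_stomata_range=(2, 6), distractor_rate=0.5,
                    angle_range_deg=(10.0, 170.0))
        base.update(overrides)
        return SynthConfig(**base)


@dataclass
class SynthSample:
    """One rendered image plus its exact ground truth."""

    image: np.ndarray                  # H×W uint8
    annotations: list[RotatedBox]
    pixel_scale: float
    seed_used: int

    def annotation_set(self, image_id: str = "synthetic") -> AnnotationSet:
        h, w = self.image.shape
        return AnnotationSet(image_id, w, h, self.pixel_scale,
                             list(self.annotations))


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_height_px, cfg.image_width_px
    base = np.full((h, w), cfg.background_level, dtype=np.float32)
    if cfg.background_texture == "perlin":
        # two octaves of smoothed gradient noise
        for sigma, amp in ((24.0, 14.0), (8.0, 6.0)):
            fieldn = ndimage.gaussian_filter(
                rng.standard_normal((h, w)).astype(np.float32), sigma)
            sd = fieldn.std()
            if sd > 0:
                base += amp * fieldn / sd
    elif cfg.background_texture == "cell-grid":
        # dark anticlinal-wall lines on a regular pavement-cell lattice
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
        period = 36.0 * 0.625 / cfg.pixel_scale  # ~36 px at default scale
        ph1, ph2 = rng.uniform(0, 2 * math.pi, size=2)
        wall_x = np.abs(np.sin(math.pi * xx / period + ph1)) < 0.10
        wall_y = np.abs(np.sin(math.pi * yy / period + ph2)) < 0.10
        base -= 30.0 * (wall_x | wall_y).astype(np.float32)
    return base


def _render_ellipse(canvas: np.ndarray, box: RotatedBox,
                    rim_level: float, pore_level: float) -> None:
    """Paint one stoma: dark outer ellipse (guard cells), light pore slit."""
    h, w = canvas.shape
    half = box.length / 2.0 + 2.0
    x0 = max(0, int(math.floor(box.cx - half)))
    x1 = min(w, int(math.ceil(box.cx + half)) + 1)
    y0 = max(0, int(math.floor(box.cy - half)))
    y1 = min(h, int(math.ceil(box.cy + half)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
    dx, dy = xx - box.cx, yy - box.cy
    t = math.radians(box.angle_deg)
    lon = dx * math.cos(t) + dy * math.sin(t)     # along long axis
    lat = -dx * math.sin(t) + dy * math.cos(t)    # across it
    a, b = box.length / 2.0, box.width / 2.0
    outer = (lon / a) ** 2 + (lat / b) ** 2 <= 1.0
    pore = (lon / (0.80 * a)) ** 2 + (lat / (0.28 * b)) ** 2 <= 1.0
    patch = canvas[y0:y1, x0:x1]
    patch[outer] = rim_level
    patch[pore] = pore_level


def _boxes_overlap(a: RotatedBox, b: RotatedBox, max_iou: float) -> bool:
    pa, pb = Polygon(corners(a)), Polygon(corners(b))
    inter = pa.intersection(pb).area
    if inter == 0.0:
        return False
    return inter / (pa.area + pb.area - inter) > max_iou


def generate_sample(config: SynthConfig, seed: int | None = None) -> SynthSample:
    """Render one image; deterministic for fixed ``(config, seed)``.

    Stomata centers are sampled uniformly inside the frame; a candidate is
    rejected if its box overlaps an accepted one beyond
    ``config.max_overlap_iou`` (rotated IoU).  After
    ``config.max_place_retries`` failed draws for a stoma a
    :class:`PlacementError` is raised.  Boxes passing the two-thirds
    visibility rule become annotations; all stomata are rendered regardless.
    """
    seed = config.seed if seed is None else int(seed)
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.Generator(np.random.PCG64(seed))
    w, h = config.image_width_px, config.image_height_px
    ps = config.pixel_scale

    canvas = _background(config, rng)

    n = int(rng.integers(config.n_stomata_range[0],
                         config.n_stomata_range[1] + 1))
    placed: list[RotatedBox] = []
    for _ in range(n):
        for attempt in range(config.max_place_retries + 1):
            length = rng.uniform(*config.length_range_um) / ps
            width = min(length, rng.uniform(*config.width_range_um) / ps)
            lo, hi = config.angle_range_deg
            angle = float(rng.uniform(lo, hi)) % 180.0
            cx = float(rng.uniform(0, w))
            cy = float(rng.uniform(0, h))
            cand = canonicalize(cx, cy, length, width, angle)
            if not any(_boxes_overlap(cand, p, config.max_overlap_iou)
                       for p in placed):
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place stoma {len(placed) + 1}/{n} within "
                f"{config.max_place_retries} retries"
            )

    for box in placed:
        _render_ellipse(canvas, box, config.rim_level, config.pore_level)

    n_distract = int(rng.poisson(config.distractor_rate))
    for _ in range(n_distract):
        r = float(rng.uniform(4.0, 11.0))
        for _ in range(config.max_place_retries):
            cx, cy = float(rng.uniform(0, w)), float(rng.uniform(0, h))
            bubble = canonicalize(cx, cy, 2 * r, 2 * r - 1e-6, 0.0)
            if not any(_boxes_overlap(bubble, p, 0.0) for p in placed):
                # bright disk with a darker ring, like a small air bubble
                _render_ellipse(canvas, canonicalize(cx, cy, 2 * r,
                                                     2 * r * 0.999, 0.0),
                                config.rim_level + 40.0,
                                config.background_level + 25.0)
                break

    canvas += rng.normal(0.0, config.noise_sd, size=canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    annotations = [b for b in placed
                   if visibility_fraction(b, w, h) > VISIBILITY_RULE]
    return SynthSample(image, annotations, ps, seed)


def _child_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(config: SynthConfig, n_images: int,
                     out_dir: str | os.PathLike, seed: int | None = None) -> dict:
    """Write ``n_images`` PNG/JSON pairs plus a manifest; returns the manifest.

    Per-image seeds are derived from ``seed`` through a seed sequence and
    recorded, so the dataset is exactly reproducible.  Images are split
    train:validation = 3:1 (train count = round(0.75·n)).
    """
    seed = config.seed if seed is None else int(seed)
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir!r}: {exc}") from exc

    n_train = int(round(n_images * 0.75))
    entries = []
    for i in range(n_images):
        child = _child_seed(seed, i)
        sample = generate_sample(config, child)
        stem = f"img_{i:04d}"
        img_path = os.path.join(out_dir, stem + ".png")
        ann_path = os.path.join(out_dir, stem + ".json")
        try:
            iio.imwrite(img_path, sample.image)
            write_annotations(sample.annotation_set(stem), ann_path)
        except OSError as exc:
            raise OSError(f"failed writing {img_path!r}: {exc}") from exc
        entries.append({
            "image": stem + ".png",
            "annotations": stem + ".json",
            "seed": child,
            "split": "train" if i < n_train else "val",
        })

    manifest = {
        "seed": seed,
        "pixel_scale_um_per_px": config.pixel_scale,
        "image_width_px": config.image_width_px,
        "image_height_px": config.image_height_px,
        "n_train": n_train,
        "n_val": n_images - n_train,
        "images": entries,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest
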