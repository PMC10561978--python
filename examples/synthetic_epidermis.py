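"""Generate a synthetic epidermis image with exact rotated-box ground truth.

Renders elliptical stomata (dark guard-cell rim, bright pore slit) at
random orientations on a textured background, plus unlabeled bubble
distractors, and prints the resulting annotation geometry and the
image-level traits implied by it.  The PNG and its annotation JSON land in
./example_out/.
"""

import os

import stomakit as sk

cfg = sk.SynthConfig.test_scale(n_stomata_range=(4, 6), seed=7)
sample = sk.generate_sample(cfg, seed=7)

print(f"image: {sample.image.shape[1]}x{sample.image.shape[0]} px at "
      f"{sample.pixel_scale} um/px")
print(f"stomata annotated: {len(sample.annotations)}")
for i, box in enumerate(sample.annotations):
    print(f"  #{i}: centre ({box.cx:6.1f},{box.cy:6.1f})  "
          f"length {box.length * cfg.pixel_scale:5.1f} um  "
          f"width {box.width * cfg.pixel_scale:5.1f} um  "
          f"angle {box.angle_deg:6.1f} deg")

density = sk.stomatal_density(len(sample.annotations), 256, 256, 0.625)
print(f"density: {density:.2f} per mm^2 "
      f"(each annotation is the tight rotated box of a rendered ellipse)")

os.makedirs("example_out", exist_ok=True)
import imageio.v3 as iio
iio.imwrite("example_out/epidermis.png", sample.image)
sk.write_annotations(sample.annotation_set("epidermis"),
                     "example_out/epidermis.json")
print("wrote example_out/epidermis.png and .json")
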