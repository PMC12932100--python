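"""Generate a small auto-labelled synthetic fluoroscopy dataset.

Builds three-channel conditioning masks (tissue / metallic device / lumen),
renders a procedural X-ray-like background, composes randomized device
instances into it with the target-contrast alpha blend, and writes
images + polygon labels + provenance to disk.
"""

from pathlib import Path

import numpy as np

import fluorosynth as fs
from fluorosynth.compositing import write_sample

out = Path("scratch/example_dataset")
n_samples = 5

for i in range(n_samples):
    seed = 100 * i
    mask3 = fs.make_mask_triple(256, 256, n_lumen_branches=2, n_devices=1, seed=seed)
    background = fs.render_background(mask3, seed=seed + 1)

    # a deformable liquid-device sprite from a random periodic spline
    contour = fs.generate_spline_contour(
        fs.SplineShapeParams(n=10, centre=(0, 0), l_min=8, l_max=14, seed=seed + 2)
    )
    sprite = fs.contour_to_sprite(contour, intensity=50, class_id=0)

    cfg = fs.RandomizationConfig(seed=seed + 3)  # rho in [0.5, 0.9], h = 24 px, ...
    noise = fs.NoiseSpec(gaussian_sigma=3.0, poisson_scale=2.0, pepper_fraction=0.001,
                         seed=seed + 4)
    sample = fs.compose_scene(background, mask3, [sprite], cfg, noise=noise)
    write_sample(sample, out, i)

    rhos = [round(inst["rho"], 3) for inst in sample.provenance["instances"]]
    print(f"sample {i}: {len(sample.labels)} labelled instance(s), contrast multipliers {rhos}")

print(f"\nwrote images/, labels/, provenance/ under {out}")
print("each label row is: class_id x1 y1 x2 y2 ... (coordinates normalized to [0,1]);")
print("rho < 1 darkens the device relative to the local background.")
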