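"""Segmentation and image-quality metrics on a synthetic scene.

Computes mAP50 / mAP50:95 for jittered detections against ground truth, then
Michelson contrast and the MAD-based noise sigma on rendered images.
"""

import numpy as np

import fluorosynth as fs

rng = np.random.default_rng(0)

# --- mAP on synthetic boxes/masks: GT squares vs 2-px-shifted detections ---
gts, dets = [], []
for k in range(6):
    x0, y0 = rng.integers(5, 80, 2)
    mask = np.zeros((128, 128), bool)
    mask[y0:y0 + 20, x0:x0 + 20] = True
    gts.append({"box": (x0, y0, x0 + 20, y0 + 20), "mask": mask})
    dx = 2  # constant localization error
    dmask = np.zeros((128, 128), bool)
    dmask[y0:y0 + 20, x0 + dx:x0 + 20 + dx] = True
    dets.append({"box": (x0 + dx, y0, x0 + 20 + dx, y0 + 20), "mask": dmask,
                 "confidence": float(rng.uniform(0.6, 0.95))})

report = fs.map_suite({0: dets}, {0: gts})
print(f"mAP50(B) {report.map50_b:.3f}   mAP50:95(B) {report.map5095_b:.3f}")
print(f"mAP50(M) {report.map50_m:.3f}   mAP50:95(M) {report.map5095_m:.3f}")
print("a 2-px shift on 20-px objects gives IoU 0.82: perfect at the 0.5")
print("threshold, failing the strictest of the ten 0.50..0.95 thresholds.\n")

# --- contrast and noise on a rendered scene ---
mask3 = fs.make_mask_triple(256, 256, n_lumen_branches=1, n_devices=1, seed=5)
img = fs.render_background(mask3, seed=6)
noisy = fs.inject_noise(img, fs.NoiseSpec(gaussian_sigma=8.0, seed=7))

regions = fs.RegionSpec(m_obj=mask3.device, m_back=mask3.tissue & ~mask3.device & ~mask3.lumen)
contrast = fs.michelson_contrast(noisy, regions)
sigma = fs.estimate_noise(noisy, ~mask3.tissue & ~mask3.device)
print(f"Michelson contrast (device vs tissue): {contrast:.3f}")
print(f"MAD noise estimate: {sigma:.2f} (true Gaussian sigma 8.0)")
print("negative contrast means the device is darker than the tissue, as")
print("expected under attenuation polarity; the MAD estimate is robust to")
print("the scene's structure-free background texture.")
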