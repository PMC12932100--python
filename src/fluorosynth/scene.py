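"""Procedural X-ray scene synthesis: conditioning masks, backgrounds, noise.

A scene is conditioned on three co-registered binary masks — soft tissue
(M_tissue), dense metallic device (M_device) and contrast-agent-filled lumen
(M_lumen) — and rendered as an 8-bit greyscale image whose region intensities
follow X-ray attenuation ordering (denser -> darker under the default
polarity).  The renderer is procedural: band-limited value-noise texture plus
per-region intensity offsets and Gaussian smoothing.  Imaging noise is
injected as Poisson photon resampling, additive Gaussian noise and pepper
corruption, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from ._image import as_u8, load_png, save_png
from .shapes import SplineShapeParams, generate_spline_contour

__all__ = [
    "MaskTriple",
    "NoiseSpec",
    "make_mask_triple",
    "render_background",
    "inject_noise",
    "save_mask_triple",
    "load_mask_triple",
]

MIN_SCENE_SIZE = 64


@dataclass
class MaskTriple:
    """The three-channel spatial conditioning of a synthetic scene."""

    tissue: np.ndarray
    device: np.ndarray
    lumen: np.ndarray

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue, dtype=bool)
        self.device = np.asarray(self.device, dtype=bool)
        self.lumen = np.asarray(self.lumen, dtype=bool)
        if not (self.tissue.shape == self.device.shape == self.lumen.shape):
            raise ValueError("the three masks must share identical dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue.shape


@dataclass(frozen=True)
class NoiseSpec:
    """Imaging-noise parameters.

    gaussian_sigma : additive zero-mean Gaussian std in intensity units (>= 0)
    poisson_scale : photons per intensity unit; larger -> less relative noise;
        None or 0 disables Poisson resampling
    pepper_fraction : fraction of pixels forced to 0, in [0, 1]
    seed : RNG seed

    An all-disabled spec (sigma 0, poisson None/0, pepper 0) is the identity.
    """

    gaussian_sigma: float = 0.0
    poisson_scale: float | None = None
    pepper_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.poisson_scale is not None and self.poisson_scale < 0:
            raise ValueError("poisson_scale must be > 0 or disabled (None/0)")
        if not 0.0 <= self.pepper_fraction <= 1.0:
            raise ValueError("pepper_fraction must be in [0, 1]")

    @property
    def disabled(self) -> bool:
        return (
            self.gaussian_sigma == 0
            and not self.poisson_scale
            and self.pepper_fraction == 0
        )


def _blob_mask(shape: tuple[int, int], centre, l_min, l_max, rng_seed: int) -> np.ndarray:
    """Filled random spline blob used for the tissue region."""
    params = SplineShapeParams(
        n=10, centre=centre, l_min=l_min, l_max=l_max, n_interp=200, seed=rng_seed
    )
    contour = generate_spline_contour(params)
    rr, cc = skdraw.polygon(contour.points[:, 1], contour.points[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _thick_polyline(shape, pts, thickness) -> np.ndarray:
    """Rasterize a polyline with a disc structuring element of given radius."""
    mask = np.zeros(shape, dtype=bool)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = skdraw.line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    r = max(1, int(round(thickness / 2)))
    return ndimage.binary_dilation(mask, structure=_disc(r))


def _disc(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return xx**2 + yy**2 <= radius**2


def make_mask_triple(
    width: int,
    height: int,
    n_lumen_branches: int = 2,
    n_devices: int = 1,
    seed: int = 0,
) -> MaskTriple:
    """Build a random but reproducible conditioning-mask triple.

    M_tissue is one simply-connected spline blob roughly centred in the frame;
    M_lumen is a union of thick random polyline channels constrained inside
    M_tissue; M_device is a union of simple bars/discs placed anywhere.
    """
    if width < MIN_SCENE_SIZE or height < MIN_SCENE_SIZE:
        raise ValueError(f"scene dimensions must be >= {MIN_SCENE_SIZE} px, got {width}x{height}")
    if n_lumen_branches < 0 or n_devices < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (height, width)
    cx = width / 2 + rng.uniform(-0.05, 0.05) * width
    cy = height / 2 + rng.uniform(-0.05, 0.05) * height
    l_max = 0.45 * min(width, height)
    tissue = _blob_mask(shape, (cx, cy), 0.6 * l_max, l_max, int(rng.integers(2**31)))
    tissue = ndimage.binary_fill_holes(tissue)

    lumen = np.zeros(shape, dtype=bool)
    inside = np.argwhere(tissue)
    for _ in range(n_lumen_branches):
        if inside.size == 0:
            break
        # random walk between points inside the tissue blob
        idx = rng.integers(len(inside), size=4)
        pts = [(inside[i][1], inside[i][0]) for i in idx]
        thickness = rng.uniform(0.02, 0.05) * min(width, height)
        lumen |= _thick_polyline(shape, pts, thickness)
    lumen &= tissue  # anatomical containment: lumens live inside tissue

    device = np.zeros(shape, dtype=bool)
    for _ in range(n_devices):
        kind = rng.integers(2)
        x = rng.uniform(0.1, 0.9) * width
        y = rng.uniform(0.1, 0.9) * height
        if kind == 0:  # bar
            length = rng.uniform(0.15, 0.4) * min(width, height)
            ang = rng.uniform(0, np.pi)
            p0 = (x - length / 2 * np.cos(ang), y - length / 2 * np.sin(ang))
            p1 = (x + length / 2 * np.cos(ang), y + length / 2 * np.sin(ang))
            device |= _thick_polyline(shape, [p0, p1], rng.uniform(0.02, 0.06) * min(width, height))
        else:  # disc
            rr, cc = skdraw.disk((y, x), rng.uniform(0.03, 0.08) * min(width, height), shape=shape)
            device[rr, cc] = True
    return MaskTriple(tissue=tissue, device=device, lumen=lumen)


def _value_noise(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited texture in [-1, 1]: upsampled smoothed white noise."""
    coarse_shape = (max(2, int(shape[0] / scale)), max(2, int(shape[1] / scale)))
    coarse = rng.standard_normal(coarse_shape)
    zoom = (shape[0] / coarse_shape[0], shape[1] / coarse_shape[1])
    tex = ndimage.zoom(coarse, zoom, order=3)[: shape[0], : shape[1]]
    pad = ((0, shape[0] - tex.shape[0]), (0, shape[1] - tex.shape[1]))
    tex = np.pad(tex, pad, mode="edge")
    peak = np.abs(tex).max()
    return tex / peak if peak > 0 else tex


def render_background(
    mask: MaskTriple,
    polarity: str = "attenuation",
    texture_scale: float = 24.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a procedural greyscale scene honouring the mask conditioning.

    Under the default ``attenuation`` polarity denser structures attenuate
    more: device darkest, lumen (contrast agent) darker than tissue, tissue
    darker than free background.  ``display-inverted`` flips the image, giving
    the clinical bright-metal convention.
    """
    if polarity not in ("attenuation", "display-inverted"):
        raise ValueError(f"unknown polarity {polarity!r}")
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    img = np.full((h, w), 225.0)
    img += 12.0 * _value_noise((h, w), texture_scale * 2, rng)
    tissue_only = mask.tissue
    img[tissue_only] = 165.0
    img += np.where(tissue_only, 18.0 * _value_noise((h, w), texture_scale, rng), 0.0)
    img[mask.lumen] = np.minimum(img[mask.lumen], 110.0) + 6.0 * _value_noise((h, w), texture_scale, rng)[mask.lumen]
    img[mask.device] = 40.0 + 5.0 * _value_noise((h, w), texture_scale / 2, rng)[mask.device]
    img = ndimage.gaussian_filter(img, sigma=1.2)
    # re-impose device darkness after smoothing so thin devices stay distinct
    img[mask.device] = np.minimum(img[mask.device], 55.0)
    img = np.clip(img, 0, 255)
    if polarity == "display-inverted":
        img = 255.0 - img
    return as_u8(img)


def inject_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply Poisson -> Gaussian -> pepper noise; clip to [0, 255].

    Poisson resampling treats each pixel as a scaled photon count:
    v' = Poisson(v * scale) / scale.  A fully disabled spec returns the input
    bit-exactly.
    """
    img = as_u8(image)
    if spec.disabled:
        return img.copy()
    rng = np.random.default_rng(spec.seed)
    out = img.astype(np.float64)
    if spec.poisson_scale:
        out = rng.poisson(out * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sigma > 0:
        out = out + rng.normal(0.0, spec.gaussian_sigma, size=out.shape)
    out = np.clip(out, 0, 255)
    if spec.pepper_fraction > 0:
        pepper = rng.random(out.shape) < spec.pepper_fraction
        out[pepper] = 0.0
    return as_u8(out)


def save_mask_triple(mask: MaskTriple, path: str | Path) -> None:
    """Persist as a 3-channel PNG, channel order (tissue, device, lumen), 0/255."""
    rgb = np.stack(
        [np.where(m, 255, 0) for m in (mask.tissue, mask.device, mask.lumen)], axis=-1
    ).astype(np.uint8)
    save_png(rgb, path)


def load_mask_triple(path: str | Path) -> MaskTriple:
    rgb = load_png(path)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("mask triple PNG must have 3 channels")
    return MaskTriple(tissue=rgb[..., 0] > 127, device=rgb[..., 1] > 127, lumen=rgb[..., 2] > 127)
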