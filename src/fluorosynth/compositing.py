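"""Sprite-into-background integration with automatic instance labels.

Each placed device instance receives a random contrast multiplier rho; the
per-pixel target value is v_t = clip(rho * v_b, v_min, v_max).  A single
scalar blending coefficient alpha is computed over the instance mask and the
composite is v = alpha * v_b + (1 - alpha) * v_r inside the mask, leaving all
other pixels untouched.  Occlusion is modelled by placing instances beneath
the metallic-device mask: occluded pixels keep the original device rendering
and the emitted polygon traces only the visible region.  Because sprite masks
are known exactly, labels are pixel-accurate and require no manual
annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from ._image import as_u8
from .scene import MaskTriple, NoiseSpec, inject_noise
from .shapes import Sprite, rasterize_polygon, trace_mask_polygon

__all__ = [
    "RandomizationConfig",
    "InstanceLabel",
    "CompositeSample",
    "sample_target_values",
    "transform_sprite",
    "blend",
    "compose_scene",
]


@dataclass(frozen=True)
class RandomizationConfig:
    """Domain-randomization ranges for scene composition.

    rho_low, rho_high : contrast multiplier bounds (rho < 1 darkens)
    v_min, v_max : clip bounds of the target value, in [0, 255]
    target_height : nominal sprite height h after rescaling, pixels
    height_jitter : fractional height perturbation (uniform in +/- jitter)
    rotation_range : max absolute rotation in degrees
    count_range : (lo, hi) inclusive bounds on instances per scene
    occlusion_probability : chance an instance is placed beneath M_device
    min_visible_fraction : instances less visible than this emit no label
    """

    rho_low: float = 0.5
    rho_high: float = 0.9
    v_min: int = 10
    v_max: int = 245
    target_height: int = 24
    height_jitter: float = 0.2
    rotation_range: float = 180.0
    count_range: tuple[int, int] = (1, 3)
    occlusion_probability: float = 0.3
    min_visible_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho_low > self.rho_high:
            raise ValueError("rho_low must be <= rho_high")
        if not (0 <= self.v_min < self.v_max <= 255):
            raise ValueError("require 0 <= v_min < v_max <= 255")
        if not (0 < self.min_visible_fraction <= 1):
            raise ValueError("min_visible_fraction must be in (0, 1]")
        if not (0 <= self.occlusion_probability <= 1):
            raise ValueError("occlusion_probability must be in [0, 1]")
        if self.count_range[0] < 0 or self.count_range[0] > self.count_range[1]:
            raise ValueError("invalid count_range")


@dataclass
class InstanceLabel:
    """One labelled instance: class id + polygon normalized to [0, 1]."""

    class_id: int
    polygon: np.ndarray  # (N, 2) normalized (x, y)

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if self.polygon.min() < -1e-9 or self.polygon.max() > 1 + 1e-9:
            raise ValueError("normalized coordinates must lie in [0, 1]")

    def to_pixels(self, width: int, height: int) -> np.ndarray:
        return self.polygon * np.array([width, height], dtype=float)


@dataclass
class CompositeSample:
    """A rendered scene with pixel-accurate labels and generation provenance."""

    image: np.ndarray
    labels: list[InstanceLabel]
    visible_masks: list[np.ndarray] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def sample_rho(cfg: RandomizationConfig, rng: np.random.Generator) -> float:
    return float(rng.uniform(cfg.rho_low, cfg.rho_high))


def sample_target_values(
    v_b: np.ndarray, cfg: RandomizationConfig, rng: np.random.Generator | int = 0,
    rho: float | None = None,
) -> tuple[np.ndarray, float]:
    """Target map v_t = clip(rho * v_b, v_min, v_max); one rho per instance.

    Returns the target map (float) and the multiplier used.
    """
    if rho is None:
        rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        rho = sample_rho(cfg, rng)
    v_t = np.clip(rho * np.asarray(v_b, dtype=float), cfg.v_min, cfg.v_max)
    return v_t, rho


def transform_sprite(
    sprite: Sprite, cfg: RandomizationConfig, rng: np.random.Generator | int = 0
) -> tuple[Sprite, dict]:
    """Rescale to the jittered target height and rotate patch + mask together.

    The mask is resampled nearest-neighbour (stays binary); the patch
    bilinearly.  Returns the transformed sprite and the drawn parameters.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    jitter = float(rng.uniform(-cfg.height_jitter, cfg.height_jitter))
    angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    target_h = cfg.target_height * (1.0 + jitter)
    scale = target_h / sprite.native_height
    out_shape = (
        max(1, int(round(sprite.patch.shape[0] * scale))),
        max(1, int(round(sprite.patch.shape[1] * scale))),
    )
    patch = sktransform.resize(sprite.patch.astype(float), out_shape, order=1,
                               anti_aliasing=scale < 1, preserve_range=True)
    mask = sktransform.resize(sprite.mask.astype(float), out_shape, order=0,
                              anti_aliasing=False, preserve_range=True) > 0.5
    if abs(angle) > 1e-9:
        patch = sktransform.rotate(patch, angle, resize=True, order=1,
                                   preserve_range=True, mode="constant", cval=0.0)
        mask = sktransform.rotate(mask.astype(float), angle, resize=True, order=0,
                                  preserve_range=True, mode="constant", cval=0.0) > 0.5
    if mask.sum() < 3:
        raise ValueError("transform collapsed the sprite mask below 3 px")
    out = Sprite(patch=as_u8(np.clip(patch, 0, 255)), mask=mask,
                 class_id=sprite.class_id, native_height=sprite.native_height)
    return out, {"jitter": jitter, "angle": angle, "scale": scale}


def blend(
    background: np.ndarray,
    sprite: Sprite,
    position: tuple[int, int],
    cfg: RandomizationConfig | None = None,
    rho: float | None = None,
    v_t: np.ndarray | None = None,
    mode: str = "corrected",
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Alpha-blend one sprite into the background at ``position`` (x, y centre).

    A single scalar alpha is computed from sums over the mask region and
    clipped to [0, 1]; blending is per-pixel inside the mask only.  The
    default ``corrected`` mode uses alpha = sum(v_t - v_r) / sum(v_b - v_r),
    under which the blended region's mean hits the target mean (v_t = v_r
    gives the raw sprite, v_t = v_b an invisible instance).  Mode
    ``verbatim`` evaluates alpha = sum(v_t - v_b) / sum(v_b - v_r) exactly as
    printed in the source formulation, for auditability.

    Returns (new image, instance mask in frame coordinates, info dict).
    """
    if mode not in ("corrected", "verbatim"):
        raise ValueError(f"unknown blend mode {mode!r}")
    bg = as_u8(background).astype(np.float64)
    h, w = bg.shape
    mh, mw = sprite.mask.shape
    cx, cy = position
    # interpret position as the mask's bounding-box centre, then clamp so the
    # sprite canvas lies fully inside the frame
    rows = np.flatnonzero(sprite.mask.any(axis=1))
    cols = np.flatnonzero(sprite.mask.any(axis=0))
    bb_cy = (rows[0] + rows[-1] + 1) / 2
    bb_cx = (cols[0] + cols[-1] + 1) / 2
    x0 = int(np.clip(round(cx - bb_cx), 0, max(0, w - mw)))
    y0 = int(np.clip(round(cy - bb_cy), 0, max(0, h - mh)))
    if mw > w or mh > h:
        raise ValueError("sprite larger than frame")
    region = (slice(y0, y0 + mh), slice(x0, x0 + mw))
    m = sprite.mask
    v_b = bg[region][m]
    v_r = sprite.patch.astype(np.float64)[m]
    if cfg is None and v_t is None:
        raise ValueError("either cfg or an explicit target map is required")
    if v_t is None:
        v_t_map, rho = sample_target_values(v_b, cfg, rho=rho if rho is not None else None,
                                            rng=np.random.default_rng(0))
    else:
        v_t_map = np.asarray(v_t, dtype=float)
        if v_t_map.shape != v_b.shape:
            v_t_map = np.broadcast_to(v_t_map, v_b.shape)
    denom = np.sum(v_b - v_r)
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("degenerate contrast: sum(v_b - v_r) = 0 over the mask")
    if mode == "corrected":
        alpha = float(np.sum(v_t_map - v_r) / denom)
    else:
        alpha = float(np.sum(v_t_map - v_b) / denom)
    alpha = float(np.clip(alpha, 0.0, 1.0))
    out = bg.copy()
    sub = out[region]
    sub[m] = alpha * v_b + (1.0 - alpha) * v_r
    out[region] = sub
    frame_mask = np.zeros((h, w), dtype=bool)
    frame_mask[region] = m
    info = {"alpha": alpha, "rho": rho, "origin": (x0, y0)}
    return as_u8(np.clip(out, 0, 255)), frame_mask, info


def _sample_position(
    mask3: MaskTriple, rng: np.random.Generator, occluded: bool
) -> tuple[int, int] | None:
    """Draw a placement centre: beneath M_device when occluding, else biased
    into the lumen (falling back to tissue, then anywhere)."""
    for region in ((mask3.device,) if occluded else ()) + (mask3.lumen, mask3.tissue):
        idx = np.argwhere(region)
        if len(idx):
            y, x = idx[rng.integers(len(idx))]
            return int(x), int(y)
    h, w = mask3.shape
    return int(rng.integers(w)), int(rng.integers(h))


def compose_scene(
    background: np.ndarray,
    mask3: MaskTriple,
    sprites: list[Sprite],
    cfg: RandomizationConfig,
    noise: NoiseSpec | None = None,
    count: int | None = None,
    max_attempts: int = 25,
    blend_mode: str = "corrected",
) -> CompositeSample:
    """Compose a full scene: place, transform and blend randomized instances,
    model occlusion beneath M_device, emit visible-region labels, then inject
    imaging noise.

    All randomness flows from ``cfg.seed``.  Instances whose visible fraction
    falls below ``cfg.min_visible_fraction`` are rendered but unlabelled.
    When the visible region is split by the occluder, the largest connected
    component defines both the stored mask and the polygon.
    """
    if not sprites:
        raise ValueError("at least one sprite is required")
    rng = np.random.default_rng(cfg.seed)
    img = as_u8(background)
    h, w = img.shape
    if count is None:
        count = int(rng.integers(cfg.count_range[0], cfg.count_range[1] + 1))
    original = img.copy()
    labels: list[InstanceLabel] = []
    visible_masks: list[np.ndarray] = []
    instances = []
    for i in range(count):
        sprite = sprites[int(rng.integers(len(sprites)))]
        occluded = bool(rng.random() < cfg.occlusion_probability) and bool(mask3.device.any())
        placed = False
        for _ in range(max_attempts):
            try:
                tsprite, tinfo = transform_sprite(sprite, cfg, rng)
            except ValueError:
                continue
            pos = _sample_position(mask3, rng, occluded)
            rho = sample_rho(cfg, rng)
            try:
                img, inst_mask, binfo = blend(
                    img, tsprite, pos, cfg=cfg, rho=rho, mode=blend_mode
                )
            except (ZeroDivisionError, ValueError):
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"no valid placement for instance {i} after {max_attempts} attempts "
                f"(frame {w}x{h}, sprite {sprite.mask.shape})"
            )
        if occluded:
            # device sits above the instance: occluded pixels revert to the
            # original rendering (which contains the device)
            covered = inst_mask & mask3.device
            img = img.copy()
            img[covered] = original[covered]
            visible = inst_mask & ~mask3.device
        else:
            visible = inst_mask
        frac = visible.sum() / inst_mask.sum()
        inst = {
            "class_id": tsprite.class_id,
            "position": pos,
            "rho": rho,
            "alpha": binfo["alpha"],
            "occluded": occluded,
            "visible_fraction": float(frac),
            **tinfo,
        }
        instances.append(inst)
        if frac >= cfg.min_visible_fraction and visible.sum() >= 3:
            stored = _largest_component(visible)
            poly_px = trace_mask_polygon(stored)
            poly_norm = np.clip(poly_px / np.array([w, h], dtype=float), 0.0, 1.0)
            labels.append(InstanceLabel(class_id=tsprite.class_id, polygon=poly_norm))
            visible_masks.append(stored)
    if noise is not None:
        img = inject_noise(img, noise)
    provenance = {"seed": cfg.seed, "count": count, "instances": instances,
                  "blend_mode": blend_mode,
                  "noise": None if noise is None else vars(noise).copy()}
    return CompositeSample(image=img, labels=labels, visible_masks=visible_masks,
                          provenance=provenance)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage as _ndi

    labels, n = _ndi.label(mask)
    if n <= 1:
        return mask.copy()
    sizes = _ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def write_sample(sample: CompositeSample, out_dir: str | Path, index: int) -> None:
    """Write one sample in the dataset layout images/NNNN.png + labels/NNNN.txt
    + provenance/NNNN.json."""
    from ._image import save_png
    from .dataset import write_labels

    out = Path(out_dir)
    stem = f"{index:04d}"
    save_png(sample.image, out / "images" / f"{stem}.png")
    write_labels(sample.labels, out / "labels" / f"{stem}.txt")
    prov_path = out / "provenance" / f"{stem}.json"
    prov_path.parent.mkdir(parents=True, exist_ok=True)
    prov_path.write_text(json.dumps(sample.provenance, default=_json_default, indent=1))


def _json_default(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
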