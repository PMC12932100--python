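"""Deformable device contours and sprite extraction.

Liquid (ferrofluid-like) device silhouettes are synthesized as closed periodic
B-spline curves through randomly perturbed points on a circle: ``n`` angular
sectors are sampled uniformly within their sector, radii uniformly within
``[l_min, l_max]``, and a periodic interpolating (smoothing-free, ``s = 0``)
cubic spline is fit through the closed point sequence and resampled at
``N_interp`` uniform parameter values.

Soft (stent-like) device sprites are extracted from clean-background captures
by automatic thresholding, largest-component selection, orientation
standardization (major axis rotated to horizontal) and tight cropping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import interpolate, ndimage
from shapely.geometry import LineString
from skimage import draw as skdraw
from skimage import measure, transform
from skimage.filters import threshold_otsu

from ._image import as_u8, load_png, save_png

__all__ = [
    "SplineShapeParams",
    "Contour",
    "Sprite",
    "generate_spline_contour",
    "contour_to_sprite",
    "extract_sprite",
    "trace_mask_polygon",
    "save_sprite",
    "load_sprite",
]


@dataclass(frozen=True)
class SplineShapeParams:
    """Parameters of the random closed-spline silhouette generator.

    n : number of control points (>= 4, periodic cubic interpolation)
    centre : (c_x, c_y) in pixels
    l_min, l_max : radial sampling bounds in pixels, 0 < l_min <= l_max
    n_interp : number of resampled contour points (>= n)
    seed : RNG seed; the generator is bit-reproducible per seed
    """

    n: int = 10
    centre: tuple[float, float] = (0.0, 0.0)
    l_min: float = 20.0
    l_max: float = 40.0
    n_interp: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"need at least 4 control points, got n={self.n}")
        if not (0 < self.l_min <= self.l_max):
            raise ValueError(f"require 0 < l_min <= l_max, got [{self.l_min}, {self.l_max}]")
        if self.n_interp < self.n:
            raise ValueError("n_interp must be >= n")


@dataclass
class Contour:
    """A sampled planar curve.

    ``points`` is an (N, 2) array of (x, y) vertices.  For closed contours the
    first and last vertex coincide.  Spline-generated contours additionally
    carry the fitted spline representation (``tck``), the parameter values of
    the control points (``control_params``) and the control points themselves,
    so that the interpolation property can be checked by direct evaluation.
    """

    points: np.ndarray
    closed: bool = True
    control_points: np.ndarray | None = None
    control_params: np.ndarray | None = None
    tck: object | None = None
    provenance: dict = field(default_factory=dict)

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Evaluate the underlying spline at parameter values ``u`` (if fitted)."""
        if self.tck is None:
            raise ValueError("contour carries no spline representation")
        x, y = interpolate.splev(np.asarray(u, dtype=float), self.tck)
        return np.column_stack([x, y])

    def is_simple(self) -> bool:
        """True if the sampled polygon does not self-intersect."""
        return bool(LineString(self.points).is_simple)


@dataclass
class Sprite:
    """A device appearance patch plus its binary mask.

    patch : 2-D uint8 image of the device on a (usually dark) canvas
    mask : boolean array, same shape; True inside the device
    class_id : integer category
    native_height : mask bounding-box height in pixels at capture scale
    """

    patch: np.ndarray
    mask: np.ndarray
    class_id: int = 0
    native_height: int = 0

    def __post_init__(self) -> None:
        self.patch = as_u8(self.patch)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.patch.shape != self.mask.shape:
            raise ValueError("patch and mask dimensions must be identical")
        if not self.mask.any():
            raise ValueError("sprite mask is empty")
        if self.native_height <= 0:
            rows = np.flatnonzero(self.mask.any(axis=1))
            self.native_height = int(rows[-1] - rows[0] + 1)


def _sample_control_points(params: SplineShapeParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n
    sectors = 2.0 * np.pi * np.arange(n) / n
    theta = rng.uniform(sectors, sectors + 2.0 * np.pi / n)
    r = rng.uniform(params.l_min, params.l_max, size=n)
    cx, cy = params.centre
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def generate_spline_contour(params: SplineShapeParams, max_retries: int = 10) -> Contour:
    """Generate a closed random silhouette as a periodic interpolating B-spline.

    Sector-wise angular sampling guarantees monotonically increasing angles
    (hence a star-shaped control polygon); the spline is cubic, periodic and
    interpolating (s = 0), and ``n_interp`` points are resampled at uniform
    parameter values u_k = k / (n_interp - 1).

    Self-intersecting resampled polygons (rare for star-shaped control points,
    but possible for extreme l_min/l_max ratios) are redrawn with an
    incremented seed; the redraw count is recorded in ``provenance``.
    """
    seed = params.seed
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        pts = _sample_control_points(params, rng)
        closed = np.vstack([pts, pts[:1]])
        if min(np.ptp(closed[:, 0]), np.ptp(closed[:, 1])) < 1e-9:
            continue  # degenerate (collinear/coincident) — redraw
        # periodic interpolating cubic spline through the closed sequence
        tck, u = interpolate.splprep([closed[:, 0], closed[:, 1]], s=0, per=1, k=3)
        u_new = np.linspace(0.0, 1.0, params.n_interp)
        x, y = interpolate.splev(u_new, tck)
        contour = Contour(
            points=np.column_stack([x, y]),
            closed=True,
            control_points=pts,
            control_params=np.asarray(u[:-1]),
            tck=tck,
            provenance={"seed": params.seed, "redraws": attempt},
        )
        if contour.is_simple():
            return contour
    raise RuntimeError(f"no simple contour found after {max_retries} redraws (seed={params.seed})")


def contour_to_sprite(
    contour: Contour,
    intensity: int = 60,
    canvas_margin: int = 2,
    class_id: int = 1,
    background: int = 0,
) -> Sprite:
    """Rasterize a closed simple contour into a sprite.

    The filled contour becomes the binary mask on a tight canvas plus
    ``canvas_margin`` pixels per side; the patch holds ``intensity`` inside the
    mask and ``background`` outside.
    """
    if not contour.closed:
        raise ValueError("contour must be closed")
    if not contour.is_simple():
        raise ValueError("self-intersecting contour: fill is ambiguous")
    pts = contour.points
    x0, y0 = np.floor(pts.min(axis=0))
    shifted = pts - [x0 - canvas_margin, y0 - canvas_margin]
    w = int(np.ceil(shifted[:, 0].max())) + 1 + canvas_margin
    h = int(np.ceil(shifted[:, 1].max())) + 1 + canvas_margin
    rr, cc = skdraw.polygon(shifted[:, 1], shifted[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("contour rasterized to an empty mask")
    patch = np.full((h, w), background, dtype=np.uint8)
    patch[mask] = np.uint8(intensity)
    return Sprite(patch=patch, mask=mask, class_id=class_id)


def extract_sprite(capture: np.ndarray, class_id: int = 0, min_area: int = 20) -> Sprite:
    """Extract a standardized sprite from a clean-background capture.

    Pipeline: Otsu threshold (device assumed darker than the near-uniform
    bright background) -> largest connected component by area (ties broken by
    first appearance in row-major order) -> rotation so the component's major
    axis is horizontal -> tight crop of blank borders.
    """
    img = as_u8(capture)
    if img.min() == img.max():
        raise ValueError("uniform capture: no component found")
    thr = threshold_otsu(img)
    fg = img <= thr  # inclusive: otsu returns the lower class value itself on bimodal integer images
    labels = measure.label(fg, connectivity=2)
    props = measure.regionprops(labels)
    props = [p for p in props if p.area >= min_area]
    if not props:
        raise ValueError(f"no component with area >= {min_area} px found")
    # max area; ties -> smallest label id == first in row-major scan order
    best = max(props, key=lambda p: (p.area, -p.label))
    comp = labels == best.label
    # regionprops orientation: angle between major axis and the row (y) axis;
    # near-isotropic components have no meaningful major axis — leave them be
    angle_deg = 0.0 if best.eccentricity < 0.1 else 90.0 - np.degrees(best.orientation)
    rot_img = transform.rotate(img.astype(float), angle_deg, resize=True, order=1,
                               center=None, mode="constant", cval=float(img.max()))
    rot_mask = transform.rotate(comp.astype(float), angle_deg, resize=True, order=0,
                                mode="constant", cval=0.0) > 0.5
    rows = np.flatnonzero(rot_mask.any(axis=1))
    cols = np.flatnonzero(rot_mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("component vanished during rotation")
    r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
    return Sprite(
        patch=as_u8(np.clip(rot_img[r0:r1, c0:c1], 0, 255)),
        mask=rot_mask[r0:r1, c0:c1],
        class_id=class_id,
    )


def mask_major_axis_angle(mask: np.ndarray) -> float:
    """Angle (degrees, in [-90, 90]) of the mask's major axis w.r.t. horizontal."""
    props = measure.regionprops(measure.label(mask.astype(int)))
    best = max(props, key=lambda p: p.area)
    ang = 90.0 - np.degrees(best.orientation)
    while ang > 90:
        ang -= 180
    while ang < -90:
        ang += 180
    return float(ang)


def trace_mask_polygon(mask: np.ndarray) -> np.ndarray:
    """Trace the boundary of a binary mask's largest component as an (N, 2)
    (x, y) polygon in pixel coordinates.

    Sub-pixel iso-contouring at level 0.5 keeps the rasterization round trip
    (polygon -> mask) accurate to IoU >= 0.99 for blob-like components.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    labels, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    rc = max(contours, key=len) - 1.0  # undo pad; (row, col)
    return rc[:, ::-1].copy()  # -> (x, y)


def rasterize_polygon(polygon_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill an (x, y) polygon into a boolean mask of the given (h, w) shape."""
    poly = np.asarray(polygon_xy, dtype=float)
    rr, cc = skdraw.polygon(poly[:, 1], poly[:, 0], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def save_sprite(sprite: Sprite, directory: str | Path, stem: str) -> None:
    """Persist a sprite as ``<stem>.png`` + ``<stem>_mask.png`` + ``<stem>.json``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_png(sprite.patch, d / f"{stem}.png")
    save_png(np.where(sprite.mask, 255, 0).astype(np.uint8), d / f"{stem}_mask.png")
    meta = {"class_id": sprite.class_id, "native_height": sprite.native_height}
    (d / f"{stem}.json").write_text(json.dumps(meta))


def load_sprite(directory: str | Path, stem: str) -> Sprite:
    d = Path(directory)
    meta = json.loads((d / f"{stem}.json").read_text())
    return Sprite(
        patch=load_png(d / f"{stem}.png"),
        mask=load_png(d / f"{stem}_mask.png") > 127,
        class_id=int(meta["class_id"]),
        native_height=int(meta["native_height"]),
    )
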