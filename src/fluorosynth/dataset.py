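"""Label I/O, patch tiling and dataset splitting.

Labels use the one-text-file-per-image polygon convention: each row is a
class index followed by 2n coordinates normalized to [0, 1] by image width
and height, space-separated at 6-decimal precision.  Frames are tiled into
overlapping patch grids (default 5 x 5, 25 patches) for patch-based
training and inference, and datasets split train:validation at 20:1 for
synthetic and 10:1 for real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .compositing import InstanceLabel

__all__ = [
    "PatchGrid",
    "write_labels",
    "read_labels",
    "tile_image",
    "split_dataset",
    "SPLIT_RATIOS",
]

SPLIT_RATIOS = {"synthetic": 20, "real": 10}  # train : validation


def write_labels(labels: list[InstanceLabel], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for lab in labels:
        coords = " ".join(f"{v:.6f}" for v in lab.polygon.ravel())
        rows.append(f"{lab.class_id} {coords}")
    path.write_text("\n".join(rows) + ("\n" if rows else ""))


def read_labels(path: str | Path) -> list[InstanceLabel]:
    """Parse a label file; malformed rows raise with the offending line number."""
    path = Path(path)
    labels: list[InstanceLabel] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        try:
            class_id = int(fields[0])
            coords = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
        if len(coords) % 2 != 0 or len(coords) < 6:
            raise ValueError(
                f"{path}:{lineno}: expected an even number (>= 6) of coordinates, got {len(coords)}"
            )
        poly = np.array(coords, dtype=float).reshape(-1, 2)
        if poly.min() < 0 or poly.max() > 1:
            raise ValueError(f"{path}:{lineno}: coordinate outside [0, 1]")
        labels.append(InstanceLabel(class_id=class_id, polygon=poly))
    return labels


@dataclass(frozen=True)
class PatchGrid:
    """An overlapping tiling of a frame.

    ``offsets`` are (x, y) top-left corners in frame coordinates; every frame
    pixel is covered by at least one patch and adjacent patches overlap by at
    least the configured minimum.
    """

    patch_width: int
    patch_height: int
    offsets: tuple[tuple[int, int], ...]
    stride_x: int
    stride_y: int

    def __len__(self) -> int:
        return len(self.offsets)

    def to_frame(self, patch_index: int, xy: np.ndarray) -> np.ndarray:
        """Lift patch-local (x, y) coordinates to frame coordinates."""
        ox, oy = self.offsets[patch_index]
        return np.asarray(xy, dtype=float) + np.array([ox, oy], dtype=float)


def _axis_layout(size: int, n: int, min_overlap: float) -> tuple[int, int, list[int]]:
    """Patch extent, stride and offsets covering ``size`` with n patches and
    pairwise overlap >= min_overlap * extent."""
    if n == 1:
        return size, size, [0]
    # (n-1)*stride + extent >= size with stride <= (1 - min_overlap) * extent;
    # integer rounding can shave the last pair's overlap below the minimum,
    # so grow the extent until every adjacent pair satisfies it
    extent = int(np.ceil(size / (1 + (n - 1) * (1 - min_overlap))))
    while extent <= size:
        stride = (size - extent) // (n - 1)
        offsets = [i * stride for i in range(n - 1)] + [size - extent]  # last clamped to edge
        gaps = np.diff(offsets)
        if gaps.size == 0 or extent - gaps.max() >= min_overlap * extent - 1e-9:
            return extent, stride, offsets
        extent += 1
    return size, size, [0] * n


def tile_image(
    image: np.ndarray,
    n_cols: int = 5,
    n_rows: int = 5,
    min_overlap_fraction: float = 0.1,
) -> tuple[PatchGrid, list[np.ndarray]]:
    """Subdivide a frame into an n_cols x n_rows grid of overlapping patches.

    Patch size and strides are computed so the union of patches covers every
    pixel and adjacent patches overlap by at least ``min_overlap_fraction`` of
    the patch extent; the last column/row is clamped to the frame edge.
    Returns the grid (with the mapping back to frame coordinates) and the
    patch arrays.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if n_cols < 1 or n_rows < 1:
        raise ValueError("grid must have at least one row and one column")
    if not 0 <= min_overlap_fraction < 1:
        raise ValueError("min_overlap_fraction must be in [0, 1)")
    if w < n_cols or h < n_rows:
        raise ValueError(f"frame {w}x{h} too small for a {n_cols}x{n_rows} grid")
    pw, sx, xs = _axis_layout(w, n_cols, min_overlap_fraction)
    ph, sy, ys = _axis_layout(h, n_rows, min_overlap_fraction)
    offsets = tuple((x, y) for y in ys for x in xs)
    grid = PatchGrid(patch_width=pw, patch_height=ph, offsets=offsets, stride_x=sx, stride_y=sy)
    patches = [img[y : y + ph, x : x + pw] for (x, y) in offsets]
    return grid, patches


def split_dataset(samples: list, kind: str = "synthetic", seed: int = 0) -> tuple[list, list]:
    """Deterministic shuffled train/validation split at the standard ratios
    (20:1 synthetic, 10:1 real)."""
    if kind not in SPLIT_RATIOS:
        raise ValueError(f"kind must be one of {sorted(SPLIT_RATIOS)}")
    ratio = SPLIT_RATIOS[kind]
    n = len(samples)
    if n < ratio + 1:
        raise ValueError(f"need at least {ratio + 1} samples for a {ratio}:1 split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = n // (ratio + 1)
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [s for i, s in enumerate(samples) if i in val_idx]
    return train, val


def write_manifest(out_dir: str | Path, train: list[str], val: list[str], meta: dict | None = None) -> None:
    manifest = {"train": train, "validation": val, **(meta or {})}
    path = Path(out_dir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=1))
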