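"""8-bit greyscale image helpers shared across modules.

Images are plain 2-D numpy uint8 arrays; coordinates are 0-based with
x = column index and y = row index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image as PILImage


def as_u8(arr: np.ndarray) -> np.ndarray:
    """Coerce to a 2-D uint8 array, validating range for float inputs."""
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D greyscale image, got shape {a.shape}")
    if a.dtype == np.uint8:
        return a
    if np.issubdtype(a.dtype, np.floating):
        if a.size and (np.nanmin(a) < -0.5 or np.nanmax(a) > 255.5):
            raise ValueError("float image values outside [0, 255]")
        return np.rint(a).clip(0, 255).astype(np.uint8)
    if a.size and (a.min() < 0 or a.max() > 255):
        raise ValueError("integer image values outside [0, 255]")
    return a.astype(np.uint8)


def save_png(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.ndim == 2:
        PILImage.fromarray(as_u8(arr), mode="L").save(path)
    elif arr.ndim == 3 and arr.shape[2] == 3:
        PILImage.fromarray(arr.astype(np.uint8), mode="RGB").save(path)
    else:
        raise ValueError(f"unsupported image shape {arr.shape}")


def load_png(path: str | Path) -> np.ndarray:
    with PILImage.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            return np.asarray(im.convert("RGB"))
        return np.asarray(im.convert("L"))
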