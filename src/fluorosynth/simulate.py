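"""Fully synthetic stress-test sequences and a mock detector.

``make_sequence`` renders a scripted device trajectory into a frame sequence
with per-frame ground-truth labels, optionally hiding the device beneath the
metallic-device mask during occlusion windows — emulating the low-contrast,
high-noise, severe-occlusion conditions a fluoroscopic tracker must survive.
``mock_detector`` wraps the ground truth in the detector interface with
controllable degradation (dropout, position jitter, uniform clutter), so the
full generate -> track -> evaluate loop runs without any trained network or
downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._image import as_u8
from .compositing import RandomizationConfig, blend, sample_rho
from .scene import MaskTriple, NoiseSpec, inject_noise
from .shapes import Sprite, trace_mask_polygon
from .tracking import Detection

__all__ = ["TrajectorySpec", "MockDetectorSpec", "make_sequence", "mock_detector", "SequenceData"]


@dataclass(frozen=True)
class TrajectorySpec:
    """A scripted waypoint path.

    waypoints : (x, y) vertices of the piecewise-linear path, pixels
    speed : pixels per frame along the path
    n_frames : number of frames to render
    occlusion_windows : list of [start, end] frame intervals (inclusive)
        during which the device is placed beneath M_device
    """

    waypoints: tuple = ((32.0, 64.0), (224.0, 64.0))
    speed: float = 2.0
    n_frames: int = 60
    occlusion_windows: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        for a, b in self.occlusion_windows:
            if not (0 <= a <= b < self.n_frames):
                raise ValueError(f"occlusion window [{a}, {b}] outside [0, {self.n_frames})")

    def positions(self) -> np.ndarray:
        """Interpolate the path at arc length speed * frame, shape (n_frames, 2)."""
        wp = np.asarray(self.waypoints, dtype=float)
        seg = np.diff(wp, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.r_[0.0, np.cumsum(seg_len)]
        s = np.minimum(np.arange(self.n_frames) * self.speed, cum[-1])
        out = np.empty((self.n_frames, 2))
        for k, sk in enumerate(s):
            i = int(np.clip(np.searchsorted(cum, sk, side="right") - 1, 0, len(seg_len) - 1))
            t = 0.0 if seg_len[i] == 0 else (sk - cum[i]) / seg_len[i]
            out[k] = wp[i] + t * seg[i]
        return out


@dataclass(frozen=True)
class MockDetectorSpec:
    """Degradation model of the ground-truth-driven mock detector.

    fn_rate : per-frame probability of dropping the true detection
    fp_rate : expected uniform clutter detections per frame (Poisson)
    position_jitter_sigma : Gaussian jitter of surviving detections, pixels
    confidence_range : [low, high] of reported confidences
    """

    fn_rate: float = 0.0
    fp_rate: float = 0.0
    position_jitter_sigma: float = 0.0
    confidence_range: tuple[float, float] = (0.6, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fn_rate <= 1:
            raise ValueError("fn_rate must be in [0, 1]")
        if self.fp_rate < 0 or self.position_jitter_sigma < 0:
            raise ValueError("fp_rate and jitter must be >= 0")
        lo, hi = self.confidence_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("confidence_range must be within [0, 1]")


@dataclass
class SequenceData:
    """A rendered sequence: frames, per-frame labels and the true path."""

    frames: list[np.ndarray]
    labels: list[list]  # per frame: list of InstanceLabel (possibly empty)
    true_positions: np.ndarray  # (n_frames, 2), NaN while fully occluded
    visible: np.ndarray  # bool per frame: any label emitted
    provenance: dict = field(default_factory=dict)


def _frame_occluded(idx: int, windows) -> bool:
    return any(a <= idx <= b for a, b in windows)


def make_sequence(
    background: np.ndarray,
    mask3: MaskTriple,
    sprite: Sprite,
    traj: TrajectorySpec,
    cfg: RandomizationConfig,
    noise: NoiseSpec | None = None,
) -> SequenceData:
    """Render a scripted single-device sequence with ground truth.

    The device follows the interpolated waypoint path at constant speed; the
    same contrast multiplier (drawn once from ``cfg``) is used on every frame
    so appearance is temporally coherent.  During occlusion windows pixels
    under M_device revert to the original rendering and frames whose visible
    fraction falls below ``cfg.min_visible_fraction`` carry no label.
    """
    from .compositing import InstanceLabel, _largest_component

    h, w = as_u8(background).shape
    path = traj.positions()
    if (path[:, 0] < 0).any() or (path[:, 0] > w - 1).any() or (path[:, 1] < 0).any() or (path[:, 1] > h - 1).any():
        raise ValueError("trajectory leaves the frame")
    rng = np.random.default_rng(cfg.seed)
    rho = sample_rho(cfg, rng)
    bg = as_u8(background)
    frames: list[np.ndarray] = []
    labels: list[list] = []
    visible_flags = np.zeros(traj.n_frames, dtype=bool)
    true_pos = path.copy()
    for idx in range(traj.n_frames):
        pos = (float(path[idx, 0]), float(path[idx, 1]))
        img, inst_mask, info = blend(bg, sprite, pos, cfg=cfg, rho=rho)
        occluded = _frame_occluded(idx, traj.occlusion_windows)
        if occluded and mask3.device.any():
            covered = inst_mask & mask3.device
            img = img.copy()
            img[covered] = bg[covered]
            vis = inst_mask & ~mask3.device
        else:
            vis = inst_mask
        frame_labels = []
        frac = vis.sum() / inst_mask.sum()
        if frac >= cfg.min_visible_fraction and vis.sum() >= 3:
            comp = _largest_component(vis)
            poly = np.clip(trace_mask_polygon(comp) / np.array([w, h]), 0.0, 1.0)
            frame_labels.append(InstanceLabel(class_id=sprite.class_id, polygon=poly))
            visible_flags[idx] = True
        if noise is not None:
            per_frame = NoiseSpec(
                gaussian_sigma=noise.gaussian_sigma,
                poisson_scale=noise.poisson_scale,
                pepper_fraction=noise.pepper_fraction,
                seed=noise.seed + idx,
            )
            img = inject_noise(img, per_frame)
        frames.append(img)
        labels.append(frame_labels)
    return SequenceData(
        frames=frames,
        labels=labels,
        true_positions=true_pos,
        visible=visible_flags,
        provenance={"rho": rho, "seed": cfg.seed, "speed": traj.speed,
                    "occlusion_windows": list(map(list, traj.occlusion_windows))},
    )


def mock_detector(spec: MockDetectorSpec, sequence: SequenceData):
    """Build a detector callable from ground truth with scripted degradation.

    The returned callable satisfies ``detector(image, frame_index, origin) ->
    list[Detection]`` and returns frame-coordinate detections restricted to
    the queried crop.  Dropout, jitter and clutter are pre-drawn per frame
    from ``spec.seed`` so the stream is identical regardless of query pattern
    (global tiling vs local crops) and across runs.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(sequence.frames)
    h, w = sequence.frames[0].shape
    lo, hi = spec.confidence_range
    per_frame: list[list[Detection]] = []
    for idx in range(n):
        dets: list[Detection] = []
        frame_labels = sequence.labels[idx]
        dropped = rng.random() < spec.fn_rate
        for lab in frame_labels:
            if dropped:
                continue
            poly = lab.polygon * np.array([w, h])
            if spec.position_jitter_sigma > 0:
                poly = poly + rng.normal(0, spec.position_jitter_sigma, size=2)
            poly = np.clip(poly, [0, 0], [w - 1, h - 1])
            dets.append(Detection(polygon=poly, confidence=float(rng.uniform(lo, hi)),
                                  class_id=lab.class_id))
        for _ in range(rng.poisson(spec.fp_rate)):
            cx, cy = rng.uniform(0, w - 1), rng.uniform(0, h - 1)
            size = rng.uniform(4, 30)
            half = size / 2
            poly = np.clip(
                np.array([[cx - half, cy - half], [cx + half, cy - half],
                          [cx + half, cy + half], [cx - half, cy + half]]),
                [0, 0], [w - 1, h - 1],
            )
            dets.append(Detection(polygon=poly, confidence=float(rng.uniform(lo, hi))))
        per_frame.append(dets)

    def detector(image: np.ndarray, frame_index: int, origin: tuple[int, int]):
        ox, oy = origin
        ch, cw = image.shape[:2]
        out = []
        for det in per_frame[frame_index]:
            cx, cy = det.centre
            if ox <= cx < ox + cw and oy <= cy < oy + ch:
                out.append(Detection(polygon=det.polygon.copy(),
                                     confidence=det.confidence,
                                     class_id=det.class_id))
        return out

    detector.per_frame = per_frame  # exposed for inspection in tests
    return detector
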