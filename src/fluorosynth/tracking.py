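"""Dual-mode device tracking: detection gating + adaptive Kalman filtering.

The tracker alternates between a GLOBAL search mode (the full frame is tiled
into overlapping patches, detections lifted back to frame coordinates and
cross-patch duplicates merged) and a LOCAL mode that queries only a cropped
region of interest around the last known position.  Raw detections pass a
five-criterion filter — (1) minimum confidence, (2) geometric consistency of
width/length, (3) temporal continuity relative to the predicted position,
(4) anatomical plausibility relative to a lumen centreline, (5) escalation
based on the recent 10-frame localization success rate — and the surviving
detection nearest the prediction feeds a constant-velocity Kalman filter
whose measurement noise scales inversely with detection confidence.  During
detection gaps the filter coasts, interpolating positions through
occlusions; after ``max_coast_frames`` consecutive misses the tracker
reverts to GLOBAL search.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import exposure

from ._image import as_u8
from .dataset import tile_image

__all__ = [
    "Detection",
    "TrackState",
    "GateConfig",
    "PreprocessConfig",
    "KalmanFilterCV",
    "preprocess",
    "filter_detections",
    "kalman_step",
    "merge_duplicates",
    "track_sequence",
    "TrackResult",
]

HISTORY_LEN = 10  # frames in the rolling success-rate window


@dataclass
class Detection:
    """A detector output in frame coordinates."""

    polygon: np.ndarray  # (N, 2) pixel (x, y)
    confidence: float
    class_id: int = 0
    source_patch: int | None = None

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """Tight axis-aligned (x0, y0, x1, y1) box of the polygon."""
        x0, y0 = self.polygon.min(axis=0)
        x1, y1 = self.polygon.max(axis=0)
        return float(x0), float(y0), float(x1), float(y1)

    @property
    def centre(self) -> np.ndarray:
        x0, y0, x1, y1 = self.bbox
        return np.array([(x0 + x1) / 2, (y0 + y1) / 2])

    @property
    def width(self) -> float:
        x0, _, x1, _ = self.bbox
        return x1 - x0

    @property
    def length(self) -> float:
        _, y0, _, y1 = self.bbox
        return y1 - y0


def box_iou(a: tuple, b: tuple) -> float:
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    if union <= 0:
        return 1.0 if inter == 0 else 0.0
    return inter / union


@dataclass(frozen=True)
class GateConfig:
    """Thresholds of the five-criterion detection filter.

    min_confidence : gate (1)
    width_range, length_range : gate (2), pixels, inclusive
    max_step : gate (3), pixels/frame from the predicted position; widened by
        x(1 + 0.5 * frames_since_detection) while coasting
    max_centreline_distance : gate (4), pixels; only applied when a lumen
        centreline is supplied
    min_history_rate : gate (5); when the 10-frame success rate drops below
        this, the confidence threshold escalates by ``escalation_factor``
    max_coast_frames : consecutive misses before reverting to GLOBAL search
    """

    min_confidence: float = 0.3
    width_range: tuple[float, float] = (2.0, 200.0)
    length_range: tuple[float, float] = (2.0, 200.0)
    max_step: float = 30.0
    max_centreline_distance: float | None = None
    min_history_rate: float = 0.3
    escalation_factor: float = 1.5
    max_coast_frames: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence must be in [0, 1]")
        for lo, hi in (self.width_range, self.length_range):
            if lo >= hi:
                raise ValueError("degenerate geometric range")


@dataclass
class TrackState:
    """Kalman state of one tracked object plus tracker bookkeeping."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(2))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    covariance: np.ndarray = field(default_factory=lambda: np.eye(4) * 100.0)
    mode: str = "GLOBAL"
    roi: tuple[int, int, int, int] | None = None
    history: deque = field(default_factory=lambda: deque(maxlen=HISTORY_LEN))
    frames_since_detection: int = 0
    object_size: float = 24.0

    @property
    def success_rate(self) -> float:
        if not self.history:
            return 1.0
        return sum(self.history) / len(self.history)


@dataclass(frozen=True)
class PreprocessConfig:
    """Linear brightness/contrast rescale followed by histogram equalization."""

    brightness: float = 0.0  # additive offset, intensity units
    contrast: float = 1.0  # multiplicative gain
    equalize: bool = False
    clip_limit: float | None = None  # CLAHE when set


def preprocess(frame: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Brightness/contrast adjustment and (optional) histogram equalization.

    A constant frame passes through equalization unchanged (degenerate
    histogram); for any non-constant input the equalized output is rescaled
    to span the full [0, 255] range.
    """
    img = as_u8(frame).astype(np.float64)
    img = np.clip(cfg.contrast * img + cfg.brightness, 0, 255)
    if cfg.equalize:
        if img.max() > img.min():
            if cfg.clip_limit is not None:
                eq = exposure.equalize_adapthist(img.astype(np.uint8), clip_limit=cfg.clip_limit)
            else:
                eq = exposure.equalize_hist(img.astype(np.uint8))
            eq = exposure.rescale_intensity(eq, out_range=(0.0, 255.0))
            img = eq
    return as_u8(img)


def _point_to_polyline_distance(p: np.ndarray, line: np.ndarray) -> float:
    """Min distance from point p to the polyline given as (N, 2) vertices."""
    line = np.asarray(line, dtype=float)
    if len(line) == 1:
        return float(np.hypot(*(p - line[0])))
    a, b = line[:-1], line[1:]
    ab = b - a
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-12), 0, 1)
    proj = a + t[:, None] * ab
    return float(np.sqrt(((p - proj) ** 2).sum(axis=1).min()))


def filter_detections(
    detections: list[Detection],
    state: TrackState,
    gates: GateConfig,
    centreline: np.ndarray | None = None,
    predicted: np.ndarray | None = None,
) -> Detection | None:
    """Apply the five gating criteria and return the accepted detection
    nearest the predicted position (or None).

    Gate (3) uses the Kalman-predicted position and widens while coasting;
    gate (4) requires a centreline plus a configured distance; gate (5)
    raises the confidence bar whenever the rolling success rate is poor.
    """
    if predicted is None:
        predicted = state.position + state.velocity
    min_conf = gates.min_confidence
    if state.history and state.success_rate < gates.min_history_rate:
        min_conf = min(0.95, min_conf * gates.escalation_factor)
    step_limit = gates.max_step * (1.0 + 0.5 * state.frames_since_detection)
    survivors: list[tuple[float, Detection]] = []
    for det in detections:
        if det.confidence < min_conf:
            continue
        w, l = det.width, det.length
        lo_w, hi_w = gates.width_range
        lo_l, hi_l = gates.length_range
        short, long_ = min(w, l), max(w, l)  # rotation-agnostic dimensions
        if not (lo_w <= short <= hi_w and lo_l <= long_ <= hi_l):
            continue
        dist = float(np.hypot(*(det.centre - predicted)))
        if dist > step_limit:
            continue
        if centreline is not None and gates.max_centreline_distance is not None:
            if _point_to_polyline_distance(det.centre, centreline) > gates.max_centreline_distance:
                continue
        survivors.append((dist, det))
    if not survivors:
        return None
    return min(survivors, key=lambda t: t[0])[1]


class KalmanFilterCV:
    """Constant-velocity Kalman filter over state [x, y, vx, vy].

    Process noise is a white-acceleration model with spectral density ``q``;
    measurement noise is isotropic with variance ``r / confidence``, so
    low-confidence detections pull the state less — the filter's adaptivity.
    """

    H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])

    def __init__(self, q: float = 0.5, r: float = 1.0, dt: float = 1.0):
        self.q, self.r, self.dt = q, r, dt
        dt2, dt3, dt4 = dt**2, dt**3, dt**4
        self.F = np.array(
            [[1, 0, dt, 0], [0, 1, 0, dt], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
        )
        qblock = q * np.array([[dt4 / 4, dt3 / 2], [dt3 / 2, dt2]])
        self.Q = np.zeros((4, 4))
        self.Q[np.ix_([0, 2], [0, 2])] = qblock
        self.Q[np.ix_([1, 3], [1, 3])] = qblock

    def predict(self, x: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.F @ x
        P = self.F @ P @ self.F.T + self.Q
        return x, 0.5 * (P + P.T)

    def update(
        self, x: np.ndarray, P: np.ndarray, z: np.ndarray, confidence: float = 1.0
    ) -> tuple[np.ndarray, np.ndarray]:
        R = (self.r / max(confidence, 1e-3)) * np.eye(2)
        S = self.H @ P @ self.H.T + R
        K = P @ self.H.T @ np.linalg.solve(S, np.eye(2))
        x = x + K @ (z - self.H @ x)
        ikh = np.eye(4) - K @ self.H
        P = ikh @ P @ ikh.T + K @ R @ K.T  # Joseph form keeps P symmetric PSD
        return x, 0.5 * (P + P.T)


def kalman_step(
    state: TrackState,
    measurement: np.ndarray | None = None,
    confidence: float = 1.0,
    kf: KalmanFilterCV | None = None,
) -> TrackState:
    """One predict(/update) cycle.

    With a measurement: standard update with confidence-scaled noise, success
    flag pushed into the history window.  Without: the state coasts on the
    prediction alone and ``frames_since_detection`` increments.  Non-finite
    measurements are treated as missing.
    """
    kf = kf or KalmanFilterCV()
    x = np.concatenate([state.position, state.velocity])
    x, P = kf.predict(x, state.covariance)
    if measurement is not None:
        z = np.asarray(measurement, dtype=float)
        if not np.all(np.isfinite(z)):
            measurement = None
    new_history = deque(state.history, maxlen=HISTORY_LEN)
    if measurement is not None:
        x, P = kf.update(x, P, z, confidence)
        new_history.append(True)
        frames_since = 0
    else:
        new_history.append(False)
        frames_since = state.frames_since_detection + 1
    return replace(
        state,
        position=x[:2].copy(),
        velocity=x[2:].copy(),
        covariance=P,
        history=new_history,
        frames_since_detection=frames_since,
    )


def merge_duplicates(detections: list[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Suppress cross-patch duplicates: greedily keep the highest-confidence
    detection among any group with pairwise box IoU >= threshold."""
    ordered = sorted(detections, key=lambda d: -d.confidence)
    kept: list[Detection] = []
    for det in ordered:
        if all(box_iou(det.bbox, k.bbox) < iou_threshold for k in kept):
            kept.append(det)
    return kept


@dataclass
class TrackResult:
    """Per-frame tracker output plus the localization success ratio.

    ``positions`` holds the Kalman position estimate per frame (NaN before
    the tracker first initializes).  A frame is *localized* when the tracker
    produced a position: either a detection was accepted, or the filter is
    interpolating through a short gap (coasting within the allowed window) —
    the gap-filling role of the Kalman filter.  ``detection_localized``
    records accepted detections only.
    """

    states: list[TrackState]
    localized: list[bool]
    detection_localized: list[bool]
    positions: np.ndarray  # (n_frames, 2) Kalman position per frame
    modes: list[str]

    @property
    def lsr(self) -> float:
        """Localization success ratio: localized frames / total frames
        (Kalman-interpolated frames count as localized)."""
        if not self.localized:
            return 0.0
        return sum(self.localized) / len(self.localized)

    @property
    def detection_lsr(self) -> float:
        """Strict ratio: frames with an accepted detection / total frames."""
        if not self.detection_localized:
            return 0.0
        return sum(self.detection_localized) / len(self.detection_localized)

    def rmse(self, true_positions: np.ndarray) -> float:
        """Position RMSE against ground truth over frames with an estimate."""
        true = np.asarray(true_positions, dtype=float)
        valid = np.isfinite(self.positions).all(axis=1) & np.isfinite(true).all(axis=1)
        if not valid.any():
            return float("nan")
        d = self.positions[valid] - true[valid]
        return float(np.sqrt((d**2).sum(axis=1).mean()))

    def to_csv(self, path) -> None:
        import csv
        from pathlib import Path

        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        with open(p, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["frame", "x", "y", "mode", "localized"])
            for i, (pos, mode, loc) in enumerate(zip(self.positions, self.modes, self.localized)):
                wr.writerow([i, f"{pos[0]:.3f}", f"{pos[1]:.3f}", mode, int(loc)])


def _roi_box(state: TrackState, frame_shape: tuple[int, int], min_side: int = 96) -> tuple[int, int, int, int]:
    side = int(max(4 * state.object_size, min_side))
    h, w = frame_shape
    cx, cy = state.position + state.velocity
    x0 = int(np.clip(round(cx - side / 2), 0, max(0, w - side)))
    y0 = int(np.clip(round(cy - side / 2), 0, max(0, h - side)))
    return x0, y0, min(w, x0 + side), min(h, y0 + side)


def track_sequence(
    frames,
    detector,
    gates: GateConfig = GateConfig(),
    grid_spec: dict | None = None,
    centreline: np.ndarray | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
    kf: KalmanFilterCV | None = None,
    min_roi_side: int = 96,
) -> TrackResult:
    """Run the dual-mode tracking loop over a frame sequence.

    ``detector`` is any callable ``detector(image, frame_index, origin)``
    returning detections in frame coordinates for the given crop (``origin``
    is the crop's top-left corner in the frame).  The loop starts in GLOBAL
    mode (tiled full-frame search with duplicate merging), switches to LOCAL
    after the first accepted detection, and falls back to GLOBAL after
    ``gates.max_coast_frames`` consecutive misses.  A frame counts as
    localized iff a detection was accepted on it.
    """
    grid_spec = grid_spec or {}
    kf = kf or KalmanFilterCV()
    state = TrackState()
    states, localized, det_localized, positions, modes = [], [], [], [], []
    initialized = False
    tentatives: list[Detection] = []
    for idx, frame in enumerate(frames):
        img = preprocess(frame, preprocess_cfg) if preprocess_cfg else as_u8(frame)
        h, w = img.shape
        try:
            if state.mode == "GLOBAL":
                grid, patches = tile_image(img, **grid_spec)
                dets: list[Detection] = []
                for pi, (patch, (ox, oy)) in enumerate(zip(patches, grid.offsets)):
                    for d in detector(patch, idx, (ox, oy)):
                        d.source_patch = pi
                        dets.append(d)
                dets = merge_duplicates(dets)
            else:
                x0, y0, x1, y1 = _roi_box(state, (h, w), min_roi_side)
                dets = list(detector(img[y0:y1, x0:x1], idx, (x0, y0)))
        except Exception:
            dets = []  # detector failure: treat the frame as missed
        if not initialized:
            # two-frame confirmation: a track starts only when detections on
            # consecutive frames are within a plausible step of each other, so
            # isolated clutter (spatially independent across frames) cannot
            # seed the filter
            gated = []
            for d in dets:
                if filter_detections([d], state, gates, centreline,
                                     predicted=d.centre) is not None:
                    gated.append(d)
            # confirm the pair with the smallest displacement (the device
            # cannot move more than max_step per frame; clutter rarely lands
            # that close to a previous detection)
            best_pair = None
            for d in gated:
                for t in tentatives:
                    dist = float(np.hypot(*(d.centre - t.centre)))
                    if dist <= gates.max_step:
                        score = (dist, -(d.confidence + t.confidence))
                        if best_pair is None or score < best_pair[0]:
                            best_pair = (score, t, d)
            if best_pair is not None:
                _, t, accepted = best_pair
                x0b, y0b, x1b, y1b = accepted.bbox
                state = replace(
                    state,
                    position=accepted.centre.copy(),
                    velocity=accepted.centre - t.centre,
                    covariance=np.diag([4.0, 4.0, 25.0, 25.0]),
                    object_size=float(max(x1b - x0b, y1b - y0b)),
                )
                initialized = True
                new_history = deque(state.history, maxlen=HISTORY_LEN)
                new_history.append(True)
                state = replace(state, history=new_history, frames_since_detection=0,
                                mode="LOCAL")
                if positions:  # the confirming pair's first frame was localized too
                    positions[-1] = t.centre.copy()
                    localized[-1] = True
                    det_localized[-1] = True
            else:
                tentatives = gated
                accepted = None
        else:
            predicted = state.position + state.velocity
            accepted = filter_detections(dets, state, gates, centreline, predicted=predicted)
            if accepted is not None:
                state = kalman_step(state, accepted.centre, accepted.confidence, kf)
                state = replace(state, mode="LOCAL")
            else:
                state = kalman_step(state, None, kf=kf)
                if state.frames_since_detection >= gates.max_coast_frames:
                    state = replace(state, mode="GLOBAL")
                if state.frames_since_detection >= 2 * gates.max_coast_frames:
                    # track lost for good: drop it and re-run confirmation
                    initialized = False
                    tentatives = []
                    state = TrackState()
        states.append(state)
        det_localized.append(accepted is not None)
        coasting_ok = (
            initialized and state.frames_since_detection <= gates.max_coast_frames
        )
        localized.append(accepted is not None or coasting_ok)
        positions.append(state.position.copy() if initialized else np.full(2, np.nan))
        modes.append(state.mode)
    return TrackResult(
        states=states,
        localized=localized,
        detection_localized=det_localized,
        positions=np.array(positions) if positions else np.zeros((0, 2)),
        modes=modes,
    )
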