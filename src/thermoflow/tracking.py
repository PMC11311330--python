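"""Nose-mouth ROI tracking and ROI-motion compensation.

A fixed-size region of interest (ROI) over the nose-mouth area is tracked
across the sequence so that the window feeding the dense-flow stage follows
the subject. Corner-like key-points on the face are detected inside the ROI
(Shi-Tomasi minimum-eigenvalue response) and their frame-to-frame
translation is estimated with local Lucas-Kanade least squares. The median
key-point displacement, passed through a +-0.5 px dead-band with sub-pixel
residual accumulation, drives integer ROI shifts that minimize per-frame
jitter. The uniform flow a ROI shift induces in crops of a static scene is
removed downstream by ``compensate_shift``.

Flow-vector convention used throughout the package: a flow field is an
``(h, w, 2)`` float array with channel 0 = v_x (column direction) and
channel 1 = v_y (row direction), in pixels/frame.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, structure_tensor

from .rawio import NormalizationParams, NormalizedFrame, ThermalSequence, normalize

__all__ = [
    "RegionOfInterest",
    "TrackState",
    "detect_keypoints",
    "estimate_shift",
    "track_sequence",
    "compensate_shift",
    "face_mask",
    "write_trajectory_csv",
]

# Detector / LK defaults (config-exposed; the acquisition protocol fixes none of these)
CORNER_THRESHOLD_REL = 0.05
KEYPOINT_REFRESH_INTERVAL = 25
MIN_KEYPOINTS = 3
LK_WINDOW = 15
LK_ITERS = 10
DEADBAND = 0.5
FACE_MASK_THRESHOLD = 0.85
FACE_MASK_DILATION = 2


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned window: top-left (row0, col0), fixed (height, width)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be positive")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI corner must be non-negative")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        fh, fw = frame.shape[:2]
        if self.row0 + self.height > fh or self.col0 + self.width > fw:
            raise ValueError("ROI extends outside the frame")
        return frame[self.row0 : self.row0 + self.height, self.col0 : self.col0 + self.width]

    def shifted(self, drow: int, dcol: int) -> "RegionOfInterest":
        return RegionOfInterest(self.row0 + drow, self.col0 + dcol, self.height, self.width)

    def clipped(self, frame_h: int, frame_w: int) -> "RegionOfInterest":
        r = min(max(self.row0, 0), frame_h - self.height)
        c = min(max(self.col0, 0), frame_w - self.width)
        return RegionOfInterest(r, c, self.height, self.width)


@dataclass
class TrackState:
    """Key-point positions plus the per-frame integer shifts applied to the ROI."""

    keypoints: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    shift_history: list[tuple[int, int]] = field(default_factory=list)
    flags: list[bool] = field(default_factory=list)  # per transition: clipped/low-confidence


def _as_pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, NormalizedFrame) else np.asarray(frame, float)


def detect_keypoints(frame, roi: RegionOfInterest, max_points: int = 20) -> np.ndarray:
    """Corner-like points inside the ROI, strongest response first.

    Returns an (n, 2) float array of (row, col) positions in full-frame
    coordinates, n <= max_points. A textureless region yields an empty array.
    """
    if max_points < 1:
        raise ValueError("max_points must be >= 1")
    px = _as_pixels(frame)
    sub = roi.crop(px)
    # Shi-Tomasi minimum-eigenvalue response; reflective borders so the crop
    # boundary itself does not register as structure
    Arr, Arc, Acc = structure_tensor(sub, sigma=1.0, mode="reflect", order="rc")
    response = 0.5 * ((Arr + Acc) - np.sqrt((Arr - Acc) ** 2 + 4 * Arc**2))
    if not np.any(response > 0):
        return np.zeros((0, 2))
    peaks = corner_peaks(
        response,
        min_distance=2,
        threshold_rel=CORNER_THRESHOLD_REL,
        num_peaks=max_points,
        exclude_border=1,
    )
    if peaks.size == 0:
        return np.zeros((0, 2))
    order = np.argsort(response[peaks[:, 0], peaks[:, 1]])[::-1]
    peaks = peaks[order]
    return peaks.astype(float) + np.array([roi.row0, roi.col0], float)


def _deadband_round(x: float) -> int:
    """Round to nearest integer with a +-DEADBAND dead-band around zero."""
    if abs(x) < DEADBAND:
        return 0
    return int(np.trunc(x + np.copysign(0.5, x)))


def _lk_displacements(
    prev: np.ndarray,
    cur: np.ndarray,
    keypoints: np.ndarray,
    window: int = LK_WINDOW,
    iters: int = LK_ITERS,
) -> np.ndarray:
    """Per-keypoint (drow, dcol) via iterative single-level Lucas-Kanade."""
    Ir = ndimage.sobel(prev, axis=0, mode="reflect") / 8.0
    Ic = ndimage.sobel(prev, axis=1, mode="reflect") / 8.0
    half = window // 2
    offs = np.arange(-half, half + 1, dtype=float)
    orow, ocol = np.meshgrid(offs, offs, indexing="ij")
    out = np.zeros((len(keypoints), 2))
    for k, (r0, c0) in enumerate(keypoints):
        rw = r0 + orow
        cw = c0 + ocol
        coords = np.array([rw.ravel(), cw.ravel()])
        ir = ndimage.map_coordinates(Ir, coords, order=1, mode="nearest")
        ic = ndimage.map_coordinates(Ic, coords, order=1, mode="nearest")
        p0 = ndimage.map_coordinates(prev, coords, order=1, mode="nearest")
        A = np.array([[ir @ ir, ir @ ic], [ir @ ic, ic @ ic]])
        if np.linalg.det(A) < 1e-12:
            continue
        Ainv = np.linalg.inv(A)
        d = np.zeros(2)
        for _ in range(iters):
            shifted = np.array([coords[0] + d[0], coords[1] + d[1]])
            p1 = ndimage.map_coordinates(cur, shifted, order=1, mode="nearest")
            it = p1 - p0
            b = -np.array([ir @ it, ic @ it])
            step = Ainv @ b
            d += step
            if np.hypot(*step) < 1e-4:
                break
        out[k] = d
    return out


def estimate_shift(
    prev,
    cur,
    keypoints: np.ndarray,
    window: int = LK_WINDOW,
) -> tuple[tuple[int, int], bool]:
    """Integer ROI shift between two frames from key-point motion.

    Lucas-Kanade displacements are aggregated by the median over key-points
    and passed through the dead-band rounding, so sub-threshold motion is
    absorbed (minimal per-frame jump). Returns ``((drow, dcol),
    low_confidence)``; with no key-points the shift is (0, 0) and the
    low-confidence flag is set.
    """
    keypoints = np.asarray(keypoints, float).reshape(-1, 2)
    if len(keypoints) == 0:
        return (0, 0), True
    disp = _lk_displacements(_as_pixels(prev), _as_pixels(cur), keypoints, window=window)
    med = np.median(disp, axis=0)
    return (_deadband_round(med[0]), _deadband_round(med[1])), False


def track_sequence(
    seq: ThermalSequence,
    initial_roi: RegionOfInterest,
    params: NormalizationParams,
    max_points: int = 20,
) -> tuple[list[RegionOfInterest], TrackState]:
    """Track the fixed-size ROI through a sequence.

    Frames are tracking-normalized; key-points are refreshed every
    ``KEYPOINT_REFRESH_INTERVAL`` frames or whenever fewer than
    ``MIN_KEYPOINTS`` survive. The sub-pixel residual of the median motion
    is accumulated across frames so slow drift is not lost to the
    dead-band. ROIs are clipped to the frame (flagged when clipping or
    low-confidence estimation occurs). Returns one ROI per frame plus the
    track state with the applied integer shift history.
    """
    fh, fw = seq.height, seq.width
    initial_roi.crop(seq.frames[0])  # validates
    rois = [initial_roi]
    state = TrackState()

    prev = normalize(seq.frames[0], params, "tracking").pixels
    kps = detect_keypoints(prev, initial_roi, max_points)
    state.keypoints = kps
    residual = np.zeros(2)

    for t in range(1, len(seq)):
        cur = normalize(seq.frames[t], params, "tracking").pixels
        roi = rois[-1]
        if len(kps) < MIN_KEYPOINTS or t % KEYPOINT_REFRESH_INTERVAL == 0:
            kps = detect_keypoints(prev, roi, max_points)
        flag = False
        if len(kps) == 0:
            raw = np.zeros(2)
            flag = True
        else:
            disp = _lk_displacements(prev, cur, kps, window=LK_WINDOW)
            raw = np.median(disp, axis=0)
            kps = kps + disp  # follow each point individually
            inside = (
                (kps[:, 0] >= 0) & (kps[:, 0] < fh) & (kps[:, 1] >= 0) & (kps[:, 1] < fw)
            )
            kps = kps[inside]
        residual += raw
        drow = _deadband_round(residual[0])
        dcol = _deadband_round(residual[1])
        residual -= (drow, dcol)
        moved = roi.shifted(drow, dcol)
        clipped = moved.clipped(fh, fw)
        if clipped != moved:
            flag = True
        applied = (clipped.row0 - roi.row0, clipped.col0 - roi.col0)
        rois.append(clipped)
        state.shift_history.append(applied)
        state.flags.append(flag)
        prev = cur

    state.keypoints = kps
    return rois, state


def compensate_shift(flow: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Remove the uniform motion a ROI shift induces from every flow vector.

    ``shift`` is the (drow, dcol) apparent uniform motion to cancel:
    channel 0 (v_x) is reduced by dcol and channel 1 (v_y) by drow. Linear
    and exactly invertible (compensating by s then -s restores the field).
    """
    drow, dcol = shift
    if drow == 0 and dcol == 0:
        return flow
    out = np.array(flow, dtype=float, copy=True)
    out[..., 0] -= dcol
    out[..., 1] -= drow
    return out


def face_mask(frame, roi: RegionOfInterest, params: NormalizationParams) -> np.ndarray:
    """Boolean mask of face pixels inside the ROI (tracking-normalized > 0.85, dilated).

    Used downstream to zero flow vectors belonging to the face itself so
    the encoded fields carry only plume motion.
    """
    if isinstance(frame, NormalizedFrame):
        crop = roi.crop(frame.pixels)
    else:
        crop = normalize(roi.crop(np.asarray(frame)), params, "tracking").pixels
    mask = crop > FACE_MASK_THRESHOLD
    if FACE_MASK_DILATION > 0:
        mask = ndimage.binary_dilation(mask, iterations=FACE_MASK_DILATION)
    return mask


def write_trajectory_csv(path: str | Path, rois: list[RegionOfInterest], state: TrackState) -> None:
    """ROI trajectory as CSV: frame_index,row0,col0,height,width,flag."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "row0", "col0", "height", "width", "flag"])
        for i, roi in enumerate(rois):
            flag = state.flags[i - 1] if 0 < i <= len(state.flags) else False
            w.writerow([i, roi.row0, roi.col0, roi.height, roi.width, int(flag)])
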