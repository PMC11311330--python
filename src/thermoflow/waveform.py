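"""Exhale waveform extraction, filtering, and per-exhale segmentation.

Each flow field collapses to one scalar: the sum over all pixels of the
vector magnitude, f(t) = sum_ij |F_t(i, j)|. One field per frame pair
yields a 1-D time series whose episodic bursts are individual exhales.
The series is cleaned by (1) replacing outliers beyond 1.5 standard
deviations with linear interpolation of their neighbors, (2) a
Savitzky-Golay filter with a 9-sample window (cubic), and (3) min-max
normalization to [0, 1]. Exhale episodes are then isolated between the
waveform minima flanking each detected peak and resampled to a fixed
length of 256 samples for the downstream 1-D models.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "SEGMENT_LENGTH",
    "ExhaleWaveform",
    "ExhaleSegment",
    "reduce_field",
    "build_waveform",
    "filter_waveform",
    "segment_exhales",
    "breathing_rate",
    "write_waveform_csv",
    "plot_waveform",
]

SEGMENT_LENGTH = 256
OUTLIER_SD = 1.5
SAVGOL_WINDOW = 9
SAVGOL_ORDER = 3
MIN_PROMINENCE = 0.1  # fraction of the normalized range
MIN_SEPARATION_S = 0.5  # seconds between exhale peaks


@dataclass
class ExhaleWaveform:
    """1-D flow-magnitude series with provenance and processing history."""

    samples: np.ndarray
    fps: float = 25.0
    provenance: str = "raw_optical_flow"  # or "fieldnet_predicted"
    processing: list[str] = dc_field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")


@dataclass
class ExhaleSegment:
    """One exhale episode resampled to SEGMENT_LENGTH samples in [0, 1]."""

    values: np.ndarray
    source_bounds: tuple[int, int]
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (SEGMENT_LENGTH,):
            raise ValueError(f"segment must have length {SEGMENT_LENGTH}")


def reduce_field(flow: np.ndarray) -> float:
    """Sum of all vector magnitudes of a flow field; zero iff the field is zero."""
    flow = np.asarray(flow, dtype=np.float64)
    return float(np.sum(np.hypot(flow[..., 0], flow[..., 1])))


def build_waveform(
    fields: list[np.ndarray], fps: float = 25.0, provenance: str = "raw_optical_flow"
) -> ExhaleWaveform:
    """One magnitude-sum sample per field, order preserved."""
    if len(fields) == 0:
        raise ValueError("need at least one flow field")
    samples = np.array([reduce_field(f) for f in fields])
    return ExhaleWaveform(samples=samples, fps=fps, provenance=provenance)


def _remove_outliers(x: np.ndarray, n_sd: float) -> np.ndarray:
    mean = x.mean()
    sd = x.std()
    if sd == 0:
        return x.copy()
    good = np.abs(x - mean) <= n_sd * sd
    if good.all():
        return x.copy()
    if not good.any():
        return np.full_like(x, mean)
    idx = np.arange(len(x))
    out = x.copy()
    out[~good] = np.interp(idx[~good], idx[good], x[good])
    return out


def filter_waveform(w: ExhaleWaveform) -> ExhaleWaveform:
    """Outlier interpolation, Savitzky-Golay smoothing, min-max to [0, 1].

    A constant signal cannot be min-max normalized; it comes back as all
    zeros with the ``degenerate`` flag set.
    """
    if len(w.samples) < SAVGOL_WINDOW:
        raise ValueError(f"need at least {SAVGOL_WINDOW} samples")
    x = _remove_outliers(w.samples, OUTLIER_SD)
    x = savgol_filter(x, SAVGOL_WINDOW, SAVGOL_ORDER)
    lo, hi = x.min(), x.max()
    # float jitter from the smoother must not masquerade as signal range
    degenerate = (hi - lo) <= 1e-9 * max(1.0, abs(hi))
    if degenerate:
        x = np.zeros_like(x)
    else:
        x = (x - lo) / (hi - lo)
    return ExhaleWaveform(
        samples=x,
        fps=w.fps,
        provenance=w.provenance,
        processing=w.processing + ["outlier_1.5sd", "savgol_w9_p3", "minmax"],
        degenerate=degenerate,
    )


def segment_exhales(
    w: ExhaleWaveform,
    min_separation: int | None = None,
    min_prominence: float = MIN_PROMINENCE,
) -> list[ExhaleSegment]:
    """Split a filtered waveform into per-exhale segments of length 256.

    Peaks are detected with the given prominence (fraction of the
    normalized range) and minimum separation (default 0.5 s at the
    waveform's rate). Each segment spans from the minimum before its peak
    to the minimum after it; adjacent segments share boundary minima.
    Returns an empty list when no peak qualifies.
    """
    x = w.samples
    if min_separation is None:
        min_separation = max(1, int(round(MIN_SEPARATION_S * w.fps)))
    peaks, _ = find_peaks(x, prominence=min_prominence, distance=min_separation)
    if len(peaks) == 0:
        return []
    # boundary between consecutive peaks = the minimum of the valley
    bounds = [int(np.argmin(x[: peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(a + np.argmin(x[a : b + 1])))
    bounds.append(int(peaks[-1] + np.argmin(x[peaks[-1] :])))
    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < 2:
            continue
        span = x[s : e + 1]
        grid = np.linspace(0, len(span) - 1, SEGMENT_LENGTH)
        vals = np.interp(grid, np.arange(len(span)), span)
        segments.append(ExhaleSegment(values=vals, source_bounds=(s, e)))
    return segments


def breathing_rate(segments: list[ExhaleSegment], n_samples: int, fps: float) -> float:
    """Detected exhales per minute over the waveform duration."""
    duration_min = n_samples / fps / 60.0
    return len(segments) / duration_min if duration_min > 0 else 0.0


def write_waveform_csv(path: str | Path, w: ExhaleWaveform) -> None:
    with open(path, "w", newline="") as fh:
        cw = csv.writer(fh)
        cw.writerow(["index", "value"])
        for i, v in enumerate(w.samples):
            cw.writerow([i, f"{v:.8g}"])


def plot_waveform(path: str | Path, w: ExhaleWaveform, segments=None) -> None:
    """Render the waveform (and optional segment boundaries) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(len(w.samples)) / w.fps
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(t, w.samples, lw=1.0, label=w.provenance)
    for seg in segments or []:
        ax.axvline(seg.source_bounds[0] / w.fps, color="0.7", lw=0.6)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("f(t)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
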