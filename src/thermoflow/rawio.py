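"""Raw 16-bit thermal sequence I/O and count normalization.

Thermal cameras in the 3-5 um band store each frame as a grid of raw
sensor *counts* (unsigned 16-bit integers, typically 5000-9000 indoors).
Sequences are headerless contiguous binary files: frame-major, row-major
within a frame. Two linear normalizations map counts into [0, 1]:

* ``tracking`` -- ``[Fc, Imax] -> [0, 1]``: spans face temperature to the
  image maximum, giving high-contrast facial texture for key-point tracking.
* ``exhale``   -- ``[Ac, Fc] -> [0, 1]``: spans ambient background to face
  temperature, the interval in which exhaled-CO2 plume intensities live.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ThermalSequence",
    "NormalizationParams",
    "NormalizedFrame",
    "read_sequence",
    "write_sequence",
    "estimate_ambient",
    "estimate_face_count",
    "normalize",
    "export_pgm",
]

COUNT_MAX = 2**16 - 1


class MalformedFileError(ValueError):
    """Raw file size is not a positive multiple of the frame stride."""


@dataclass
class ThermalSequence:
    """Ordered stack of raw count frames plus the capture frame rate.

    ``frames`` is an ``(n, h, w)`` uint16 array; all frames share a shape
    and counts lie in ``[0, 65535]`` by construction of the dtype.
    """

    frames: np.ndarray
    fps: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be an (n, h, w) array")
        if self.frames.dtype != np.uint16:
            if self.frames.min() < 0 or self.frames.max() > COUNT_MAX:
                raise ValueError("counts must lie in [0, 65535]")
            self.frames = self.frames.astype(np.uint16)
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass(frozen=True)
class NormalizationParams:
    """Count levels anchoring the two normalization intervals.

    Fc: count at face temperature; Ac: ambient background count;
    Imax: top count used for the tracking interval. Requires Ac < Fc <= Imax.
    """

    Fc: float
    Ac: float
    Imax: float = float(COUNT_MAX)

    def __post_init__(self) -> None:
        if not (self.Ac < self.Fc <= self.Imax):
            raise ValueError(
                f"require Ac < Fc <= Imax, got Ac={self.Ac}, Fc={self.Fc}, Imax={self.Imax}"
            )


@dataclass
class NormalizedFrame:
    """A count frame mapped into [0, 1] under one of the two modes."""

    pixels: np.ndarray
    mode: str  # "tracking" | "exhale"

    def __post_init__(self) -> None:
        if self.mode not in ("tracking", "exhale"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")


def read_sequence(
    path: str | Path,
    height: int,
    width: int,
    fps: float = 25.0,
    byteorder: str = "little",
) -> ThermalSequence:
    """Read a headerless contiguous binary sequence of 16-bit count frames.

    The frame count is inferred from the file size, which must be a
    positive multiple of ``height * width * 2`` bytes.
    """
    if height <= 0 or width <= 0:
        raise ValueError("height and width must be positive")
    path = Path(path)
    nbytes = path.stat().st_size
    stride = height * width * 2
    if nbytes == 0 or nbytes % stride != 0:
        raise MalformedFileError(
            f"{path}: size {nbytes} is not a positive multiple of frame stride {stride}"
        )
    dtype = np.dtype(np.uint16).newbyteorder("<" if byteorder == "little" else ">")
    raw = np.fromfile(path, dtype=dtype)
    frames = raw.reshape(-1, height, width).astype(np.uint16)
    return ThermalSequence(frames=frames, fps=fps)


def write_sequence(seq: ThermalSequence, path: str | Path, byteorder: str = "little") -> None:
    """Write a sequence in the headerless raw binary format (round-trips bit-exactly)."""
    dtype = np.dtype(np.uint16).newbyteorder("<" if byteorder == "little" else ">")
    seq.frames.astype(dtype).tofile(Path(path))


def estimate_ambient(frame: np.ndarray, background_region) -> float:
    """Robust ambient count Ac: the median count inside a background region.

    The median resists hot pixels and stray warm objects in the sampled
    background window.
    """
    sub = background_region.crop(frame)
    if sub.size == 0:
        raise ValueError("background region is empty")
    return float(np.median(sub))


def estimate_face_count(frame: np.ndarray, face_region, percentile: float = 99.0) -> float:
    """Face-temperature count Fc: a high percentile of counts in the face region."""
    sub = face_region.crop(frame)
    if sub.size == 0:
        raise ValueError("face region is empty")
    return float(np.percentile(sub, percentile))


def normalize(
    frame: np.ndarray, params: NormalizationParams, mode: str = "exhale"
) -> NormalizedFrame:
    """Linearly map the mode's count interval onto [0, 1], clamping outside values.

    ``tracking`` maps ``[Fc, Imax]``, ``exhale`` maps ``[Ac, Fc]``. Values
    outside the interval clamp to 0 or 1 (the interval deliberately targets
    a sub-range of observed counts).
    """
    f = np.asarray(frame, dtype=np.float64)
    if mode == "tracking":
        lo, hi = params.Fc, params.Imax
    elif mode == "exhale":
        lo, hi = params.Ac, params.Fc
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if hi <= lo:
        raise ValueError(f"degenerate normalization range [{lo}, {hi}] for mode {mode!r}")
    p = np.clip((f - lo) / (hi - lo), 0.0, 1.0)
    return NormalizedFrame(pixels=p, mode=mode)


def export_pgm(frame: NormalizedFrame, path: str | Path) -> None:
    """Export a normalized frame as a 16-bit binary PGM for inspection."""
    px = np.round(frame.pixels * COUNT_MAX).astype(">u2")
    h, w = px.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n{COUNT_MAX}\n".encode())
        fh.write(px.tobytes())
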