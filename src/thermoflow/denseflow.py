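"""Dense 2-D optical flow between consecutive exhale-normalized frames.

The flow field is the minimizer of the classical brightness-constancy +
smoothness energy

    min  iint (grad I . v + dI/dt)^2 + alpha (||grad v_x||^2 + ||grad v_y||^2)

solved with the standard Jacobi-style iteration: starting from v = 0, each
step replaces v by its neighborhood average v_bar minus the brightness
residual projected on the image gradient,

    v_x <- v_bar_x - Ix (Ix v_bar_x + Iy v_bar_y + It) / (alpha + Ix^2 + Iy^2)
    v_y <- v_bar_y - Iy (Ix v_bar_x + Iy v_bar_y + It) / (alpha + Ix^2 + Iy^2)

Note the denominator carries alpha (not alpha^2 as in some classical
write-ups); alpha is a plain config value so either convention is
reachable. A small alpha (default 0.15) keeps intensity shifts near the
sensor noise floor as valid flow contributions, which is what makes the
rapidly dissipating exhale plume measurable at all.

Fields are (h, w, 2) float arrays: channel 0 = v_x (columns), channel 1 =
v_y (rows), in pixels/frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .rawio import NormalizedFrame
from .tracking import RegionOfInterest, compensate_shift

__all__ = [
    "FlowParams",
    "spatial_gradients",
    "horn_schunck",
    "flow_sequence",
    "save_fields",
    "load_fields",
]

# Neighborhood-average stencil for v_bar: 4-neighbors 1/6, diagonals 1/12.
AVG_KERNEL = np.array(
    [
        [1 / 12, 1 / 6, 1 / 12],
        [1 / 6, 0.0, 1 / 6],
        [1 / 12, 1 / 6, 1 / 12],
    ]
)


@dataclass(frozen=True)
class FlowParams:
    """Iteration parameters for the dense flow solver.

    alpha: smoothness weight (default 0.15). n_iter: fixed iteration count
    (default 64; a mean-absolute-update early stop at ``tol`` is available
    but off by default to preserve bitwise determinism).
    """

    alpha: float = 0.15
    n_iter: int = 64
    tol: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _pixels(frame) -> np.ndarray:
    px = frame.pixels if isinstance(frame, NormalizedFrame) else np.asarray(frame, float)
    return np.asarray(px, dtype=np.float64)


def spatial_gradients(frame) -> tuple[np.ndarray, np.ndarray]:
    """Sobel x/y gradients, normalized by 1/8 so a unit ramp has unit gradient.

    Border handling is reflective. Returns (Ix, Iy) with Ix the column
    (x) derivative and Iy the row (y) derivative.
    """
    px = _pixels(frame)
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError("frame must be at least 3x3 for the Sobel stencil")
    Ix = ndimage.sobel(px, axis=1, mode="reflect") / 8.0
    Iy = ndimage.sobel(px, axis=0, mode="reflect") / 8.0
    return Ix, Iy


def horn_schunck(f1, f2, params: FlowParams = FlowParams()) -> np.ndarray:
    """Dense flow field between two normalized frames via the iterative scheme.

    Spatial gradients are taken on the first frame; the temporal
    derivative is the pointwise difference f2 - f1. The field starts at
    zero, so identical frames yield an exactly zero field for any
    iteration count. Deterministic for fixed inputs and parameters.
    """
    a = _pixels(f1)
    b = _pixels(f2)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("frames must be finite")
    Ix, Iy = spatial_gradients(a)
    It = b - a
    denom = params.alpha + Ix * Ix + Iy * Iy
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    for _ in range(params.n_iter):
        ubar = ndimage.convolve(u, AVG_KERNEL, mode="reflect")
        vbar = ndimage.convolve(v, AVG_KERNEL, mode="reflect")
        common = (Ix * ubar + Iy * vbar + It) / denom
        un = ubar - common * Ix
        vn = vbar - common * Iy
        if params.tol > 0:
            delta = np.mean(np.abs(un - u)) + np.mean(np.abs(vn - v))
            u, v = un, vn
            if delta < params.tol:
                break
        else:
            u, v = un, vn
    return np.stack([u, v], axis=-1)


def flow_sequence(
    frames: list,
    rois: list[RegionOfInterest] | None = None,
    params: FlowParams = FlowParams(),
    compensation: str = "window",
) -> list[np.ndarray]:
    """Flow fields for consecutive frame pairs, with ROI-shift compensation.

    Two compensation modes remove the uniform motion the tracked ROI's own
    movement would otherwise imprint on the field:

    * ``"window"`` (default) -- the inverse transform is applied to the
      sampling itself: both frames of a pair are cropped at the leading
      frame's ROI, so static background is genuinely static in the crop
      pair and the solver never sees an induced shift. (Subtracting the
      shift from the solved field instead would fabricate uniform flow
      over textureless background, where the solver correctly reports
      near-zero motion.)
    * ``"field"`` -- crops each frame at its own ROI and subtracts the
      induced uniform motion from the solved field via
      :func:`compensate_shift`.

    Returns n-1 fields.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if rois is not None and len(rois) != len(frames):
        raise ValueError("rois must align one-to-one with frames")
    if compensation not in ("window", "field"):
        raise ValueError(f"unknown compensation mode {compensation!r}")
    fields = []
    for t in range(len(frames) - 1):
        a = _pixels(frames[t])
        b = _pixels(frames[t + 1])
        if rois is None:
            fields.append(horn_schunck(a, b, params))
            continue
        ra, rb = rois[t], rois[t + 1]
        if compensation == "window":
            field = horn_schunck(ra.crop(a), ra.crop(b), params)
        else:
            field = horn_schunck(ra.crop(a), rb.crop(b), params)
            field = compensate_shift(field, (ra.row0 - rb.row0, ra.col0 - rb.col0))
        fields.append(field)
    return fields


def save_fields(
    path: str | Path, fields: list[np.ndarray], params: FlowParams, attrs: dict | None = None
) -> None:
    """Serialize a flow sequence as an (n, h, w, 2) HDF5 dataset with metadata."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("fields", data=np.stack(fields).astype(np.float32))
        ds.attrs["alpha"] = params.alpha
        ds.attrs["n_iter"] = params.n_iter
        for k, v in (attrs or {}).items():
            ds.attrs[k] = v


def load_fields(path: str | Path) -> tuple[list[np.ndarray], dict]:
    with h5py.File(path, "r") as fh:
        ds = fh["fields"]
        fields = [np.asarray(f, dtype=np.float64) for f in ds]
        attrs = dict(ds.attrs)
    return fields, attrs
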