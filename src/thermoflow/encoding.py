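"""Flow-field encoding, masking, augmentation, and interleaved dataset assembly.

The interpolation network consumes flow fields normalized into [-1, 1] per
component by the maximum vector magnitude ``n_max`` of the field (or of a
whole sequence, which keeps temporal magnitude comparability for the
waveform reduction). The angle/magnitude encoding

    theta -> (y1, y2) = (sin theta, cos theta) * (n / m)

is mathematically identical to the direct component normalization with the
two channels interchanged -- since sin theta = v_y / n and cos theta =
v_x / n, the scaled pair is exactly (v_y / m, v_x / m). ``encode_angular``
exists to make that equivalence checkable; the pipeline uses the direct
normalization.

Training items are interleaved triples: inputs are the encoded fields at
t and t+2 stacked to (h, w, 4); the target is the field at t+1. Because
the acquisition protocol always places the subject on the left breathing
rightward, right-angle rotations and mirrorings (applied to both the grid
and the vector components) augment the data to remove that bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "EncodedField",
    "InterleavedDataset",
    "encode_field",
    "decode_field",
    "encode_angular",
    "apply_face_mask",
    "collate_interleaved",
    "augment",
    "split_dataset",
    "save_dataset",
    "load_dataset",
    "AUGMENT_OPS",
]


@dataclass
class EncodedField:
    """Component-normalized flow field in [-1, 1]^2 with its scale n_max."""

    data: np.ndarray  # (h, w, 2)
    n_max: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.n_max < 0:
            raise ValueError("n_max must be non-negative")


@dataclass
class InterleavedDataset:
    """Paired (h,w,4) inputs and (h,w,2) targets with per-item split tags."""

    x: list[np.ndarray]
    y: list[np.ndarray]
    tags: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if not self.tags:
            self.tags = [None] * len(self.x)

    def __len__(self) -> int:
        return len(self.x)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.stack(self.x), np.stack(self.y)


def encode_field(flow: np.ndarray, n_max: float | None = None) -> EncodedField:
    """Divide both components by n_max (auto: the field's max vector magnitude).

    Values are clipped into [-1, 1]. An all-zero field with auto n_max
    encodes to zeros with n_max = 0 (no division).
    """
    flow = np.asarray(flow, dtype=np.float64)
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow field must be finite")
    if n_max is None:
        n_max = float(np.max(np.hypot(flow[..., 0], flow[..., 1])))
    if n_max == 0:
        return EncodedField(np.zeros_like(flow), 0.0)
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    return EncodedField(np.clip(flow / n_max, -1.0, 1.0), float(n_max))


def decode_field(enc: EncodedField) -> np.ndarray:
    """Inverse of encode_field: multiply components by n_max."""
    return enc.data * enc.n_max


def encode_angular(flow: np.ndarray, n_max: float | None = None) -> EncodedField:
    """Angle/magnitude encoding (sin theta, cos theta) * (n / m).

    Zero-magnitude vectors encode to (0, 0): the angle is undefined but
    the magnitude scaling zeroes the pair anyway. Provided to verify the
    equivalence with ``encode_field`` (equal with channels swapped).
    """
    flow = np.asarray(flow, dtype=np.float64)
    vx, vy = flow[..., 0], flow[..., 1]
    n = np.hypot(vx, vy)
    m = float(np.max(n)) if n_max is None else float(n_max)
    if m == 0:
        return EncodedField(np.zeros_like(flow), 0.0)
    theta = np.arctan2(vy, vx)
    scale = n / m
    y1 = np.sin(theta) * scale
    y2 = np.cos(theta) * scale
    out = np.stack([y1, y2], axis=-1)
    out[n == 0] = 0.0
    return EncodedField(np.clip(out, -1.0, 1.0), m)


def apply_face_mask(flow: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero flow vectors at masked (face) pixels; others unchanged."""
    flow = np.asarray(flow, dtype=np.float64)
    mask = np.asarray(mask, bool)
    if mask.shape != flow.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} != field shape {flow.shape[:2]}")
    out = flow.copy()
    out[mask] = 0.0
    return out


def collate_interleaved(fields: list[EncodedField], stride: int = 1) -> InterleavedDataset:
    """Sliding triples: item k is x = stack(field[k], field[k+2]), y = field[k+1].

    With stride 1 this yields n - 2 items from n fields.
    """
    if len(fields) < 3:
        raise ValueError("need at least 3 fields to collate")
    xs, ys = [], []
    for k in range(0, len(fields) - 2, stride):
        xs.append(np.concatenate([fields[k].data, fields[k + 2].data], axis=-1))
        ys.append(fields[k + 1].data.copy())
    return InterleavedDataset(xs, ys)


def _transform_field(arr: np.ndarray, op: str) -> np.ndarray:
    """Apply a spatial transform to both the grid and the vector components.

    ``arr`` is (h, w, 2k): channels alternate pairs (vx, vy). Mirroring a
    vector field flips the corresponding component; quarter rotations also
    exchange components: rot90 maps (vx, vy) -> (-vy, vx).
    """
    pairs = arr.shape[-1] // 2
    vx = arr[..., 0::2]
    vy = arr[..., 1::2]
    if op == "hflip":
        vx, vy = -vx[:, ::-1], vy[:, ::-1]
    elif op == "vflip":
        vx, vy = vx[::-1, :], -vy[::-1, :]
    elif op == "rot90":
        # grid point (r, c) -> (H-1-c, r), so displacement (vx, vy) -> (vy, -vx)
        vx, vy = np.rot90(vy), -np.rot90(vx)
    elif op == "rot180":
        vx, vy = -np.rot90(vx, 2), -np.rot90(vy, 2)
    elif op == "rot270":
        vx, vy = -np.rot90(vy, 3), np.rot90(vx, 3)
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    out = np.empty(vx.shape[:2] + (2 * pairs,), dtype=arr.dtype)
    out[..., 0::2] = vx
    out[..., 1::2] = vy
    return out


AUGMENT_OPS = ("hflip", "vflip", "rot90", "rot180", "rot270")


def augment(ds: InterleavedDataset, ops=("hflip", "vflip", "rot180")) -> InterleavedDataset:
    """Append transformed copies of every item; originals are preserved.

    Each transformed copy inherits its source item's split tag, so
    augmenting after splitting cannot leak between train and validation.
    """
    for op in ops:
        if op not in AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {op!r}")
    xs = list(ds.x)
    ys = list(ds.y)
    tags = list(ds.tags)
    for op in ops:
        for x, y, tag in zip(ds.x, ds.y, ds.tags):
            xs.append(_transform_field(x, op))
            ys.append(_transform_field(y, op))
            tags.append(tag)
    return InterleavedDataset(xs, ys, tags)


def split_dataset(
    ds: InterleavedDataset, train_fraction: float = 0.9, seed: int = 0
) -> tuple[InterleavedDataset, InterleavedDataset]:
    """Deterministic shuffled train/validation split at the stated fraction."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(ds))
    n_train = int(round(train_fraction * len(ds)))
    tr = idx[:n_train]
    va = idx[n_train:]

    def take(ind, tag):
        return InterleavedDataset(
            [ds.x[i] for i in ind], [ds.y[i] for i in ind], [tag] * len(ind)
        )

    return take(tr, "train"), take(va, "val")


def save_dataset(path: str | Path, ds: InterleavedDataset, attrs: dict | None = None) -> None:
    x, y = ds.arrays()
    with h5py.File(path, "w") as fh:
        fh.create_dataset("x", data=x.astype(np.float32))
        fh.create_dataset("y", data=y.astype(np.float32))
        tags = np.array([t or "" for t in ds.tags], dtype="S8")
        fh.create_dataset("tags", data=tags)
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v


def load_dataset(path: str | Path) -> InterleavedDataset:
    with h5py.File(path, "r") as fh:
        x = [np.asarray(a, np.float64) for a in fh["x"]]
        y = [np.asarray(a, np.float64) for a in fh["y"]]
        tags = [t.decode() or None for t in fh["tags"][...]]
    return InterleavedDataset(x, y, tags)
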