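"""FieldNet: the U-Net-style flow-field interpolation network.

Given the encoded flow fields at times t and t+2 stacked into an
(h, w, 4) input, the network predicts the encoded intermediate field at
t+1 of shape (h, w, 2). Because the encoding lives in [-1, 1], every
layer uses the hyperbolic tangent activation. Skip connections at the two
encoder levels preserve the spatial arrangement of the vectors, which is
what lets the model keep coherent plume structure (including vortex-like
patterns) while suppressing background noise.

Architecture (input + 18 layers): two encoder blocks (conv3x3-tanh x2,
2x2 max pool, dropout), a bottleneck block (conv3x3-tanh x2, dropout),
two decoder blocks (2x upsample, skip concat, conv3x3-tanh x2), and a
final 1x1 conv with tanh -- 11 convolutions, 2 pools, 2 upsamples, 3
dropouts. The reference configuration uses channel widths (202, 404, 808),
giving 18,740,754 trainable parameters (18.7 M). The desk-scale default
(64 x 64 input, widths 16/32/64) trains in minutes on one CPU.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .encoding import EncodedField, InterleavedDataset

__all__ = [
    "FieldNetConfig",
    "TrainedFieldNet",
    "reference_config",
    "build_fieldnet",
    "count_parameters",
    "train_fieldnet",
    "predict_intermediate",
    "predict_sequence",
    "save_fieldnet",
    "load_fieldnet",
]


@dataclass
class FieldNetConfig:
    """Hyperparameters of the interpolation network.

    ``base_channels`` sets the first encoder width; the two deeper levels
    double and quadruple it. ``h`` and ``w`` must be divisible by
    2**depth so pooling and upsampling tile exactly.
    """

    h: int = 64
    w: int = 64
    base_channels: int = 16
    depth: int = 2
    skip_levels: int = 2
    dropout: float = 0.025
    learning_rate: float = 1.0e-3
    batch_size: int = 16
    epochs: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        div = 2**self.depth
        if self.h % div or self.w % div:
            raise ValueError(f"h and w must be divisible by {div}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def widths(self) -> tuple[int, int, int]:
        return (self.base_channels, 2 * self.base_channels, 4 * self.base_channels)


def reference_config() -> FieldNetConfig:
    """The frozen full-scale configuration: widths (202, 404, 808), 18.7 M params."""
    return FieldNetConfig(h=64, w=64, base_channels=202, batch_size=64, epochs=16)


class _UNet(nn.Layer):
    """Depth-2 encoder-decoder with two skip concatenations, all-tanh."""

    def __init__(self, widths: tuple[int, int, int], dropout: float, rng: np.random.Generator):
        c1, c2, c3 = widths
        R = rng
        self.e11 = nn.Conv2D(4, c1, 3, R)
        self.e12 = nn.Conv2D(c1, c1, 3, R)
        self.pool1 = nn.MaxPool2D()
        self.drop1 = nn.Dropout(dropout, R)
        self.e21 = nn.Conv2D(c1, c2, 3, R)
        self.e22 = nn.Conv2D(c2, c2, 3, R)
        self.pool2 = nn.MaxPool2D()
        self.drop2 = nn.Dropout(dropout, R)
        self.b1 = nn.Conv2D(c2, c3, 3, R)
        self.b2 = nn.Conv2D(c3, c3, 3, R)
        self.drop3 = nn.Dropout(dropout, R)
        self.up1 = nn.Upsample2D()
        self.d11 = nn.Conv2D(c3 + c2, c2, 3, R)
        self.d12 = nn.Conv2D(c2, c2, 3, R)
        self.up2 = nn.Upsample2D()
        self.d21 = nn.Conv2D(c2 + c1, c1, 3, R)
        self.d22 = nn.Conv2D(c1, c1, 3, R)
        self.final = nn.Conv2D(c1, 2, 1, R)
        self._convs = [
            self.e11, self.e12, self.e21, self.e22, self.b1, self.b2,
            self.d11, self.d12, self.d21, self.d22, self.final,
        ]
        self._acts = [nn.Tanh() for _ in self._convs]
        self._c1, self._c2 = c1, c2

    def params(self):
        out = []
        for conv in self._convs:
            out.extend(conv.params())
        return out

    def forward(self, x, train=False):
        a = self._acts
        s1 = a[0].forward(self.e11.forward(x, train), train)
        s1 = a[1].forward(self.e12.forward(s1, train), train)
        h = self.drop1.forward(self.pool1.forward(s1, train), train)
        s2 = a[2].forward(self.e21.forward(h, train), train)
        s2 = a[3].forward(self.e22.forward(s2, train), train)
        h = self.drop2.forward(self.pool2.forward(s2, train), train)
        h = a[4].forward(self.b1.forward(h, train), train)
        h = a[5].forward(self.b2.forward(h, train), train)
        h = self.drop3.forward(h, train)
        h = self.up1.forward(h, train)
        h = np.concatenate([h, s2], axis=-1)
        h = a[6].forward(self.d11.forward(h, train), train)
        h = a[7].forward(self.d12.forward(h, train), train)
        h = self.up2.forward(h, train)
        h = np.concatenate([h, s1], axis=-1)
        h = a[8].forward(self.d21.forward(h, train), train)
        h = a[9].forward(self.d22.forward(h, train), train)
        return a[10].forward(self.final.forward(h, train), train)

    def backward(self, g):
        a = self._acts
        g = self.final.backward(a[10].backward(g))
        g = self.d22.backward(a[9].backward(g))
        g = self.d21.backward(a[8].backward(g))
        g_s1 = g[..., -self._c1 :]
        g = self.up2.backward(g[..., : -self._c1])
        g = self.d12.backward(a[7].backward(g))
        g = self.d11.backward(a[6].backward(g))
        g_s2 = g[..., -self._c2 :]
        g = self.up1.backward(g[..., : -self._c2])
        g = self.drop3.backward(g)
        g = self.b2.backward(a[5].backward(g))
        g = self.b1.backward(a[4].backward(g))
        g = self.pool2.backward(self.drop2.backward(g))
        g = self.e22.backward(a[3].backward(g)) + g_s2
        g = self.e21.backward(a[2].backward(g))
        g = self.pool1.backward(self.drop1.backward(g))
        g = self.e12.backward(a[1].backward(g)) + g_s1
        g = self.e11.backward(a[0].backward(g))
        return g


@dataclass
class TrainedFieldNet:
    """Network + config + per-epoch train/val MSE history."""

    net: _UNet
    config: FieldNetConfig
    history: list[dict] = dc_field(default_factory=list)


def build_fieldnet(config: FieldNetConfig) -> TrainedFieldNet:
    """Instantiate an (untrained) FieldNet from its configuration."""
    rng = np.random.default_rng(config.seed)
    net = _UNet(config.widths, config.dropout, rng)
    return TrainedFieldNet(net=net, config=config)


def count_parameters(model: TrainedFieldNet) -> int:
    """Total trainable parameter count (weights + biases of all convs)."""
    return nn.count_parameters(model.net)


def _dataset_arrays(ds: InterleavedDataset, config: FieldNetConfig):
    x, y = ds.arrays()
    if x.shape[1:] != (config.h, config.w, 4) or y.shape[1:] != (config.h, config.w, 2):
        raise ValueError(
            f"dataset shapes {x.shape[1:]} / {y.shape[1:]} do not match config "
            f"({config.h}, {config.w})"
        )
    return x, y


def train_fieldnet(
    model: TrainedFieldNet,
    train: InterleavedDataset,
    val: InterleavedDataset | None = None,
    epochs: int | None = None,
) -> TrainedFieldNet:
    """MSE training with Adam at the configured learning rate and batch size."""
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    cfg = model.config
    X, Y = _dataset_arrays(train, cfg)
    Xv = Yv = None
    if val is not None and len(val):
        Xv, Yv = _dataset_arrays(val, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    hist = nn.fit(
        model.net,
        X,
        Y,
        epochs=epochs if epochs is not None else cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        rng=rng,
        X_val=Xv,
        Y_val=Yv,
    )
    model.history.extend(hist)
    return model


def evaluate_mse(model: TrainedFieldNet, ds: InterleavedDataset) -> float:
    X, Y = _dataset_arrays(ds, model.config)
    pred = nn.predict(model.net, X, batch_size=model.config.batch_size)
    return float(np.mean((pred - Y.astype(np.float32)) ** 2))


def predict_intermediate(
    model: TrainedFieldNet, f_t: EncodedField, f_t2: EncodedField
) -> EncodedField:
    """Predict the encoded intermediate field between two encoded fields.

    Inference is deterministic (dropout disabled). The prediction's
    decoding scale is the larger of the two input scales.
    """
    x = np.concatenate([f_t.data, f_t2.data], axis=-1)[None].astype(np.float32)
    if x.shape[1:3] != (model.config.h, model.config.w):
        raise ValueError("input field shape does not match the model configuration")
    out = model.net.forward(x, train=False)[0].astype(np.float64)
    return EncodedField(out, max(f_t.n_max, f_t2.n_max))


def predict_sequence(model: TrainedFieldNet, fields: list[EncodedField]) -> list[EncodedField]:
    """Predict intermediate fields for every (t, t+2) pair of a sequence (n-2 outputs)."""
    if len(fields) < 3:
        raise ValueError("need at least 3 fields")
    X = np.stack(
        [
            np.concatenate([fields[k].data, fields[k + 2].data], axis=-1)
            for k in range(len(fields) - 2)
        ]
    ).astype(np.float32)
    out = nn.predict(model.net, X, batch_size=model.config.batch_size)
    return [
        EncodedField(out[k].astype(np.float64), max(fields[k].n_max, fields[k + 2].n_max))
        for k in range(len(out))
    ]


def save_fieldnet(model: TrainedFieldNet, path: str | Path) -> None:
    """Weights as NPZ next to a YAML config and CSV history."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.params())}
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(model.config.__dict__, fh)
    if model.history:
        with open(path.with_suffix(".history.csv"), "w", newline="") as fh:
            keys = list(model.history[0])
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            w.writerows(model.history)


def load_fieldnet(path: str | Path) -> TrainedFieldNet:
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        config = FieldNetConfig(**yaml.safe_load(fh))
    model = build_fieldnet(config)
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.net.params()):
        p.value[...] = data[f"p{i}"]
    return model
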