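"""Exhale-segment denoising autoencoder and reference-based anomaly scoring.

Two small 1-D convolutional models operate on fixed-length (256) exhale
segments:

* a filtering autoencoder (two stride-2 conv layers down to a 32-channel
  latent of length 64, two transposed-conv layers back up, relu, kernel 7)
  trained with identity targets to suppress turbulent per-exhale variance;
* an anomaly scorer trained on the cross product of a reference set of
  regular exhale shapes with a mixed input set. Each training pair maps an
  input segment to the elementwise error waveform e(t) = |ref(t) - x(t)|,
  so the trained network predicts the expected divergence of a new segment
  from the reference population. The scalar anomaly summary is the mean of
  the predicted error waveform (the max is reported alongside).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import nn
from .waveform import SEGMENT_LENGTH, ExhaleSegment

__all__ = [
    "AnomalyTrainingPair",
    "AnomalyScore",
    "train_autoencoder",
    "denoise_segment",
    "build_anomaly_training_set",
    "train_anomaly_model",
    "score_segment",
    "write_scores_csv",
]

KERNEL = 7
LATENT_CHANNELS = 32
DEFAULT_EPOCHS = 50
LEARNING_RATE = 1.0e-3


@dataclass
class AnomalyTrainingPair:
    """(input segment, elementwise |ref - input| error waveform) with provenance."""

    x: np.ndarray
    y: np.ndarray
    ref_id: int
    input_id: int


@dataclass
class AnomalyScore:
    """Predicted error waveform plus scalar summaries."""

    error_waveform: np.ndarray
    summary: float
    max_error: float


@dataclass
class TrainedModel1D:
    net: nn.Sequential
    history: list[dict] = dc_field(default_factory=list)


def _segment_matrix(segments: list[ExhaleSegment]) -> np.ndarray:
    return np.stack([s.values for s in segments]).astype(np.float32)[..., None]


def _build_autoencoder(rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Conv1D(1, LATENT_CHANNELS, KERNEL, 2, rng),
            nn.ReLU(),
            nn.Conv1D(LATENT_CHANNELS, LATENT_CHANNELS, KERNEL, 2, rng),
            nn.ReLU(),
            nn.ConvTranspose1D(LATENT_CHANNELS, LATENT_CHANNELS, KERNEL, 2, rng),
            nn.ReLU(),
            nn.ConvTranspose1D(LATENT_CHANNELS, 1, KERNEL, 2, rng),
            nn.ReLU(),
        ]
    )


def _build_scorer(rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Conv1D(1, 32, KERNEL, 1, rng),
            nn.ReLU(),
            nn.Conv1D(32, 32, KERNEL, 1, rng),
            nn.ReLU(),
            nn.Conv1D(32, 1, KERNEL, 1, rng),
            nn.ReLU(),
        ]
    )


def _fit_1d(
    net: nn.Sequential,
    X: np.ndarray,
    Y: np.ndarray,
    seed: int,
    epochs: int,
    batch_size: int = 32,
) -> list[dict]:
    """Train with a held-out 10% for early stopping (patience 5)."""
    rng = np.random.default_rng(seed)
    n = len(X)
    idx = rng.permutation(n)
    n_val = max(1, n // 10) if n >= 5 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    return nn.fit(
        net,
        X[tr_idx],
        Y[tr_idx],
        epochs=epochs,
        batch_size=batch_size,
        lr=LEARNING_RATE,
        rng=rng,
        X_val=X[val_idx] if n_val else None,
        Y_val=Y[val_idx] if n_val else None,
        patience=5 if n_val else None,
    )


def train_autoencoder(
    segments: list[ExhaleSegment], seed: int = 0, epochs: int = DEFAULT_EPOCHS
) -> TrainedModel1D:
    """Train the identity-target filtering autoencoder on exhale segments."""
    if len(segments) == 0:
        raise ValueError("need at least one segment")
    X = _segment_matrix(segments)
    net = _build_autoencoder(np.random.default_rng(seed))
    history = _fit_1d(net, X, X, seed + 1, epochs)
    return TrainedModel1D(net=net, history=history)


def denoise_segment(model: TrainedModel1D, segment: ExhaleSegment) -> ExhaleSegment:
    """Reconstruct a segment through the autoencoder (deterministic)."""
    out = nn.predict(model.net, segment.values.astype(np.float32)[None, :, None])
    return ExhaleSegment(
        values=np.clip(out[0, :, 0].astype(np.float64), 0.0, None),
        source_bounds=segment.source_bounds,
        label=segment.label,
    )


def build_anomaly_training_set(
    refs: list[ExhaleSegment], inputs: list[ExhaleSegment]
) -> list[AnomalyTrainingPair]:
    """Full reference x input cross product: |refs| * |inputs| pairs.

    Each pair's target is the elementwise absolute difference between the
    reference and the input segment.
    """
    if len(refs) == 0 or len(inputs) == 0:
        raise ValueError("reference and input sets must be non-empty")
    for s in list(refs) + list(inputs):
        if s.values.shape != (SEGMENT_LENGTH,):
            raise ValueError(f"all segments must have length {SEGMENT_LENGTH}")
    pairs = []
    for i, ref in enumerate(refs):
        for j, x in enumerate(inputs):
            pairs.append(
                AnomalyTrainingPair(
                    x=x.values.copy(),
                    y=np.abs(ref.values - x.values),
                    ref_id=i,
                    input_id=j,
                )
            )
    return pairs


def train_anomaly_model(
    pairs: list[AnomalyTrainingPair], seed: int = 0, epochs: int = DEFAULT_EPOCHS
) -> TrainedModel1D:
    """Train the error-waveform predictor on (input, |ref - input|) pairs."""
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    X = np.stack([p.x for p in pairs]).astype(np.float32)[..., None]
    Y = np.stack([p.y for p in pairs]).astype(np.float32)[..., None]
    net = _build_scorer(np.random.default_rng(seed))
    history = _fit_1d(net, X, Y, seed + 1, epochs)
    return TrainedModel1D(net=net, history=history)


def score_segment(
    model: TrainedModel1D,
    segment: ExhaleSegment,
    denoiser: TrainedModel1D | None = None,
) -> AnomalyScore:
    """Predicted anomaly error waveform and its mean/max summaries.

    If a denoiser is given the segment is filtered through the
    autoencoder first (the default pipeline order); pass ``denoiser=None``
    to bypass. Deterministic for fixed weights.
    """
    if segment.values.shape != (SEGMENT_LENGTH,):
        raise ValueError(f"segment must have length {SEGMENT_LENGTH}")
    if denoiser is not None:
        segment = denoise_segment(denoiser, segment)
    out = nn.predict(model.net, segment.values.astype(np.float32)[None, :, None])
    err = np.clip(out[0, :, 0].astype(np.float64), 0.0, None)
    return AnomalyScore(
        error_waveform=err, summary=float(err.mean()), max_error=float(err.max())
    )


def write_scores_csv(path: str | Path, scores: list[AnomalyScore], labels=None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["segment_id", "summary", "max_error", "label"])
        for i, s in enumerate(scores):
            lab = labels[i] if labels is not None else ""
            w.writerow([i, f"{s.summary:.8g}", f"{s.max_error:.8g}", lab])
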