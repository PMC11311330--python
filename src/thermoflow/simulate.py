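"""Synthetic thermal exhale sequences with ground truth.

Emulates what a mid-wavelength infrared camera records during natural
breathing: an ambient background around 6000 counts with Gaussian sensor
noise, a warmer face region (about 8800 counts) carrying smooth trackable
texture and slow positional drift, and a turbulent CO2 plume emitted in
episodic exhales from a nozzle at the face's right edge. The plume is a
passive scalar advected semi-Lagrangically by a base rightward velocity
plus seeded curl-noise turbulence, blurred by Gaussian diffusion and
attenuated by multiplicative decay each frame, so each exhale burst
rapidly dissipates toward the noise floor -- the regime the measurement
pipeline has to cope with.

Every stage is deterministic per seed, and the generator returns the exact
emission schedule, face trajectory, and per-exhale normal/anomalous labels
so downstream stages can be tested against ground truth. Anomalous exhales
are amplitude-scaled by U(1.3, 1.8) and duration-scaled by U(0.5, 0.7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .rawio import NormalizationParams, ThermalSequence, write_sequence
from .tracking import RegionOfInterest

__all__ = [
    "PlumeParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_breathing_schedule",
    "simulate_sequence",
    "make_cohort",
    "exhale_norm_params",
    "tracking_norm_params",
    "write_simulation",
]


@dataclass
class PlumeParams:
    """Passive-scalar plume dynamics, in pixels/frame units."""

    emission_amplitude: float = 1.0
    diffusion: float = 0.8  # Gaussian sigma per frame
    advection: tuple[float, float] = (1.8, -0.2)  # (vx, vy): rightward, slightly up
    decay: float = 0.92  # multiplicative per frame
    turbulence: float = 0.5  # curl-noise velocity scale


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic recording.

    Defaults emulate indoor thermal counts (ambient 6000, face 8800,
    within the typical 5000-9000 range) at quarter scale (128 x 160) and
    25 Hz; full 512 x 640 generation is just a parameter change.
    """

    h: int = 128
    w: int = 160
    fps: float = 25.0
    duration_s: float = 20.0
    ambient_count: float = 6000.0
    face_count: float = 8800.0
    noise_sd: float = 15.0
    breaths_per_min: float = 12.0
    drift_speed: float = 0.05  # random-walk step sd, px/frame
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # deterministic (drow, dcol)/frame
    plume: PlumeParams = dc_field(default_factory=PlumeParams)
    anomaly_fraction: float = 0.0
    roi_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.anomaly_fraction <= 1:
            raise ValueError("anomaly_fraction must be in [0, 1]")
        if self.ambient_count >= self.face_count:
            raise ValueError("ambient_count must be below face_count")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """Generator-side truth for validating every pipeline stage."""

    emission_series: np.ndarray  # per-frame emission rate
    exhale_labels: list[str]  # "normal" | "anomalous", per exhale
    exhale_spans: list[tuple[int, int]]  # (onset, end) frame indices
    face_trajectory: np.ndarray  # (n, 2) float (row_off, col_off) of the face
    plume_velocity: np.ndarray  # (n, 2) mean (vx, vy) of the plume advection
    initial_roi: RegionOfInterest | None = None
    face_box: tuple[int, int, int, int] | None = None  # r0, r1, c0, c1 at zero offset


# breath pulse shape constants (seconds); expiration occupies roughly the
# first half of a natural breathing cycle
RISE_S = 0.35
TAU_S = 0.8
DUR_S = 2.2


def simulate_breathing_schedule(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[str], list[tuple[int, int]]]:
    """Episodic emission series: raised-cosine rise, exponential decay, zero between.

    Onset times and amplitudes are jittered; a seeded fraction of exhales
    is perturbed (higher amplitude, shorter duration) and labeled
    anomalous. Returns (per-frame emission, labels, exhale frame spans).
    """
    if config.breaths_per_min <= 0:
        raise ValueError("breaths_per_min must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_frames
    emission = np.zeros(n)
    labels: list[str] = []
    spans: list[tuple[int, int]] = []
    interval = 60.0 / config.breaths_per_min
    t_on = 0.4 * interval
    while t_on < config.duration_s - 0.5:
        amp = 1.0 + 0.15 * rng.standard_normal()
        amp = max(amp, 0.3)
        dur = min(DUR_S, 0.85 * interval)
        anomalous = rng.random() < config.anomaly_fraction
        if anomalous:
            amp *= rng.uniform(1.3, 1.8)
            dur *= rng.uniform(0.5, 0.7)
        f0 = int(round(t_on * config.fps))
        f1 = min(n, int(round((t_on + dur) * config.fps)))
        if f0 >= n:
            break
        rise = min(RISE_S, 0.4 * dur)
        for f in range(f0, f1):
            tt = (f - f0) / config.fps
            if tt < rise:
                emission[f] += amp * 0.5 * (1 - np.cos(np.pi * tt / rise))
            else:
                emission[f] += amp * np.exp(-(tt - rise) / TAU_S)
        labels.append("anomalous" if anomalous else "normal")
        spans.append((f0, f1))
        t_on += interval * (1.0 + 0.08 * rng.standard_normal())
    return emission, labels, spans


def _curl_noise(rng: np.random.Generator, shape, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Divergence-free velocity perturbation from a smoothed random potential."""
    psi = ndimage.gaussian_filter(rng.standard_normal(shape), 5.0)
    gr, gc = np.gradient(psi)
    mag = np.sqrt(gr * gr + gc * gc).max()
    if mag == 0:
        return np.zeros(shape), np.zeros(shape)
    k = scale / mag
    return gr * k, -gc * k  # (vx, vy) = (dpsi/dr, -dpsi/dc): curl of psi z-hat


def simulate_sequence(config: SimulationConfig) -> tuple[ThermalSequence, GroundTruth]:
    """Render a full synthetic recording plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    emission, labels, spans = simulate_breathing_schedule(config, rng.spawn(1)[0])
    h, w, n = config.h, config.w, config.n_frames
    pl = config.plume

    # static face geometry at zero offset; drift moves it
    r0, r1 = int(0.20 * h), int(0.80 * h)
    c0, c1 = 0, int(0.35 * w)
    tex_pad = 32
    texture = ndimage.gaussian_filter(
        rng.standard_normal((h + 2 * tex_pad, w + 2 * tex_pad)), 1.2
    )
    texture *= 150.0 / texture.std()

    R, C = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((n, h, w), dtype=np.uint16)
    offsets = np.zeros((n, 2))
    vel_series = np.zeros((n, 2))
    P = np.zeros((h, w))
    off = np.zeros(2)
    noz_r0 = 0.5 * (r0 + r1)
    render_scale = 0.9 * (config.face_count - config.ambient_count)

    for t in range(n):
        offsets[t] = off
        tvx, tvy = _curl_noise(rng, (h, w), pl.turbulence)
        vx = pl.advection[0] + tvx
        vy = pl.advection[1] + tvy
        vel_series[t] = (pl.advection[0], pl.advection[1])
        # semi-Lagrangian advection: pull back along the velocity field
        P = ndimage.map_coordinates(P, [R - vy, C - vx], order=1, mode="constant")
        if pl.diffusion > 0:
            P = ndimage.gaussian_filter(P, pl.diffusion)
        P *= pl.decay
        if emission[t] > 0 and pl.emission_amplitude > 0:
            nr = noz_r0 + off[0]
            nc = c1 + off[1] + 2.0
            d2 = (R - nr) ** 2 + (C - nc) ** 2
            P += 0.5 * emission[t] * pl.emission_amplitude * np.exp(-d2 / (2 * 2.5**2))

        # soft saturation keeps the rendered plume below face temperature while
        # preserving internal intensity gradients (a hard clip would flatten the core)
        img = config.ambient_count + (1.0 - np.exp(-np.clip(P, 0.0, None))) * render_scale
        face = (
            (R >= r0 + off[0]) & (R <= r1 + off[0]) & (C >= c0) & (C <= c1 + off[1])
        )
        tex = ndimage.map_coordinates(
            texture,
            [R + tex_pad - off[0], C + tex_pad - off[1]],
            order=1,
            mode="nearest",
        )
        img[face] = config.face_count + tex[face]
        img += rng.normal(0.0, config.noise_sd, size=(h, w))
        frames[t] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

        step = rng.normal(0.0, config.drift_speed, size=2)
        off = off + step + np.asarray(config.drift_velocity)
        # keep the face inside the frame
        off[0] = np.clip(off[0], -r0 + 1, h - r1 - 2)
        off[1] = np.clip(off[1], -1.0, w - c1 - 2)

    roi_size = config.roi_size
    roi_row = int(np.clip(round(noz_r0 - roi_size / 2), 0, h - roi_size))
    roi_col = int(np.clip(c1 - roi_size // 4, 0, w - roi_size))
    gt = GroundTruth(
        emission_series=emission,
        exhale_labels=labels,
        exhale_spans=spans,
        face_trajectory=offsets,
        plume_velocity=vel_series,
        initial_roi=RegionOfInterest(roi_row, roi_col, roi_size, roi_size),
        face_box=(r0, r1, c0, c1),
    )
    return ThermalSequence(frames=frames, fps=config.fps), gt


def make_cohort(
    config: SimulationConfig, n_subjects: int
) -> list[tuple[ThermalSequence, GroundTruth]]:
    """Per-subject parameter draws so waveform signatures differ across subjects."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(config.seed)
    out = []
    for i in range(n_subjects):
        sub = np.random.default_rng(config.seed + 1000 * (i + 1))
        angle = sub.uniform(-0.25, 0.25)
        speed = sub.uniform(1.4, 2.2)
        cfg = SimulationConfig(
            h=config.h,
            w=config.w,
            fps=config.fps,
            duration_s=config.duration_s,
            ambient_count=config.ambient_count,
            face_count=config.face_count,
            noise_sd=config.noise_sd,
            breaths_per_min=float(sub.uniform(8.0, 16.0)),
            drift_speed=config.drift_speed,
            drift_velocity=config.drift_velocity,
            plume=PlumeParams(
                emission_amplitude=float(sub.uniform(0.8, 1.3)),
                diffusion=config.plume.diffusion,
                advection=(float(speed * np.cos(angle)), float(speed * np.sin(angle))),
                decay=float(sub.uniform(0.90, 0.94)),
                turbulence=config.plume.turbulence,
            ),
            anomaly_fraction=config.anomaly_fraction,
            roi_size=config.roi_size,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        out.append(simulate_sequence(cfg))
    return out


def exhale_norm_params(seq: ThermalSequence, gt: GroundTruth) -> NormalizationParams:
    """Exhale normalization anchors: ambient median and 99th-percentile face count."""
    frame = seq.frames[0].astype(float)
    h, w = frame.shape
    bg = frame[: h // 4, 3 * w // 4 :]  # top-right corner: plume-free background
    r0, r1, c0, c1 = gt.face_box
    face = frame[r0:r1, c0:c1]
    return NormalizationParams(
        Fc=float(np.percentile(face, 99)),
        Ac=float(np.median(bg)),
        Imax=float(frame.max()),
    )


def tracking_norm_params(seq: ThermalSequence, gt: GroundTruth) -> NormalizationParams:
    """Tracking normalization spans the ROI's median count up to the image maximum.

    A low anchor at the ROI median (instead of the face's high percentile)
    keeps the facial texture spread over the upper half of [0, 1], which
    is what the corner detector and Lucas-Kanade step need.
    """
    frame = seq.frames[0].astype(float)
    roi = gt.initial_roi
    crop = roi.crop(frame)
    lo = float(np.median(crop))
    hi = float(frame.max())
    return NormalizationParams(Fc=lo, Ac=lo - 1.0, Imax=hi)


def write_simulation(
    path_prefix: str | Path, seq: ThermalSequence, gt: GroundTruth, config: SimulationConfig
) -> None:
    """Raw binary sequence plus a JSON ground-truth/config sidecar."""
    prefix = Path(path_prefix)
    write_sequence(seq, prefix.with_suffix(".raw"))
    roi = gt.initial_roi
    sidecar = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "plume"},
            "plume": asdict(config.plume),
        },
        "emission_series": gt.emission_series.tolist(),
        "exhale_labels": gt.exhale_labels,
        "exhale_spans": [list(s) for s in gt.exhale_spans],
        "face_trajectory": gt.face_trajectory.tolist(),
        "face_box": list(gt.face_box),
        "initial_roi": [roi.row0, roi.col0, roi.height, roi.width],
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)
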