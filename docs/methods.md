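# Methods

This note documents the models and numerical choices behind `thermoflow`,
the assumptions they rest on, and what the synthetic study conditions do
and do not establish about real recordings.

## Acquisition model and normalization

Input is a headerless binary stream of 16-bit sensor counts, frame-major
and row-major, little-endian by default (a flag covers big-endian
sources). Indoors, counts concentrate around 5000–9000. Two linear maps
put counts into [0, 1]:

* tracking: `[Fc, Imax] → [0, 1]`, emphasizing facial texture;
* exhale: `[Ac, Fc] → [0, 1]`, the ambient-to-face interval in which
  plume intensities live.

`Ac` is estimated as the median count of a background window (the median
resists hot pixels); `Fc` as the 99th percentile of the face region. For
the *tracking* map we anchor the low end at the ROI's median count rather
than at the 99th-percentile face count: anchoring at the top percentile
would clamp nearly the entire face to zero and leave the corner detector
nothing to work with. Out-of-interval values clamp to {0, 1} by design —
each map deliberately targets a sub-range of the observed counts.

## ROI tracking

A fixed-size nose–mouth window (matching the flow model's input size) is
tracked by: Shi–Tomasi minimum-eigenvalue corners inside the window
(reflective-border structure tensor, threshold 0.05 of the maximum
response, refreshed every 25 frames or when fewer than 3 points survive),
iterative single-level Lucas–Kanade displacement per key-point (15×15
window, 10 iterations), median aggregation, and integer rounding with a
±0.5 px dead-band. The sub-pixel residual is accumulated across frames so
slow drift is not permanently absorbed by the dead-band. On generator
sequences with drift up to 1 px/frame the mean absolute position error
stays well under 1 px over 200 frames.

ROI motion must not masquerade as airflow. We remove it by
inverse-transforming the *sampling window*: both frames of a pair are
cropped at the leading frame's ROI, so static background is genuinely
static in the pair and the solver sees no induced shift. The alternative
— solving on crops at each frame's own ROI and subtracting the induced
uniform motion from the solved field — is also implemented
(`compensation="field"`), but it fabricates uniform flow over textureless
background, where a correct solver reports near-zero motion; summed over
thousands of pixels this produced large spurious waveform spikes at every
integer ROI step, which is why window-mode is the default. Face-own
motion that remains inside the crop is real motion and is removed by the
face mask (tracking-normalized value > 0.85, dilated 2 px) before
encoding.

## Dense flow

The flow field between consecutive exhale-normalized crops minimizes the
brightness-constancy + smoothness energy with weight α, iterated from
v = 0:

    v ← v̄ − ∇I (∇I·v̄ + I_t) / (α + I_x² + I_y²)

Choices, in order of likely surprise:

* The denominator uses α, not the α² of some classical write-ups. α is a
  plain parameter, so either convention is reachable by passing α or α².
  Default α = 0.15: small, so intensity shifts near the sensor noise
  floor still contribute flow — the dissipating plume tail is signal
  here, not noise.
* Spatial gradients: 3×3 Sobel normalized by 1/8 (unit ramp → unit
  gradient), reflective borders, taken on the first frame. Temporal
  derivative: pointwise difference.
* Neighborhood average v̄: the standard 3×3 stencil (4-neighbors 1/6,
  diagonals 1/12), reflective borders.
* Fixed n_iter = 64 by default; an early-stop tolerance on the mean
  absolute update is available but off, preserving bitwise determinism.
  Identical frames give an exactly zero field for any iteration count
  (zero is a fixed point and the initializer).

A loop-based re-implementation of the same update (used only in tests)
agrees with the vectorized solver to 10⁻¹⁰ on small instances. Note that
64 Jacobi-style iterations recover only part of a unit displacement on
smooth texture (convergence is slow); this under-estimation is uniform
across the sequence and cancels in all relative quantities the pipeline
reports.

## Encoding, interleaving, augmentation

Fields are normalized per component by the maximum vector magnitude
`n_max` into [−1, 1]². The scope of `n_max` defaults to the whole
sequence, keeping temporal magnitude comparability for the waveform
reduction. The angle encoding (sin θ, cos θ)·(n/m) is identically the
direct normalization with channels swapped (sin θ = v_y/n, cos θ =
v_x/n); `encode_angular` exists to make the equivalence checkable, and
the pipeline uses the cheaper direct form.

Training items interleave a sliding window of stride 1 (configurable to
2): x = (F⃗ₜ, F⃗ₜ₊₂) of shape (h, w, 4), y = F⃗ₜ₊₁. The acquisition
geometry always puts the subject on the left breathing rightward, so
augmentation appends mirrored and rotated copies. Spatial transforms act
on both the grid and the vector components (hflip negates v_x; rot90
maps (v_x, v_y) → (v_y, −v_x) to match the grid map (r, c) → (H−1−c, r));
restricting rotation to right angles avoids resampling. Augmented copies
inherit their source's train/validation tag, so augmenting after the
90/10 split cannot leak.

## FieldNet

An encoder–decoder with two skip concatenations predicts the encoded
intermediate field: two encoder blocks (conv3×3–tanh ×2, 2×2 max pool,
dropout), a bottleneck block (with dropout), two decoder blocks (2×
nearest upsample, skip concat, conv3×3–tanh ×2), and a 1×1 output conv
with tanh — input + 18 layers (11 convs, 2 pools, 3 dropouts, 2
upsamples). Tanh everywhere matches the [−1, 1] encoding. Training: MSE,
Adam at 10⁻³, dropout 0.025.

The reference configuration freezes channel widths (202, 404, 808),
giving 18,740,754 trainable parameters (18.7 M). The desk-scale
configuration used for tests is 64×64 input, widths (16, 32, 64), batch
size 16 — the smaller batch gives a small dataset enough optimizer steps
per epoch. All three networks in the package run on an in-package numpy
layer library (im2col convolutions, exact backward passes, Adam); no
external deep-learning framework is used, and inference is deterministic
(dropout disabled).

Interpolation inference feeds fields at t and t+2 and takes the predicted
field as the estimate at t+1; the prediction decodes with the larger of
the two input scales. The minimal quantitative claim — the trained
desk-scale model beats the two-frame arithmetic-average baseline in
held-out MSE after 4 epochs on ~500 synthetic fields — is asserted in the
test suite, along with the downstream consequence: the waveform built
from predicted fields has lower inter-breath baseline variance than the
raw optical-flow waveform of the same sequence. That comparison is run on
unmasked fields, where face-motion jitter provides the artifact noise the
network is meant to suppress; with the face analytically masked the
synthetic inter-breath fields are already near zero and there is nothing
left to denoise.

## Waveform, segmentation

f(t) = Σ |F⃗ₜ(i, j)| over the full ROI, masked zeros included, with no
area normalization (the ROI is fixed-size, so the constant would cancel).
Filtering is the three-step chain: outliers beyond 1.5 SD of the mean are
replaced by linear interpolation of their neighbors (replacement rather
than deletion keeps the sample grid aligned with frames); Savitzky–Golay,
window 9, polynomial order 3; min–max to [0, 1]. A constant signal cannot
be min–max normalized and returns all-zeros with a degenerate flag; the
degeneracy test uses a relative 10⁻⁹ range threshold so smoother float
jitter does not masquerade as signal.

Exhale episodes are isolated by peak detection (prominence ≥ 0.1 of the
normalized range, separation ≥ 0.5 s) and bounded by the minima between
consecutive peaks (waveform ends serve as outer boundaries). Adjacent
segments share boundary minima; each span is linearly resampled to 256
samples. Breathing rate is segment count over duration.

## Denoising autoencoder and anomaly model

The filtering autoencoder is Conv1D(1→32, k=7, stride 2) →
Conv1D(32→32, k=7, stride 2) → ConvTranspose1D(32→32, k=7, stride 2) →
ConvTranspose1D(32→1, k=7, stride 2), relu throughout: a 32-channel
latent at length 64, trained with identity targets (Adam 10⁻³, default
50 epochs with early stopping on a 10% holdout, patience 5).

The anomaly model is three Conv1D layers (k=7, widths 32–32–1, relu)
mapping a (256, 1) segment to a predicted error waveform. Its training
set is the full cross product of a reference set (n segments of regular
exhale shape) with a mixed input set (m segments), target
e(t) = |ref(t) − x(t)| — so n·m pairs exactly, and the trained network
approximates the expected elementwise divergence of an input from the
reference population. At inference a segment is passed through the
denoiser first (a bypass is available), and the clamped-nonnegative
predicted error waveform is summarized by its mean (the max is reported
alongside). On synthetic cohorts, "reference" means segments extracted
from recordings with no planted anomalies, and "anomalous" means exhales
the generator perturbed — labeling is a generator parameter, not an
algorithmic judgment.

## Synthetic study conditions

The generator emulates the statistical structure the pipeline assumes,
at quarter scale (128×160 at 25 Hz; full 512×640 is a parameter change):

* ambient background ≈ 6000 counts with Gaussian sensor noise (σ = 15);
* a warm face (≈ 8800 counts) with smooth random texture (σ ≈ 150
  counts), drifting by a seeded random walk and/or constant velocity;
* episodic exhale plumes from a nozzle at the face's right edge: a
  passive scalar advected semi-Lagrangically by a rightward base velocity
  plus divergence-free curl-noise turbulence, Gaussian diffusion,
  multiplicative decay ≈ 0.92/frame — each burst rapidly dissipates
  toward the noise floor;
* rendered brightness saturates softly (1 − e⁻ᴾ) below face temperature,
  preserving internal plume gradients;
* breathing schedule: raised-cosine rise (0.35 s), exponential decay
  (τ = 0.8 s), duration ≈ 2.2 s at 12/min — roughly the half-duty-cycle
  appearance of natural expiration; onsets, amplitudes jittered.
  Anomalous exhales get amplitude × U(1.3, 1.8) and duration
  × U(0.5, 0.7);
* cohorts draw per-subject rates (8–16/min), amplitudes, plume direction
  and decay from seeded distributions, so waveform signatures differ
  across subjects.

Everything is deterministic per seed. Problem sizes used in the test
suite: 20 s sequences (≈ 500 flow fields) for interpolation training, a
60 s clean sequence for references and a 120 s mixed sequence (35%
anomalies) for scoring, and five 20 s subjects for the 2500-field
training pool — sizes chosen so a single desk CPU reproduces every claim
in minutes.

What passing on this generator shows: the pipeline's stages compose
correctly, the interpolation network denoises real (simulated) turbulent
flow rather than memorizing it, rates are recovered to ±1/min, and
planted shape/amplitude perturbations are ranked above normal exhales.
What it does not show: robustness to real facial geometry and occlusion,
radiometric camera effects, out-of-plane plume projection, or clinical
discrimination between specific pulmonary conditions — all of which
require real cohorts.

## Known limitations

* The flow solver is single-level; large inter-frame displacements
  (> ~2 px on smooth structure) are under-estimated. At 25 Hz plume
  advection of 1–2 px/frame this is uniform attenuation, harmless to the
  relative waveform but not a calibrated velocity.
* f(t) is in arbitrary flow units; no conversion to L/s or clinical PFT
  quantities is attempted.
* The anomaly score is relative to its reference set; it is a screening
  signal, not a diagnosis.
* Segmentation assumes breathing episodes separated by ≥ 0.5 s minima;
  severely irregular or overlapping breaths merge into single segments.
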