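import numpy as np
import pytest
from hypothesis import given, strategies as st

import thermoflow as tf
from thermoflow.waveform import SEGMENT_LENGTH


def _template(amp=0.8, width=0.5, center=0.45, noise=0.0, seed=None):
    """Raised-cosine exhale template of length 256 in [0, 1]."""
    t = np.linspace(0, 1, SEGMENT_LENGTH)
    tt = (t - (center - width / 2)) / width
    v = np.where((tt >= 0) & (tt <= 1), amp * 0.5 * (1 - np.cos(2 * np.pi * tt)), 0.0)
    if noise > 0:
        v = v + noise * np.random.default_rng(seed).standard_normal(SEGMENT_LENGTH)
    return tf.ExhaleSegment(np.clip(v, 0.0, 1.0), (0, SEGMENT_LENGTH - 1))


def _ref_population(n, seed=0):
    gen = np.random.default_rng(seed)
    return [
        _template(
            amp=0.65 + 0.1 * gen.standard_normal(),
            width=0.5 + 0.05 * gen.standard_normal(),
            center=0.45 + 0.03 * gen.standard_normal(),
            noise=0.02,
            seed=int(gen.integers(1 << 30)),
        )
        for _ in range(n)
    ]


def _distorted(seed=0):
    """Amplitude-scaled x1.5 and time-warped (compressed) exhale."""
    gen = np.random.default_rng(seed)
    return _template(
        amp=min(1.5 * 0.65, 1.0),
        width=0.3,
        center=0.4,
        noise=0.02,
        seed=int(gen.integers(1 << 30)),
    )


class TestTrainingSet:
    def test_cross_product_size(self):
        pairs = tf.build_anomaly_training_set(_ref_population(4), _ref_population(7, seed=1))
        assert len(pairs) == 28

    @given(n=st.integers(1, 6), m=st.integers(1, 6))
    def test_size_is_n_times_m(self, n, m):
        pairs = tf.build_anomaly_training_set(
            _ref_population(n, seed=2), _ref_population(m, seed=3)
        )
        assert len(pairs) == n * m

    def test_identical_pair_zero_error(self):
        seg = _template()
        pairs = tf.build_anomaly_training_set([seg], [seg])
        assert np.all(pairs[0].y == 0)

    def test_absolute_difference_values(self):
        a = tf.ExhaleSegment(np.full(SEGMENT_LENGTH, 0.2), (0, 1))
        b = tf.ExhaleSegment(np.full(SEGMENT_LENGTH, 0.5), (0, 1))
        pairs = tf.build_anomaly_training_set([a], [b])
        assert np.allclose(pairs[0].y, 0.3)

    def test_error_properties_symmetric_nonneg_triangle(self, rng):
        a, b, c = (rng.random(SEGMENT_LENGTH) for _ in range(3))
        seg = lambda v: tf.ExhaleSegment(v, (0, 1))
        ab = tf.build_anomaly_training_set([seg(a)], [seg(b)])[0].y
        ba = tf.build_anomaly_training_set([seg(b)], [seg(a)])[0].y
        ac = tf.build_anomaly_training_set([seg(a)], [seg(c)])[0].y
        cb = tf.build_anomaly_training_set([seg(c)], [seg(b)])[0].y
        assert np.array_equal(ab, ba)
        assert np.all(ab >= 0)
        assert np.all(ab <= ac + cb + 1e-12)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            tf.build_anomaly_training_set([], [_template()])


class TestAutoencoder:
    def test_reconstruction_shape_and_training_descent(self):
        segs = _ref_population(24, seed=5)
        model = tf.train_autoencoder(segs, seed=0, epochs=12)
        out = tf.denoise_segment(model, segs[0])
        assert out.values.shape == (SEGMENT_LENGTH,)
        assert model.history[-1]["train_mse"] < model.history[0]["train_mse"]

    def test_reconstruction_suppresses_high_frequencies(self):
        segs = [
            _template(noise=0.08, seed=k) for k in range(32)
        ]
        model = tf.train_autoencoder(segs, seed=1, epochs=40)
        probe = _template(noise=0.08, seed=999)

        def hf_power(v):
            spec = np.abs(np.fft.rfft(v - v.mean())) ** 2
            cut = len(spec) // 8  # above 1/8 Nyquist
            return spec[cut:].sum()

        recon = tf.denoise_segment(model, probe)
        assert hf_power(recon.values) < hf_power(probe.values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tf.train_autoencoder([])


class TestAnomalyModel:
    def test_prediction_shape_and_descent(self):
        refs = _ref_population(6, seed=6)
        inputs = _ref_population(8, seed=7)
        pairs = tf.build_anomaly_training_set(refs, inputs)
        model = tf.train_anomaly_model(pairs, seed=0, epochs=10)
        score = tf.score_segment(model, inputs[0])
        assert score.error_waveform.shape == (SEGMENT_LENGTH,)
        assert model.history[-1]["train_mse"] < model.history[0]["train_mse"]

    def test_distorted_segment_scores_above_reference_like(self):
        refs = _ref_population(20, seed=8)
        inputs = _ref_population(14, seed=9) + [_distorted(seed=k) for k in range(6)]
        pairs = tf.build_anomaly_training_set(refs, inputs)
        model = tf.train_anomaly_model(pairs, seed=1, epochs=30)
        held_ref = _ref_population(1, seed=123)[0]
        held_bad = _distorted(seed=321)
        s_ref = tf.score_segment(model, held_ref)
        s_bad = tf.score_segment(model, held_bad)
        assert s_bad.summary > s_ref.summary

    def test_scoring_deterministic_and_summary_is_mean(self):
        refs = _ref_population(4, seed=10)
        pairs = tf.build_anomaly_training_set(refs, refs)
        model = tf.train_anomaly_model(pairs, seed=2, epochs=3)
        seg = refs[0]
        a = tf.score_segment(model, seg)
        b = tf.score_segment(model, seg)
        assert np.array_equal(a.error_waveform, b.error_waveform)
        assert a.summary == pytest.approx(a.error_waveform.mean())
        assert np.all(a.error_waveform >= 0)

    def test_wrong_length_rejected(self):
        refs = _ref_population(2, seed=11)
        model = tf.train_anomaly_model(
            tf.build_anomaly_training_set(refs, refs), seed=0, epochs=1
        )
        bad = tf.ExhaleSegment(np.zeros(SEGMENT_LENGTH), (0, 1))
        bad.values = np.zeros(100)  # corrupt after construction
        with pytest.raises(ValueError):
            tf.score_segment(model, bad)
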