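import numpy as np
import pytest
from hypothesis import given, strategies as st

import thermoflow as tf
from thermoflow.encoding import AUGMENT_OPS


def _rand_fields(rng, n=5, h=6, w=6):
    return [rng.normal(size=(h, w, 2)) for _ in range(n)]


class TestEncodeDecode:
    def test_three_four_five_vector(self):
        field = np.zeros((1, 1, 2))
        field[0, 0] = (3.0, 4.0)
        enc = tf.encode_field(field)
        assert enc.n_max == pytest.approx(5.0)
        assert enc.data[0, 0] == pytest.approx([0.6, 0.8])

    def test_zero_field(self):
        enc = tf.encode_field(np.zeros((4, 4, 2)))
        assert enc.n_max == 0.0
        assert np.all(enc.data == 0)
        assert np.all(tf.decode_field(enc) == 0)

    def test_round_trip(self, rng):
        for _ in range(5):
            field = rng.normal(size=(6, 6, 2)) * rng.uniform(0.1, 50)
            enc = tf.encode_field(field)
            assert np.abs(tf.decode_field(enc) - field).max() < 1e-12

    def test_values_bounded(self, rng):
        field = rng.normal(size=(8, 8, 2))
        enc = tf.encode_field(field, n_max=0.5)  # smaller than max magnitude: clips
        assert np.all((enc.data >= -1) & (enc.data <= 1))


class TestAngularEncoding:
    def test_three_four_five_angle(self):
        field = np.zeros((1, 1, 2))
        field[0, 0] = (3.0, 4.0)
        enc = tf.encode_angular(field)
        assert enc.data[0, 0] == pytest.approx([0.8, 0.6])

    def test_zero_vector_encodes_to_zero(self):
        field = np.zeros((2, 2, 2))
        field[0, 0] = (1.0, 1.0)
        enc = tf.encode_angular(field)
        assert enc.data[1, 1] == pytest.approx([0.0, 0.0])

    def test_equivalent_to_direct_with_channels_swapped(self, rng):
        for _ in range(5):
            field = rng.normal(size=(7, 7, 2)) * 3
            ang = tf.encode_angular(field)
            direct = tf.encode_field(field)
            assert np.abs(ang.data[..., 0] - direct.data[..., 1]).max() < 1e-9
            assert np.abs(ang.data[..., 1] - direct.data[..., 0]).max() < 1e-9


class TestFaceMask:
    def test_all_false_unchanged(self, rng):
        field = rng.normal(size=(5, 5, 2))
        out = tf.apply_face_mask(field, np.zeros((5, 5), bool))
        assert np.array_equal(out, field)

    def test_all_true_zeroes(self, rng):
        out = tf.apply_face_mask(rng.normal(size=(5, 5, 2)), np.ones((5, 5), bool))
        assert np.all(out == 0)

    def test_masking_reduces_magnitude_sum(self, rng):
        field = rng.normal(size=(6, 6, 2))
        mask = np.zeros((6, 6), bool)
        mask[:3] = True
        assert tf.reduce_field(tf.apply_face_mask(field, mask)) <= tf.reduce_field(field)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            tf.apply_face_mask(rng.normal(size=(5, 5, 2)), np.zeros((4, 5), bool))


class TestCollate:
    def test_counts(self, rng):
        enc = [tf.encode_field(f) for f in _rand_fields(rng, 3)]
        assert len(tf.collate_interleaved(enc)) == 1
        enc = [tf.encode_field(f) for f in _rand_fields(rng, 10)]
        assert len(tf.collate_interleaved(enc)) == 8
        with pytest.raises(ValueError):
            tf.collate_interleaved(enc[:2])

    def test_target_is_intermediate_field(self, rng):
        enc = [tf.encode_field(f) for f in _rand_fields(rng, 4)]
        ds = tf.collate_interleaved(enc)
        assert np.array_equal(ds.y[0], enc[1].data)
        assert np.array_equal(ds.x[0][..., :2], enc[0].data)
        assert np.array_equal(ds.x[0][..., 2:], enc[2].data)


class TestAugment:
    def _dataset(self, rng, n=4):
        enc = [tf.encode_field(f) for f in _rand_fields(rng, n)]
        return tf.collate_interleaved(enc)

    def test_hflip_is_involution(self, rng):
        ds = self._dataset(rng)
        once = tf.augment(ds, ("hflip",))
        twice_x = tf.augment(
            tf.InterleavedDataset(once.x[len(ds):], once.y[len(ds):]), ("hflip",)
        )
        assert np.array_equal(twice_x.x[-1], ds.x[-1])
        assert np.array_equal(twice_x.y[-1], ds.y[-1])

    @pytest.mark.parametrize("op", AUGMENT_OPS)
    def test_magnitude_sum_preserved(self, rng, op):
        ds = self._dataset(rng)
        aug = tf.augment(ds, (op,))
        for orig, new in zip(ds.y, aug.y[len(ds):]):
            assert tf.reduce_field(new) == pytest.approx(tf.reduce_field(orig))

    def test_hflip_mirrors_single_vector(self):
        field = np.zeros((4, 4, 2))
        field[1, 0, 0] = 1.0  # right-pointing vector at column 0
        ds = tf.InterleavedDataset([np.concatenate([field, field], -1)], [field])
        aug = tf.augment(ds, ("hflip",))
        out = aug.y[1]
        assert out[1, 3, 0] == -1.0  # left-pointing at the mirrored column
        assert np.count_nonzero(out) == 1

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError):
            tf.augment(self._dataset(rng), ("diagflip",))

    def test_split_tags_inherited(self, rng):
        ds = self._dataset(rng, n=6)
        train, val = tf.split_dataset(ds, 0.75, seed=1)
        aug = tf.augment(train, ("rot180",))
        assert set(aug.tags) == {"train"}
        assert len(aug) == 2 * len(train)


class TestSplit:
    def test_fraction(self, rng):
        enc = [tf.encode_field(f) for f in _rand_fields(rng, 102)]
        ds = tf.collate_interleaved(enc)  # 100 items
        train, val = tf.split_dataset(ds, 0.9, seed=0)
        assert (len(train), len(val)) == (90, 10)

    def test_deterministic_and_partition(self, rng):
        enc = [tf.encode_field(f) for f in _rand_fields(rng, 12)]
        ds = tf.collate_interleaved(enc)
        t1, v1 = tf.split_dataset(ds, 0.8, seed=7)
        t2, v2 = tf.split_dataset(ds, 0.8, seed=7)
        for a, b in zip(t1.x, t2.x):
            assert np.array_equal(a, b)
        keys = sorted(arr.tobytes() for arr in ds.x)
        split_keys = sorted(arr.tobytes() for arr in t1.x + v1.x)
        assert keys == split_keys

    @given(frac=st.floats(0.1, 0.9), n=st.integers(3, 30))
    def test_sizes_complement(self, frac, n):
        gen = np.random.default_rng(0)
        enc = [tf.encode_field(f) for f in _rand_fields(gen, n)]
        ds = tf.collate_interleaved(enc)
        train, val = tf.split_dataset(ds, frac, seed=0)
        assert len(train) + len(val) == len(ds)


def test_dataset_hdf5_round_trip(tmp_path, rng):
    enc = [tf.encode_field(f) for f in _rand_fields(rng, 5)]
    ds = tf.collate_interleaved(enc)
    from thermoflow.encoding import load_dataset, save_dataset

    save_dataset(tmp_path / "d.h5", ds, {"n_max": 1.0})
    back = load_dataset(tmp_path / "d.h5")
    assert len(back) == len(ds)
    assert np.allclose(back.x[0], ds.x[0], atol=1e-6)
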