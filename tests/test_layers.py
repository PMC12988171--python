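"""Patch extraction, dense/conv layer fitting and forward maps."""

import numpy as np
import pytest

from fpnet.layers import (
    ConvSpec,
    FPConvLayer,
    FPDenseLayer,
    extract_patches,
    global_avg_pool,
)
from fpnet.linear_solver import RidgePenalty
from fpnet.targets import ProjectionPair, target_potentials
from tests.conftest import random_one_hot


class TestExtractPatches:
    @pytest.mark.parametrize("stride,expected", [(1, 3), (2, 2)])
    def test_position_counts_1d(self, stride, expected):
        x = np.zeros((4, 1, 5))
        pm = extract_patches(x, ConvSpec(2, 3, stride=stride, padding="valid"))
        assert pm.positions_per_sample == expected
        assert pm.rows.shape == (4 * expected, 3)

    def test_ramp_enumeration(self):
        x = np.arange(5.0).reshape(1, 1, 5)
        pm = extract_patches(x, ConvSpec(1, 3, stride=1, padding="valid"))
        np.testing.assert_array_equal(pm.rows, [[0, 1, 2], [1, 2, 3], [2, 3, 4]])
        np.testing.assert_array_equal(pm.position_index, [0, 1, 2])

    def test_same_padding_output_length(self):
        x = np.ones((2, 1, 7))
        pm = extract_patches(x, ConvSpec(1, 3, stride=2, padding="same"))
        assert pm.out_shape == (4,)  # ceil(7/2)

    def test_channel_major_flattening(self):
        x = np.stack([np.arange(4.0), 10 + np.arange(4.0)])[None]  # (1,2,4)
        pm = extract_patches(x, ConvSpec(1, 2, stride=1, padding="valid"))
        np.testing.assert_array_equal(pm.rows[0], [0, 1, 10, 11])

    def test_2d_raster_order(self):
        x = np.arange(9.0).reshape(1, 1, 3, 3)
        pm = extract_patches(x, ConvSpec(1, (2, 2), stride=1, padding="valid"))
        assert pm.out_shape == (2, 2)
        np.testing.assert_array_equal(pm.rows[0], [0, 1, 3, 4])
        np.testing.assert_array_equal(pm.rows[1], [1, 2, 4, 5])

    def test_kernel_too_large(self):
        with pytest.raises(ValueError, match="kernel"):
            extract_patches(np.zeros((1, 1, 2)), ConvSpec(1, 3, padding="valid"))


class TestGlobalAvgPool:
    def test_constant_tensor(self):
        np.testing.assert_array_equal(global_avg_pool(np.full((2, 3, 5), 4.2)), np.full((2, 3), 4.2))

    def test_simple_mean(self):
        assert global_avg_pool(np.array([[[1.0, 2.0, 3.0]]]))[0, 0] == 2.0

    def test_2d_pooling(self, rng):
        x = rng.normal(size=(2, 3, 4, 5))
        np.testing.assert_allclose(global_avg_pool(x), x.mean(axis=(2, 3)))


class TestDenseLayer:
    def test_forward_applies_activation(self, rng):
        layer = FPDenseLayer(2, 2, 2, f="relu", seed=0)
        layer.W = np.eye(2)
        layer.fitted = True
        np.testing.assert_array_equal(layer.forward(np.array([[-1.0, 2.0]])), [[0.0, 2.0]])

    def test_unfitted_forward_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            FPDenseLayer(2, 2, 2).forward(np.zeros((1, 2)))

    def test_single_sample_matches_hand_solve(self):
        layer = FPDenseLayer(2, 1, 2, seed=3)
        a = np.array([[1.0, 0.0]])
        y = np.array([[1.0, 0.0]])
        layer.fit([(a, y)], penalty=RidgePenalty(0.5, "absolute"))
        zt = target_potentials(a, y, layer.pair, "sign", "fp")
        w_hand = np.linalg.inv(a.T @ a + 0.5 * np.eye(2)) @ (a.T @ zt)
        np.testing.assert_allclose(layer.W, w_hand, atol=1e-12)

    def test_batch_order_invariance(self, rng):
        a = rng.normal(size=(12, 4))
        y = random_one_hot(rng, 12, 3)
        l1 = FPDenseLayer(4, 6, 3, seed=5).fit([(a, y)])
        perm = rng.permutation(12)
        batches = [(a[perm[i : i + 3]], y[perm[i : i + 3]]) for i in range(0, 12, 3)]
        l2 = FPDenseLayer(4, 6, 3, seed=5).fit(batches)
        np.testing.assert_allclose(l1.W, l2.W, atol=1e-8)

    def test_exact_interpolation_residual_vanishes(self, rng):
        # identity g with a zero label projection: targets are exactly linear
        # in the (full-column-rank) inputs, so the ridge fit interpolates
        a = rng.normal(size=(20, 4))
        y = random_one_hot(rng, 20, 2)
        w_true = rng.normal(size=(4, 3))
        pair = ProjectionPair(
            Q=w_true, U=np.zeros((2, 3)), U_pinv=np.zeros((3, 2)),
            seed=0, scale_q=1.0, scale_u=1.0,
        )
        layer = FPDenseLayer(4, 3, 2, g="identity", pair=pair)
        layer.fit([(a, y)], penalty=RidgePenalty(1e-12, "absolute"))
        assert layer.train_residual < 1e-5

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError, match="empty"):
            FPDenseLayer(2, 2, 2).fit([])

    def test_double_fit_refused(self, rng):
        layer = FPDenseLayer(2, 2, 2).fit([(rng.normal(size=(4, 2)), random_one_hot(rng, 4, 2))])
        with pytest.raises(RuntimeError, match="already"):
            layer.fit([(rng.normal(size=(4, 2)), random_one_hot(rng, 4, 2))])

    def test_random_features_weights_are_seeded(self):
        l1 = FPConvLayer(1, ConvSpec(4, 3), 2, seed=9).set_random_weights()
        l2 = FPConvLayer(1, ConvSpec(4, 3), 2, seed=9).set_random_weights()
        np.testing.assert_array_equal(l1.W, l2.W)


class TestConvLayer:
    def test_zero_inputs_give_zero_weights(self):
        x = np.zeros((4, 1, 6))
        y = random_one_hot(np.random.default_rng(0), 4, 2)
        layer = FPConvLayer(1, ConvSpec(3, 3), 2, seed=2)
        layer.fit([(x, y)], penalty=RidgePenalty(0.1, "absolute"))
        np.testing.assert_allclose(layer.W, 0.0, atol=1e-12)

    def test_matches_dense_fit_on_patch_rows(self, rng):
        x = rng.normal(size=(1, 1, 4))
        y = random_one_hot(rng, 1, 2)
        spec = ConvSpec(5, 3, stride=1, padding="valid")
        conv = FPConvLayer(1, spec, 2, seed=7).fit([(x, y)], penalty=RidgePenalty(0.2, "absolute"))
        pm = extract_patches(x, spec)
        dense = FPDenseLayer(3, 5, 2, seed=7)
        dense.pair = conv.pair
        dense.fit([(pm.rows, y[pm.sample_index])], penalty=RidgePenalty(0.2, "absolute"))
        np.testing.assert_allclose(conv.W, dense.W, atol=1e-10)
        assert conv.train_residual == pytest.approx(dense.train_residual)

    def test_forward_equals_patch_matrix_product(self, rng):
        x = rng.normal(size=(3, 2, 8))
        y = random_one_hot(rng, 3, 2)
        spec = ConvSpec(4, 3, stride=2, padding="same")
        layer = FPConvLayer(2, spec, 2, seed=1).fit([(x, y)])
        pm = extract_patches(x, spec)
        expected = (pm.rows @ layer.W).reshape(3, -1, 4)
        out = layer.potentials(x)
        np.testing.assert_allclose(np.moveaxis(out, 1, 2).reshape(3, -1, 4), expected)

    def test_full_extent_kernel_reproduces_dense_layer(self, rng):
        x = rng.normal(size=(10, 2, 6))
        y = random_one_hot(rng, 10, 2)
        conv = FPConvLayer(2, ConvSpec(5, 6, stride=1, padding="valid"), 2, seed=4)
        conv.fit([(x, y)], penalty=RidgePenalty(0.3, "absolute"))
        dense = FPDenseLayer(12, 5, 2, seed=4)
        dense.pair = conv.pair
        flat = extract_patches(x, conv.spec).rows
        dense.fit([(flat, y)], penalty=RidgePenalty(0.3, "absolute"))
        np.testing.assert_allclose(conv.forward(x)[:, :, 0], dense.forward(flat), atol=1e-10)

    def test_stride_two_same_padding_halves_length(self, rng):
        for length in (9, 10):
            x = rng.normal(size=(2, 1, length))
            y = random_one_hot(rng, 2, 2)
            layer = FPConvLayer(1, ConvSpec(3, 3, stride=2, padding="same"), 2, seed=0)
            layer.fit([(x, y)])
            assert layer.potentials(x).shape[2] == int(np.ceil(length / 2))

    def test_filters_property_shape(self, rng):
        x = rng.normal(size=(4, 3, 7))
        y = random_one_hot(rng, 4, 2)
        layer = FPConvLayer(3, ConvSpec(6, 3), 2, seed=0).fit([(x, y)])
        assert layer.filters.shape == (6, 3, 3)

    def test_position_subsampling_bounds_rows(self, rng):
        x = rng.normal(size=(4, 1, 50))
        y = random_one_hot(rng, 4, 2)
        layer = FPConvLayer(1, ConvSpec(2, 3), 2, seed=0, subsample=0.2)
        stream = layer._patch_row_stream(lambda: iter([(x, y)]))
        rows, _ = next(stream())
        assert rows.shape[0] < 4 * 48 * 0.5
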