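"""Dynamic snake convolution: position geometry, extents, operator oracle."""

import numpy as np
import pytest
from scipy import ndimage

from snakereg import autodiff as ad
from snakereg.autodiff import Tensor
from snakereg.snake import (AXES, DSConv3d, SnakeKernelSpec, SnakeOffsets,
                            dsconv3d_reference, enumerate_saturated_positions,
                            receptive_extent, snake_positions)


def make_layer(rng, cin=1, cout=1, spec=None, random_offsets=True):
    layer = DSConv3d(cin, cout, rng, spec or SnakeKernelSpec())
    if random_offsets:
        layer.offset_conv.weight.data = rng.uniform(
            -0.5, 0.5, layer.offset_conv.weight.shape).astype(np.float32)
        layer.offset_conv.bias.data = rng.uniform(
            -0.5, 0.5, layer.offset_conv.bias.shape).astype(np.float32)
    return layer


class TestSnakePositions:
    def test_zero_offsets_straight_segment(self):
        spec = SnakeKernelSpec(points_per_kernel=9)
        pos = snake_positions((2.0, 3.0, 4.0), np.zeros((2, 4, 2)), "x", spec)
        expected = [(2.0, 3.0, 4.0 + k) for k in range(-4, 5)]
        np.testing.assert_array_equal(pos, expected)

    def test_saturated_offsets_reach_corner(self):
        # every offset +1: lateral displacement (c, c) at step c, max reach 4
        spec = SnakeKernelSpec()
        pos = snake_positions((0, 0, 0), np.ones((2, 4, 2)), "x", spec)
        np.testing.assert_array_equal(pos[-1], (4.0, 4.0, 4.0))
        for c in range(1, 5):
            np.testing.assert_array_equal(pos[4 + c][:2], (c, c))

    def test_running_sum_oracle(self):
        spec = SnakeKernelSpec()
        off = np.zeros((2, 4, 2))
        off[1, :, 0] = [0.5, -0.25, 0.1, 0.3]  # plus side, first lateral (d for x-snake)
        pos = snake_positions((0, 0, 0), off, "x", spec)
        np.testing.assert_allclose(pos[5:, 0], np.cumsum([0.5, -0.25, 0.1, 0.3]))

    def test_center_carries_zero_offset(self, rng):
        spec = SnakeKernelSpec()
        off = rng.uniform(-1, 1, (2, 4, 2))
        for axis in AXES:
            pos = snake_positions((1.0, 2.0, 3.0), off, axis, spec)
            np.testing.assert_array_equal(pos[4], (1.0, 2.0, 3.0))


class TestReceptiveExtent:
    @pytest.mark.parametrize("spec,expected", [
        (SnakeKernelSpec(), (9, 9, 9)),
        (SnakeKernelSpec(points_per_kernel=3, max_step=1.0), (3, 3, 3)),
        (SnakeKernelSpec(points_per_kernel=9, max_step=0.5), (9, 5, 5)),
    ])
    def test_formula(self, spec, expected):
        assert receptive_extent(spec) == expected

    def test_formula_matches_exhaustive_enumeration(self):
        for spec in (SnakeKernelSpec(), SnakeKernelSpec(points_per_kernel=5, max_step=0.5)):
            pos = enumerate_saturated_positions(spec)
            cube = pos.max(axis=0) - pos.min(axis=0) + 1
            along, lat, _ = receptive_extent(spec)
            assert cube.max() == max(along, lat)
            # per-variant check for the x-snake
            xpos = np.array([snake_positions((0, 0, 0), sgn * spec.max_step
                                             * np.ones((2, spec.half, 2)), "x", spec)
                             for sgn in (+1, -1)]).reshape(-1, 3)
            extent = np.ceil(xpos.max(0)) - np.floor(xpos.min(0)) + 1
            assert tuple(extent[[2, 0, 1]]) == receptive_extent(spec)


class TestOffsets:
    def test_zero_predictor_gives_zero_offsets(self, rng):
        layer = make_layer(rng, random_offsets=False)
        with ad.no_grad():
            off = layer.predict_offsets(Tensor(rng.random((1, 5, 5, 5)))).data
        assert np.all(off == 0)

    def test_offsets_bounded_by_construction(self, rng):
        spec = SnakeKernelSpec(max_step=0.7)
        layer = make_layer(rng, spec=spec)
        layer.offset_conv.weight.data *= 100  # drive tanh to saturation
        with ad.no_grad():
            off = layer.predict_offsets(Tensor(rng.random((1, 5, 5, 5)))).data
        assert np.abs(off).max() <= 0.7
        SnakeOffsets(off, spec)  # invariant holds

    def test_offsets_deterministic(self, rng):
        layer = make_layer(rng)
        x = Tensor(rng.random((1, 5, 5, 5)).astype(np.float32))
        with ad.no_grad():
            a = layer.predict_offsets(x).data
            b = layer.predict_offsets(x).data
        assert np.array_equal(a, b)


class TestDSConv:
    def test_delta_kernel_identity(self, rng):
        layer = make_layer(rng, spec=SnakeKernelSpec(), random_offsets=False)
        K = layer.spec.points_per_kernel
        w = np.zeros((3, 1, K), dtype=np.float32)
        w[:, 0, K // 2] = 1.0
        layer.weight.data = w
        layer.bias.data[:] = 0
        x = rng.random((1, 6, 6, 6)).astype(np.float32)
        with ad.no_grad():
            out = layer(Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_constant_preservation(self, rng):
        layer = make_layer(rng, random_offsets=True)
        K = layer.spec.points_per_kernel
        layer.weight.data = np.full((3, 1, K), 1.0 / K, dtype=np.float32)
        layer.bias.data[:] = 0
        x = np.full((1, 6, 6, 6), 7.0, dtype=np.float32)
        with ad.no_grad():
            out = layer(Tensor(x)).data
        np.testing.assert_allclose(out, 7.0, atol=1e-5)

    @pytest.mark.parametrize("fusion", ["mean", "sum", "concat"])
    def test_matches_gather_and_sum_oracle(self, rng, fusion):
        spec = SnakeKernelSpec(points_per_kernel=5, fusion=fusion)
        layer = make_layer(rng, cin=2, cout=3, spec=spec)
        x = rng.standard_normal((2, 6, 6, 6)).astype(np.float32)
        with ad.no_grad():
            fast = layer(Tensor(x)).data
        np.testing.assert_allclose(fast, dsconv3d_reference(x, layer), atol=1e-5)

    def test_zero_offsets_equal_separable_axial_convolutions(self, rng):
        spec = SnakeKernelSpec(points_per_kernel=5, fusion="sum")
        layer = make_layer(rng, cin=1, cout=1, spec=spec, random_offsets=False)
        layer.bias.data[:] = 0
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        with ad.no_grad():
            out = layer(Tensor(x)).data
        w = layer.weight.data.reshape(3, 5)
        # independent oracle: 1-D correlations along w, h, d with edge replication
        expected = (ndimage.correlate1d(x[0], w[0], axis=2, mode="nearest")
                    + ndimage.correlate1d(x[1 - 1], w[1], axis=1, mode="nearest")
                    + ndimage.correlate1d(x[0], w[2], axis=0, mode="nearest"))
        np.testing.assert_allclose(out[0], expected, atol=1e-6)

    def test_linearity_in_input(self, rng):
        layer = make_layer(rng, cin=1, cout=2)
        u = rng.standard_normal((1, 6, 6, 6)).astype(np.float32)
        v = rng.standard_normal((1, 6, 6, 6)).astype(np.float32)
        layer.bias.data[:] = 0
        with ad.no_grad():
            off = layer.predict_offsets(Tensor(u))
            lhs = layer(Tensor(2 * u + 3 * v), offsets=off).data
            rhs = 2 * layer(Tensor(u), offsets=off).data + 3 * layer(Tensor(v), offsets=off).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-5)

    def test_sampled_positions_inside_receptive_extent(self, rng):
        spec = SnakeKernelSpec()
        off = rng.uniform(-1, 1, (2, 4, 2))
        along, lat, _ = receptive_extent(spec)
        for axis in AXES:
            rel = snake_positions((0, 0, 0), off, axis, spec)
            assert np.abs(rel).max() <= (along - 1) / 2
            lat_axes = [i for i in range(3) if i != {"x": 2, "y": 1, "z": 0}[axis]]
            assert np.abs(rel[:, lat_axes]).max() <= (lat - 1) / 2

    def test_translation_equivariance_interior(self, rng):
        """Constant offsets => output commutes with integer translation away
        from the borders."""
        spec = SnakeKernelSpec(points_per_kernel=3)
        layer = make_layer(rng, spec=spec, random_offsets=False)
        layer.offset_conv.bias.data = rng.uniform(
            -0.5, 0.5, layer.offset_conv.bias.shape).astype(np.float32)  # constant offsets
        x = rng.standard_normal((1, 10, 10, 10)).astype(np.float32)
        shifted = np.roll(x, 1, axis=3)
        with ad.no_grad():
            a = layer(Tensor(x)).data
            b = layer(Tensor(shifted)).data
        np.testing.assert_allclose(np.roll(a, 1, axis=3)[:, 3:-3, 3:-3, 3:-3],
                                   b[:, 3:-3, 3:-3, 3:-3], atol=1e-5)

    def test_forward_deterministic(self, rng):
        layer = make_layer(rng, cin=2, cout=2)
        x = Tensor(rng.standard_normal((2, 6, 6, 6)).astype(np.float32))
        with ad.no_grad():
            assert np.array_equal(layer(x).data, layer(x).data)

    def test_offset_shape_mismatch_rejected(self, rng):
        layer = make_layer(rng)
        x = Tensor(rng.random((1, 6, 6, 6)).astype(np.float32))
        bad = Tensor(np.zeros((3, 2, 4, 2, 5, 5, 5), dtype=np.float32))
        with pytest.raises(ValueError, match="offsets"):
            layer(x, offsets=bad)


class TestSpecValidation:
    def test_even_points_rejected(self):
        with pytest.raises(ValueError):
            SnakeKernelSpec(points_per_kernel=4)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            SnakeKernelSpec(max_step=0.0)
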