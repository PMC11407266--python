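"""Differentiable ops: oracle equivalence and finite-difference gradients."""

import numpy as np
import pytest
from scipy import ndimage

from octvolsr.nn import functional as F
from octvolsr.nn.tensor import Tensor, no_grad


def leaf(a):
    return Tensor(np.asarray(a, dtype=np.float64), requires_grad=True)


def numeric_grad(fn, t, eps=1e-6):
    num = np.zeros_like(t.data)
    it = np.nditer(t.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = t.data[idx]
        t.data[idx] = orig + eps
        plus = float(fn().data)
        t.data[idx] = orig - eps
        minus = float(fn().data)
        t.data[idx] = orig
        num[idx] = (plus - minus) / (2 * eps)
    return num


class TestConv:
    def test_matches_scipy_correlate(self, rng):
        # independent oracle: per-channel scipy correlation with zero padding
        x = rng.standard_normal((1, 3, 5, 6, 4))
        w = rng.standard_normal((2, 3, 3, 3, 3))
        with no_grad():
            out = F.conv_same(Tensor(x), Tensor(w)).data
        ref = np.zeros((1, 2, 5, 6, 4))
        for o in range(2):
            for c in range(3):
                ref[0, o] += ndimage.correlate(
                    x[0, c], w[o, c], mode="constant", cval=0.0
                )
        np.testing.assert_allclose(out, ref, rtol=1e-10, atol=1e-10)

    @pytest.mark.parametrize(
        "xshape,wshape",
        [
            ((1, 2, 4, 5, 3), (2, 2, 3, 3, 3)),
            ((2, 3, 6, 5), (4, 3, 3, 3)),
            ((1, 4, 3, 4, 5), (16, 4, 1, 1, 1)),
        ],
    )
    def test_gradients(self, rng, xshape, wshape):
        x, w = leaf(rng.standard_normal(xshape)), leaf(rng.standard_normal(wshape))
        b = leaf(rng.standard_normal(wshape[0]))

        def fn():
            return F.mean(F.abs_(F.conv_same(x, w, b)))

        fn().backward()
        for t in (x, w, b):
            np.testing.assert_allclose(t.grad, numeric_grad(fn, t), atol=1e-7)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            F.conv_same(Tensor(np.zeros((1, 1, 4, 4))), Tensor(np.zeros((1, 1, 2, 2))))


class TestPoolAndResample:
    def test_maxpool_matches_blockwise_oracle(self, rng):
        x = rng.standard_normal((1, 2, 4, 6, 8))
        with no_grad():
            out = F.max_pool(Tensor(x), (2, 2, 2)).data
        ref = x.reshape(1, 2, 2, 2, 3, 2, 4, 2).max(axis=(3, 5, 7))
        np.testing.assert_array_equal(out, ref)

    @pytest.mark.parametrize("factors", [(2, 2, 2), (1, 2, 2)])
    def test_maxpool_gradient(self, rng, factors):
        x = leaf(rng.standard_normal((1, 2, 4, 4, 4)))

        def fn():
            return F.mean(F.abs_(F.max_pool(x, factors)))

        fn().backward()
        np.testing.assert_allclose(x.grad, numeric_grad(fn, x), atol=1e-7)

    def test_upsample_preserves_constants(self):
        x = Tensor(np.full((1, 1, 3, 4, 5), 0.37))
        with no_grad():
            out = F.upsample_linear(x, (1, 4, 4)).data
        assert out.shape == (1, 1, 3, 16, 20)
        np.testing.assert_allclose(out, 0.37)

    def test_upsample_preserves_interior_ramp(self):
        ramp = np.arange(8, dtype=np.float64)[None, None, None, :]
        with no_grad():
            out = F.upsample_linear(Tensor(ramp), (1, 2)).data[0, 0, 0]
        # interior samples at half-pixel centers lie exactly on the ramp
        expect = (np.arange(16) + 0.5) / 2 - 0.5
        np.testing.assert_allclose(out[1:-1], expect[1:-1])

    def test_upsample_gradient(self, rng):
        x = leaf(rng.standard_normal((1, 2, 3, 4)))

        def fn():
            return F.mean(F.abs_(F.upsample_linear(x, (2, 4))))

        fn().backward()
        np.testing.assert_allclose(x.grad, numeric_grad(fn, x), atol=1e-7)


class TestPixelShuffle:
    def test_identity_for_unit_factors(self, rng):
        x = rng.standard_normal((2, 1, 3, 4))
        with no_grad():
            out = F.pixel_shuffle(Tensor(x), (1, 1)).data
        np.testing.assert_array_equal(out, x)

    def test_constant_channels_tile_by_index_formula(self):
        # 16 constant channels, factors (4, 4): output voxel (4i+j, 4k+l)
        # must read channel 4*j + l (brute-force index-mapping oracle)
        consts = np.arange(16, dtype=np.float64)
        x = np.broadcast_to(consts[None, :, None, None, None], (1, 16, 2, 3, 3)).copy()
        with no_grad():
            out = F.pixel_shuffle(Tensor(x), (1, 4, 4)).data[0, 0]
        for y in range(12):
            for z in range(12):
                assert out[0, y, z] == 4 * (y % 4) + (z % 4)

    def test_round_trip_bijection(self, rng):
        x = rng.standard_normal((2, 8, 3, 4, 6))
        with no_grad():
            back = F.pixel_unshuffle(F.pixel_shuffle(Tensor(x), (1, 2, 4)), (1, 2, 4))
        np.testing.assert_array_equal(back.data, x)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            F.pixel_shuffle(Tensor(np.zeros((1, 3, 2, 2))), (2, 2))


class TestMiscGradients:
    def test_composite_graph_gradient(self, rng):
        x = leaf(rng.standard_normal((3, 4, 5)))

        def fn():
            a = F.forward_diff(x, 1)
            b = F.take(x, np.array([0, 2, 2]), 0)
            return F.add(F.mean(F.abs_(a)), F.mean(F.abs_(b)))

        fn().backward()
        np.testing.assert_allclose(x.grad, numeric_grad(fn, x), atol=1e-7)

    def test_no_grad_builds_no_tape(self):
        x = leaf(np.ones((2, 2)))
        with no_grad():
            y = F.relu(x)
        assert y._parents == () and not y.requires_grad
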