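"""Two-path volumetric network: MRD oracle, identities, shape contracts."""

import numpy as np
import pytest

from octvolsr import NetworkConfig, UNet3D, mrd_combine
from octvolsr.models.twopath import upper_path
from octvolsr.nn import functional as F
from octvolsr.nn.layers import Conv
from octvolsr.nn.optim import Adam
from octvolsr.nn.tensor import Tensor, no_grad
from octvolsr.volumes import ShapeContractError


def interp_1d_oracle(v: np.ndarray, f: int) -> np.ndarray:
    """Independent linear x-f upsampling along the last axis via np.interp."""
    n = v.shape[-1]
    src = np.arange(n, dtype=np.float64)
    dst = (np.arange(n * f) + 0.5) / f - 0.5
    dst = np.clip(dst, 0, n - 1)
    flat = v.reshape(-1, n)
    out = np.stack([np.interp(dst, src, row) for row in flat])
    return out.reshape(v.shape[:-1] + (n * f,))


def upsample_oracle(v: np.ndarray, factors) -> np.ndarray:
    """Separable linear upsampling written independently of the engine."""
    out = np.asarray(v, dtype=np.float64)
    for ax_offset, f in enumerate(factors):
        ax = out.ndim - len(factors) + ax_offset
        if f == 1:
            continue
        moved = np.moveaxis(out, ax, -1)
        moved = interp_1d_oracle(moved, f)
        out = np.moveaxis(moved, -1, ax)
    return out


class TestMRDCombine:
    def test_single_level_is_identity(self, rng):
        r = Tensor(rng.standard_normal((1, 4, 2, 3, 3)))
        with no_grad():
            out = mrd_combine([r], (2, 2, 2))
        np.testing.assert_array_equal(out.data, r.data)

    def test_two_constant_levels_sum(self):
        coarse = Tensor(np.full((1, 1, 2, 2, 2), 3.0))
        fine = Tensor(np.full((1, 1, 4, 4, 4), 4.0))
        with no_grad():
            out = mrd_combine([coarse, fine], (2, 2, 2))
        np.testing.assert_allclose(out.data, 7.0)

    def test_three_level_pyramid_matches_summation_oracle(self, rng):
        # brute force: each residue map upsampled to the finest grid and summed
        shapes = [(1, 4, 2, 2, 2), (1, 4, 4, 4, 4), (1, 4, 8, 8, 8)]
        rs = [rng.standard_normal(s) for s in shapes]
        with no_grad():
            out = mrd_combine([Tensor(r) for r in rs], (2, 2, 2)).data
        expect = np.zeros(shapes[-1])
        for lvl, r in enumerate(rs):
            up = r
            for _ in range(len(rs) - 1 - lvl):
                up = upsample_oracle(up, (2, 2, 2))
            expect += up
        np.testing.assert_allclose(out, expect, rtol=1e-5)

    def test_mismatched_shapes_name_level(self, rng):
        rs = [Tensor(rng.standard_normal((1, 4, 2, 2, 2))),
              Tensor(rng.standard_normal((1, 4, 4, 4, 5)))]
        with pytest.raises(ShapeContractError, match="level 1"):
            mrd_combine(rs, (2, 2, 2))


class TestUpperPath:
    def test_constant_preserved(self):
        x = Tensor(np.full((1, 1, 4, 4, 2), 0.5))
        with no_grad():
            out = upper_path(x, (1, 4, 4)).data
        assert out.shape == (1, 1, 4, 16, 8)
        np.testing.assert_allclose(out, 0.5)

    def test_shape_arithmetic(self, rng):
        x = Tensor(rng.random((1, 1, 64, 16, 8)))
        with no_grad():
            out = upper_path(x, (1, 4, 4)).data
        assert out.shape == (1, 1, 64, 64, 32)

    def test_matches_independent_oracle(self, rng):
        x = rng.standard_normal((1, 1, 3, 5, 4))
        with no_grad():
            out = upper_path(Tensor(x), (1, 2, 4)).data
        np.testing.assert_allclose(out, upsample_oracle(x, (1, 2, 4)), rtol=1e-6)


class TestForward:
    def test_desk_scale_shape_contract(self, desk_config, tiny_triplet):
        model = UNet3D(desk_config, seed=0)
        out = model.forward_volume(tiny_triplet.low.data)
        assert out.shape == tiny_triplet.high.shape

    def test_zero_projection_reduces_to_interpolation(self, desk_config, tiny_triplet):
        # the output projection is zero-initialized, so an untrained network
        # IS the pure-interpolation baseline, bit for bit in fp32
        model = UNet3D(desk_config, seed=0)
        out = model.forward_volume(tiny_triplet.low.data)
        with no_grad():
            up = upper_path(Tensor(tiny_triplet.low.data[None, None]), (1, 4, 4))
        np.testing.assert_array_equal(out, up.data[0, 0])

    def test_indivisible_input_rejected_before_compute(self, desk_config):
        model = UNet3D(desk_config, seed=0)
        with pytest.raises(ShapeContractError, match="divisible"):
            model.forward_volume(np.zeros((10, 6, 6), dtype=np.float32))

    def test_gradient_reaches_every_parameter(self, desk_config, tiny_triplet):
        from octvolsr.losses import total_loss

        model = UNet3D(desk_config, seed=0)
        opt = Adam(model.parameters(), lr=1e-3)
        x = Tensor(tiny_triplet.low.data[None, None])
        t = Tensor(tiny_triplet.high.data[None, None])
        for _ in range(2):  # one step to leave the zero-projection point
            model.zero_grad()
            loss, _ = total_loss(model(x), t)
            loss.backward()
            opt.step()
        dead = [
            k
            for k, p in model.named_parameters().items()
            if p.grad is None or not np.any(p.grad)
        ]
        assert dead == []

    def test_no_mrd_variant_runs_and_differs(self, tiny_triplet, rng):
        # ablation arm: classical decoder (finest level only); after random
        # projection init the two variants give different outputs
        out = {}
        for use_mrd in (True, False):
            cfg = NetworkConfig(depth=3, base_channels=4, use_mrd=use_mrd)
            model = UNet3D(cfg, seed=0)
            proj = model.net.out_proj.weight
            proj.data = rng.standard_normal(proj.data.shape).astype(np.float32) * 0.1
            out[use_mrd] = model.forward_volume(tiny_triplet.low.data)
        assert out[True].shape == out[False].shape
        assert not np.array_equal(out[True], out[False])


class TestParameters:
    def test_single_conv_parameter_count(self, rng):
        conv = Conv(1, 1, 3, 3, rng)
        assert conv.weight.data.size + conv.bias.data.size == 28

    def test_fp16_bytes_exactly_half(self, desk_config):
        model = UNet3D(desk_config, seed=0)
        assert model.parameter_bytes("fp16") * 2 == model.parameter_bytes("fp32")

    def test_full_scale_parameter_size_order_of_magnitude(self):
        # the published full configuration stores parameters in the MB range
        cfg = NetworkConfig(depth=5, base_channels=4)
        model = UNet3D(cfg, seed=0)
        mb = model.parameter_bytes("fp32") / 2**20
        assert 0.1 < mb < 100

    def test_fp16_output_close_to_fp32(self, desk_config, tiny_triplet, rng):
        model = UNet3D(desk_config, seed=0)
        proj = model.net.out_proj.weight
        proj.data = rng.standard_normal(proj.data.shape).astype(np.float32) * 0.05
        out32 = model.forward_volume(tiny_triplet.low.data)
        model.cast(np.float16)
        out16 = model.forward_volume(tiny_triplet.low.data)
        assert out16.dtype == np.float16
        assert np.abs(out16.astype(np.float32) - out32).max() < 1e-2
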