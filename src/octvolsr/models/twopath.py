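"""The two-path super-resolution network, generic over dimensionality.

The upper path is plain separable linear interpolation of the input by the
lateral upsampling factors; it carries the low-frequency content, which
low- and high-resolution OCT volumes largely share.  The lower path is a
U-Net-style encoder/decoder of residue blocks (no batch normalization)
whose decoder is the multi-level residue decoder (MRD): every level's
features pass through a 4-channel residue head R_i, and the decoder output
is accumulated coarsest-to-finest as

    D_coarsest = R_coarsest,      D_i = R_i + Up2(D_{i-1}),

where Up2 is linear x2 upsampling along the pooled axes.  The finest
accumulator is projected 1x1 to ``prod(up_factors)`` channels and
rearranged channel-to-space (sub-pixel / PixelShuffle upsampling) into a
single-channel high-frequency map, which is added to the upper path.

The final projection is zero-initialized, so an untrained network is
exactly the linear-interpolation baseline and training only has to learn
the high-frequency residue.
"""

from __future__ import annotations

import numpy as np

from ..nn import functional as F
from ..nn.layers import Conv, Module, ResidueBlock
from ..nn.tensor import Tensor
from ..volumes import ShapeContractError
from .config import NetworkConfig


def upper_path(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Separable linear interpolation of ``(N, C, *spatial)`` features."""
    return F.upsample_linear(x, factors)


def channel_to_space(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Channel-to-space rearrangement (see :func:`nn.functional.pixel_shuffle`)."""
    return F.pixel_shuffle(x, factors)


def mrd_combine(
    r_levels: list[Tensor], up_factors: tuple[int, ...]
) -> Tensor:
    """Accumulate per-level residue maps coarsest-to-finest.

    ``r_levels`` is ordered coarsest first; each step upsamples the running
    accumulator by ``up_factors`` (linear) and adds the next finer residue
    map.  Returns the finest accumulator.
    """
    d = r_levels[0]
    for lvl, r in enumerate(r_levels[1:], start=1):
        up = F.upsample_linear(d, up_factors)
        if up.data.shape != r.data.shape:
            raise ShapeContractError(
                f"MRD level {lvl}: upsampled accumulator {up.data.shape} does not "
                f"match residue map {r.data.shape}"
            )
        d = F.add(r, up)
    return d


class TwoPathNet(Module):
    """Dimension-generic two-path network (3D C-scans or 2D slice batches).

    Parameters
    ----------
    ndim:
        Number of spatial axes (2 or 3).
    up_factors:
        Per-spatial-axis lateral upsampling factors of the whole network,
        e.g. ``(1, 4, 4)`` for the volumetric model (axial axis untouched).
    pool_factors:
        Per-spatial-axis encoder halving factors per level (1 = keep).
    """

    def __init__(
        self,
        ndim: int,
        up_factors: tuple[int, ...],
        pool_factors: tuple[int, ...],
        depth: int = 3,
        base_channels: int = 4,
        channel_growth: int = 2,
        head_channels: int = 4,
        max_channels: int = 64,
        use_mrd: bool = True,
        skip_connections: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if len(up_factors) != ndim or len(pool_factors) != ndim:
            raise ValueError("factor tuples must have one entry per spatial axis")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.ndim = ndim
        self.up_factors = tuple(up_factors)
        self.pool_factors = tuple(pool_factors)
        self.depth = depth
        self.use_mrd = use_mrd
        self.skip_connections = skip_connections

        ch = [
            min(base_channels * channel_growth**i, max_channels)
            for i in range(depth)
        ]
        self.enc_blocks = [
            ResidueBlock(1 if i == 0 else ch[i - 1], ch[i], ndim, rng)
            for i in range(depth)
        ]
        # decoder: upsample -> conv -> (concat skip) -> residue block
        self.dec_up_convs = [
            Conv(ch[i + 1], ch[i], 3, ndim, rng) for i in range(depth - 1)
        ]
        self.dec_blocks = [
            ResidueBlock(ch[i] * (2 if skip_connections else 1), ch[i], ndim, rng)
            for i in range(depth - 1)
        ]
        # per-level residue heads R_i (coarsest = bottleneck, finest = level 0)
        self.heads = [ResidueBlock(c, head_channels, ndim, rng) for c in ch]
        self.out_block = ResidueBlock(head_channels, head_channels, ndim, rng)
        self.out_proj = Conv(
            head_channels, int(np.prod(up_factors)), 1, ndim, rng, zero_init=True
        )

    # -- shape contract --------------------------------------------------
    def validate_input(self, spatial: tuple[int, ...]) -> None:
        for ax, (s, f) in enumerate(zip(spatial, self.pool_factors)):
            need = f ** (self.depth - 1)
            if s % need != 0:
                raise ShapeContractError(
                    f"spatial axis {ax} extent {s} not divisible by "
                    f"{need} (pool factor {f} over {self.depth - 1} levels)"
                )

    # -- forward ----------------------------------------------------------
    def __call__(self, x: Tensor) -> Tensor:
        """Map ``(N, 1, *spatial)`` to ``(N, 1, *spatial * up_factors)``."""
        self.validate_input(x.data.shape[2:])
        if x.data.dtype != self.dtype:
            if x._parents or x.requires_grad:
                raise TypeError(
                    f"input dtype {x.data.dtype} does not match parameter "
                    f"dtype {self.dtype}"
                )
            x = Tensor(x.data.astype(self.dtype))

        skips: list[Tensor] = []
        f = x
        for i in range(self.depth - 1):
            f = self.enc_blocks[i](f)
            skips.append(f)
            f = F.max_pool(f, self.pool_factors)
        f = self.enc_blocks[self.depth - 1](f)

        r_levels = [self.heads[self.depth - 1](f)]  # coarsest R
        d = f
        for i in range(self.depth - 2, -1, -1):
            d = self.dec_up_convs[i](F.upsample_linear(d, self.pool_factors))
            if self.skip_connections:
                d = F.concat([d, skips[i]], axis=1)
            d = self.dec_blocks[i](d)
            r_levels.append(self.heads[i](d))

        if self.use_mrd:
            finest = mrd_combine(r_levels, self.pool_factors)
        else:
            finest = r_levels[-1]

        residue = channel_to_space(
            self.out_proj(self.out_block(finest)), self.up_factors
        )
        return F.add(upper_path(x, self.up_factors), residue)


class UNet3D(Module):
    """Volumetric two-path network operating on (X, Y, Z) C-scans."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.net = TwoPathNet(
            ndim=3,
            up_factors=(1, cfg.up_factor_y, cfg.up_factor_z),
            pool_factors=cfg.pool_factors_3d(),
            depth=cfg.depth,
            base_channels=cfg.base_channels,
            channel_growth=cfg.channel_growth,
            head_channels=cfg.head_channels,
            max_channels=cfg.max_channels,
            use_mrd=cfg.use_mrd,
            skip_connections=cfg.skip_connections,
            rng=np.random.default_rng(seed),
        )
        if cfg.precision == "fp16":
            self.cast(np.float16)

    def __call__(self, x: Tensor) -> Tensor:
        return self.net(x)

    def forward_volume(self, vol: np.ndarray) -> np.ndarray:
        """Inference convenience: (X, Y, Z) array in, upsampled array out."""
        from ..nn.tensor import no_grad

        x = Tensor(vol[None, None].astype(self.dtype))
        with no_grad():
            y = self.net(x)
        return y.data[0, 0]

    def parameter_bytes(self, precision: str | None = None) -> int:
        precision = precision or self.cfg.precision
        width = {"fp32": 4, "fp16": 2}[precision]
        return self.parameter_count() * width


def parameter_count(cfg: NetworkConfig) -> int:
    """Exact trainable-scalar count for a configuration."""
    return UNet3D(cfg).parameter_count()


def parameter_bytes(cfg: NetworkConfig, precision: str | None = None) -> int:
    return UNet3D(cfg).parameter_bytes(precision)
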