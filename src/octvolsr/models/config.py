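"""Network configuration shared by the 3D model and the dual-2D baseline."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of a two-path super-resolution network.

    Defaults follow the full-scale configuration: 5 resolution levels
    (4 poolings), 4 base feature maps doubling per level, and a x4
    upsampling along both lateral axes.  ``pool_axes`` selects which axes
    the encoder halves per level ("xyz" classic, "yz" keeps the axial axis
    at full length); the multi-level residue decoder upsamples the same
    axes by 2 per level.
    """

    depth: int = 5
    base_channels: int = 4
    channel_growth: int = 2
    up_factor_y: int = 4
    up_factor_z: int = 4
    use_mrd: bool = True
    precision: str = "fp32"
    pool_axes: str = "xyz"
    head_channels: int = 4
    max_channels: int = 64
    skip_connections: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1 or self.head_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.up_factor_y < 1 or self.up_factor_z < 1:
            raise ValueError("upsampling factors must be >= 1")
        if self.precision not in ("fp32", "fp16"):
            raise ValueError("precision must be fp32 or fp16")
        if self.pool_axes not in ("xyz", "yz"):
            raise ValueError('pool_axes must be "xyz" or "yz"')

    def channels_at(self, level: int) -> int:
        return min(self.base_channels * self.channel_growth**level, self.max_channels)

    def pool_factors_3d(self) -> tuple[int, int, int]:
        return (2, 2, 2) if self.pool_axes == "xyz" else (1, 2, 2)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)
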