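"""Dual-2D-UNet baseline: sequential fast-axis then slow-axis upsampling.

The first stage (Y-UNet) sees the low-resolution volume as a batch of
Z-indexed XY B-scans and upsamples the fast axis x4; the second stage
(Z-UNet) sees the Y-stage prediction as a batch of X-indexed YZ en-face
images and upsamples the slow axis x4.  Both stages are the same two-path
architecture as the volumetric model with 2D operators; because each stage
upsamples a single axis by 4, the channel-to-space head consumes exactly 4
channels and needs no channel expansion beyond the zero-initialized 1x1
projection.

During training the Z-stage batch (one image per A-scan position, 1024 at
full scale) is randomly subsampled to bound memory; at test time the full
batch is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import functional as F
from ..nn.layers import Module
from ..nn.tensor import Tensor, no_grad
from ..volumes import Volume
from .config import NetworkConfig
from .twopath import TwoPathNet


@dataclass
class SliceBatch:
    """An ordered stack of 2D slices cut from a volume along one axis."""

    images: np.ndarray  # (B, H, W)
    slice_axis: str  # volume axis indexing the batch
    in_plane_axes: tuple[str, str]

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("SliceBatch expects (batch, H, W) images")

    @property
    def batch_size(self) -> int:
        return self.images.shape[0]


def slice_for_y_stage(low: Volume) -> SliceBatch:
    """Cut a low-resolution volume into Z-indexed XY B-scan images."""
    return SliceBatch(
        images=np.ascontiguousarray(np.moveaxis(low.data, 2, 0)),
        slice_axis="Z",
        in_plane_axes=("X", "Y"),
    )


def slice_for_z_stage(mid_pred: Volume) -> SliceBatch:
    """Cut a mid-resolution volume into X-indexed YZ en-face images."""
    return SliceBatch(
        images=np.ascontiguousarray(mid_pred.data),
        slice_axis="X",
        in_plane_axes=("Y", "Z"),
    )


def reassemble(batch: SliceBatch) -> Volume:
    """Stack a slice batch back into an (X, Y, Z) volume."""
    if batch.slice_axis == "Z":
        return Volume(np.moveaxis(batch.images, 0, 2))
    if batch.slice_axis == "X":
        return Volume(batch.images)
    raise ValueError(f"unsupported slice axis {batch.slice_axis!r}")


def subsample_training_batch(
    batch: SliceBatch, k: int, seed: int | np.random.Generator
) -> tuple[SliceBatch, np.ndarray]:
    """Draw ``k`` distinct slices (without replacement), reproducibly.

    Returns the subsampled batch and the chosen indices so a caller can
    align ground-truth slices.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > batch.batch_size:
        raise ValueError(f"k={k} exceeds batch size {batch.batch_size}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = np.sort(rng.choice(batch.batch_size, size=k, replace=False))
    return (
        SliceBatch(batch.images[idx], batch.slice_axis, batch.in_plane_axes),
        idx,
    )


class DualUNet2D(Module):
    """Y-UNet + Z-UNet pipeline with a shared two-path 2D architecture."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg

        def stage(up_factor: int) -> TwoPathNet:
            return TwoPathNet(
                ndim=2,
                up_factors=(1, up_factor),
                pool_factors=(2, 2),
                depth=cfg.depth,
                base_channels=cfg.base_channels,
                channel_growth=cfg.channel_growth,
                head_channels=cfg.head_channels,
                max_channels=cfg.max_channels,
                use_mrd=cfg.use_mrd,
                skip_connections=cfg.skip_connections,
                rng=rng,
            )

        self.y_net = stage(cfg.up_factor_y)
        self.z_net = stage(cfg.up_factor_z)
        if cfg.precision == "fp16":
            self.cast(np.float16)

    # graph-building forward over Tensors -------------------------------
    def forward_tensors(
        self,
        low: Tensor,
        z_subsample: np.ndarray | None = None,
    ) -> tuple[Tensor, Tensor]:
        """``low``: (1, 1, X, Y, Z) tensor.  Returns (mid_pred, high_pred)
        as (1, 1, X, 4Y, Z) and (1|k, 1, Y', Z*4) stage outputs re-stitched
        into volume-shaped tensors; with ``z_subsample`` the high output
        holds only the selected A-scan rows (training mode).
        """
        _, _, nx, ny, nz = low.data.shape
        # Y stage: batch of Z-indexed XY images
        yb = F.reshape(
            F.transpose(low, (0, 4, 1, 2, 3)), (nz, 1, nx, ny)
        )
        y_out = self.y_net(yb)  # (Z, 1, X, 4Y)
        mid = F.transpose(
            F.reshape(y_out, (1, nz, 1, nx, ny * self.cfg.up_factor_y)),
            (0, 2, 3, 4, 1),
        )  # (1, 1, X, 4Y, Z)

        # Z stage: batch of X-indexed YZ images
        zb = F.reshape(
            F.transpose(mid, (0, 2, 1, 3, 4)),
            (nx, 1, ny * self.cfg.up_factor_y, nz),
        )
        if z_subsample is not None:
            zb = F.take(zb, z_subsample, axis=0)
        z_out = self.z_net(zb)  # (B, 1, 4Y, 4Z)
        return mid, z_out

    def forward_volume(self, vol: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference on an (X, Y, Z) array; full Z-stage batch."""
        x = Tensor(vol[None, None].astype(self.dtype))
        with no_grad():
            mid, z_out = self.forward_tensors(x)
        mid_pred = mid.data[0, 0]
        high_pred = z_out.data[:, 0]  # (X, 4Y, 4Z)
        return mid_pred, high_pred


def forward_d2d(
    low: Volume, model: DualUNet2D
) -> tuple[Volume, Volume]:
    """Run both stages on a volume, returning (mid_pred, high_pred)."""
    mid, high = model.forward_volume(low.data)
    return Volume(mid), Volume(high)
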