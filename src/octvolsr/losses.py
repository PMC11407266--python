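"""Composite training objective: L1 pixel loss plus anisotropic gradient loss.

The pixel term is the mean absolute voxel difference.  The gradient term
compares forward finite differences along each volume axis, weighted per
axis: axes with a coarser physical sampling pitch get a larger weight
because the same intensity step over a larger physical separation implies a
smaller true gradient.  Defaults: lambda = (16, 0.4, 0.05) for (x, y, z),
total = alpha * L_pixel + beta * L_gradient with alpha = 16, beta = 1.

Both losses are means over the *total* voxel count N (the difference arrays
have N - 1 entries per axis row), so loss magnitudes are independent of
volume size and batch construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F
from .nn.tensor import Tensor, as_tensor


@dataclass(frozen=True)
class LossWeights:
    """Balancing factors of the composite objective."""

    lambda1: float = 16.0  # axial (x) gradient weight
    lambda2: float = 0.4  # fast-axis (y) gradient weight
    lambda3: float = 0.05  # slow-axis (z) gradient weight
    alpha: float = 16.0  # pixel-loss weight
    beta: float = 1.0  # gradient-loss weight

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3, self.alpha, self.beta) < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def lambdas(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)


@dataclass
class LossReport:
    pixel: float
    gradient: float
    total: float
    components: dict[str, float] = field(default_factory=dict)


def _pair(pred, target) -> tuple[Tensor, Tensor]:
    p, t = as_tensor(pred), as_tensor(target)
    if p.data.shape != t.data.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {t.data.shape}")
    return p, t


def pixel_loss(pred, target) -> Tensor:
    """Mean absolute voxel difference (L1 / Manhattan distance over N)."""
    p, t = _pair(pred, target)
    return F.mean(F.abs_(F.sub(p, t)))


def gradient_loss(
    pred,
    target,
    w: LossWeights = LossWeights(),
    spatial_axes: tuple[int, ...] | None = None,
    lambdas: tuple[float, ...] | None = None,
) -> Tensor:
    """Weighted L1 distance between forward-difference gradients.

    ``spatial_axes`` maps the weights onto array axes; by default the last
    three axes for volume-shaped input (bare ``(X, Y, Z)`` or
    ``(N, C, X, Y, Z)``) with weights (lambda1, lambda2, lambda3), and the
    two in-plane axes for 2D slice batches ``(B, C, H, W)`` with weights
    (lambda2, lambda3) — the YZ en-face convention; pass ``lambdas``
    explicitly for XY B-scan batches.
    """
    p, t = _pair(pred, target)
    nd = p.data.ndim
    if spatial_axes is None:
        if nd == 4:  # (B, C, H, W) slice batch
            spatial_axes = (2, 3)
        elif nd >= 3:
            spatial_axes = tuple(range(nd - 3, nd))
        else:
            spatial_axes = tuple(range(nd))
    if lambdas is None:
        lambdas = (
            (w.lambda2, w.lambda3)
            if len(spatial_axes) == 2
            else (w.lambda1, w.lambda2, w.lambda3)[: len(spatial_axes)]
        )
    if len(lambdas) != len(spatial_axes):
        raise ValueError("need one gradient weight per spatial axis")
    n_total = p.data.size
    terms = None
    for lam, ax in zip(lambdas, spatial_axes):
        if p.data.shape[ax] < 2:
            raise ValueError(
                f"axis {ax} has extent {p.data.shape[ax]}; gradient undefined"
            )
        diff = F.abs_(F.sub(F.forward_diff(p, ax), F.forward_diff(t, ax)))
        term = F.scale(F.sum_(diff), lam / n_total)
        terms = term if terms is None else F.add(terms, term)
    return terms


def total_loss(
    pred,
    target,
    w: LossWeights = LossWeights(),
    spatial_axes: tuple[int, ...] | None = None,
    lambdas: tuple[float, ...] | None = None,
) -> tuple[Tensor, LossReport]:
    """Composite objective; returns the scalar graph node and a report."""
    lp = pixel_loss(pred, target)
    lg = gradient_loss(pred, target, w, spatial_axes, lambdas)
    lt = F.add(F.scale(lp, w.alpha), F.scale(lg, w.beta))
    report = LossReport(
        pixel=float(lp.data), gradient=float(lg.data), total=float(lt.data)
    )
    return lt, report


def d2d_loss(
    mid_pred,
    mid_true,
    high_pred,
    high_true,
    w: LossWeights = LossWeights(),
) -> tuple[Tensor, LossReport]:
    """Dual-2D objective: L = L_Ystage + L_Zstage, each the composite loss.

    The Y-stage prediction is scored against the mid-resolution member and
    the Z-stage prediction against the high-resolution member; gradients
    flow through both stages jointly.
    """
    ly, ry = total_loss(mid_pred, mid_true, w)
    lz, rz = total_loss(high_pred, high_true, w)
    lt = F.add(ly, lz)
    report = LossReport(
        pixel=ry.pixel + rz.pixel,
        gradient=ry.gradient + rz.gradient,
        total=float(lt.data),
        components={"y_stage": ry.total, "z_stage": rz.total},
    )
    return lt, report


def pixel_loss_value(pred: np.ndarray, target: np.ndarray) -> float:
    return float(pixel_loss(pred, target).data)


def gradient_loss_value(
    pred: np.ndarray, target: np.ndarray, w: LossWeights = LossWeights()
) -> float:
    return float(gradient_loss(pred, target, w).data)
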