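"""Differentiable ops for the two-path super-resolution networks.

All spatial ops take tensors shaped ``(N, C, *spatial)`` with ``spatial``
either 2D (slice batches) or 3D (whole C-scans), so the same U-Net blocks
serve both the volumetric model and the dual-2D baseline.

Convolutions are same-padded correlations with odd kernels, evaluated as
im2col + BLAS matmul; large volumes are processed in slabs along the first
spatial axis to bound the column-matrix footprint.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor, make_node

# im2col slab budget (elements of the column matrix per chunk)
_COL_BUDGET = 32_000_000


# ---------------------------------------------------------------------------
# elementwise / reduction
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward():
        g = out.grad
        if a.requires_grad or a._parents:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b.accumulate_grad(_unbroadcast(g, b.data.shape))

    out = make_node(out_data, (a, b), backward)
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward():
        g = out.grad
        if a.requires_grad or a._parents:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b.accumulate_grad(_unbroadcast(-g, b.data.shape))

    out = make_node(out_data, (a, b), backward)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    # sum over broadcast axes
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def scale(a: Tensor, s: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data * np.asarray(s, dtype=a.dtype)

    def backward():
        a.accumulate_grad(out.grad * np.asarray(s, dtype=a.dtype))

    return (out := make_node(out_data, (a,), backward))


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, np.asarray(0, dtype=a.dtype))

    def backward():
        a.accumulate_grad(out.grad * mask)

    return (out := make_node(out_data, (a,), backward))


def abs_(a: Tensor) -> Tensor:
    a = as_tensor(a)
    sign = np.sign(a.data)
    out_data = np.abs(a.data)

    def backward():
        a.accumulate_grad(out.grad * sign)

    return (out := make_node(out_data, (a,), backward))


def sum_(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(dtype=np.float64).astype(a.dtype)

    def backward():
        a.accumulate_grad(np.broadcast_to(out.grad, a.data.shape))

    return (out := make_node(np.asarray(out_data), (a,), backward))


def mean(a: Tensor) -> Tensor:
    return scale(sum_(a), 1.0 / as_tensor(a).data.size)


def forward_diff(a: Tensor, axis: int) -> Tensor:
    """First-order forward finite difference along the given array axis."""
    a = as_tensor(a)
    n = a.data.shape[axis]
    if n < 2:
        raise ValueError(f"axis {axis} has extent {n}; gradient undefined")
    hi = [slice(None)] * a.data.ndim
    lo = [slice(None)] * a.data.ndim
    hi[axis] = slice(1, None)
    lo[axis] = slice(None, -1)
    out_data = a.data[tuple(hi)] - a.data[tuple(lo)]

    def backward():
        g = np.zeros_like(a.data)
        g[tuple(hi)] += out.grad
        g[tuple(lo)] -= out.grad
        a.accumulate_grad(g)

    return (out := make_node(out_data, (a,), backward))


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    out_data = np.ascontiguousarray(np.transpose(a.data, axes))
    inv = tuple(np.argsort(axes))

    def backward():
        a.accumulate_grad(np.ascontiguousarray(np.transpose(out.grad, inv)))

    return (out := make_node(out_data, (a,), backward))


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward():
        a.accumulate_grad(out.grad.reshape(a.data.shape))

    return (out := make_node(out_data, (a,), backward))


def take(a: Tensor, indices: np.ndarray, axis: int) -> Tensor:
    """Index-select along an axis (gather); backward scatter-adds."""
    a = as_tensor(a)
    indices = np.asarray(indices)
    out_data = np.take(a.data, indices, axis=axis)

    def backward():
        g = np.zeros_like(a.data)
        sl: list = [slice(None)] * a.data.ndim
        sl[axis] = indices
        np.add.at(g, tuple(sl), out.grad)
        a.accumulate_grad(g)

    return (out := make_node(out_data, (a,), backward))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def backward():
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t.accumulate_grad(g)

    return (out := make_node(out_data, tuple(tensors), backward))


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _pad_same(x: np.ndarray, k: tuple[int, ...]) -> np.ndarray:
    pads = [(0, 0), (0, 0)] + [(kk // 2, kk // 2) for kk in k]
    return np.pad(x, pads)


def _conv_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded correlation; x (N,C,*S), w (O,C,*K), all K odd."""
    k = w.shape[2:]
    nd = len(k)
    spatial = x.shape[2:]
    N, C = x.shape[:2]
    O = w.shape[0]
    xp = _pad_same(x, k)
    wmat = w.reshape(O, -1)
    out = np.empty((N, O) + spatial, dtype=x.dtype)
    kprod = int(np.prod(k))
    rest = int(np.prod(spatial[1:], dtype=np.int64)) if nd > 1 else 1
    per_row = C * kprod * rest * max(N, 1)
    chunk = max(1, int(_COL_BUDGET // max(per_row, 1)))
    halo = k[0] - 1
    for i in range(0, spatial[0], chunk):
        j = min(i + chunk, spatial[0])
        xs = xp[:, :, i : j + halo]
        win = sliding_window_view(xs, k, axis=tuple(range(2, 2 + nd)))
        # (N, C, *Schunk, *K) -> (N, *Schunk, C*K)
        perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
        cols = np.ascontiguousarray(np.transpose(win, perm)).reshape(-1, C * kprod)
        res = cols @ wmat.T  # (N*Schunk, O)
        res = res.reshape((N,) + (j - i,) + spatial[1:] + (O,))
        out[:, :, i:j] = np.moveaxis(res, -1, 1)
    return out


def _conv_grad_w(x: np.ndarray, gout: np.ndarray, k: tuple[int, ...]) -> np.ndarray:
    nd = len(k)
    spatial = x.shape[2:]
    N, C = x.shape[:2]
    O = gout.shape[1]
    xp = _pad_same(x, k)
    kprod = int(np.prod(k))
    gw = np.zeros((O, C * kprod), dtype=np.float64)
    rest = int(np.prod(spatial[1:], dtype=np.int64)) if nd > 1 else 1
    per_row = C * kprod * rest * max(N, 1)
    chunk = max(1, int(_COL_BUDGET // max(per_row, 1)))
    halo = k[0] - 1
    for i in range(0, spatial[0], chunk):
        j = min(i + chunk, spatial[0])
        xs = xp[:, :, i : j + halo]
        win = sliding_window_view(xs, k, axis=tuple(range(2, 2 + nd)))
        perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
        cols = np.ascontiguousarray(np.transpose(win, perm)).reshape(-1, C * kprod)
        gmat = np.moveaxis(gout[:, :, i:j], 1, -1).reshape(-1, O)
        gw += gmat.T @ cols
    return gw.reshape((O, C) + k).astype(x.dtype)


def conv_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded multi-channel correlation with optional bias."""
    x, w = as_tensor(x), as_tensor(w)
    k = w.data.shape[2:]
    if any(kk % 2 == 0 for kk in k):
        raise ValueError("conv_same requires odd kernel extents")
    out_data = _conv_raw(x.data, w.data)
    if b is not None:
        bshape = (1, -1) + (1,) * len(k)
        out_data = out_data + b.data.reshape(bshape)

    def backward():
        g = out.grad
        if w.requires_grad:
            w.accumulate_grad(_conv_grad_w(x.data, g, k))
        if b is not None and b.requires_grad:
            axes = (0,) + tuple(range(2, g.ndim))
            b.accumulate_grad(g.sum(axis=axes))
        if x.requires_grad or x._parents:
            wf = w.data[..., ::-1, ::-1] if len(k) == 2 else w.data[..., ::-1, ::-1, ::-1]
            wt = np.ascontiguousarray(np.swapaxes(wf, 0, 1))
            x.accumulate_grad(_conv_raw(g, wt))

    parents = (x, w) if b is None else (x, w, b)
    return (out := make_node(out_data, parents, backward))


# ---------------------------------------------------------------------------
# pooling / resampling / shuffling
# ---------------------------------------------------------------------------

def max_pool(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Non-overlapping max pooling; per-spatial-axis factors (1 = keep)."""
    x = as_tensor(x)
    spatial = x.data.shape[2:]
    if len(factors) != len(spatial):
        raise ValueError("one pooling factor per spatial axis required")
    for s, f in zip(spatial, factors):
        if f < 1 or s % f != 0:
            raise ValueError(f"spatial extent {s} not divisible by pool factor {f}")
    shape = [x.data.shape[0], x.data.shape[1]]
    for s, f in zip(spatial, factors):
        shape += [s // f, f]
    xr = x.data.reshape(shape)
    # move all factor axes to the tail and flatten them
    nf = len(spatial)
    perm = [0, 1] + [2 + 2 * i for i in range(nf)] + [3 + 2 * i for i in range(nf)]
    xr = np.transpose(xr, perm)
    lead = xr.shape[: 2 + nf]
    xr = xr.reshape(lead + (-1,))
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward():
        g = np.zeros(lead + (int(np.prod(factors)),), dtype=x.data.dtype)
        np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=-1)
        g = g.reshape(lead + tuple(factors))
        # interleave block axes back: (N,C,s1',..,f1,..) -> (N,C,s1',f1,s2',f2,..)
        order = [0, 1]
        for i in range(nf):
            order += [2 + i, 2 + nf + i]
        g = np.transpose(g, order).reshape(x.data.shape)
        x.accumulate_grad(g)

    return (out := make_node(np.ascontiguousarray(out_data), (x,), backward))


def _interp_matrix(n: int, f: int, dtype) -> np.ndarray:
    """Linear-interpolation upsampling matrix (n*f, n), half-pixel centers."""
    m = np.zeros((n * f, n), dtype=dtype)
    for i in range(n * f):
        src = (i + 0.5) / f - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        i0c = min(max(i0, 0), n - 1)
        i1c = min(max(i0 + 1, 0), n - 1)
        m[i, i0c] += 1.0 - t
        m[i, i1c] += t
    return m


def upsample_linear(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Separable linear upsampling by integer factors per spatial axis.

    Uses half-pixel sample alignment with edge clamping, so constants are
    reproduced exactly and interior samples of a linear ramp stay on the
    ramp.
    """
    x = as_tensor(x)
    spatial = x.data.shape[2:]
    if len(factors) != len(spatial):
        raise ValueError("one upsampling factor per spatial axis required")
    if any(f < 1 for f in factors):
        raise ValueError("upsampling factors must be >= 1")
    mats = []
    out_data = x.data
    for ax, (n, f) in enumerate(zip(spatial, factors)):
        if f == 1:
            mats.append(None)
            continue
        m = _interp_matrix(n, f, x.data.dtype)
        mats.append(m)
        out_data = np.moveaxis(
            np.tensordot(m, out_data, axes=(1, 2 + ax)), 0, 2 + ax
        )
    out_data = np.ascontiguousarray(out_data)

    def backward():
        g = out.grad
        for ax, m in enumerate(mats):
            if m is None:
                continue
            g = np.moveaxis(np.tensordot(m.T, g, axes=(1, 2 + ax)), 0, 2 + ax)
        x.accumulate_grad(np.ascontiguousarray(g))

    return (out := make_node(out_data, (x,), backward))


def pixel_shuffle(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Channel-to-space rearrangement (sub-pixel convolution upsampling).

    Moves blocks of ``prod(factors)`` channels into an interleaved sub-grid
    of spatial positions: output voxel ``(f1*i1+j1, ...)`` reads input
    channel block offset ``(j1, ...)`` at position ``(i1, ...)``.  A factor
    of 1 leaves that axis untouched; the rearrangement is a bijection.
    """
    x = as_tensor(x)
    spatial = x.data.shape[2:]
    nd = len(spatial)
    if len(factors) != nd:
        raise ValueError("one shuffle factor per spatial axis required")
    fprod = int(np.prod(factors))
    N, C = x.data.shape[:2]
    if C % fprod != 0:
        raise ValueError(
            f"channel count {C} is not divisible by prod(factors)={fprod}"
        )
    Cout = C // fprod
    xr = x.data.reshape((N, Cout) + tuple(factors) + spatial)
    # (N, Cout, f1..fd, s1..sd) -> (N, Cout, s1, f1, s2, f2, ...)
    order = [0, 1]
    for i in range(nd):
        order += [2 + nd + i, 2 + i]
    out_data = np.ascontiguousarray(np.transpose(xr, order)).reshape(
        (N, Cout) + tuple(s * f for s, f in zip(spatial, factors))
    )

    def backward():
        g = out.grad.reshape(
            (N, Cout) + tuple(v for s, f in zip(spatial, factors) for v in (s, f))
        )
        inv = [0, 1] + [2 + 2 * i + 1 for i in range(nd)] + [2 + 2 * i for i in range(nd)]
        g = np.transpose(g, inv).reshape(x.data.shape)
        x.accumulate_grad(np.ascontiguousarray(g))

    return (out := make_node(out_data, (x,), backward))


def pixel_unshuffle(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Inverse of :func:`pixel_shuffle` (space-to-channel)."""
    x = as_tensor(x)
    spatial = x.data.shape[2:]
    nd = len(spatial)
    N, C = x.data.shape[:2]
    for s, f in zip(spatial, factors):
        if s % f != 0:
            raise ValueError("spatial extents must be divisible by factors")
    out_spatial = tuple(s // f for s, f in zip(spatial, factors))
    xr = x.data.reshape(
        (N, C) + tuple(v for s, f in zip(out_spatial, factors) for v in (s, f))
    )
    order = [0, 1] + [2 + 2 * i + 1 for i in range(nd)] + [2 + 2 * i for i in range(nd)]
    out_data = np.ascontiguousarray(np.transpose(xr, order)).reshape(
        (N, C * int(np.prod(factors))) + out_spatial
    )

    def backward():
        g = out.grad.reshape((N, C) + tuple(factors) + out_spatial)
        inv = [0, 1]
        for i in range(nd):
            inv += [2 + nd + i, 2 + i]
        g = np.transpose(g, inv).reshape(x.data.shape)
        x.accumulate_grad(np.ascontiguousarray(g))

    return (out := make_node(out_data, (x,), backward))
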