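"""Parameter containers and the building blocks shared by all networks."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Lightweight module tree with named-parameter traversal."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def cast(self, dtype) -> "Module":
        """Cast all parameters in place (e.g. to float16 for inference)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    @property
    def dtype(self):
        params = self.parameters()
        return params[0].data.dtype if params else np.float32

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch for parameters: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.astype(p.data.dtype)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}


class Conv(Module):
    """Same-padded convolution, Kaiming-uniform init, optional zero init."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        ndim: int,
        rng: np.random.Generator,
        zero_init: bool = False,
    ):
        shape = (out_ch, in_ch) + (kernel,) * ndim
        if zero_init:
            w = np.zeros(shape, dtype=np.float32)
        else:
            fan_in = in_ch * kernel**ndim
            bound = float(np.sqrt(6.0 / fan_in))
            w = rng.uniform(-bound, bound, size=shape).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_same(x, self.weight, self.bias)


class ResidueBlock(Module):
    """Two same-padded convolutions, each followed by ReLU, plus an
    identity shortcut added to the output.

    Batch normalization is deliberately absent: for super-resolution it
    re-centers feature statistics and measurably hurts reconstruction of
    high-frequency detail.  When the channel count changes, the shortcut is
    a 1x1 projection so the residual sum stays well-defined.
    """

    def __init__(self, in_ch: int, out_ch: int, ndim: int, rng: np.random.Generator):
        self.conv1 = Conv(in_ch, out_ch, 3, ndim, rng)
        self.conv2 = Conv(out_ch, out_ch, 3, ndim, rng)
        self.proj = None if in_ch == out_ch else Conv(in_ch, out_ch, 1, ndim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = F.relu(self.conv2(F.relu(self.conv1(x))))
        shortcut = x if self.proj is None else self.proj(x)
        return F.add(shortcut, y)
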