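"""Layer abstractions over the autograd tensors.

Modules own named :class:`Parameter` leaves and compose into networks the
way torch.nn modules do, but the surface is deliberately tiny: only what a
3-D encoder-decoder with attention blocks needs.
"""

from __future__ import annotations

from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from .autograd import Tensor, conv3d


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self._modules: Dict[str, "Module"] = {}
        self._params: Dict[str, Parameter] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._seq = mods

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x


class Conv3d(Module):
    """Grouped 3-D convolution with Kaiming-normal init."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        padding: Optional[int] = None,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if c_in % groups or c_out % groups:
            raise ValueError(f"groups={groups} must divide c_in={c_in} and c_out={c_out}")
        if padding is None:  # "same" for stride 1
            padding = dilation * (kernel - 1) // 2
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        rng = rng or np.random.default_rng()
        fan_in = (c_in // groups) * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in // groups, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding,
            dilation=self.dilation, groups=self.groups,
        )


class GroupNorm(Module):
    """Group normalization over (C/G, D, H, W) per group; batch-independent."""

    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % num_groups:
            raise ValueError(f"num_groups={num_groups} must divide channels={channels}")
        self.num_groups, self.channels, self.eps = num_groups, channels, eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.shape[:2]
        spatial = x.shape[2:]
        xg = x.reshape(B, self.num_groups, -1)
        mu = xg.mean(axis=2, keepdims=True)
        d = xg - mu
        var = (d * d).mean(axis=2, keepdims=True)
        xn = d / (var + self.eps).sqrt()
        xn = xn.reshape(B, C, *spatial)
        shape = (1, C) + (1,) * len(spatial)
        return xn * self.weight.reshape(shape) + self.bias.reshape(shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, std, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


def norm_groups_for(channels: int, preferred: int = 8) -> int:
    """Largest divisor of `channels` not exceeding `preferred`."""
    g = min(preferred, channels)
    while channels % g:
        g -= 1
    return g
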