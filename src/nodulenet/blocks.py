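"""Architectural primitives: multi-scale grouped convolution and the three
attention blocks (global-semantic, dual-spatial, channel).

The multi-scale block runs four grouped convolutional branches in parallel
over the same input — kernels 1³, 3³ and 5³ plus a residual 3³ branch — and
sums them element-wise:

    Y = Conv_res^(g)(X) + sum_{k in {1,3,5}} Conv_k^(g)(X)

All branches share one group number g, chosen adaptively as the largest
integer with g <= min(floor(C_in / 2), C_out) and g | C_out. Parallel
kernels give each output voxel simultaneous access to fine texture (1³),
local structure (3³) and broader context (5³), which is what makes the
decoder robust to the 3–30 mm size range of pulmonary nodules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .nn import Conv3d, GroupNorm, Linear, Module, Tensor, norm_groups_for


def group_number(c_in: int, c_out: int) -> int:
    """Adaptive group count: largest g with g <= min(c_in // 2, c_out) and g | c_out.

    Returns 1 when c_in // 2 == 0 (g = 1 is always admissible).
    """
    if c_in < 1 or c_out < 1:
        raise ValueError("channel counts must be >= 1")
    cap = min(c_in // 2, c_out)
    for g in range(max(cap, 1), 0, -1):
        if c_out % g == 0:
            return g
    return 1


@dataclass(frozen=True)
class MSConvSpec:
    """Channel/kernel/group configuration of one multi-scale block."""

    c_in: int
    c_out: int
    kernel_sizes: Tuple[int, int, int] = (1, 3, 5)
    residual_kernel: int = 3
    dilation: int = 1  # alternative reading: same kernels with dilation > 1

    @property
    def groups(self) -> int:
        g = group_number(self.c_in, self.c_out)
        # a realizable grouped conv additionally needs g | c_in
        while self.c_in % g or self.c_out % g:
            g -= 1
        return g


class MSConv(Module):
    """Four parallel grouped-conv branches summed element-wise."""

    def __init__(self, spec: MSConvSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.spec = spec
        g, d = spec.groups, spec.dilation
        ks = list(spec.kernel_sizes) + [spec.residual_kernel]
        for i, k in enumerate(ks):
            dil = d if k > 1 else 1
            setattr(
                self, f"branch{i}",
                Conv3d(spec.c_in, spec.c_out, k, dilation=dil, groups=g, rng=rng),
            )
        self._branches = [getattr(self, f"branch{i}") for i in range(len(ks))]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.c_in:
            raise ValueError(f"expected {self.spec.c_in} channels, got {x.shape[1]}")
        out = self._branches[0](x)
        for br in self._branches[1:]:
            out = out + br(x)
        return out

    def branch_outputs(self, x: Tensor):
        """Per-branch outputs (F1, F2, F3, F_res) for inspection/testing."""
        return [br(x) for br in self._branches]


@dataclass(frozen=True)
class AttentionBlockSpec:
    """Free hyper-parameters of one attention block."""

    kind: str  # {"GSA", "DSA", "CA"}
    channels: int
    reduction: int = 4          # CA: squeeze-excite bottleneck ratio
    spatial_kernel: int = 7     # DSA: conv kernel on the pooled spatial maps
    norm_groups: int = 0        # GSA: 0 -> largest divisor of channels <= 8

    def __post_init__(self):
        if self.kind not in ("GSA", "DSA", "CA"):
            raise ValueError(f"unknown attention kind {self.kind!r}")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")
        if self.channels < 1 or self.reduction < 1:
            raise ValueError("channels and reduction must be positive")


class GSA(Module):
    """Global semantic attention on skip-connection features.

    Two bottleneck projections (1³ conv to C/2 with group-norm + ReLU, then
    1³ conv back to C) produce two response maps. Each map passes through a
    sigmoid; the first is reduced by global average pooling, the second by
    global max pooling, giving two channel descriptors in (0, 1)^C. The
    input is reweighted channel-wise by both descriptors (multiplicative
    gating), then refined by a 3³ conv with group-norm + ReLU.
    """

    def __init__(self, spec: AttentionBlockSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if spec.kind != "GSA":
            raise ValueError("spec.kind must be GSA")
        C = spec.channels
        mid = max(C // 2, 1)
        ng = spec.norm_groups or norm_groups_for(C)
        ng_mid = norm_groups_for(mid, ng)
        self.spec = spec
        self.proj_avg_in = Conv3d(C, mid, 1, rng=rng)
        self.proj_avg_norm = GroupNorm(ng_mid, mid)
        self.proj_avg_out = Conv3d(mid, C, 1, rng=rng)
        self.proj_max_in = Conv3d(C, mid, 1, rng=rng)
        self.proj_max_norm = GroupNorm(ng_mid, mid)
        self.proj_max_out = Conv3d(mid, C, 1, rng=rng)
        self.refine = Conv3d(C, C, 3, rng=rng)
        self.refine_norm = GroupNorm(ng, C)

    def descriptors(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        r_avg = self.proj_avg_out(self.proj_avg_norm(self.proj_avg_in(x)).relu())
        r_max = self.proj_max_out(self.proj_max_norm(self.proj_max_in(x)).relu())
        d_avg = r_avg.sigmoid().mean(axis=(2, 3, 4), keepdims=True)
        d_max = r_max.sigmoid().max(axis=(2, 3, 4), keepdims=True)
        return d_avg, d_max

    def reweight(self, x: Tensor) -> Tensor:
        d_avg, d_max = self.descriptors(x)
        return x * d_avg * d_max

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.channels:
            raise ValueError(f"expected {self.spec.channels} channels, got {x.shape[1]}")
        return self.refine_norm(self.refine(self.reweight(x))).relu()


class DSA(Module):
    """Dual spatial attention after decoder fusion.

    Channel-wise average pooling and channel-wise max pooling each give a
    one-channel spatial map; each is convolved (spatial_kernel³, padding
    same) and squashed by a sigmoid into a spatial weighting map. The two
    weighted rescalings of the input are summed: the average branch keeps
    the nodule core stable, the max branch sharpens boundaries.
    """

    def __init__(self, spec: AttentionBlockSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if spec.kind != "DSA":
            raise ValueError("spec.kind must be DSA")
        self.spec = spec
        k = spec.spatial_kernel
        self.conv_avg = Conv3d(1, 1, k, rng=rng)
        self.conv_max = Conv3d(1, 1, k, rng=rng)

    def spatial_maps(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        pooled_avg = x.mean(axis=1, keepdims=True)
        pooled_max = x.max(axis=1, keepdims=True)
        return (
            self.conv_avg(pooled_avg).sigmoid(),
            self.conv_max(pooled_max).sigmoid(),
        )

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.channels:
            raise ValueError(f"expected {self.spec.channels} channels, got {x.shape[1]}")
        m_avg, m_max = self.spatial_maps(x)
        return x * m_avg + x * m_max


class CA(Module):
    """Squeeze-excite channel attention: global average pool, bottleneck
    (C / reduction) with ReLU, expansion, sigmoid channel weights."""

    def __init__(self, spec: AttentionBlockSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if spec.kind != "CA":
            raise ValueError("spec.kind must be CA")
        self.spec = spec
        C = spec.channels
        mid = max(C // spec.reduction, 1)
        self.squeeze = Linear(C, mid, rng=rng)
        self.excite = Linear(mid, C, rng=rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3, 4))  # (B, C)
        return self.excite(self.squeeze(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.channels:
            raise ValueError(f"expected {self.spec.channels} channels, got {x.shape[1]}")
        w = self.channel_weights(x)
        B, C = w.shape
        return x * w.reshape(B, C, 1, 1, 1)
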