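"""Multi-task 3-D network: shared residual encoder, attention-gated decoder
for voxel-wise nodule segmentation, and a channel-attention classification
branch for benign/malignant prediction.

Topology
--------
* Encoder: 3-D adaptation of an 18-layer residual network. Stem = 7³ conv,
  stride 2, then 2³ max-pool stride 2; four stages of two basic residual
  blocks each at strides 4/8/16/32 of the input.
* Decoder: three fusion stages. Each stage trilinearly upsamples the
  deeper feature, reduces channels with a 3³ conv, gates the encoder skip
  through global semantic attention (GSA), fuses by concatenation + 3³
  conv, refines with the multi-scale block (MSConv), and — in the two
  deepest stages — applies dual spatial attention (DSA). A final head
  upsamples ×4 back to input resolution and emits 2-channel logits.
* Classification branch: taps encoder stages 3 and 4 and the early-fusion
  decoder map (third fusion, pre-MSConv); each stream passes its own
  channel attention (CA), is globally average-pooled, concatenated, and
  mapped through one hidden fully connected layer to 2 logits.

Every attention block and the multi-scale block can be switched off via
``active_blocks`` to reproduce the ablation variants (baseline, +CA,
+CA+GSA, +CA+GSA+DSA, full); ``with_classification=False`` yields the pure
segmentation topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Optional, Tuple

import numpy as np

from .blocks import CA, DSA, GSA, AttentionBlockSpec, MSConv, MSConvSpec
from .nn import (
    Conv3d,
    GroupNorm,
    Linear,
    Module,
    Tensor,
    concat,
    maxpool3d_2,
    norm_groups_for,
    upsample_trilinear_2,
)

ALL_BLOCKS = frozenset({"CA", "GSA", "DSA", "MSConv"})


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    seg_classes: int = 2
    cls_classes: int = 2
    stage_channels: Tuple[int, int, int, int] = (64, 128, 256, 512)
    active_blocks: FrozenSet[str] = ALL_BLOCKS
    with_classification: bool = True
    ca_reduction: int = 4
    dsa_kernel: int = 7
    gsa_norm_groups: int = 0
    msconv_dilation: int = 1
    cls_hidden: int = 128
    seed: int = 0

    def __post_init__(self):
        if len(self.stage_channels) != 4:
            raise ValueError("exactly 4 encoder stages are required")
        if self.seg_classes != 2 or self.cls_classes != 2:
            raise ValueError("the network is binary in both tasks")
        unknown = set(self.active_blocks) - ALL_BLOCKS
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")
        object.__setattr__(self, "active_blocks", frozenset(self.active_blocks))

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "seg_classes": self.seg_classes,
            "cls_classes": self.cls_classes,
            "stage_channels": list(self.stage_channels),
            "active_blocks": sorted(self.active_blocks),
            "with_classification": self.with_classification,
            "ca_reduction": self.ca_reduction,
            "dsa_kernel": self.dsa_kernel,
            "gsa_norm_groups": self.gsa_norm_groups,
            "msconv_dilation": self.msconv_dilation,
            "cls_hidden": self.cls_hidden,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "stage_channels" in d:
            d["stage_channels"] = tuple(d["stage_channels"])
        if "active_blocks" in d:
            d["active_blocks"] = frozenset(d["active_blocks"])
        return cls(**d)


class ResidualBlock(Module):
    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        ng = norm_groups_for(c_out)
        self.conv1 = Conv3d(c_in, c_out, 3, stride=stride, padding=1, rng=rng)
        self.norm1 = GroupNorm(ng, c_out)
        self.conv2 = Conv3d(c_out, c_out, 3, padding=1, rng=rng)
        self.norm2 = GroupNorm(ng, c_out)
        self.project = None
        if stride != 1 or c_in != c_out:
            self.project = Conv3d(c_in, c_out, 1, stride=stride, padding=0, rng=rng)
            self.project_norm = GroupNorm(ng, c_out)

    def forward(self, x: Tensor) -> Tensor:
        out = self.norm2(self.conv2(self.norm1(self.conv1(x)).relu()))
        skip = x if self.project is None else self.project_norm(self.project(x))
        return (out + skip).relu()


class ConvNormRelu(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.conv = Conv3d(c_in, c_out, kernel, rng=rng)
        self.norm = GroupNorm(norm_groups_for(c_out), c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).relu()


class DecoderStage(Module):
    """Upsample deep features, gate the skip, fuse, refine."""

    def __init__(self, c_deep: int, c_skip: int, config: NetworkConfig,
                 use_dsa: bool, rng: Optional[np.random.Generator] = None):
        super().__init__()
        active = config.active_blocks
        self.reduce = ConvNormRelu(c_deep, c_skip, rng=rng)
        self.gsa = None
        if "GSA" in active:
            self.gsa = GSA(AttentionBlockSpec(
                "GSA", c_skip, norm_groups=config.gsa_norm_groups), rng=rng)
        self.fuse = ConvNormRelu(2 * c_skip, c_skip, rng=rng)
        self.msconv = None
        if "MSConv" in active:
            self.msconv = MSConv(MSConvSpec(
                c_skip, c_skip, dilation=config.msconv_dilation), rng=rng)
        self.dsa = None
        if use_dsa and "DSA" in active:
            self.dsa = DSA(AttentionBlockSpec(
                "DSA", c_skip, spatial_kernel=config.dsa_kernel), rng=rng)

    def forward(self, deep: Tensor, skip: Tensor) -> Tuple[Tensor, Tensor]:
        """Returns (stage output, post-fusion map)."""
        up = self.reduce(upsample_trilinear_2(deep))
        gated = self.gsa(skip) if self.gsa is not None else skip
        fused = self.fuse(concat([up, gated], axis=1))
        out = self.msconv(fused) if self.msconv is not None else fused
        if self.dsa is not None:
            out = self.dsa(out)
        return out, fused


class MultiTaskNoduleNet(Module):
    """The assembled encoder-decoder with the classification branch."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3, c4 = config.stage_channels

        # encoder
        self.stem = Conv3d(config.in_channels, c1, 7, stride=2, padding=3, rng=rng)
        self.stem_norm = GroupNorm(norm_groups_for(c1), c1)
        self.enc1a = ResidualBlock(c1, c1, rng=rng)
        self.enc1b = ResidualBlock(c1, c1, rng=rng)
        self.enc2a = ResidualBlock(c1, c2, stride=2, rng=rng)
        self.enc2b = ResidualBlock(c2, c2, rng=rng)
        self.enc3a = ResidualBlock(c2, c3, stride=2, rng=rng)
        self.enc3b = ResidualBlock(c3, c3, rng=rng)
        self.enc4a = ResidualBlock(c3, c4, stride=2, rng=rng)
        self.enc4b = ResidualBlock(c4, c4, rng=rng)

        # decoder, deepest fusion first
        self.dec1 = DecoderStage(c4, c3, config, use_dsa=True, rng=rng)
        self.dec2 = DecoderStage(c3, c2, config, use_dsa=True, rng=rng)
        self.dec3 = DecoderStage(c2, c1, config, use_dsa=False, rng=rng)

        # segmentation head: 1/4 resolution back to full
        self.head1 = ConvNormRelu(c1, max(c1 // 2, 2), rng=rng)
        self.head2 = ConvNormRelu(max(c1 // 2, 2), max(c1 // 4, 2), rng=rng)
        self.seg_out = Conv3d(max(c1 // 4, 2), config.seg_classes, 1, rng=rng)

        # classification branch
        if config.with_classification:
            streams = (c3, c4, c1)
            self._cls_cas = []
            for i, c in enumerate(streams):
                ca = None
                if "CA" in config.active_blocks:
                    ca = CA(AttentionBlockSpec("CA", c, reduction=config.ca_reduction), rng=rng)
                    setattr(self, f"cls_ca{i}", ca)
                self._cls_cas.append(ca)
            self.cls_hidden_fc = Linear(sum(streams), config.cls_hidden, rng=rng)
            self.cls_out = Linear(config.cls_hidden, config.cls_classes, rng=rng)

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor) -> Tuple[Tensor, Optional[Tensor]]:
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (B, {self.config.in_channels}, D, H, W), got {x.shape}")
        if any(s % 32 for s in x.shape[2:]):
            raise ValueError(f"spatial dims must be multiples of 32, got {x.shape[2:]}")

        h = maxpool3d_2(self.stem_norm(self.stem(x)).relu())
        f1 = self.enc1b(self.enc1a(h))        # c1 @ 1/4
        f2 = self.enc2b(self.enc2a(f1))       # c2 @ 1/8
        f3 = self.enc3b(self.enc3a(f2))       # c3 @ 1/16
        f4 = self.enc4b(self.enc4a(f3))       # c4 @ 1/32

        d1, _ = self.dec1(f4, f3)
        d2, _ = self.dec2(d1, f2)
        d3, ffm = self.dec3(d2, f1)           # ffm: early-fusion map at 1/4

        h = self.head1(upsample_trilinear_2(d3))
        h = self.head2(upsample_trilinear_2(h))
        seg_logits = self.seg_out(h)

        cls_logits = None
        if self.config.with_classification:
            pooled = []
            for stream, ca in zip((f3, f4, ffm), self._cls_cas):
                if ca is not None:
                    stream = ca(stream)
                pooled.append(stream.mean(axis=(2, 3, 4)))
            feats = concat(pooled, axis=1)
            cls_logits = self.cls_out(self.cls_hidden_fc(feats).relu())
        return seg_logits, cls_logits


def build_model(config: NetworkConfig) -> MultiTaskNoduleNet:
    return MultiTaskNoduleNet(config)


def scaled_down_config(
    stage_channels: Tuple[int, int, int, int] = (8, 16, 32, 64),
    **overrides,
) -> NetworkConfig:
    """A reduced-width configuration for CPU-scale experiments."""
    overrides.setdefault("cls_hidden", 32)
    return NetworkConfig(stage_channels=stage_channels, **overrides)
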