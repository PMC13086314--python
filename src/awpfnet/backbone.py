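"""Truncated residual backbone.

The feature extractor keeps only the stem (7x7 conv stride 2 + 3x3
max-pool) and the first two residual stages of an 18-layer residual
network, then maps channels to a common pyramid width with a 1x1
adapter.  Truncation preserves spatial detail that deeper stages would
downsample away — useful for fine-grained cap/gill texture — and keeps
the model small.  The full 18-layer classifier is also provided as an
ablation baseline.

The spatial contract: input side S (a multiple of 8) maps to S/8
(stem conv /2, max-pool /2, stage-2 /2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


@dataclass
class FeatureMap:
    """A (B, C, H, W) activation tagged with its pyramid level (0 is finest)."""

    data: nn.Tensor
    level: int = 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def numpy(self) -> np.ndarray:
        return self.data.numpy()


@dataclass
class BackboneConfig:
    adapter_channels: int = 256
    truncate_after_stage: int = 2   # 2 = truncated pyramid backbone, 4 = full net
    pretrained: bool | str = False  # path to a .npz weight file, or False
    adapter_norm_act: bool = True   # BN+ReLU after the 1x1 adapter

    def __post_init__(self):
        if self.adapter_channels <= 0:
            raise ValueError("adapter_channels must be positive")
        if self.truncate_after_stage not in (2, 4):
            raise ValueError("truncate_after_stage must be 2 or 4")


def validate_image_batch(images: np.ndarray) -> None:
    """Check the (B, 3, H, W) contract of an image batch."""
    if images.ndim != 4:
        raise ValueError(f"expected a 4-axis (B, C, H, W) array, got ndim={images.ndim}")
    if images.shape[1] != 3:
        raise ValueError(
            f"channel axis (axis 1) must have size 3 (RGB), got {images.shape[1]}")
    if min(images.shape[2], images.shape[3]) < 32:
        raise ValueError(
            f"spatial side must be at least 32, got {images.shape[2:]} "
            "(pooling would collapse the map)")


class BasicBlock(nn.Module):
    """Two 3x3 convs with identity (or 1x1-projected) skip connection."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, *, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + skip).relu()


_STAGE_WIDTHS = (64, 128, 256, 512)


class _ResNetTrunk(nn.Module):
    """Stem plus the first ``num_stages`` residual stages."""

    def __init__(self, num_stages: int, *, rng):
        super().__init__()
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(64)
        stages = []
        in_ch = 64
        for s, width in enumerate(_STAGE_WIDTHS[:num_stages]):
            stride = 1 if s == 0 else 2
            stages.append(BasicBlock(in_ch, width, stride, rng=rng))
            stages.append(BasicBlock(width, width, 1, rng=rng))
            in_ch = width
        self.stages = stages
        self.out_channels = in_ch

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = nn.max_pool2d(self.stem_bn(self.stem_conv(x)).relu(), 3, 2, 1)
        for block in self.stages:
            x = block(x)
        return x


class TruncatedBackbone(nn.Module):
    """Stem + stages 1-2 + 1x1 channel adapter producing the base feature F0."""

    def __init__(self, cfg: BackboneConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or BackboneConfig()
        rng = np.random.default_rng(seed)
        self.trunk = _ResNetTrunk(cfg.truncate_after_stage, rng=rng)
        self.adapter = nn.Conv2d(self.trunk.out_channels, cfg.adapter_channels, 1,
                                 rng=rng)
        self.adapter_bn = nn.BatchNorm2d(cfg.adapter_channels) if cfg.adapter_norm_act else None
        if cfg.pretrained:
            if cfg.pretrained is True:
                raise ValueError(
                    "no pretrained weights are bundled; pass a .npz weight-file "
                    "path as BackboneConfig.pretrained")
            with np.load(cfg.pretrained) as npz:
                self.load_state_dict(dict(npz))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = self.trunk(x)
        x = self.adapter(x)
        if self.adapter_bn is not None:
            x = self.adapter_bn(x).relu()
        return x


def extract_base_features(images, cfg: BackboneConfig | None = None,
                          backbone: TruncatedBackbone | None = None,
                          seed: int = 0) -> FeatureMap:
    """Run the truncated backbone on an image batch, returning level-0 features.

    A freshly seeded backbone is built unless ``backbone`` is supplied;
    passing the same seed gives identical weights and hence identical output.
    """
    arr = images.numpy() if isinstance(images, nn.Tensor) else np.asarray(images)
    validate_image_batch(arr)
    if backbone is None:
        backbone = TruncatedBackbone(cfg, seed=seed)
    backbone.eval()
    x = images if isinstance(images, nn.Tensor) else nn.Tensor(arr)
    return FeatureMap(backbone(x), level=0)


class BaselineResNet18(nn.Module):
    """Canonical untruncated 18-layer residual classifier (ablation baseline)."""

    def __init__(self, num_classes: int, seed: int = 0):
        super().__init__()
        if num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {num_classes}")
        rng = np.random.default_rng(seed)
        self.trunk = _ResNetTrunk(4, rng=rng)
        self.fc = nn.Linear(512, num_classes, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        feats = self.trunk(x)
        pooled = feats.mean(axis=(2, 3))
        return self.fc(pooled)


def baseline_resnet18(num_classes: int, seed: int = 0) -> BaselineResNet18:
    return BaselineResNet18(num_classes, seed=seed)
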