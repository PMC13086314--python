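"""Adaptive Window Pyramid Fusion (AWPF) and the assembled classifier.

The pipeline: the backbone's base feature F0 (28x28x256 for a 224 input)
is downsampled twice by stride-2 3x3 convolutions into a pyramid
(F0, F1, F2).  Fusion then runs bottom-up: the deepest map is enhanced
by DSW attention at its own resolution, upsampled, and added to the next
shallower map; the result is enhanced and propagated again until the
fused map F_AWPF at the F0 resolution feeds a global-average-pool +
linear head.  With cross-scale fusion disabled (ablation) the additive
skip terms are dropped and only the attention chain output is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import (BackboneConfig, FeatureMap, TruncatedBackbone,
                       validate_image_batch)
from .dsw import DSWConfig, DSWStack


@dataclass
class PyramidLevels:
    F0: FeatureMap
    F1: FeatureMap
    F2: FeatureMap

    def __iter__(self):
        return iter((self.F0, self.F1, self.F2))


@dataclass
class AWPFConfig:
    num_classes: int = 7
    cross_scale: bool = True
    fusion_order: str = "post"      # "post": DSW at native size, then upsample
                                    # "pre_add": DSW after upsampling (variant)
    dsw: DSWConfig = field(default_factory=DSWConfig)

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.fusion_order not in ("post", "pre_add"):
            raise ValueError(f"unknown fusion_order {self.fusion_order!r}")


class PyramidDown(nn.Module):
    """One stride-2 3x3 conv + BN + ReLU: halves the spatial resolution."""

    def __init__(self, channels: int, *, rng):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, stride=2, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.bn(self.conv(x)).relu()


def build_pyramid(F0: FeatureMap, down1: PyramidDown | None = None,
                  down2: PyramidDown | None = None, seed: int = 0) -> PyramidLevels:
    """Derive F1, F2 from F0 by two stride-2 3x3 conv + BN + ReLU steps."""
    if F0.level != 0:
        raise ValueError(f"build_pyramid expects a level-0 map, got level {F0.level}")
    H, W = F0.shape[2:]
    if min(H, W) < 4:
        raise ValueError(f"F0 side must be >= 4 to build two levels, got {H}x{W}")
    if down1 is None or down2 is None:
        rng = np.random.default_rng(seed)
        C = F0.shape[1]
        down1 = down1 or PyramidDown(C, rng=rng)
        down2 = down2 or PyramidDown(C, rng=rng)
        down1.eval(), down2.eval()
    F1 = FeatureMap(down1(F0.data), level=1)
    F2 = FeatureMap(down2(F1.data), level=2)
    return PyramidLevels(F0, F1, F2)


def fuse(p: PyramidLevels, dsw_level1: DSWStack, dsw_level2: DSWStack,
         cross_scale: bool = True, fusion_order: str = "post") -> FeatureMap:
    """Bottom-up attention fusion of the pyramid into a map at F0 resolution."""
    f0, f1, f2 = p.F0.data, p.F1.data, p.F2.data
    hw1, hw0 = f1.shape[2:], f0.shape[2:]
    if fusion_order == "pre_add":
        # variant ordering: upsample first, run DSW on the upsampled map
        u1 = dsw_level2(nn.upsample_bilinear(f2, hw1))
        f1_enh = (f1 + u1) if cross_scale else u1
        u0 = dsw_level1(nn.upsample_bilinear(f1_enh, hw0))
    else:
        u1 = nn.upsample_bilinear(dsw_level2(f2), hw1)
        f1_enh = (f1 + u1) if cross_scale else u1
        u0 = nn.upsample_bilinear(dsw_level1(f1_enh), hw0)
    fused = (f0 + u0) if cross_scale else u0
    if fused.shape[2:] != f0.shape[2:]:  # pragma: no cover - internal contract
        raise AssertionError("fused map does not match the F0 resolution")
    return FeatureMap(fused, level=0)


class ClassifierHead(nn.Module):
    """Global average pooling followed by a linear map to K classes."""

    def __init__(self, channels: int, num_classes: int, *, rng):
        super().__init__()
        if num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {num_classes}")
        self.fc = nn.Linear(channels, num_classes, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc(x.mean(axis=(2, 3)))


def classify(F: FeatureMap, head: ClassifierHead) -> nn.Tensor:
    """Logits (B, K) from a fused feature map; no softmax is applied."""
    x = F.data if isinstance(F, FeatureMap) else F
    if not isinstance(x, nn.Tensor):
        x = nn.Tensor(np.asarray(x))
    return head(x)


class AWPFResNet18(nn.Module):
    """Truncated residual backbone + AWPF fusion + GAP/linear head."""

    def __init__(self, cfg: AWPFConfig | None = None,
                 backbone_cfg: BackboneConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or AWPFConfig()
        self.backbone = TruncatedBackbone(backbone_cfg, seed=seed)
        C = self.backbone.cfg.adapter_channels
        rng = np.random.default_rng(seed + 1)
        self.down1 = PyramidDown(C, rng=rng)
        self.down2 = PyramidDown(C, rng=rng)
        self.dsw_level1 = DSWStack(C, level=1, cfg=cfg.dsw, rng=rng)
        self.dsw_level2 = DSWStack(C, level=2, cfg=cfg.dsw, rng=rng)
        self.head = ClassifierHead(C, cfg.num_classes, rng=rng)
        self._captured: dict[str, FeatureMap] = {}
        self.capture_features = False   # keep feature maps for Grad-CAM

    def forward(self, images) -> nn.Tensor:
        x = images if isinstance(images, nn.Tensor) else nn.Tensor(np.asarray(images))
        validate_image_batch(x.numpy())
        f0 = FeatureMap(self.backbone(x), level=0)
        pyramid = build_pyramid(f0, self.down1, self.down2)
        fused = fuse(pyramid, self.dsw_level1, self.dsw_level2,
                     self.cfg.cross_scale, self.cfg.fusion_order)
        self._captured = ({"fused": fused, "backbone": f0}
                          if self.capture_features else {})
        return self.head(fused.data)

    @property
    def fused_features(self) -> FeatureMap | None:
        """Fused map F_AWPF of the last forward (when capture_features is on)."""
        return self._captured.get("fused")

    @property
    def captured_features(self) -> dict[str, FeatureMap]:
        return self._captured


def build_model(cfg: AWPFConfig | None = None, seed: int = 0) -> AWPFResNet18:
    return AWPFResNet18(cfg, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable weight elements."""
    return model.num_parameters()
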