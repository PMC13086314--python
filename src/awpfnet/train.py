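"""Training loop, evaluation, and checkpointing.

Defaults follow the study protocol for this task: 224x224 inputs,
AdamW at learning rate 1e-3, batch size 32, 50 epochs, five replicate
seeds.  The best checkpoint is selected by validation macro recall
(MR), the metric weighted most heavily for imbalanced classes; the
selection criterion is configurable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .awpf import AWPFConfig, AWPFResNet18
from .backbone import BackboneConfig
from .data import LabeledImageSet
from .dsw import DSWConfig
from .metrics import MetricsReport, aggregate_reports, confusion

log = logging.getLogger(__name__)

DEFAULT_SEEDS = (0, 1, 2, 3, 4)


@dataclass
class TrainConfig:
    image_size: int = 224
    batch_size: int = 32
    lr: float = 1e-3
    optimizer: str = "adamw"
    weight_decay: float = 0.01
    epochs: int = 50
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    device: str = "cpu"
    num_classes: int = 7
    # ablation axes
    window_strategy: str = "mix"
    cross_scale: bool = True
    dsw_depth: int = 2
    heads: int = 8
    with_ffn: bool = True
    fusion_order: str = "post"
    best_metric: str = "mr"       # checkpoint selection criterion
    arch: str = "awpf"            # "awpf" | "resnet18" baseline
    hflip: bool = False           # random horizontal flip augmentation

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1 or self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("hyperparameters must be positive")
        if self.optimizer.lower() != "adamw":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.best_metric not in ("acc", "mp", "mr", "mf"):
            raise ValueError(f"unknown best_metric {self.best_metric!r}")
        if self.arch not in ("awpf", "resnet18"):
            raise ValueError(f"unknown arch {self.arch!r}")

    def model_config(self) -> AWPFConfig:
        dsw = DSWConfig(depth=self.dsw_depth, window_strategy=self.window_strategy,
                        num_heads=self.heads, with_ffn=self.with_ffn)
        return AWPFConfig(num_classes=self.num_classes, cross_scale=self.cross_scale,
                          fusion_order=self.fusion_order, dsw=dsw)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seeds" in raw:
            raw["seeds"] = tuple(raw["seeds"])
        return cls(**raw)


@dataclass
class RunRecord:
    seed: int
    config: dict
    epochs: list[dict] = field(default_factory=list)
    final_report: MetricsReport | None = None
    checkpoint_path: str | None = None


def build_from_config(cfg: TrainConfig, seed: int = 0) -> nn.Module:
    if cfg.arch == "resnet18":
        from .backbone import baseline_resnet18
        return baseline_resnet18(cfg.num_classes, seed=seed)
    return AWPFResNet18(cfg.model_config(), BackboneConfig(), seed=seed)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: nn.Module, path, cfg: TrainConfig | None = None,
                    seed: int = 0, epoch: int = 0) -> None:
    """Weights keyed by layer path, plus a JSON metadata block."""
    state = model.state_dict()
    meta = {"seed": seed, "epoch": epoch,
            "config": asdict(cfg) if cfg is not None else None}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[nn.Module, dict]:
    """Rebuild the model recorded in a checkpoint and load its weights."""
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
        meta = json.loads(bytes(npz["__meta__"]).decode())
    cfg_dict = meta.get("config") or {}
    if "seeds" in cfg_dict and cfg_dict["seeds"] is not None:
        cfg_dict["seeds"] = tuple(cfg_dict["seeds"])
    cfg = TrainConfig(**cfg_dict) if cfg_dict else TrainConfig()
    model = build_from_config(cfg, seed=meta.get("seed", 0))
    model.load_state_dict(state)
    return model, meta


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def predict_scores(model: nn.Module, dataset: LabeledImageSet,
                   batch_size: int = 16) -> np.ndarray:
    """Softmax class scores (n, K) for every item, in dataset order."""
    model.eval()
    chunks = []
    for start in range(0, len(dataset), batch_size):
        idx = range(start, min(start + batch_size, len(dataset)))
        logits = model(nn.Tensor(dataset.load_batch(idx)))
        chunks.append(logits.softmax(axis=1).numpy())
    return np.concatenate(chunks) if chunks else np.zeros((0, 0))


def evaluate_model(model: nn.Module, dataset: LabeledImageSet,
                   batch_size: int = 16):
    """MetricsReport plus raw scores for a labelled set."""
    scores = predict_scores(model, dataset, batch_size)
    y_true = dataset.labels
    y_pred = scores.argmax(axis=1)
    cm = confusion(y_true, y_pred, len(dataset.class_names))
    return MetricsReport.from_confusion(cm, dataset.class_names), scores


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(train_set: LabeledImageSet, val_set: LabeledImageSet,
                cfg: TrainConfig | None = None, seed: int = 0,
                checkpoint_path=None, verbose: bool = False) -> RunRecord:
    """Train one model; all stochastic sources derive from ``seed``."""
    cfg = cfg or TrainConfig()
    k = len(train_set.class_names)
    if k != cfg.num_classes:
        raise ValueError(
            f"dataset has {k} classes but the model head expects "
            f"{cfg.num_classes}; set TrainConfig.num_classes accordingly")
    model = build_from_config(cfg, seed=seed)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(seed)
    labels = train_set.labels
    record = RunRecord(seed=seed, config=asdict(cfg))
    best_score = -1.0

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = train_set.load_batch(idx)
            if cfg.hflip:
                flip = rng.random(len(idx)) < 0.5
                batch[flip] = batch[flip, :, :, ::-1]
            images = nn.Tensor(batch)
            opt.zero_grad()
            loss = nn.cross_entropy(model(images), labels[idx])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        report, _ = evaluate_model(model, val_set, batch_size=cfg.batch_size)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "val_acc": report.acc, "val_mp": report.mp,
                 "val_mr": report.mr, "val_mf": report.mf}
        record.epochs.append(entry)
        if verbose:
            log.info("epoch %d: loss=%.4f acc=%.3f mr=%.3f",
                     epoch, entry["train_loss"], report.acc, report.mr)
        score = getattr(report, cfg.best_metric)
        if score > best_score:
            best_score = score
            record.final_report = report
            if checkpoint_path is not None:
                save_checkpoint(model, checkpoint_path, cfg, seed, epoch)
                record.checkpoint_path = str(checkpoint_path)
    return record


def evaluate(checkpoint_path, val_set: LabeledImageSet,
             seeds=(0,), batch_size: int = 16) -> dict:
    """Replicated evaluation of a checkpoint, aggregated as mean +/- SD."""
    model, _ = load_checkpoint(checkpoint_path)
    k_model = model.state_dict()["head.fc.bias"].shape[0] \
        if "head.fc.bias" in model.state_dict() else model.state_dict()["fc.bias"].shape[0]
    if k_model != len(val_set.class_names):
        raise ValueError(f"checkpoint head has {k_model} classes, dataset has "
                         f"{len(val_set.class_names)}")
    reports = []
    for _seed in seeds:
        report, _ = evaluate_model(model, val_set, batch_size)
        reports.append(report)
    agg = aggregate_reports(reports)
    agg["per_replicate"] = [r.to_dict() for r in reports]
    return agg
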