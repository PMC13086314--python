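"""High-level modelling interface: a classifier bound to data, whose
``fit`` returns a results object with metrics, diagnostics and plots.

    >>> clf = AWPFClassifier.from_synthetic(scale=1/16, epochs=5)
    >>> res = clf.fit(seeds=[0])
    >>> print(res.summary())

The classifier object holds the dataset and the training configuration;
fitting trains one network per replicate seed and the results object
carries the per-replicate metric reports, their mean +/- SD aggregate,
the best checkpointed network (by validation macro recall), per-class
diagnostics, and Grad-CAM explanations.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import nn
from .data import (DatasetSpec, LabeledImageSet, generate_synthetic_dataset,
                   load_image_folder, stratified_split)
from .explain import grad_cam, save_heatmap_png
from .metrics import (MetricsReport, aggregate_reports, plot_confusion,
                      plot_pr_curves)
from .train import (RunRecord, TrainConfig, evaluate_model, load_checkpoint,
                    save_checkpoint, train_model)


class AWPFClassifier:
    """Pyramid-fusion mushroom classifier bound to a train/validation set."""

    def __init__(self, train_set: LabeledImageSet, val_set: LabeledImageSet,
                 config: TrainConfig | None = None):
        if train_set.class_names != val_set.class_names:
            raise ValueError("train and validation sets disagree on classes")
        self.train_set = train_set
        self.val_set = val_set
        k = len(train_set.class_names)
        self.config = config or TrainConfig(num_classes=k)
        if self.config.num_classes != k:
            raise ValueError(f"config.num_classes={self.config.num_classes} "
                             f"but the dataset has {k} classes")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_folder(cls, root, config: TrainConfig | None = None,
                    image_size: int = 224) -> "AWPFClassifier":
        """Read ``root/train`` and ``root/val`` class-subdirectory trees."""
        root = Path(root)
        size = (image_size, image_size)
        if (root / "train").is_dir() and (root / "val").is_dir():
            train = load_image_folder(root / "train", size)
            val = load_image_folder(root / "val", size)
        else:
            full = load_image_folder(root, size)
            train, val = stratified_split(full, 0.7)
        return cls(train, val, config)

    @classmethod
    def from_synthetic(cls, spec: DatasetSpec | None = None, out_dir=None,
                       scale: float | None = None,
                       config: TrainConfig | None = None,
                       **config_kwargs) -> "AWPFClassifier":
        """Generate (or reuse) a synthetic dataset and bind to it."""
        spec = spec or DatasetSpec()
        if scale is not None:
            spec = spec.scaled(scale)
        if out_dir is None:
            out_dir = Path(tempfile.mkdtemp(prefix="awpf_synth_"))
        full = generate_synthetic_dataset(spec, out_dir)
        train, val = full.subset("train"), full.subset("val")
        if config is None and config_kwargs:
            config = TrainConfig(num_classes=len(train.class_names),
                                 **config_kwargs)
        return cls(train, val, config)

    # -- fitting -----------------------------------------------------------

    def fit(self, seeds=None, checkpoint_dir=None,
            verbose: bool = False) -> "FitResults":
        """Train one replicate per seed; aggregate metrics as mean +/- SD."""
        seeds = list(seeds if seeds is not None else self.config.seeds)
        if not seeds:
            raise ValueError("at least one seed is required")
        if checkpoint_dir is None:
            checkpoint_dir = Path(tempfile.mkdtemp(prefix="awpf_ckpt_"))
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for seed in seeds:
            ckpt = checkpoint_dir / f"seed{seed}.npz"
            records.append(train_model(self.train_set, self.val_set,
                                       self.config, seed=seed,
                                       checkpoint_path=ckpt, verbose=verbose))
        return FitResults(self, records)


class FitResults:
    """Estimates and diagnostics from fitted replicates."""

    def __init__(self, model: AWPFClassifier, records: list[RunRecord]):
        self.model = model
        self.records = records
        self.reports = [r.final_report for r in records]
        self.aggregate = aggregate_reports(self.reports)
        crit = model.config.best_metric
        self.best_index = int(np.argmax([getattr(r, crit) for r in self.reports]))
        self.best_record = records[self.best_index]
        self._network = None

    # -- access ------------------------------------------------------------

    @property
    def best_report(self) -> MetricsReport:
        return self.reports[self.best_index]

    @property
    def network(self) -> nn.Module:
        """The best replicate's network, reloaded from its checkpoint."""
        if self._network is None:
            net, _ = load_checkpoint(self.best_record.checkpoint_path)
            net.eval()
            self._network = net
        return self._network

    def predict(self, images) -> np.ndarray:
        """Class scores (softmax) for a (B, 3, H, W) image array."""
        return self.network(nn.Tensor(np.asarray(images))).softmax(axis=1).numpy()

    def grad_cam(self, image, class_index: int, target: str = "fused"):
        return grad_cam(self.network, image, class_index, target)

    def save(self, path) -> None:
        save_checkpoint(self.network, path, self.model.config,
                        seed=self.best_record.seed)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Statsmodels-style text summary of the fit."""
        cfg = self.model.config
        agg = self.aggregate
        lines = []
        w = 72
        lines.append("AWPF-ResNet18 classification results".center(w))
        lines.append("=" * w)
        lines.append(f"{'No. train images:':<28}{len(self.model.train_set):>10}"
                     f"    {'Replicate seeds:':<20}{len(self.records):>6}")
        lines.append(f"{'No. val images:':<28}{len(self.model.val_set):>10}"
                     f"    {'Epochs:':<20}{cfg.epochs:>6}")
        lines.append(f"{'Classes:':<28}{cfg.num_classes:>10}"
                     f"    {'Batch size:':<20}{cfg.batch_size:>6}")
        lines.append(f"{'Optimizer:':<28}{cfg.optimizer:>10}"
                     f"    {'Learning rate:':<20}{cfg.lr:>6}")
        lines.append(f"{'Window strategy:':<28}{cfg.window_strategy:>10}"
                     f"    {'Cross-scale:':<20}{str(cfg.cross_scale):>6}")
        lines.append("-" * w)
        lines.append(f"{'metric':<10}{'mean':>10}{'sd':>10}    ({agg['sd_convention']})")
        for key, label in (("acc", "Acc"), ("mp", "MP"), ("mr", "MR"), ("mf", "MF")):
            m, s = agg[key]["mean"], agg[key]["sd"]
            lines.append(f"{label:<10}{m:>10.4f}{s:>10.4f}")
        lines.append("-" * w)
        lines.append("Per-class (best replicate, selected by validation "
                     f"{cfg.best_metric.upper()}):")
        lines.append(f"{'class':<22}{'precision':>10}{'recall':>10}{'f1':>10}"
                     f"{'support':>9}")
        for row in self.best_report.per_class:
            lines.append(f"{str(row['class']):<22}{row['precision']:>10.3f}"
                         f"{row['recall']:>10.3f}{row['f1']:>10.3f}"
                         f"{row['support']:>9}")
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_confusion(self, path) -> None:
        plot_confusion(self.best_report.confusion_matrix, path,
                       self.model.val_set.class_names)

    def plot_pr(self, path) -> None:
        _, scores = evaluate_model(self.network, self.model.val_set)
        plot_pr_curves(scores, self.model.val_set.labels, path,
                       self.model.val_set.class_names)

    def plot_grad_cam(self, image, class_index: int, path,
                      target: str = "fused") -> None:
        cam = self.grad_cam(image, class_index, target)
        save_heatmap_png(cam, image, path)
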