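"""Training protocol, evaluation metrics, Grad-CAM heat maps, ablations.

The protocol: mini-batches of 32, up to 40 epochs of SGD with momentum on a
cross-entropy loss over softmax class probabilities, Glorot (Xavier) weight
initialization with zero biases.  Batch normalization uses batch statistics
during training and accumulated running statistics at evaluation time.  An
optional validation-accuracy plateau stop ends training early once the
model has converged; the returned report always states how many epochs ran.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path as FSPath

import numpy as np
from PIL import Image

from . import nn
from .data_pipeline import batch_indices, channel_stats, load_manifest_images
from .model import Network, init_network
from .model_zoo import ModelConfig, config_param_total, parameter_size_mb
from .synthetic_herd import DatasetManifest

__all__ = [
    "TrainConfig",
    "TrainReport",
    "HeatMap",
    "init_xavier",
    "train_model",
    "evaluate",
    "gradcam_heatmap",
    "ablation_run",
    "ablation_variants",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol. Defaults follow the study protocol: 40 epochs
    of batch-32 SGD (momentum 0.9, learning rate 0.01), cross-entropy loss,
    Xavier initialization with zero bias."""

    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 20210601
    image_size: tuple[int, int] = (224, 224)
    stop_at_val_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")


@dataclass
class TrainReport:
    """Per-epoch curves plus the final validation confusion matrix."""

    train_loss: list[float]
    train_accuracy: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    confusion: np.ndarray
    best_val_accuracy: float
    best_epoch: int
    epochs_run: int
    wall_time_s: float

    def to_json(self, path: str | FSPath) -> None:
        payload = {
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "confusion": self.confusion.tolist(),
            "best_val_accuracy": self.best_val_accuracy,
            "best_epoch": self.best_epoch,
            "epochs_run": self.epochs_run,
            "wall_time_s": self.wall_time_s,
        }
        FSPath(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class HeatMap:
    """A [0, 1]-normalized class-evidence map at input resolution."""

    values: np.ndarray
    source: str
    target_class: int


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


def init_xavier(model: Network, seed: int) -> Network:
    """(Re-)initialize: Glorot-normal weights, zero biases and BN shifts,
    unit BN scales; deterministic under ``seed``."""
    init_network(model, seed)
    return model


def _forward_in_chunks(model: Network, images: np.ndarray, chunk: int = 64) -> np.ndarray:
    outs = [model.forward(images[i : i + chunk]) for i in range(0, len(images), chunk)]
    return np.concatenate(outs, axis=0)


def train_model(
    model: Network,
    train_manifest: DatasetManifest,
    val_manifest: DatasetManifest,
    config: TrainConfig,
) -> TrainReport:
    """Run the optimization protocol and return the full learning record.

    Images are cached in memory once (resized to ``config.image_size``,
    normalized by the training set's own per-channel statistics); each epoch
    reshuffles deterministically under ``(seed, epoch)``.  The best
    validation weights are restored into the model before returning.
    """
    if not train_manifest.records or not val_manifest.records:
        raise ValueError("train and validation manifests must be non-empty")
    train_paths = {(r.path, r.rotation) for r in train_manifest.records}
    val_paths = {(r.path, r.rotation) for r in val_manifest.records}
    if train_paths & val_paths:
        raise ValueError("train and validation manifests overlap")

    t0 = time.perf_counter()
    x_train, y_train = load_manifest_images(train_manifest, config.image_size)
    x_val, y_val = load_manifest_images(val_manifest, config.image_size)
    mean, std = channel_stats(x_train)
    x_train = (x_train - mean[None, :, None, None]) / std[None, :, None, None]
    x_val = (x_val - mean[None, :, None, None]) / std[None, :, None, None]

    opt = nn.SGD(
        model.parameters(), model.gradients(),
        lr=config.learning_rate, momentum=config.momentum,
    )
    report = TrainReport(
        train_loss=[], train_accuracy=[], val_loss=[], val_accuracy=[],
        confusion=np.zeros((model.config.n_classes,) * 2, dtype=np.int64),
        best_val_accuracy=-1.0, best_epoch=-1, epochs_run=0, wall_time_s=0.0,
    )
    best_state = None
    for epoch in range(config.epochs):
        losses, correct, seen = [], 0, 0
        for idx in batch_indices(len(y_train), config.batch_size, config.seed, epoch):
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch + 1)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
            seen += len(idx)
        report.train_loss.append(float(np.mean(losses)))
        report.train_accuracy.append(correct / seen)

        val_logits = _forward_in_chunks(model, x_val)
        vloss, _ = nn.cross_entropy(val_logits, y_val)
        vacc = float((val_logits.argmax(axis=1) == y_val).mean())
        report.val_loss.append(float(vloss))
        report.val_accuracy.append(vacc)
        report.epochs_run = epoch + 1
        if vacc > report.best_val_accuracy:
            report.best_val_accuracy = vacc
            report.best_epoch = epoch + 1
            best_state = model.state_dict()
        if (
            config.stop_at_val_accuracy is not None
            and vacc >= config.stop_at_val_accuracy
        ):
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    preds = _forward_in_chunks(model, x_val).argmax(axis=1)
    report.confusion = confusion_matrix(y_val, preds, model.config.n_classes)
    report.wall_time_s = time.perf_counter() - t0
    return report


def confusion_matrix(labels: np.ndarray, preds: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    return cm


def evaluate(
    model: Network,
    manifest: DatasetManifest,
    image_size: tuple[int, int] = (224, 224),
    mean: np.ndarray | None = None,
    std: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Accuracy (correct/total) and confusion matrix on a manifest.

    Rows of the confusion matrix sum to per-class image counts; its trace
    over its sum equals the accuracy by construction.
    """
    labels = manifest.labels()
    if labels.max(initial=0) >= model.config.n_classes or labels.min(initial=0) < 0:
        raise ValueError(
            f"manifest labels exceed the model's {model.config.n_classes} classes"
        )
    images, _ = load_manifest_images(manifest, image_size)
    if mean is not None:
        images = (images - mean[None, :, None, None]) / std[None, :, None, None]
    preds = _forward_in_chunks(model, images).argmax(axis=1)
    cm = confusion_matrix(labels, preds, model.config.n_classes)
    return float((preds == labels).mean()), cm


def gradcam_heatmap(
    model: Network,
    image: np.ndarray,
    target_class: int,
    stage: str = "se3",
    source: str = "<array>",
) -> HeatMap:
    """Grad-CAM on the last attention-weighted convolutional stage.

    The class logit's gradient is taken w.r.t. that stage's activations; the
    spatial mean of the gradient weights each channel, the weighted sum is
    ReLU-rectified, bilinearly upsampled to the input size and min-max
    normalized to [0, 1] (a uniformly zero map stays zero).
    """
    if not 0 <= target_class < model.config.n_classes:
        raise ValueError(
            f"target class {target_class} outside [0, {model.config.n_classes})"
        )
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3 and x.shape[-1] == 3:  # HWC -> CHW
        x = x.transpose(2, 0, 1)
    x = x[None]
    try:
        model.get_stage(stage)
    except KeyError:
        stage = "se1"  # ablated models without a second stage
    logits = model.forward(x, train=True, capture=stage)
    onehot = np.zeros_like(logits)
    onehot[0, target_class] = 1.0
    model.backward(onehot)
    act = model.captured["activation"][0]
    grad = model.captured["gradient"][0]
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    h, w = x.shape[2], x.shape[3]
    cam_img = Image.fromarray(cam.astype(np.float32), mode="F").resize(
        (w, h), Image.BILINEAR
    )
    cam = np.asarray(cam_img, dtype=np.float32)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return HeatMap(values=cam, source=source, target_class=target_class)


def save_heatmap_overlay(hm: HeatMap, image: np.ndarray, path: str | FSPath) -> None:
    """Write the heat map blended over the source image as a PNG."""
    import matplotlib.cm as mpl_cm

    base = np.asarray(image, dtype=np.float32)
    if base.max() > 1.5:
        base = base / 255.0
    colored = mpl_cm.jet(hm.values)[..., :3]
    overlay = np.clip(0.5 * base + 0.5 * colored, 0, 1)
    Image.fromarray((overlay * 255).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------


def ablation_variants(config: ModelConfig) -> list[tuple[str, ModelConfig]]:
    """The three module-attribution variants sharing the full model's widths.

    "multi-scale+SE": stem and the first multi-scale+SE stage only;
    "BasicBlock+SE": the full model minus the second multi-scale+SE stage;
    "full": the complete architecture.
    """
    from dataclasses import replace as dc_replace

    keep = tuple(
        (s, p) for s, p in config.downsample_schedule if s in ("stem", "se1")
    )
    ms_se = dc_replace(
        config, block=None, se2=None, ms2=None, se3=None, downsample_schedule=keep
    )
    keep2 = tuple(
        (s, p) for s, p in config.downsample_schedule if s in ("stem", "se1", "se2")
    )
    block_se = dc_replace(config, ms2=None, se3=None, downsample_schedule=keep2)
    return [("multi-scale+SE", ms_se), ("BasicBlock+SE", block_se), ("full", config)]


def ablation_run(
    variants: list[tuple[str, ModelConfig]],
    train_manifest: DatasetManifest,
    val_manifest: DatasetManifest,
    config: TrainConfig,
) -> list[dict]:
    """Train each variant under one protocol; one row per variant with the
    size-accounting columns: name, validation accuracy (%), total trainable
    parameters, parameter size (MB)."""
    from .model import assemble_model

    rows = []
    for name, cfg in variants:
        try:
            net = assemble_model(cfg, seed=config.seed)
        except Exception as exc:
            raise RuntimeError(f"variant {name!r} failed to assemble: {exc}") from exc
        report = train_model(net, train_manifest, val_manifest, config)
        total = config_param_total(cfg)
        rows.append(
            {
                "name": name,
                "val_accuracy_pct": round(100.0 * report.best_val_accuracy, 2),
                "total_parameters": total,
                "parameter_size_mb": parameter_size_mb(total),
            }
        )
    return rows
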