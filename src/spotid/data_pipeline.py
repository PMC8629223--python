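"""Preprocessing pipeline: resize, stratified 8:2 split, rotation tripling,
normalization and batching.

The protocol mirrors a small-herd identification study: images are
bilinearly resized to a common square resolution, each individual's images
are split 8:2 into training and validation (floor on the training share, so
every individual appears in validation), and the training set is then
tripled by adding two rotated copies of every image.  Augmenting after the
split guarantees no validation image leaks into training in any rotated
form.

Augmented records are lazy: they reference the source file plus a rotation
angle applied at load time (90/180/270 degree rotations are lossless), so no
extra files are written.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path as FSPath

import numpy as np
from PIL import Image

from .synthetic_herd import DatasetManifest, ManifestRecord

__all__ = [
    "SplitSpec",
    "AugmentSpec",
    "Batch",
    "load_and_resize",
    "split_dataset",
    "augment_rotations",
    "batch_indices",
    "iterate_batches",
    "load_manifest_images",
    "channel_stats",
]

LOSSLESS_ANGLES = frozenset({90, 180, 270})


@dataclass(frozen=True)
class SplitSpec:
    """Per-identity stratified train/validation split."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class AugmentSpec:
    """Rotation augmentation: each original gains ``copies_per_image`` rotated
    copies with angles drawn without replacement from ``angles``."""

    angles: tuple[int, int, int] = (90, 180, 270)
    copies_per_image: int = 2
    seed: int = 0
    include_flips: bool = False

    def __post_init__(self) -> None:
        if len(set(self.angles)) < 3:
            raise ValueError("exactly three distinct rotation angles are required")


@dataclass(frozen=True)
class Batch:
    images: np.ndarray  # (B, 3, H, W) float32, normalized
    labels: np.ndarray  # (B,) int64


def load_and_resize(path: str | FSPath, size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Read an image, resize bilinearly, scale to [0, 1].

    Returns (H, W, 3) float32; greyscale inputs are replicated across the
    three channels.  Unreadable files raise OSError carrying the path.
    """
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != (size[1], size[0]):
                im = im.resize((size[1], size[0]), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float32)
    except OSError as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    return arr / 255.0


def split_dataset(
    manifest: DatasetManifest, spec: SplitSpec
) -> tuple[DatasetManifest, DatasetManifest]:
    """Stratified split: floor(train_fraction * n) of each identity's images
    go to training, the remainder to validation, shuffled under the seed.

    An identity with fewer than 2 images cannot appear on both sides; it is
    sent entirely to training with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    by_id: dict[int, list[ManifestRecord]] = {}
    for r in manifest.records:
        by_id.setdefault(r.id_label, []).append(r)
    train, val = [], []
    for label in sorted(by_id):
        recs = by_id[label]
        if len(recs) < 2:
            warnings.warn(
                f"identity {label} has {len(recs)} image(s); assigning all to training"
            )
            train += [replace(r, split="train") for r in recs]
            continue
        order = rng.permutation(len(recs))
        n_train = int(np.floor(spec.train_fraction * len(recs)))
        for k, idx in enumerate(order):
            tag = "train" if k < n_train else "val"
            (train if k < n_train else val).append(replace(recs[idx], split=tag))
    mk = lambda recs: DatasetManifest(
        records=recs,
        n_identities=manifest.n_identities,
        root=manifest.root,
        base_seed=manifest.base_seed,
    )
    return mk(train), mk(val)


def augment_rotations(manifest: DatasetManifest, spec: AugmentSpec) -> DatasetManifest:
    """Triple a training manifest: every original record plus two rotated
    copies, angles drawn without replacement from the three-angle set.

    Labels are preserved; new records carry provenance "augmented" and the
    rotation to apply at load time.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[ManifestRecord] = []
    angles = tuple(spec.angles)
    for r in manifest.records:
        out.append(r)
        chosen = rng.choice(len(angles), size=spec.copies_per_image, replace=False)
        for c in chosen:
            out.append(replace(r, provenance="augmented", rotation=int(angles[c])))
    return DatasetManifest(
        records=out,
        n_identities=manifest.n_identities,
        root=manifest.root,
        base_seed=manifest.base_seed,
    )


def _apply_rotation(arr: np.ndarray, angle: int, flip: bool = False) -> np.ndarray:
    if angle:
        if angle % 90 == 0:
            arr = np.rot90(arr, k=angle // 90, axes=(0, 1))
        else:  # non-lossless angles fall back to interpolated rotation
            im = Image.fromarray((arr * 255).astype(np.uint8))
            arr = np.asarray(im.rotate(angle, Image.BILINEAR), dtype=np.float32) / 255.0
    if flip:
        arr = arr[:, ::-1]
    return np.ascontiguousarray(arr)


def load_manifest_images(
    manifest: DatasetManifest,
    size: tuple[int, int] = (224, 224),
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize a manifest as ((N,3,H,W) float32 in [0,1], (N,) labels).

    Rotations recorded on augmented records are applied here.
    """
    imgs = np.empty((len(manifest.records), 3, size[0], size[1]), dtype=np.float32)
    for i, rec in enumerate(manifest.records):
        arr = load_and_resize(FSPath(manifest.root) / rec.path, size)
        arr = _apply_rotation(arr, rec.rotation)
        imgs[i] = arr.transpose(2, 0, 1)
    return imgs, manifest.labels()


def channel_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and standard deviation of an (N,3,H,W) stack."""
    mean = images.mean(axis=(0, 2, 3))
    std = images.std(axis=(0, 2, 3))
    return mean.astype(np.float32), np.maximum(std, 1e-6).astype(np.float32)


def batch_indices(n_items: int, batch_size: int, seed: int, epoch: int = 0):
    """Yield index arrays that partition ``range(n_items)`` after a seeded
    shuffle; all batches are full except possibly the last."""
    if n_items < 1:
        raise ValueError("nothing to batch")
    rng = np.random.default_rng(np.random.SeedSequence([seed, epoch]))
    order = rng.permutation(n_items)
    for start in range(0, n_items, batch_size):
        yield order[start : start + batch_size]


def iterate_batches(
    manifest: DatasetManifest,
    batch_size: int = 32,
    seed: int = 0,
    epoch: int = 0,
    size: tuple[int, int] = (224, 224),
    mean: np.ndarray | None = None,
    std: np.ndarray | None = None,
):
    """Yield normalized :class:`Batch` objects covering the manifest once.

    Each epoch reshuffles under ``(seed, epoch)``; batches partition the
    manifest with only the final batch possibly short.  ``mean``/``std``
    (per-channel) default to 0/1, i.e. plain [0, 1] scaling.
    """
    images, labels = load_manifest_images(manifest, size)
    if mean is not None:
        images = (images - mean[None, :, None, None]) / std[None, :, None, None]
    for idx in batch_indices(len(labels), batch_size, seed, epoch):
        yield Batch(images=images[idx], labels=labels[idx])
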