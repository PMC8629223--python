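"""Resize contracts, stratified splitting, rotation tripling, batching."""

import numpy as np
import pytest
from PIL import Image

from spotid.data_pipeline import (
    AugmentSpec,
    SplitSpec,
    augment_rotations,
    batch_indices,
    iterate_batches,
    load_and_resize,
    load_manifest_images,
    split_dataset,
)
from spotid.synthetic_herd import DatasetManifest, ManifestRecord


def make_manifest(counts: dict[int, int]) -> DatasetManifest:
    """A path-only manifest (no files on disk) for cardinality tests."""
    records = [
        ManifestRecord(path=f"id_{label:02d}/img_{j:03d}.png", id_label=label)
        for label, n in counts.items()
        for j in range(n)
    ]
    return DatasetManifest(records=records, n_identities=len(counts), root="/dev/null")


class TestLoadAndResize:
    def test_resizes_to_224(self, tmp_path):
        p = tmp_path / "big.png"
        Image.new("RGB", (560, 374), (10, 20, 30)).save(p)
        arr = load_and_resize(p)
        assert arr.shape == (224, 224, 3)
        assert arr.dtype == np.float32
        assert 0 <= arr.min() and arr.max() <= 1

    def test_identity_size_unchanged(self, tmp_path):
        p = tmp_path / "exact.png"
        Image.new("RGB", (224, 224)).save(p)
        assert load_and_resize(p).shape == (224, 224, 3)

    def test_greyscale_replicated_to_three_channels(self, tmp_path):
        p = tmp_path / "grey.png"
        Image.new("L", (100, 80), 77).save(p)
        arr = load_and_resize(p, (64, 64))
        assert arr.shape == (64, 64, 3)
        np.testing.assert_array_equal(arr[..., 0], arr[..., 1])

    def test_unreadable_file_raises_with_path(self, tmp_path):
        p = tmp_path / "corrupt.png"
        p.write_bytes(b"not an image")
        with pytest.raises(OSError, match="corrupt.png"):
            load_and_resize(p)


class TestSplit:
    def test_near_balanced_1485_splits_1188_297(self):
        """13 identities totalling 1485 images (counts all multiples of 5)
        split exactly 8:2 under the per-identity floor rule."""
        counts = {i: 115 for i in range(11)} | {11: 110, 12: 110}
        train, val = split_dataset(make_manifest(counts), SplitSpec(seed=0))
        assert len(train.records) == 1188
        assert len(val.records) == 297

    def test_exact_ratio_single_identity_pair(self):
        train, val = split_dataset(make_manifest({0: 10, 1: 10}), SplitSpec(seed=1))
        per_id = lambda recs, k: sum(r.id_label == k for r in recs)
        assert per_id(train.records, 0) == 8 and per_id(val.records, 0) == 2

    def test_partition_disjoint_and_exhaustive(self):
        m = make_manifest({0: 13, 1: 7, 2: 21})
        train, val = split_dataset(m, SplitSpec(seed=3))
        got = sorted(r.path for r in train.records + val.records)
        assert got == sorted(r.path for r in m.records)

    def test_deterministic_under_seed(self):
        m = make_manifest({0: 20, 1: 20})
        a = split_dataset(m, SplitSpec(seed=5))
        b = split_dataset(m, SplitSpec(seed=5))
        assert a[0].records == b[0].records and a[1].records == b[1].records

    def test_tiny_identity_warned_into_training(self):
        with pytest.warns(UserWarning, match="identity 1"):
            train, val = split_dataset(make_manifest({0: 10, 1: 1}), SplitSpec(seed=0))
        assert sum(r.id_label == 1 for r in train.records) == 1
        assert all(r.id_label != 1 for r in val.records)


class TestAugment:
    def test_tripling(self):
        m = make_manifest({0: 4, 1: 4})
        out = augment_rotations(m, AugmentSpec(seed=0))
        assert len(out.records) == 3 * len(m.records)

    def test_empty_manifest_stays_empty(self):
        m = DatasetManifest(records=[], n_identities=0, root=".")
        assert augment_rotations(m, AugmentSpec(seed=0)).records == []

    def test_labels_and_provenance(self):
        m = make_manifest({0: 3, 1: 2})
        out = augment_rotations(m, AugmentSpec(seed=2))
        by_src: dict[str, list] = {}
        for r in out.records:
            by_src.setdefault(r.path, []).append(r)
        for src, recs in by_src.items():
            labels = {r.id_label for r in recs}
            assert len(labels) == 1  # augmentation never changes the label
            rotations = sorted(r.rotation for r in recs)
            assert rotations[0] == 0 and len(rotations) == 3
            assert all(r.rotation in (90, 180, 270) for r in recs if r.provenance == "augmented")

    def test_fewer_than_three_angles_rejected(self):
        with pytest.raises(ValueError):
            AugmentSpec(angles=(90, 180, 180))

    def test_no_leakage_after_split_then_augment(self):
        m = make_manifest({0: 10, 1: 10})
        train, val = split_dataset(m, SplitSpec(seed=7))
        aug = augment_rotations(train, AugmentSpec(seed=7))
        val_paths = {r.path for r in val.records}
        assert all(r.path not in val_paths for r in aug.records)

    def test_composed_cardinality_on_balanced_herd(self):
        m = make_manifest({i: 20 for i in range(13)})
        train, _ = split_dataset(m, SplitSpec(seed=0))
        aug = augment_rotations(train, AugmentSpec(seed=0))
        assert len(aug.records) == 3 * 13 * 16  # 3 * 13 * floor(0.8 * 20)


class TestBatching:
    def test_3564_records_give_111_full_plus_12(self):
        sizes = [len(b) for b in batch_indices(3564, 32, seed=0)]
        assert sizes.count(32) == 111
        assert sizes[-1] == 12

    def test_single_full_batch(self):
        sizes = [len(b) for b in batch_indices(32, 32, seed=0)]
        assert sizes == [32]

    def test_partition_no_duplicates(self):
        seen = np.concatenate(list(batch_indices(100, 32, seed=4, epoch=2)))
        assert sorted(seen.tolist()) == list(range(100))

    def test_epochs_reshuffle_deterministically(self):
        a = np.concatenate(list(batch_indices(50, 16, seed=1, epoch=0)))
        b = np.concatenate(list(batch_indices(50, 16, seed=1, epoch=1)))
        c = np.concatenate(list(batch_indices(50, 16, seed=1, epoch=0)))
        assert not np.array_equal(a, b)
        np.testing.assert_array_equal(a, c)


class TestManifestLoading:
    def test_rotation_applied_at_load(self, herd_manifest):
        sub = DatasetManifest(
            records=[herd_manifest.records[0]],
            n_identities=13,
            root=herd_manifest.root,
        )
        imgs, _ = load_manifest_images(sub, size=(96, 96))
        rot = DatasetManifest(
            records=[
                type(sub.records[0])(
                    path=sub.records[0].path, id_label=0,
                    provenance="augmented", rotation=180,
                )
            ],
            n_identities=13,
            root=herd_manifest.root,
        )
        rimgs, _ = load_manifest_images(rot, size=(96, 96))
        np.testing.assert_allclose(rimgs[0], imgs[0, :, ::-1, ::-1])

    def test_iterate_batches_covers_manifest(self, herd_manifest):
        sub = DatasetManifest(
            records=herd_manifest.records[:40],
            n_identities=13,
            root=herd_manifest.root,
        )
        batches = list(iterate_batches(sub, batch_size=32, seed=0, size=(96, 96)))
        assert [len(b.labels) for b in batches] == [32, 8]
        assert batches[0].images.shape == (32, 3, 96, 96)
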