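"""Initialization, the training loop, evaluation, Grad-CAM, ablations."""

from dataclasses import replace

import numpy as np
import pytest

from spotid import nn
from spotid.data_pipeline import AugmentSpec, SplitSpec, augment_rotations, split_dataset
from spotid.model import assemble_model
from spotid.train_eval import (
    TrainConfig,
    ablation_run,
    ablation_variants,
    confusion_matrix,
    evaluate,
    gradcam_heatmap,
    init_xavier,
    train_model,
)


@pytest.fixture(scope="module")
def split_herd(herd_manifest):
    train, val = split_dataset(herd_manifest, SplitSpec(seed=11))
    train = augment_rotations(train, AugmentSpec(seed=11))
    return train, val


@pytest.fixture(scope="module")
def small_model(tiny_config):
    cfg = replace(tiny_config, n_classes=13, input_size=(64, 64))
    return cfg


class TestXavierInit:
    def test_biases_zero_weight_variance_glorot(self, default_cfg):
        net = assemble_model(default_cfg, seed=9)
        init_xavier(net, seed=9)
        for name, p in net.parameters():
            if name.endswith(".b") or name.endswith("beta"):
                assert not p.any(), name
        # the biggest conv weight array: sample variance near 2/(fan_in+fan_out)
        stem = net.get_stage("ms2").branches[0].layers[0][1]
        fan_in = stem.in_channels * stem.kernel**2
        fan_out = stem.out_channels * stem.kernel**2
        expected = 2.0 / (fan_in + fan_out)
        assert abs(stem.W.var() / expected - 1) < 0.10

    def test_deterministic(self, small_model):
        a = assemble_model(small_model, seed=4)
        b = assemble_model(small_model, seed=4)
        for (na, pa), (nb, pb) in zip(a.parameters(), b.parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa, pb)

    def test_seed_changes_weights(self, small_model):
        a = assemble_model(small_model, seed=4)
        b = assemble_model(small_model, seed=5)
        assert any(
            not np.array_equal(pa, pb)
            for (_, pa), (_, pb) in zip(a.parameters(), b.parameters())
        )


class TestTrainLoop:
    def test_report_lengths_and_confusion_row_sums(self, small_model, split_herd):
        train, val = split_herd
        net = assemble_model(small_model, seed=2)
        tc = TrainConfig(epochs=2, image_size=(64, 64), seed=2)
        report = train_model(net, train, val, tc)
        assert report.epochs_run == 2
        for arr in (report.train_loss, report.train_accuracy,
                    report.val_loss, report.val_accuracy):
            assert len(arr) == 2
        # confusion rows sum to per-class validation counts
        counts = np.bincount(val.labels(), minlength=13)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), counts)

    def test_default_protocol_is_40_epochs_batch_32(self):
        tc = TrainConfig()
        assert tc.epochs == 40 and tc.batch_size == 32

    def test_zero_learning_rate_leaves_weights_untouched(self, small_model, split_herd):
        train, val = split_herd
        net = assemble_model(small_model, seed=3)
        before = [p.copy() for _, p in net.parameters()]
        tc = TrainConfig(epochs=2, learning_rate=0.0, image_size=(64, 64), seed=3)
        train_model(net, train, val, tc)
        for old, (name, new) in zip(before, net.parameters()):
            np.testing.assert_array_equal(old, new, err_msg=name)

    def test_empty_manifest_rejected(self, small_model, split_herd):
        from spotid.synthetic_herd import DatasetManifest

        _, val = split_herd
        empty = DatasetManifest(records=[], n_identities=13, root=val.root)
        net = assemble_model(small_model, seed=0)
        with pytest.raises(ValueError):
            train_model(net, empty, val, TrainConfig(epochs=1))

    def test_overlapping_manifests_rejected(self, small_model, split_herd):
        train, _ = split_herd
        net = assemble_model(small_model, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            train_model(net, train, train, TrainConfig(epochs=1))


class TestEvaluate:
    def test_confusion_trace_identity(self):
        labels = np.array([0, 1, 2, 1, 0])
        preds = np.array([0, 1, 1, 1, 2])
        cm = confusion_matrix(labels, preds, 3)
        assert cm.trace() / cm.sum() == pytest.approx(3 / 5)

    def test_accuracy_matches_confusion(self, small_model, split_herd):
        _, val = split_herd
        net = assemble_model(small_model, seed=1)
        acc, cm = evaluate(net, val, image_size=(64, 64))
        assert acc == pytest.approx(cm.trace() / cm.sum())
        assert cm.sum() == len(val.records)

    def test_label_outside_model_range_rejected(self, split_herd):
        from spotid.model_zoo import (
            ConvBlockSpec, ModelConfig, MultiScaleSpec, PoolSpec, SEBlockSpec,
        )

        _, val = split_herd
        cfg = ModelConfig(
            stem=ConvBlockSpec(kernel=11, in_channels=3, out_channels=4, stride=4, padding=2),
            ms1=MultiScaleSpec(4, (2, 2, 2, 2)),
            se1=SEBlockSpec(8, 4),
            block=None, se2=None, ms2=None, se3=None,
            n_classes=2, input_size=(64, 64),
            downsample_schedule=(("stem", PoolSpec()),),
        )
        net = assemble_model(cfg, seed=0)
        with pytest.raises(ValueError):
            evaluate(net, val, image_size=(64, 64))


class TestGradCam:
    def test_output_shape_and_range(self, small_model, herd_manifest):
        from spotid.data_pipeline import load_and_resize
        from pathlib import Path

        net = assemble_model(small_model, seed=6)
        img = load_and_resize(
            Path(herd_manifest.root) / herd_manifest.records[0].path, (64, 64)
        )
        hm = gradcam_heatmap(net, img, target_class=0)
        assert hm.values.shape == (64, 64)
        assert hm.values.min() >= 0 and hm.values.max() <= 1
        assert hm.values.max() == pytest.approx(1.0)

    def test_target_class_out_of_range(self, small_model):
        net = assemble_model(small_model, seed=6)
        x = np.zeros((64, 64, 3), dtype=np.float32)
        with pytest.raises(ValueError):
            gradcam_heatmap(net, x, target_class=99)

    def test_single_channel_model_peaks_at_activation_peak(self):
        """With one positive-weight channel feeding the logit, the heat map
        argmax must coincide with that channel's activation argmax."""
        from spotid.model_zoo import (
            ConvBlockSpec, ModelConfig, MultiScaleSpec, PoolSpec, SEBlockSpec,
        )

        cfg = ModelConfig(
            stem=ConvBlockSpec(kernel=11, in_channels=3, out_channels=4, stride=4, padding=2),
            ms1=MultiScaleSpec(4, (1, 1, 1, 1)),
            se1=SEBlockSpec(4, 4),
            block=None, se2=None, ms2=None, se3=None,
            n_classes=2, input_size=(64, 64),
            downsample_schedule=(("stem", PoolSpec()),),
        )
        net = assemble_model(cfg, seed=8)
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(64, 64, 3)).astype(np.float32)
        x = img.transpose(2, 0, 1)[None]
        act = None
        xs = x
        for name, layer in net.stages:
            xs = layer.forward(xs)
            if name == "se1":
                act = xs[0]
        # weight only channel 0 positively into the target logit
        fc = net.get_stage("fc")
        fc.W[...] = 0
        fc.W[1, 0] = 1.0
        hm = gradcam_heatmap(net, img, target_class=1, stage="se1")
        up = 64 // act.shape[1]
        peak = np.unravel_index(hm.values.argmax(), hm.values.shape)
        act_peak = np.unravel_index(act[0].argmax(), act[0].shape)
        assert abs(peak[0] / up - act_peak[0]) <= 1.5
        assert abs(peak[1] / up - act_peak[1]) <= 1.5


class TestAblation:
    def test_variant_structure_and_param_ordering(self, default_cfg):
        variants = ablation_variants(default_cfg)
        names = [n for n, _ in variants]
        assert names == ["multi-scale+SE", "BasicBlock+SE", "full"]
        from spotid.model_zoo import config_param_total

        totals = {n: config_param_total(c) for n, c in variants}
        # removing the heavy second multi-scale stage shrinks the model
        assert totals["multi-scale+SE"] < totals["BasicBlock+SE"] < totals["full"]
        assert totals["full"] == 1_707_592

    def test_table_schema(self, small_model, split_herd):
        train, val = split_herd
        variants = ablation_variants(small_model)
        tc = TrainConfig(epochs=1, image_size=(64, 64), seed=1)
        rows = ablation_run(variants, train, val, tc)
        assert len(rows) == 3
        for row in rows:
            assert set(row) == {
                "name", "val_accuracy_pct", "total_parameters", "parameter_size_mb"
            }

    def test_empty_variant_list(self, split_herd):
        train, val = split_herd
        assert ablation_run([], train, val, TrainConfig(epochs=1)) == []
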