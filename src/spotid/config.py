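"""YAML serialization of ModelConfig and the frozen default architecture.

The default configuration ships with the package; its widths were fixed
once by the documented calibration search (:func:`spotid.model_zoo.
calibrate_width_config`) against the 1,707,592-parameter budget and are
loaded, never re-searched, at run time.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path as FSPath

import yaml

from .model_zoo import (
    BasicBlockSpec,
    ConvBlockSpec,
    ModelConfig,
    MultiScaleSpec,
    PoolSpec,
    SEBlockSpec,
)

__all__ = ["load_config", "save_config", "default_config", "config_to_dict"]


def config_to_dict(config: ModelConfig) -> dict:
    d: dict = {
        "n_classes": config.n_classes,
        "input_size": list(config.input_size),
        "stem": {
            "kernel": config.stem.kernel,
            "out_channels": config.stem.out_channels,
            "stride": config.stem.stride,
            "padding": config.stem.padding,
        },
        "ms1": {"branch_widths": list(config.ms1.branch_widths)},
        "se_reduction_ratio": config.se1.reduction_ratio,
        "downsample_schedule": [
            {"after": stage, "kernel": p.kernel, "stride": p.stride, "padding": p.padding}
            for stage, p in config.downsample_schedule
        ],
    }
    d["basic_block"] = config.block is not None
    if config.ms2 is not None:
        d["ms2"] = {"branch_widths": list(config.ms2.branch_widths)}
    return d


def config_from_dict(d: dict) -> ModelConfig:
    stem_d = d["stem"]
    stem = ConvBlockSpec(
        kernel=stem_d.get("kernel", 11),
        in_channels=stem_d.get("in_channels", 3),
        out_channels=stem_d["out_channels"],
        stride=stem_d.get("stride", 4),
        padding=stem_d.get("padding", 2),
    )
    r = d.get("se_reduction_ratio", 16)
    ms1 = MultiScaleSpec(stem.out_channels, tuple(d["ms1"]["branch_widths"]))
    c1 = ms1.out_channels
    block = se2 = ms2 = se3 = None
    if d.get("basic_block", True):
        block = BasicBlockSpec(c1)
        se2 = SEBlockSpec(c1, r)
    if "ms2" in d:
        ms2 = MultiScaleSpec(c1, tuple(d["ms2"]["branch_widths"]))
        se3 = SEBlockSpec(ms2.out_channels, r)
    schedule = tuple(
        (p["after"], PoolSpec(p.get("kernel", 3), p.get("stride", 2), p.get("padding", 1)))
        for p in d.get(
            "downsample_schedule",
            [{"after": "stem"}, {"after": "se2"}, {"after": "se3"}],
        )
    )
    return ModelConfig(
        stem=stem,
        ms1=ms1,
        se1=SEBlockSpec(c1, r),
        block=block,
        se2=se2,
        ms2=ms2,
        se3=se3,
        n_classes=d.get("n_classes", 13),
        input_size=tuple(d.get("input_size", (224, 224))),
        downsample_schedule=schedule,
    )


def save_config(config: ModelConfig, path: str | FSPath) -> None:
    FSPath(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: str | FSPath) -> ModelConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_config() -> ModelConfig:
    """The committed default architecture (13 classes, 224x224 input)."""
    text = resources.files("spotid").joinpath("resources/default_config.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))
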