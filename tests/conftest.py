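import numpy as np
import pytest

from spotid.config import default_config
from spotid.model_zoo import (
    BasicBlockSpec,
    ConvBlockSpec,
    ModelConfig,
    MultiScaleSpec,
    PoolSpec,
    SEBlockSpec,
)
from spotid.synthetic_herd import RenderParams, generate_dataset

HERD_SEED = 20210601


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def tiny_config():
    """A small but structurally complete architecture for fast tests."""
    return ModelConfig(
        stem=ConvBlockSpec(kernel=11, in_channels=3, out_channels=8, stride=4, padding=2),
        ms1=MultiScaleSpec(8, (4, 4, 4, 4)),
        se1=SEBlockSpec(16, 4),
        block=BasicBlockSpec(16),
        se2=SEBlockSpec(16, 4),
        ms2=MultiScaleSpec(16, (6, 6, 6, 6)),
        se3=SEBlockSpec(24, 4),
        n_classes=5,
        input_size=(64, 64),
        downsample_schedule=(("stem", PoolSpec()), ("se2", PoolSpec())),
    )


@pytest.fixture(scope="session")
def herd_dir(tmp_path_factory):
    """A small complex-background herd: 13 identities x 12 images at 96x96."""
    root = tmp_path_factory.mktemp("herd")
    generate_dataset(
        13, 12, RenderParams(image_size=(96, 96)), seed=HERD_SEED, out_dir=root
    )
    return root


@pytest.fixture(scope="session")
def herd_manifest(herd_dir):
    from spotid.synthetic_herd import load_manifest

    return load_manifest(herd_dir)


def random_valid_config(rng: np.random.Generator) -> ModelConfig:
    """Sample a structurally valid configuration with small random widths."""
    stem_out = int(rng.integers(2, 17))
    ms1 = MultiScaleSpec(stem_out, tuple(int(rng.integers(1, 13)) for _ in range(4)))
    c1 = ms1.out_channels
    r = int(rng.choice([1, 2, 4, 8, 16, 32]))
    with_block = bool(rng.integers(0, 2))
    with_ms2 = bool(rng.integers(0, 2))
    ms2 = se3 = None
    if with_ms2:
        ms2 = MultiScaleSpec(c1, tuple(int(rng.integers(1, 13)) for _ in range(4)))
        se3 = SEBlockSpec(ms2.out_channels, r)
    return ModelConfig(
        stem=ConvBlockSpec(
            kernel=int(rng.choice([7, 11])),
            in_channels=3,
            out_channels=stem_out,
            stride=4,
            padding=2,
            has_bias=bool(rng.integers(0, 2)),
            has_bn=False,
        )
        if rng.integers(0, 4) == 0
        else ConvBlockSpec(kernel=11, in_channels=3, out_channels=stem_out, stride=4, padding=2),
        ms1=ms1,
        se1=SEBlockSpec(c1, r),
        block=BasicBlockSpec(c1) if with_block else None,
        se2=SEBlockSpec(c1, r) if with_block else None,
        ms2=ms2,
        se3=se3,
        n_classes=int(rng.integers(2, 16)),
        input_size=(64, 64),
        downsample_schedule=(("stem", PoolSpec()),),
    )
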