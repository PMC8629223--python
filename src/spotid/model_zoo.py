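"""Declarative architecture specs, exact parameter accounting, and width calibration.

The network identifies individual cows from side-view coat patterns with a
deliberately small parameter budget.  Its skeleton is: an 11x11 stem
convolution block, a four-branch multi-scale (inception-style) module with
squeeze-and-excitation (SE) channel attention, a residual BasicBlock (again
followed by SE), a second multi-scale+SE stage, and a global-average-pooling
head feeding one fully connected classifier.

Every layer family here has a closed-form trainable-parameter count; these
formulas are the independent oracle against which constructed weight arrays
are checked, and they drive the width-calibration search that pins the
default configuration to an exact total budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "InvalidSpecError",
    "ConfigurationError",
    "CalibrationError",
    "ShapeError",
    "MS_KERNELS",
    "ConvBlockSpec",
    "MultiScaleSpec",
    "SEBlockSpec",
    "BasicBlockSpec",
    "PoolSpec",
    "ModelConfig",
    "ParamReport",
    "conv_block_params",
    "se_block_params",
    "multiscale_out_channels",
    "multiscale_params",
    "basicblock_params",
    "config_param_total",
    "parameter_size_mb",
    "WidthSearchBounds",
    "calibrate_width_config",
]


class InvalidSpecError(ValueError):
    """A layer spec violates its invariants."""


class ConfigurationError(ValueError):
    """Stage-to-stage chaining in a ModelConfig is inconsistent."""


class ShapeError(ValueError):
    """A tensor does not match the shape a stage requires."""


class CalibrationError(RuntimeError):
    """No width assignment reaches the requested budget exactly.

    Carries the nearest achievable totals bracketing the budget in
    ``below`` / ``above`` (either may be None).
    """

    def __init__(self, budget: int, below: int | None, above: int | None):
        self.budget = budget
        self.below = below
        self.above = above
        super().__init__(
            f"no exact width assignment for budget {budget:,}; "
            f"nearest achievable totals: {below!r} below, {above!r} above"
        )


#: kernel sizes of the four parallel multi-scale branches, largest first
MS_KERNELS: tuple[int, int, int, int] = (7, 5, 3, 1)


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolution block: conv (+bias) (+BatchNorm) (+activation).

    Bias and BatchNorm are mutually exclusive: BN's shift parameter absorbs
    any conv bias, so carrying both would waste budget.
    """

    kernel: int
    in_channels: int
    out_channels: int
    stride: int = 1
    padding: int | str = "same"
    has_bias: bool = False
    has_bn: bool = True
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise InvalidSpecError(f"kernel must be odd and >=1, got {self.kernel}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise InvalidSpecError(
                f"channel counts must be >=1, got in={self.in_channels} "
                f"out={self.out_channels}"
            )
        if self.stride < 1:
            raise InvalidSpecError(f"stride must be >=1, got {self.stride}")
        if self.has_bias and self.has_bn:
            raise InvalidSpecError("bias and BN are mutually exclusive")
        if isinstance(self.padding, str) and self.padding != "same":
            raise InvalidSpecError(f"padding must be an int or 'same', got {self.padding!r}")
        if self.activation not in ("relu", "none"):
            raise InvalidSpecError(f"unknown activation {self.activation!r}")

    @property
    def pad(self) -> int:
        return self.kernel // 2 if self.padding == "same" else int(self.padding)


@dataclass(frozen=True)
class MultiScaleSpec:
    """Four parallel conv branches (7x7, 5x5, 3x3, 1x1) merged by depth concat.

    Each branch is a same-padding stride-1 conv + BN + ReLU, so all branches
    share the input spatial size and the merge is a pure channel
    concatenation: ``out_channels == sum(branch_widths)``.
    """

    in_channels: int
    branch_widths: tuple[int, int, int, int]
    merge: str = "depth_concat"

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise InvalidSpecError(f"in_channels must be >=1, got {self.in_channels}")
        widths = tuple(self.branch_widths)
        if len(widths) != 4:
            raise InvalidSpecError(
                f"exactly 4 branch widths required (kernels {MS_KERNELS}), got {widths}"
            )
        if any(w < 1 for w in widths):
            raise InvalidSpecError(f"branch widths must all be >=1, got {widths}")
        if self.merge != "depth_concat":
            raise InvalidSpecError(f"unsupported merge {self.merge!r}")
        object.__setattr__(self, "branch_widths", widths)

    @property
    def out_channels(self) -> int:
        return sum(self.branch_widths)


@dataclass(frozen=True)
class SEBlockSpec:
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pooling to one value per channel.  Excitation: a
    two-layer fully connected bottleneck (reduction ``channels/r``) ending in
    a sigmoid, whose outputs rescale each channel.  Both FC layers carry
    biases.
    """

    channels: int
    reduction_ratio: int = 16

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise InvalidSpecError(f"channels must be >=1, got {self.channels}")
        if self.reduction_ratio < 1:
            raise InvalidSpecError(
                f"reduction_ratio must be >=1, got {self.reduction_ratio}"
            )

    @property
    def bottleneck(self) -> int:
        return max(1, self.channels // self.reduction_ratio)


@dataclass(frozen=True)
class BasicBlockSpec:
    """Residual block: two 3x3 conv+BN layers with an identity shortcut.

    The shortcut is a plain addition, so input and output channel counts are
    identical by construction.
    """

    channels: int

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise InvalidSpecError(f"channels must be >=1, got {self.channels}")


@dataclass(frozen=True)
class PoolSpec:
    """Max-pooling geometry for one downsampling step."""

    kernel: int = 3
    stride: int = 2
    padding: int = 1

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1 or self.padding < 0:
            raise InvalidSpecError(f"invalid pool geometry {self}")


# stage names, in forward order, that a downsample schedule may follow
_POOLABLE_STAGES = ("stem", "se1", "block", "se2", "ms2", "se3")


@dataclass(frozen=True)
class ModelConfig:
    """Full declarative description of the identification network.

    Stage order: stem -> [pool] -> ms1 -> se1 -> block -> se2 -> [pool]
    -> ms2 -> se3 -> [pool] -> GAP -> FC(n_classes).  ``block``/``se2`` and
    ``ms2``/``se3`` may be None to express ablation variants (the partial
    architectures used to attribute size and accuracy to modules).

    ``downsample_schedule`` maps stage name -> PoolSpec for a max-pool
    inserted after that stage.
    """

    stem: ConvBlockSpec
    ms1: MultiScaleSpec
    se1: SEBlockSpec
    block: BasicBlockSpec | None
    se2: SEBlockSpec | None
    ms2: MultiScaleSpec | None
    se3: SEBlockSpec | None
    n_classes: int = 13
    input_size: tuple[int, int] = (224, 224)
    downsample_schedule: tuple[tuple[str, PoolSpec], ...] = (
        ("stem", PoolSpec()),
        ("se2", PoolSpec()),
        ("se3", PoolSpec()),
    )

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >=2, got {self.n_classes}")
        if self.ms1.in_channels != self.stem.out_channels:
            raise ConfigurationError(
                f"ms1.in_channels ({self.ms1.in_channels}) != stem.out_channels "
                f"({self.stem.out_channels})"
            )
        c1 = self.ms1.out_channels
        if self.se1.channels != c1:
            raise ConfigurationError(
                f"se1.channels ({self.se1.channels}) != ms1 output ({c1})"
            )
        if (self.block is None) != (self.se2 is None):
            raise ConfigurationError("block and se2 must be present or absent together")
        if self.block is not None:
            if self.block.channels != c1:
                raise ConfigurationError(
                    f"block.channels ({self.block.channels}) != ms1 output ({c1})"
                )
            assert self.se2 is not None
            if self.se2.channels != c1:
                raise ConfigurationError(
                    f"se2.channels ({self.se2.channels}) != block channels ({c1})"
                )
        if (self.ms2 is None) != (self.se3 is None):
            raise ConfigurationError("ms2 and se3 must be present or absent together")
        if self.ms2 is not None:
            if self.ms2.in_channels != c1:
                raise ConfigurationError(
                    f"ms2.in_channels ({self.ms2.in_channels}) != preceding stage "
                    f"output ({c1})"
                )
            assert self.se3 is not None
            if self.se3.channels != self.ms2.out_channels:
                raise ConfigurationError(
                    f"se3.channels ({self.se3.channels}) != ms2 output "
                    f"({self.ms2.out_channels})"
                )
        for stage, _pool in self.downsample_schedule:
            if stage not in _POOLABLE_STAGES:
                raise ConfigurationError(f"unknown schedule stage {stage!r}")
        object.__setattr__(
            self, "downsample_schedule", tuple(self.downsample_schedule)
        )
        object.__setattr__(self, "input_size", tuple(self.input_size))

    @property
    def classifier_in_channels(self) -> int:
        if self.ms2 is not None:
            return self.ms2.out_channels
        return self.ms1.out_channels


@dataclass(frozen=True)
class ParamReport:
    """Per-layer trainable-element counts plus the 32-bit storage size."""

    per_layer: tuple[tuple[str, int], ...]
    total: int
    size_mb: float

    def to_rows(self) -> list[tuple[str, int]]:
        return list(self.per_layer)


# ---------------------------------------------------------------------------
# closed-form counting (the oracle formulas)
# ---------------------------------------------------------------------------


def conv_block_params(spec: ConvBlockSpec) -> int:
    """k^2 * in * out weights, + out bias terms, + 2*out BN scale/shift."""
    n = spec.kernel**2 * spec.in_channels * spec.out_channels
    if spec.has_bias:
        n += spec.out_channels
    if spec.has_bn:
        n += 2 * spec.out_channels
    return n


def se_block_params(spec: SEBlockSpec) -> int:
    """Both bottleneck FC layers carry biases: C*b + b + b*C + C."""
    c, b = spec.channels, spec.bottleneck
    return c * b + b + b * c + c


def multiscale_out_channels(spec: MultiScaleSpec) -> int:
    """Depth concatenation: output channels are the sum of branch widths."""
    return spec.out_channels


def multiscale_params(spec: MultiScaleSpec) -> int:
    """Sum of the four branch conv+BN blocks (no biases under BN)."""
    return sum(
        conv_block_params(
            ConvBlockSpec(kernel=k, in_channels=spec.in_channels, out_channels=w)
        )
        for k, w in zip(MS_KERNELS, spec.branch_widths)
    )


def basicblock_params(spec: BasicBlockSpec) -> int:
    """Two 3x3 conv+BN layers at constant width."""
    c = spec.channels
    return 2 * (9 * c * c + 2 * c)


def config_param_total(config: ModelConfig) -> int:
    """Closed-form trainable-parameter total of a full or ablated config."""
    total = conv_block_params(config.stem)
    total += multiscale_params(config.ms1) + se_block_params(config.se1)
    if config.block is not None:
        assert config.se2 is not None
        total += basicblock_params(config.block) + se_block_params(config.se2)
    if config.ms2 is not None:
        assert config.se3 is not None
        total += multiscale_params(config.ms2) + se_block_params(config.se3)
    # GAP head: single FC with bias
    total += config.classifier_in_channels * config.n_classes + config.n_classes
    return total


def parameter_size_mb(count: int) -> float:
    """Model size in MB at 4 bytes/parameter and 2^20 bytes/MB.

    Rounded half-up to two decimals; this is the convention consistent with
    printed (count, MB) pairs such as 1,707,592 -> 6.51 and
    58,314,120 -> 222.45.
    """
    if count < 0:
        raise ValueError(f"parameter count must be >=0, got {count}")
    mb = count * 4 / 2**20
    return math.floor(mb * 100 + 0.5) / 100


# ---------------------------------------------------------------------------
# width calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WidthSearchBounds:
    """Search space for :func:`calibrate_width_config`.

    ``stem_range`` bounds the stem output width; ``branch_range`` bounds each
    multi-scale branch width; ``reduction_ratios`` are tried in order (first
    is preferred); ``coarse_step`` is the granularity of the coarse pass.
    """

    stem_range: tuple[int, int] = (32, 96)
    branch_range: tuple[int, int] = (8, 128)
    reduction_ratios: tuple[int, ...] = (16, 8, 4)
    coarse_step: int = 8
    n_classes: int = 13


def _build_config(
    stem_out: int,
    ms1_widths: tuple[int, int, int, int],
    ms2_widths: tuple[int, int, int, int],
    ratio: int,
    n_classes: int,
) -> ModelConfig:
    stem = ConvBlockSpec(kernel=11, in_channels=3, out_channels=stem_out, stride=4, padding=2)
    ms1 = MultiScaleSpec(in_channels=stem_out, branch_widths=ms1_widths)
    c1 = ms1.out_channels
    ms2 = MultiScaleSpec(in_channels=c1, branch_widths=ms2_widths)
    return ModelConfig(
        stem=stem,
        ms1=ms1,
        se1=SEBlockSpec(c1, ratio),
        block=BasicBlockSpec(c1),
        se2=SEBlockSpec(c1, ratio),
        ms2=ms2,
        se3=SEBlockSpec(ms2.out_channels, ratio),
        n_classes=n_classes,
    )


def calibrate_width_config(
    budget: int, constraints: WidthSearchBounds | None = None
) -> ModelConfig:
    """Find channel widths whose exact trainable-parameter total is ``budget``.

    Deterministic ordered enumeration: a coarse pass assigns the stem width
    and equal multi-scale-1 branch widths on a ``coarse_step`` grid, then the
    second multi-scale stage's 3x3 and 1x1 branches are refined at unit
    granularity (its 7x7 and 5x5 branches stay on the grid).  For a fixed
    prefix the residual budget R must satisfy, with C1 the first-stage output
    width and C2 the second-stage output width,

        R = se(C2, r) + (C2 + 1) * n_classes + 2*C2 + C1 * (49*w7 + 25*w5 + 9*w3 + w1)

    which reduces to an integer divisibility condition solved in closed form
    for (w3, w1).  Stage widths are required not to shrink along the network
    (stem <= C1 <= C2), the usual pyramid of a classification CNN.  Among all
    exact hits the most balanced second-stage branch widths win; remaining
    ties prefer the first reduction ratio listed, a stem width near 64 and a
    second stage near twice the first, then the lexicographically smallest
    widths.

    Raises :class:`CalibrationError` (reporting the nearest achievable totals
    bracketing the budget) when no exact assignment exists.
    """
    bounds = constraints or WidthSearchBounds()
    lo, hi = bounds.branch_range
    s_lo, s_hi = bounds.stem_range
    step = bounds.coarse_step
    ncls = bounds.n_classes

    hits: list[tuple[tuple, ModelConfig]] = []
    below: int | None = None
    above: int | None = None

    def note(total: int) -> None:
        nonlocal below, above
        if total <= budget:
            below = total if below is None else max(below, total)
        if total >= budget:
            above = total if above is None else min(above, total)

    for ridx, r in enumerate(bounds.reduction_ratios):
        for s in range(s_lo, s_hi + 1, step):
            stem_n = 121 * 3 * s + 2 * s
            for a in range(lo, hi + 1, step):
                c1 = 4 * a
                if c1 < s:
                    continue
                se_c1 = se_block_params(SEBlockSpec(c1, r))
                prefix = (
                    stem_n
                    + (49 + 25 + 9 + 1) * s * a + 2 * c1
                    + se_c1
                    + 2 * (9 * c1 * c1 + 2 * c1)
                    + se_c1
                )
                resid = budget - prefix
                note(prefix + _min_tail(c1, r, lo, ncls))
                if resid <= 0:
                    continue
                for w7 in range(lo, hi + 1, step):
                    for w5 in range(lo, hi + 1, step):
                        for c2 in range(w7 + w5 + 2 * lo, w7 + w5 + 2 * hi + 1):
                            b = max(1, c2 // r)
                            tail_fixed = (2 * c2 * b + b + c2) + (c2 + 1) * ncls + 2 * c2
                            rem = resid - tail_fixed
                            if rem < 0:
                                break
                            if rem % c1:
                                continue
                            k = rem // c1
                            t = k - c2 - 48 * w7 - 24 * w5
                            if t < 0 or t % 8:
                                continue
                            w3 = t // 8
                            w1 = c2 - w7 - w5 - w3
                            if not (lo <= w3 <= hi and lo <= w1 <= hi):
                                continue
                            if c2 < c1:
                                continue
                            widths2 = (w7, w5, w3, w1)
                            cfg = _build_config(s, (a, a, a, a), widths2, r, ncls)
                            key = (
                                max(widths2) - min(widths2),
                                ridx,
                                abs(s - 64),
                                abs(c2 - 2 * c1),
                                s,
                                a,
                                widths2,
                            )
                            hits.append((key, cfg))

    if not hits:
        raise CalibrationError(budget, below, above)
    hits.sort(key=lambda kv: kv[0])
    best = hits[0][1]
    assert config_param_total(best) == budget
    return best


def _min_tail(c1: int, r: int, lo: int, ncls: int) -> int:
    """Cheapest possible second stage + head for bracketing reports."""
    widths = (lo, lo, lo, lo)
    c2 = 4 * lo
    ms2 = sum(k * k * c1 * w + 2 * w for k, w in zip(MS_KERNELS, widths))
    return ms2 + se_block_params(SEBlockSpec(c2, r)) + (c2 + 1) * ncls
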