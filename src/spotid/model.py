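"""Assembly of the identification network from a ModelConfig, shape tracing,
and construction-based parameter enumeration.

The enumeration here (walking actual weight arrays) and the closed-form
formulas in :mod:`spotid.model_zoo` are two independent routes to the same
totals; tests hold them equal on randomly sampled configurations.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .model_zoo import (
    ConfigurationError,
    ModelConfig,
    ParamReport,
    ShapeError,
    parameter_size_mb,
)

__all__ = [
    "Network",
    "assemble_model",
    "forward_shape_trace",
    "count_trainable_parameters",
    "apply_se",
    "basicblock_forward",
]


class Network:
    """The assembled network: an ordered list of named stages.

    ``forward`` returns raw logits; use :meth:`predict_proba` for softmax
    class probabilities (softmax is applied only at inference, never inside
    the training loss, which works on logits).
    """

    def __init__(self, config: ModelConfig, stages: list[tuple[str, nn.Layer]]):
        self.config = config
        self.stages = stages
        self._capture: dict[str, np.ndarray] = {}
        self._capture_stage: str | None = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for name, layer in self.stages:
            out += [(f"{name}.{n}", p) for n, p in layer.parameters()]
        return out

    def gradients(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for name, layer in self.stages:
            out += [(f"{name}.{n}", g) for n, g in layer.gradients()]
        return out

    def get_stage(self, name: str) -> nn.Layer:
        for n, layer in self.stages:
            if n == name:
                return layer
        raise KeyError(name)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.copy() for n, p in self.parameters()}
        # BN running statistics are buffers, keyed positionally
        for i, bn in enumerate(self._batchnorms()):
            state[f"__bn{i}.running_mean"] = bn.running_mean.copy()
            state[f"__bn{i}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.parameters():
            p[...] = state[n]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = state[f"__bn{i}.running_mean"]
            bn.running_var[...] = state[f"__bn{i}.running_var"]

    def _batchnorms(self) -> list[nn.BatchNorm2d]:
        out = []
        for _, layer in self.stages:
            out += [s for s in nn._walk_layers(layer) if isinstance(s, nn.BatchNorm2d)]
        return out

    # -- execution ----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                capture: str | None = None) -> np.ndarray:
        """Run the network on an (N,3,H,W) batch.

        ``capture`` names a stage whose output (and, after ``backward``, its
        gradient) is stashed in ``captured`` — used by Grad-CAM.
        """
        self._capture = {}
        self._capture_stage = capture
        for name, layer in self.stages:
            x = layer.forward(x, train)
            if name == capture:
                self._capture["activation"] = x
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        stop = self._capture_stage
        for name, layer in reversed(self.stages):
            grad = layer.backward(grad)
            if name == stop:
                self._capture["gradient"] = grad
                break

    @property
    def captured(self) -> dict[str, np.ndarray]:
        return self._capture

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False).argmax(axis=1)


def assemble_model(config: ModelConfig, seed: int = 20210601) -> Network:
    """Build an executable, Xavier-initialized network from ``config``.

    Stage order: stem -> ms1 -> se1 -> [block -> se2] -> [ms2 -> se3]
    -> gap -> fc, with max-pools inserted per the downsample schedule.
    Channel-chaining violations surface as :class:`ConfigurationError` when
    the config is constructed.
    """
    pools = dict(config.downsample_schedule)
    stages: list[tuple[str, nn.Layer]] = []

    def add(name: str, layer: nn.Layer) -> None:
        stages.append((name, layer))
        if name in pools:
            p = pools[name]
            stages.append((f"pool_{name}", nn.MaxPool2d(p.kernel, p.stride, p.padding)))

    stem = config.stem
    stem_layers: list[tuple[str, nn.Layer]] = [
        ("conv", nn.Conv2d(stem.in_channels, stem.out_channels, stem.kernel,
                           stride=stem.stride, padding=stem.pad,
                           bias=stem.has_bias)),
    ]
    if stem.has_bn:
        stem_layers.append(("bn", nn.BatchNorm2d(stem.out_channels)))
    if stem.activation == "relu":
        stem_layers.append(("relu", nn.ReLU()))
    add("stem", nn.Sequential(stem_layers))
    add("ms1", nn.MultiScale(config.ms1.in_channels, config.ms1.branch_widths))
    add("se1", nn.SEBlock(config.se1.channels, config.se1.reduction_ratio))
    if config.block is not None:
        add("block", nn.BasicBlock(config.block.channels))
        add("se2", nn.SEBlock(config.se2.channels, config.se2.reduction_ratio))
    if config.ms2 is not None:
        add("ms2", nn.MultiScale(config.ms2.in_channels, config.ms2.branch_widths))
        add("se3", nn.SEBlock(config.se3.channels, config.se3.reduction_ratio))
    add("gap", nn.GlobalAvgPool())
    add("fc", nn.Linear(config.classifier_in_channels, config.n_classes))

    net = Network(config, stages)
    init_network(net, seed)
    return net


def init_network(net: Network, seed: int) -> None:
    """Glorot-normal weights over the whole network in stage order, zero
    biases, unit BN scales / zero shifts; deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    for _, stage in net.stages:
        for layer in nn._walk_layers(stage):
            if isinstance(layer, (nn.Conv2d, nn.Linear)):
                if isinstance(layer, nn.Conv2d):
                    k2 = layer.kernel**2
                    fan_in, fan_out = layer.in_channels * k2, layer.out_channels * k2
                else:
                    fan_in, fan_out = layer.in_features, layer.out_features
                std = np.sqrt(2.0 / (fan_in + fan_out))
                layer.W[...] = rng.normal(0.0, std, size=layer.W.shape).astype(np.float32)
                if layer.b is not None:
                    layer.b[...] = 0.0
            elif isinstance(layer, nn.BatchNorm2d):
                layer.gamma[...] = 1.0
                layer.beta[...] = 0.0
                layer.running_mean[...] = 0.0
                layer.running_var[...] = 1.0


def _conv_out(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def forward_shape_trace(
    config: ModelConfig, input_shape: tuple[int, int, int] | None = None
) -> list[tuple[str, tuple]]:
    """Trace per-stage output shapes (H, W, C) without building weights.

    Same-padding stride-1 stages (multi-scale, SE, BasicBlock) preserve the
    spatial size; the GAP stage collapses to 1x1xC; the final entry is the
    logit shape ``(n_classes,)``.  Raises :class:`ShapeError`, naming the
    failing stage, if the input is too small for the downsample schedule.
    """
    if input_shape is None:
        h, w = config.input_size
        c = config.stem.in_channels
    else:
        h, w, c = input_shape
    if c != config.stem.in_channels:
        raise ShapeError(
            f"stem expects {config.stem.in_channels} input channels, got {c}"
        )
    pools = dict(config.downsample_schedule)
    trace: list[tuple[str, tuple]] = [("input", (h, w, c))]

    def pool_after(stage: str, h: int, w: int) -> tuple[int, int]:
        if stage not in pools:
            return h, w
        p = pools[stage]
        ho = _conv_out(h, p.kernel, p.stride, p.padding)
        wo = _conv_out(w, p.kernel, p.stride, p.padding)
        if ho < 1 or wo < 1:
            raise ShapeError(f"input too small at stage pool_{stage}")
        trace.append((f"pool_{stage}", (ho, wo, trace[-1][1][2])))
        return ho, wo

    stem = config.stem
    h2 = _conv_out(h, stem.kernel, stem.stride, stem.pad)
    w2 = _conv_out(w, stem.kernel, stem.stride, stem.pad)
    if h2 < 1 or w2 < 1:
        raise ShapeError("input too small at stage stem")
    trace.append(("stem", (h2, w2, stem.out_channels)))
    h, w = pool_after("stem", h2, w2)

    c1 = config.ms1.out_channels
    trace.append(("ms1", (h, w, c1)))
    trace.append(("se1", (h, w, c1)))
    h, w = pool_after("se1", h, w)
    if config.block is not None:
        trace.append(("block", (h, w, c1)))
        trace.append(("se2", (h, w, c1)))
        h, w = pool_after("se2", h, w)
    if config.ms2 is not None:
        c2 = config.ms2.out_channels
        trace.append(("ms2", (h, w, c2)))
        trace.append(("se3", (h, w, c2)))
        h, w = pool_after("se3", h, w)
    cf = config.classifier_in_channels
    if h < 1 or w < 1:
        raise ShapeError("input too small at stage gap")
    trace.append(("gap", (1, 1, cf)))
    trace.append(("fc", (config.n_classes,)))
    return trace


def count_trainable_parameters(model: Network) -> ParamReport:
    """Enumerate every trainable array in the constructed model.

    Covers conv weights (and biases where configured), BN scale/shift pairs,
    SE bottleneck FC weights/biases and the classifier FC.  BN running
    statistics are buffers, not trainable parameters, and are excluded.
    """
    rows = tuple((name, int(np.asarray(p).size)) for name, p in model.parameters())
    total = sum(n for _, n in rows)
    return ParamReport(per_layer=rows, total=total, size_mb=parameter_size_mb(total))


def apply_se(feature_map: np.ndarray, se: nn.SEBlock) -> np.ndarray:
    """Rescale ``feature_map`` channels by the SE block's excitation weights.

    Raises :class:`ShapeError` when the channel count does not match the
    block's width.
    """
    return se.forward(np.asarray(feature_map, dtype=np.float32), train=False)


def basicblock_forward(feature_map: np.ndarray, block: nn.BasicBlock) -> np.ndarray:
    """Run the residual BasicBlock: relu(x + conv2(relu(bn1(conv1(x)))))."""
    return block.forward(np.asarray(feature_map, dtype=np.float32), train=False)
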