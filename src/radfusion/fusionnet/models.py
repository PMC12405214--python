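"""Classifier architectures: base CNNs and the ASPP feature-fusion models.

The base classifier is a convolutional backbone followed by global average
pooling, a 256-unit dense layer, dropout (0.3) and a 2-class softmax.

The fusion model processes the backbone feature map through five parallel
paths: four atrous (dilated) 3x3 convolutions with rates 1 / 6 / 12 / 18
(512 filters, batch norm + ReLU; the ASPP module) and a global-context path
(global average pooling -> 1x1 conv with 512 filters -> upsampling back to
the feature-map grid). The five outputs are concatenated (7x7x2560 at full
scale) and compressed by a 1x1 convolution to 512 channels. A parallel
radiomics branch maps the 50 selected features through Dense(128) and
Dense(512) with dropout, reshapes to 1x1x512 and upsamples to the grid.
Image and radiomics branches are concatenated channel-wise (7x7x1024),
globally pooled, and classified through Dense(256) + dropout + softmax.

Two backbone styles are provided. The "dense" style uses concatenative
(dense-connectivity) blocks and ends in a 1920-channel feature map at 1/32
resolution — the geometry of a DenseNet-201 trunk; the "mobile" style uses
narrow 1x1-expansion blocks ending at 960 channels, the geometry of a
MobileNet-V3-Large trunk. Both are compact trunks built from scratch; the
paper-scale channel widths and grid sizes are exact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import (
    Adam,
    AvgPool2D,
    BatchNorm,
    BroadcastUpsample,
    Concat,
    Conv2D,
    Dense,
    Dropout,
    GlobalAvgPool,
    Graph,
    ReLU,
    Reshape,
    softmax,
    softmax_cross_entropy,
)

_BACKBONE_ALIASES = {
    "densenet201-style": "dense",
    "mobilenetv3large-style": "mobile",
    "dense": "dense",
    "mobile": "mobile",
}

#: canonical channel width of the final backbone feature map
_BACKBONE_OUT = {"dense": 1920, "mobile": 960}


@dataclass(frozen=True)
class FusionConfig:
    """All architecture constants of the base and fusion classifiers."""

    backbone: str = "densenet201-style"
    input_size: int = 224
    in_channels: int = 3
    aspp_dilations: tuple[int, ...] = (1, 6, 12, 18)
    aspp_filters: int = 512
    context_filters: int = 512
    compress_filters: int = 512
    radiomics_input_dim: int = 50
    radiomics_widths: tuple[int, int] = (128, 512)
    head_width: int = 256
    dropout_head: float = 0.3
    dropout_radiomics: float = 0.3
    n_classes: int = 2
    # backbone plan: stem width, per-stage widths (one stride-2 reduction per
    # stage incl. the stem), and the final feature-map channel count
    stem_width: int = 64
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    backbone_channels: int | None = None  # None -> canonical width per style

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONE_ALIASES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if len(self.aspp_dilations) != 4:
            raise ValueError("aspp_dilations must have 4 entries")
        if any(w <= 0 for w in (self.aspp_filters, self.context_filters,
                                self.compress_filters, self.head_width,
                                *self.radiomics_widths, *self.stage_widths)):
            raise ValueError("all widths must be positive")
        n_red = 1 + len(self.stage_widths)
        if self.input_size % (2**n_red) != 0:
            raise ValueError("input_size must be divisible by the total stride")

    @property
    def style(self) -> str:
        return _BACKBONE_ALIASES[self.backbone]

    @property
    def grid(self) -> int:
        return self.input_size // (2 ** (1 + len(self.stage_widths)))

    @property
    def backbone_out(self) -> int:
        return self.backbone_channels or _BACKBONE_OUT[self.style]

    @classmethod
    def tiny(cls, backbone: str = "densenet201-style") -> "FusionConfig":
        """Reduced-scale configuration for desk-scale training runs."""
        return cls(
            backbone=backbone, input_size=32, stem_width=16,
            stage_widths=(16, 32), backbone_channels=96, aspp_filters=32,
            context_filters=32, compress_filters=32,
            radiomics_widths=(32, 64), head_width=32,
        )


def _add_conv_bn_relu(g: Graph, rng, name: str, src: str, in_ch: int,
                      out_ch: int, k: int, stride: int = 1,
                      dilation: int = 1) -> str:
    g.add(f"{name}_conv", Conv2D(in_ch, out_ch, k, rng, stride=stride,
                                 dilation=dilation, bias=False), src)
    g.add(f"{name}_bn", BatchNorm(out_ch), f"{name}_conv")
    g.add(name, ReLU(), f"{name}_bn")
    return name


def _build_backbone(g: Graph, rng, cfg: FusionConfig, src: str) -> str:
    """Append the backbone; returns the feature-map node name and channels."""
    style = cfg.style
    x = _add_conv_bn_relu(g, rng, "stem", src, cfg.in_channels,
                          cfg.stem_width, 3, stride=2)
    ch = cfg.stem_width
    for si, width in enumerate(cfg.stage_widths):
        tag = f"s{si + 1}"
        if style == "dense":
            # dense-connectivity pair: grow by concatenation, then transition
            growth = max(width // 2, 4)
            _add_conv_bn_relu(g, rng, f"{tag}_grow", x, ch, growth, 3)
            x = g.add(f"{tag}_cat", Concat(), x, f"{tag}_grow")
            ch = ch + growth
            _add_conv_bn_relu(g, rng, f"{tag}_trans", x, ch, width, 1)
        else:
            # narrow inverted-expansion block: 1x1 expand, 3x3, 1x1 project
            exp = width * 4
            _add_conv_bn_relu(g, rng, f"{tag}_exp", x, ch, exp, 1)
            _add_conv_bn_relu(g, rng, f"{tag}_dw", f"{tag}_exp", exp, exp, 3)
            _add_conv_bn_relu(g, rng, f"{tag}_trans", f"{tag}_dw", exp, width, 1)
        x = g.add(f"{tag}_pool", AvgPool2D(2), f"{tag}_trans")
        ch = width
    _add_conv_bn_relu(g, rng, "backbone_map", x, ch, cfg.backbone_out, 1)
    return "backbone_map"


@dataclass
class ModelHandle:
    """A built model: graph, config, and the ordered layer inventory."""

    graph: Graph
    config: FusionConfig
    kind: str  # "base" | "fusion"
    seed: int

    @property
    def layer_inventory(self) -> list[tuple[str, int]]:
        return [(name, layer.n_params()) for name, layer in self.graph.param_layers()]

    @property
    def n_params(self) -> int:
        return self.graph.n_params()

    def _feed(self, images: np.ndarray, radiomics: np.ndarray | None):
        feed = {"image": images}
        if self.kind == "fusion":
            if radiomics is None:
                raise ValueError("fusion model requires a radiomics input")
            if radiomics.shape[1] != self.config.radiomics_input_dim:
                raise ValueError(
                    f"radiomics input dim {radiomics.shape[1]} != "
                    f"configured {self.config.radiomics_input_dim}"
                )
            feed["radiomics"] = radiomics
        return feed

    def predict_proba(self, images: np.ndarray,
                      radiomics: np.ndarray | None = None) -> np.ndarray:
        logits = self.graph.forward(self._feed(images, radiomics), training=False)
        return softmax(logits)

    def loss(self, images, radiomics, onehot) -> float:
        logits = self.graph.forward(self._feed(images, radiomics), training=False)
        return softmax_cross_entropy(logits, onehot)[0]

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.graph, lr=lr)

    def train_step(self, opt: Adam, images, radiomics, onehot) -> float:
        logits = self.graph.forward(self._feed(images, radiomics), training=True)
        loss, dlogits = softmax_cross_entropy(logits, onehot)
        self.graph.backward(dlogits)
        opt.step()
        return loss

    # -- weight transport -------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        out = []
        for _, layer in self.graph.param_layers():
            for p in layer.params.values():
                out.append(p.copy())
            if isinstance(layer, BatchNorm):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for _, layer in self.graph.param_layers():
            for k in layer.params:
                layer.params[k][...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    def weight_checksum(self) -> str:
        h = hashlib.sha256()
        for w in self.get_weights():
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()


def build_base_model(config: FusionConfig, seed: int = 0) -> ModelHandle:
    """Backbone -> GAP -> Dense(256) -> Dropout(0.3) -> softmax(2)."""
    rng = np.random.default_rng(seed)
    g = Graph(("image",), "logits")
    bb = _build_backbone(g, rng, config, "image")
    g.add("gap", GlobalAvgPool(), bb)
    g.add("head_fc", Dense(config.backbone_out, config.head_width, rng), "gap")
    g.add("head_relu", ReLU(), "head_fc")
    g.add("head_drop", Dropout(config.dropout_head, np.random.default_rng(rng.integers(2**31))), "head_relu")
    g.add("logits", Dense(config.head_width, config.n_classes, rng), "head_drop")
    return ModelHandle(g, config, "base", seed)


def build_fusion_model(config: FusionConfig, seed: int = 0) -> ModelHandle:
    """The dual-branch ASPP + radiomics fusion classifier."""
    rng = np.random.default_rng(seed)
    g = Graph(("image", "radiomics"), "logits")
    bb = _build_backbone(g, rng, config, "image")
    ch = config.backbone_out
    grid = config.grid

    aspp_names = []
    for d in config.aspp_dilations:
        aspp_names.append(
            _add_conv_bn_relu(g, rng, f"aspp_d{d}", bb, ch,
                              config.aspp_filters, 3, dilation=d)
        )
    g.add("context_gap", GlobalAvgPool(), bb)
    g.add("context_pool", Reshape((1, 1, ch)), "context_gap")
    _add_conv_bn_relu(g, rng, "context_conv", "context_pool", ch,
                      config.context_filters, 1)
    g.add("context_upsample", BroadcastUpsample((grid, grid)), "context_conv")

    g.add("aspp_concat", Concat(), *aspp_names, "context_upsample")
    cat_ch = 4 * config.aspp_filters + config.context_filters
    _add_conv_bn_relu(g, rng, "aspp_compress", "aspp_concat", cat_ch,
                      config.compress_filters, 1)

    w1, w2 = config.radiomics_widths
    g.add("rad_fc1", Dense(config.radiomics_input_dim, w1, rng), "radiomics")
    g.add("rad_relu1", ReLU(), "rad_fc1")
    g.add("rad_drop1", Dropout(config.dropout_radiomics, np.random.default_rng(rng.integers(2**31))), "rad_relu1")
    g.add("rad_fc2", Dense(w1, w2, rng), "rad_drop1")
    g.add("rad_relu2", ReLU(), "rad_fc2")
    g.add("rad_drop2", Dropout(config.dropout_radiomics, np.random.default_rng(rng.integers(2**31))), "rad_relu2")
    g.add("rad_reshape", Reshape((1, 1, w2)), "rad_drop2")
    g.add("rad_upsample", BroadcastUpsample((grid, grid)), "rad_reshape")

    g.add("fusion_concat", Concat(), "aspp_compress", "rad_upsample")
    g.add("fusion_gap", GlobalAvgPool(), "fusion_concat")
    g.add("head_fc", Dense(config.compress_filters + w2, config.head_width, rng),
          "fusion_gap")
    g.add("head_relu", ReLU(), "head_fc")
    g.add("head_drop", Dropout(config.dropout_head, np.random.default_rng(rng.integers(2**31))), "head_relu")
    g.add("logits", Dense(config.head_width, config.n_classes, rng), "head_drop")
    return ModelHandle(g, config, "fusion", seed)


def inspect_shapes(handle: ModelHandle, batch: int = 1,
                   seed: int = 0) -> pd.DataFrame:
    """Run a probe batch and report every named activation shape."""
    rng = np.random.default_rng(seed)
    cfg = handle.config
    images = rng.standard_normal(
        (batch, cfg.input_size, cfg.input_size, cfg.in_channels)
    )
    rad = (rng.standard_normal((batch, cfg.radiomics_input_dim))
           if handle.kind == "fusion" else None)
    handle.graph.forward(handle._feed(images, rad), training=False)
    rows = [
        dict(name=k, shape=v, channels=v[-1])
        for k, v in handle.graph.shapes.items()
    ]
    return pd.DataFrame(rows)


def freeze_fraction(handle: ModelHandle, fraction: float = 0.7) -> ModelHandle:
    """Freeze the first floor(fraction * L) layers of the inventory."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    layers = handle.graph.param_layers()
    n_freeze = int(np.floor(fraction * len(layers)))
    for i, (_, layer) in enumerate(layers):
        layer.trainable = i >= n_freeze
    return handle


def unfreeze_all(handle: ModelHandle) -> ModelHandle:
    for _, layer in handle.graph.param_layers():
        layer.trainable = True
    return handle
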