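"""Densely connected patch classifier for 64x64 OCT windows.

Two variants share one architecture family:

* ``densenet161`` — the full configuration: 7x7 stride-2 stem convolution,
  3x3 stride-2 max pooling, dense blocks of (6, 12, 36, 24) bottlenecked
  layers with growth rate 48, 0.5-compression transition layers, batch
  normalization and ReLU before every dense-block convolution and
  transition, a final batch normalization before the classifier, and a
  softmax head.  On a 64x64 input the stage resolutions are
  32 -> 16 -> 16 -> 8 -> 4 -> 2.
* ``reduced`` — a desk-scale variant with the same wiring but two small
  dense blocks, so the training regimes can be exercised end-to-end on a
  CPU in seconds.

Convolutions are Kaiming-initialized, fully connected layers uniformly;
`replace_head` swaps the terminal fully connected layer for a new class
count while preserving every other parameter bit-for-bit, which is the
mechanism both transfer regimes rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["BackboneConfig", "ModelHandle", "build_backbone", "replace_head",
           "save_model", "load_model"]

_VARIANT_DEFAULTS = {
    "densenet161": dict(block_layout=(6, 12, 36, 24), growth=48,
                        init_channels=96, bn_size=4, stem_kernel=7,
                        stem_stride=2),
    "reduced": dict(block_layout=(2, 2), growth=12, init_channels=16,
                    bn_size=2, stem_kernel=5, stem_stride=4),
}


@dataclass(frozen=True)
class BackboneConfig:
    variant: str = "reduced"
    input_side: int = 64
    n_classes: int = 4
    block_layout: tuple[int, ...] | None = None
    growth: int | None = None
    init_channels: int | None = None
    bn_size: int | None = None
    compression: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_DEFAULTS:
            raise ValueError(f"unsupported backbone variant {self.variant!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.block_layout is not None and min(self.block_layout) < 1:
            raise ValueError("block_layout entries must be positive")

    def resolved(self) -> dict:
        d = dict(_VARIANT_DEFAULTS[self.variant])
        for key in ("block_layout", "growth", "init_channels", "bn_size"):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        d["block_layout"] = tuple(d["block_layout"])
        return d


class DenseNet(nn.Module):
    """Stem -> dense blocks with transitions -> BN-ReLU-global pool -> FC."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        p = config.resolved()
        stem_pad = p["stem_kernel"] // 2
        ch = p["init_channels"]
        self.stem = nn.Sequential(
            nn.Conv2d(1, ch, p["stem_kernel"], stride=p["stem_stride"],
                      pad=stem_pad, rng=rng),
            nn.BatchNorm2d(ch), nn.ReLU(),
        )
        self.pool = nn.MaxPool2d(3, 2, pad=1) if config.variant == "densenet161" \
            else nn.MaxPool2d(2, 2)
        self.stages: list[nn.Module] = []
        layout = p["block_layout"]
        for i, n_layers in enumerate(layout):
            block = nn.DenseBlock(ch, n_layers, p["growth"], p["bn_size"], rng)
            ch = block.out_ch
            self.stages.append(block)
            if i < len(layout) - 1:
                trans = nn.Transition(ch, int(ch * config.compression), rng)
                ch = trans.out_ch
                self.stages.append(trans)
        self.final_norm = nn.BatchNorm2d(ch)
        self.final_relu = nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.classifier = nn.Linear(ch, config.n_classes, rng=rng)
        self.feature_channels = ch
        self.stage_sizes: list[int] = []

    def forward(self, x):
        x = self.stem(x)
        sizes = [x.shape[-1]]
        x = self.pool(x)
        sizes.append(x.shape[-1])
        for stage in self.stages:
            x = stage(x)
            sizes.append(x.shape[-1])
        self.stage_sizes = sizes
        x = self.final_relu(self.final_norm(x))
        return self.classifier(self.gap(x))

    def backward(self, grad):
        grad = self.gap.backward(self.classifier.backward(grad))
        grad = self.final_norm.backward(self.final_relu.backward(grad))
        for stage in reversed(self.stages):
            grad = stage.backward(grad)
        return self.stem.backward(self.pool.backward(grad))


@dataclass
class ModelHandle:
    """A trainable patch classifier plus its provenance metadata.

    ``provenance`` is one of ``scratch``, ``generalist_pretrained`` or
    ``binary_pretrained`` and records which regime produced the weights.
    """

    net: DenseNet
    config: BackboneConfig
    provenance: str = "scratch"
    extra: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return self.config.n_classes

    @property
    def variant(self) -> str:
        return self.config.variant

    @staticmethod
    def _prepare(patches: np.ndarray) -> np.ndarray:
        """uint8/uint16 patches -> centered float NCHW."""
        arr = np.asarray(patches)
        scale = 65535.0 if arr.dtype == np.uint16 else 255.0
        x = arr.astype(np.float64)
        if x.ndim == 2:
            x = x[None]
        x = x / scale - 0.5
        return x[:, None, :, :]

    def forward_logits(self, patches: np.ndarray) -> np.ndarray:
        return self.net.forward(self._prepare(patches))

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Per-class probabilities (softmax over the terminal scores)."""
        self.net.set_training(False)
        return nn.softmax(self.net.forward(self._prepare(patches)))

    def predict(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Hard labels for a stack of patches, evaluated in batches."""
        self.net.set_training(False)
        x = np.asarray(patches)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.predict_proba(x[i: i + batch_size]).argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    def head_parameter_names(self) -> set[str]:
        return {name for name, _ in self.net.classifier.named_parameters("classifier.")}

    def body_state(self) -> dict[str, np.ndarray]:
        head = self.head_parameter_names()
        return {k: v for k, v in self.net.state_dict().items() if k not in head}


def build_backbone(config: BackboneConfig) -> ModelHandle:
    """Construct and initialize a classifier (deterministic in config.seed)."""
    rng = np.random.default_rng(config.seed)
    net = DenseNet(config, rng)
    return ModelHandle(net=net, config=config, provenance="scratch")


def replace_head(model: ModelHandle, n_classes: int, seed: int = 0) -> ModelHandle:
    """Swap the terminal fully connected layer for a fresh ``n_classes`` one.

    Every parameter and running statistic outside the head is carried over
    bit-for-bit; the new head is uniform-initialized from ``seed``.  The
    returned handle is independent of the input model.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    new_config = replace(model.config, n_classes=n_classes)
    new_model = build_backbone(new_config)
    rng = np.random.default_rng(seed)
    new_model.net.classifier = nn.Linear(model.net.feature_channels, n_classes,
                                         rng=rng)
    head = new_model.head_parameter_names()
    state = {k: v for k, v in model.net.state_dict().items() if k not in head}
    state.update({k: v for k, v in new_model.net.state_dict().items() if k in head})
    new_model.net.load_state_dict(state)
    new_model.provenance = model.provenance
    new_model.extra = dict(model.extra)
    return new_model


def save_model(model: ModelHandle, path: Path) -> None:
    """Native .npz weights plus a JSON sidecar with config and provenance."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **model.net.state_dict())
    meta = {
        "variant": model.config.variant,
        "n_classes": model.config.n_classes,
        "input_side": model.config.input_side,
        "block_layout": list(model.config.resolved()["block_layout"]),
        "seed": model.config.seed,
        "provenance": model.provenance,
        "extra": model.extra,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(path: Path) -> ModelHandle:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = BackboneConfig(variant=meta["variant"], n_classes=meta["n_classes"],
                            input_side=meta["input_side"],
                            block_layout=tuple(meta["block_layout"]),
                            seed=meta["seed"])
    model = build_backbone(config)
    with np.load(path.with_suffix(".npz")) as data:
        model.net.load_state_dict({k: data[k] for k in data.files})
    model.provenance = meta["provenance"]
    model.extra = meta.get("extra", {})
    return model
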