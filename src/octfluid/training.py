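"""Shared training loop and the three training regimes.

Regimes
-------
baseline
    4-class (healthy/CME/DRT/SRD) training from scratch; windows centered in
    uncertainty regions are discarded outright.
generalist transfer
    Start from a classifier pretrained on a generalist domain, replace its
    head with the four target classes (keeping every other weight) and
    fine-tune exactly like the baseline.  When no external weights are
    supplied, a synthetic oriented-texture pretext task stands in as the
    generalist domain (recorded in the model's provenance).
uncertainty transfer
    Stage 1 trains a binary healthy-vs-pathological classifier where the
    pathological side pools CME, DRT, SRD *and* uncertainty windows, so the
    filters see the weakly labeled patterns; stage 2 replaces the head with
    the four subtype classes and fine-tunes on defined labels only.

The loop is AdamW (decoupled weight decay) with AMSGrad, class-imbalance
weights applied per sample in the cross-entropy, horizontal-flip
augmentation, a reduce-on-plateau learning-rate schedule, early stopping,
and best-validation-loss model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, ModelHandle, build_backbone, replace_head
from .dataset import ClassWeights, ExperimentSplit, Sample, class_weights, sample_counts
from .nn import AdamW, weighted_cross_entropy
from .phantom import LABEL_HEALTHY, LABEL_UNCERTAINTY

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "PlateauController",
    "FOUR_CLASS_MAP",
    "FOUR_CLASS_NAMES",
    "binary_label_map",
    "train_model",
    "run_baseline",
    "pretrain_generalist",
    "run_generalist_transfer",
    "run_uncertainty_transfer",
]

#: mask label code -> model class index for the 4-class subtype problem
FOUR_CLASS_MAP = {1: 0, 2: 1, 3: 2, 4: 3}
FOUR_CLASS_NAMES = ("healthy", "CME", "DRT", "SRD")


def binary_label_map() -> dict[int, int]:
    """Healthy -> 0; CME, DRT, SRD and uncertainty pooled into 1."""
    return {LABEL_HEALTHY: 0, 2: 1, 3: 1, 4: 1, LABEL_UNCERTAINTY: 1}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 250
    reduced_batch_size: int = 64     # applied automatically to the reduced variant
    lr0: float = 0.01
    weight_decay: float = 0.01
    betas: tuple[float, float] = (0.9, 0.999)
    epsilon: float = 1e-8
    amsgrad: bool = True
    scheduler_factor: float = 0.66
    scheduler_patience: int = 10
    early_stop_patience: int = 25
    min_delta: float = 1e-6
    flip_p: float = 0.5
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.scheduler_factor < 1.0:
            raise ValueError("scheduler_factor must lie in (0,1)")
        if self.early_stop_patience <= self.scheduler_patience:
            raise ValueError("early_stop_patience must exceed scheduler_patience")


@dataclass
class TrainingLog:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""


class PlateauController:
    """Improvement tracking for the scheduler and early stopping.

    An epoch "improves" when its validation loss undercuts the best seen by
    at least ``min_delta``.  After ``scheduler_patience`` consecutive
    non-improving epochs the learning rate is cut by ``factor`` (and that
    counter resets); after ``early_stop_patience`` consecutive non-improving
    epochs training stops.  The best epoch is tracked for model selection.
    """

    def __init__(self, factor: float = 0.66, scheduler_patience: int = 10,
                 early_stop_patience: int = 25, min_delta: float = 1e-6):
        self.factor = factor
        self.scheduler_patience = scheduler_patience
        self.early_stop_patience = early_stop_patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = -1
        self._sched_bad = 0
        self._stop_bad = 0

    def update(self, epoch: int, val_loss: float) -> dict[str, bool]:
        improved = val_loss < self.best_loss - self.min_delta
        reduce_lr = stop = False
        if improved:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self._sched_bad = self._stop_bad = 0
        else:
            self._sched_bad += 1
            self._stop_bad += 1
            if self._sched_bad >= self.scheduler_patience:
                reduce_lr = True
                self._sched_bad = 0
            if self._stop_bad >= self.early_stop_patience:
                stop = True
        return {"improved": improved, "reduce_lr": reduce_lr, "stop": stop}


def _to_arrays(samples: list[Sample], label_map: dict[int, int]):
    x = np.stack([s.patch for s in samples])
    y = np.array([label_map[s.label] for s in samples], dtype=np.int64)
    return x, y


def _epoch_val_loss(model: ModelHandle, x, y, w, batch: int) -> float:
    model.net.set_training(False)
    num = den = 0.0
    for i in range(0, len(x), batch):
        logits = model.forward_logits(x[i: i + batch])
        yb, wb = y[i: i + batch], w[i: i + batch]
        loss, _ = weighted_cross_entropy(logits, yb, wb)
        num += loss * wb.sum()
        den += wb.sum()
    return num / den


def train_model(model: ModelHandle, train_samples: list[Sample],
                val_samples: list[Sample], weights: ClassWeights,
                config: TrainConfig,
                label_map: dict[int, int] | None = None
                ) -> tuple[ModelHandle, TrainingLog]:
    """Train ``model`` in place; return it with the best-validation snapshot
    restored, plus the full log.

    ``label_map`` maps mask label codes to model class indices (default: the
    4-class subtype mapping); ``weights`` must be keyed by class index and
    cover every mapped training label.  Validation loss uses the same
    weights so it is comparable across regimes.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation samples must be non-empty")
    label_map = dict(label_map or FOUR_CLASS_MAP)
    present = {label_map.get(s.label) for s in train_samples}
    if None in present:
        raise ValueError("a training sample's label is missing from label_map")
    missing = present - set(weights.weights)
    if missing:
        raise ValueError(f"class weights missing for classes {sorted(missing)}")

    xt, yt = _to_arrays(train_samples, label_map)
    xv, yv = _to_arrays(val_samples, label_map)
    wt = np.array([weights[int(c)] for c in yt])
    wv = np.array([weights[int(c)] for c in yv])

    batch = config.batch_size if model.variant == "densenet161" \
        else min(config.batch_size, config.reduced_batch_size)
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.net.parameters(), lr=config.lr0, betas=config.betas,
                eps=config.epsilon, weight_decay=config.weight_decay,
                amsgrad=config.amsgrad)
    ctrl = PlateauController(config.scheduler_factor, config.scheduler_patience,
                             config.early_stop_patience, config.min_delta)
    log = TrainingLog()
    best_state = None
    stop_reason = "max_epochs"

    for epoch in range(config.max_epochs):
        model.net.set_training(True)
        order = rng.permutation(len(xt))
        flip = rng.random(len(xt)) < config.flip_p
        epoch_num = epoch_den = 0.0
        for i in range(0, len(order), batch):
            idx = order[i: i + batch]
            xb = xt[idx].copy()
            fb = flip[idx]
            xb[fb] = xb[fb, :, ::-1]
            logits = model.forward_logits(xb)
            loss, dlogits = weighted_cross_entropy(logits, yt[idx], wt[idx])
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            epoch_num += loss * wt[idx].sum()
            epoch_den += wt[idx].sum()
        val_loss = _epoch_val_loss(model, xv, yv, wv, batch)
        log.train_losses.append(epoch_num / epoch_den)
        log.val_losses.append(val_loss)
        log.lrs.append(opt.lr)
        action = ctrl.update(epoch, val_loss)
        if action["improved"]:
            best_state = model.net.state_dict()
        if action["reduce_lr"]:
            opt.lr *= config.scheduler_factor
        if action["stop"]:
            stop_reason = "early_stop"
            break

    if best_state is not None:
        model.net.load_state_dict(best_state)
    log.best_epoch = ctrl.best_epoch
    log.stop_reason = stop_reason
    return model, log


# ---------------------------------------------------------------------------
# sample routing


def split_samples(samples: list[Sample], folds: dict[str, int],
                  split: ExperimentSplit) -> dict[str, list[Sample]]:
    """Route samples into train/val/test by their source image's fold."""
    out: dict[str, list[Sample]] = {"train": [], "val": [], "test": []}
    for s in samples:
        out[split.role_of(folds[s.image_id])].append(s)
    return out


def _defined_only(samples: list[Sample]) -> list[Sample]:
    return [s for s in samples if s.label != LABEL_UNCERTAINTY]


def _four_class_weights(train: list[Sample]) -> ClassWeights:
    cw = class_weights(sample_counts(train), scheme="four_class")
    return ClassWeights({FOUR_CLASS_MAP[c]: w for c, w in cw.weights.items()})


# ---------------------------------------------------------------------------
# regimes


def run_baseline(split: ExperimentSplit, samples: list[Sample],
                 folds: dict[str, int], config: TrainConfig,
                 backbone_config: BackboneConfig | None = None
                 ) -> tuple[ModelHandle, TrainingLog]:
    """Scratch 4-class training; uncertainty-centered windows discarded."""
    backbone_config = backbone_config or BackboneConfig(seed=config.seed)
    routed = split_samples(samples, folds, split)
    train = _defined_only(routed["train"])
    val = _defined_only(routed["val"])
    model = build_backbone(backbone_config)
    return train_model(model, train, val, _four_class_weights(train), config)


def pretrain_generalist(backbone_config: BackboneConfig, config: TrainConfig,
                        n_classes: int = 6, n_per_class: int = 80,
                        side: int = 64) -> ModelHandle:
    """Pretrain on a synthetic generalist pretext task.

    The task is n-way classification of procedurally generated textures
    (oriented sinusoidal gratings at distinct angles plus blob and speckle
    fields), a small stand-in domain that forces generic edge/texture
    filters into the body before transfer.  The returned model's provenance
    is ``generalist_pretrained`` with a ``synthetic_pretext`` source marker.
    """
    rng = np.random.default_rng(backbone_config.seed + 1)
    yy, xx = np.mgrid[0:side, 0:side]
    patches, labels = [], []
    for cls in range(n_classes):
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            freq = rng.uniform(0.15, 0.5)
            if cls < 4:  # oriented gratings at 0/45/90/135 degrees
                angle = cls * np.pi / 4
                field_ = np.sin(freq * (xx * np.cos(angle) + yy * np.sin(angle)) + phase)
            elif cls == 4:  # blob field
                from scipy.ndimage import gaussian_filter
                field_ = gaussian_filter(rng.standard_normal((side, side)), 6.0)
                field_ /= max(np.abs(field_).max(), 1e-9)
            else:  # raw speckle
                field_ = rng.standard_normal((side, side)) * 0.5
            img = 127.0 + 90.0 * field_ + rng.standard_normal((side, side)) * 10.0
            patches.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(cls)
    samples = [Sample(patch=p, label=l, image_id=f"pretext-{i}", center=(0, 0))
               for i, (p, l) in enumerate(zip(patches, labels))]
    order = np.random.default_rng(backbone_config.seed + 2).permutation(len(samples))
    n_val = max(len(samples) // 5, n_classes)
    train = [samples[i] for i in order[n_val:]]
    val = [samples[i] for i in order[:n_val]]

    from dataclasses import replace as dc_replace

    pre_cfg = dc_replace(config, max_epochs=min(config.max_epochs, 10),
                         early_stop_patience=min(config.early_stop_patience, 8),
                         scheduler_patience=min(config.scheduler_patience, 4))
    model = build_backbone(
        BackboneConfig(variant=backbone_config.variant, n_classes=n_classes,
                       block_layout=backbone_config.block_layout,
                       growth=backbone_config.growth,
                       init_channels=backbone_config.init_channels,
                       bn_size=backbone_config.bn_size,
                       compression=backbone_config.compression,
                       seed=backbone_config.seed))
    weights = ClassWeights(dict.fromkeys(range(n_classes), 1.0))
    model, _ = train_model(model, train, val, weights, pre_cfg,
                           label_map={c: c for c in range(n_classes)})
    model.provenance = "generalist_pretrained"
    model.extra["source"] = "synthetic_pretext"
    return model


def run_generalist_transfer(pretrained: ModelHandle | None,
                            split: ExperimentSplit, samples: list[Sample],
                            folds: dict[str, int], config: TrainConfig,
                            backbone_config: BackboneConfig | None = None,
                            allow_pretext_fallback: bool = True
                            ) -> tuple[ModelHandle, TrainingLog]:
    """Generalist transfer: head replaced with the 4 target classes (body
    kept), then fine-tuned exactly like the baseline."""
    backbone_config = backbone_config or BackboneConfig(seed=config.seed)
    if pretrained is None:
        if not allow_pretext_fallback:
            raise ValueError("no pretrained generalist model and fallback disabled")
        pretrained = pretrain_generalist(backbone_config, config)
    model = replace_head(pretrained, n_classes=4, seed=config.seed)
    model.provenance = "generalist_pretrained"
    routed = split_samples(samples, folds, split)
    train = _defined_only(routed["train"])
    val = _defined_only(routed["val"])
    model, log = train_model(model, train, val, _four_class_weights(train), config)
    return model, log


def run_uncertainty_transfer(split: ExperimentSplit, samples: list[Sample],
                             folds: dict[str, int], config: TrainConfig,
                             backbone_config: BackboneConfig | None = None
                             ) -> tuple[ModelHandle, TrainingLog]:
    """Two-stage uncertainty-aware transfer.

    Stage 1: binary healthy vs {CME, DRT, SRD, uncertainty} with the binary
    imbalance weights.  Stage 2: head replaced to 4 classes (body carried
    over), fine-tuned on defined labels only with the 4-class weights.
    """
    backbone_config = backbone_config or BackboneConfig(seed=config.seed)
    routed = split_samples(samples, folds, split)
    if not any(s.label == LABEL_UNCERTAINTY for s in routed["train"]):
        raise ValueError("uncertainty transfer requires uncertainty samples "
                         "in the training folds (stage 1 degenerates)")

    from dataclasses import replace as dc_replace

    stage1_model = build_backbone(dc_replace(backbone_config, n_classes=2))
    bin_weights = class_weights(sample_counts(routed["train"]),
                                scheme="binary_with_uncertainty")
    stage1_model, _ = train_model(stage1_model, routed["train"], routed["val"],
                                  bin_weights, config,
                                  label_map=binary_label_map())
    stage1_model.provenance = "binary_pretrained"

    model = replace_head(stage1_model, n_classes=4, seed=config.seed)
    model.provenance = "binary_pretrained"
    train = _defined_only(routed["train"])
    val = _defined_only(routed["val"])
    model, log = train_model(model, train, val, _four_class_weights(train), config)
    return model, log


def evaluate_model(model: ModelHandle, samples: list[Sample]):
    """4-class metrics report on defined-label samples only (uncertainty
    windows carry no reference subtype and are excluded)."""
    from .metrics import per_class_report

    defined = _defined_only(samples)
    x = np.stack([s.patch for s in defined])
    y = np.array([FOUR_CLASS_MAP[s.label] for s in defined])
    scores = []
    for i in range(0, len(x), 256):
        scores.append(model.predict_proba(x[i: i + 256]))
    return per_class_report(y, np.vstack(scores), FOUR_CLASS_NAMES)
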