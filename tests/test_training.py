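import numpy as np
import pytest

import octfluid.training as training
from octfluid.backbone import BackboneConfig, build_backbone
from octfluid.dataset import (
    ClassWeights,
    Sample,
    class_weights,
    enumerate_experiments,
    extract_samples,
    make_folds,
    sample_counts,
)
from octfluid.phantom import LABEL_UNCERTAINTY
from octfluid.training import (
    FOUR_CLASS_MAP,
    PlateauController,
    TrainConfig,
    TrainingLog,
    binary_label_map,
    run_baseline,
    run_uncertainty_transfer,
    split_samples,
    train_model,
)


class TestPlateauController:
    def test_scripted_sequence_reduce_and_stop(self):
        """30 improving epochs then a flat plateau: the learning rate must
        drop after flat epochs 10 and 20 and training must stop at 25, with
        the last improving epoch selected as best."""
        ctrl = PlateauController(factor=0.66, scheduler_patience=10,
                                 early_stop_patience=25)
        losses = [1.0 - 0.01 * e for e in range(30)] + [0.71] * 40
        reduces, stopped_at = [], None
        for epoch, loss in enumerate(losses):
            action = ctrl.update(epoch, loss)
            if action["reduce_lr"]:
                reduces.append(epoch)
            if action["stop"]:
                stopped_at = epoch
                break
        assert reduces == [39, 49]          # flat epochs 10 and 20
        assert stopped_at == 54             # flat epoch 25
        assert ctrl.best_epoch == 29

    def test_improvement_requires_min_delta(self):
        ctrl = PlateauController(min_delta=1e-6, scheduler_patience=2,
                                 early_stop_patience=4)
        assert ctrl.update(0, 1.0)["improved"]
        assert not ctrl.update(1, 1.0 - 1e-9)["improved"]
        assert ctrl.update(2, 0.9)["improved"]

    def test_lr_applied_in_train_loop(self):
        """The loop multiplies the optimizer lr by the scheduler factor."""
        samples = _toy_samples(np.random.default_rng(0), n=24)
        cfg = TrainConfig(max_epochs=8, scheduler_patience=2,
                          early_stop_patience=6, seed=0, lr0=1e-5)
        model = build_backbone(BackboneConfig(seed=0, n_classes=2))
        weights = ClassWeights({0: 1.0, 1: 1.0})
        _, log = train_model(model, samples, samples, weights, cfg,
                             label_map={1: 0, 2: 1})
        lrs = np.array(log.lrs)
        ratios = lrs[1:] / lrs[:-1]
        assert set(np.round(ratios, 3)) <= {1.0, 0.66}


def _toy_samples(rng, n=24, bright=200, dark=40):
    """Trivially separable two-class patches (labels 1 and 2)."""
    out = []
    for i in range(n):
        label = 1 + i % 2
        mean = bright if label == 1 else dark
        patch = np.clip(rng.normal(mean, 8, (64, 64)), 0, 255).astype(np.uint8)
        out.append(Sample(patch=patch, label=label, image_id=f"im{i % 4}",
                          center=(32, 32)))
    return out


class TestTrainModel:
    def test_determinism(self, rng):
        samples = _toy_samples(rng)
        cfg = TrainConfig(max_epochs=3, seed=5)
        logs = []
        for _ in range(2):
            model = build_backbone(BackboneConfig(seed=9, n_classes=2))
            _, log = train_model(model, samples, samples,
                                 ClassWeights({0: 1.0, 1: 1.0}), cfg,
                                 label_map={1: 0, 2: 1})
            logs.append(log)
        assert logs[0].train_losses == logs[1].train_losses
        assert logs[0].val_losses == logs[1].val_losses

    def test_separable_patches_high_accuracy(self, rng):
        samples = _toy_samples(rng, n=60)
        cfg = TrainConfig(max_epochs=8, seed=0)
        model = build_backbone(BackboneConfig(seed=0, n_classes=2))
        model, _ = train_model(model, samples[:40], samples[40:],
                               ClassWeights({0: 1.0, 1: 1.0}), cfg,
                               label_map={1: 0, 2: 1})
        x = np.stack([s.patch for s in samples[40:]])
        y = np.array([s.label - 1 for s in samples[40:]])
        assert (model.predict(x) == y).mean() > 0.95

    def test_best_model_contract(self, rng):
        """Returned parameters reproduce the minimum recorded val loss."""
        samples = _toy_samples(rng, n=40)
        cfg = TrainConfig(max_epochs=6, seed=1)
        model = build_backbone(BackboneConfig(seed=1, n_classes=2))
        model, log = train_model(model, samples[:24], samples[24:],
                                 ClassWeights({0: 1.0, 1: 1.0}), cfg,
                                 label_map={1: 0, 2: 1})
        from octfluid.training import _epoch_val_loss

        x = np.stack([s.patch for s in samples[24:]])
        y = np.array([s.label - 1 for s in samples[24:]])
        w = np.ones(len(y))
        re_eval = _epoch_val_loss(model, x, y, w, 64)
        assert re_eval == pytest.approx(min(log.val_losses), rel=1e-5)
        assert log.best_epoch == int(np.argmin(log.val_losses))

    def test_missing_weight_rejected(self, rng):
        samples = _toy_samples(rng)
        model = build_backbone(BackboneConfig(seed=0, n_classes=2))
        with pytest.raises(ValueError, match="weights"):
            train_model(model, samples, samples, ClassWeights({0: 1.0}),
                        TrainConfig(max_epochs=1), label_map={1: 0, 2: 1})


@pytest.fixture()
def phantom_samples(contrast_images):
    rng = np.random.default_rng(3)
    samples = []
    for img in contrast_images:
        samples.extend(extract_samples(img, n_per_label=6, rng_state=rng))
    folds = make_folds(contrast_images, k=6, rng_state=0)
    return samples, folds, enumerate_experiments()[0]


class _SpyCalls:
    def __init__(self):
        self.calls = []

    def __call__(self, model, train, val, weights, config, label_map=None):
        self.calls.append({
            "model": model,
            "body": {k: v.copy() for k, v in model.body_state().items()},
            "train": list(train),
            "val": list(val),
            "weights": weights,
            "label_map": dict(label_map or FOUR_CLASS_MAP),
        })
        return model, TrainingLog()


class TestRegimeContracts:
    def test_baseline_discards_uncertainty(self, phantom_samples, monkeypatch):
        samples, folds, split = phantom_samples
        spy = _SpyCalls()
        monkeypatch.setattr(training, "train_model", spy)
        run_baseline(split, samples, folds, TrainConfig(max_epochs=1))
        routed = split_samples(samples, folds, split)
        n_unc = sum(1 for s in routed["train"] if s.label == LABEL_UNCERTAINTY)
        call = spy.calls[0]
        assert len(call["train"]) == len(routed["train"]) - n_unc
        assert all(s.label != LABEL_UNCERTAINTY for s in call["train"])
        assert all(s.label != LABEL_UNCERTAINTY for s in call["val"])

    def test_baseline_weights_match_independent_recompute(self, phantom_samples,
                                                          monkeypatch):
        samples, folds, split = phantom_samples
        spy = _SpyCalls()
        monkeypatch.setattr(training, "train_model", spy)
        run_baseline(split, samples, folds, TrainConfig(max_epochs=1))
        call = spy.calls[0]
        counts = sample_counts(call["train"])
        expected = class_weights(counts, scheme="four_class")
        for code, idx in FOUR_CLASS_MAP.items():
            assert call["weights"][idx] == pytest.approx(expected[code])

    def test_uncertainty_regime_stage_contracts(self, phantom_samples,
                                                monkeypatch):
        samples, folds, split = phantom_samples
        spy = _SpyCalls()
        monkeypatch.setattr(training, "train_model", spy)
        run_uncertainty_transfer(split, samples, folds, TrainConfig(max_epochs=1))
        stage1, stage2 = spy.calls

        # stage 1: binary mapping healthy->0, all pathological (+unc) -> 1
        assert stage1["label_map"] == binary_label_map()
        assert stage1["model"].n_classes == 2
        routed = split_samples(samples, folds, split)
        assert len(stage1["train"]) == len(routed["train"])
        counts = sample_counts(routed["train"])
        eq2 = class_weights(counts, scheme="binary_with_uncertainty")
        assert stage1["weights"][0] == pytest.approx(eq2[0])
        assert stage1["weights"][1] == pytest.approx(eq2[1])

        # stage 2: no uncertainty samples at all; 4-class head on stage-1 body
        assert all(s.label != LABEL_UNCERTAINTY for s in stage2["train"])
        assert all(s.label != LABEL_UNCERTAINTY for s in stage2["val"])
        assert stage2["model"].n_classes == 4
        assert stage2["model"].provenance == "binary_pretrained"
        s1_body = stage1["model"].body_state()
        for name, arr in stage2["body"].items():
            assert np.array_equal(arr, s1_body[name])

    def test_generalist_transfer_keeps_pretrained_body(self, phantom_samples,
                                                       monkeypatch):
        samples, folds, split = phantom_samples
        spy = _SpyCalls()
        monkeypatch.setattr(training, "train_model", spy)
        model, _ = training.run_generalist_transfer(
            None, split, samples, folds, TrainConfig(max_epochs=1))
        pretext, finetune = spy.calls
        assert pretext["model"].n_classes == 6      # synthetic pretext task
        assert finetune["model"].n_classes == 4
        pre_body = pretext["model"].body_state()
        for name, arr in finetune["body"].items():
            assert np.array_equal(arr, pre_body[name])
        assert model.provenance == "generalist_pretrained"
        assert model.extra.get("source") == "synthetic_pretext"

    def test_generalist_transfer_without_fallback_rejected(self,
                                                           phantom_samples):
        samples, folds, split = phantom_samples
        with pytest.raises(ValueError, match="fallback"):
            training.run_generalist_transfer(
                None, split, samples, folds, TrainConfig(max_epochs=1),
                allow_pretext_fallback=False)

    def test_uncertainty_regime_requires_uncertainty_samples(self,
                                                             phantom_samples):
        samples, folds, split = phantom_samples
        defined = [s for s in samples if s.label != LABEL_UNCERTAINTY]
        with pytest.raises(ValueError, match="uncertainty"):
            run_uncertainty_transfer(split, defined, folds,
                                     TrainConfig(max_epochs=1))
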