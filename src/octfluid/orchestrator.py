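"""End-to-end experiment orchestration.

Runs the full pipeline on phantoms: dataset generation, window-sample
extraction, image-level folds, the split x regime experiment grid with
per-split test metrics, aggregation into mean +/- std tables, and optional
confidence-map generation on held-out test images (a map is only ever
produced by a model whose training folds exclude the source image).

Two profiles are provided: ``desk`` (reduced backbone, two dozen phantoms,
a handful of splits — minutes on one CPU) and ``full`` (the complete
60-split grid with the densenet161 variant — intended for serious hardware).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import BackboneConfig, ModelHandle
from .confmap import generate_confidence_map
from .dataset import ExperimentSplit, enumerate_experiments, extract_samples, make_folds
from .phantom import PhantomConfig, generate_dataset
from .training import (
    FOUR_CLASS_NAMES,
    TrainConfig,
    evaluate_model,
    pretrain_generalist,
    run_baseline,
    run_generalist_transfer,
    run_uncertainty_transfer,
    split_samples,
)

__all__ = ["RunManifest", "Profile", "PROFILES", "run_experiment_grid",
           "aggregate_reports"]

APPROACHES = ("baseline", "generalist", "uncertainty")


@dataclass(frozen=True)
class Profile:
    n_images: int
    n_splits: int
    backbone_variant: str
    n_per_label: int = 25
    k_folds: int = 6


PROFILES = {
    "desk": Profile(n_images=24, n_splits=6, backbone_variant="reduced",
                    n_per_label=12),
    "full": Profile(n_images=356, n_splits=60, backbone_variant="densenet161"),
}


@dataclass
class RunManifest:
    """Everything needed to re-create a completed run."""

    config: dict
    seed: int
    sub_seeds: dict[str, int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def record_artifact(self, name: str, path: Path) -> None:
        path = Path(path)
        self.artifacts[name] = str(path)
        self.checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _train_one(approach: str, split: ExperimentSplit, samples, folds,
               train_config: TrainConfig, backbone_config: BackboneConfig,
               pretrained: ModelHandle | None):
    if approach == "baseline":
        return run_baseline(split, samples, folds, train_config, backbone_config)
    if approach == "generalist":
        return run_generalist_transfer(pretrained, split, samples, folds,
                                       train_config, backbone_config)
    if approach == "uncertainty":
        return run_uncertainty_transfer(split, samples, folds, train_config,
                                        backbone_config)
    raise ValueError(f"unknown approach {approach!r}")


def aggregate_reports(per_split: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- std over splits, per approach and class row."""
    metric_cols = [c for c in per_split.columns
                   if c not in ("approach", "split", "class", "support")]
    grouped = per_split.groupby(["approach", "class"])[metric_cols]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def run_experiment_grid(images=None, approaches=APPROACHES, n_splits: int = 6,
                        profile: str = "desk", seed: int = 0,
                        phantom_config: PhantomConfig | None = None,
                        train_config: TrainConfig | None = None,
                        backbone_config: BackboneConfig | None = None,
                        out_dir: Path | None = None,
                        generate_maps: bool = False):
    """Run the split x regime grid; returns (summary, per_split, manifest).

    ``n_splits`` is clamped (with a warning) to the number of available fold
    combinations.  Per-(split, approach) training seeds are spawned from
    ``seed`` so the whole run is re-creatable from its manifest.
    """
    prof = PROFILES[profile]
    t0 = time.time()
    ss = np.random.SeedSequence(seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ("phantoms", "sampling", "folds", "grid", "pretext"),
                 ss.spawn(5))}

    phantom_config = phantom_config or PhantomConfig(seed=seeds["phantoms"])
    if images is None:
        images = generate_dataset(prof.n_images, phantom_config, seeds["phantoms"])

    sample_rng = np.random.default_rng(seeds["sampling"])
    samples = []
    for img in images:
        samples.extend(extract_samples(img, n_per_label=prof.n_per_label,
                                       rng_state=sample_rng))
    folds = make_folds(images, k=prof.k_folds, rng_state=seeds["folds"])
    splits = enumerate_experiments(k=prof.k_folds)
    if n_splits > len(splits):
        warnings.warn(f"requested {n_splits} splits but only {len(splits)} "
                      "fold combinations exist; clamping", stacklevel=2)
        n_splits = len(splits)
    splits = splits[:n_splits]

    train_config = train_config or TrainConfig(max_epochs=12, seed=seeds["grid"])
    backbone_config = backbone_config or BackboneConfig(
        variant=prof.backbone_variant, seed=seeds["grid"])

    pretrained = None
    if "generalist" in approaches:
        pretrained = pretrain_generalist(backbone_config, train_config)

    grid_ss = np.random.SeedSequence(seeds["grid"])
    rows = []
    manifest = RunManifest(
        config={
            "profile": profile, "approaches": list(approaches),
            "n_splits": n_splits,
            "phantom": dataclasses.asdict(phantom_config) if hasattr(
                phantom_config, "__dataclass_fields__") else str(phantom_config),
            "train": dataclasses.asdict(train_config),
            "backbone": dataclasses.asdict(backbone_config),
        },
        seed=seed, sub_seeds=seeds)
    by_image = {img.image_id: img for img in images}

    for si, split in enumerate(splits):
        for approach in approaches:
            sub = int(grid_ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            manifest.sub_seeds[f"split{si}-{approach}"] = sub
            cfg = dataclasses.replace(train_config, seed=sub)
            bcfg = dataclasses.replace(backbone_config, seed=sub)
            model, _ = _train_one(approach, split, samples, folds, cfg, bcfg,
                                  pretrained)
            routed = split_samples(samples, folds, split)
            report = evaluate_model(model, routed["test"])
            for cls in (*FOUR_CLASS_NAMES, "overall"):
                row = report.table.loc[cls].to_dict()
                row.update({"approach": approach, "split": si, "class": cls})
                rows.append(row)

            if generate_maps and out_dir is not None and si == 0:
                test_ids = [iid for iid, f in folds.items()
                            if f in split.test_folds]
                img = by_image[test_ids[0]]
                assert folds[img.image_id] not in split.train_folds
                conf = generate_confidence_map(model, img)
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                npz = out_dir / f"map_{approach}_{img.image_id}.npz"
                np.savez_compressed(npz, proportions=conf.proportions,
                                    coverage=conf.coverage, roi=conf.roi)
                manifest.record_artifact(f"map-{approach}", npz)

    per_split = pd.DataFrame(rows)
    summary = aggregate_reports(per_split)
    manifest.timings["total_s"] = time.time() - t0

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_split.to_csv(out_dir / "per_split_metrics.csv", index=False)
        summary.to_csv(out_dir / "summary_metrics.csv", index=False)
        manifest.record_artifact("per_split_metrics", out_dir / "per_split_metrics.csv")
        manifest.record_artifact("summary_metrics", out_dir / "summary_metrics.csv")
        manifest.save(out_dir / "manifest.json")
    return summary, per_split, manifest
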