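"""Window-sample extraction, image-level folds, experiment enumeration and
class weighting.

The unit of supervision is a 64x64 intensity patch labeled by the class of
its *center* pixel (a weak, diffuse label — the window may straddle several
tissues).  Cross-validation is at image level: images are partitioned into
six folds and every assignment of folds into 3 training / 2 validation /
1 test roles is one experiment, 60 in total, so no window of an image can
appear in two roles of any split.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantom import (
    CLASS_LABELS,
    LABEL_HEALTHY,
    LABEL_NAMES,
    LABEL_UNCERTAINTY,
    LabeledImage,
)

__all__ = [
    "Sample",
    "ExperimentSplit",
    "ClassWeights",
    "crop_with_mirror",
    "extract_samples",
    "make_folds",
    "enumerate_experiments",
    "class_weights",
    "augment_flip",
]


@dataclass(frozen=True)
class Sample:
    """A window patch with its center label and provenance."""

    patch: np.ndarray          # (window, window) intensities
    label: int                 # center-pixel label code
    image_id: str
    center: tuple[int, int]    # (row, col), 0-based image coordinates

    @property
    def label_name(self) -> str:
        return LABEL_NAMES[self.label]


@dataclass(frozen=True)
class ExperimentSplit:
    """One assignment of the k folds into train/val/test roles."""

    train_folds: frozenset[int]
    val_folds: frozenset[int]
    test_folds: frozenset[int]

    def __post_init__(self) -> None:
        roles = (self.train_folds, self.val_folds, self.test_folds)
        all_ids = set().union(*roles)
        if sum(len(r) for r in roles) != len(all_ids):
            raise ValueError("fold roles must be pairwise disjoint")

    @property
    def test_fold(self) -> int:
        (fold,) = self.test_folds
        return fold

    def role_of(self, fold: int) -> str:
        if fold in self.train_folds:
            return "train"
        if fold in self.val_folds:
            return "val"
        if fold in self.test_folds:
            return "test"
        raise KeyError(fold)


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights; each class is weighted by the size of the rest
    of the dataset relative to its own support, inverting the imbalance."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("class weights must be positive")

    def __getitem__(self, label: int) -> float:
        return self.weights[label]


def _reflect_index(i: np.ndarray, n: int) -> np.ndarray:
    """Map arbitrary integer positions onto [0, n) by reflection about the
    array edges *without* repeating the border pixel (period 2n-2)."""
    if n == 1:
        return np.zeros_like(i)
    period = 2 * (n - 1)
    i = np.abs(i) % period
    return np.where(i >= n, period - i, i)


def crop_with_mirror(intensities: np.ndarray, center: tuple[int, int],
                     window: int) -> np.ndarray:
    """Extract the ``window``-sided patch centered at ``center``.

    An even window of side w centered at c spans the half-open range
    [c - w//2, c + w//2) on each axis.  Positions outside the image are
    filled by mirroring across the border (border pixel not duplicated),
    completing the missing edge patterns.  Fully interior crops are verbatim
    sub-grids of the input.
    """
    h, w = intensities.shape[:2]
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"center {center} outside image of shape {(h, w)}")
    half = window // 2
    if window > 2 * h - 1 or window > 2 * w - 1:
        raise ValueError("window too large for mirrored completion")
    rows = np.arange(r - half, r - half + window)
    cols = np.arange(c - half, c - half + window)
    if rows[0] >= 0 and rows[-1] < h and cols[0] >= 0 and cols[-1] < w:
        return intensities[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1].copy()
    return intensities[np.ix_(_reflect_index(rows, h), _reflect_index(cols, w))]


def extract_samples(image: LabeledImage, n_per_label: int = 25,
                    window: int = 64, rng_state=None) -> list[Sample]:
    """Randomly collect up to ``n_per_label`` window samples for each label
    present in the image's mask.

    Centers are drawn uniformly *without replacement* from the pixels
    carrying each label; a label with fewer candidate centers than
    ``n_per_label`` contributes all of them.  Uncertainty centers are drawn
    from retinal uncertainty pixels only (label masks are confined to the
    ROI, so vitreous/choroid pixels are never candidates).  Patches reaching
    past the image border are completed by mirroring.
    """
    if n_per_label < 1:
        raise ValueError("n_per_label must be >= 1")
    h, w = image.shape
    if window > 2 * h - 1 or window > 2 * w - 1:
        raise ValueError("window exceeds image extent even after mirroring")
    rng = np.random.default_rng(rng_state)
    samples: list[Sample] = []
    for label in CLASS_LABELS:
        mask = image.labels == label
        if label == LABEL_UNCERTAINTY:
            mask &= image.roi  # inner-retina uncertainty only
        candidates = np.flatnonzero(mask)
        if candidates.size == 0:
            continue
        n_take = min(n_per_label, candidates.size)
        chosen = rng.choice(candidates, size=n_take, replace=False)
        for flat in chosen:
            r, c = divmod(int(flat), w)
            samples.append(Sample(
                patch=crop_with_mirror(image.intensities, (r, c), window),
                label=label, image_id=image.image_id, center=(r, c)))
    return samples


def make_folds(images: list, k: int = 6, rng_state=None) -> dict[str, int]:
    """Assign images to k folds uniformly at random, sizes differing by <=1.

    ``images`` may be LabeledImages or bare image-id strings.  Fold
    assignment at image level is what prevents train/test leakage of
    overlapping windows.
    """
    ids = [img if isinstance(img, str) else img.image_id for img in images]
    if len(ids) < k:
        raise ValueError(f"need at least {k} images for {k} folds, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids")
    rng = np.random.default_rng(rng_state)
    order = rng.permutation(len(ids))
    return {ids[int(idx)]: pos % k for pos, idx in enumerate(order)}


def enumerate_experiments(k: int = 6, n_train: int = 3, n_val: int = 2,
                          n_test: int = 1) -> list[ExperimentSplit]:
    """All assignments of k folds into train/val/test roles of the given
    sizes, each exactly once: C(k, n_train) * C(k - n_train, n_val) splits
    (60 for the 6 -> 3/2/1 default)."""
    if n_train + n_val + n_test != k:
        raise ValueError("role sizes must sum to the number of folds")
    folds = set(range(k))
    splits = []
    for train in itertools.combinations(sorted(folds), n_train):
        rest = folds - set(train)
        for val in itertools.combinations(sorted(rest), n_val):
            test = rest - set(val)
            splits.append(ExperimentSplit(frozenset(train), frozenset(val),
                                          frozenset(test)))
    return splits


def class_weights(counts: dict[int, int], scheme: str = "four_class") -> ClassWeights:
    """Imbalance-inverting class weights.

    ``four_class`` weighs each of {healthy, CME, DRT, SRD} by the summed
    support of the *other three* classes over its own (e.g. the healthy
    weight is (CME + DRT + SRD) / healthy).  ``binary_with_uncertainty``
    weighs healthy by (uncertainty + CME + DRT + SRD) / healthy and the
    pooled pathological class by the reciprocal ratio.
    """
    if scheme == "four_class":
        needed = [l for l in CLASS_LABELS if l != LABEL_UNCERTAINTY]
        _require_positive(counts, needed)
        total = sum(counts[l] for l in needed)
        return ClassWeights({l: (total - counts[l]) / counts[l] for l in needed})
    if scheme == "binary_with_uncertainty":
        needed = list(CLASS_LABELS)
        _require_positive(counts, needed)
        healthy = counts[LABEL_HEALTHY]
        pathological = sum(counts[l] for l in needed if l != LABEL_HEALTHY)
        return ClassWeights({0: pathological / healthy, 1: healthy / pathological})
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def _require_positive(counts: dict[int, int], labels: list[int]) -> None:
    for label in labels:
        if counts.get(label, 0) <= 0:
            raise ValueError(
                f"class {LABEL_NAMES.get(label, label)!r} has zero samples; "
                "weights undefined for this scheme")


def sample_counts(samples: list[Sample]) -> dict[int, int]:
    """Label -> number of samples."""
    return dict(Counter(s.label for s in samples))


def augment_flip(sample: Sample, p: float = 0.5, rng_state=None) -> Sample:
    """Horizontal flip with probability ``p`` (label unchanged)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    rng = np.random.default_rng(rng_state)
    if rng.random() < p:
        return Sample(patch=sample.patch[:, ::-1].copy(), label=sample.label,
                      image_id=sample.image_id, center=sample.center)
    return sample


# ---------------------------------------------------------------------------
# persistence


def save_splits(splits: list[ExperimentSplit], folds: dict[str, int],
                path: Path) -> None:
    payload = {
        "folds": folds,
        "splits": [
            {"train": sorted(s.train_folds), "val": sorted(s.val_folds),
             "test": sorted(s.test_folds)}
            for s in splits
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_splits(path: Path) -> tuple[list[ExperimentSplit], dict[str, int]]:
    payload = json.loads(Path(path).read_text())
    splits = [ExperimentSplit(frozenset(d["train"]), frozenset(d["val"]),
                              frozenset(d["test"]))
              for d in payload["splits"]]
    return splits, payload["folds"]
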