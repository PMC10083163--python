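"""Confidence maps from overlapping-window voting.

The retina ROI is tiled with 64x64 windows on a regular lattice with 60 px
overlap (stride 4).  Each window is classified by the patch classifier;
each ROI pixel's confidence for a class is then the proportion of windows
covering that pixel that were assigned that class — e.g. a CME confidence
of 0.8 means 8 of every 10 covering windows voted CME.  The number of
windows covering a pixel sets the resolution of the attainable confidence
levels.

Rendering maps confidence through a cold-to-warm palette with steepened
mid-range contrast, alpha-blended over the grayscale B-scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import _reflect_index
from .phantom import LabeledImage
from .training import FOUR_CLASS_NAMES

__all__ = ["WindowGrid", "ConfidenceMap", "tile_windows", "vote_map",
           "generate_confidence_map", "render_map"]


@dataclass(frozen=True)
class WindowGrid:
    """Regular lattice of window origins (top-left corners) covering the ROI.

    Origins may be negative or reach past the image edge: such windows are
    completed by mirror padding when classified, but their votes land only
    on in-image ROI pixels.
    """

    window: int
    overlap: int
    origins: tuple[tuple[int, int], ...]

    @property
    def stride(self) -> int:
        return self.window - self.overlap


def tile_windows(roi: np.ndarray, window: int = 64, overlap: int = 60,
                 anchor: str = "roi") -> WindowGrid:
    """Lay out the voting lattice over the ROI.

    Origins sit on a ``stride = window - overlap`` lattice anchored at the
    ROI bounding box top-left (``anchor="roi"``, default) or at the image
    origin (``anchor="image"``); trailing rows/columns are appended when the
    lattice would leave the far ROI edge uncovered (breaking uniform stride
    at most once per axis).  Only windows intersecting the ROI are kept, and
    every ROI pixel ends up covered by at least one window.
    """
    if overlap >= window:
        raise ValueError("overlap must be smaller than the window size")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        return WindowGrid(window, overlap, ())
    stride = window - overlap
    rows_any = np.flatnonzero(roi.any(axis=1))
    cols_any = np.flatnonzero(roi.any(axis=0))
    r_lo, r_hi = int(rows_any[0]), int(rows_any[-1])
    c_lo, c_hi = int(cols_any[0]), int(cols_any[-1])
    if anchor == "image":
        r_start = c_start = 0
    elif anchor == "roi":
        r_start, c_start = r_lo, c_lo
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    def axis_origins(start: int, last: int) -> list[int]:
        # lattice until the window starting at o covers `last`; append a
        # trailing origin if the final lattice window falls short
        out = list(range(start, last + 1, stride))
        if out[-1] + window - 1 < last:
            out.append(last - window + 1)
        return out

    origins = [(r, c)
               for r in axis_origins(r_start, r_hi)
               for c in axis_origins(c_start, c_hi)
               if roi[max(r, 0): r + window, max(c, 0): c + window].any()]
    return WindowGrid(window, overlap, tuple(origins))


@dataclass
class ConfidenceMap:
    """Per-pixel class-vote proportions over the ROI.

    ``proportions`` has shape (H, W, n_classes); inside the ROI where
    ``coverage > 0`` each pixel's vector sums to 1, elsewhere it is NaN.
    """

    proportions: np.ndarray
    coverage: np.ndarray
    roi: np.ndarray
    class_names: tuple[str, ...] = FOUR_CLASS_NAMES

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}") from None


def vote_map(grid: WindowGrid, window_labels, shape: tuple[int, int],
             roi: np.ndarray, n_classes: int = 4,
             class_names: tuple[str, ...] = FOUR_CLASS_NAMES) -> ConfidenceMap:
    """Pixel-level voting: for each ROI pixel, the per-class proportion of
    covering windows assigned that class."""
    labels = np.asarray(window_labels)
    if labels.shape[0] != len(grid.origins):
        raise ValueError(
            f"{len(grid.origins)} windows but {labels.shape[0]} labels")
    h, w = shape
    roi = np.asarray(roi, dtype=bool)
    counts = np.zeros((h, w, n_classes), dtype=np.int64)
    coverage = np.zeros((h, w), dtype=np.int64)
    for (r, c), lab in zip(grid.origins, labels):
        r0, c0 = max(r, 0), max(c, 0)
        r1, c1 = min(r + grid.window, h), min(c + grid.window, w)
        counts[r0:r1, c0:c1, int(lab)] += 1
        coverage[r0:r1, c0:c1] += 1
    coverage[~roi] = 0
    proportions = np.full((h, w, n_classes), np.nan)
    covered = coverage > 0
    proportions[covered] = counts[covered] / coverage[covered, None]
    return ConfidenceMap(proportions=proportions, coverage=coverage, roi=roi,
                         class_names=tuple(class_names))


def generate_confidence_map(model, image: LabeledImage, window: int = 64,
                            overlap: int = 60, anchor: str = "roi",
                            batch_size: int = 256) -> ConfidenceMap:
    """Tile the ROI, classify every window, and vote.

    ``model`` is a 4-class :class:`~octfluid.backbone.ModelHandle` (or any
    object with ``predict(patches) -> labels`` and ``n_classes``).  The image
    must come from a fold whose windows the model never saw in training —
    enforced by the orchestrator, not here.
    """
    if getattr(model, "n_classes", 4) != 4:
        raise ValueError("confidence maps require a 4-class model")
    grid = tile_windows(image.roi, window=window, overlap=overlap, anchor=anchor)
    h, w = image.shape
    patches = np.stack([
        image.intensities[np.ix_(_reflect_index(np.arange(r, r + window), h),
                                 _reflect_index(np.arange(c, c + window), w))]
        for r, c in grid.origins
    ]) if grid.origins else np.empty((0, window, window))
    labels = model.predict(patches, batch_size=batch_size) if len(patches) \
        else np.empty(0, dtype=int)
    return vote_map(grid, labels, image.shape, image.roi)


# ---------------------------------------------------------------------------
# rendering

# cold-to-warm control points (confidence, RGB); the compressed central
# segment (0.35-0.65 spanning blue->yellow) gives the steep mid-range
# gradient that makes near-threshold confidence differences visible
_PALETTE_STOPS = (
    (0.00, (20, 40, 200)),     # cold blue
    (0.35, (60, 170, 215)),    # cyan
    (0.50, (120, 220, 120)),   # green
    (0.65, (250, 220, 60)),    # yellow
    (1.00, (215, 30, 20)),     # warm red
)


def _palette_lut(n: int = 256) -> np.ndarray:
    xs = np.linspace(0.0, 1.0, n)
    stops_x = np.array([s[0] for s in _PALETTE_STOPS])
    stops_rgb = np.array([s[1] for s in _PALETTE_STOPS], dtype=float)
    lut = np.stack([np.interp(xs, stops_x, stops_rgb[:, ch]) for ch in range(3)],
                   axis=1)
    return lut


def render_map(conf: ConfidenceMap, class_name: str,
               image: np.ndarray | None = None, alpha: float = 0.6,
               palette: np.ndarray | None = None) -> np.ndarray:
    """RGB uint8 overlay of one class's confidence.

    Confidence 0 renders cold (blue) through warm (red) at 1 via a
    piecewise-linear cold-to-warm palette with steepened mid-range contrast;
    pixels outside the ROI (or with no coverage) show the underlying
    grayscale (neutral gray when no image is supplied).
    """
    ci = conf.class_index(class_name)
    lut = _palette_lut() if palette is None else np.asarray(palette, dtype=float)
    h, w = conf.roi.shape
    if image is None:
        base = np.full((h, w), 128.0)
    else:
        base = np.asarray(image, dtype=float)
        if base.max() > 255:
            base = base / 257.0
    out = np.repeat(base[:, :, None], 3, axis=2)
    values = conf.proportions[:, :, ci]
    covered = conf.roi & (conf.coverage > 0) & np.isfinite(values)
    idx = np.clip((values[covered] * (len(lut) - 1)).round().astype(int),
                  0, len(lut) - 1)
    out[covered] = (1.0 - alpha) * out[covered] + alpha * lut[idx]
    return np.clip(out, 0, 255).astype(np.uint8)
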