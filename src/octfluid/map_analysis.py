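"""Connected-component confidence profiling of test maps.

For each 4-connected component of a class in the reference labeling, record
its pixel size and the maximum confidence the map assigned anywhere inside
it.  The size/confidence scatter is summarized by a sliding-median trend
(windows of 1000 size units advanced in steps of 10, closed-open on size)
smoothed with a degree-3 b-spline, exposing how confidence grows with
lesion size (small cystoid bodies — microcysts — typically draw the lowest
confidences because few windows fit inside them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .confmap import ConfidenceMap

__all__ = ["CCRecord", "TrendCurve", "cc_max_confidence", "trend_line",
           "records_to_frame"]


@dataclass(frozen=True)
class CCRecord:
    """One connected component of the reference mask for one class."""

    class_name: str
    size: int
    max_confidence: float
    component_id: int
    image_id: str = ""


@dataclass
class TrendCurve:
    """Sliding-median support points and their b-spline smoothing.

    ``support_sizes``/``support_medians`` are the raw medians (bounded by
    the data range); ``curve_x``/``curve_y`` sample the smoothed spline,
    which may overshoot.  ``raw_only`` flags inputs too small for the
    requested spline degree, in which case the curve is the raw medians.
    """

    support_sizes: np.ndarray
    support_medians: np.ndarray
    curve_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    curve_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    raw_only: bool = False


def cc_max_confidence(reference_mask: np.ndarray, conf: ConfidenceMap,
                      class_name: str, label_code: int | None = None,
                      image_id: str = "") -> list[CCRecord]:
    """Per-component maximum map confidence for one class.

    ``reference_mask`` is a label grid; pixels equal to ``label_code``
    (default: the class's map channel index + 1, matching the phantom's
    palette where healthy=1 ... SRD=4) form the class mask, whose
    4-connected components are profiled.
    """
    ci = conf.class_index(class_name)
    if label_code is None:
        label_code = ci + 1
    mask = np.asarray(reference_mask) == label_code
    if mask.shape != conf.roi.shape:
        raise ValueError("reference mask and map must share geometry")
    if not mask.any():
        return []
    comp = cc_label(mask, connectivity=1)
    chan = conf.proportions[:, :, ci]
    records = []
    for region in regionprops(comp):
        vals = chan[comp == region.label]
        vals = vals[np.isfinite(vals)]
        maxv = float(vals.max()) if vals.size else float("nan")
        records.append(CCRecord(class_name=class_name, size=int(region.area),
                                max_confidence=maxv, component_id=int(region.label),
                                image_id=image_id))
    return records


def trend_line(points, window_range: int = 1000, step: int = 10,
               spline_degree: int = 3, resolution: int = 10,
               n_curve_samples: int = 200) -> TrendCurve:
    """Sliding-median trend of confidence against component size.

    ``points`` is a sequence of (size, confidence) pairs.  Window positions
    start at the smallest size and advance by ``step``; each covers sizes in
    [s, s + window_range) and contributes the median confidence of the
    points inside (empty windows are skipped).  The support sequence is then
    smoothed by a degree-``spline_degree`` b-spline through ``resolution``
    evenly spaced support points; when fewer than ``spline_degree + 1``
    support points exist the raw medians are returned with ``raw_only`` set.
    Support x-coordinates are window midpoints.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        return TrendCurve(np.empty(0), np.empty(0), raw_only=True)
    sizes, confs = pts[:, 0], pts[:, 1]
    s_min, s_max = sizes.min(), sizes.max()
    starts = np.arange(s_min, s_max + 1, step)
    sup_x, sup_y = [], []
    for s in starts:
        inside = (sizes >= s) & (sizes < s + window_range)
        if inside.any():
            sup_x.append(s + window_range / 2.0)
            sup_y.append(np.median(confs[inside]))
    sup_x = np.asarray(sup_x)
    sup_y = np.asarray(sup_y)

    # distinct x needed for interpolation; medians at duplicate x cannot occur
    # (starts are unique) but guard against too few points for the spline
    if sup_x.size < spline_degree + 1 or np.unique(sup_x).size < spline_degree + 1:
        return TrendCurve(sup_x, sup_y, curve_x=sup_x.copy(),
                          curve_y=sup_y.copy(), raw_only=True)

    n_knots = min(resolution, sup_x.size)
    knot_idx = np.unique(np.linspace(0, sup_x.size - 1, n_knots).round().astype(int))
    if knot_idx.size < spline_degree + 1:
        return TrendCurve(sup_x, sup_y, curve_x=sup_x.copy(),
                          curve_y=sup_y.copy(), raw_only=True)
    spline = make_interp_spline(sup_x[knot_idx], sup_y[knot_idx], k=spline_degree)
    curve_x = np.linspace(sup_x[0], sup_x[-1], n_curve_samples)
    return TrendCurve(sup_x, sup_y, curve_x=curve_x, curve_y=spline(curve_x))


def records_to_frame(records: list[CCRecord]):
    """CSV-ready table (class, size, max_conf, component, image)."""
    import pandas as pd

    return pd.DataFrame(
        [{"class": r.class_name, "size": r.size,
          "max_confidence": r.max_confidence, "component_id": r.component_id,
          "image_id": r.image_id} for r in records])
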