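"""Synthetic layered-retina phantoms for OCT B-scan analysis.

A phantom emulates the geometry and texture statistics of a macular OCT
B-scan: a curved retinal band delimited above by an ILM-like boundary and
below by an RPE-like boundary, layered internal reflectivity, multiplicative
speckle, and planted fluid regions of the three diabetic macular edema (DME)
types — cystoid macular edema (CME, hyporeflective blobs), diffuse retinal
thickening (DRT, speckled boundary-less patches) and serous retinal
detachment (SRD, a dome resting on the RPE floor).  Expert "uncertainty"
labels are synthesized as halos around each planted region (where a real
grader could not commit to a subtype) plus optional free-standing diffuse
patches.

Label codes follow a fixed palette: 0 outside the retina, 1 healthy,
2 CME, 3 DRT, 4 SRD, 5 uncertainty.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_dilation

__all__ = [
    "LABEL_OUTSIDE",
    "LABEL_HEALTHY",
    "LABEL_CME",
    "LABEL_DRT",
    "LABEL_SRD",
    "LABEL_UNCERTAINTY",
    "LABEL_NAMES",
    "CLASS_LABELS",
    "PhantomConfig",
    "LabeledImage",
    "generate_phantom",
    "generate_dataset",
    "save_labeled_image",
    "load_labeled_image",
    "write_dataset",
]

LABEL_OUTSIDE = 0
LABEL_HEALTHY = 1
LABEL_CME = 2
LABEL_DRT = 3
LABEL_SRD = 4
LABEL_UNCERTAINTY = 5

LABEL_NAMES = {
    LABEL_OUTSIDE: "outside",
    LABEL_HEALTHY: "healthy",
    LABEL_CME: "CME",
    LABEL_DRT: "DRT",
    LABEL_SRD: "SRD",
    LABEL_UNCERTAINTY: "uncertainty",
}
#: labels that can be the center of a training sample
CLASS_LABELS = (LABEL_HEALTHY, LABEL_CME, LABEL_DRT, LABEL_SRD, LABEL_UNCERTAINTY)

# indexed-PNG palette: label code -> RGB
_PALETTE = {
    LABEL_OUTSIDE: (0, 0, 0),
    LABEL_HEALTHY: (0, 160, 0),
    LABEL_CME: (220, 40, 40),
    LABEL_DRT: (230, 180, 40),
    LABEL_SRD: (60, 90, 230),
    LABEL_UNCERTAINTY: (150, 150, 150),
}

# 4-connected structuring element used for the uncertainty halos
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class TextureParams:
    """Per-class intensity model: Gaussian texture under multiplicative speckle.

    ``mean``/``noise_std`` are in 8-bit gray levels; ``pattern`` selects the
    morphology of planted regions ("blob" for hyporeflective CME-like
    pockets, "speckle" for diffuse DRT-like patches, "dome" for SRD-like
    fluid resting on the RPE floor).
    """

    mean: float
    noise_std: float
    pattern: str = "blob"


def _default_textures() -> dict[str, TextureParams]:
    # Means chosen so class contrast dominates speckle: pairwise mean gaps are
    # several noise standard deviations, giving the separability downstream
    # training tests rely on.
    return {
        "healthy": TextureParams(mean=120.0, noise_std=12.0, pattern="layers"),
        "CME": TextureParams(mean=38.0, noise_std=8.0, pattern="blob"),
        "DRT": TextureParams(mean=185.0, noise_std=18.0, pattern="speckle"),
        "SRD": TextureParams(mean=70.0, noise_std=7.0, pattern="dome"),
        "uncertainty": TextureParams(mean=150.0, noise_std=14.0, pattern="speckle"),
    }


def _default_prevalences() -> dict[str, float]:
    # Per-image probability that a region of each fluid type is planted.  The
    # source imaging study does not report per-image type prevalence, so these
    # are free parameters set once to values that make all classes common in a
    # modest dataset while keeping healthy tissue dominant, mimicking the
    # class imbalance of graded clinical B-scans.
    return {"CME": 0.7, "DRT": 0.6, "SRD": 0.45, "uncertainty": 0.35}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, class prevalence and texture of one synthetic B-scan."""

    height: int = 256
    width: int = 384
    n_layers: int = 5
    class_prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    texture_params: dict[str, TextureParams] = field(default_factory=_default_textures)
    uncertainty_halo: int = 3
    speckle_std: float = 0.10
    vitreous_mean: float = 18.0
    choroid_mean: float = 55.0
    sixteen_bit: bool = False
    seed: int = 0

    @classmethod
    def high_contrast(cls, **overrides) -> "PhantomConfig":
        """Controlled-contrast preset: every fluid type planted in every
        image, widened class mean gaps and damped noise, so a small
        classifier can separate the classes — the conditions under which the
        training-regime sanity checks are run."""
        params = dict(
            class_prevalences={"CME": 1.0, "DRT": 1.0, "SRD": 1.0,
                               "uncertainty": 0.5},
            texture_params={
                "healthy": TextureParams(mean=120.0, noise_std=8.0, pattern="layers"),
                "CME": TextureParams(mean=25.0, noise_std=5.0, pattern="blob"),
                "DRT": TextureParams(mean=210.0, noise_std=12.0, pattern="speckle"),
                "SRD": TextureParams(mean=72.0, noise_std=5.0, pattern="dome"),
                "uncertainty": TextureParams(mean=160.0, noise_std=10.0,
                                             pattern="speckle"),
            },
            speckle_std=0.04,
        )
        params.update(overrides)
        return cls(**params)

    def __post_init__(self) -> None:
        if self.height < 128 or self.width < 128:
            raise ValueError(
                "phantom must be at least 128x128 to admit 64x64 windows; "
                f"got {self.height}x{self.width}"
            )
        for name, p in self.class_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} must be in [0,1], got {p}")
        if self.uncertainty_halo < 0:
            raise ValueError("uncertainty_halo must be >= 0")


@dataclass
class LabeledImage:
    """One OCT-like B-scan with its label mask and retina ROI mask.

    Invariants: the three grids share shape; ``labels != outside`` only where
    ``roi`` is true; the image (not the window) is the unit of fold
    assignment downstream.
    """

    intensities: np.ndarray
    labels: np.ndarray
    roi: np.ndarray
    image_id: str

    def __post_init__(self) -> None:
        if not (self.intensities.shape == self.labels.shape == self.roi.shape):
            raise ValueError("intensities, labels and roi must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def labels_present(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != LABEL_OUTSIDE)


def _smooth_curve(rng: np.random.Generator, width: int, lo: float, hi: float,
                  n_ctrl: int = 5) -> np.ndarray:
    """Smooth random boundary: cubic interpolation of a few control points."""
    from scipy.interpolate import CubicSpline

    x_ctrl = np.linspace(0, width - 1, n_ctrl)
    y_ctrl = rng.uniform(lo, hi, size=n_ctrl)
    return CubicSpline(x_ctrl, y_ctrl)(np.arange(width))


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center
    ra, rb = radii
    return ((rr - r0) / ra) ** 2 + ((cc - c0) / rb) ** 2 <= 1.0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 4-connected component (planted regions must be
    4-connected after ROI clipping)."""
    from scipy.ndimage import label as cc_label

    lab, n = cc_label(mask, structure=_CROSS)
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def generate_phantom(config: PhantomConfig, rng_state) -> LabeledImage:
    """Generate one phantom B-scan.

    Deterministic given ``(config, rng_state)``; ``rng_state`` is an integer
    seed or a :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(rng_state)
    h, w = config.height, config.width

    # --- retinal band between an ILM-like and an RPE-like smooth curve ---
    top = _smooth_curve(rng, w, 0.12 * h, 0.30 * h)
    thickness = rng.uniform(0.35 * h, 0.55 * h)
    bottom = np.clip(top + thickness + _smooth_curve(rng, w, -0.04 * h, 0.04 * h),
                     None, 0.92 * h)
    rows = np.arange(h)[:, None]
    roi = (rows >= top[None, :]) & (rows < bottom[None, :])

    labels = np.full((h, w), LABEL_OUTSIDE, dtype=np.uint8)
    labels[roi] = LABEL_HEALTHY

    tex = config.texture_params
    mean_map = np.full((h, w), config.vitreous_mean, dtype=np.float64)
    mean_map[rows >= bottom[None, :]] = config.choroid_mean

    # layered reflectivity inside the retina: alternate bands around the
    # healthy mean, echoing the plexiform/nuclear layer alternation
    depth = (rows - top[None, :]) / np.maximum(bottom - top, 1.0)[None, :]
    layer_idx = np.clip((depth * config.n_layers).astype(int), 0, config.n_layers - 1)
    layer_offsets = rng.uniform(-18.0, 18.0, size=config.n_layers)
    healthy = tex["healthy"]
    mean_map[roi] = healthy.mean + layer_offsets[layer_idx[roi]]
    noise_map = np.full((h, w), healthy.noise_std, dtype=np.float64)

    prev = config.class_prevalences

    def plant(mask: np.ndarray, code: int, name: str) -> None:
        mask = mask & roi
        mask = _largest_component(mask)
        if not mask.any():
            return
        labels[mask] = code
        mean_map[mask] = tex[name].mean
        noise_map[mask] = tex[name].noise_std

    col_mid = np.clip((top + bottom) / 2.0, 1, h - 2)

    # CME: hyporeflective elliptical pockets
    if rng.random() < prev.get("CME", 0.0):
        for _ in range(rng.integers(1, 4)):
            c0 = rng.uniform(0.1 * w, 0.9 * w)
            r0 = rng.uniform(top[int(c0)] + 0.2 * thickness,
                             bottom[int(c0)] - 0.25 * thickness)
            radii = (rng.uniform(4, 0.14 * h), rng.uniform(6, 0.10 * w))
            plant(_ellipse_mask((h, w), (r0, c0), radii), LABEL_CME, "CME")

    # DRT: diffuse speckled patch with an irregular (thresholded-noise) border
    if rng.random() < prev.get("DRT", 0.0):
        c0 = rng.uniform(0.15 * w, 0.85 * w)
        r0 = col_mid[int(c0)]
        base = _ellipse_mask((h, w), (r0, c0),
                             (rng.uniform(0.10 * h, 0.20 * h),
                              rng.uniform(0.10 * w, 0.18 * w)))
        from scipy.ndimage import gaussian_filter

        wobble = gaussian_filter(rng.standard_normal((h, w)), 4.0) > -0.3
        plant(base & wobble, LABEL_DRT, "DRT")

    # SRD: dome of fluid resting on the RPE floor (flat bottom along the
    # lower ROI boundary, elliptical top)
    if rng.random() < prev.get("SRD", 0.0):
        c0 = rng.uniform(0.2 * w, 0.8 * w)
        rb = rng.uniform(0.08 * w, 0.16 * w)
        ra = rng.uniform(0.08 * h, 0.16 * h)
        floor = bottom[None, :]
        rr = np.arange(h)[:, None]
        # half-ellipse whose flat side sits on the RPE curve
        dome = ((rr - (floor - 1)) / ra) ** 2 + \
               ((np.arange(w)[None, :] - c0) / rb) ** 2 <= 1.0
        dome &= rr < floor
        plant(dome, LABEL_SRD, "SRD")

    # uncertainty halos around every planted pathological region
    if config.uncertainty_halo > 0:
        path_mask = np.isin(labels, (LABEL_CME, LABEL_DRT, LABEL_SRD))
        if path_mask.any():
            halo = binary_dilation(path_mask, structure=_CROSS,
                                   iterations=config.uncertainty_halo)
            halo &= roi & ~path_mask
            labels[halo] = LABEL_UNCERTAINTY

    # free-standing diffuse uncertainty patches
    if rng.random() < prev.get("uncertainty", 0.0):
        c0 = rng.uniform(0.1 * w, 0.9 * w)
        r0 = col_mid[int(c0)]
        patch = _ellipse_mask((h, w), (r0, c0),
                              (rng.uniform(4, 0.08 * h), rng.uniform(6, 0.08 * w)))
        patch &= roi & (labels == LABEL_HEALTHY)
        if patch.any():
            labels[patch] = LABEL_UNCERTAINTY
            mean_map[patch] = tex["uncertainty"].mean
            noise_map[patch] = tex["uncertainty"].noise_std

    # --- intensity: Gaussian texture + multiplicative speckle ---
    img = mean_map + rng.standard_normal((h, w)) * noise_map
    img *= 1.0 + config.speckle_std * rng.standard_normal((h, w))
    if config.sixteen_bit:
        intensities = np.clip(img * 257.0, 0, 65535).astype(np.uint16)
    else:
        intensities = np.clip(img, 0, 255).astype(np.uint8)

    assert not (labels[~roi] != LABEL_OUTSIDE).any()
    return LabeledImage(intensities=intensities, labels=labels, roi=roi,
                        image_id="phantom")


def generate_dataset(n_images: int, config: PhantomConfig, seed: int) -> list[LabeledImage]:
    """Generate ``n_images`` phantoms with per-image sub-seeds spawned from
    ``seed`` (two calls with the same arguments return identical lists)."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_images)
    images = []
    for i, child in enumerate(children):
        img = generate_phantom(config, np.random.default_rng(child))
        img.image_id = f"phantom-{seed}-{i:04d}"
        images.append(img)
    return images


# ---------------------------------------------------------------------------
# PNG / manifest I/O


def _labels_to_png(labels: np.ndarray, path: Path) -> None:
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = [0] * 768
    for code, rgb in _PALETTE.items():
        flat[3 * code: 3 * code + 3] = rgb
    im.putpalette(flat)
    im.save(path)


def save_labeled_image(image: LabeledImage, out_dir: Path) -> dict[str, str]:
    """Write intensity / label / ROI PNGs; return their relative paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = image.image_id
    paths = {
        "image": f"{stem}_img.png",
        "labels": f"{stem}_labels.png",
        "roi": f"{stem}_roi.png",
    }
    Image.fromarray(image.intensities).save(out_dir / paths["image"])
    _labels_to_png(image.labels, out_dir / paths["labels"])
    Image.fromarray((image.roi * 255).astype(np.uint8), mode="L").save(out_dir / paths["roi"])
    return paths


def load_labeled_image(out_dir: Path, image_id: str) -> LabeledImage:
    out_dir = Path(out_dir)
    intensities = np.asarray(Image.open(out_dir / f"{image_id}_img.png"))
    labels = np.asarray(Image.open(out_dir / f"{image_id}_labels.png")).astype(np.uint8)
    roi = np.asarray(Image.open(out_dir / f"{image_id}_roi.png")) > 0
    return LabeledImage(intensities=intensities, labels=labels, roi=roi, image_id=image_id)


def write_dataset(images: list[LabeledImage], out_dir: Path) -> Path:
    """Persist a phantom dataset; returns the manifest CSV path (one row per
    image: id, file paths, which classes were planted)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "image", "labels", "roi"]
                        + [LABEL_NAMES[c] for c in CLASS_LABELS])
        for img in images:
            paths = save_labeled_image(img, out_dir)
            present = set(img.labels_present())
            writer.writerow([img.image_id, paths["image"], paths["labels"], paths["roi"]]
                            + [int(c in present) for c in CLASS_LABELS])
    return manifest
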