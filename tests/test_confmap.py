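import numpy as np
import pytest

from octfluid.confmap import (
    ConfidenceMap,
    generate_confidence_map,
    render_map,
    tile_windows,
    vote_map,
)
from octfluid.phantom import PhantomConfig, generate_phantom


def brute_force_vote(grid, labels, shape, roi, n_classes=4):
    """Per-pixel recount oracle: loop over every pixel and every window."""
    h, w = shape
    counts = np.zeros((h, w, n_classes))
    coverage = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if not roi[r, c]:
                continue
            for (orow, ocol), lab in zip(grid.origins, labels):
                if orow <= r < orow + grid.window and ocol <= c < ocol + grid.window:
                    counts[r, c, int(lab)] += 1
                    coverage[r, c] += 1
    props = np.full((h, w, n_classes), np.nan)
    covered = coverage > 0
    props[covered] = counts[covered] / coverage[covered, None]
    return props, coverage


class TestTileWindows:
    def test_stride_is_window_minus_overlap(self):
        grid = tile_windows(np.ones((128, 128), bool), window=64, overlap=60)
        assert grid.stride == 4

    def test_interior_coverage_full_rectangle(self):
        roi = np.ones((256, 256), bool)
        grid = tile_windows(roi, window=64, overlap=60)
        cmap = vote_map(grid, np.zeros(len(grid.origins), int), roi.shape, roi)
        # an interior pixel is covered by a full 16x16 block of lattice windows
        assert cmap.coverage[128, 128] == 256

    def test_zero_overlap_tiles_without_overlap(self):
        roi = np.ones((128, 128), bool)
        grid = tile_windows(roi, window=64, overlap=0)
        cmap = vote_map(grid, np.zeros(len(grid.origins), int), roi.shape, roi)
        assert (cmap.coverage[roi] == 1).all()

    def test_every_roi_pixel_covered(self, default_phantom):
        roi = default_phantom.roi
        grid = tile_windows(roi, window=64, overlap=48)
        cmap = vote_map(grid, np.zeros(len(grid.origins), int), roi.shape, roi)
        assert (cmap.coverage[roi] >= 1).all()

    def test_overlap_monotone_coverage(self):
        roi = np.ones((150, 150), bool)
        prev = None
        for overlap in (0, 32, 48, 56):
            grid = tile_windows(roi, window=64, overlap=overlap)
            cov = vote_map(grid, np.zeros(len(grid.origins), int),
                           roi.shape, roi).coverage
            if prev is not None:
                assert (cov >= prev).all()
            prev = cov

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            tile_windows(np.ones((128, 128), bool), window=64, overlap=64)


class TestVoteMap:
    def test_unanimous_vote(self):
        roi = np.ones((96, 96), bool)
        grid = tile_windows(roi, window=32, overlap=24)
        labels = np.full(len(grid.origins), 1)
        cmap = vote_map(grid, labels, roi.shape, roi)
        assert np.allclose(cmap.proportions[roi][:, 1], 1.0)

    def test_eight_of_ten_windows_gives_80_percent(self):
        # one pixel covered by exactly 10 hand-placed windows, 8 voting CME
        from octfluid.confmap import WindowGrid

        origins = tuple((0, 4 * k) for k in range(10))
        grid = WindowGrid(window=64, overlap=60, origins=origins)
        labels = np.array([1] * 8 + [0] * 2)  # 1 = CME channel
        roi = np.ones((64, 100), bool)
        cmap = vote_map(grid, labels, roi.shape, roi)
        pixel = (32, 38)  # covered by all ten windows
        assert cmap.coverage[pixel] == 10
        assert cmap.proportions[pixel][1] == pytest.approx(0.8)

    def test_proportions_sum_to_one_where_covered(self, rng, default_phantom):
        roi = default_phantom.roi
        grid = tile_windows(roi, window=64, overlap=56)
        labels = rng.integers(0, 4, len(grid.origins))
        cmap = vote_map(grid, labels, roi.shape, roi)
        covered = cmap.coverage > 0
        assert np.allclose(cmap.proportions[covered].sum(axis=1), 1.0)
        assert np.isnan(cmap.proportions[~covered]).all()

    def test_matches_brute_force_recount(self, rng):
        img = generate_phantom(PhantomConfig(height=128, width=128, seed=2), 2)
        roi = img.roi
        grid = tile_windows(roi, window=32, overlap=24)
        labels = rng.integers(0, 4, len(grid.origins))
        cmap = vote_map(grid, labels, roi.shape, roi)
        props, coverage = brute_force_vote(grid, labels, roi.shape, roi)
        assert np.array_equal(cmap.coverage[roi], coverage[roi])
        both = np.isfinite(props)
        assert np.array_equal(np.isfinite(cmap.proportions), both)
        assert np.allclose(cmap.proportions[both], props[both])

    def test_label_length_mismatch_rejected(self):
        roi = np.ones((96, 96), bool)
        grid = tile_windows(roi, window=32, overlap=16)
        with pytest.raises(ValueError):
            vote_map(grid, np.zeros(3, int), roi.shape, roi)


class _ConstantModel:
    n_classes = 4

    def __init__(self, label):
        self.label = label

    def predict(self, patches, batch_size=None):
        return np.full(len(patches), self.label)


class TestGenerateConfidenceMap:
    def test_constant_classifier_gives_constant_map(self, default_phantom):
        cmap = generate_confidence_map(_ConstantModel(2), default_phantom,
                                       window=32, overlap=24)
        covered = cmap.coverage > 0
        assert np.allclose(cmap.proportions[covered][:, 2], 1.0)

    def test_determinism(self, default_phantom):
        a = generate_confidence_map(_ConstantModel(1), default_phantom,
                                    window=32, overlap=16)
        b = generate_confidence_map(_ConstantModel(1), default_phantom,
                                    window=32, overlap=16)
        cov = a.coverage > 0
        assert np.array_equal(a.coverage, b.coverage)
        assert np.allclose(a.proportions[cov], b.proportions[cov])

    def test_oracle_classifier_peaks_inside_regions(self):
        # classify every window by its true center label: the resulting map
        # must agree with a direct recomputation and peak inside regions
        from octfluid.confmap import tile_windows as tw

        img = generate_phantom(PhantomConfig.high_contrast(
            height=128, width=192), 5)

        class Oracle:
            n_classes = 4

            def predict(self_, patches, batch_size=None):
                grid = tw(img.roi, window=32, overlap=24)
                half = 16
                labs = []
                for r, c in grid.origins:
                    rr = min(max(r + half, 0), img.shape[0] - 1)
                    cc = min(max(c + half, 0), img.shape[1] - 1)
                    code = img.labels[rr, cc]
                    labs.append({1: 0, 2: 1, 3: 2, 4: 3}.get(int(code), 0))
                return np.array(labs)

        cmap = generate_confidence_map(Oracle(), img, window=32, overlap=24)
        cme = img.labels == 2
        if cme.sum() > 100:
            inside = np.nanmean(cmap.proportions[cme][:, 1])
            healthy = img.labels == 1
            outside = np.nanmean(cmap.proportions[healthy][:, 1])
            assert inside > outside

    def test_wrong_class_count_rejected(self, default_phantom):
        class TwoClass:
            n_classes = 2

        with pytest.raises(ValueError):
            generate_confidence_map(TwoClass(), default_phantom)


class TestRenderMap:
    def _flat_map(self, value):
        h, w = 32, 32
        roi = np.ones((h, w), bool)
        props = np.zeros((h, w, 4))
        props[:, :, 1] = value
        props[:, :, 0] = 1 - value
        return ConfidenceMap(proportions=props,
                             coverage=np.full((h, w), 5), roi=roi)

    def test_zero_confidence_fully_cold(self):
        img = render_map(self._flat_map(0.0), "CME")
        r, g, b = img[16, 16]
        assert b > r  # cold end: blue dominates

    def test_full_confidence_fully_warm(self):
        img = render_map(self._flat_map(1.0), "CME")
        r, g, b = img[16, 16]
        assert r > b  # warm end: red dominates

    def test_monotone_warmth_progression(self):
        h, w = 4, 101
        roi = np.ones((h, w), bool)
        props = np.zeros((h, w, 4))
        ramp = np.linspace(0, 1, w)
        props[:, :, 1] = ramp[None, :]
        props[:, :, 0] = 1 - props[:, :, 1]
        cmap = ConfidenceMap(proportions=props, coverage=np.full((h, w), 5),
                             roi=roi)
        img = render_map(cmap, "CME", alpha=1.0).astype(int)
        warmth = img[2, :, 0] - img[2, :, 2]  # R - B along the ramp
        # monotone up to the +/-1 jitter of 8-bit channel quantization
        assert (np.diff(warmth) >= -1).all()
        assert warmth[-1] - warmth[0] > 300  # cold blue -> warm red overall

    def test_unknown_class_rejected(self):
        with pytest.raises(KeyError):
            render_map(self._flat_map(0.5), "PED")

    def test_non_roi_shows_background(self):
        cmap = self._flat_map(1.0)
        cmap.roi[:, :16] = False
        cmap.coverage[:, :16] = 0
        base = np.full((32, 32), 200, dtype=np.uint8)
        img = render_map(cmap, "CME", image=base, alpha=1.0)
        assert (img[:, :16] == 200).all()
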