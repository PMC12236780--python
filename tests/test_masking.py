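"""Clipping, Otsu thresholding, chromatin masks, nuclear segmentation."""

import numpy as np
import pytest

from embryohub import (
    Projection,
    SimConfig,
    clip_intensities,
    combined_chromatin_mask,
    otsu_threshold,
    segment_nuclei,
    simulate_embryo_movie,
)


def otsu_variance_curve(image, n_bins=256):
    """Exhaustive between-class variance at every histogram cut.

    Returns (thresholds, variances): variances[i] is the between-class
    variance when the foreground starts above thresholds[i] (= the centre
    of bin i).  Runs of empty bins produce exactly tied maxima, so any
    threshold attaining the maximum is a valid Otsu output.
    """
    counts, edges = np.histogram(image.ravel(), bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    variances = np.full(n_bins - 1, -np.inf)
    for k in range(1, n_bins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        variances[k - 1] = w0 * w1 * (mu0 - mu1) ** 2
    return centers[:-1], variances


def assert_is_otsu_maximizer(image, thr, n_bins=256):
    """The threshold must be a histogram-cut maximiser of the exhaustive
    between-class-variance curve (ties allowed, to float tolerance)."""
    thresholds, variances = otsu_variance_curve(image, n_bins)
    i = int(np.argmin(np.abs(thresholds - thr)))
    assert thresholds[i] == pytest.approx(thr)
    assert variances[i] >= variances.max() * (1 - 1e-9)


class TestClip:
    def test_definition(self):
        out = clip_intensities(np.array([[10.0, 200.0]]), 100, 50)
        np.testing.assert_array_equal(out, [[10.0, 50.0]])

    def test_identity_below_threshold(self):
        img = np.array([[1.0, 99.0]])
        np.testing.assert_array_equal(clip_intensities(img, 100, 50), img)

    def test_replacement_above_threshold_rejected(self):
        with pytest.raises(ValueError):
            clip_intensities(np.zeros((2, 2)), 100, 150)


class TestOtsu:
    def test_separates_two_level_image(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 10.0
        thr = otsu_threshold(img)
        assert 0 <= thr < 10
        assert ((img > thr) == (img == 10.0)).all()

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 3.0))

    def test_maximizes_exhaustive_between_class_variance(self, rng):
        for _ in range(20):
            img = np.concatenate(
                [rng.normal(20, 5, 2000), rng.normal(200, 20, 2000)]
            ).reshape(40, 100)
            thr = otsu_threshold(img, n_bins=256)
            assert_is_otsu_maximizer(img, thr, n_bins=256)
            # and it must separate the two modes
            assert 30 < thr < 170


def _two_disk_projection(overlap=0.0):
    """Noise-free frame with two disk nuclei, plus a truth mask."""
    sim = SimConfig(
        shape=(128, 128),
        cycles=((2.0, 1.0),),
        n_initial_nuclei=2,
        nuclear_radius=12,
        channels=("histone", "polymerase"),
        drift_px_per_frame=0.0,
        photon_scale=None,
        rng_seed=2,  # both nuclei well inside the field
    )
    movie, truth = simulate_embryo_movie(sim)
    proj = Projection(
        data=movie.data[:1, 0],
        channel_names=list(movie.channel_names),
    )
    nuc = truth.nuclei[truth.nuclei.frame == 0]
    yy, xx = np.mgrid[0:128, 0:128]
    truth_mask = np.zeros((128, 128), dtype=bool)
    for _, r in nuc.iterrows():
        truth_mask |= (yy - r.y) ** 2 + (xx - r.x) ** 2 <= r.radius**2
    return proj, nuc, truth_mask


class TestChromatinMask:
    def test_covers_truth_nuclei(self):
        proj, _, truth_mask = _two_disk_projection()
        masks = combined_chromatin_mask(proj, channels=(0, 1))
        got = masks.data[0]
        coverage = (got & truth_mask).sum() / truth_mask.sum()
        false_fg = (got & ~truth_mask).sum() / (~truth_mask).sum()
        assert coverage >= 0.95
        assert false_fg <= 0.05

    def test_clipping_protects_against_bright_focus(self):
        proj, nuc, _ = _two_disk_projection()
        data = proj.data.copy()
        r = nuc.iloc[0]
        cy, cx = int(r.y), int(r.x)
        data[0, 0, cy - 1 : cy + 2, cx - 1 : cx + 2] = 50000.0
        spiked = Projection(data=data, channel_names=proj.channel_names)
        # clip level between the body level (~65 summed) and the focus
        with_clip = combined_chromatin_mask(
            spiked, channels=(0, 1), clip_threshold=200.0, replacement=65.0
        )
        without_clip = combined_chromatin_mask(
            spiked, channels=(0, 1), clip_threshold=1e9, replacement=1e9
        )
        assert without_clip.data[0].sum() < with_clip.data[0].sum()
        # clipped mask still covers the body of the spiked nucleus
        rr = r.radius * 0.5
        yy, xx = np.mgrid[0:128, 0:128]
        body = (yy - r.y) ** 2 + (xx - r.x) ** 2 <= rr**2
        assert (with_clip.data[0] & body).sum() / body.sum() > 0.95

    def test_blank_frame_error_names_frame(self):
        proj = Projection(data=np.zeros((2, 2, 32, 32)))
        with pytest.raises(ValueError, match="frame 0"):
            combined_chromatin_mask(proj, channels=(0, 1))

    def test_shift_invariance_with_shifted_clip(self):
        proj, _, _ = _two_disk_projection()
        base = combined_chromatin_mask(
            proj, channels=(0, 1), clip_threshold=80.0, replacement=40.0
        )
        shifted = Projection(
            data=proj.data + 10.0, channel_names=proj.channel_names
        )
        # sum of two channels shifts by 20, so the clip shifts by 20 too
        moved = combined_chromatin_mask(
            shifted, channels=(0, 1), clip_threshold=100.0, replacement=60.0
        )
        np.testing.assert_array_equal(base.data, moved.data)


class TestSegmentNuclei:
    def test_two_disjoint_disks(self):
        proj, nuc, _ = _two_disk_projection()
        labels = segment_nuclei(proj, channel=0)
        regions = labels.regions
        assert len(regions) == 2
        got = regions[["centroid_y", "centroid_x"]].to_numpy()
        want = nuc[["y", "x"]].to_numpy()
        from scipy.spatial.distance import cdist

        d = cdist(got, want)
        assert d.min(axis=1).max() <= 2.0

    def test_watershed_splits_touching_disks(self):
        yy, xx = np.mgrid[0:96, 0:96]
        img = np.zeros((96, 96))
        centers = [(48, 34), (48, 58)]  # overlap ~20% of radius (r=14)
        for cy, cx in centers:
            img += 100.0 / (1 + np.exp((np.hypot(yy - cy, xx - cx) - 14) / 1.5))
        proj = Projection(data=img[None, None])
        labels = segment_nuclei(proj, channel=0, min_peak_distance=8)
        regions = labels.regions
        assert len(regions) == 2
        got = regions[["centroid_y", "centroid_x"]].to_numpy()
        from scipy.spatial.distance import cdist

        d = cdist(got, np.array(centers, dtype=float))
        assert d.min(axis=1).max() <= 2.0

    def test_border_touching_nucleus_removed(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.zeros((64, 64))
        img += 100.0 / (1 + np.exp((np.hypot(yy - 0, xx - 30) - 10) / 1.5))
        img += 100.0 / (1 + np.exp((np.hypot(yy - 40, xx - 30) - 10) / 1.5))
        proj = Projection(data=img[None, None])
        labels = segment_nuclei(proj, channel=0, min_area=10)
        assert len(labels.regions) == 1
        assert labels.regions.iloc[0].centroid_y == pytest.approx(40, abs=2)

    def test_min_area_monotonicity(self):
        proj, _, _ = _two_disk_projection()
        counts = []
        for min_area in (1, 100, 400, 10000):
            labels = segment_nuclei(proj, channel=0, min_area=min_area)
            counts.append(len(labels.regions))
        assert counts == sorted(counts, reverse=True)

    def test_watershed_partitions_foreground(self):
        proj, _, _ = _two_disk_projection()
        labels = segment_nuclei(proj, channel=0, min_area=0)
        lab = labels.data[0]
        uniq = np.unique(lab)
        assert uniq[0] == 0 and len(uniq) >= 2
        # labels are consecutively renumbered and pairwise disjoint by
        # construction; every labelled pixel belongs to exactly one region
        assert set(uniq[1:]) == set(range(1, len(uniq)))
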