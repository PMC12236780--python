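"""DoG spot detection, window quantification, gap-linked tracking,
sorting and montage construction."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from embryohub import (
    Projection,
    build_montage,
    detect_spots_dog,
    filter_tracks,
    link_spots,
    quantify_spot,
    sort_tracks,
)
from embryohub.dual_reporter import SpotDetection, SpotTrack, median_onset_lag


def _proj_with_spot(cy=32.0, cx=32.0, amp=100.0, sigma=2.0, shape=(64, 64)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    spot = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    data = np.zeros((1, 2) + shape)
    data[0, 0] = spot  # 5' channel only; 3' channel blank
    return Projection(data=data, channel_names=["mcp", "pcp"])


class TestDetectSpotsDog:
    def test_spot_in_one_channel_found_on_sum(self):
        dets = detect_spots_dog(_proj_with_spot(), channels=(0, 1), threshold=1.0)
        assert len(dets) == 1
        assert abs(dets[0].y - 32) <= 1 and abs(dets[0].x - 32) <= 1

    def test_blank_movie_yields_nothing(self):
        proj = Projection(data=np.zeros((2, 2, 32, 32)))
        assert detect_spots_dog(proj, channels=(0, 1), threshold=0.5) == []

    def test_response_equals_direct_convolution_difference(self):
        proj = _proj_with_spot()
        blur_sigma, s0, s1 = 1.0, 1.5, 3.0
        dets = detect_spots_dog(
            proj, channels=(0, 1), blur_sigma=blur_sigma,
            dog_sigmas=(s0, s1), threshold=1.0,
        )
        summed = ndi.gaussian_filter(
            proj.data[0, 0] + proj.data[0, 1], blur_sigma
        )
        direct = ndi.gaussian_filter(summed, s0) - ndi.gaussian_filter(summed, s1)
        d = dets[0]
        assert d.response == pytest.approx(direct[int(d.y), int(d.x)])

    def test_degenerate_sigmas_rejected(self):
        proj = _proj_with_spot()
        with pytest.raises(ValueError):
            detect_spots_dog(proj, channels=(0, 1), dog_sigmas=(3.0, 1.5))


class TestQuantifySpot:
    def test_flat_image_corrects_to_zero(self):
        img = np.full((40, 40), 100.0)
        raw, bg, corr, border = quantify_spot(img, 20, 20)
        assert (raw, bg, corr, border) == (100.0, 100.0, 0.0, False)
        _, _, corr_full, _ = quantify_spot(img, 20, 20, background_mode="full")
        assert corr_full == 0.0

    def test_inner_box_elevation_measured_exactly(self):
        img = np.full((40, 40), 100.0)
        img[20 - 8 : 20 + 9, 20 - 8 : 20 + 9] += 50.0
        raw, bg, corr, _ = quantify_spot(img, 20, 20)
        assert corr == pytest.approx(50.0)

    def test_matches_brute_force_window_means(self, rng):
        img = rng.uniform(0, 1000, size=(40, 40))
        raw, bg, corr, border = quantify_spot(img, 20, 20)
        inner_vals, outer_vals = [], []
        for y in range(40):
            for x in range(40):
                if abs(y - 20) <= 8 and abs(x - 20) <= 8:
                    inner_vals.append(img[y, x])
                if abs(y - 20) <= 15 and abs(x - 20) <= 15:
                    outer_vals.append(img[y, x])
        want_raw = np.mean(inner_vals)
        want_bg = (np.sum(outer_vals) - np.sum(inner_vals)) / (
            len(outer_vals) - len(inner_vals)
        )
        assert not border
        assert raw == pytest.approx(want_raw)
        assert bg == pytest.approx(want_bg)
        assert corr == pytest.approx(want_raw - want_bg)
        _, bg_full, _, _ = quantify_spot(img, 20, 20, background_mode="full")
        assert bg_full == pytest.approx(np.mean(outer_vals))

    def test_border_spot_flagged(self):
        img = np.zeros((40, 40))
        raw, bg, corr, border = quantify_spot(img, 5, 20)
        assert border and np.isnan(raw)


def _dets(frame_positions):
    return [
        SpotDetection(frame=f, y=float(y), x=float(x), response=1.0)
        for f, y, x in frame_positions
    ]


class TestLinkSpots:
    def test_gap_of_five_allowed(self):
        dets = _dets([(t, 10, 10) for t in [1, 2, 3, 9, 10]])
        tracks = link_spots(dets, max_displacement=5, max_gap=5)
        assert len(tracks) == 1
        assert tracks[0].frames == [1, 2, 3, 9, 10]

    def test_gap_of_six_splits(self):
        dets = _dets([(t, 10, 10) for t in [1, 2, 3, 10]])
        tracks = link_spots(dets, max_displacement=5, max_gap=5)
        assert len(tracks) == 2

    def test_parallel_spots_do_not_swap(self):
        dets = []
        for t in range(6):
            dets += _dets([(t, 10, 10 + t), (t, 40, 10 + t)])
        tracks = link_spots(dets, max_displacement=10, max_gap=5)
        assert len(tracks) == 2
        for tr in tracks:
            assert len(set(np.round(tr.ys))) == 1  # y never jumps 30 px

    def test_each_detection_used_once(self):
        dets = _dets([(0, 10, 10), (0, 12, 10), (1, 11, 10)])
        tracks = link_spots(dets, max_displacement=5, max_gap=5)
        used = [(t, y) for tr in tracks for t, y in zip(tr.frames, tr.ys)]
        assert sorted(used) == [(0, 10.0), (0, 12.0), (1, 11.0)]


class TestFilterSort:
    def _track(self, tid, frames, pcp_total, border=False):
        tr = SpotTrack(
            track_id=tid,
            frames=list(frames),
            ys=[20.0] * len(frames),
            xs=[20.0] * len(frames),
            border_touching=border,
        )
        tr.corrected["pcp"] = [pcp_total / len(frames)] * len(frames)
        return tr

    def test_single_frame_and_border_tracks_removed(self):
        tracks = [
            self._track(1, [4], 0),
            self._track(2, [1, 2], 0, border=True),
            self._track(3, [1, 2], 0),
        ]
        kept = filter_tracks(tracks)
        assert [tr.track_id for tr in kept] == [3]

    def test_sort_key(self):
        tracks = [
            self._track(1, [2, 3], 10),
            self._track(2, [1, 2], 0),
            self._track(3, [1, 2], 99),
        ]
        out = sort_tracks(tracks)
        assert [tr.track_id for tr in out] == [3, 2, 1]

    def test_sort_stable_on_equal_keys(self):
        tracks = [self._track(i, [1, 2], 5) for i in range(5)]
        out = sort_tracks(tracks)
        assert [tr.track_id for tr in out] == list(range(5))

    def test_sort_matches_brute_force(self, rng):
        tracks = [
            self._track(i, [int(rng.integers(0, 10)) + 1, 20],
                        float(rng.integers(0, 50)))
            for i in range(50)
        ]
        out = sort_tracks(tracks)
        want = sorted(
            tracks, key=lambda tr: (tr.frames[0], -sum(tr.corrected["pcp"]))
        )
        assert [tr.track_id for tr in out] == [tr.track_id for tr in want]


class TestMontage:
    def _proj(self, rng, n_frames=3, shape=(64, 64)):
        return Projection(
            data=rng.uniform(0, 100, size=(n_frames, 1, *shape)),
            channel_names=["mcp"],
        )

    def _track(self, tid, frames, y, x):
        return SpotTrack(
            track_id=tid, frames=list(frames),
            ys=[float(y)] * len(frames), xs=[float(x)] * len(frames),
        )

    def test_dimensions(self, rng):
        proj = self._proj(rng, n_frames=3)
        tracks = [self._track(1, [0, 1, 2], 30, 30), self._track(2, [0, 2], 20, 40)]
        mont = build_montage(proj, tracks, channel=0)
        assert mont.data.shape == (2 * 17, 3 * 17)

    def test_n_tracks_clamped(self, rng):
        proj = self._proj(rng)
        tracks = [self._track(1, [0, 1, 2], 30, 30)]
        mont = build_montage(proj, tracks, channel=0, n_tracks=50)
        assert mont.n_tracks == 1

    def test_tiles_equal_direct_crops(self, rng):
        proj = self._proj(rng, n_frames=4)
        tracks = [self._track(1, [0, 1, 3], 30, 25)]  # gap at frame 2
        mont = build_montage(proj, tracks, channel=0)
        for col, t in enumerate(range(4)):
            tile = mont.data[0:17, col * 17 : (col + 1) * 17]
            want = proj.data[t, 0, 30 - 8 : 30 + 9, 25 - 8 : 25 + 9]
            np.testing.assert_array_equal(tile, want)  # gap reuses last pos

    def test_blank_before_first_appearance(self, rng):
        proj = self._proj(rng, n_frames=4)
        tracks = [
            self._track(1, [0, 1, 2, 3], 30, 30),
            self._track(2, [2, 3], 20, 40),
        ]
        mont = build_montage(proj, tracks, channel=0)
        np.testing.assert_array_equal(mont.data[17:34, 0:34], 0.0)


class TestElongationLagRecovery:
    def test_median_lag_matches_configured_delay(self, dual_result):
        from conftest import DUAL_SIM

        lag = median_onset_lag(dual_result["tracks"])
        assert abs(lag - DUAL_SIM.elongation_delay_frames) <= 1

    def test_corrected_intensity_zero_on_constant_frames(self):
        img = np.full((64, 64), 42.0)
        for mode in ("annulus", "full"):
            _, _, corr, _ = quantify_spot(img, 32, 32, background_mode=mode)
            assert corr == pytest.approx(0.0)
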