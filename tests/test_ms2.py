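"""MS2 spot detection, linking, persistence filtering, regional stats."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gapdyn.errors import InvalidInputError
from gapdyn.ms2 import (ANTERIOR_REGIONS, APAxisCalibration, MovieStack,
                        SpotCandidate, Track, TrackingConfig, detect_spots,
                        filter_tracks, link_tracks, persistence_stats,
                        residual_signal_window_min, select_pixels,
                        spot_density)

CAL = APAxisCalibration(el_at_x0=100.0, el_per_px=-0.5)


def stack_from(frames, interval=40.0):
    return MovieStack(frames=np.asarray(frames, dtype=float),
                      frame_interval_s=interval, ap_axis=CAL)


def spot(frame, x, y, intensity=500.0):
    return SpotCandidate(frame_index=frame, x=x, y=y,
                         mean_intensity=intensity, ap_position=CAL.el(x))


def brute_force_selection(frame, config, mask):
    """Independent per-pixel re-implementation of the selection rule."""
    n = config.spot_size_n
    m = n + 2
    half = m // 2
    inner_half = n // 2
    H, W = frame.shape
    out = np.zeros((H, W), dtype=bool)
    for y in range(H):
        for x in range(W):
            if frame[y, x] < config.intensity_threshold or not mask[y, x]:
                continue
            if (y - half < 0 or y + half >= H or
                    x - half < 0 or x + half >= W):
                continue           # window leaves the frame: skipped
            window = frame[y - half:y + half + 1, x - half:x + half + 1]
            total = window.sum()
            inner = frame[y - inner_half:y + inner_half + 1,
                          x - inner_half:x + inner_half + 1].sum()
            ring_mean = (total - inner) / (m * m - n * n)
            if frame[y, x] - ring_mean >= config.contrast_threshold:
                out[y, x] = True
    return out


class TestDetectSpots:
    def test_uniform_frame_no_spots(self):
        spots = detect_spots(stack_from(np.full((1, 32, 32), 10.0)),
                             TrackingConfig(),
                             mask=np.ones((32, 32), bool))
        assert spots == [[]]

    def test_single_bright_pixel(self):
        frame = np.zeros((32, 32))
        frame[16, 20] = 1000.0
        spots = detect_spots(stack_from(frame[None]),
                             TrackingConfig(intensity_threshold=100.0,
                                            contrast_threshold=50.0,
                                            spot_size_n=3),
                             mask=np.ones((32, 32), bool))
        assert len(spots[0]) == 1
        s = spots[0][0]
        assert (s.x, s.y) == (20.0, 16.0)
        assert s.mean_intensity == pytest.approx(1000.0)
        assert s.ap_position == pytest.approx(CAL.el(20.0))

    def test_bright_pixel_outside_mask_excluded(self):
        frame = np.zeros((32, 32))
        frame[16, 20] = 1000.0
        mask = np.ones((32, 32), bool)
        mask[:, 18:] = False
        spots = detect_spots(stack_from(frame[None]), TrackingConfig(),
                             mask=mask)
        assert spots == [[]]

    def test_adjacent_pixels_merge_with_weighted_centroid(self):
        frame = np.zeros((32, 32))
        frame[10, 10] = 300.0
        frame[10, 11] = 100.0        # 8-connected, merged
        cfg = TrackingConfig(intensity_threshold=50.0, contrast_threshold=10.0)
        spots = detect_spots(stack_from(frame[None]), cfg,
                             mask=np.ones((32, 32), bool))
        assert len(spots[0]) == 1
        s = spots[0][0]
        assert s.x == pytest.approx((10 * 300 + 11 * 100) / 400)
        assert s.mean_intensity == pytest.approx(200.0)

    def test_matches_brute_force_oracle_on_random_frames(self, rng):
        cfg = TrackingConfig(intensity_threshold=200.0, spot_size_n=3,
                             contrast_threshold=30.0)
        for _ in range(20):
            frame = rng.uniform(0.0, 255.0, size=(64, 64))
            frame[rng.integers(3, 61), rng.integers(3, 61)] = 300.0
            mask = np.ones((64, 64), bool)
            mask[:, :5] = False
            fast = select_pixels(frame, cfg, mask)
            slow = brute_force_selection(frame, cfg, mask)
            assert np.array_equal(fast, slow)

    def test_mask_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            detect_spots(stack_from(np.zeros((1, 16, 16))), TrackingConfig(),
                         mask=np.ones((8, 8), bool))

    @given(st.floats(0.0, 300.0))
    def test_raising_threshold_never_adds_spots(self, thr):
        rng = np.random.default_rng(7)
        frame = rng.uniform(0.0, 255.0, size=(40, 40))
        mask = np.ones((40, 40), bool)
        lo = select_pixels(frame, TrackingConfig(intensity_threshold=thr),
                           mask)
        hi = select_pixels(frame,
                           TrackingConfig(intensity_threshold=thr + 30.0),
                           mask)
        assert not np.any(hi & ~lo)


class TestLinkTracks:
    def test_drifting_spot_single_track(self):
        spots = [[spot(t, 10.0 + t, 8.0)] for t in range(6)]
        tracks = link_tracks(spots, TrackingConfig(max_displacement_px=5.0))
        assert len(tracks) == 1
        assert tracks[0].n_spots == 6

    def test_far_spots_never_linked(self):
        spots = [[spot(t, 0.0, 0.0), spot(t, 20.0, 0.0)] for t in range(3)]
        tracks = link_tracks(spots, TrackingConfig(max_displacement_px=5.0))
        # the two spots persist as two parallel tracks, never cross-linked
        assert sorted(t.n_spots for t in tracks) == [3, 3]
        for tr in tracks:
            xs = {s.x for s in tr.spots}
            assert len(xs) == 1

    def test_displacement_bound_is_inclusive_cut(self):
        spots = [[spot(0, 0.0, 0.0)], [spot(1, 6.0, 0.0)]]
        tracks = link_tracks(spots, TrackingConfig(max_displacement_px=5.0))
        assert sorted(t.n_spots for t in tracks) == [1, 1]

    def test_equidistant_tie_broken_lexicographically(self):
        # one spot at t=0; two candidates at t=1 equally distant.
        # enumeration: linking either gives one 2-track + one 1-track;
        # the stated rule picks the smaller (y, x) candidate.
        a = spot(1, 5.0, 2.0)     # (y=2, x=5)  <- smaller (y, x)
        b = spot(1, 5.0, 8.0)     # (y=8, x=5)
        origin = spot(0, 5.0, 5.0)
        tracks = link_tracks([[origin], [b, a]],
                             TrackingConfig(max_displacement_px=5.0))
        linked = next(t for t in tracks if t.n_spots == 2)
        assert linked.spots[1] is a

    def test_one_to_one_competition_by_ascending_distance(self):
        # two spots at t=0, two at t=1; the globally closest pair links
        # first, forcing the remaining pair together
        p0, p1 = spot(0, 0.0, 0.0), spot(0, 4.0, 0.0)
        q_near, q_far = spot(1, 3.5, 0.0), spot(1, 7.0, 0.0)
        tracks = link_tracks([[p0, p1], [q_near, q_far]],
                             TrackingConfig(max_displacement_px=5.0))
        linked = next(t for t in tracks if t.n_spots == 2)
        assert linked.spots[0] is p1 and linked.spots[1] is q_near
        # p0 (at x=0) is 7.0 px from q_far: beyond range, both stay single
        assert sorted(t.n_spots for t in tracks) == [1, 1, 2]

    def test_empty_frames_yield_no_links(self):
        assert link_tracks([[], []], TrackingConfig()) == []


class TestFilterTracks:
    @staticmethod
    def track_of(n_frames, interval=40.0, convention="count"):
        return Track(spots=[spot(t, 1.0, 1.0) for t in range(n_frames)],
                     frame_interval_s=interval,
                     duration_convention=convention)

    def test_three_frames_at_40s_excluded(self):
        cfg = TrackingConfig(min_duration_s=160.0)
        assert filter_tracks([self.track_of(3)], cfg) == []

    def test_four_frames_at_40s_retained(self):
        # exactly 160 s under the count convention: not "less than 160 s"
        cfg = TrackingConfig(min_duration_s=160.0)
        kept = filter_tracks([self.track_of(4)], cfg)
        assert len(kept) == 1
        assert kept[0].duration_s == 160.0

    def test_span_convention_shifts_boundary(self):
        cfg = TrackingConfig(min_duration_s=160.0,
                             duration_convention="span")
        assert filter_tracks([self.track_of(4, convention="span")], cfg) == []
        kept = filter_tracks([self.track_of(5, convention="span")], cfg)
        assert len(kept) == 1

    def test_empty_input(self):
        assert filter_tracks([], TrackingConfig()) == []

    @given(st.lists(st.integers(1, 12), max_size=12))
    def test_idempotent(self, lengths):
        cfg = TrackingConfig(min_duration_s=160.0)
        tracks = [self.track_of(n) for n in lengths]
        once = filter_tracks(tracks, cfg)
        assert filter_tracks(once, cfg) == once


class TestPersistenceStats:
    def test_single_track_all_mass_at_its_duration(self):
        tr = Track(spots=[spot(t, 10.0, 1.0) for t in range(5)],
                   frame_interval_s=40.0)      # 200 s at 95 %EL
        stats = persistence_stats([tr])
        region = stats["100-75"]
        assert region.n_tracks == 1
        assert region.mean_min == pytest.approx(200.0 / 60.0)
        assert region.hist_probs.tolist() == [1.0]

    def test_region_assignment_72_percent_el(self):
        x = CAL.px(72.0)
        tr = Track(spots=[spot(0, float(x), 1.0)], frame_interval_s=40.0)
        persistence_stats([tr])
        assert tr.region == "75-70"

    def test_region_edges_half_open(self):
        tr_hi = Track(spots=[spot(0, float(CAL.px(75.0)), 1.0)])
        tr_top = Track(spots=[spot(0, float(CAL.px(100.0)), 1.0)])
        persistence_stats([tr_hi, tr_top])
        assert tr_hi.region == "75-70"     # 75 belongs to the lower region
        assert tr_top.region == "100-75"

    def test_unassigned_bucket_warns(self):
        tr = Track(spots=[spot(0, float(CAL.px(10.0)), 1.0)])
        with pytest.warns(UserWarning):
            stats = persistence_stats([tr], regions=ANTERIOR_REGIONS)
        assert stats["unassigned"].n_tracks == 1

    def test_histogram_sums_to_one(self, rng):
        tracks = [Track(spots=[spot(t, 20.0, 1.0)
                               for t in range(int(n))])
                  for n in rng.integers(1, 10, size=30)]
        stats = persistence_stats(tracks)
        for region in stats.values():
            if region.n_tracks:
                assert region.hist_probs.sum() == pytest.approx(1.0)


class TestSpotDensity:
    def test_no_spots_zero_everywhere(self):
        dens = spot_density([[], [], []], (100.0, 40.0), CAL, height_px=100)
        assert dens.tolist() == [0.0, 0.0, 0.0]

    def test_unit_area_arithmetic(self):
        # domain 100->75 %EL is 50 px wide at 0.5 %EL/px; height 200 px
        # -> area 10000 px^2 = 1 unit; 5 spots -> density 5.0
        spots = [[spot(0, 10.0, 5.0) for _ in range(5)]]
        dens = spot_density(spots, (100.0, 75.0), CAL, height_px=200)
        assert dens[0] == pytest.approx(5.0)

    def test_zero_area_rejected(self):
        with pytest.raises(InvalidInputError):
            spot_density([[]], (50.0, 50.0), CAL, height_px=100)


class TestResidualSignalWindow:
    def test_reporter_traversal_truncates_to_whole_minutes(self):
        assert residual_signal_window_min(6.4, 1.54) == 4

    def test_invalid(self):
        with pytest.raises(InvalidInputError):
            residual_signal_window_min(0.0, 1.0)


class TestTrackInvariants:
    def test_gap_rejected(self):
        with pytest.raises(InvalidInputError):
            Track(spots=[spot(0, 1.0, 1.0), spot(2, 1.0, 1.0)])

    def test_duration_conventions(self):
        tr = Track(spots=[spot(t, 1.0, 1.0) for t in range(4)],
                   frame_interval_s=30.0)
        assert tr.duration_s == 120.0
        tr_span = Track(spots=[spot(t, 1.0, 1.0) for t in range(4)],
                        frame_interval_s=30.0, duration_convention="span")
        assert tr_span.duration_s == 90.0
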