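import collections

import numpy as np
import pytest

from aircine.io import CineSequence
from aircine.metrics import frame_metrics
from aircine.phantom import PhantomSpec, make_phantom_frame, make_phantom_sequence
from aircine.segmentation import (
    AirwayMask,
    ProfileBounds,
    SeedError,
    SeedPoint,
    SegmentationError,
    SegmentationParams,
    auto_threshold,
    profile_bounds,
    region_grow,
    segment_frame,
    segment_sequence,
)

from conftest import random_phantom_spec, seed_for


def flood_fill_oracle(frame, seed, bounds, threshold):
    """Brute-force BFS flood fill of {intensity < threshold} within bounds."""
    mask = np.zeros(frame.shape, dtype=bool)
    if frame[seed.row, seed.col] >= threshold:
        return mask
    queue = collections.deque([(seed.row, seed.col)])
    mask[seed.row, seed.col] = True
    while queue:
        r, c = queue.popleft()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if (bounds.row_lo <= rr <= bounds.row_hi
                    and bounds.col_lo <= cc <= bounds.col_hi
                    and not mask[rr, cc] and frame[rr, cc] < threshold):
                mask[rr, cc] = True
                queue.append((rr, cc))
    return mask


class TestProfileBounds:
    def test_single_dark_well_limits_at_bright_flanks(self):
        """A dark well flanked by bright plateaus bounds at the flank edges."""
        profile = np.array([150, 150, 20, 20, 20, 150, 150], dtype=float)
        # frame[r, c] = max(profile[r], profile[c]): both central profiles
        # equal `profile`, with a dark 3x3 well in the middle
        frame = np.maximum.outer(profile, profile)
        b = profile_bounds(frame, SeedPoint(3, 3), smoothing_window=1)
        assert (b.col_lo, b.col_hi) == (1, 5)
        assert (b.row_lo, b.row_hi) == (1, 5)

    def test_uniform_dark_image_falls_back_to_borders(self):
        frame = np.full((9, 11), 30.0)
        b = profile_bounds(frame, SeedPoint(4, 5))
        assert (b.row_lo, b.row_hi, b.col_lo, b.col_hi) == (0, 8, 0, 10)

    def test_noiseless_ellipse_bounds_match_analytic_extent(self):
        spec = PhantomSpec(ap_semiaxis=5.0, tx_semiaxis=3.0, modulation_fraction=0,
                           noise_sd=0, psf_sigma=0)
        frame, _ = make_phantom_frame(spec, 0)
        # smoothing off: the frame is noise-free and smoothing widens the
        # apparent flank plateau by one pixel per side
        b = profile_bounds(frame, SeedPoint(64, 64), smoothing_window=1)
        # analytic spans: 20 px AP (10 mm / 0.5 mm), 12 px TX, +-2 px slack
        assert abs((b.row_hi - b.row_lo) - 20) <= 2
        assert abs((b.col_hi - b.col_lo) - 12) <= 2

    def test_seed_in_tissue_rejected(self):
        spec = PhantomSpec(noise_sd=0, psf_sigma=0)
        frame, _ = make_phantom_frame(spec, 0)
        with pytest.raises(SeedError, match="seed not in lumen"):
            profile_bounds(frame, SeedPoint(5, 5))

    def test_seed_outside_image_rejected(self):
        with pytest.raises(SeedError):
            profile_bounds(np.zeros((8, 8)), SeedPoint(10, 2))


class TestRegionGrow:
    def test_dark_block_labeled_exactly(self):
        frame = np.full((10, 10), 200.0)
        frame[4:7, 4:7] = 10.0
        bounds = ProfileBounds(0, 9, 0, 9)
        mask = region_grow(frame, SeedPoint(5, 5), bounds, threshold=100.0)
        expected = frame < 100
        np.testing.assert_array_equal(mask.mask, expected)
        assert mask.area_pixels == 9

    def test_only_seeded_blob_grows(self):
        """Two dark blobs separated by bright tissue: only the seeded one labels."""
        frame = np.full((10, 14), 200.0)
        frame[4:7, 2:5] = 10.0    # seeded blob
        frame[4:7, 9:12] = 10.0   # bystander blob
        bounds = ProfileBounds(0, 9, 0, 13)
        mask = region_grow(frame, SeedPoint(5, 3), bounds, threshold=100.0)
        assert mask.mask[5, 3] and not mask.mask[5, 10]
        assert mask.area_pixels == 9

    def test_union_mode_fills_bbox_holes_any_mode_fills_bounds(self):
        frame = np.full((10, 10), 200.0)
        frame[4:7, 2:5] = 10.0
        frame[5, 6] = 10.0   # dark but disconnected, outside the component bbox
        frame[8, 8] = 10.0   # dark, far outside the component bbox
        bounds = ProfileBounds(0, 9, 0, 9)
        union = region_grow(frame, SeedPoint(5, 3), bounds, 100.0, fill_mode="union")
        anym = region_grow(frame, SeedPoint(5, 3), bounds, 100.0, fill_mode="any")
        conn = region_grow(frame, SeedPoint(5, 3), bounds, 100.0, fill_mode="connected")
        assert not union.mask[8, 8] and anym.mask[8, 8]
        assert union.area_pixels >= conn.area_pixels
        assert anym.area_pixels > union.area_pixels

    def test_bright_seed_gives_empty_mask(self):
        frame = np.full((10, 10), 200.0)
        mask = region_grow(frame, SeedPoint(5, 5), ProfileBounds(0, 9, 0, 9), 100.0)
        assert mask.empty and mask.area_pixels == 0

    def test_degenerate_bounds_give_empty_mask_not_error(self):
        frame = np.zeros((10, 10))
        mask = region_grow(frame, SeedPoint(3, 3), ProfileBounds(3, 3, 0, 9), 100.0)
        assert mask.empty

    def test_matches_flood_fill_oracle_on_random_noiseless_phantoms(self):
        """Pixel-exact equivalence with an independent BFS flood fill."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            spec = random_phantom_spec(rng, noiseless=True, n_frames=2)
            frame, _ = make_phantom_frame(spec, 0)
            seed = seed_for(spec)
            bounds = profile_bounds(frame, seed)
            thr = auto_threshold(frame, bounds, seed)
            mask = region_grow(frame, seed, bounds, thr)
            oracle = flood_fill_oracle(frame, seed, bounds, thr)
            np.testing.assert_array_equal(mask.mask, oracle)


class TestAutoThreshold:
    def test_two_level_image_threshold_separates_levels(self):
        frame = np.full((20, 20), 150.0)
        frame[8:12, 8:12] = 20.0
        bounds = ProfileBounds(0, 19, 0, 19)
        thr = auto_threshold(frame, bounds, SeedPoint(10, 10))
        assert 20.0 < thr < 150.0
        labeled = frame < thr
        np.testing.assert_array_equal(labeled, frame == 20.0)

    def test_constant_region_raises_no_contrast(self):
        frame = np.full((10, 10), 80.0)
        with pytest.raises(ValueError, match="no contrast"):
            auto_threshold(frame, ProfileBounds(0, 9, 0, 9))

    def test_threshold_lands_between_modes_under_noise(self):
        """Monte-Carlo: threshold separates the intensity modes in >=95/100 runs."""
        ok = 0
        for k in range(100):
            spec = PhantomSpec(noise_sd=10.0, psf_sigma=0.0, seed=k)
            frame, _ = make_phantom_frame(spec, 0)
            seed = SeedPoint(64, 64)
            bounds = profile_bounds(frame, seed)
            thr = auto_threshold(frame, bounds, seed)
            if spec.lumen_intensity + 20 < thr < spec.tissue_intensity - 20:
                ok += 1
        assert ok >= 95


class TestSegmentSequence:
    def test_constant_phantom_yields_identical_masks(self, clean_spec, center_seed):
        seq, _ = make_phantom_sequence(clean_spec)
        masks = segment_sequence(seq, center_seed)
        assert len(masks) == clean_spec.n_frames
        for m in masks[1:]:
            np.testing.assert_array_equal(m.mask, masks[0].mask)

    def test_segmentation_is_deterministic(self, breathing_sequence, center_seed):
        seq, _ = breathing_sequence
        masks1 = segment_sequence(seq, center_seed)
        masks2 = segment_sequence(seq, center_seed)
        for a, b in zip(masks1, masks2):
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_seed_tracks_drifting_lumen(self):
        """Lumen drifting 3 px across the sequence: centroids stay within 2 px."""
        n = 24
        frames, centers = [], []
        for t in range(n):
            dr = 3.0 * t / (n - 1)
            spec = PhantomSpec(lumen_center=(64.0 + dr, 64.0 + dr), noise_sd=5.0,
                               psf_sigma=0.5, modulation_fraction=0.0, n_frames=n, seed=t)
            frame, _ = make_phantom_frame(spec, t)
            frames.append(frame)
            centers.append((64.0 + dr, 64.0 + dr))
        seq = CineSequence(np.stack(frames), (0.5, 0.5), 350.0, "drift")
        masks = segment_sequence(seq, SeedPoint(64, 64))
        for mask, (r0, c0) in zip(masks, centers):
            assert not mask.empty
            cr, cc = mask.centroid()
            assert abs(cr - r0) <= 2 and abs(cc - c0) <= 2

    def test_transient_airway_closure_recovers(self):
        """Frames 10-12 closed (tissue-level lumen): empty masks, then recovery."""
        spec = PhantomSpec(noise_sd=5.0, psf_sigma=0.5, modulation_fraction=0.0,
                           n_frames=20, seed=11)
        seq, _ = make_phantom_sequence(spec)
        rng = np.random.default_rng(0)
        for t in (10, 11, 12):
            seq.frames[t] = 150.0 + rng.normal(0, 5.0, seq.frames[t].shape)
        masks = segment_sequence(seq, SeedPoint(64, 64))
        assert all(masks[t].empty for t in (10, 11, 12))
        assert not masks[13].empty
        assert masks[13].area_pixels == pytest.approx(masks[9].area_pixels, rel=0.1)

    def test_initial_seed_failure_is_fatal(self, clean_spec):
        seq, _ = make_phantom_sequence(clean_spec)
        with pytest.raises((SegmentationError, SeedError)):
            segment_sequence(seq, SeedPoint(5, 5))

    def test_mostly_closed_sequence_warns_but_completes(self):
        spec = PhantomSpec(noise_sd=5.0, psf_sigma=0.5, modulation_fraction=0.0,
                           n_frames=10, seed=2)
        seq, _ = make_phantom_sequence(spec)
        for t in range(1, 9):
            seq.frames[t] = 150.0  # fully closed: uniform tissue
        with pytest.warns(RuntimeWarning, match="closure"):
            masks = segment_sequence(seq, SeedPoint(64, 64))
        assert len(masks) == 10

    def test_mask_area_monotone_in_lumen_radius(self):
        areas = []
        for radius in (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0):
            spec = PhantomSpec(ap_semiaxis=radius, tx_semiaxis=radius,
                               modulation_fraction=0.0, noise_sd=8.0, psf_sigma=0.5,
                               n_frames=2, seed=123)
            seq, _ = make_phantom_sequence(spec)
            masks = segment_sequence(seq, SeedPoint(64, 64))
            areas.append(masks[0].area_pixels)
        assert all(a2 > a1 for a1, a2 in zip(areas, areas[1:]))
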