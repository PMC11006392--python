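import numpy as np
import pandas as pd
import pytest

from filocausal.puncta_overlap import (
    PunctaSet,
    align_to_events,
    density_by_length_group,
    detect_puncta,
    link_puncta,
    overlap_puncta,
    smlm_filter,
    smlm_render,
    threshold_mask,
    tip_localized,
)
from filocausal.synthetic_data import (
    ImageSimParams,
    simulate_event_traces,
    simulate_localizations,
    simulate_two_channel_stack,
)

PX = 0.065  # um, study pixel size


def blob_mask(shape, pixels):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return m


def square(r0, c0, side):
    return [(r, c) for r in range(r0, r0 + side) for c in range(c0, c0 + side)]


class TestThresholdMask:
    def test_threshold_above_max_gives_empty_mask(self):
        img = np.arange(16.0).reshape(4, 4)
        assert not threshold_mask(img, 100.0).any()

    def test_hand_built_image_enumeration(self):
        img = np.array([[1, 5, 2], [7, 5, 0], [4, 9, 5]], dtype=float)
        np.testing.assert_array_equal(
            threshold_mask(img, 5.0),
            np.array([[0, 1, 0], [1, 1, 0], [0, 1, 1]], dtype=bool),
        )

    def test_masking_a_mask_is_idempotent(self):
        mask = np.random.default_rng(0).random((8, 8)) > 0.5
        np.testing.assert_array_equal(threshold_mask(mask.astype(float), 0.5), mask)

    def test_auto_uses_otsu_on_bimodal_image(self):
        img = np.concatenate([np.full(50, 1.0), np.full(50, 10.0)]).reshape(10, 10)
        mask = threshold_mask(img, "auto")
        assert mask.sum() == 50


class TestDetectPuncta:
    def test_minimum_area_is_fourteen_pixels_at_study_pixel_size(self):
        assert round(0.06 / PX**2) == 14
        mask14 = blob_mask((30, 30), square(2, 2, 4)[:14])
        mask13 = blob_mask((30, 30), square(2, 2, 4)[:13])
        assert len(detect_puncta(mask14, PX)) == 1
        assert len(detect_puncta(mask13, PX)) == 0

    def test_area_band_keeps_only_mid_sized_components(self):
        mask = np.zeros((80, 80), dtype=bool)
        for r, c in square(2, 2, 4)[:10] + square(20, 20, 5)[:20] + square(40, 40, 18)[:300]:
            mask[r, c] = True
        found = detect_puncta(mask, PX)
        assert len(found) == 1
        assert found.puncta[0].area == pytest.approx(20 * PX**2)

    def test_empty_mask_gives_empty_set(self):
        assert len(detect_puncta(np.zeros((10, 10), dtype=bool), PX)) == 0

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            detect_puncta(np.zeros((5, 5), dtype=bool), 0.0)

    def test_translation_invariance(self):
        base = blob_mask((40, 40), square(5, 5, 5)[:20])
        shifted = np.roll(np.roll(base, 7, axis=0), 3, axis=1)
        a = detect_puncta(base, PX)
        b = detect_puncta(shifted, PX)
        assert len(a) == len(b) == 1
        dr = b.puncta[0].centroid[0] - a.puncta[0].centroid[0]
        dc = b.puncta[0].centroid[1] - a.puncta[0].centroid[1]
        assert dr == pytest.approx(7 * PX) and dc == pytest.approx(3 * PX)

    def test_eight_connectivity_joins_diagonal_pixels(self):
        # (6, 3) touches the block only diagonally, via (5, 2)
        mask = blob_mask((20, 20), square(2, 2, 4)[:13] + [(6, 3)])
        assert len(detect_puncta(mask, PX)) == 1


class TestOverlapPuncta:
    def test_disjoint_masks_give_no_overlap(self):
        a = blob_mask((30, 30), square(2, 2, 5))
        b = blob_mask((30, 30), square(20, 20, 5))
        assert len(overlap_puncta(a, b, PX)) == 0

    def test_identical_blobs_overlap_fully(self):
        a = blob_mask((30, 30), square(5, 5, 5)[:20])
        ov = overlap_puncta(a, a.copy(), PX)
        assert len(ov) == 1
        assert ov.puncta[0].area == pytest.approx(20 * PX**2)
        assert ov.puncta[0].channel == "overlap"

    def test_fourteen_pixel_intersection_retained_thirteen_rejected(self):
        a = blob_mask((30, 30), square(2, 2, 6))
        b14 = blob_mask((30, 30), square(2, 2, 4)[:14])
        b13 = blob_mask((30, 30), square(2, 2, 4)[:13])
        assert len(overlap_puncta(a, b14, PX)) == 1
        assert len(overlap_puncta(a, b13, PX)) == 0

    def test_overlap_mask_is_subset_of_inputs(self):
        rng = np.random.default_rng(0)
        a = rng.random((40, 40)) > 0.4
        b = rng.random((40, 40)) > 0.4
        ov = overlap_puncta(a, b, PX, min_area=0.0, max_area=np.inf)
        for p in ov.puncta:
            for r, c in p.pixels:
                assert a[r, c] and b[r, c]


class TestTipLocalized:
    def _puncta(self, pixels):
        mask = blob_mask((40, 40), pixels)
        return detect_puncta(mask, PX)

    def test_small_punctum_centred_on_tip_retained(self):
        pixels = square(18, 18, 4)[:14]
        puncta = self._puncta(pixels)
        tip = puncta.puncta[0].centroid
        assert len(tip_localized(puncta, tip, circle_diameter=1.0)) == 1

    def test_half_inside_rule_at_the_boundary(self):
        # 14-px punctum: two columns of 7 pixels; tip circle covering one column
        pixels = [(r, 10) for r in range(5, 12)] + [(r, 11) for r in range(5, 12)]
        puncta = self._puncta(pixels)
        radius_px = 0.5 / PX  # ~7.7 px
        # centre the circle on the left column, far enough that only it fits
        tip_in = (8.0 * PX, (11 - radius_px + 0.4) * PX)
        kept = tip_localized(puncta, tip_in, circle_diameter=1.0)
        assert len(kept) == 1
        tip_out = (8.0 * PX, (11 - radius_px - 2.0) * PX)
        assert len(tip_localized(puncta, tip_out, circle_diameter=1.0)) == 0

    def test_distant_punctum_rejected(self):
        puncta = self._puncta(square(30, 30, 4)[:14])
        assert len(tip_localized(puncta, (0.0, 0.0), circle_diameter=1.0)) == 0


def _frame(centroids_um, frame_index):
    """PunctaSet with single-pixel puncta at given um centroids."""
    from filocausal.puncta_overlap import Punctum

    puncta = [
        Punctum(
            label=i,
            pixels=np.array([[int(r / PX), int(c / PX)]]),
            area=PX**2,
            centroid=(r, c),
            channel="overlap",
        )
        for i, (r, c) in enumerate(centroids_um)
    ]
    return PunctaSet(frame_index=frame_index, pixel_size=PX, puncta=puncta)


class TestLinkPuncta:
    def test_slow_punctum_tracked_across_six_frames(self):
        frames = [_frame([(1.0 + 0.5 * f, 1.0)], f) for f in range(6)]
        tracks = link_puncta(frames, max_link=0.65, min_frames=5)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 6

    def test_fast_punctum_breaks_into_short_fragments(self):
        frames = [_frame([(1.0 + 0.7 * f, 1.0)], f) for f in range(6)]
        assert link_puncta(frames, max_link=0.65, min_frames=5) == []

    def test_distant_puncta_never_merge(self):
        frames = [_frame([(1.0, 1.0), (3.0, 1.0)], f) for f in range(6)]
        tracks = link_puncta(frames, max_link=0.65, min_frames=5)
        assert len(tracks) == 2
        starts = sorted(t.start_centroid[0] for t in tracks)
        assert starts == pytest.approx([1.0, 3.0])

    def test_boundary_start_rule(self):
        frames = [_frame([(2.5, 1.0)], f) for f in range(6)]
        boundary = np.array([[0.0, 0.0], [0.0, 5.0]])  # edge along row 0
        assert link_puncta(frames, boundary=boundary, start_boundary_dist=1.0) == []
        near = [_frame([(0.8, 1.0)], f) for f in range(6)]
        assert len(link_puncta(near, boundary=boundary, start_boundary_dist=1.0)) == 1


class TestDensityByLength:
    def test_density_is_count_over_length(self):
        out = density_by_length_group([{"length": 4.0, "count": 2}], [0, 10])
        assert out["median"].iloc[0] == pytest.approx(0.5)

    def test_group_medians_match_enumeration(self):
        filos = [
            {"length": 1.0, "count": 2}, {"length": 2.0, "count": 2},
            {"length": 2.5, "count": 1},
            {"length": 5.0, "count": 1}, {"length": 8.0, "count": 2},
            {"length": 10.0, "count": 1},
        ]
        out = density_by_length_group(filos, [0, 4, 12])
        assert out.loc[0, "median"] == pytest.approx(1.0)   # {2, 1, 0.4} -> 1
        assert out.loc[1, "median"] == pytest.approx(0.2)   # {0.2, 0.25, 0.1} -> 0.2

    def test_zero_length_excluded(self):
        out = density_by_length_group(
            [{"length": 0.0, "count": 3}, {"length": 2.0, "count": 1}], [0, 4]
        )
        assert out["n"].sum() == 1


class TestAlignToEvents:
    def test_constant_position_gives_zero_velocity(self):
        traces = [{"position": np.full(11, 2.0), "overlap": np.zeros(11)}]
        events = [{"event_id": "e", "type": "initiation", "frame": 5}]
        out = align_to_events(traces, events, window=6.0, frame_interval=1.5)
        v = out.velocity[0]
        assert np.allclose(v[np.isfinite(v)], 0.0)

    def test_overlap_step_recovered_with_binomial_ci(self):
        n = 200
        traces, events = simulate_event_traces(n, 0.3, 0.75, 1.0, window=10, seed=5)
        out = align_to_events(traces, events, window=9.0, frame_interval=1.5)
        pooled = out.pooled
        pre = pooled[pooled.rel_time <= -3.0]["prevalence"].mean()
        post = pooled[pooled.rel_time >= 3.0]["prevalence"].mean()
        assert pre == pytest.approx(0.3, abs=1.96 * np.sqrt(0.3 * 0.7 / n) + 0.02)
        assert post == pytest.approx(0.75, abs=1.96 * np.sqrt(0.75 * 0.25 / n) + 0.02)

    def test_event_at_first_frame_pads_pre_side_with_missing(self):
        traces = [{"position": np.arange(8.0), "overlap": np.ones(8)}]
        events = [{"event_id": "e", "type": "initiation", "frame": 0}]
        out = align_to_events(traces, events, window=4.5, frame_interval=1.5)
        w = len(out.rel_time) // 2
        assert np.all(np.isnan(out.overlap[0, :w]))
        assert np.isfinite(out.overlap[0, w + 1 :]).all()

    def test_velocity_burst_appears_at_time_zero(self):
        traces, events = simulate_event_traces(50, 0.2, 0.8, 3.0, window=8, seed=2)
        out = align_to_events(traces, events, window=9.0, frame_interval=1.5)
        pooled = out.pooled
        peak_t = pooled.loc[pooled["velocity"].idxmax(), "rel_time"]
        assert abs(peak_t) <= 1.5  # smoothing can shift the peak one frame


class TestSMLM:
    def test_low_photon_localisation_removed(self):
        table, _ = simulate_localizations(5, scenario="in_bounds", seed=1)
        table.loc[2, "photons"] = 40.0
        kept = smlm_filter(table)
        assert len(kept) == 4

    def test_straddling_fixture_survivors_match_enumeration(self):
        table, labels = simulate_localizations(24, scenario="straddle", seed=3)
        kept = smlm_filter(table)
        assert len(kept) == labels.sum()
        pd.testing.assert_frame_equal(
            kept, table[labels].reset_index(drop=True)
        )

    def test_empty_table_passes_through(self):
        table, _ = simulate_localizations(0)
        assert smlm_filter(table).empty

    def test_filter_is_idempotent(self):
        table, _ = simulate_localizations(24, scenario="straddle", seed=4)
        once = smlm_filter(table)
        pd.testing.assert_frame_equal(smlm_filter(once), once)

    def test_boundary_values_follow_inclusive_and_strict_rules(self):
        row = {"x": 0.0, "y": 0.0, "photons": 50.0, "precision": 50.0,
               "llr": 150.0, "sigma": 150.0}
        table = pd.DataFrame([row])
        assert smlm_filter(table).empty  # llr bound is strict
        row["llr"] = 149.9
        assert len(smlm_filter(pd.DataFrame([row]))) == 1

    def test_single_localisation_renders_to_unit_mass(self):
        locs = pd.DataFrame(
            [{"x": 200.0, "y": 200.0, "photons": 100, "precision": 10.0,
              "llr": 1.0, "sigma": 100.0}]
        )
        img = smlm_render(locs, pixel_size=16.0, shape=(40, 40))
        assert img.sum() == pytest.approx(1.0, abs=1e-6)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert peak == (12, 12)  # floor(200/16)

    def test_two_localisations_160nm_apart_are_ten_pixels_apart(self):
        locs = pd.DataFrame(
            [{"x": 160.0, "y": 320.0, "photons": 100, "precision": 3.0,
              "llr": 1.0, "sigma": 100.0},
             {"x": 320.0, "y": 320.0, "photons": 100, "precision": 3.0,
              "llr": 1.0, "sigma": 100.0}]
        )
        img = smlm_render(locs, pixel_size=16.0, shape=(40, 40))
        row = img[20]
        peaks = np.argsort(row)[-2:]
        assert abs(int(peaks[0]) - int(peaks[1])) == 10

    def test_empty_table_renders_zero_image(self):
        locs = pd.DataFrame(columns=["x", "y", "photons", "precision", "llr", "sigma"])
        assert not smlm_render(locs, shape=(5, 5)).any()


class TestImageRecovery:
    def test_noise_free_stack_counts_match_ground_truth(self):
        p = ImageSimParams(
            n_puncta_a=8, n_puncta_b=6, overlap_fraction=0.5, seed=12,
            amplitude=100.0, radius=0.13,
        )
        stack, truth = simulate_two_channel_stack(p)
        thr = 20.0
        mask_a = threshold_mask(stack[0, 0], thr)
        mask_b = threshold_mask(stack[1, 0], thr)
        n_a = len(detect_puncta(mask_a, p.pixel_size))
        n_b = len(detect_puncta(mask_b, p.pixel_size))
        n_ov = len(overlap_puncta(mask_a, mask_b, p.pixel_size))
        assert n_a == (truth.channel == "A").sum() == 8
        assert n_b == (truth.channel == "B").sum() == 6
        assert n_ov == truth[truth.channel == "A"].shared.sum() == 3
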