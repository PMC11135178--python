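import numpy as np
import pytest
from scipy import ndimage

from ecgpaper import extract, paper_render as pr
from ecgpaper.errors import ParameterError


def flood_fill_labels(mask: np.ndarray) -> np.ndarray:
    """Brute-force 4-connected labelling oracle."""
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                nxt += 1
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ny, nx_ = y + dy, x + dx
                        if (0 <= ny < mask.shape[0]
                                and 0 <= nx_ < mask.shape[1]
                                and mask[ny, nx_] and labels[ny, nx_] == 0):
                            labels[ny, nx_] = nxt
                            stack.append((ny, nx_))
    return labels


class TestRowProfile:
    def test_profile_and_smoothing_lengths(self):
        img = np.random.default_rng(0).uniform(0, 255, (50, 80))
        prof = extract.row_profile(img, 11)
        assert prof.mean_intensity.shape == (50,)
        assert prof.smoothed.shape == (50,)

    def test_moving_average_matches_direct_computation(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (40, 30))
        prof = extract.row_profile(img, 11)
        ibar = img.mean(axis=1)
        padded = np.pad(ibar, 5, mode="edge")
        for x in range(40):
            assert prof.smoothed[x] == pytest.approx(
                padded[x:x + 11].mean())

    def test_even_filter_order_rejected(self):
        with pytest.raises(ParameterError):
            extract.row_profile(np.zeros((10, 10)), 10)


class TestDetectStrips:
    def test_full_page_has_four_row_bands(self, page):
        from ecgpaper.cleanup import remove_grid
        img, _ = page
        cleaned = remove_grid(img, method="classical")
        rois = extract.detect_strips(cleaned)
        assert len(rois) == 4          # 3 layout rows + 1 rhythm strip
        for (a0, a1), (b0, b1) in zip(rois[:-1], rois[1:]):
            assert a1 <= b0            # disjoint, ordered

    def test_single_strip_image(self):
        img = np.full((120, 300), 255.0)
        img[60, :] = 0.0
        rois = extract.detect_strips(img, min_gap_px=20)
        assert len(rois) == 1
        assert rois[0][0] <= 60 < rois[0][1]

    def test_blank_image_rejected(self):
        with pytest.raises(ParameterError):
            extract.detect_strips(np.full((50, 50), 255.0))


class TestBinarize:
    def test_all_white_empty(self):
        assert not extract.binarize(np.full((20, 20), 255.0)).any()

    def test_polyline_recovered_with_bounded_halo(self):
        img = np.full((40, 200), 255.0)
        rows = (20 + 5 * np.sin(np.arange(200) / 15)).astype(int)
        img[rows, np.arange(200)] = 0.0
        mask = extract.binarize(img)
        assert mask[rows, np.arange(200)].all()
        assert mask.sum() <= 2 * 200

    def test_inverted_contrast_flag(self):
        img = np.full((30, 60), 255.0)
        img[15, :] = 0.0
        upright = extract.binarize(img)
        flipped = extract.binarize(255.0 - img, inverted=True)
        np.testing.assert_array_equal(upright, flipped)


class TestAnalyzeComponents:
    def test_labels_match_flood_fill_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mask = rng.random((20, 20)) < 0.35
            ours = extract.analyze_components(mask, min_h=1, min_w=1,
                                              min_area=1, fuse_dist=0)
            oracle = flood_fill_labels(mask)
            assert ours.labels.max() == oracle.max()
            # same partition up to label permutation
            for i in range(1, oracle.max() + 1):
                vals = np.unique(ours.labels[oracle == i])
                assert len(vals) == 1 and vals[0] > 0

    def test_speck_removed_by_area_threshold(self):
        mask = np.zeros((20, 20), bool)
        mask[3, 3] = True
        mask[10:14, 10:14] = True
        cs = extract.analyze_components(mask, min_h=1, min_w=1, min_area=4,
                                        fuse_dist=0)
        assert len(cs.ids) == 1
        assert not cs.mask()[3, 3]

    def test_nearby_fragments_fused_by_hausdorff(self):
        mask = np.zeros((10, 40), bool)
        mask[5, 2:18] = True
        mask[5, 19:36] = True          # 1-px gap
        cs = extract.analyze_components(mask, min_h=1, min_w=1, min_area=2,
                                        fuse_dist=2.0)
        assert len(cs.ids) == 1

    def test_distant_fragments_not_fused(self):
        mask = np.zeros((10, 60), bool)
        mask[5, 0:10] = True
        mask[5, 40:50] = True
        cs = extract.analyze_components(mask, min_h=1, min_w=1, min_area=2,
                                        fuse_dist=5.0)
        assert len(cs.ids) == 2

    def test_empty_mask_allowed(self):
        cs = extract.analyze_components(np.zeros((5, 5), bool))
        assert cs.ids == []


class TestExtractTrace:
    def test_horizontal_line(self):
        mask = np.zeros((60, 100), bool)
        mask[40, :] = True
        trace = extract.extract_trace(mask)
        np.testing.assert_array_equal(trace.y_hat, 40.0)

    def test_blur_context_prefers_continuous_stroke(self):
        """Two candidate strokes in one column: the one continuous with its
        neighbors wins the 1x3-blur argmin."""
        mask = np.zeros((50, 21), bool)
        mask[30, :] = True             # continuous stroke at row 30
        mask[10, 10] = True            # isolated blob at row 10
        trace = extract.extract_trace(mask)
        assert trace.y_hat[10] == 30

    def test_missing_columns_interpolated(self):
        mask = np.zeros((30, 9), bool)
        mask[10, 0:3] = True
        mask[20, 6:9] = True
        trace = extract.extract_trace(mask)
        assert trace.missing[4]
        assert 10 < trace.y_hat[4] < 20

    def test_rendered_sine_recovered_within_one_pixel(self):
        spec = pr.RenderSpec(show_grid=False, show_calibration=False)
        from ecgpaper import ecg_source as es
        fs = 250.0
        t = np.arange(2500) / fs
        sig = 0.6 * np.sin(2 * np.pi * 1.1 * t)
        ecg = es.ECGTimeSeries(np.tile(sig, (12, 1)), fs, es.STANDARD_LEADS)
        img, truth = pr.render_ecg(ecg, spec)
        seg = truth.segments[0]
        gray = img.gray()
        c0, c1 = int(seg.cols.min()), int(seg.cols.max()) + 1
        r0, r1 = int(seg.rows.min()) - 5, int(seg.rows.max()) + 6
        sub = gray[r0:r1, c0:c1]
        trace = extract.extract_trace(sub < 250, intensities=sub)
        assert np.abs(trace.y_hat + r0 - seg.rows).max() <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            extract.extract_trace(np.zeros((10, 10), bool))


class TestGridPeriod:
    @pytest.mark.parametrize("dpi", [200.0, 300.0])
    def test_coarse_pitch_recovered(self, dpi):
        img = pr.render_grid(pr.RenderSpec(dpi=dpi, paper_size=(6, 4)))
        est = extract.estimate_grid_period(img)
        expected = 5 * dpi / 25.4
        assert est == pytest.approx(expected, rel=0.02)

    def test_white_image_rejected(self):
        with pytest.raises(ParameterError):
            extract.estimate_grid_period(np.full((200, 200), 255.0))


class TestPhysicalUnits:
    def test_baseline_maps_to_zero(self):
        mv, _ = extract.to_physical_units(np.full(10, 120.0), 120.0,
                                          coarse_grid_px=39.37)
        np.testing.assert_allclose(mv, 0.0)

    def test_one_coarse_cell_is_half_millivolt(self):
        mv, _ = extract.to_physical_units(np.array([120.0 - 39.37]), 120.0,
                                          coarse_grid_px=39.37)
        assert mv[0] == pytest.approx(0.5)

    def test_linearity_in_pixel_deviation(self):
        y = 120.0 - np.array([1.0, 2.0, 4.0])
        mv, _ = extract.to_physical_units(y, 120.0, coarse_grid_px=40.0)
        np.testing.assert_allclose(mv / mv[0], [1.0, 2.0, 4.0])

    def test_two_route_sampling_frequency_consistency(self):
        """At 200 DPI the grid-derived rate 39.37 px / 0.2 s equals the
        DPI-derived rate 200/1.016 within 0.1%."""
        _, fs_grid = extract.to_physical_units(
            np.zeros(4), 0.0, coarse_grid_px=5 * 200 / 25.4)
        _, fs_dpi = extract.to_physical_units(np.zeros(4), 0.0, dpi=200.0)
        assert fs_grid == pytest.approx(fs_dpi, rel=0.001)
        assert fs_dpi == pytest.approx(200 / 1.016)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ParameterError):
            extract.to_physical_units(np.zeros(4), 0.0)


class TestResampleAlign:
    def test_identical_series_lag_zero(self):
        x = np.sin(np.arange(500) / 10.0)
        est, ref, lag = extract.resample_and_align(x, 250.0, x, 250.0)
        assert lag == 0
        np.testing.assert_allclose(est, ref, atol=1e-9)

    def test_known_delay_recovered(self):
        rng = np.random.default_rng(0)
        base = np.convolve(rng.standard_normal(600), np.ones(5) / 5, "same")
        ref = base[25:525]
        est = base[0:500]
        _, _, lag = extract.resample_and_align(est, 250.0, ref, 250.0)
        assert lag == 25

    def test_sine_amplitude_preserved_through_resampling(self):
        fs_img = 196.85
        t = np.arange(int(2 * fs_img)) / fs_img
        sig = np.sin(2 * np.pi * 10.0 * t)
        est, _, _ = extract.resample_and_align(sig, fs_img,
                                               np.zeros(500), 250.0)
        assert est.max() == pytest.approx(1.0, abs=0.01)

    def test_zero_variance_skips_alignment(self):
        est, ref, lag = extract.resample_and_align(
            np.zeros(100), 250.0, np.ones(100), 250.0)
        assert lag == 0
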