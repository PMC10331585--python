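import numpy as np
import pytest
from scipy import stats

from nmjscreen import nmj_imaging as im
from nmjscreen import synthetic_data as syn
from nmjscreen.nmj_imaging import (
    EmptyImageError,
    NMJImage,
    QuantifyConfig,
    SpotSet,
    axon_area,
    detect_spots,
    extract_cord,
    find_body_region,
    individualize_axons,
    overlap_percent,
    quantify_embryo,
    roi_mean_intensity,
    shrink_mask,
    short_axon_fraction,
)
from nmjscreen.synthetic_data import (
    ImageTruth,
    Spot,
    make_image_truth,
    render_axon_mask,
    simulate_nmj_image,
    spot_mask_from_truth,
)


class TestFindBodyRegion:
    def test_uniform_image_error(self):
        with pytest.raises(EmptyImageError):
            find_body_region(np.full((50, 50), 7.0))

    def test_synthetic_embryo_coverage(self):
        truth = make_image_truth(seed=1)
        img, _ = simulate_nmj_image(truth)
        body = find_body_region(img[1])
        top, thick = truth.body_band
        gt = np.zeros(truth.image_shape, dtype=bool)
        gt[top : top + thick, :] = True
        assert (body & gt).sum() / gt.sum() >= 0.99

    def test_two_blobs_largest_returned(self):
        channel = np.zeros((60, 60))
        channel[5:35, 5:35] = 1000.0  # 30x30
        channel[45:55, 45:55] = 1000.0  # 10x10
        body = find_body_region(channel, threshold_policy=500.0)
        assert body[10, 10] and not body[50, 50]

    def test_holes_filled(self):
        channel = np.zeros((40, 40))
        channel[5:35, 5:35] = 1000.0
        channel[15:20, 15:20] = 0.0
        body = find_body_region(channel, threshold_policy=500.0)
        assert body[17, 17]


class TestShrinkMask:
    def test_margin_zero_identity(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        assert np.array_equal(shrink_mask(mask, 0), mask)

    def test_square_variant_hand_count(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True  # 20x20
        out = shrink_mask(mask, 7, footprint="square")
        assert out.sum() == 6 * 6

    def test_disk_erosion_against_pixel_oracle(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((24, 24), dtype=bool)
        mask[4:20, 6:22] = True
        mask[10:14, 2:6] = True
        margin = 3
        out = shrink_mask(mask, margin)

        dy, dx = np.mgrid[-margin : margin + 1, -margin : margin + 1]
        offsets = [(a, b) for a, b in zip(dy.ravel(), dx.ravel()) if a * a + b * b <= margin * margin]
        oracle = np.zeros_like(mask)
        h, w = mask.shape
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                ok = True
                for a, b in offsets:
                    rr, cc = r + a, c + b
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        ok = False
                        break
                oracle[r, c] = ok
        assert np.array_equal(out, oracle)

    def test_annihilation_warns(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, 4:6] = True
        with pytest.warns(RuntimeWarning):
            out = shrink_mask(mask, 5)
        assert not out.any()

    def test_negative_margin(self):
        with pytest.raises(ValueError):
            shrink_mask(np.ones((5, 5), dtype=bool), -1)


class TestDetectSpots:
    def test_noise_free_exact_count(self, noise_free_truth):
        img, _ = simulate_nmj_image(noise_free_truth)
        body = find_body_region(img[1])
        roi = shrink_mask(body, 7)
        spotset = detect_spots(img[1], roi)
        assert spotset.count == len(noise_free_truth.spots) == 12

    def test_empty_roi_zero_spots(self):
        channel = np.random.default_rng(0).random((30, 30))
        spotset = detect_spots(channel, np.zeros((30, 30), dtype=bool))
        assert spotset.count == 0
        assert not spotset.mask.any()

    def test_area_filter(self, noise_free_truth):
        img, _ = simulate_nmj_image(noise_free_truth)
        roi = shrink_mask(find_body_region(img[1]), 7)
        spotset = detect_spots(img[1], roi, min_area_px=10_000)
        assert spotset.count == 0

    def test_split_touching_matches_local_maxima_oracle(self):
        # two overlapping Gaussians closer than their threshold contours
        channel = np.zeros((60, 60))
        rr, cc = np.mgrid[0:60, 0:60]
        for center in [(30.0, 24.0), (30.0, 36.0)]:
            d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
            channel += 1000.0 * np.exp(-d2 / (2 * 3.0**2))
        roi = np.ones((60, 60), dtype=bool)

        merged = detect_spots(channel, roi, threshold_policy=100.0, split_touching=False)
        assert merged.count == 1  # the documented default merges them

        split = detect_spots(channel, roi, threshold_policy=100.0, split_touching=True)

        fg = channel > 100.0
        n_maxima = 0
        for r in range(60):
            for c in range(60):
                if not fg[r, c]:
                    continue
                window = channel[max(0, r - 5) : r + 6, max(0, c - 5) : c + 6]
                if channel[r, c] >= window.max() and (window == channel[r, c]).sum() == 1:
                    n_maxima += 1
        assert n_maxima == 2
        assert split.count == n_maxima

    def test_spot_properties_reported(self, noise_free_truth):
        img, _ = simulate_nmj_image(noise_free_truth)
        roi = shrink_mask(find_body_region(img[1]), 7)
        spotset = detect_spots(img[1], roi)
        for s in spotset.spots:
            assert s["area_px2"] >= 4
            assert s["mean_intensity"] > 0
        # each designed center has a detected centroid within 2 px
        found = [s["centroid"] for s in spotset.spots]
        for s in noise_free_truth.spots:
            best = min(np.hypot(s.center[0] - r, s.center[1] - c) for r, c in found)
            assert best < 2.0


class TestAxonArea:
    def test_zero_signal_empty(self):
        roi = np.ones((40, 40), dtype=bool)
        mask, area = axon_area(np.zeros((40, 40)), roi)
        assert not mask.any()
        assert area["area_px2"] == 0

    def test_area_close_to_rendered(self):
        truth = make_image_truth(n_spots=0, seed=2, noise_sd=(10.0, 10.0))
        img, _ = simulate_nmj_image(truth)
        body = find_body_region(img[1])
        roi = shrink_mask(body, 7)
        mask, area = axon_area(img[0], roi)
        rendered = render_axon_mask(truth, include_cord=True) & roi
        assert area["area_px2"] == pytest.approx(rendered.sum(), rel=0.10)

    def test_unit_scaling(self):
        roi = np.ones((30, 30), dtype=bool)
        channel = np.zeros((30, 30))
        channel[10:20, 10:20] = 500.0
        _, a1 = axon_area(channel, roi, threshold_policy=250.0, pixel_size_um=1.0)
        _, a2 = axon_area(channel, roi, threshold_policy=250.0, pixel_size_um=2.0)
        assert a2["area_px2"] == a1["area_px2"]
        assert a2["area_um2"] == 4 * a1["area_um2"]


class TestOverlap:
    def test_containment_gives_100(self):
        spot_mask = np.zeros((20, 20), dtype=bool)
        spot_mask[5:8, 5:8] = True
        axon_mask = np.zeros((20, 20), dtype=bool)
        axon_mask[3:10, 3:10] = True
        ss = SpotSet(spots=[{"centroid": (6.0, 6.0), "area_px2": 9, "mean_intensity": 1.0}], mask=spot_mask)
        assert overlap_percent(ss, axon_mask) == 100.0

    def test_disjoint_gives_0(self):
        spot_mask = np.zeros((20, 20), dtype=bool)
        spot_mask[1:3, 1:3] = True
        axon_mask = np.zeros((20, 20), dtype=bool)
        axon_mask[10:, 10:] = True
        ss = SpotSet(spots=[], mask=spot_mask)
        assert overlap_percent(ss, axon_mask) == 0.0

    def test_no_spots_in_window_gives_0(self):
        ss = SpotSet(spots=[], mask=np.zeros((10, 10), dtype=bool))
        assert overlap_percent(ss, np.ones((10, 10), dtype=bool)) == 0.0

    def test_half_on_axon_near_50(self):
        # wide axons so on-axon spots are fully contained in the axon region
        truth = make_image_truth(
            n_spots=16,
            on_axon_fraction=0.5,
            axon_width_px=17,
            spot_radius_px=(3.0, 3.0),
            image_shape=(224, 448),
            noise_sd=(0.0, 0.0),
            seed=11,
        )
        img, _ = simulate_nmj_image(truth)
        roi = shrink_mask(find_body_region(img[1]), 7)
        spotset = detect_spots(img[1], roi)
        axon_mask, _ = axon_area(img[0], roi)
        val = overlap_percent(spotset, axon_mask, None)
        assert val == pytest.approx(50.0, abs=5.0)

    def test_monotone_in_on_axon_fraction(self):
        # rank correlation across designed fractions over seeds
        fracs = [0.0, 0.25, 0.5, 0.75, 1.0]
        values = []
        for i, f in enumerate(fracs):
            truth = make_image_truth(
                n_spots=12,
                on_axon_fraction=f,
                axon_width_px=17,
                spot_radius_px=(3.0, 3.0),
                image_shape=(224, 448),
                seed=100 + i,
            )
            img, _ = simulate_nmj_image(truth)
            roi = shrink_mask(find_body_region(img[1]), 7)
            spotset = detect_spots(img[1], roi)
            axon_mask, _ = axon_area(img[0], roi)
            values.append(overlap_percent(spotset, axon_mask, None))
        rho = stats.spearmanr(fracs, values).statistic
        assert rho > 0.9


class TestExtractCord:
    def test_band_recovery(self):
        truth = make_image_truth(n_spots=0, seed=3)
        img, _ = simulate_nmj_image(truth)
        roi = shrink_mask(find_body_region(img[1]), 7)
        cord, _ = extract_cord(img[0], roi)
        top, thick = truth.cord_band
        band = np.zeros(truth.image_shape, dtype=bool)
        band[top : top + thick, :] = True
        band &= roi
        assert (cord & band).sum() / band.sum() >= 0.9

    def test_cord_only_image_leaves_no_axons(self):
        truth = ImageTruth(axons=[], spots=[], seed=1)
        img, _ = simulate_nmj_image(truth)
        roi = np.zeros(truth.image_shape, dtype=bool)
        top, thick = truth.body_band
        roi[top : top + thick, :] = True
        cord, axon_only = extract_cord(img[0], roi)
        assert axon_only.sum() <= 0.01 * roi.sum()

    def test_median_radius_zero_is_identity_smoothing(self):
        truth = ImageTruth(axons=[], spots=[], noise_sd=(0.0, 0.0), seed=1)
        img, _ = simulate_nmj_image(truth)
        body = np.ones(truth.image_shape, dtype=bool)
        cord, _ = extract_cord(img[0], body, median_radius_px=0, density_quantile=0.95)
        top, thick = truth.cord_band
        band = np.zeros(truth.image_shape, dtype=bool)
        band[top : top + thick, :] = True
        assert np.array_equal(cord, band)

    def test_empty_body_error(self):
        with pytest.raises(EmptyImageError):
            extract_cord(np.zeros((20, 20)), np.zeros((20, 20), dtype=bool))


class TestIndividualizeAxons:
    def test_straight_axon_length_within_5pct(self):
        truth = ImageTruth(axons=[[(60.0, 100.0), (180.0, 100.0)]], spots=[], noise_sd=(0, 0))
        mask = render_axon_mask(truth, include_cord=False)
        meas = individualize_axons(mask)
        assert meas.count == 1
        assert meas.lengths_um[0] == pytest.approx(120.0, rel=0.05)

    def test_diagonal_axon_sqrt2_rule(self):
        r1, c1 = 60.0 + 120 / np.sqrt(2), 100.0 + 120 / np.sqrt(2)
        truth = ImageTruth(axons=[[(60.0, 100.0), (r1, c1)]], spots=[], noise_sd=(0, 0))
        mask = render_axon_mask(truth, include_cord=False)
        meas = individualize_axons(mask)
        assert meas.count == 1
        assert meas.lengths_um[0] == pytest.approx(120.0, rel=0.05)

    def test_two_disjoint_axons(self):
        truth = ImageTruth(
            axons=[[(60.0, 50.0), (180.0, 50.0)], [(60.0, 300.0), (180.0, 300.0)]],
            spots=[],
            noise_sd=(0, 0),
        )
        mask = render_axon_mask(truth, include_cord=False)
        assert individualize_axons(mask).count == 2

    def test_specks_filtered(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[5:8, 5:8] = True
        mask[20:22, 30:32] = True
        meas = individualize_axons(mask, min_length_um=10.0)
        assert meas.count == 0
        assert meas.lengths_um == []

    def test_empty_mask(self):
        meas = individualize_axons(np.zeros((10, 10), dtype=bool))
        assert meas.count == 0

    def test_pixel_size_scales_length(self):
        truth = ImageTruth(axons=[[(60.0, 100.0), (180.0, 100.0)]], spots=[], noise_sd=(0, 0))
        mask = render_axon_mask(truth, include_cord=False)
        a = individualize_axons(mask, pixel_size_um=1.0)
        b = individualize_axons(mask, pixel_size_um=2.0)
        assert b.lengths_um[0] == pytest.approx(2 * a.lengths_um[0])


class TestShortAxonFraction:
    def test_listed_lengths(self):
        assert short_axon_fraction([60, 80, 90, 50]) == 50.0

    def test_all_long(self):
        assert short_axon_fraction([70, 80, 200]) == 0.0

    def test_all_short(self):
        assert short_axon_fraction([1, 5, 69.9]) == 100.0

    def test_empty_absent(self):
        assert short_axon_fraction([]) is None

    def test_cutoff_strict(self):
        assert short_axon_fraction([70.0]) == 0.0


class TestRoiMeanIntensity:
    def test_constant_image_zero(self):
        channel = np.full((20, 20), 42.0)
        roi = np.zeros((20, 20), dtype=bool)
        roi[5:15, 5:15] = True
        assert roi_mean_intensity(channel, roi, background=42.0) == 0.0

    def test_gaussian_spot_closed_form(self):
        # mean over a disk ROI of a rendered Gaussian vs the analytic integral
        h = w = 81
        peak, sigma, radius = 1000.0, 3.0, 15.0
        rr, cc = np.mgrid[0:h, 0:w]
        d2 = (rr - 40.0) ** 2 + (cc - 40.0) ** 2
        channel = peak * np.exp(-d2 / (2 * sigma**2))
        roi = d2 <= radius**2
        measured = roi_mean_intensity(channel, roi, background=0.0)
        analytic = peak * 2 * np.pi * sigma**2 * (1 - np.exp(-(radius**2) / (2 * sigma**2))) / (
            np.pi * radius**2
        )
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_empty_roi_error(self):
        with pytest.raises(EmptyImageError):
            roi_mean_intensity(np.ones((5, 5)), np.zeros((5, 5), dtype=bool))

    def test_background_from_outside_body(self):
        channel = np.full((30, 30), 100.0)
        channel[10:20, 10:20] = 600.0
        body = np.zeros((30, 30), dtype=bool)
        body[10:20, 10:20] = True
        val = roi_mean_intensity(channel, body, body_mask=body)
        assert val == pytest.approx(500.0)


class TestQuantifyEmbryo:
    def test_deterministic(self):
        truth = make_image_truth(seed=6)
        img, _ = simulate_nmj_image(truth)
        image = NMJImage.from_array(img)
        assert quantify_embryo(image) == quantify_embryo(image)

    def test_wt_mo_contrast(self):
        common = dict(
            axon_width_px=15, spot_radius_px=(3.0, 4.0), image_shape=(224, 448)
        )
        wt = make_image_truth(
            n_spots=20, axon_length_um=110, on_axon_fraction=0.9, seed=21, **common
        )
        mo = make_image_truth(
            n_spots=6, axon_length_um=40, on_axon_fraction=0.2, seed=21, **common
        )
        m_wt = quantify_embryo(NMJImage.from_array(simulate_nmj_image(wt)[0]))
        m_mo = quantify_embryo(NMJImage.from_array(simulate_nmj_image(mo)[0]))
        assert m_wt.n_achr_clusters > m_mo.n_achr_clusters
        assert m_wt.overlap_percent > m_mo.overlap_percent
        assert m_wt.mean_axon_length_um > m_mo.mean_axon_length_um
        assert m_wt.short_axon_percent < m_mo.short_axon_percent

    def test_batch_order_stable(self):
        images = []
        for i in range(3):
            truth = make_image_truth(seed=30 + i)
            images.append(NMJImage.from_array(simulate_nmj_image(truth)[0], embryo_id=f"E{i}"))
        rows = [quantify_embryo(img) for img in images]
        assert [r.embryo_id for r in rows] == ["E0", "E1", "E2"]

    def test_stage_named_on_error(self):
        blank = NMJImage(np.zeros((50, 50)), np.zeros((50, 50)))
        with pytest.raises(EmptyImageError, match="find_body_region"):
            quantify_embryo(blank)

    def test_spot_recall_at_default_noise(self):
        hits = total = 0
        for seed in range(3):
            truth = make_image_truth(n_spots=15, seed=50 + seed)
            img, _ = simulate_nmj_image(truth)
            roi = shrink_mask(find_body_region(img[1]), 7)
            spotset = detect_spots(img[1], roi)
            found = [s["centroid"] for s in spotset.spots]
            for s in truth.spots:
                total += 1
                if any(np.hypot(s.center[0] - r, s.center[1] - c) < 5 for r, c in found):
                    hits += 1
        assert hits / total >= 0.9
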