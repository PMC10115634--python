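import numpy as np
import pytest
from scipy import ndimage

from exsrrf.nanometrics import (
    NanometricsConfig,
    _isodata_cut_index,
    expansion_factor,
    extract_roi,
    isodata_threshold,
    local_spacing,
    measure_fp_widths,
    measure_sd_width,
    psf_separation,
    quantify_ridges,
    ridge_density,
    segment_fp,
    segment_ridges,
)
from exsrrf.stacks_io import Image2D
from exsrrf.synthetic import make_interdigitation, make_ridge_lattice


def brute_force_isodata_cut(hist):
    """Exhaustive scan for the smallest intermeans fixed-point cut."""
    n = len(hist)
    idx = np.arange(n, dtype=float)
    for k in range(n - 1):
        lo, hi = hist[: k + 1], hist[k + 1 :]
        if lo.sum() == 0 or hi.sum() == 0:
            continue
        mean_lo = (idx[: k + 1] * lo).sum() / lo.sum()
        mean_hi = (idx[k + 1 :] * hi).sum() / hi.sum()
        if k >= 0.5 * (mean_lo + mean_hi):
            return k
    return None


def brute_force_spacing(free):
    """Exhaustive largest-inscribed-disk local thickness on a small mask."""
    ny, nx = free.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    pts = np.stack([ys.ravel(), xs.ravel()], 1)
    bg = [
        (y, x)
        for y in range(-1, ny + 1)
        for x in range(-1, nx + 1)
        if y < 0 or x < 0 or y >= ny or x >= nx or not free[y, x]
    ]
    bg = np.asarray(bg, dtype=float)
    centres = pts[free.ravel()].astype(float)
    d2 = np.round(((centres[:, None, :] - bg[None, :, :]) ** 2).sum(-1).min(1)).astype(np.int64)
    pd2 = ((pts[free.ravel()][:, None, :] - pts[free.ravel()][None, :, :]) ** 2).sum(-1)
    best = np.where(pd2 <= (d2[None, :] - 1), d2[None, :], 0).max(1)
    out = np.zeros(free.shape)
    out[free] = 2.0 * np.sqrt(best)
    return out


def random_ridge_scene(seed, shape=(48, 48)):
    rng = np.random.default_rng(seed)
    smooth = ndimage.gaussian_filter(rng.random(shape), 6)
    roi = smooth > np.percentile(smooth, 30)
    ridges = ndimage.gaussian_filter(rng.random(shape), 1.5) > 0.55
    return roi, ridges


class TestIsodataThreshold:
    def test_matches_brute_force_fixed_point(self, rng):
        for _ in range(20):
            vals = np.concatenate(
                [
                    rng.normal(rng.uniform(20, 100), rng.uniform(5, 30), rng.integers(50, 1000)),
                    rng.normal(rng.uniform(120, 240), rng.uniform(5, 40), rng.integers(50, 1000)),
                ]
            )
            vals = np.clip(np.round(vals), 0, 255).astype(np.uint8)
            hist = np.bincount(vals.ravel(), minlength=256).astype(float)
            assert _isodata_cut_index(hist) == brute_force_isodata_cut(hist)

    def test_constant_input(self):
        assert isodata_threshold(np.full((8, 8), 42.0)) == 42.0

    def test_bimodal_image_splits_the_modes(self, rng):
        img = np.full((32, 32), 30, dtype=np.uint8)
        img[8:24, 8:24] = 200
        t = isodata_threshold(img)
        assert 30 < t < 200


class TestExtractRoi:
    def test_all_zero_image_gives_empty_roi(self):
        cfg = NanometricsConfig.sd(min_component_px=10)
        assert not extract_roi(Image2D(np.zeros((64, 64))), cfg).any()

    def test_full_intensity_image_covers_frame(self):
        cfg = NanometricsConfig.sd(min_component_px=10)
        roi = extract_roi(Image2D(np.full((64, 64), 200.0)), cfg)
        assert roi.all()

    def test_large_component_kept_small_dropped(self):
        img = np.zeros((256, 256))
        yy, xx = np.mgrid[0:256, 0:256]
        img[(yy - 80) ** 2 + (xx - 80) ** 2 < 60**2] = 100.0  # large disk
        img[(yy - 210) ** 2 + (xx - 210) ** 2 < 10**2] = 100.0  # small blob
        cfg = NanometricsConfig.sd(min_component_px=300)  # in 64x64 downsampled px
        roi = extract_roi(Image2D(img), cfg)
        assert roi[80, 80]
        assert not roi[210, 210]

    def test_er_preset_two_gaussians_fill_only(self):
        img = np.zeros((256, 256))
        img[40:200, 40:200] = 150.0
        cfg = NanometricsConfig.er(min_component_px=300)
        roi = extract_roi(Image2D(img), cfg)
        assert roi[120, 120]


class TestSegmentRidges:
    def test_blank_image_has_no_ridges(self):
        cfg = NanometricsConfig.sd()
        roi = np.ones((64, 64), dtype=bool)
        assert not segment_ridges(Image2D(np.zeros((64, 64))), roi, cfg).any()

    def test_single_line_midline_recovered(self):
        # one bright 3 px line through the frame interior
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        p0, p1 = np.array([14.0, 6.0]), np.array([50.0, 58.0])
        v = p1 - p0
        t = np.clip(((yy - p0[0]) * v[0] + (xx - p0[1]) * v[1]) / (v @ v), 0, 1)
        dist = np.hypot(yy - (p0[0] + t * v[0]), xx - (p0[1] + t * v[1]))
        img = Image2D(np.clip(1.5 + 0.5 - dist, 0, 1) * 100)
        roi = np.ones((64, 64), dtype=bool)
        mask = segment_ridges(img, roi, NanometricsConfig.sd())
        assert mask.sum() > 50
        # the detected ridge hugs the midline and is one connected curve
        assert dist[mask].max() <= 2.0
        assert ndimage.label(mask)[1] == 1

    def test_lattice_component_count_matches_line_count(self):
        img, _ = make_ridge_lattice(20.0, 3.0, 0.0, (100, 100), phase_px=10.0)
        roi = np.ones((100, 100), dtype=bool)
        mask = segment_ridges(img, roi, NanometricsConfig.sd())
        n_components = ndimage.label(mask)[1]
        # midlines at s = 10, 30, 50, 70, 90
        assert n_components == 5


class TestRidgeDensity:
    def test_empty_ridges_give_zero(self):
        roi = np.ones((16, 16), dtype=bool)
        assert ridge_density(np.zeros((16, 16), bool), roi) == 0.0

    def test_half_coverage(self):
        roi = np.ones((16, 16), dtype=bool)
        ridges = np.zeros((16, 16), bool)
        ridges[:8] = True
        assert ridge_density(ridges, roi) == 0.5

    def test_empty_roi_is_undefined(self):
        assert np.isnan(ridge_density(np.zeros((8, 8), bool), np.zeros((8, 8), bool)))

    def test_invariant_to_content_outside_roi(self):
        roi = np.zeros((16, 16), dtype=bool)
        roi[:8] = True
        ridges = np.zeros((16, 16), bool)
        ridges[6:12] = True  # partly outside the ROI
        d = ridge_density(ridges, roi)
        ridges2 = ridges.copy()
        ridges2[12:] = True  # extra ridges fully outside
        assert ridge_density(ridges2, roi) == d


class TestLocalSpacing:
    def test_matches_brute_force_oracle(self):
        for seed in range(3):
            roi, ridges = random_ridge_scene(seed)
            spacing, _, _ = local_spacing(ridges, roi)
            expected = brute_force_spacing(roi & ~ridges)
            np.testing.assert_array_equal(spacing, expected)

    def test_parallel_ridges_median_equals_gap(self):
        roi = np.ones((64, 64), dtype=bool)
        ridges = np.zeros((64, 64), bool)
        ridges[20, :] = True
        ridges[37, :] = True  # 16 free rows between
        # restrict the ROI to the inter-ridge band so the inscribed disk is
        # bounded by the two ridges, not the frame border
        band = np.zeros((64, 64), bool)
        band[20:38] = True
        spacing, stats, _ = local_spacing(ridges, band)
        assert abs(stats["median"] - 16.0) <= 1.0

    def test_disk_roi_spacing_at_centre_is_diameter(self):
        yy, xx = np.mgrid[0:65, 0:65]
        roi = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        spacing, _, _ = local_spacing(np.zeros_like(roi), roi)
        assert spacing[32, 32] == pytest.approx(2 * 20.0, abs=1.5)

    def test_adding_ridges_never_increases_median(self):
        roi, ridges = random_ridge_scene(11)
        _, stats_sparse, _ = local_spacing(ridges, roi)
        more = ridges | (ndimage.gaussian_filter(np.random.default_rng(5).random(roi.shape), 2) > 0.6)
        _, stats_dense, _ = local_spacing(more, roi)
        if np.isfinite(stats_dense["median"]):
            assert stats_dense["median"] <= stats_sparse["median"]

    def test_full_ridge_coverage_is_undefined(self):
        roi = np.ones((8, 8), dtype=bool)
        _, stats, _ = local_spacing(np.ones((8, 8), bool), roi)
        assert np.isnan(stats["median"])

    def test_8bit_map_spans_full_range(self):
        roi, ridges = random_ridge_scene(2)
        _, _, map8 = local_spacing(ridges, roi)
        free = roi & ~ridges
        assert map8[free].min() == 0
        assert map8[free].max() == 255


class TestMeasureWidth:
    def test_perpendicular_band_width(self):
        img = np.zeros((32, 32))
        img[:, 10:15] = 200.0
        m = measure_sd_width(Image2D(img), ((16.0, 2.0), (16.0, 29.0)))
        assert m.width_px == pytest.approx(5.0, abs=1.0)

    def test_diagonal_crossing_foreshortens(self):
        img = np.zeros((64, 64))
        img[:, 30:35] = 200.0
        m = measure_sd_width(Image2D(img), ((10.0, 10.0), (54.0, 54.0)))
        assert m.width_px == pytest.approx(5.0 * np.sqrt(2), abs=1.5)

    def test_no_signal_gives_zero_width(self):
        img = np.zeros((16, 16))
        img[0, 0] = 1.0  # threshold anchors below the empty profile line
        m = measure_sd_width(Image2D(img), ((8.0, 1.0), (8.0, 14.0)))
        assert m.width_px == 0.0

    def test_nm_conversion_divides_by_expansion(self):
        img = np.zeros((32, 32))
        img[:, 10:15] = 200.0
        image = Image2D(img, pixel_size_nm=65.0)
        m = measure_sd_width(image, ((16.0, 2.0), (16.0, 29.0)), expansion_factor=3.8)
        assert m.width_nm == pytest.approx(m.width_px * 65.0 / 3.8)


class TestSegmentFp:
    def test_two_regions_split_by_bright_line(self):
        img = np.zeros((40, 40))
        img[:, 19:21] = 200.0  # bright separator spanning the frame
        labels = segment_fp(Image2D(img))
        left = np.unique(labels[:, :19])
        right = np.unique(labels[:, 21:])
        assert set(left) != {0} and set(right) != {0}
        assert len(np.setdiff1d(np.unique(labels), [0])) == 2

    def test_blank_image_has_no_labels(self):
        assert segment_fp(Image2D(np.zeros((16, 16)))).max() == 0

    def test_interdigitation_widths_and_counts_recovered(self):
        widths = []
        for seed in range(4):
            _, sd, truth = make_interdigitation(
                fp_width_px=14.0, sd_gap_px=4.0, waviness=1.0, shape=(192, 192),
                margin_px=24, seed=seed,
            )
            labels = segment_fp(sd)
            widths.extend(measure_fp_widths(labels))
            # interior labels = comb teeth; the two edge teeth touch the frame
            border = np.zeros(labels.shape, bool)
            border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
            inner = [
                lab
                for lab in range(1, labels.max() + 1)
                if not (labels == lab)[border].any()
            ]
            assert len(inner) == truth["n_fingers"] - 2
        med = np.median(widths)
        assert abs(med - 14.0) / 14.0 <= 0.15


class TestPsfSeparation:
    def test_far_apart_gaussians_separated(self):
        x = np.arange(200, dtype=float)
        prof = np.exp(-((x - 60) ** 2) / 8) + np.exp(-((x - 140) ** 2) / 8)
        separated, maxima = psf_separation(prof)
        assert separated
        assert sorted(maxima.tolist()) == [60.0, 140.0]

    def test_single_gaussian_not_separated(self):
        x = np.arange(100, dtype=float)
        separated, maxima = psf_separation(np.exp(-((x - 50) ** 2) / 30))
        assert not separated
        assert maxima.tolist() == [50.0]

    def test_noise_bump_is_not_a_second_maximum(self):
        x = np.arange(100, dtype=float)
        prof = np.exp(-((x - 30) ** 2) / 20)
        prof[80] = 0.2  # above the signal-free cut but far below dominance
        separated, _ = psf_separation(prof)
        assert not separated

    def test_separability_monotone_in_distance(self):
        sigma = 4.0
        outcomes = []
        for mult in range(1, 11):
            d = mult * sigma / 2
            x = np.arange(300, dtype=float)
            prof = np.exp(-((x - 150 + d / 2) ** 2) / (2 * sigma**2)) + np.exp(
                -((x - 150 - d / 2) ** 2) / (2 * sigma**2)
            )
            outcomes.append(psf_separation(prof)[0])
        assert outcomes == sorted(outcomes)  # False ... False True ... True

    def test_two_dimensional_crop(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        img = np.exp(-((yy - 32) ** 2 + (xx - 16) ** 2) / 8) + np.exp(
            -((yy - 32) ** 2 + (xx - 48) ** 2) / 8
        )
        separated, maxima = psf_separation(img)
        assert separated
        assert {tuple(m) for m in maxima.astype(int)} == {(32, 16), (32, 48)}


class TestExpansionFactor:
    def _measurement(self, distance_nm):
        from exsrrf.nanometrics import ProfileMeasurement

        return ProfileMeasurement(
            line=((0.0, 0.0), (0.0, 1.0)),
            profile=np.zeros(2),
            sample_spacing_px=1.0,
            width_px=0.0,
            peak_distance_px=distance_nm / 65.0,
            peak_distance_nm=distance_nm,
        )

    def test_definitional_ratio(self):
        assert expansion_factor(self._measurement(100.0), self._measurement(380.0)) == pytest.approx(3.8)

    def test_identical_measurements_give_unity(self):
        m = self._measurement(120.0)
        assert expansion_factor(m, m) == 1.0

    def test_zero_pre_distance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            expansion_factor(self._measurement(0.0), self._measurement(100.0))


class TestPipeline:
    def test_quantify_ridges_on_phantom(self):
        _, sd, _ = make_interdigitation(
            fp_width_px=12.0, sd_gap_px=4.0, shape=(384, 384), margin_px=36, seed=0
        )
        result = quantify_ridges(sd, NanometricsConfig.sd())
        assert result.roi_mask.any()
        assert 0.0 < result.density < 1.0
        assert np.isfinite(result.spacing_stats["median"])
        assert result.spacing_map_8bit.dtype == np.uint8
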