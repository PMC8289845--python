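"""Image preprocessing, compartment counting and colocalization metrics."""

import numpy as np
import pandas as pd
import pytest

from evquant import coloc
from evquant.simulate import ImageSimConfig, gen_coloc_stack


class TestPreprocess:
    def test_constant_image_becomes_zero(self):
        out = coloc.preprocess(np.full((40, 40), 7.0), 1, 10)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_single_hot_pixel_removed_by_median(self):
        img = np.zeros((40, 40))
        img[20, 20] = 100.0
        assert coloc.preprocess(img, 1, 10).max() == 0.0

    def test_blob_peak_survives_background_subtraction(self):
        # small bright blob on a sloped background: the rolling ball removes
        # the slowly varying ramp, preserving the blob amplitude within 10%
        yy, xx = np.mgrid[0:80, 0:80]
        ramp = 0.2 * xx
        img = ramp.astype(float)
        img[38:43, 38:43] += 100.0
        out = coloc.preprocess(img, 1, 20)
        assert out.max() == pytest.approx(100.0, rel=0.10)
        # background-only region flattened
        assert out[:20, :20].max() < 10.0

    def test_leading_axes_preserved(self):
        stack = np.zeros((2, 3, 32, 32))
        assert coloc.preprocess(stack, 1, 10).shape == stack.shape

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            coloc.preprocess(np.zeros((20, 20)), 0, 10)
        with pytest.raises(ValueError):
            coloc.preprocess(np.zeros((20, 20)), 1, 30)


class TestCountSmallCompartments:
    def test_blank_image_counts_zero(self):
        assert coloc.count_small_compartments(np.zeros((32, 32)), prominence=5)[0] == 0

    def test_twelve_disjoint_squares(self):
        img = np.zeros((64, 64))
        for i in range(3):
            for j in range(4):
                img[5 + i * 15 : 8 + i * 15, 5 + j * 15 : 8 + j * 15] = 50.0
        assert coloc.count_small_compartments(img, prominence=10, max_size=15)[0] == 12

    def test_large_component_excluded(self):
        img = np.zeros((64, 64))
        img[10:20, 10:20] = 50.0  # area 100 >= 15
        assert coloc.count_small_compartments(img, prominence=10, max_size=15)[0] == 0

    def test_per_timepoint_counts(self):
        frames = np.zeros((2, 32, 32))
        frames[1, 5:8, 5:8] = 40.0
        counts = coloc.count_small_compartments(frames, prominence=10)
        assert list(counts) == [0, 1]


class TestRegionIntensityKinetics:
    def test_single_qualifying_component(self):
        img = np.zeros((32, 32))
        img[5:10, 5:10] = 100.0  # 25 px >= 20
        out = coloc.region_intensity_kinetics(img, intensity_threshold=10.0)
        assert out["golgi_mean"].iloc[0] == pytest.approx(100.0)

    def test_empty_frame_gives_absent_not_zero(self):
        out = coloc.region_intensity_kinetics(np.zeros((32, 32)), 10.0)
        assert np.isnan(out["golgi_mean"].iloc[0])
        assert np.isnan(out["large_mean"].iloc[0])

    def test_size_threshold_selects_components(self):
        img = np.zeros((40, 40))
        img[2:8, 2:7] = 100.0  # 30 px: Golgi-sized
        img[20:25, 20:22] = 40.0  # 10 px: below both cutoffs
        out = coloc.region_intensity_kinetics(img, intensity_threshold=10.0)
        assert out["golgi_mean"].iloc[0] == pytest.approx(100.0)

    def test_large_series_starts_at_configured_timepoint(self):
        frames = np.zeros((3, 32, 32))
        frames[:, 5:9, 5:9] = 60.0  # 16 px: large but not Golgi-sized
        out = coloc.region_intensity_kinetics(frames, 10.0, large_start=2)
        assert np.isnan(out["large_mean"].iloc[0])
        assert out["large_mean"].iloc[2] == pytest.approx(60.0)


class TestPearson:
    def test_identical_channels_fully_colocalized(self):
        rng = np.random.default_rng(0)
        ch = rng.uniform(0, 100, (16, 16))
        assert coloc.pearson_in_mask(ch, ch) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(1)
        ch = rng.uniform(0, 100, (16, 16))
        assert coloc.pearson_in_mask(ch, -2.0 * ch + 300.0) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.normal(50, 10, 100_000)
        b = rng.normal(50, 10, 100_000)
        assert abs(coloc.pearson_in_mask(a, b)) < 0.02

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 100, 5000)
        b = rng.uniform(0, 100, 5000)
        r1 = coloc.pearson_in_mask(a, b)
        r2 = coloc.pearson_in_mask(3.7 * a + 11.0, b)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_mask_restricts_support(self):
        a = np.array([[1.0, 2.0], [3.0, 100.0]])
        b = np.array([[1.0, 2.0], [3.0, -50.0]])
        mask = np.array([[True, True], [True, False]])
        assert coloc.pearson_in_mask(a, b, mask) == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(coloc.pearson_in_mask(np.ones(10), np.arange(10.0)))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            coloc.pearson_in_mask(np.ones(4), np.ones(4), np.zeros(4, bool))


class TestManders:
    def test_identical_channels_unity(self):
        rng = np.random.default_rng(0)
        ch = rng.uniform(0, 100, (20, 20))
        m1, m2 = coloc.manders(ch, ch, 30.0, 30.0)
        assert m1 == pytest.approx(1.0) and m2 == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[:5] = 100.0
        b[5:] = 100.0
        assert coloc.manders(a, b, 10.0, 10.0) == (0.0, 0.0)

    def test_coefficients_bounded(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 100, (30, 30))
        b = rng.uniform(0, 100, (30, 30))
        m1, m2 = coloc.manders(a, b, 20.0, 70.0)
        assert 0.0 <= m1 <= 1.0 and 0.0 <= m2 <= 1.0

    def test_raising_other_threshold_never_increases_m1(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 100, (30, 30))
        b = rng.uniform(0, 100, (30, 30))
        m_prev = 1.0
        for t2 in (10.0, 40.0, 70.0, 95.0):
            m1, _ = coloc.manders(a, b, 20.0, t2)
            assert m1 <= m_prev + 1e-12
            m_prev = m1

    def test_no_signal_above_threshold_flagged(self):
        m1, m2 = coloc.manders(np.zeros((5, 5)), np.ones((5, 5)) * 50, 10.0, 10.0)
        assert np.isnan(m1) and m2 == 0.0


class TestGeneratedStacks:
    @pytest.mark.parametrize("overlap", [0.0, 0.5, 1.0])
    def test_manders_recovers_planted_overlap(self, overlap):
        cfg = ImageSimConfig(overlap_fraction=overlap, n_compartments=40, seed=3)
        stack, masks, truth = gen_coloc_stack(cfg)
        m1, m2 = coloc.manders(stack[0, 0], stack[0, 1], 30.0, 30.0)
        target = truth["overlap_fraction"].iloc[0]
        tol = 1e-9 if overlap in (0.0, 1.0) else 0.1
        assert m1 == pytest.approx(target, abs=max(tol, 1e-9))

    def test_identical_channels_at_full_overlap_no_noise(self):
        cfg = ImageSimConfig(overlap_fraction=1.0, noise_sd=0.0, seed=3)
        stack, _, _ = gen_coloc_stack(cfg)
        np.testing.assert_array_equal(stack[0, 0], stack[0, 1])
        assert coloc.pearson_in_mask(stack[0, 0], stack[0, 1]) == pytest.approx(1.0)

    def test_mask_counts_match_truth_bookkeeping(self):
        cfg = ImageSimConfig(seed=7)
        _, masks, truth = gen_coloc_stack(cfg)
        rec = truth[(truth.channel_i == 0) & (truth.channel_j == 1)].iloc[0]
        assert rec["voxels_i"] == int(masks[0, 0].sum())

    def test_determinism(self):
        cfg = ImageSimConfig(seed=11)
        s1, m1, t1 = gen_coloc_stack(cfg)
        s2, m2, t2 = gen_coloc_stack(cfg)
        np.testing.assert_array_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            ImageSimConfig(shape=(4, 16, 16), radius_range=(9.0, 10.0))


class TestTripleOverlap:
    def test_identical_masks_all_one(self):
        m = np.zeros((4, 8, 8), bool)
        m[1:3, 2:6, 2:6] = True
        res = coloc.triple_overlap([m, m, m])
        np.testing.assert_allclose(res["overlap_fraction"], 1.0)

    def test_nested_masks(self):
        big = np.zeros((20, 20), bool)
        big[:10] = True
        small = np.zeros((20, 20), bool)
        small[:5] = True
        res = coloc.triple_overlap([small, big, big]).set_index(["reference", "other"])
        assert res.loc[(0, 1), "overlap_fraction"] == pytest.approx(1.0)
        assert res.loc[(1, 0), "overlap_fraction"] == pytest.approx(0.5)

    def test_independent_masks_follow_product_law(self):
        rng = np.random.default_rng(8)
        n = 200_000
        p, q = 0.3, 0.2
        m1 = rng.uniform(size=n) < p
        m2 = rng.uniform(size=n) < q
        m3 = rng.uniform(size=n) < 0.5
        res = coloc.triple_overlap([m1, m2, m3]).set_index(["reference", "other"])
        se = np.sqrt(q * (1 - q) / (n * p))
        assert res.loc[(0, 1), "overlap_fraction"] == pytest.approx(q, abs=3 * se)

    def test_empty_mask_flagged(self):
        m = np.ones((5, 5), bool)
        res = coloc.triple_overlap([np.zeros((5, 5), bool), m, m])
        ref0 = res[res.reference == 0]
        assert ref0["overlap_fraction"].isna().all()


class TestEVDiameter:
    def test_square_and_rectangle_means(self):
        d, _ = coloc.ev_diameter([(50.0, 50.0), (40.0, 60.0)])
        np.testing.assert_allclose(d, [50.0, 50.0])

    def test_histogram_frequencies_normalized(self):
        rng = np.random.default_rng(9)
        rects = list(zip(rng.uniform(30, 200, 593), rng.uniform(30, 200, 593)))
        d, hist = coloc.ev_diameter(rects, bin_width=10.0)
        assert len(d) == 593
        assert hist["frequency"].sum() == pytest.approx(1.0)
        assert hist["count"].sum() == 593

    def test_nonpositive_rectangle_rejected_with_warning(self):
        d, _ = coloc.ev_diameter([(50.0, 50.0), (0.0, 40.0), (-3.0, 10.0)])
        assert len(d) == 1
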