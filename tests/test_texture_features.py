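import numpy as np
import pandas as pd
import pytest

from flairseg.superpixel import segment_volume
from flairseg.texture_features import (
    FEATURE_COLUMNS,
    STAT_COLUMNS,
    TEXTON_COLUMNS,
    GaborBank,
    assemble_and_scale,
    assign_textons,
    box_count_dimension,
    curvature_features,
    curvature_map,
    extract_case_features,
    filter_responses,
    gabor_kernel,
    intensity_stats,
    multi_otsu,
    sfta_features,
    texton_fit,
    texton_histogram,
    texton_map,
)


class TestIntensityStats:
    def test_constant_region(self):
        s = dict(zip(STAT_COLUMNS, intensity_stats(np.full(10, 7.0))))
        for key in ("int_mean", "int_median", "int_mode", "int_min", "int_max"):
            assert s[key] == 7.0
        for key in ("int_std", "int_var", "int_mad", "int_medad", "int_range",
                    "int_iqr", "int_entropy", "int_skew", "int_kurt"):
            assert s[key] == 0.0

    def test_hand_computed_values(self):
        s = dict(zip(STAT_COLUMNS, intensity_stats(np.array([1.0, 2.0, 3.0, 4.0]))))
        assert s["int_mean"] == pytest.approx(2.5)
        assert s["int_range"] == pytest.approx(3.0)
        assert s["int_median"] == pytest.approx(2.5)
        assert s["int_var"] == pytest.approx(np.var([1, 2, 3, 4], ddof=1))

    def test_symmetric_set_zero_skew(self):
        s = dict(zip(STAT_COLUMNS, intensity_stats(np.array([-3.0, 0.0, 3.0]))))
        assert s["int_skew"] == pytest.approx(0.0, abs=1e-12)
        assert s["int_cm3"] == pytest.approx(0.0, abs=1e-12)

    def test_length_and_empty_error(self):
        assert intensity_stats(np.array([5.0])).shape == (16,)
        with pytest.raises(ValueError):
            intensity_stats(np.array([]))


class TestGaborKernel:
    def test_centre_value_one_at_zero_phase(self):
        for theta in (0, 30, 45, 90):
            k = gabor_kernel(theta, 1.0, 1.2)
            c = k.shape[0] // 2
            assert k[c, c] == pytest.approx(1.0 + 0.0j)

    def test_rotation_transpose_symmetry(self):
        k0 = gabor_kernel(0.0, 1.0, 1.2, gamma=1.0)
        k90 = gabor_kernel(90.0, 1.0, 1.2, gamma=1.0)
        assert np.allclose(k0, k90.T, atol=1e-12)

    def test_default_bank_has_120_filters(self):
        assert GaborBank().n_filters == 6 * 5 * 4

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            gabor_kernel(0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            gabor_kernel(0.0, 1.0, 0.0)


@pytest.fixture(scope="module")
def small_bank():
    return GaborBank(sigmas=(0.6, 1.2), lambdas=(1.0,))


@pytest.fixture(scope="module")
def two_region_setup(small_bank):
    gen = np.random.default_rng(5)
    img = np.zeros((40, 40))
    img[:, 20:] = 1.0
    img += gen.normal(0, 0.01, img.shape)
    resp = filter_responses(img, small_bank)
    model = texton_fit([resp], [np.ones((40, 40), bool)], k=2, seed=0)
    return img, resp, model


class TestTextons:
    def test_two_flat_regions_get_distinct_textons(self, two_region_setup):
        _, resp, model = two_region_setup
        tmap = assign_textons(resp, model)
        left, right = tmap[:, :15], tmap[:, 25:]
        assert max(np.mean(left == 1), np.mean(left == 2)) >= 0.99
        assert max(np.mean(right == 1), np.mean(right == 2)) >= 0.99
        assert np.median(left) != np.median(right)

    def test_fit_deterministic(self, two_region_setup, small_bank):
        _, resp, model = two_region_setup
        again = texton_fit([resp], [np.ones((40, 40), bool)], k=2, seed=0)
        assert np.array_equal(model.centers, again.centers)

    def test_map_matches_brute_force_nearest_centroid(self, two_region_setup, rng):
        _, resp, model = two_region_setup
        tmap = assign_textons(resp, model)
        ys = rng.integers(0, 40, 100)
        xs = rng.integers(0, 40, 100)
        for y, x in zip(ys, xs):
            d = np.linalg.norm(model.centers - resp[y, x], axis=1)
            assert tmap[y, x] == np.argmin(d) + 1

    def test_map_range_and_dimension_check(self, two_region_setup, small_bank):
        img, _, model = two_region_setup
        tmap = texton_map(img, small_bank, model)
        assert tmap.min() >= 1 and tmap.max() <= model.k
        bad_bank = GaborBank(sigmas=(0.6,), lambdas=(1.0,))
        with pytest.raises(ValueError):
            texton_map(img, bad_bank, model)

    def test_flat_image_single_texton(self, two_region_setup, small_bank):
        _, _, model = two_region_setup
        tmap = texton_map(np.full((20, 20), 0.5), small_bank, model)
        assert np.unique(tmap).size == 1

    def test_too_few_distinct_vectors(self, small_bank):
        resp = np.zeros((5, 5, small_bank.n_filters))
        with pytest.raises(ValueError):
            texton_fit([resp], [np.ones((5, 5), bool)], k=2, seed=0)

    def test_histogram_counts(self):
        tmap = np.full((6, 6), 3)
        idx = np.nonzero(np.ones((6, 6), bool))
        assert texton_histogram(idx, tmap, k=5).tolist() == [0, 0, 36, 0, 0]
        tmap2 = np.ones((6, 6), dtype=int)
        tmap2[3:] = 2
        h = texton_histogram(idx, tmap2, k=5)
        assert h.tolist() == [18, 18, 0, 0, 0]
        assert h.sum() == 36  # partition of the superpixel


class TestMultiOtsu:
    def test_two_delta_histogram(self, rng):
        img = np.concatenate([rng.normal(0.2, 0.005, 400), rng.normal(0.8, 0.005, 400)])
        (t,) = multi_otsu(img, n_t=1)
        assert 0.2 < t < 0.8  # splits the two spikes

    def test_thresholds_strictly_increasing(self, rng):
        img = rng.random(3000)
        thr = multi_otsu(img, n_t=3)
        assert thr.shape == (3,)
        assert np.all(np.diff(thr) > 0)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            multi_otsu(np.array([1.0, 1.0, 2.0, 2.0]), n_t=3)


class TestSftaAndBoxCounting:
    def test_line_dimension_near_one(self):
        img = np.zeros((256, 256), bool)
        img[100, :] = True
        assert 0.9 <= box_count_dimension(img).dimension <= 1.1

    def test_filled_block_dimension_near_two(self):
        assert 1.85 <= box_count_dimension(np.ones((256, 256), bool)).dimension <= 2.0

    def test_empty_input_dimension_zero(self):
        res = box_count_dimension(np.zeros((64, 64), bool))
        assert res.dimension == 0.0

    def test_counts_nonincreasing_and_monotone_inclusion(self):
        line = np.zeros((128, 128), bool)
        line[64, :] = True
        res = box_count_dimension(line)
        assert np.all(np.diff(res.counts) <= 0)
        # nested sets: line within filled block has lower dimension
        assert box_count_dimension(line).dimension <= box_count_dimension(
            np.ones((128, 128), bool)).dimension

    def test_step_edge_band_border_count(self):
        img = np.full((12, 12), 0.1)
        img[:, 6:] = 0.9
        thr = np.array([0.05, 0.5, 0.95])
        rows, cols = np.mgrid[3:9, 3:9]
        feats = sfta_features(img, (rows.ravel(), cols.ravel()), thr)
        # band 1 = [0.05, 0.5): its border inside the 6x6 superpixel is the
        # column of 6 pixels adjacent to the step
        assert feats[0] == 6.0
        assert feats[1] == pytest.approx(0.1)
        # band 2 = [0.5, 0.95): 6 border pixels on the bright side
        assert feats[3] == 6.0
        assert feats[4] == pytest.approx(0.9)

    def test_flat_region_all_zero(self):
        rows, cols = np.mgrid[3:9, 3:9]
        thr = np.array([0.2, 0.5, 0.8])
        feats = sfta_features(np.full((12, 12), 0.5), (rows.ravel(), cols.ravel()), thr)
        assert np.all(feats[:3] == 0.0) or feats[0] == 0.0  # band without borders -> zeros
        assert feats[2] == 0.0 and feats[5] == 0.0


class TestCurvature:
    def test_linear_ramp_zero_interior(self):
        yy, xx = np.mgrid[0:50, 0:50].astype(float)
        cm = curvature_map(0.3 * yy + 0.1 * xx, smooth_sigma=1.0)
        # the smoothing kernel (truncated at 4 sigma) perturbs an edge frame;
        # beyond it the ramp is exactly linear and curvature vanishes
        assert np.abs(cm[8:-8, 8:-8]).max() < 1e-8

    def test_circular_pattern_inverse_radius(self):
        yy, xx = np.mgrid[0:101, 0:101].astype(float)
        r = np.hypot(yy - 50, xx - 50)
        cm = curvature_map(r, smooth_sigma=1.0)
        for radius in (5, 10, 20, 30):
            ring = np.abs(r - radius) < 0.5
            measured = np.abs(cm[ring]).mean()
            assert measured == pytest.approx(1.0 / radius, rel=0.05)

    def test_constant_image_gradient_floor(self):
        cm = curvature_map(np.full((20, 20), 3.0))
        assert np.all(cm == 0.0)

    def test_superpixel_mean(self):
        yy, xx = np.mgrid[0:60, 0:60].astype(float)
        r = np.hypot(yy - 30, xx - 30)
        rows, cols = np.nonzero((r > 9) & (r < 11))
        val = curvature_features(r, (rows, cols))
        assert abs(val) == pytest.approx(0.1, rel=0.1)


class TestAssembleAndScale:
    def _rows(self, values):
        n = len(values)
        data = {c: np.linspace(0, 1, n) for c in FEATURE_COLUMNS}
        data["int_mean"] = np.asarray(values, dtype=float)
        frame = pd.DataFrame(data)
        frame.insert(0, "case", "c")
        frame.insert(1, "slice", 0)
        frame.insert(2, "label", np.arange(1, n + 1))
        return frame

    def test_training_minmax_to_0_30(self):
        fm = assemble_and_scale(self._rows([10.0, 20.0, 40.0]), fit=True)
        assert fm.frame["int_mean"].tolist() == pytest.approx([0.0, 10.0, 30.0])

    def test_constant_column_zero(self):
        fm = assemble_and_scale(self._rows([5.0, 5.0, 5.0]), fit=True)
        assert np.all(fm.frame["int_mean"] == 0.0)

    def test_texton_columns_pass_through(self):
        rows = self._rows([1.0, 2.0, 3.0])
        rows[list(TEXTON_COLUMNS)] = np.arange(15, dtype=float).reshape(3, 5) * 7
        fm = assemble_and_scale(rows, fit=True)
        assert np.array_equal(fm.frame[list(TEXTON_COLUMNS)].to_numpy(),
                              rows[list(TEXTON_COLUMNS)].to_numpy())

    def test_apply_requires_params_and_can_exceed_range(self):
        train = assemble_and_scale(self._rows([0.0, 10.0]), fit=True)
        with pytest.raises(ValueError):
            assemble_and_scale(self._rows([1.0, 2.0]), fit=False)
        test = assemble_and_scale(self._rows([20.0, -5.0]), fit=False,
                                  scale_params=(train.scale_lo, train.scale_hi))
        assert test.frame["int_mean"].max() > 30.0
        assert test.frame["int_mean"].min() < 0.0


def test_descriptor_length_is_28(small_bank, rng):
    """Every superpixel row carries exactly 16 + 5 + 6 + 1 features."""
    assert len(FEATURE_COLUMNS) == 28
    img = rng.random((2, 36, 36))
    mask = np.ones((2, 36, 36), bool)
    spx = segment_volume(img, mask, S=8)
    resp = filter_responses(img[0], small_bank)
    model = texton_fit([resp], [mask[0]], k=5, seed=0)
    frame = extract_case_features(img, spx, small_bank, model, case_id="t")
    assert frame.shape[0] == spx.n_superpixels()
    assert list(frame.columns[3:]) == FEATURE_COLUMNS
    assert np.all(np.isfinite(frame[FEATURE_COLUMNS].to_numpy()))
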