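"""Unit tests for CV maps, F' maps, Triangle thresholding and range masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flimqc as fq
from flimqc.exceptions import (
    DegenerateHistogramError,
    DimensionError,
    ParameterError,
)

from helpers import brute_force_cv


class TestLocalCVMap:
    def test_constant_image_has_zero_cv(self):
        cv = fq.local_cv_map(fq.ScalarMap(np.full((8, 8), 3.7)), 3)
        assert np.allclose(cv.values, 0.0)
        assert cv.kind == "cv"

    def test_two_pixel_example(self):
        # both windows see {2, 4}: mu = 3, population sigma = 1, CV = 1/3
        cv = fq.local_cv_map(fq.ScalarMap(np.array([[2.0, 4.0]])), 3)
        assert np.allclose(cv.values, 1.0 / 3.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ParameterError):
            fq.local_cv_map(fq.ScalarMap(np.ones((4, 4))), 4)

    @pytest.mark.parametrize("kernel", [1, 3, 5, 49])
    def test_matches_bruteforce_oracle_with_nans(self, kernel, rng):
        v = rng.uniform(0.1, 1.0, (32, 32))
        v[rng.random((32, 32)) < 0.1] = np.nan
        got = fq.local_cv_map(fq.ScalarMap(v), kernel).values
        expected = brute_force_cv(v, kernel)
        m = np.isfinite(expected)
        assert np.array_equal(np.isfinite(got), m)
        assert np.allclose(got[m], expected[m], rtol=1e-10, atol=0)

    def test_kernel_one_gives_zero_cv_at_finite_pixels(self, rng):
        v = rng.uniform(1, 2, (6, 6))
        v[0, 0] = np.nan
        cv = fq.local_cv_map(fq.ScalarMap(v), 1)
        assert np.isnan(cv.values[0, 0])
        assert np.allclose(cv.values[np.isfinite(cv.values)], 0.0)

    def test_scale_invariance(self, rng):
        v = rng.uniform(10, 20, (16, 16))
        base = fq.local_cv_map(fq.ScalarMap(v), 5).values
        for scale in (0.001, 3.0, 1e6):
            scaled = fq.local_cv_map(fq.ScalarMap(v * scale), 5).values
            assert np.allclose(scaled, base, rtol=1e-9)

    def test_nan_center_stays_nan_despite_finite_neighbors(self):
        v = np.ones((5, 5))
        v[2, 2] = np.nan
        cv = fq.local_cv_map(fq.ScalarMap(v), 3)
        assert np.isnan(cv.values[2, 2])

    def test_zero_mean_window_is_nan(self):
        cv = fq.local_cv_map(fq.ScalarMap(np.zeros((4, 4))), 3)
        assert np.all(np.isnan(cv.values))


class TestFprimeMap:
    def _cv(self, arr):
        return fq.ScalarMap(np.asarray(arr, dtype=float), kind="cv")

    def test_identical_inputs_give_unit_ratio(self, rng):
        c = self._cv(rng.uniform(0.1, 1, (4, 4)))
        f = fq.fprime_map(c, c)
        assert np.allclose(f.values, 1.0)
        assert f.kind == "fprime"

    def test_zero_numerator_gives_zero(self):
        f = fq.fprime_map(self._cv(np.zeros((3, 3))), self._cv(np.full((3, 3), 0.2)))
        assert np.allclose(f.values, 0.0)

    def test_zero_denominator_gives_nan(self):
        den = np.full((3, 3), 0.5)
        den[1, 1] = 0.0
        f = fq.fprime_map(self._cv(np.full((3, 3), 0.2)), self._cv(den))
        assert np.isnan(f.values[1, 1])
        assert np.isfinite(f.values[0, 0])

    def test_nan_propagates(self):
        num = np.full((2, 2), 0.3)
        num[0, 0] = np.nan
        f = fq.fprime_map(self._cv(num), self._cv(np.full((2, 2), 0.3)))
        assert np.isnan(f.values[0, 0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            fq.fprime_map(self._cv(np.ones((2, 2))), self._cv(np.ones((3, 3))))

    def test_scale_invariance_of_ratio(self, rng):
        a = rng.uniform(0.1, 1, (5, 5))
        b = rng.uniform(0.1, 1, (5, 5))
        f1 = fq.fprime_map(self._cv(a), self._cv(b)).values
        f2 = fq.fprime_map(self._cv(a * 7), self._cv(b * 0.01)).values
        assert np.allclose(f2, f1 * 700)


def _triangle_oracle(vals, n_bins=256):
    """Exhaustive perpendicular-distance scan over every histogram bin."""
    hist, edges = np.histogram(vals, bins=n_bins)
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    if nz[-1] - peak >= peak - nz[0]:
        end = int(nz[-1])
    else:
        end = int(nz[0])
    # line through (peak, h_peak) and (end, 0)
    x1, y1, x2, y2 = peak, float(hist[peak]), end, 0.0
    best, best_d = None, -1.0
    lo, hi = (peak + 1, end) if end > peak else (end, peak - 1)
    for b in range(lo, hi + 1):
        num = abs((y2 - y1) * b - (x2 - x1) * hist[b] + x2 * y1 - y2 * x1)
        d = num / np.hypot(x2 - x1, y2 - y1)
        if d > best_d:
            best_d, best = d, b
    return float(edges[best + 1])


class TestTriangleThreshold:
    @pytest.mark.parametrize("seed", range(4))
    def test_bimodal_threshold_between_modes(self, seed):
        r = np.random.default_rng(seed)
        vals = np.concatenate([r.normal(5, 1.5, 8000), r.normal(100, 10, 2000)])
        img = fq.ScalarMap(vals.reshape(100, 100))
        thr = fq.triangle_threshold(img)
        assert 5 < thr < 100
        assert thr == _triangle_oracle(vals)

    def test_invariant_under_pixel_shuffling(self, rng):
        vals = np.concatenate([rng.normal(10, 2, 5000), rng.normal(80, 8, 1000)])
        a = fq.triangle_threshold(fq.ScalarMap(vals.reshape(60, 100)))
        shuffled = rng.permutation(vals)
        b = fq.triangle_threshold(fq.ScalarMap(shuffled.reshape(100, 60)))
        assert a == b

    def test_matches_reference_implementation_within_one_bin(self, rng):
        skimage_filters = pytest.importorskip("skimage.filters")
        vals = np.concatenate([rng.normal(5, 1.5, 8000), rng.normal(100, 10, 2000)])
        img = vals.reshape(100, 100)
        mine = fq.triangle_threshold(fq.ScalarMap(img), 256)
        ref = skimage_filters.threshold_triangle(img, nbins=256)
        bin_width = (vals.max() - vals.min()) / 256
        assert abs(mine - ref) <= bin_width

    def test_nan_pixels_ignored(self, rng):
        vals = np.concatenate([rng.normal(5, 1.5, 8000), rng.normal(100, 10, 2000)])
        img = vals.reshape(100, 100).copy()
        clean = fq.triangle_threshold(fq.ScalarMap(img.copy()))
        img[0, :10] = np.nan
        dirty = fq.triangle_threshold(fq.ScalarMap(img))
        assert np.isfinite(dirty)
        assert abs(dirty - clean) < 5  # same bimodal structure

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            fq.triangle_threshold(fq.ScalarMap(np.full((4, 4), 2.0)))


class TestApplyThreshold:
    def test_threshold_below_minimum_changes_nothing(self, rng):
        v = rng.uniform(10, 20, (6, 6))
        intensity = fq.ScalarMap(v, kind="intensity")
        out, = fq.apply_intensity_threshold([intensity], intensity, 5.0)
        assert np.array_equal(out.values, v)

    def test_threshold_above_maximum_blanks_everything(self, rng):
        v = rng.uniform(10, 20, (6, 6))
        intensity = fq.ScalarMap(v, kind="intensity")
        other = fq.ScalarMap(rng.normal(size=(6, 6)))
        a, b = fq.apply_intensity_threshold([intensity, other], intensity, 100.0)
        assert np.all(np.isnan(a.values)) and np.all(np.isnan(b.values))

    def test_exactly_the_below_threshold_pixels_blanked(self, rng):
        v = rng.uniform(0, 1, (8, 8))
        intensity = fq.ScalarMap(v, kind="intensity")
        other = fq.ScalarMap(np.arange(64, dtype=float).reshape(8, 8))
        a, b = fq.apply_intensity_threshold([intensity, other], intensity, 0.5)
        below = v < 0.5
        assert np.array_equal(np.isnan(a.values), below)
        assert np.array_equal(np.isnan(b.values), below)
        assert np.array_equal(b.values[~below], other.values[~below])

    def test_inputs_not_mutated(self, rng):
        v = rng.uniform(0, 1, (4, 4))
        intensity = fq.ScalarMap(v.copy(), kind="intensity")
        fq.apply_intensity_threshold([intensity], intensity, 0.5)
        assert np.array_equal(intensity.values, v)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            fq.apply_intensity_threshold(
                [fq.ScalarMap(np.ones((2, 3)))], fq.ScalarMap(np.ones((3, 2)), kind="intensity"), 1
            )


class TestMasksFromRanges:
    def test_disjoint_ranges_partition_finite_span(self, rng):
        v = rng.uniform(0, 1, (16, 16))
        v[rng.random((16, 16)) < 0.2] = np.nan
        smap = fq.ScalarMap(v, kind="fprime")
        ranges = [
            fq.RangeSpec("low", 0.0, 0.25),
            fq.RangeSpec("mid", 0.25, 0.4),
            fq.RangeSpec("high", 0.4, 1.0),
        ]
        ms = fq.masks_from_ranges(smap, ranges)
        masks = list(ms.masks.values())
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not np.any(masks[i] & masks[j])
        union = ms.union()
        expected = np.isfinite(v) & (v >= 0) & (v < 1)
        assert np.array_equal(union, expected)
        assert not np.any(union & ~np.isfinite(v))

    def test_full_span_mask_equals_finite_mask(self, rng):
        v = rng.uniform(5, 10, (8, 8))
        v[0, 0] = np.nan
        ms = fq.masks_from_ranges(fq.ScalarMap(v), [fq.RangeSpec("all", 0, 100)])
        assert np.array_equal(ms.masks["all"], np.isfinite(v))

    def test_empty_range_flagged(self, rng):
        v = rng.uniform(0, 1, (4, 4))
        ms = fq.masks_from_ranges(fq.ScalarMap(v), [fq.RangeSpec("void", 100, 200)])
        assert not ms.masks["void"].any()
        row = ms.stats.iloc[0]
        assert row["n"] == 0 and bool(row["empty"])
        assert np.isnan(row["mean"])

    def test_stats_computed_on_designated_map(self, rng):
        v = np.array([[0.1, 0.9], [0.2, 0.8]])
        stats_map = fq.ScalarMap(np.array([[100.0, 200.0], [110.0, 210.0]]))
        ms = fq.masks_from_ranges(
            fq.ScalarMap(v), [fq.RangeSpec("low", 0, 0.5)], stats_map=stats_map
        )
        row = ms.stats.iloc[0]
        assert row["n"] == 2
        assert row["mean"] == pytest.approx(105.0)

    def test_invalid_range_rejected(self):
        with pytest.raises(ParameterError):
            fq.RangeSpec("bad", 1.0, 1.0)


class TestQCPipeline:
    RANGES = [
        fq.RangeSpec("low", 0.0, 0.25),
        fq.RangeSpec("mid", 0.25, 0.4),
        fq.RangeSpec("high", 0.4, 1.0),
    ]

    def test_low_intensity_region_has_higher_lifetime_cv(self, striped_mosaic):
        spec, intensity, lifetime, label = striped_mosaic
        res = fq.qc_pipeline(intensity, lifetime, kernel=15, ranges=self.RANGES)
        low_cv = np.nanmean(res.cv_tau.values[label == 1])
        base_cv = np.nanmean(res.cv_tau.values[label == 0])
        assert low_cv > base_cv

    def test_blank_tiles_stay_nan_through_pipeline(self, striped_mosaic):
        spec, intensity, lifetime, label = striped_mosaic
        res = fq.qc_pipeline(intensity, lifetime, kernel=5, ranges=self.RANGES)
        blank = label == -1
        assert blank.any()
        for smap in (res.cv_tau, res.cv_intensity, res.fprime):
            assert np.all(np.isnan(smap.values[blank]))

    def test_all_nan_after_threshold_warns_and_yields_empty_masks(self, striped_mosaic):
        spec, intensity, lifetime, label = striped_mosaic
        huge = float(np.nanmax(intensity.values)) + 1
        with pytest.warns(UserWarning, match="no finite pixels"):
            res = fq.qc_pipeline(
                intensity, lifetime, kernel=5, ranges=self.RANGES,
                threshold_mode="fixed", fixed_threshold=huge,
            )
        assert all(not m.any() for m in res.masks.masks.values())

    def test_matches_bruteforce_cv_on_crop(self, striped_mosaic):
        spec, intensity, lifetime, label = striped_mosaic
        res = fq.qc_pipeline(intensity, lifetime, kernel=15, ranges=self.RANGES)
        thresholded = intensity.values.copy()
        lt = lifetime.values.copy()
        below = intensity.values < res.threshold
        thresholded[below] = np.nan
        lt[below] = np.nan
        crop = np.s_[16:48, 16:48]
        expected = brute_force_cv(lt[crop[0].start - 7 : crop[0].stop + 7,
                                     crop[1].start - 7 : crop[1].stop + 7], 15)
        got = res.cv_tau.values[crop]
        inner = expected[7:-7, 7:-7]
        m = np.isfinite(inner)
        assert np.allclose(got[m], inner[m], rtol=1e-10)

    def test_nan_containment(self, striped_mosaic):
        spec, intensity, lifetime, label = striped_mosaic
        res = fq.qc_pipeline(intensity, lifetime, kernel=5, ranges=self.RANGES)
        src_nan = ~np.isfinite(lifetime.values)
        assert np.all(np.isnan(res.cv_tau.values[src_nan]))

    def test_kernel_coarseness_smooths_cv_map(self):
        # homogeneous striped mosaic: CV structure is pure sampling noise,
        # which larger windows average away
        spec = fq.MosaicSpec(
            regions=(fq.Region("base", "full", (), 1500.0, 50.0, 80.0),),
            tile_shape=(16, 16), grid_shape=(8, 8), stripe_amplitude=0.3, seed=5,
        )
        _, lifetime, _ = fq.generate_mosaic(spec)
        variances = [
            np.nanvar(fq.local_cv_map(lifetime, k).values) for k in (3, 9, 25, 49)
        ]
        assert all(a >= b for a, b in zip(variances, variances[1:]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_cv_scale_invariance_property(scale, seed):
    """sigma/mu is invariant under positive rescaling of the input map."""
    v = np.random.default_rng(seed).uniform(1, 5, (8, 8))
    base = fq.local_cv_map(fq.ScalarMap(v), 3).values
    scaled = fq.local_cv_map(fq.ScalarMap(v * scale), 3).values
    assert np.allclose(scaled, base, rtol=1e-8)
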