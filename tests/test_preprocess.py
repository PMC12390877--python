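import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bolusmap import PreprocessConfig, run_preprocess
from bolusmap.preprocess import (
    apply_noise_threshold,
    crop,
    normalize_global,
    spatial_median_filter,
    subtract_background,
    temporal_median_filter,
)

from conftest import curve_series, make_series


# -- independent brute-force oracles ----------------------------------------

def oracle_temporal_median(data, window):
    """Per-voxel sliding-window sort with edge-inclusive mirror padding."""
    h = window // 2
    padded = np.pad(data, [(h, h)] + [(0, 0)] * 3, mode="symmetric")
    out = np.empty_like(data)
    for t in range(data.shape[0]):
        out[t] = np.sort(padded[t : t + window], axis=0)[h]
    return out

def oracle_spatial_median(plane, ky, kx):
    """Exhaustive neighborhood gathering; even counts average the middle pair."""
    oy, ox = (ky - 1) // 2, (kx - 1) // 2
    ny, nx = plane.shape
    padded = np.pad(plane, ((oy, ky - 1 - oy), (ox, kx - 1 - ox)), mode="symmetric")
    out = np.empty_like(plane)
    for i in range(ny):
        for j in range(nx):
            vals = np.sort(padded[i : i + ky, j : j + kx].ravel())
            m = len(vals)
            out[i, j] = vals[m // 2] if m % 2 else 0.5 * (vals[m // 2 - 1] + vals[m // 2])
    return out


class TestSubtractBackground:
    def test_removes_pre_injection_frame(self):
        s = curve_series([5, 7, 9], modality_tag="projection")
        out = subtract_background(s, PreprocessConfig())
        assert out.intensities.ravel().tolist() == [0, 2, 4]
        assert out.background_subtracted

    def test_static_series_becomes_zero(self):
        s = make_series(np.full((4, 1, 3, 3), 2.5), modality_tag="projection")
        out = subtract_background(s, PreprocessConfig())
        assert not out.intensities.any()

    def test_negative_contrast_polarity_flips(self):
        s = curve_series([9, 7, 5], modality_tag="projection")
        cfg = PreprocessConfig(polarity="negative_contrast")
        assert subtract_background(s, cfg).intensities.ravel().tolist() == [0, 2, 4]

    def test_double_subtraction_rejected(self):
        s = curve_series([5, 7], background_subtracted=True)
        with pytest.raises(ValueError, match="already"):
            subtract_background(s, PreprocessConfig())

    def test_negatives_clipped(self):
        s = curve_series([5, 3, 9], modality_tag="projection")
        assert subtract_background(s, PreprocessConfig()).intensities.min() == 0


class TestCrop:
    def test_extracts_subgrid(self, rng):
        s = make_series(rng.uniform(size=(3, 2, 16, 16)))
        out = crop(s, ((0, 2), (4, 12), (4, 12)))
        assert out.intensities.shape == (3, 2, 8, 8)
        assert np.array_equal(out.intensities, s.intensities[:, :, 4:12, 4:12])
        assert out.dt == s.dt and out.spacing == s.spacing

    def test_full_extent_box_is_identity(self, random_series):
        box = tuple((0, e) for e in random_series.spatial_shape)
        assert np.array_equal(
            crop(random_series, box).intensities, random_series.intensities
        )

    def test_zero_width_box_rejected(self, random_series):
        with pytest.raises(ValueError, match="invalid"):
            crop(random_series, ((0, 2), (3, 3), (0, 6)))


class TestTemporalMedian:
    def test_isolated_spike_removed(self):
        out = temporal_median_filter(curve_series([0, 0, 9, 0, 0]), 3)
        assert not out.intensities.any()

    def test_constant_course_unchanged(self):
        s = make_series(np.full((6, 1, 2, 2), 3.3))
        assert np.array_equal(
            temporal_median_filter(s, 5).intensities, s.intensities
        )

    def test_matches_sliding_sort_oracle(self, rng):
        data = rng.uniform(0, 100, size=(7, 2, 3, 3))
        out = temporal_median_filter(make_series(data), 5).intensities
        assert np.array_equal(out, oracle_temporal_median(data, 5))

    @pytest.mark.parametrize("window", [2, 4])
    def test_even_window_rejected(self, window, random_series):
        with pytest.raises(ValueError, match="odd"):
            temporal_median_filter(random_series, window)

    def test_window_beyond_series_rejected(self, random_series):
        with pytest.raises(ValueError, match="exceeds"):
            temporal_median_filter(random_series, 9)


class TestSpatialMedian:
    def test_impulse_rejected(self):
        frame = np.zeros((5, 5))
        frame[2, 2] = 1.0
        s = make_series(np.stack([frame, frame])[:, None])
        assert not spatial_median_filter(s, (3, 3)).intensities.any()

    def test_constant_frame_unchanged(self):
        s = make_series(np.full((2, 1, 6, 6), 4.2))
        assert np.array_equal(
            spatial_median_filter(s, (2, 2)).intensities, s.intensities
        )

    @pytest.mark.parametrize("kernel", [(2, 2), (3, 3), (6, 6), (2, 3)])
    def test_matches_neighborhood_oracle(self, kernel, rng):
        frame = rng.uniform(0, 50, size=(8, 8))
        s = make_series(np.stack([frame, frame])[:, None])
        out = spatial_median_filter(s, kernel).intensities[0, 0]
        assert np.allclose(out, oracle_spatial_median(frame, *kernel), atol=1e-12)

    def test_kernel_larger_than_plane_rejected(self, random_series):
        with pytest.raises(ValueError, match="larger than"):
            spatial_median_filter(random_series, (7, 7))

    def test_filters_each_z_slice_independently(self, rng):
        data = rng.uniform(size=(2, 3, 8, 8))
        out = spatial_median_filter(make_series(data), (3, 3)).intensities
        for z in range(3):
            single = make_series(data[:, z : z + 1])
            assert np.array_equal(
                out[:, z], spatial_median_filter(single, (3, 3)).intensities[:, 0]
            )


class TestNormalizeAndThreshold:
    def test_affine_map_to_unit_interval(self):
        s = curve_series([2, 4, 6])
        assert normalize_global(s).intensities.ravel().tolist() == [0, 0.5, 1]

    def test_idempotent_on_attained_unit_range(self, rng):
        data = rng.uniform(size=(4, 1, 4, 4))
        data.flat[0], data.flat[1] = 0.0, 1.0
        s = make_series(data)
        assert np.allclose(normalize_global(s).intensities, data, atol=1e-15)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_global(make_series(np.full((3, 1, 2, 2), 7.0)))

    def test_prior_affine_rescale_is_invisible(self, random_series):
        a, b = 3.7, 11.0
        scaled = random_series.with_intensities(a * random_series.intensities + b)
        assert np.allclose(
            normalize_global(scaled).intensities,
            normalize_global(random_series).intensities,
            atol=1e-12,
        )

    def test_threshold_zeroes_below_fraction_of_max(self):
        s = curve_series([0, 0.05, 0.5, 1.0])
        out = apply_noise_threshold(s, 0.08)
        assert out.intensities.ravel().tolist() == [0, 0, 0.5, 1.0]

    def test_zero_fraction_is_identity(self, random_series):
        out = apply_noise_threshold(random_series, 0.0)
        assert np.array_equal(out.intensities, random_series.intensities)

    def test_zeroed_count_matches_loop_oracle(self, rng):
        data = rng.uniform(size=(5, 2, 6, 6))
        s = make_series(data)
        out = apply_noise_threshold(s, 0.1).intensities
        expected = int(np.sum(data < 0.1 * data.max()))
        assert int(np.sum((out == 0) & (data != 0))) == expected

    @pytest.mark.parametrize("frac", [-0.1, 1.0])
    def test_invalid_fraction_rejected(self, frac, random_series):
        with pytest.raises(ValueError):
            apply_noise_threshold(random_series, frac)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_odd_median_commutes_with_monotone_maps(seed):
    """Odd-window medians are order statistics: f(median(x)) == median(f(x))."""
    rng = np.random.default_rng(seed)
    data = rng.uniform(0.1, 5.0, size=(7, 1, 6, 6))
    s = make_series(data)
    f = lambda x: x**3  # strictly increasing on positives
    for op in (
        lambda q: temporal_median_filter(q, 3),
        lambda q: spatial_median_filter(q, (3, 3)),
    ):
        direct = op(make_series(f(data))).intensities
        mapped = f(op(s).intensities)
        assert np.allclose(direct, mapped, atol=1e-9)


def test_chain_preserves_shape_and_records_normalization(random_series):
    out = run_preprocess(random_series, PreprocessConfig(temporal_window=3,
                                                         spatial_kernel=(2, 2)))
    assert out.intensities.shape == random_series.intensities.shape
    assert out.intensities.min() >= 0 and out.intensities.max() <= 1
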