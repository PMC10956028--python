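import numpy as np
import pytest

from patchflow import (
    GridImage,
    IntensityBand,
    LabelMap,
    clip_band,
    equalize_global,
    rescale_range,
    resample,
    threshold_band,
    zscore_normalize,
)
from patchflow.errors import NormalizationError
from patchflow.harmonize import PreprocSpec, apply_preprocessing, augment


def image_of(values, shape=None):
    arr = np.asarray(values, dtype=float)
    if shape is not None:
        arr = arr.reshape(shape)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1, 1)  # one channel, Nx1 spatial grid
    elif arr.ndim == 2:
        arr = arr[None]
    return GridImage(arr, (1.0,) * (arr.ndim - 1))


class TestBandOps:
    def test_threshold_zeroes_outside_band(self):
        img = image_of([-2, 0, 3, 7])
        out = threshold_band(img, IntensityBand(0, 5))
        np.testing.assert_array_equal(out.data.ravel(), [0, 0, 3, 0])

    def test_clip_clamps_to_band(self):
        img = image_of([-2, 0, 3, 7])
        out = clip_band(img, IntensityBand(0, 5))
        np.testing.assert_array_equal(out.data.ravel(), [0, 0, 3, 5])

    def test_hounsfield_lung_window(self):
        """CT values clipped to the [-900, -300] HU lung window."""
        img = image_of([-1200, -900, -600, -300, 0])
        out = clip_band(img, IntensityBand(-900, -300))
        np.testing.assert_array_equal(out.data.ravel(), [-900, -900, -600, -300, -300])

    def test_degenerate_band_collapses(self):
        img = image_of([-5, 0, 5])
        out = clip_band(img, IntensityBand(2.0, 2.0))
        np.testing.assert_array_equal(out.data.ravel(), [2.0, 2.0, 2.0])

    def test_infinite_band_is_identity(self, small_image):
        out = threshold_band(small_image, IntensityBand(-np.inf, np.inf))
        np.testing.assert_array_equal(out.data, small_image.data)

    def test_band_ops_match_per_element_rules(self, rng):
        """Vectorized band ops agree with an elementwise reference loop."""
        data = rng.normal(scale=3, size=(1, 6, 6))
        img = GridImage(data, (1.0, 1.0))
        lo, hi = -1.0, 2.0
        thr = threshold_band(img, IntensityBand(lo, hi)).data
        clp = clip_band(img, IntensityBand(lo, hi)).data
        for idx in np.ndindex(data.shape):
            x = data[idx]
            assert thr[idx] == (0.0 if (x < lo or x > hi) else x)
            assert clp[idx] == (lo if x < lo else hi if x > hi else x)

    def test_clip_is_idempotent(self, small_image):
        band = IntensityBand(-0.5, 0.5)
        once = clip_band(small_image, band)
        twice = clip_band(once, band)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_threshold_idempotent_when_band_contains_zero(self, small_image):
        band = IntensityBand(-0.5, 0.5)
        once = threshold_band(small_image, band)
        twice = threshold_band(once, band)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            IntensityBand(1.0, 0.0)


class TestRescale:
    def test_hand_affine_map(self):
        out = rescale_range(image_of([2.0, 4.0, 6.0]), 0.0, 1.0)
        np.testing.assert_allclose(out.data.ravel(), [0.0, 0.5, 1.0])

    def test_unit_interval_fixpoint(self):
        img = image_of([0.0, 0.25, 1.0])
        out = rescale_range(img, 0.0, 1.0)
        np.testing.assert_allclose(out.data, img.data, atol=1e-9)

    def test_eight_bit_to_unit(self):
        out = rescale_range(image_of([0.0, 127.5, 255.0]), 0.0, 1.0)
        np.testing.assert_allclose(out.data.ravel(), [0.0, 0.5, 1.0])

    def test_constant_channel_maps_to_out_min(self):
        out = rescale_range(image_of([3.0, 3.0, 3.0]), -1.0, 1.0)
        np.testing.assert_array_equal(out.data, -1.0)

    def test_output_hits_range_endpoints(self, small_image):
        out = rescale_range(small_image, -2.0, 5.0)
        for c in range(out.n_channels):
            assert out.data[c].min() == pytest.approx(-2.0, abs=1e-9)
            assert out.data[c].max() == pytest.approx(5.0, abs=1e-9)


class TestZScore:
    def test_two_values(self):
        out = zscore_normalize(image_of([1.0, 3.0]))
        np.testing.assert_allclose(out.data.ravel(), [-1.0, 1.0])

    def test_nonzero_only_keeps_background_at_zero(self):
        out = zscore_normalize(image_of([0.0, 0.0, 1.0, 3.0]), nonzero_only=True)
        np.testing.assert_allclose(out.data.ravel(), [0.0, 0.0, -1.0, 1.0])

    def test_population_moments(self, small_image):
        out = zscore_normalize(small_image)
        for c in range(out.n_channels):
            assert out.data[c].mean() == pytest.approx(0.0, abs=1e-6)
            assert out.data[c].std() == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_affine_reexpression(self, rng):
        x = rng.normal(size=(1, 5, 5))
        a, b = 2.7, -4.0
        base = zscore_normalize(GridImage(x, (1, 1))).data
        shifted = zscore_normalize(GridImage(a * x + b, (1, 1))).data
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_zero_std_raises(self):
        with pytest.raises(NormalizationError, match="channel 0"):
            zscore_normalize(image_of([2.0, 2.0, 2.0]))


class TestResample:
    def test_identity_when_target_matches(self, small_volume):
        out = resample(small_volume, target_spacing=small_volume.spacing)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_constant_preserved(self):
        img = GridImage(np.full((1, 8, 8), 2.0), (1.0, 1.0))
        out = resample(img, target_shape=(4, 4))
        assert out.spatial_shape == (4, 4)
        np.testing.assert_allclose(out.data, 2.0)

    def test_ramp_matches_center_interpolation(self):
        """Downsampling a ramp samples the linear interpolant at the new
        pixel centers: x_in = (j + 0.5) * factor - 0.5."""
        ramp = np.tile(np.arange(8.0), (8, 1))
        img = GridImage(ramp[None], (1.0, 1.0))
        out = resample(img, target_spacing=(1.0, 2.0))
        assert out.spatial_shape == (8, 4)
        np.testing.assert_allclose(out.data[0, 0], [0.5, 2.5, 4.5, 6.5])

    def test_physical_extent_preserved(self, small_volume):
        out = resample(small_volume, target_spacing=(2.0, 2.0, 1.0))
        for n_new, s_new, n_old, s_old in zip(
            out.spatial_shape, out.spacing, small_volume.spatial_shape, small_volume.spacing
        ):
            assert abs(n_new * s_new - n_old * s_old) <= max(s_new, s_old)

    def test_label_map_nearest_and_closed_label_set(self):
        lm = LabelMap(np.kron(np.array([[0, 1], [2, 0]]), np.ones((4, 4), dtype=int)))
        out = resample(lm, target_shape=(4, 4))
        assert isinstance(out, LabelMap)
        assert out.labels <= lm.labels

    def test_round_trip_constant_exact(self):
        img = GridImage(np.full((1, 6, 6), 1.25), (1.0, 1.0))
        there = resample(img, target_spacing=(3.0, 3.0))
        back = resample(there, target_shape=(6, 6))
        np.testing.assert_array_equal(back.data, img.data)

    def test_bad_arguments(self, small_image):
        with pytest.raises(ValueError):
            resample(small_image)
        with pytest.raises(ValueError):
            resample(small_image, target_spacing=(0.0, 1.0))


class TestEqualize:
    def test_two_valued_cdf(self):
        data = np.array([0.1] * 8 + [0.9] * 8).reshape(1, 4, 4)
        out = equalize_global(GridImage(data, (1, 1)), n_bins=4)
        assert set(np.round(out.data.ravel(), 6)) == {0.5, 1.0}

    def test_constant_input_constant_output(self):
        out = equalize_global(GridImage(np.full((1, 4, 4), 7.0), (1, 1)))
        assert np.unique(out.data).size == 1

    def test_monotone_and_bounded(self, rng):
        img = GridImage(rng.normal(size=(1, 16, 16)), (1, 1))
        out = equalize_global(img, n_bins=32)
        assert out.data.min() >= 0 and out.data.max() <= 1
        order = np.argsort(img.data.ravel())
        eq = out.data.ravel()[order]
        assert (np.diff(eq) >= -1e-12).all()

    def test_uniform_input_approximates_rescale(self, rng):
        vals = rng.uniform(2.0, 6.0, size=(1, 64, 64))
        img = GridImage(vals, (1, 1))
        eq = equalize_global(img, n_bins=64).data
        lin = rescale_range(img, 0.0, 1.0).data
        assert np.abs(eq - lin).mean() < 0.05


class TestAugment:
    def test_flip_is_involution(self, small_image):
        once, _ = augment(small_image, None, "flip", {"axis": 1})
        twice, _ = augment(once, None, "flip", {"axis": 1})
        np.testing.assert_array_equal(twice.data, small_image.data)

    def test_flip_moves_image_and_label_together(self, rng):
        img = GridImage(rng.normal(size=(1, 6, 6)), (1, 1))
        lab = LabelMap((img.data[0] > 0).astype(int))
        fi, fl = augment(img, lab, "flip", {"axis": 0})
        np.testing.assert_array_equal(fl.data, (fi.data[0] > 0).astype(int))

    def test_zero_noise_is_identity(self, small_image):
        out, _ = augment(small_image, None, "noise", {"std": 0.0}, rng_seed=3)
        np.testing.assert_array_equal(out.data, small_image.data)

    def test_same_seed_bit_identical(self, small_image):
        a, _ = augment(small_image, None, "noise", {"std": 0.5}, rng_seed=9)
        b, _ = augment(small_image, None, "noise", {"std": 0.5}, rng_seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_blur_leaves_label_untouched(self, rng):
        img = GridImage(rng.normal(size=(1, 8, 8)), (1, 1))
        lab = LabelMap(np.ones((8, 8), dtype=int))
        _, out_lab = augment(img, lab, "blur", {"sigma": 1.0})
        np.testing.assert_array_equal(out_lab.data, lab.data)

    def test_unsupported_kind_lists_options(self, small_image):
        with pytest.raises(ValueError, match="flip"):
            augment(small_image, None, "shear", {})


class TestPreprocSpec:
    def test_pipeline_application_order(self):
        spec = PreprocSpec.from_config(
            [{"clip": {"min": 0, "max": 4}}, {"rescale": {"min": 0, "max": 1}}]
        )
        out = apply_preprocessing(image_of([-2.0, 2.0, 8.0]), spec)
        np.testing.assert_allclose(out.data.ravel(), [0.0, 0.5, 1.0])

    def test_unknown_step_rejected(self):
        from patchflow.errors import ConfigError

        with pytest.raises(ConfigError, match="unknown preprocessing step"):
            PreprocSpec.from_config(["stain_normalize"])
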