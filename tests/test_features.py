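import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radiomodal import (
    DegenerateInputError,
    EmptyMaskError,
    PreprocessConfig,
    SliceImage,
    SliceMask,
    extract_cohort_features,
    first_order_features,
    load_nifti_stack,
    preprocess_slice,
    shape2d_features,
)
from conftest import disk_mask


def make_pair(pixels, mask, spacing=(0.6, 0.6), index=0):
    return (
        SliceImage(np.asarray(pixels, dtype=float), spacing, index),
        SliceMask(np.asarray(mask, dtype=np.uint8), spacing),
    )


class TestPreprocess:
    def test_identity_when_disabled_and_spacing_matches(self):
        img, mask = make_pair(np.arange(16.0).reshape(4, 4), np.ones((4, 4)))
        config = PreprocessConfig(normalize=False, resample_spacing=(0.6, 0.6))
        out_img, out_mask = preprocess_slice(img, mask, config)
        np.testing.assert_array_equal(out_img.pixels, img.pixels)
        np.testing.assert_array_equal(out_mask.pixels, mask.pixels)

    def test_zscore_then_clip(self):
        rng = np.random.default_rng(7)
        img, mask = make_pair(rng.normal(50, 5, (12, 12)), np.ones((12, 12)))
        out_img, _ = preprocess_slice(img, mask, PreprocessConfig())
        assert abs(out_img.pixels.mean()) < 0.2  # clipping may shift the mean slightly
        assert out_img.pixels.max() <= 3.0 and out_img.pixels.min() >= -3.0

    def test_far_outlier_clips_to_exactly_three(self):
        # one value at mean + 10 sd of the grid lands exactly on the clip bound
        pixels = np.zeros((10, 10))
        pixels[::2, ::2] = 1.0
        mean, sd = pixels.mean(), pixels.std()
        pixels[0, 0] = mean + 10 * sd
        img, mask = make_pair(pixels, np.ones((10, 10)))
        out_img, _ = preprocess_slice(img, mask, PreprocessConfig())
        assert out_img.pixels.max() == pytest.approx(3.0, abs=0)

    def test_zero_variance_rejected(self):
        img, mask = make_pair(np.full((4, 4), 9.0), np.ones((4, 4)))
        with pytest.raises(DegenerateInputError):
            preprocess_slice(img, mask, PreprocessConfig())

    def test_resampling_changes_grid_and_preserves_mask_binarity(self):
        rng = np.random.default_rng(0)
        shape = disk_mask(6, pad=3).shape  # 19x19
        img, mask = make_pair(rng.normal(size=shape), disk_mask(6, pad=3), spacing=(1.2, 1.2))
        out_img, out_mask = preprocess_slice(img, mask, PreprocessConfig())
        assert out_img.pixels.shape == (38, 38)
        assert out_img.spacing == (0.6, 0.6)
        assert set(np.unique(out_mask.pixels)) <= {0, 1}


class TestFirstOrder:
    def test_symmetric_values_have_zero_skew(self):
        skew, _ = first_order_features([1.0, 2.0, 3.0])
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_two_point_distribution_kurtosis(self):
        # m2 = 1 and m4 = 1 for {-1,-1,1,1}
        _, kurt = first_order_features([-1.0, -1.0, 1.0, 1.0])
        assert kurt == pytest.approx(1.0)

    def test_normal_sample_kurtosis_near_three(self):
        rng = np.random.default_rng(123)
        _, kurt = first_order_features(rng.standard_normal(200_000))
        assert kurt == pytest.approx(3.0, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            first_order_features([2.0, 2.0, 2.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=200) + rng.exponential(size=200)
        base = first_order_features(x)
        transformed = first_order_features(scale * x + shift)
        assert transformed == pytest.approx(base, rel=1e-8, abs=1e-8)


class TestShape2D:
    def test_single_pixel_diamond_area(self):
        mask = SliceMask(np.pad(np.ones((1, 1), np.uint8), 1), (0.6, 0.6))
        area, _, _, elongation = shape2d_features(mask)
        assert area == pytest.approx(0.6 * 0.6 / 2.0)
        assert elongation == 1.0

    @pytest.mark.parametrize("radius", [10, 20, 40])
    def test_disk_is_round(self, radius):
        area, _, sphericity, elongation = shape2d_features(
            SliceMask(disk_mask(radius), (0.6, 0.6))
        )
        assert area == pytest.approx(np.pi * (radius * 0.6) ** 2, rel=0.05)
        assert sphericity == pytest.approx(1.0, rel=0.05)
        assert elongation == pytest.approx(1.0, rel=0.05)

    def test_thin_bar_is_elongated(self):
        bar = np.zeros((5, 24), np.uint8)
        bar[2, 2:22] = 1
        _, _, sphericity, elongation = shape2d_features(SliceMask(bar, (0.6, 0.6)))
        assert elongation < 0.3
        assert sphericity < 1.0

    def test_union_of_components_sums_area_and_perimeter(self):
        single = np.zeros((5, 9), np.uint8)
        single[2, 2] = 1
        double = single.copy()
        double[2, 6] = 1
        a1, p1, _, _ = shape2d_features(SliceMask(single, (0.6, 0.6)))
        a2, p2, _, _ = shape2d_features(SliceMask(double, (0.6, 0.6)))
        assert a2 == pytest.approx(2 * a1)
        assert p2 == pytest.approx(2 * p1)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            shape2d_features(SliceMask(np.zeros((4, 4), np.uint8), (0.6, 0.6)))

    def test_random_blob_invariants(self):
        from scipy import ndimage

        rng = np.random.default_rng(42)
        for _ in range(40):
            blob = (ndimage.gaussian_filter(rng.random((40, 40)), rng.uniform(1, 4)) > 0.5)
            if not blob.any():
                continue
            _, _, sphericity, elongation = shape2d_features(
                SliceMask(blob.astype(np.uint8), (0.6, 0.6))
            )
            assert sphericity <= 1.05
            assert 0.0 <= elongation <= 1.0


class TestCohortExtraction:
    def _patient(self, rng, n_slices, empty=()):
        pairs = []
        for k in range(n_slices):
            mask = np.zeros((30, 30), np.uint8)
            if k not in empty:
                mask[8:21, 8:21] = disk_mask(6, pad=0)  # 13x13 disk block
            img = rng.normal(60, 15, (30, 30))
            img[mask > 0] = rng.normal(100, 20, int(mask.sum()))
            pairs.append(make_pair(img, mask, index=k))
        return pairs

    def test_empty_slices_skipped(self):
        rng = np.random.default_rng(5)
        table = extract_cohort_features({"p1": self._patient(rng, 3, empty=(1,))})
        assert len(table) == 2
        assert list(table["slice_index"]) == [0, 2]

    def test_determinism(self):
        table1 = extract_cohort_features({"p1": self._patient(np.random.default_rng(5), 3)})
        table2 = extract_cohort_features({"p1": self._patient(np.random.default_rng(5), 3)})
        assert table1.equals(table2)

    def test_patient_without_usable_slice_named_in_error(self):
        rng = np.random.default_rng(5)
        with pytest.raises(EmptyMaskError, match="p9"):
            extract_cohort_features({"p9": self._patient(rng, 2, empty=(0, 1))})

    def test_disk_lesions_score_high_sphericity(self):
        rng = np.random.default_rng(5)
        table = extract_cohort_features({"p1": self._patient(rng, 3)})
        assert (table["sphericity"] > 0.9).all()


def test_nifti_round_trip(tmp_path):
    import nibabel as nib

    rng = np.random.default_rng(11)
    vol = rng.normal(60, 15, (20, 24, 3)).astype(np.float32)
    mask = np.zeros((20, 24, 3), np.uint8)
    mask[5:15, 6:18, :] = 1
    affine = np.diag([0.6, 0.6, 4.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), tmp_path / "p_image.nii.gz")
    nib.save(nib.Nifti1Image(mask, affine), tmp_path / "p_mask.nii.gz")
    pairs = load_nifti_stack(tmp_path / "p_image.nii.gz", tmp_path / "p_mask.nii.gz")
    assert len(pairs) == 3
    img, msk = pairs[0]
    assert img.spacing == pytest.approx((0.6, 0.6))
    assert img.pixels.shape == (20, 24)
    assert msk.pixels.sum() == 10 * 12
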