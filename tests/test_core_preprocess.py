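import numpy as np
import pytest

from oarseg.core import (CTVolume, FormatError, HUWindow, ROISpec, SegCase,
                         ValidationError, default_roi_spec)
from oarseg.io import read_case, write_case
from oarseg.preprocess import (apply_hu_window, crop_roi, flip_lateral,
                               normalize, preprocess_case)

from conftest import make_ball_case


class TestHUWindow:
    def test_center_width_bounds_round_trip(self):
        w = HUWindow(center=50.0, width=250.0)
        assert (w.lower, w.upper) == (-75.0, 175.0)
        assert HUWindow.from_bounds(-75, 175) == w

    @pytest.mark.parametrize("organ,bounds", [("SMG", (-75, 175)), ("PG", (-190, 310))])
    def test_organ_default_windows(self, organ, bounds):
        spec = default_roi_spec(organ)
        assert (spec.hu_window.lower, spec.hu_window.upper) == bounds

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            HUWindow(center=0, width=0)


class TestSegCaseInvariants:
    def test_nonbinary_mask_rejected(self, ball_case):
        bad = ball_case.organ_mask.astype(np.int16).copy()
        bad[0, 0, 0] = 2
        with pytest.raises(ValidationError, match="0/1"):
            ball_case.replace(organ_mask=bad)

    def test_organ_outside_body_rejected(self, ball_case):
        body = ball_case.body_mask.copy()
        body[:] = 0
        with pytest.raises(ValidationError, match="subset"):
            ball_case.replace(body_mask=body)

    def test_empty_organ_rejected(self, ball_case):
        with pytest.raises(ValidationError, match="empty"):
            ball_case.replace(organ_mask=np.zeros_like(ball_case.organ_mask))

    def test_shape_mismatch_rejected(self, ball_case):
        with pytest.raises(FormatError):
            ball_case.replace(organ_mask=np.ones((4, 4, 4), dtype=np.uint8))


class TestNiftiIO:
    def test_round_trip_preserves_voxels_and_spacing(self, tmp_path, phantom_case):
        paths = write_case(phantom_case, tmp_path)
        back = read_case(paths["image"], paths["organ_mask"], paths["body_mask"],
                         organ=phantom_case.organ, laterality=phantom_case.laterality)
        np.testing.assert_array_equal(back.image.voxels, phantom_case.image.voxels)
        np.testing.assert_array_equal(back.organ_mask, phantom_case.organ_mask)
        np.testing.assert_array_equal(back.body_mask, phantom_case.body_mask)
        assert back.image.spacing == pytest.approx(phantom_case.image.spacing)

    def test_invalid_mask_file_rejected(self, tmp_path, phantom_case):
        paths = write_case(phantom_case, tmp_path)
        bad = phantom_case.image  # HU-valued, not binary
        from oarseg.io import write_volume
        write_volume(bad, tmp_path / "bad.nii.gz")
        with pytest.raises(ValidationError):
            read_case(paths["image"], tmp_path / "bad.nii.gz", paths["body_mask"],
                      organ="SMG", laterality="left")

    def test_shape_mismatch_rejected(self, tmp_path, phantom_case):
        paths = write_case(phantom_case, tmp_path)
        small = make_ball_case(shape=(8, 8, 8), radius=2)
        p2 = write_case(small, tmp_path, stem="small")
        with pytest.raises(FormatError):
            read_case(paths["image"], p2["organ_mask"], paths["body_mask"],
                      organ="SMG", laterality="left")


class TestFlip:
    def test_involution_bit_exact(self, phantom_case):
        twice = flip_lateral(flip_lateral(phantom_case))
        np.testing.assert_array_equal(twice.image.voxels, phantom_case.image.voxels)
        np.testing.assert_array_equal(twice.organ_mask, phantom_case.organ_mask)
        assert twice.laterality == phantom_case.laterality

    def test_centroid_mirrored_and_count_preserved(self, phantom_case):
        flipped = flip_lateral(phantom_case)
        assert flipped.laterality == "right"
        assert flipped.organ_mask.sum() == phantom_case.organ_mask.sum()
        nx = phantom_case.shape[0]
        c0 = phantom_case.organ_centroid()
        c1 = flipped.organ_centroid()
        assert c1[0] == pytest.approx(nx - 1 - c0[0])
        assert c1[1:] == pytest.approx(c0[1:])


class TestCrop:
    def test_centered_crop_arithmetic(self):
        case = make_ball_case(shape=(128, 128, 128), center=(64, 64, 64), radius=6)
        spec = default_roi_spec("SMG")  # 64x64x32
        case.image.voxels[32, 32, 48] = 1234.0  # corner of the expected box
        out = crop_roi(case, spec)
        assert out.shape == (64, 64, 32)
        assert out.image.voxels[0, 0, 0] == 1234.0
        assert out.organ_mask.sum() == case.organ_mask.sum()

    def test_border_crop_padded_with_lower_bound(self):
        case = make_ball_case(shape=(64, 64, 64), center=(5, 32, 32), radius=3)
        spec = default_roi_spec("SMG", crop_shape=(64, 64, 32))
        out = crop_roi(case, spec)
        assert out.shape == (64, 64, 32)
        # left x-side falls outside the volume: padded with the window lower bound
        assert np.all(out.image.voxels[:20, 0, 0] == spec.hu_window.lower)
        assert out.organ_mask.sum() == case.organ_mask.sum()

    def test_pg_output_shape(self):
        case = make_ball_case(shape=(128, 96, 96), center=(64, 48, 48), radius=8, organ="PG")
        out = crop_roi(case, default_roi_spec("PG"))
        assert out.shape == (96, 64, 64)

    def test_oversized_organ_warns_but_crops(self):
        case = make_ball_case(shape=(48, 48, 48), radius=10)
        spec = default_roi_spec("SMG", crop_shape=(12, 12, 8))
        with pytest.warns(UserWarning, match="exceeds crop shape"):
            out = crop_roi(case, spec)
        assert out.shape == (12, 12, 8)


class TestWindowNormalize:
    def test_clipping_values(self):
        vol = CTVolume(np.array([[[200.0, -100.0, 0.0]]]))
        out = apply_hu_window(vol, HUWindow.from_bounds(-75, 175))
        np.testing.assert_array_equal(out.voxels[0, 0], [175.0, -75.0, 0.0])

    def test_idempotent(self, phantom_case):
        w = HUWindow.from_bounds(-75, 175)
        once = apply_hu_window(phantom_case.image, w)
        twice = apply_hu_window(once, w)
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_inside_window_identity(self):
        vol = CTVolume(np.full((3, 3, 3), 12.0))
        out = apply_hu_window(vol, HUWindow.from_bounds(-75, 175))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_normalize_two_voxel_hand_value(self):
        # {-75, 175} under the SMG window: maps to {0, 1}, mean 0.5 -> {-0.5, +0.5}
        vol = CTVolume(np.array([-75.0, 175.0]).reshape(1, 1, 2))
        out = normalize(vol, HUWindow.from_bounds(-75, 175))
        np.testing.assert_allclose(out.voxels.ravel(), [-0.5, 0.5], atol=1e-6)

    def test_normalize_constant_volume_all_zero(self):
        vol = CTVolume(np.full((4, 4, 4), 50.0))
        out = normalize(vol, HUWindow.from_bounds(-75, 175))
        np.testing.assert_allclose(out.voxels, 0.0, atol=1e-7)


class TestPreprocessChain:
    def test_shape_mean_range(self, phantom_case, smg_spec):
        out = preprocess_case(phantom_case, smg_spec)
        assert out.shape == smg_spec.crop_shape
        assert abs(out.image.voxels.mean()) < 1e-6
        assert out.image.voxels.min() >= -1.0 and out.image.voxels.max() <= 1.0
        assert out.organ_mask.shape == smg_spec.crop_shape

    def test_translation_equivariance(self, smg_spec):
        base = make_ball_case(shape=(40, 40, 24), center=(20, 20, 12), radius=4)
        shifted = make_ball_case(shape=(40, 40, 24), center=(23, 18, 14), radius=4)
        a = preprocess_case(base, smg_spec)
        b = preprocess_case(shifted, smg_spec)
        np.testing.assert_allclose(a.image.voxels, b.image.voxels, atol=1e-6)
        np.testing.assert_array_equal(a.organ_mask, b.organ_mask)
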