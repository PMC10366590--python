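import numpy as np
import nibabel as nib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from broadvol import (
    DimensionalityError,
    PreprocessConfig,
    Volume,
    center_crop,
    load_volume,
    preprocess_volume,
    resample_isotropic,
    save_volume,
    scale_intensity,
)


def write_nifti(path, data, affine=None, spacing=None):
    img = nib.Nifti1Image(np.asarray(data), affine if affine is not None else np.eye(4))
    if spacing is not None:
        img.header.set_zooms(spacing)
    nib.save(img, str(path))


class TestLoadVolume:
    def test_round_trip_preserves_data_and_spacing(self, tmp_path, rng):
        data = rng.random((10, 12, 8))
        v = Volume(data=data, spacing=(1, 1, 1), affine=np.eye(4), id="x")
        save_volume(v, tmp_path / "x.nii.gz")
        back = load_volume(tmp_path / "x.nii.gz")
        assert np.array_equal(back.data, data)
        assert back.spacing == pytest.approx((1, 1, 1))
        assert back.id == "x"

    def test_spacing_read_from_affine(self, tmp_path, rng):
        write_nifti(tmp_path / "a.nii", rng.random((6, 6, 6)), affine=np.diag([2, 2, 2, 1]))
        v = load_volume(tmp_path / "a.nii")
        assert v.spacing == pytest.approx((2, 2, 2))

    def test_4d_time_series_rejected(self, tmp_path, rng):
        write_nifti(tmp_path / "fmri.nii", rng.random((8, 8, 8, 5)))
        with pytest.raises(DimensionalityError):
            load_volume(tmp_path / "fmri.nii")

    def test_trailing_singleton_axis_squeezed(self, tmp_path, rng):
        write_nifti(tmp_path / "s.nii", rng.random((8, 8, 8, 1)))
        assert load_volume(tmp_path / "s.nii").data.ndim == 3

    def test_corrupt_file_raises_ioerror_naming_path(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"not a nifti at all")
        with pytest.raises(IOError, match="bad.nii"):
            load_volume(bad)


class TestResample:
    def test_noop_at_target_spacing(self, rng):
        v = Volume(rng.random((10, 10, 10)), (1.5, 1.5, 1.5), np.eye(4))
        out = resample_isotropic(v, 1.5)
        assert np.array_equal(out.data, v.data)
        assert out.spacing == (1.5, 1.5, 1.5)

    def test_shape_arithmetic(self, rng):
        v = Volume(rng.random((64, 64, 64)), (3, 3, 3), np.diag([3, 3, 3, 1]))
        out = resample_isotropic(v, 1.5)
        assert out.shape == (128, 128, 128)
        assert out.spacing == (1.5, 1.5, 1.5)

    def test_constant_volume_stays_constant(self):
        v = Volume(np.full((9, 9, 9), 7.0), (2, 2, 2), np.eye(4))
        out = resample_isotropic(v, 1.0)
        assert np.allclose(out.data, 7.0)

    def test_round_trip_on_constant_is_exact(self):
        v = Volume(np.full((8, 8, 8), 3.0), (2, 2, 2), np.eye(4))
        back = resample_isotropic(resample_isotropic(v, 1.0), 2.0)
        assert back.shape == v.shape
        assert np.allclose(back.data, 3.0)

    def test_degenerate_output_rejected(self):
        v = Volume(np.zeros((2, 2, 2)), (0.1, 0.1, 0.1), np.eye(4))
        with pytest.raises(ValueError):
            resample_isotropic(v, 10.0)


class TestScaleIntensity:
    def test_hand_example(self):
        v = Volume(np.array([0.0, 5.0, 10.0]).reshape(1, 1, 3), (1, 1, 1), np.eye(4))
        out = scale_intensity(v, 0, 1)
        assert np.array_equal(out.data.ravel(), [0.0, 0.5, 1.0])

    def test_exact_range_on_random_volume(self, rng):
        v = Volume(rng.normal(50, 20, (8, 8, 8)), (1, 1, 1), np.eye(4))
        out = scale_intensity(v)
        assert out.data.min() == 0.0 and out.data.max() == 1.0

    def test_already_normalized_unchanged(self, rng):
        data = rng.random((6, 6, 6))
        data.ravel()[0], data.ravel()[1] = 0.0, 1.0
        v = Volume(data, (1, 1, 1), np.eye(4))
        assert np.array_equal(scale_intensity(v).data, data)

    def test_constant_input_maps_to_lo_not_nan(self, caplog):
        v = Volume(np.full((4, 4, 4), 9.0), (1, 1, 1), np.eye(4))
        with caplog.at_level("WARNING"):
            out = scale_intensity(v, 0.25, 1.0)
        assert np.all(out.data == 0.25)
        assert "constant" in caplog.text

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent(self, seed):
        data = np.random.default_rng(seed).normal(0, 10, (5, 5, 5))
        v = Volume(data, (1, 1, 1), np.eye(4))
        once = scale_intensity(v)
        twice = scale_intensity(once)
        assert np.array_equal(once.data, twice.data)


class TestCenterCrop:
    def test_native_to_model_grid_offsets(self, rng):
        data = rng.random((256, 256, 160))
        out = center_crop(Volume(data, (1.5,) * 3, np.eye(4)), (224, 224, 128))
        assert out.shape == (224, 224, 128)
        assert np.array_equal(out.data, data[16:240, 16:240, 16:144])

    def test_identity_when_shapes_match(self, rng):
        data = rng.random((12, 10, 8))
        out = center_crop(Volume(data, (1,) * 3, np.eye(4)), (12, 10, 8))
        assert np.array_equal(out.data, data)

    def test_small_axis_zero_padded_symmetrically(self, rng):
        data = rng.random((200, 224, 128))
        out = center_crop(Volume(data, (1,) * 3, np.eye(4)), (224, 224, 128))
        assert out.shape == (224, 224, 128)
        assert np.all(out.data[:12] == 0) and np.all(out.data[-12:] == 0)
        assert np.array_equal(out.data[12:212], data)

    def test_crop_twice_is_identity_on_first_output(self, rng):
        v = Volume(rng.random((30, 20, 25)), (1,) * 3, np.eye(4))
        once = center_crop(v, (16, 24, 10))
        twice = center_crop(once, (16, 24, 10))
        assert np.array_equal(once.data, twice.data)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        nx=st.integers(1, 40), ny=st.integers(1, 40), nz=st.integers(1, 40),
        cx=st.integers(1, 30), cy=st.integers(1, 30), cz=st.integers(1, 30),
    )
    def test_total_on_any_shape(self, nx, ny, nz, cx, cy, cz):
        v = Volume(np.ones((nx, ny, nz)), (1,) * 3, np.eye(4))
        assert center_crop(v, (cx, cy, cz)).shape == (cx, cy, cz)


class TestPreprocessVolume:
    def test_composed_postconditions(self, tmp_path, rng):
        write_nifti(tmp_path / "v.nii.gz", rng.random((40, 30, 20)) * 100,
                    affine=np.diag([2, 2, 2, 1]))
        out = preprocess_volume(tmp_path / "v.nii.gz",
                                PreprocessConfig(crop_shape=(32, 32, 32)))
        assert out.shape == (32, 32, 32)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_fixed_point_input_unchanged(self, tmp_path, rng):
        data = rng.random((24, 24, 16))
        data.ravel()[0], data.ravel()[1] = 0.0, 1.0
        write_nifti(tmp_path / "fp.nii", data, affine=np.diag([1.5, 1.5, 1.5, 1.0]))
        out = preprocess_volume(tmp_path / "fp.nii",
                                PreprocessConfig(crop_shape=(24, 24, 16)))
        assert np.allclose(out.data, data)

    def test_resample_makes_crop_identity(self, tmp_path, rng):
        # 3 mm input at half the grid: resampling to 1.5 mm lands exactly
        # on the crop target, so cropping removes nothing
        write_nifti(tmp_path / "c.nii", rng.random((16, 16, 8)),
                    affine=np.diag([3, 3, 3, 1]))
        out = preprocess_volume(tmp_path / "c.nii",
                                PreprocessConfig(crop_shape=(32, 32, 16)))
        assert out.shape == (32, 32, 16)
        assert out.spacing == (1.5, 1.5, 1.5)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(intensity_range=(1.0, 0.0))
    with pytest.raises(ValueError):
        PreprocessConfig(crop_shape=(0, 10, 10))
    with pytest.raises(ValueError):
        PreprocessConfig(target_spacing_mm=-1)
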