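"""Volume model, normalization, sparse A-scan selection and grid arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octvolsr import (
    ScanGrid,
    Volume,
    downsample_grid,
    make_triplet,
    normalize,
    nyquist_coverage,
    nyquist_min_samples,
    sampling_fraction,
)
from octvolsr.volumes import DegenerateRangeError, ShapeContractError


def vol(arr) -> Volume:
    return Volume(np.asarray(arr, dtype=np.float32))


class TestVolume:
    def test_rejects_non_3d(self):
        with pytest.raises(ValueError, match="3D"):
            Volume(np.zeros((4, 4)))

    def test_rejects_non_finite(self):
        bad = np.zeros((2, 2, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Volume(bad)


class TestNormalize:
    def test_affine_endpoints(self):
        v = normalize(vol([[[2.0, 4.0]], [[6.0, 4.0]]]))
        assert v.data.min() == 0.0 and v.data.max() == 1.0
        np.testing.assert_allclose(np.unique(v.data), [0.0, 0.5, 1.0])

    def test_identity_on_normalized(self):
        data = np.linspace(0, 1, 24, dtype=np.float32).reshape(2, 3, 4)
        np.testing.assert_array_equal(normalize(vol(data)).data, data)

    def test_constant_volume_errors(self):
        with pytest.raises(DegenerateRangeError):
            normalize(vol(np.full((2, 2, 2), 0.7)))

    def test_order_preserved(self, random_volume):
        out = normalize(random_volume)
        flat_in = random_volume.data.ravel()
        flat_out = out.data.ravel()
        assert out.data.min() == 0.0 and out.data.max() == 1.0
        # rank-comparison oracle: argsort orders must agree
        np.testing.assert_array_equal(
            np.argsort(flat_in, kind="stable"), np.argsort(flat_out, kind="stable")
        )

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        data = np.random.default_rng(seed).random((4, 5, 6)).astype(np.float32)
        once = normalize(vol(data))
        twice = normalize(once)
        np.testing.assert_array_equal(once.data, twice.data)


class TestDownsample:
    def test_acquisition_grid_selection(self):
        v = vol(np.zeros((8, 1024, 128), dtype=np.float32))
        out = downsample_grid(v, step_y=4, step_z=4)
        assert out.shape == (8, 256, 32)

    def test_unit_step_is_identity(self, random_volume):
        out = downsample_grid(random_volume, 1, 1)
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_selected_indices(self):
        data = np.broadcast_to(
            np.arange(16, dtype=np.float32)[None, :, None], (2, 16, 4)
        )
        out = downsample_grid(vol(data), step_y=4, step_z=1)
        np.testing.assert_array_equal(np.unique(out.data), [0, 4, 8, 12])

    @given(a=st.integers(1, 4), b=st.integers(1, 4))
    @settings(max_examples=16, deadline=None)
    def test_step_composition(self, a, b):
        data = np.random.default_rng(a * 7 + b).random((3, 24, 24)).astype(np.float32)
        twice = downsample_grid(downsample_grid(vol(data), a, a), b, b)
        once = downsample_grid(vol(data), a * b, a * b)
        np.testing.assert_array_equal(twice.data, once.data)

    def test_optional_prefilter_matches_filter_then_select(self, rng):
        from scipy import ndimage

        data = rng.random((4, 16, 16), dtype=np.float32)
        out = downsample_grid(vol(data), 4, 4, prefilter=True)
        expect = ndimage.gaussian_filter(data, (0, 2.0, 2.0))[:, ::4, ::4]
        np.testing.assert_allclose(out.data, expect, rtol=1e-6)
        assert not np.array_equal(out.data, data[:, ::4, ::4])

    def test_oversized_step_warns(self, caplog):
        v = vol(np.zeros((2, 4, 4), dtype=np.float32))
        with caplog.at_level("WARNING"):
            out = downsample_grid(v, step_y=10, step_z=1)
        assert out.shape[1] == 1
        assert "step" in caplog.text


class TestMakeTriplet:
    def test_desk_scale_shapes(self):
        trip = make_triplet(vol(np.zeros((64, 64, 32), dtype=np.float32)))
        assert trip.low.shape == (64, 16, 8)
        assert trip.mid.shape == (64, 64, 8)
        assert trip.high.shape == (64, 64, 32)

    def test_members_are_exact_subgrids(self, rng):
        high = vol(rng.random((8, 16, 16), dtype=np.float32))
        trip = make_triplet(high)
        np.testing.assert_array_equal(trip.low.data, high.data[:, ::4, ::4])
        np.testing.assert_array_equal(trip.mid.data, high.data[:, :, ::4])

    def test_non_divisible_errors_name_axis(self):
        with pytest.raises(ShapeContractError, match="Y"):
            make_triplet(vol(np.zeros((4, 6, 8), dtype=np.float32)))
        with pytest.raises(ShapeContractError, match="Z"):
            make_triplet(vol(np.zeros((4, 8, 6), dtype=np.float32)))

    def test_triplet_sampling_fraction_is_one_sixteenth(self):
        trip = make_triplet(vol(np.zeros((16, 32, 32), dtype=np.float32)))
        sub = ScanGrid(nx=trip.low.nx, ny=trip.low.ny, nz=trip.low.nz)
        full = ScanGrid(nx=trip.high.nx, ny=trip.high.ny, nz=trip.high.nz)
        assert sampling_fraction(sub, full) == 1 / 16


class TestGridArithmetic:
    def test_nyquist_acquisition_geometry(self):
        grid = ScanGrid()  # 7 mm field, 25.8 um lateral resolution
        assert nyquist_min_samples(grid, "Y") == 543
        assert nyquist_min_samples(grid, "Z") == 543

    def test_nyquist_single_element(self):
        grid = ScanGrid(extent_y_mm=0.0258, lateral_resolution_um=25.8)
        assert nyquist_min_samples(grid, "Y") == 2

    def test_nyquist_direct_arithmetic(self):
        grid = ScanGrid(extent_y_mm=10.0, lateral_resolution_um=50.0)
        assert nyquist_min_samples(grid, "Y") == 400

    def test_coverage_fractions(self):
        cov = nyquist_coverage(ScanGrid(ny=256, nz=32))
        assert cov["Y"] == pytest.approx(256 / 543)
        assert cov["Z"] == pytest.approx(32 / 543)

    def test_sampling_fraction_acquisition_grids(self):
        assert sampling_fraction(
            ScanGrid(nx=1024, ny=256, nz=32), ScanGrid(nx=1024, ny=1024, nz=128)
        ) == 0.0625

    def test_sampling_fraction_identity_and_half(self):
        g = ScanGrid(nx=1024, ny=1024, nz=128)
        assert sampling_fraction(g, g) == 1.0
        assert sampling_fraction(ScanGrid(nx=1024, ny=512, nz=128), g) == 0.5
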