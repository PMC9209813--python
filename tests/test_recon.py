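"""Delay-and-sum reconstruction, normalization and pair generation."""

import numpy as np
import pytest

from patkit.forward import ScanGeometry, Sinogram, Transducer, plan_scan, simulate_sinogram
from patkit.grid import preset_1ust, preset_8ust
from patkit.phantoms import PressureMap, gen_point_phantom
from patkit.recon import ReconImage, das_reconstruct, make_pair, normalize

from conftest import das_oracle


def small_sinogram(seed=0, n_pos=24, n_time=400):
    rng = np.random.default_rng(seed)
    geo = ScanGeometry(37.0, 1, n_pos, 1.0, 10.0)
    values = rng.normal(size=(n_pos, n_time))
    return Sinogram(values, 40e-9, geo, Transducer(ideal=True))


class TestDasAgainstOracle:
    @pytest.mark.parametrize("backend", ["numpy", "numba"])
    def test_matches_bruteforce_double_loop(self, backend):
        sino = small_sinogram()
        img = das_reconstruct(sino, out_size=32, backend=backend).values
        ref = das_oracle(sino, 32, 40.0)
        scale = np.abs(ref).max()
        assert np.abs(img - ref).max() <= 1e-9 * scale

    def test_backends_agree(self):
        sino = small_sinogram(seed=3)
        a = das_reconstruct(sino, out_size=64, backend="numpy").values
        b = das_reconstruct(sino, out_size=64, backend="numba").values
        assert np.abs(a - b).max() <= 1e-9 * np.abs(a).max()


class TestDasPhysics:
    def test_dense_scan_localizes_point_source(self, grid_1ust):
        pm = gen_point_phantom(grid_1ust, 1, seed=4, point_diameter_mm=0.5)
        ys, xs = np.nonzero(pm.values)
        x_mm, y_mm = grid_1ust.coords()
        cx, cy = x_mm[xs].mean(), y_mm[ys].mean()
        geo = plan_scan(480.0, 10.0)  # 4800 positions
        sino = simulate_sinogram(pm, geo, Transducer(ideal=True))
        img = das_reconstruct(sino)
        iy, ix = np.unravel_index(np.argmax(np.abs(img.values)), img.values.shape)
        pitch = img.pitch_mm
        px = (ix - 63.5) * pitch
        py = (iy - 63.5) * pitch
        assert np.hypot(px - cx, py - cy) <= 1.5 * pitch  # within one output pixel

    def test_tangential_width_grows_with_offset_under_finite_aperture(self, grid_1ust):
        """A 13 mm flat element blurs off-centre points tangentially: the
        point farther from the scan axis reconstructs wider than the near
        one, and wider than with an ideal point detector."""

        def tangential_width(r_mm, transducer):
            vals = np.zeros((grid_1ust.ny, grid_1ust.nx))
            col = int(round(r_mm / grid_1ust.dx + (grid_1ust.nx - 1) / 2))
            vals[grid_1ust.ny // 2, col] = 1.0
            sino = simulate_sinogram(
                PressureMap(grid_1ust, vals), plan_scan(10.0, 10.0), transducer
            )
            img = np.abs(das_reconstruct(sino, dtype=np.float32).values)
            iy, ix = np.unravel_index(np.argmax(img), img.shape)
            prof = img[:, ix]  # tangential direction for a point on the x axis
            return int((prof >= 0.5 * prof[iy]).sum())

        ap = Transducer(aperture_mm=13.0)
        assert tangential_width(15.0, ap) > tangential_width(5.0, ap)
        assert tangential_width(15.0, ap) > tangential_width(15.0, Transducer(ideal=True))

    def test_zero_sinogram_gives_zero_image(self):
        sino = small_sinogram()
        zero = Sinogram(np.zeros_like(sino.values), sino.dt, sino.geometry, sino.transducer)
        assert not das_reconstruct(zero).values.any()

    def test_inconsistent_geometry_rejected(self):
        sino = small_sinogram()
        bad_geo = ScanGeometry(37.0, 1, sino.geometry.positions_per_ust + 1, 1.0, 10.0)
        bad = Sinogram(sino.values, sino.dt, bad_geo, sino.transducer)
        with pytest.raises(ValueError):
            das_reconstruct(bad)


class TestNormalize:
    def test_symmetric_bipolar_maps_to_unit_interval(self):
        img = ReconImage(np.array([[-2.0, 0.0], [2.0, 2.0]]), 0.3125)
        out = normalize(img).values
        np.testing.assert_allclose(out, [[0.0, 0.5], [1.0, 1.0]])

    def test_already_normalized_unchanged(self):
        vals = np.array([[0.0, 0.25], [0.75, 1.0]])
        np.testing.assert_allclose(normalize(ReconImage(vals, 0.3125)).values, vals)

    def test_output_range_exact(self):
        rng = np.random.default_rng(0)
        out = normalize(ReconImage(rng.normal(size=(16, 16)), 0.3125)).values
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            normalize(ReconImage(np.full((4, 4), 3.0), 0.3125))


class TestMakePair:
    def test_1ust_pair_contract(self, grid_1ust):
        pm = gen_point_phantom(grid_1ust, 5, seed=2)
        x, y = make_pair(pm, preset_1ust(), seed=1, scan_time_input=3.0, dtype=np.float32)
        assert x.values.shape == (128, 128) and y.values.shape == (128, 128)
        assert x.normalized and y.normalized
        assert x.values.min() == 0.0 and x.values.max() == 1.0

    def test_identical_seeds_identical_pairs(self, grid_1ust):
        pm = gen_point_phantom(grid_1ust, 5, seed=2)
        x1, y1 = make_pair(pm, preset_1ust(), seed=9, dtype=np.float32)
        x2, y2 = make_pair(pm, preset_1ust(), seed=9, dtype=np.float32)
        np.testing.assert_array_equal(x1.values, x2.values)
        np.testing.assert_array_equal(y1.values, y2.values)

    def test_8ust_pair_end_to_end(self):
        """Eight-transducer preset: 240-position noisy input against the
        1600-position ideal ground truth, on the 0.1 mm grid."""
        from patkit.phantoms import gen_vessel_phantom

        preset = preset_8ust()
        pm = gen_vessel_phantom(preset.grid, seed=5)
        x, y = make_pair(pm, preset, seed=3, dtype=np.float32)
        assert x.values.shape == (128, 128) and y.values.shape == (128, 128)
        assert x.normalized and y.normalized
        assert y.values.min() == 0.0 and y.values.max() == 1.0

    def test_preset_position_counts(self):
        p1 = preset_1ust()
        assert plan_scan(5.0, p1.prr, p1.n_ust, averaging_factor=p1.averaging_factor).n_positions == 50
        assert plan_scan(p1.gt_duration, p1.prr).n_positions == 4800
        p8 = preset_8ust()
        geo_in = plan_scan(0.3, p8.prr, p8.n_ust, averaging_factor=p8.averaging_factor)
        assert geo_in.n_positions == 240 and geo_in.positions_per_ust == 30
        assert p8.gt_positions == 1600
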