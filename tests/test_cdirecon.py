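import numpy as np
import pytest

from mreitep import (BzMap, Grid, MU0, ParameterError, magnitude,
                     recover_current_bz, recover_current_full)
from mreitep.cdirecon import central_divergence
from mreitep.forward import CurrentDensityField
from mreitep.benchmarks import cdi_roundtrip_benchmark


class TestSingleComponentRecovery:
    def test_linear_bz_gives_uniform_current(self):
        grid = Grid.square(32, 1.0)
        _, y = grid.coords()
        bz = BzMap(grid=grid, bz=MU0 * 10.0 * y)
        J = recover_current_bz(bz)
        assert np.allclose(J.J[..., 0], 10.0, atol=1e-9)
        assert np.allclose(J.J[..., 1], 0.0, atol=1e-9)
        assert J.provenance == "cdi_recovered"

    def test_constant_bz_gives_zero(self):
        grid = Grid.square(32, 1.0)
        bz = BzMap(grid=grid, bz=np.full(grid.shape, 3.3e-6))
        assert np.abs(recover_current_bz(bz).J).max() < 1e-12

    def test_gauge_invariance(self):
        J, _ = _smooth_current(64)
        bz = _bz_of(J)
        J1 = recover_current_bz(bz)
        shifted = BzMap(grid=bz.grid, bz=bz.bz + np.abs(bz.bz).max())
        J2 = recover_current_bz(shifted)
        assert np.abs(J2.J - J1.J).max() <= 1e-9 * np.abs(J1.J).max()

    def test_roundtrip_second_order(self):
        bench = cdi_roundtrip_benchmark(levels=(64, 128))
        assert bench["rel_l2"][128] < 0.01
        assert bench["rel_l2"][128] < bench["rel_l2"][64] / 3

    def test_mask_zeroes_exterior(self):
        grid = Grid.square(32, 1.0)
        _, y = grid.coords()
        bz = BzMap(grid=grid, bz=MU0 * y)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[8:24, 8:24] = True
        J = recover_current_bz(bz, mask=mask)
        assert np.all(J.J[~mask] == 0.0)
        assert np.all(J.J[mask][:, 0] != 0.0)

    def test_3d_grid_rejected(self):
        grid = Grid(shape=(16, 16, 16), spacing=(1e-3,) * 3)
        bz = BzMap(grid=grid, bz=np.zeros(grid.shape))
        with pytest.raises(ParameterError):
            recover_current_bz(bz)


class TestFullRecovery:
    @pytest.fixture()
    def grid3(self):
        return Grid(shape=(24, 24, 24), spacing=(1.0 / 24,) * 3,
                    origin=(-0.5, -0.5, -0.5))

    def test_single_term_curl(self, grid3):
        x, y, z = grid3.coords()
        J0 = 7.0
        J = recover_current_full(np.zeros(grid3.shape),
                                 np.zeros(grid3.shape),
                                 MU0 * J0 * y, grid3)
        assert np.allclose(J.J[..., 0], J0, atol=1e-9)
        assert np.allclose(J.J[..., 1:], 0.0, atol=1e-9)

    def test_gradient_field_has_zero_curl(self, grid3):
        x, y, z = grid3.coords()
        f = np.sin(2 * x) * np.cos(3 * y) * np.exp(z)
        h = grid3.spacing[0]
        from mreitep.fieldsim import central_gradient
        gx = central_gradient(f, grid3.spacing[0], 0)
        gy = central_gradient(f, grid3.spacing[1], 1)
        gz = central_gradient(f, grid3.spacing[2], 2)
        J = recover_current_full(gx, gy, gz, grid3)
        gmax = max(np.abs(gx).max(), np.abs(gy).max(), np.abs(gz).max())
        # curl of a (discrete) gradient: only truncation remains
        inner = (slice(2, -2),) * 3
        assert np.abs(J.J[inner]).max() * MU0 <= 1e-2 * gmax / h * h

    def test_div_of_curl_vanishes(self, grid3):
        rng = np.random.default_rng(5)
        bx, by, bz = (rng.normal(0, 1e-6, grid3.shape) for _ in range(3))
        J = recover_current_full(bx, by, bz, grid3)
        div = central_divergence(J)
        inner = (slice(2, -2),) * 3
        assert np.abs(div[inner]).max() <= 1e-10 * J.magnitude().max()

    def test_shape_mismatch(self, grid3):
        with pytest.raises(ParameterError):
            recover_current_full(np.zeros((8, 8, 8)), np.zeros(grid3.shape),
                                 np.zeros(grid3.shape), grid3)


class TestMagnitude:
    def test_euclidean_norm(self):
        grid = Grid.square(8, 1.0)
        J = np.zeros((8, 8, 2))
        J[..., 0], J[..., 1] = 3.0, 4.0
        assert np.allclose(
            magnitude(CurrentDensityField(grid=grid, J=J)), 5.0)

    def test_rotation_invariance(self):
        grid = Grid.square(8, 1.0)
        rng = np.random.default_rng(0)
        v = rng.normal(size=(8, 8, 2))
        th = 0.73
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        vr = v @ R.T
        m1 = magnitude(CurrentDensityField(grid=grid, J=v))
        m2 = magnitude(CurrentDensityField(grid=grid, J=vr))
        assert np.allclose(m1, m2)


class TestAccuracyOrder:
    def test_second_order_on_analytic_field(self):
        errs = []
        for n in (32, 64, 128):
            grid = Grid.square(n, 1.0, origin=(-0.5, -0.5))
            x, y = grid.coords()
            bz = BzMap(grid=grid, bz=MU0 * np.sin(3 * x) * np.cos(2 * y))
            J = recover_current_bz(bz)
            jx_true = -2 * np.sin(3 * x) * np.sin(2 * y)
            jy_true = -3 * np.cos(3 * x) * np.cos(2 * y)
            err = max(np.abs(J.J[..., 0] - jx_true).max(),
                      np.abs(J.J[..., 1] - jy_true).max())
            errs.append(err)
        slope = np.polyfit(np.log([1 / 32, 1 / 64, 1 / 128]),
                           np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)


def _smooth_current(n):
    from mreitep.benchmarks import _gaussian_stream_current
    return _gaussian_stream_current(n)


def _bz_of(J):
    from mreitep import bz_from_current_2d
    return bz_from_current_2d(J)
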