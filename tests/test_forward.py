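import numpy as np
import pytest

from mreitep import (ConductivityMap, ConfigurationError, Electrode,
                     ElectrodeConfig, Grid, ParameterError, PhantomSpec,
                     build_phantom, current_density, electric_field,
                     electrode_current, flux_divergence, solve_potential)
from mreitep.benchmarks import annulus_benchmark


class TestParallelPlate:
    def test_linear_potential_exact(self, unit_square):
        grid, sigma_map, electrodes = unit_square
        u = solve_potential(sigma_map, electrodes)
        n = grid.shape[0]
        expected = 1.0 - np.arange(n) / (n - 1)
        assert np.abs(u.u - expected[:, None]).max() < 1e-10

    def test_uniform_current_and_field(self, unit_square):
        grid, sigma_map, electrodes = unit_square
        u = solve_potential(sigma_map, electrodes)
        J = current_density(sigma_map, u)
        E = electric_field(u)
        interior = J.J[2:-2, 2:-2]
        assert np.allclose(interior[..., 0], 1.0, atol=1e-10)
        assert np.allclose(interior[..., 1], 0.0, atol=1e-10)
        assert np.allclose(E.magnitude[2:-2, 2:-2], 1.0, atol=1e-10)

    def test_current_scales_with_sigma(self, unit_square):
        grid, sigma_map, electrodes = unit_square
        u = solve_potential(sigma_map, electrodes)
        J1 = current_density(sigma_map, u)
        doubled = ConductivityMap(grid, 2 * sigma_map.sigma, sigma_map.mask)
        J2 = current_density(doubled, u)
        assert np.allclose(J2.J, 2 * J1.J)


@pytest.fixture(scope="module")
def bench():
    return annulus_benchmark(levels=(64, 128))


class TestAnnulusOracle:
    """Closed-form coaxial solution u(r) = U ln(b/r)/ln(b/a)."""

    def test_potential_error_small(self, bench):
        assert bench["rel_l2"][128] < 0.01

    def test_error_drops_under_refinement(self, bench):
        assert bench["rel_l2"][128] < bench["rel_l2"][64] / 3

    def test_current_density_and_field_closed_form(self, bench):
        assert bench["j_rel_l2"] < 0.02
        assert bench["e_rel_l2"] < 0.02

    def test_total_current_closed_form(self, bench):
        assert bench["current_rel_err"] < 0.02


class TestLinearityAndConservation:
    def test_voltage_linearity(self, disc_forward):
        d = disc_forward
        doubled = ElectrodeConfig(d["electrodes"].electrodes,
                                  2 * d["electrodes"].voltage)
        u2 = solve_potential(d["sigma"], doubled)
        assert np.allclose(u2.u, 2 * d["u"].u, atol=1e-8 * d["u"].u.max())

    def test_interior_divergence_free(self, disc_forward):
        d = disc_forward
        div = flux_divergence(d["J"])
        interior = d["u"].labels == 0
        jmax = d["J"].magnitude().max()
        h = d["grid"].spacing[0]
        assert np.abs(div[interior]).max() * h <= 1e-8 * jmax

    def test_current_balance(self, disc_forward):
        d = disc_forward
        ia = electrode_current(d["J"], d["electrodes"], 1)
        ic = electrode_current(d["J"], d["electrodes"], 2)
        assert abs(ia + ic) <= 1e-6 * abs(ia)

    def test_inactive_electrode_carries_no_current(self):
        spec = PhantomSpec.exvivo_liver_4electrode(active_pair=(1, 2))
        grid = Grid.square(64, 30e-3)
        sigma_map, electrodes = build_phantom(spec, grid)
        u = solve_potential(sigma_map, electrodes)
        J = current_density(sigma_map, u)
        assert electrode_current(J, electrodes, 4) == 0.0

    def test_unknown_electrode_id(self, disc_forward):
        d = disc_forward
        with pytest.raises(KeyError):
            electrode_current(d["J"], d["electrodes"], 99)


class TestMaximumPrinciple:
    def test_extrema_on_electrodes(self, disc_forward):
        d = disc_forward
        u = d["u"]
        interior = u.labels == 0
        U = d["electrodes"].voltage
        assert u.u[interior].min() > 0.0
        assert u.u[interior].max() < U
        assert u.u[u.labels >= 1].max() == pytest.approx(U)

    def test_field_peaks_near_electrodes(self, disc_forward):
        d = disc_forward
        E = electric_field(d["u"])
        grid = d["grid"]
        x, y = grid.coords()
        near = np.zeros(grid.shape, dtype=bool)
        for e in d["electrodes"].electrodes:
            r = np.hypot(x - e.center[0], y - e.center[1])
            near |= (r <= e.radius + 2 * grid.spacing[0])
        inside = d["sigma"].mask & (d["u"].labels == 0)
        assert E.magnitude[inside & near].max() > \
            2 * E.magnitude[inside & ~near].max()


class TestErrors:
    def test_no_active_electrodes_in_mask(self):
        grid = Grid.square(32, 30e-3)
        x, y = grid.coords()
        mask = np.hypot(x - 15e-3, y - 15e-3) < 5e-3
        sigma_map = ConductivityMap(grid, np.full(grid.shape, 0.1), mask)
        far = ElectrodeConfig(
            [Electrode(1, (1e-3, 1e-3), 0.8e-3, "anode"),
             Electrode(2, (29e-3, 29e-3), 0.8e-3, "cathode")], 100.0)
        with pytest.raises(ConfigurationError):
            solve_potential(sigma_map, far)

    def test_bad_tolerance(self, disc_forward):
        d = disc_forward
        with pytest.raises(ParameterError):
            solve_potential(d["sigma"], d["electrodes"], tol=1e-2)

    def test_grid_mismatch(self, disc_forward):
        d = disc_forward
        other = Grid.square(32, 30e-3)
        wrong = ConductivityMap(other, np.full(other.shape, 0.1),
                                np.ones(other.shape, dtype=bool))
        with pytest.raises(ParameterError):
            current_density(wrong, d["u"])


class TestSolver3D:
    def test_slab_parallel_plate(self):
        n = 16
        grid = Grid(shape=(n, n, 8), spacing=(1.0 / (n - 1),) * 3)
        mask = np.ones(grid.shape, dtype=bool)
        left = np.zeros(grid.shape, dtype=bool)
        left[0] = True
        right = np.zeros(grid.shape, dtype=bool)
        right[-1] = True
        electrodes = ElectrodeConfig(
            [Electrode(1, (0, 0, 0), 1.0, "anode", cells=left),
             Electrode(2, (0, 0, 0), 1.0, "cathode", cells=right)], 1.0)
        sigma_map = ConductivityMap(grid, np.ones(grid.shape), mask)
        u = solve_potential(sigma_map, electrodes)
        expected = 1.0 - np.arange(n) / (n - 1)
        assert np.abs(u.u - expected[:, None, None]).max() < 1e-10
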