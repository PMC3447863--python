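import numpy as np
import pytest

from mreitep import (ConductivityMap, Electrode, ElectrodeConfig, Grid,
                     ParameterError, PhantomSpec, ReconstructionConfig,
                     build_phantom, current_density, electric_field,
                     jsub_reconstruct, reconstruct_efield, solve_potential,
                     update_conductivity)
from mreitep.forward import CurrentDensityField
from mreitep.pipeline import electrode_exclusion_mask
from mreitep.benchmarks import sigma_recovery_benchmark, two_region_spec_64


class TestUpdateRule:
    def test_fixed_point_when_magnitudes_match(self, disc_forward):
        d = disc_forward
        jm = d["J"].magnitude()
        out = update_conductivity(d["sigma"], jm, jm)
        assert np.array_equal(out.sigma, d["sigma"].sigma)

    def test_direct_ratio_arithmetic(self):
        grid = Grid.square(8, 1.0)
        mask = np.ones(grid.shape, dtype=bool)
        sig = ConductivityMap(grid, np.full(grid.shape, 0.2), mask)
        out = update_conductivity(sig, np.full(grid.shape, 100.0),
                                  np.full(grid.shape, 50.0))
        assert np.allclose(out.sigma, 0.4)

    def test_clamping(self):
        grid = Grid.square(8, 1.0)
        mask = np.ones(grid.shape, dtype=bool)
        sig = ConductivityMap(grid, np.full(grid.shape, 1.0), mask)
        out = update_conductivity(sig, np.full(grid.shape, 100.0),
                                  np.full(grid.shape, 1.0),
                                  sigma_cap=10.0)
        assert np.all(out.sigma == 10.0)

    def test_weak_current_cells_untouched(self):
        grid = Grid.square(8, 1.0)
        mask = np.ones(grid.shape, dtype=bool)
        sig = ConductivityMap(grid, np.full(grid.shape, 0.2), mask)
        jk = np.full(grid.shape, 50.0)
        jk[0, 0] = 1e-9  # below the information floor
        out = update_conductivity(sig, np.full(grid.shape, 100.0), jk)
        assert out.sigma[0, 0] == 0.2
        assert np.allclose(out.sigma[1:, 1:], 0.4)

    def test_self_consistency_no_drift(self, disc_forward):
        """Feeding the model's own |J| keeps the true sigma fixed."""
        d = disc_forward
        jm = d["J"].magnitude()
        sigma_map = d["sigma"].copy()
        for _ in range(10):
            u = solve_potential(sigma_map, d["electrodes"])
            jk = current_density(sigma_map, u).magnitude()
            sigma_map = update_conductivity(sigma_map, jm, jk)
        drift = np.abs(sigma_map.sigma[sigma_map.mask]
                       - d["sigma"].sigma[sigma_map.mask]) / 0.1
        assert drift.max() <= 1e-3


@pytest.fixture(scope="module")
def bench():
    return sigma_recovery_benchmark()


class TestInverseCrimeRecovery:
    def test_homogeneous_disc(self, bench):
        h = bench["homogeneous"]
        assert h["converged"] and h["iterations"] <= 50
        assert h["median_rel_err"] <= 0.02

    def test_two_region_plateaus(self, bench):
        t = bench["two_region"]
        assert t["converged"] and t["iterations"] <= 50
        assert t["median_rel_err"]["tumor"] <= 0.05
        assert t["median_rel_err"]["liver"] <= 0.05

    def test_stopping_contract(self):
        spec = PhantomSpec.homogeneous_disc(sigma=0.1, voltage=1000.0)
        grid = Grid.square(64, 30e-3)
        sigma_true, electrodes = build_phantom(spec, grid)
        u = solve_potential(sigma_true, electrodes)
        j = current_density(sigma_true, u)
        res = jsub_reconstruct(j, electrodes,
                               ReconstructionConfig(sigma_init=0.05),
                               mask=sigma_true.mask)
        assert len(res.history) == res.iterations
        assert res.converged
        assert res.history[-1] < 0.01

    def test_monotone_residual_trend(self):
        spec, grid = two_region_spec_64()
        sigma_true, electrodes = build_phantom(spec, grid)
        u = solve_potential(sigma_true, electrodes)
        j = current_density(sigma_true, u)
        res = jsub_reconstruct(j, electrodes, ReconstructionConfig(),
                               mask=sigma_true.mask)
        r = res.residual_history
        increases = sum(r[i + 1] > r[i] for i in range(len(r) - 1))
        assert increases <= 1

    def test_scale_anchoring(self):
        """Scaling true sigma by c scales |J| by c and the reconstruction
        recovers the absolute level c*sigma (voltage data anchor it)."""
        grid = Grid.square(64, 30e-3)
        meds = []
        for c in (1.0, 2.0):
            spec = PhantomSpec.homogeneous_disc(sigma=0.1 * c,
                                                voltage=1000.0)
            sigma_true, electrodes = build_phantom(spec, grid)
            u = solve_potential(sigma_true, electrodes)
            j = current_density(sigma_true, u)
            res = jsub_reconstruct(
                j, electrodes, ReconstructionConfig(sigma_init=0.05),
                mask=sigma_true.mask)
            roi = sigma_true.mask & ~electrode_exclusion_mask(
                grid, electrodes, 2e-3)
            meds.append(np.median(res.sigma_mreit.sigma[roi]))
        assert meds[1] / meds[0] == pytest.approx(2.0, rel=1e-3)


class TestNonUniqueness:
    def test_series_profiles_share_current_density(self, unit_square):
        """Two distinct layered conductivities with equal series
        resistance produce the same current everywhere: single-direction
        |J| data cannot distinguish them."""
        grid, sigma_map, electrodes = unit_square
        n = grid.shape[0]
        sig_a = np.full(grid.shape, 0.1)
        sig_b = np.where(np.arange(n)[:, None] < n // 2, 0.075, 0.15) \
            * np.ones(grid.shape)
        # equal integral of 1/sigma across the plates
        assert (1 / sig_a).sum() == pytest.approx((1 / sig_b).sum())
        mags = []
        for s in (sig_a, sig_b):
            sm = ConductivityMap(grid, s, sigma_map.mask)
            u = solve_potential(sm, electrodes)
            mags.append(current_density(sm, u).magnitude())
        inner = (slice(2, -2), slice(None))
        assert np.abs(sig_a - sig_b).max() > 0.02  # clearly distinct maps
        assert np.abs(mags[0][inner] - mags[1][inner]).max() \
            <= 1e-6 * mags[0][inner].max()


class TestOhmsLawField:
    def test_arithmetic(self):
        grid = Grid.square(8, 1.0)
        mask = np.ones(grid.shape, dtype=bool)
        sig = ConductivityMap(grid, np.full(grid.shape, 0.4), mask)
        J = np.zeros((8, 8, 2))
        J[..., 0] = 200.0
        e = reconstruct_efield(CurrentDensityField(grid=grid, J=J), sig)
        assert np.allclose(e.magnitude, 500.0)
        sig2 = ConductivityMap(grid, np.full(grid.shape, 0.8), mask)
        e2 = reconstruct_efield(CurrentDensityField(grid=grid, J=J), sig2)
        assert np.allclose(e2.magnitude, 250.0)

    def test_sigma_below_floor_rejected(self):
        grid = Grid.square(8, 1.0)
        mask = np.ones(grid.shape, dtype=bool)
        sig = ConductivityMap(grid, np.full(grid.shape, 1e-5), mask)
        J = CurrentDensityField(grid=grid, J=np.ones((8, 8, 2)))
        with pytest.raises(ParameterError):
            reconstruct_efield(J, sig, sigma_floor=1e-4)

    def test_matches_forward_field_on_forward_solution(self):
        spec = PhantomSpec.tumor_region()
        grid = Grid.square(128, 60e-3)
        sigma_true, electrodes = build_phantom(spec, grid)
        u = solve_potential(sigma_true, electrodes)
        j = current_density(sigma_true, u)
        e_fwd = electric_field(u)
        e_ohm = reconstruct_efield(j, sigma_true)
        sel = sigma_true.mask & (e_fwd.magnitude > 0)
        rel = np.abs(e_ohm.magnitude[sel] - e_fwd.magnitude[sel]) \
            / e_fwd.magnitude.max()
        assert rel.max() <= 1e-8


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [dict(tol=0.0), dict(max_iter=0),
                                    dict(sigma_floor=1.0, sigma_cap=0.5),
                                    dict(change_norm="bogus")])
    def test_invalid_configs(self, kw):
        with pytest.raises(ParameterError):
            ReconstructionConfig(**kw)

    def test_scalar_init_requires_mask(self, disc_forward):
        d = disc_forward
        with pytest.raises(ParameterError):
            jsub_reconstruct(d["J"], d["electrodes"],
                             ReconstructionConfig())
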