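import numpy as np
import pytest

from mreitep import (AcquisitionParams, BzMap, GAMMA_PROTON, Grid, MU0,
                     ParameterError, add_phase_noise, bz_biot_savart_slab,
                     bz_from_current_2d, decode_phase, encode_phase,
                     unwrap_phase)
from mreitep.forward import CurrentDensityField
from mreitep.benchmarks import _gaussian_stream_current, loop_current


@pytest.fixture(scope="module")
def acq():
    return AcquisitionParams()


class TestAcquisitionParams:
    def test_tc_is_pulse_train_duration(self, acq):
        assert acq.t_c == pytest.approx(400e-6)

    def test_positive_required(self):
        with pytest.raises(ParameterError):
            AcquisitionParams(n_pulses=0)


class TestBzSynthesis:
    def test_zero_current_gives_zero_field(self):
        grid = Grid.square(32, 1.0)
        J = CurrentDensityField(grid=grid, J=np.zeros((32, 32, 2)))
        bz = bz_from_current_2d(J)
        assert np.allclose(bz.bz, 0.0)

    def test_stream_function_identity(self):
        J, psi = _gaussian_stream_current(128)
        bz = bz_from_current_2d(J)
        dev = bz.bz - MU0 * psi
        dev -= np.median(dev)
        assert np.abs(dev).max() <= 1e-3 * MU0 * psi.max()

    def test_linearity_in_current(self):
        J, _ = _gaussian_stream_current(64)
        bz1 = bz_from_current_2d(J)
        J2 = CurrentDensityField(grid=J.grid, J=2 * J.J)
        bz2 = bz_from_current_2d(J2)
        assert np.allclose(bz2.bz, 2 * bz1.bz, atol=1e-12 * np.abs(bz1.bz).max())

    def test_three_component_rejected(self):
        grid = Grid.square(16, 1.0)
        J = CurrentDensityField(grid=grid, J=np.zeros((16, 16, 3)))
        with pytest.raises(ParameterError):
            bz_from_current_2d(J)

    def test_nonsolenoidal_input_warns(self):
        grid = Grid.square(32, 1.0, origin=(-0.5, -0.5))
        x, y = grid.coords()
        # pure source flow: divergent, carries no vorticity
        r2 = np.maximum(x ** 2 + y ** 2, 1e-4)
        J = CurrentDensityField(
            grid=grid, J=np.stack([x / r2, y / r2], axis=-1))
        bz = bz_from_current_2d(J)
        assert bz.warnings


class TestBiotSavartSlab:
    def test_antisymmetric_about_single_cell(self):
        grid = Grid.square(32, 1.0)
        J = np.zeros((32, 32, 2))
        c = 16
        J[c, c, 0] = 1.0
        bz = bz_biot_savart_slab(
            CurrentDensityField(grid=grid, J=J), thickness=0.5)
        # mirror through the source cell: B_z flips sign (relative to the
        # gauge value at the source cell, where the self-term vanishes)
        b0 = bz.bz[c, c]
        for d in (3, 7):
            assert bz.bz[c, c + d] - b0 == pytest.approx(
                -(bz.bz[c, c - d] - b0), rel=1e-9)

    def test_linearity(self):
        J = loop_current(24)
        b1 = bz_biot_savart_slab(J, thickness=0.1)
        b2 = bz_biot_savart_slab(
            CurrentDensityField(grid=J.grid, J=2 * J.J), thickness=0.1)
        assert np.allclose(b2.bz, 2 * b1.bz, atol=1e-15)

    def test_size_guard(self):
        grid = Grid.square(128, 1.0)
        J = CurrentDensityField(grid=grid, J=np.zeros((128, 128, 2)))
        with pytest.raises(ParameterError):
            bz_biot_savart_slab(J, thickness=0.1)

    def test_thicker_slab_approaches_planar_limit(self):
        from mreitep.benchmarks import biot_savart_benchmark
        thin = biot_savart_benchmark(thickness=0.05)["rel_l2_away"]
        thick = biot_savart_benchmark(thickness=0.4)["rel_l2_away"]
        assert thick < thin


class TestPhaseChannel:
    def test_encode_reference_value(self, acq):
        grid = Grid.square(8, 1.0)
        bz = BzMap(grid=grid, bz=np.full((8, 8), 1e-6))
        phi = encode_phase(bz, acq)
        # gamma * 1 uT * 400 us with the standard proton gamma
        assert phi.phi[0, 0] == pytest.approx(0.10701, abs=5e-5)

    def test_round_trip_identity(self, acq):
        rng = np.random.default_rng(7)
        grid = Grid.square(32, 1.0)
        for _ in range(100):
            bz = BzMap(grid=grid, bz=rng.normal(0, 1e-6, (32, 32)))
            back = decode_phase(encode_phase(bz, acq), acq)
            assert np.abs(back.bz - bz.bz).max() <= 1e-12

    def test_decode_linearity(self, acq):
        grid = Grid.square(16, 1.0)
        from mreitep.fieldsim import PhaseImage
        phi = PhaseImage(grid=grid, phi=np.linspace(
            0, 1, 256).reshape(16, 16))
        b1 = decode_phase(phi, acq)
        phi2 = PhaseImage(grid=grid, phi=2 * phi.phi)
        b2 = decode_phase(phi2, acq)
        assert np.allclose(b2.bz, 2 * b1.bz)

    def test_wrapped_decode_rejected(self, acq):
        grid = Grid.square(16, 1.0)
        bz = BzMap(grid=grid, bz=np.full((16, 16), 1e-4))
        phi = encode_phase(bz, acq, wrap=True)
        with pytest.raises(ParameterError):
            decode_phase(phi, acq)

    def test_unwrap_recovers_smooth_phase(self, acq):
        J, psi = _gaussian_stream_current(64)
        bz = BzMap(grid=J.grid, bz=40e-6 * psi)  # several wraps
        wrapped = encode_phase(bz, acq, wrap=True)
        unwrapped = unwrap_phase(wrapped)
        back = decode_phase(unwrapped, acq)
        dev = back.bz - bz.bz
        dev -= np.median(dev)
        assert np.abs(dev).max() < 1e-9


class TestPhaseNoise:
    def test_vanishing_noise(self):
        grid = Grid.square(16, 1.0)
        from mreitep.fieldsim import PhaseImage
        phi = PhaseImage(grid=grid, phi=np.zeros((16, 16)))
        out = add_phase_noise(phi, snr=1e12, seed=0)
        assert np.abs(out.phi).max() < 1e-10

    def test_seed_determinism(self):
        grid = Grid.square(16, 1.0)
        from mreitep.fieldsim import PhaseImage
        phi = PhaseImage(grid=grid, phi=np.zeros((16, 16)))
        a = add_phase_noise(phi, snr=10.0, seed=42)
        b = add_phase_noise(phi, snr=10.0, seed=42)
        assert np.array_equal(a.phi, b.phi)

    def test_noise_level(self):
        grid = Grid.square(64, 1.0)
        from mreitep.fieldsim import PhaseImage
        phi = PhaseImage(grid=grid, phi=np.zeros((64, 64)))
        out = add_phase_noise(phi, snr=20.0, seed=3)
        assert out.phi.std() == pytest.approx(1 / 20.0, rel=0.05)

    def test_invalid_snr(self):
        grid = Grid.square(16, 1.0)
        from mreitep.fieldsim import PhaseImage
        phi = PhaseImage(grid=grid, phi=np.zeros((16, 16)))
        with pytest.raises(ParameterError):
            add_phase_noise(phi, snr=0.0, seed=0)
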