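import numpy as np
import pytest

from mreitep import (ConductivityMap, Electrode, ElectrodeConfig, Grid,
                     PhantomSpec, build_phantom, current_density,
                     solve_potential)


@pytest.fixture(scope="session")
def disc_forward():
    """Homogeneous 20 mm disc with an axial needle pair, solved once."""
    spec = PhantomSpec.homogeneous_disc(sigma=0.1, voltage=1000.0)
    grid = Grid.square(64, 30e-3)
    sigma_map, electrodes = build_phantom(spec, grid)
    u = solve_potential(sigma_map, electrodes)
    J = current_density(sigma_map, u)
    return dict(spec=spec, grid=grid, sigma=sigma_map,
                electrodes=electrodes, u=u, J=J)


@pytest.fixture()
def unit_square():
    """Unit 'parallel-plate' sample: Dirichlet strips on the left/right
    cell columns, insulated top/bottom; plate separation is exactly 1 m
    between the strip centers so the analytic solution is u(x) = 1 - x."""
    n = 32
    grid = Grid.square(n, n / (n - 1))
    mask = np.ones((n, n), dtype=bool)
    left = np.zeros((n, n), dtype=bool)
    left[0, :] = True
    right = np.zeros((n, n), dtype=bool)
    right[-1, :] = True
    electrodes = ElectrodeConfig(
        [Electrode(1, (0.0, 0.0), 1.0, "anode", cells=left),
         Electrode(2, (0.0, 0.0), 1.0, "cathode", cells=right)],
        voltage=1.0)
    sigma_map = ConductivityMap(grid, np.ones((n, n)), mask)
    return grid, sigma_map, electrodes
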