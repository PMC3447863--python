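"""Current density imaging recovery: J from magnetic flux density.

Two routes are provided.  With all three components of the current-induced
field available (which requires rotating the sample), Ampere's law gives
J = curl(B) / mu0.  Without rotation only B_z is measurable; for planar
currents the in-plane components of the curl reduce to

    J_CDI = (1/mu0) * (dBz/dy, -dBz/dx),

which is the single-component recovery used during treatment monitoring.

All derivatives are second-order finite differences (central in the
interior, one-sided at boundaries).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .geometry import Grid, ParameterError
from .fieldsim import BzMap, MU0, central_gradient, monopole_source_field
from .forward import CurrentDensityField

__all__ = [
    "recover_current_bz",
    "recover_current_full",
    "magnitude",
    "central_divergence",
]


def _as_array(b: Union[BzMap, np.ndarray]) -> np.ndarray:
    return b.bz if isinstance(b, BzMap) else np.asarray(b, dtype=float)


def recover_current_bz(bz: BzMap, mask: Optional[np.ndarray] = None,
                       presmooth_sigma: float = 0.0,
                       sources=None) -> CurrentDensityField:
    """Single-component CDI recovery: J = (dBz/dy, -dBz/dx) / mu0.

    Parameters
    ----------
    bz
        Measured (or synthesized) B_z map on a 2D grid.  The additive gauge
        constant drops out of the derivatives.
    mask
        Optional sample mask; cells outside are zeroed after
        differentiation, which suppresses edge spikes where the exterior
        gauge plateau meets the sample.
    presmooth_sigma
        Optional Gaussian smoothing (in cells) applied to B_z before
        differentiation, for noisy data.  Default off.
    sources
        Optional ``(center, current, radius)`` per active needle.  B_z
        carries no trace of the irrotational monopole flow the needles
        feed into the plane; when the electrode positions and the
        generator-measured current are supplied, that component is
        restored analytically after differentiation (inside the mask).
    """
    if bz.grid.ndim != 2:
        raise ParameterError("single-component recovery is defined on 2D grids")
    field = bz.bz
    if presmooth_sigma > 0:
        from scipy.ndimage import gaussian_filter
        field = gaussian_filter(field, presmooth_sigma)
    hx, hy = bz.grid.spacing
    jx = central_gradient(field, hy, 1) / MU0
    jy = -central_gradient(field, hx, 0) / MU0
    J = np.stack([jx, jy], axis=-1)
    if sources:
        J += monopole_source_field(bz.grid, sources)
    if mask is not None:
        J[~np.asarray(mask, dtype=bool)] = 0.0
    return CurrentDensityField(grid=bz.grid, J=J, provenance="cdi_recovered",
                               mask=mask)


def recover_current_full(bx, by, bz, grid: Grid) -> CurrentDensityField:
    """Full Ampere's-law recovery J = curl(B) / mu0 from three co-registered
    3D field components (the rotate-the-sample acquisition)."""
    if grid.ndim != 3:
        raise ParameterError("full recovery needs a 3D grid")
    comps = [_as_array(b) for b in (bx, by, bz)]
    for c in comps:
        if c.shape != grid.shape:
            raise ParameterError("field components must match the grid shape")
    hx, hy, hz = grid.spacing
    bxa, bya, bza = comps
    jx = central_gradient(bza, hy, 1) - central_gradient(bya, hz, 2)
    jy = central_gradient(bxa, hz, 2) - central_gradient(bza, hx, 0)
    jz = central_gradient(bya, hx, 0) - central_gradient(bxa, hy, 1)
    J = np.stack([jx, jy, jz], axis=-1) / MU0
    return CurrentDensityField(grid=grid, J=J, provenance="cdi_recovered")


def magnitude(J: CurrentDensityField) -> np.ndarray:
    """Euclidean norm of J per cell (A/m^2)."""
    return J.magnitude()


def central_divergence(J: CurrentDensityField) -> np.ndarray:
    """Divergence of J by the same second-order differences used for the
    recovery; with central interior stencils, div(curl(.)) cancels to
    rounding on interior cells."""
    grid = J.grid
    out = np.zeros(grid.shape)
    for a in range(grid.ndim):
        out += central_gradient(J.J[..., a], grid.spacing[a], a)
    return out
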