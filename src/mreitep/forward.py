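"""Forward electrostatics: potential, current density and electric field.

Solves the generalized Laplace problem div(sigma grad u) = 0 on the sample
body with mixed boundary conditions: the driven electrodes are equipotential
(anode at U_el, cathode at 0 V) and the remaining sample boundary is
insulating (sigma du/dn = 0).

Discretization is cell-centered finite volume on the phantom grid with
harmonic averaging of sigma at cell faces, which keeps fluxes consistent
across the sharp tumor/liver conductivity contrast.  Faces adjacent to an
electrode use the sub-cell distance from the cell center to the analytic
electrode surface (a Shortley-Weller correction), so staircased circular
electrodes do not degrade the convergence order.

Inactive electrodes are modelled as non-conductive markers (holes in the
domain), not as floating equipotential bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (ConductivityMap, Electrode, ElectrodeConfig, Grid,
                       ParameterError)

__all__ = [
    "ConfigurationError",
    "SolverError",
    "PotentialField",
    "CurrentDensityField",
    "EFieldMap",
    "solve_potential",
    "current_density",
    "electric_field",
    "electrode_current",
    "flux_divergence",
]

_DIRECT_SOLVE_MAX = 256 * 256  # unknowns; above this fall back to CG


class ConfigurationError(ValueError):
    """The boundary-value problem is not well posed as configured."""


class SolverError(RuntimeError):
    """The linear solver failed to reach the requested residual."""

    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


# ---------------------------------------------------------------------------
# Field containers
# ---------------------------------------------------------------------------

@dataclass
class PotentialField:
    """Discrete electric potential u (V) with its boundary record.

    ``valid`` marks conductive sample cells (unknowns plus active electrode
    cells); ``labels`` is 0 on unknowns, k >= 1 on cells of the k-th active
    electrode, -1 outside the conductive domain.  The per-face conductance
    factors used in the solve are retained so that derived quantities
    (current density, electric field, electrode currents) are flux-consistent
    with the discrete solution.
    """

    grid: Grid
    u: np.ndarray
    valid: np.ndarray
    labels: np.ndarray
    boundary: dict
    residual: float
    face_sigma: list = field(repr=False, default=None)
    face_geom: list = field(repr=False, default=None)
    electrodes: ElectrodeConfig = field(repr=False, default=None)
    sigma_ref: np.ndarray = field(repr=False, default=None)

    def face_fluxes(self) -> list:
        """Signed face currents (A per unit depth in 2D, A in 3D).

        ``flux[a][i]`` is the current crossing the face between cells i-1 and
        i along axis ``a``, positive in the +axis direction.
        """
        out = []
        for a in range(self.grid.ndim):
            du = -np.diff(self.u, axis=a)  # u[i-1] - u[i]
            flux = np.zeros(self.face_sigma[a].shape)
            core = _inner_faces(self.grid.ndim, a)
            flux[core] = self.face_sigma[a][core] * self.face_geom[a][core] * du
            out.append(flux)
        return out


@dataclass
class CurrentDensityField:
    """Vector current density J (A/m^2) on a grid.

    ``provenance`` records whether the field came from the forward model
    (``"forward"``) or from the measurement channel (``"cdi_recovered"``).
    """

    grid: Grid
    J: np.ndarray  # shape (*grid.shape, ncomp)
    provenance: str = "forward"
    face_flux: list = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape[:-1] != self.grid.shape:
            raise ParameterError("J shape must match grid shape")

    @property
    def ncomp(self) -> int:
        return self.J.shape[-1]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.J ** 2, axis=-1))


@dataclass
class EFieldMap:
    """Electric field E (V/m) with its magnitude attached."""

    grid: Grid
    E: np.ndarray
    magnitude: np.ndarray = None

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        if self.magnitude is None:
            self.magnitude = np.sqrt(np.sum(self.E ** 2, axis=-1))


def _inner_faces(ndim: int, axis: int):
    """Slicer selecting interior faces of the staggered face array."""
    sl = [slice(None)] * ndim
    sl[axis] = slice(1, -1)
    return tuple(sl)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _classify(sigma: ConductivityMap, electrodes: ElectrodeConfig):
    """Label cells: -1 exterior/hole, 0 unknown, k>=1 active electrode k."""
    grid = sigma.grid
    labels = np.zeros(grid.shape, dtype=int)
    voltages = []
    active = [e for e in electrodes.electrodes if e.role != "inactive"]
    for k, e in enumerate(active, start=1):
        cells = e.rasterize(grid) & sigma.mask
        labels[cells] = k
        voltages.append(electrodes.electrode_voltage(e))
    for e in electrodes.electrodes:
        if e.role == "inactive":
            cells = e.rasterize(grid) & sigma.mask
            labels[cells] = -1  # non-conductive marker
    labels[~sigma.mask] = -1
    return labels, active, np.asarray(voltages)


def _dirichlet_distance(elec: Electrode, points: np.ndarray, axis: int,
                        step: float) -> np.ndarray:
    """Vectorized distance from cell centers to the electrode circle along
    one axis (sub-cell Dirichlet correction).  Falls back to |step| where the
    segment does not cross the analytic surface."""
    n = points.shape[0]
    out = np.full(n, abs(step))
    if elec.cells is not None or axis >= 2:
        return out
    d = points[:, :2] - np.asarray(elec.center[:2])
    sgn = 1.0 if step > 0 else -1.0
    b = 2.0 * sgn * d[:, axis]
    c = np.sum(d ** 2, axis=1) - elec.radius ** 2
    disc = b * b - 4.0 * c
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for root in ((-b - sq) / 2.0, (-b + sq) / 2.0):
        hit = ok & (root > 0) & (root <= abs(step) + 1e-15) & (out >= abs(step))
        out[hit] = root[hit]
    return np.clip(out, 1e-3 * abs(step), abs(step))


def _face_factors(sigma: ConductivityMap, electrodes: ElectrodeConfig,
                  labels: np.ndarray, active: list):
    """Per-face sigma and geometric (area/distance) factors.

    Faces between two unknown cells carry the harmonic mean of sigma over
    the nominal spacing; faces between an unknown cell and an electrode cell
    carry the unknown cell's sigma over the corrected distance; all other
    faces are non-conductive.
    """
    grid = sigma.grid
    sig = sigma.effective
    unknown = labels == 0
    face_sigma, face_geom = [], []
    centers = grid.coords()
    vol = float(np.prod(grid.spacing))
    for a in range(grid.ndim):
        h = grid.spacing[a]
        area = vol / h
        shape = list(grid.shape)
        shape[a] += 1
        fs = np.zeros(shape)
        fg = np.zeros(shape)
        core = _inner_faces(grid.ndim, a)
        lo = [slice(None)] * grid.ndim
        hi = [slice(None)] * grid.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        s1, s2 = sig[lo], sig[hi]
        l1, l2 = labels[lo], labels[hi]
        uu = (l1 == 0) & (l2 == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            harm = np.where(s1 + s2 > 0, 2.0 * s1 * s2 / (s1 + s2), 0.0)
        fs_core = np.where(uu, harm, 0.0)
        fg_core = np.where(uu, area / h, 0.0)
        # unknown | electrode faces: sub-cell Dirichlet distance
        for k, elec in enumerate(active, start=1):
            for unk_sl, el_sl, step in ((lo, hi, +h), (hi, lo, -h)):
                pair = (labels[unk_sl] == 0) & (labels[el_sl] == k)
                if not pair.any():
                    continue
                idx = np.argwhere(pair)
                pts = np.stack([centers[ax][unk_sl][pair]
                                for ax in range(grid.ndim)], axis=1)
                dist = _dirichlet_distance(elec, pts, a, step)
                fs_core[tuple(idx.T)] = sig[unk_sl][pair]
                fg_core[tuple(idx.T)] = area / dist
        fs[core] = fs_core
        fg[core] = fg_core
        face_sigma.append(fs)
        face_geom.append(fg)
    return face_sigma, face_geom


def solve_potential(sigma: ConductivityMap, electrodes: ElectrodeConfig,
                    tol: float = 1e-10) -> PotentialField:
    """Solve div(sigma grad u) = 0 with electrode Dirichlet conditions.

    The anode is held at the applied voltage, the cathode at 0 V, and the
    non-electrode sample boundary is insulating.  Uses a sparse direct solve
    up to 256^2 unknowns and diagonally preconditioned conjugate gradients
    beyond.

    Parameters
    ----------
    sigma
        Conductivity map; cells outside its mask are insulating.
    electrodes
        Electrode layout with one active anode/cathode pair.
    tol
        Relative algebraic residual bound, in (0, 1e-3].

    Raises
    ------
    ConfigurationError
        If no active electrode cells or no unknowns exist.
    SolverError
        If the requested residual is not reached.
    """
    if not 0 < tol <= 1e-3:
        raise ParameterError("tol must be in (0, 1e-3]")
    grid = sigma.grid
    labels, active, voltages = _classify(sigma, electrodes)
    if len(active) < 2 or not np.any(labels >= 1):
        raise ConfigurationError("no active electrode cells inside the sample")
    unknown = labels == 0
    n = int(unknown.sum())
    if n == 0:
        raise ConfigurationError("no unknown cells: electrodes cover the sample")
    index = -np.ones(grid.shape, dtype=np.int64)
    index[unknown] = np.arange(n)

    face_sigma, face_geom = _face_factors(sigma, electrodes, labels, active)

    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows, cols, vals = [], [], []
    u_fixed = np.zeros(grid.shape)
    for k, v in enumerate(voltages, start=1):
        u_fixed[labels == k] = v

    for a in range(grid.ndim):
        core = _inner_faces(grid.ndim, a)
        g = (face_sigma[a] * face_geom[a])[core]
        lo = [slice(None)] * grid.ndim
        hi = [slice(None)] * grid.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        l1, l2 = labels[lo], labels[hi]
        i1, i2 = index[lo], index[hi]
        uu = (l1 == 0) & (l2 == 0) & (g > 0)
        rows.append(i1[uu]); cols.append(i2[uu]); vals.append(-g[uu])
        rows.append(i2[uu]); cols.append(i1[uu]); vals.append(-g[uu])
        np.add.at(diag, i1[uu], g[uu])
        np.add.at(diag, i2[uu], g[uu])
        for unk_l, el_l, unk_i, fix in ((l1, l2, i1, u_fixed[hi]),
                                        (l2, l1, i2, u_fixed[lo])):
            ue = (unk_l == 0) & (el_l >= 1) & (g > 0)
            np.add.at(diag, unk_i[ue], g[ue])
            np.add.at(rhs, unk_i[ue], g[ue] * fix[ue])

    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    if np.any(diag <= 0):
        raise ConfigurationError("isolated conductive cells with no path to "
                                 "an electrode; check the mask")

    if n <= _DIRECT_SOLVE_MAX:
        x = spla.spsolve(A.tocsc(), rhs)
    else:
        M = sp.diags(1.0 / diag)
        x, info = spla.cg(A, rhs, rtol=tol * 1e-2, atol=0.0, M=M, maxiter=20000)
        if info != 0:
            res = np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
            raise SolverError(f"CG did not converge (info={info})", residual=res)
    bnorm = np.linalg.norm(rhs)
    residual = float(np.linalg.norm(A @ x - rhs) / max(bnorm, 1e-300))
    if residual > tol:
        raise SolverError(f"residual {residual:.2e} exceeds tol {tol:.2e}",
                          residual=residual)

    u = u_fixed.copy()
    u[unknown] = x
    valid = labels >= 0
    boundary = {e.id: electrodes.electrode_voltage(e) for e in active}
    return PotentialField(grid=grid, u=u, valid=valid, labels=labels,
                          boundary=boundary, residual=residual,
                          face_sigma=face_sigma, face_geom=face_geom,
                          electrodes=electrodes, sigma_ref=sigma.sigma)


# ---------------------------------------------------------------------------
# Derived fields
# ---------------------------------------------------------------------------

def _cell_average_from_faces(grid: Grid, face_vals: list) -> np.ndarray:
    """Average the two face values per axis onto cell centers."""
    comps = []
    for a in range(grid.ndim):
        lo = [slice(None)] * grid.ndim
        hi = [slice(None)] * grid.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        comps.append(0.5 * (face_vals[a][tuple(lo)] + face_vals[a][tuple(hi)]))
    return np.stack(comps, axis=-1)


def _face_E(u_field: PotentialField) -> list:
    """Per-face normal electric field -du/dn; zero on non-conductive faces."""
    grid = u_field.grid
    vol = float(np.prod(grid.spacing))
    out = []
    for a in range(grid.ndim):
        area = vol / grid.spacing[a]
        du = -np.diff(u_field.u, axis=a)  # u[i-1] - u[i]
        e = np.zeros(u_field.face_sigma[a].shape)
        core = _inner_faces(grid.ndim, a)
        conduct = u_field.face_sigma[a][core] > 0
        e[core] = np.where(conduct, u_field.face_geom[a][core] * du / area, 0.0)
        out.append(e)
    return out


def current_density(sigma: ConductivityMap, u_field: PotentialField
                    ) -> CurrentDensityField:
    """Ohmic current density J = -sigma grad u from a solved potential.

    Face-normal fluxes (the ones the solver balances) are averaged to cell
    centers; J is zero outside the conductive sample.
    """
    if sigma.grid.shape != u_field.grid.shape:
        raise ParameterError("sigma and potential live on different grids")
    grid = u_field.grid
    face_e = _face_E(u_field)
    if sigma.sigma is u_field.sigma_ref:
        face_sigma = u_field.face_sigma  # the factors the solver balanced
    else:
        active = [e for e in u_field.electrodes.electrodes
                  if e.role != "inactive"]
        face_sigma, _ = _face_factors(sigma, u_field.electrodes,
                                      u_field.labels, active)
    face_j = [face_sigma[a] * face_e[a] for a in range(grid.ndim)]
    J = _cell_average_from_faces(grid, face_j)
    J[~u_field.valid] = 0.0
    vol = float(np.prod(grid.spacing))
    flux = [face_j[a] * (vol / grid.spacing[a]) for a in range(grid.ndim)]
    return CurrentDensityField(grid=grid, J=J, provenance="forward",
                               face_flux=flux, labels=u_field.labels,
                               mask=u_field.valid)


def electric_field(u_field: PotentialField) -> EFieldMap:
    """Electric field E = -grad u, flux-consistent with `current_density`.

    The same face-normal differences are used, so on homogeneous regions
    E equals J / sigma identically.
    """
    grid = u_field.grid
    E = _cell_average_from_faces(grid, _face_E(u_field))
    E[~u_field.valid] = 0.0
    return EFieldMap(grid=grid, E=E)


def electrode_current(J: CurrentDensityField, electrodes: ElectrodeConfig,
                      which: int) -> float:
    """Net current leaving an electrode (A per unit depth in 2D, A in 3D).

    Computed as the flux balance over the electrode's cells; requires a
    forward-model J carrying face fluxes.
    """
    elec = electrodes.get(which)  # raises KeyError on unknown id
    if J.face_flux is None or J.labels is None:
        raise ParameterError("electrode currents need a forward-model J "
                             "with face fluxes")
    grid = J.grid
    if elec.role == "inactive":
        return 0.0  # non-conductive marker: carries no current by model
    active = [e for e in electrodes.electrodes if e.role != "inactive"]
    k = 1 + [e.id for e in active].index(which)
    cells = J.labels == k
    total = 0.0
    for a in range(grid.ndim):
        lo = [slice(None)] * grid.ndim
        hi = [slice(None)] * grid.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        outflow = (J.face_flux[a][tuple(hi)] - J.face_flux[a][tuple(lo)])
        total += float(np.sum(outflow[cells]))
    return total


def flux_divergence(J: CurrentDensityField) -> np.ndarray:
    """Discrete divergence of J from its face fluxes (A/m^3, or A/m^2 per
    unit depth in 2D); machine-small on interior cells of a forward solve."""
    if J.face_flux is None:
        raise ParameterError("flux divergence needs face fluxes")
    grid = J.grid
    vol = float(np.prod(grid.spacing))
    div = np.zeros(grid.shape)
    for a in range(grid.ndim):
        lo = [slice(None)] * grid.ndim
        hi = [slice(None)] * grid.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        div += (J.face_flux[a][tuple(hi)] - J.face_flux[a][tuple(lo)]) / vol
    return div
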