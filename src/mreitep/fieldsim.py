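"""Measurement channel: current-induced B_z and its MR phase encoding.

During pulse delivery the in-plane currents induce a magnetic flux density
whose z component (parallel to the scanner's main field) accrues signal
phase phi = gamma * B_z * t_c, where gamma is the proton gyromagnetic ratio
and t_c the total duration of the applied pulses.  This module synthesizes
B_z from a planar current density, encodes/decodes the phase, and adds
measurement noise, providing the channel that the CDI recovery inverts.

For z-invariant (planar) currents B_z is proportional to the current stream
function: if J = curl(psi z_hat) then B_z = mu0 psi + const.  The synthesis
therefore solves the Poisson problem lap(psi) = dJx/dy - dJy/dx with psi = 0
on the window boundary — a discrete Helmholtz projection that is exact for
compactly supported divergence-free currents (their true psi vanishes
outside the support).  A direct pairwise Biot-Savart summation over a slab
of finite thickness serves as an independent cross-check of the planar
idealization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.fft

from .geometry import Grid, ParameterError
from .forward import CurrentDensityField

__all__ = [
    "MU0",
    "GAMMA_PROTON",
    "AcquisitionParams",
    "BzMap",
    "PhaseImage",
    "bz_from_current_2d",
    "bz_biot_savart_slab",
    "encode_phase",
    "decode_phase",
    "add_phase_noise",
    "unwrap_phase",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T m / A
#: CODATA proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.6752218744e8


@dataclass(frozen=True)
class AcquisitionParams:
    """CDI acquisition timing.

    Defaults follow the pulse protocol used throughout: four 100 us
    high-voltage pulses, so the total current-encoding time is
    t_c = n_pulses * pulse_duration = 400 us.
    """

    n_pulses: int = 4
    pulse_duration: float = 100e-6  # s
    gamma: float = GAMMA_PROTON     # rad / (s T)

    def __post_init__(self):
        if self.n_pulses <= 0 or self.pulse_duration <= 0 or self.gamma <= 0:
            raise ParameterError("acquisition parameters must be positive")

    @property
    def t_c(self) -> float:
        """Total current-encoding duration (s)."""
        return self.n_pulses * self.pulse_duration


@dataclass
class BzMap:
    """Current-induced magnetic flux density component B_z (T).

    The additive gauge constant is fixed so that the median over
    current-free (exterior) cells is zero; ``gauge`` records the convention.
    """

    grid: Grid
    bz: np.ndarray
    gauge: str = "exterior median = 0"
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.bz = np.asarray(self.bz, dtype=float)
        if self.bz.shape != self.grid.shape:
            raise ParameterError("bz shape must match grid shape")


@dataclass
class PhaseImage:
    """MR signal phase phi (rad) accrued during current encoding."""

    grid: Grid
    phi: np.ndarray
    wrapped: bool = False
    snr: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != self.grid.shape:
            raise ParameterError("phi shape must match grid shape")


# ---------------------------------------------------------------------------
# B_z synthesis
# ---------------------------------------------------------------------------

def _poisson_dirichlet(rhs: np.ndarray, spacing, pad: int = 1) -> np.ndarray:
    """Solve lap(psi) = rhs on a cell-centered grid, psi = 0 at the window
    faces (ghost-cell reflection), via fast sine transforms.

    ``pad`` >= 1 embeds the window centrally in a ``pad``-times larger
    zero-source domain before solving, pushing the artificial Dirichlet
    boundary away from any slowly decaying stream-function tail.
    """
    nx, ny = rhs.shape
    if pad > 1:
        big = np.zeros((nx * pad, ny * pad))
        ox = (nx * (pad - 1)) // 2
        oy = (ny * (pad - 1)) // 2
        big[ox:ox + nx, oy:oy + ny] = rhs
        sol = _poisson_dirichlet(big, spacing, pad=1)
        return sol[ox:ox + nx, oy:oy + ny]
    lam = []
    for n, h in zip((nx, ny), spacing):
        k = np.arange(n)
        lam.append((2.0 * np.cos(np.pi * (k + 1) / n) - 2.0) / h ** 2)
    ev = lam[0][:, None] + lam[1][None, :]
    coef = scipy.fft.dstn(rhs, type=2, norm="ortho")
    return scipy.fft.idstn(coef / ev, type=2, norm="ortho")


def monopole_source_field(grid: Grid, sources) -> np.ndarray:
    """In-plane current field of disk-spread monopole sources (A/m^2).

    ``sources`` is a sequence of ``(center_xy, current, radius)``: each
    entry contributes the radial field of a current ``I`` fed uniformly
    over a disk of the given radius — ``I r / (2 pi R^2)`` inside the disk
    and ``I / (2 pi r)`` outside.  This is the irrotational (curl-free)
    component of the current that needle electrodes feed into the imaging
    plane; it induces no B_z and must be accounted for separately on both
    sides of the measurement channel.
    """
    x, y = grid.coords()[:2]
    out = np.zeros((*grid.shape, 2))
    for (cx, cy), current, radius in sources:
        dx = x - cx
        dy = y - cy
        r2 = dx * dx + dy * dy
        r2in = np.maximum(r2, 1e-30)
        scale = np.where(r2 <= radius ** 2,
                         current / (2 * np.pi * radius ** 2),
                         current / (2 * np.pi * r2in))
        out[..., 0] += scale * dx
        out[..., 1] += scale * dy
    return out


def central_gradient(f: np.ndarray, spacing: float, axis: int) -> np.ndarray:
    """Second-order gradient: central in the interior, second-order
    one-sided at the two boundary layers."""
    g = np.empty_like(np.asarray(f, dtype=float))
    f = np.asarray(f, dtype=float)
    n = f.shape[axis]
    if n < 3:
        raise ParameterError("need at least 3 samples to differentiate")
    sl = lambda s: tuple(s if a == axis else slice(None)
                         for a in range(f.ndim))
    g[sl(slice(1, -1))] = (f[sl(slice(2, None))] - f[sl(slice(None, -2))]) / (2 * spacing)
    g[sl(slice(0, 1))] = (-3 * f[sl(slice(0, 1))] + 4 * f[sl(slice(1, 2))]
                          - f[sl(slice(2, 3))]) / (2 * spacing)
    g[sl(slice(-1, None))] = (3 * f[sl(slice(-1, None))] - 4 * f[sl(slice(-2, -1))]
                              + f[sl(slice(-3, -2))]) / (2 * spacing)
    return g


def bz_from_current_2d(J: CurrentDensityField,
                       electrode_mask: Optional[np.ndarray] = None,
                       div_rtol: float = 1e-2,
                       sources=None, pad: int = 4) -> BzMap:
    """Synthesize B_z induced by a planar current distribution.

    Uses the stream-function identity B_z = mu0 psi + const for
    J = curl(psi z_hat): psi is obtained as the Dirichlet solution of
    lap(psi) = dJx/dy - dJy/dx on the (padded) imaging window.  The gauge
    constant is then fixed so the median of B_z over current-free cells is
    zero.

    B_z is blind to the irrotational component of the in-plane current:
    needle electrodes feed the plane through monopole sources whose radial
    flow induces no B_z at all.  When ``sources`` (``(center, current,
    radius)`` per active needle, currents summing to zero) are given, that
    analytically known component is removed before the stream-function
    solve, leaving a divergence-free remainder whose B_z is synthesized
    exactly; the recovery side restores the same component (see
    `mreitep.cdirecon.recover_current_bz` and the pipeline).

    A current that is not divergence-free away from the electrode cells
    and declared sources indicates an inconsistent input; this is recorded
    as a warning on the output rather than raised, mirroring how a real
    acquisition would simply measure whatever field is present.
    """
    if J.ncomp != 2 or J.grid.ndim != 2:
        raise ParameterError("planar B_z synthesis needs a 2-component J on "
                             "a 2D grid")
    grid = J.grid
    hx, hy = grid.spacing
    jx, jy = J.J[..., 0], J.J[..., 1]
    if sources:
        js = monopole_source_field(grid, sources)
        jx = jx - js[..., 0]
        jy = jy - js[..., 1]
    warnings = []
    jmax = float(np.max(np.hypot(jx, jy)))
    if jmax > 0:
        div = central_gradient(jx, hx, 0) + central_gradient(jy, hy, 1)
        check = np.ones(grid.shape, dtype=bool)
        if electrode_mask is not None:
            # residual source mismatch concentrates at the needles
            from scipy.ndimage import binary_dilation
            check &= ~binary_dilation(electrode_mask, iterations=2)
        bad = np.abs(div[check]).max() if check.any() else 0.0
        if bad > div_rtol * jmax / min(hx, hy):
            warnings.append(
                f"non-solenoidal J outside electrode cells: max |div J| = "
                f"{bad:.3e} A/m^3 (tolerance {div_rtol * jmax / min(hx, hy):.3e})")
    vort = central_gradient(jx, hy, 1) - central_gradient(jy, hx, 0)
    psi = _poisson_dirichlet(vort, grid.spacing, pad=pad)
    bz = MU0 * psi
    free = ~(J.magnitude() > 0)
    if free.any():
        bz = bz - np.median(bz[free])
    else:
        bz = bz - bz[0, 0]
    return BzMap(grid=grid, bz=bz, warnings=warnings)


def bz_biot_savart_slab(J: CurrentDensityField, thickness: float,
                        max_cells: int = 64 * 64,
                        force: bool = False) -> BzMap:
    """Direct Biot-Savart summation for a slab of finite thickness.

    Each cell carries a z-invariant planar current over the slab height;
    the z component of the field is evaluated at the mid-plane by exact
    integration of the kernel along z.  O(N^2) in the number of cells —
    intended as an independent oracle on small grids (guarded at
    ``max_cells`` unless ``force``).
    """
    if J.ncomp != 2 or J.grid.ndim != 2:
        raise ParameterError("slab Biot-Savart needs a 2-component planar J")
    if thickness <= 0:
        raise ParameterError("slab thickness must be positive")
    grid = J.grid
    ncells = int(np.prod(grid.shape))
    if ncells > max_cells and not force:
        raise ParameterError(
            f"grid has {ncells} cells > guard {max_cells}; pass force=True "
            "to override the O(N^2) size guard")
    x, y = grid.coords()
    jx, jy = J.J[..., 0], J.J[..., 1]
    src = J.magnitude() > 0
    xs, ys = x[src], y[src]
    jxs, jys = jx[src], jy[src]
    dv = float(np.prod(grid.spacing))  # cell area; thickness enters the kernel
    half = thickness / 2.0
    bz = np.zeros(grid.shape)
    xt, yt = x.ravel(), y.ravel()
    acc = np.zeros(xt.shape)
    for k in range(xs.size):
        rx = xt - xs[k]
        ry = yt - ys[k]
        rho2 = rx * rx + ry * ry
        with np.errstate(divide="ignore", invalid="ignore"):
            kern = thickness / (rho2 * np.sqrt(rho2 + half * half))
        kern[rho2 == 0] = 0.0  # self term vanishes by symmetry
        acc += (jxs[k] * ry - jys[k] * rx) * kern
    bz = (MU0 / (4.0 * np.pi)) * dv * acc.reshape(grid.shape)
    free = ~src
    if free.any():
        bz = bz - np.median(bz[free])
    return BzMap(grid=grid, bz=bz,
                 gauge="exterior median = 0 (slab summation)")


# ---------------------------------------------------------------------------
# Phase encoding
# ---------------------------------------------------------------------------

def encode_phase(bz: BzMap, acq: AcquisitionParams,
                 wrap: bool = False) -> PhaseImage:
    """MR phase accrued by B_z over the current-encoding window:
    phi = gamma * B_z * t_c, optionally wrapped into (-pi, pi]."""
    phi = acq.gamma * bz.bz * acq.t_c
    if wrap:
        phi = np.angle(np.exp(1j * phi))
        # np.angle returns [-pi, pi); shift the -pi branch to +pi
        phi = np.where(phi == -np.pi, np.pi, phi)
    return PhaseImage(grid=bz.grid, phi=phi, wrapped=wrap)


def decode_phase(phi: PhaseImage, acq: AcquisitionParams) -> BzMap:
    """Invert the phase encoding: B_z = phi / (gamma t_c).

    Raises if the image is flagged wrapped — unwrap first.
    """
    if phi.wrapped:
        raise ParameterError("phase image is wrapped; apply unwrap_phase first")
    return BzMap(grid=phi.grid, bz=phi.phi / (acq.gamma * acq.t_c),
                 gauge="inherited from phase image")


def add_phase_noise(phi: PhaseImage, snr: float, seed: int) -> PhaseImage:
    """Add zero-mean Gaussian phase noise of standard deviation 1/snr rad.

    Reproducible under a fixed seed; models the CDI sensitivity floor that
    dominates near the sample boundary.
    """
    if snr <= 0:
        raise ParameterError("snr must be positive")
    rng = np.random.default_rng(seed)
    noisy = phi.phi + rng.normal(0.0, 1.0 / snr, size=phi.phi.shape)
    return PhaseImage(grid=phi.grid, phi=noisy, wrapped=phi.wrapped,
                      snr=snr, seed=seed)


def unwrap_phase(phi: PhaseImage) -> PhaseImage:
    """Quality-guided 2D phase unwrapping (for wrapped, noisy inputs)."""
    from skimage.restoration import unwrap_phase as _unwrap
    out = np.asarray(_unwrap(phi.phi), dtype=float)
    return PhaseImage(grid=phi.grid, phi=out, wrapped=False,
                      snr=phi.snr, seed=phi.seed)
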