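"""Quantitative benchmarks of the whole chain against independent oracles.

Each function recomputes one headline quantity from scratch: the forward
solver against the closed-form coaxial (annulus) potential, the B_z
round trip against its defining identity, the slab Biot-Savart summation
against the planar synthesis, inverse-crime conductivity recovery against
phantom truth, the in-silico electric-field agreement along the
inter-electrode line, the conservation/identity suite, and the
noise-robustness trend.  `scripts/acceptance.py` and the acceptance tests
are thin wrappers around these.
"""

from __future__ import annotations

import numpy as np

from . import cdirecon, fieldsim, forward, jsubstitution, pipeline
from .fieldsim import AcquisitionParams, MU0
from .forward import CurrentDensityField
from .geometry import (ConductivityMap, Electrode, ElectrodeConfig, Grid,
                       PhantomSpec, build_phantom,
                       region_labels_tumor_liver)
from .jsubstitution import ReconstructionConfig
from .pipeline import electrode_exclusion_mask

__all__ = [
    "annulus_benchmark",
    "cdi_roundtrip_benchmark",
    "biot_savart_benchmark",
    "sigma_recovery_benchmark",
    "efield_agreement_benchmark",
    "conservation_suite",
    "noise_robustness",
]

_ANNULUS = dict(sigma=0.1, inner_radius_mm=2.0, outer_radius_mm=10.0,
                voltage=1.0)


def _annulus_setup(n: int):
    spec = PhantomSpec.annulus(**_ANNULUS)
    grid = Grid.square(n, 24e-3, origin=(-12e-3, -12e-3))
    sigma_map, electrodes = build_phantom(spec, grid)
    return spec, grid, sigma_map, electrodes


def annulus_benchmark(levels=(64, 128, 256)) -> dict:
    """Forward solver vs the closed-form coaxial potential
    u(r) = U ln(b/r) / ln(b/a), with the grid-refinement order."""
    a = _ANNULUS["inner_radius_mm"] * 1e-3
    b = _ANNULUS["outer_radius_mm"] * 1e-3
    U = _ANNULUS["voltage"]
    sig0 = _ANNULUS["sigma"]
    errs = {}
    extras = {}
    for n in levels:
        _, grid, sigma_map, electrodes = _annulus_setup(n)
        u = forward.solve_potential(sigma_map, electrodes)
        x, y = grid.coords()
        r = np.hypot(x, y)
        interior = u.labels == 0
        truth = U * np.log(b / r) / np.log(b / a)
        errs[n] = float(np.linalg.norm(u.u[interior] - truth[interior])
                        / np.linalg.norm(truth[interior]))
        if n == max(levels):
            J = forward.current_density(sigma_map, u)
            E = forward.electric_field(u)
            h = grid.spacing[0]
            ring = interior & (r > a + 2 * h) & (r < b - 2 * h)
            jt = sig0 * U / (r * np.log(b / a))
            et = U / (r * np.log(b / a))
            jm = J.magnitude()
            extras["j_rel_l2"] = float(
                np.linalg.norm(jm[ring] - jt[ring]) / np.linalg.norm(jt[ring]))
            extras["e_rel_l2"] = float(
                np.linalg.norm(E.magnitude[ring] - et[ring])
                / np.linalg.norm(et[ring]))
            i_anode = forward.electrode_current(J, electrodes, 1)
            i_true = 2 * np.pi * sig0 * U / np.log(b / a)
            extras["current_rel_err"] = float(abs(i_anode - i_true) / i_true)
    ns = np.array(sorted(errs))
    ev = np.array([errs[n] for n in ns])
    order = float(np.polyfit(np.log(1.0 / ns), np.log(ev), 1)[0])
    return {"rel_l2": errs, "order": order, **extras}


def _gaussian_stream_current(n: int, s: float = 0.1) -> CurrentDensityField:
    """Divergence-free current built analytically as the curl of a
    Gaussian stream function on the unit window."""
    grid = Grid.square(n, 1.0, origin=(-0.5, -0.5))
    x, y = grid.coords()
    psi = np.exp(-(x ** 2 + y ** 2) / (2 * s ** 2))
    jx = -y / s ** 2 * psi   # d psi / dy
    jy = x / s ** 2 * psi    # -d psi / dx
    return CurrentDensityField(grid=grid, J=np.stack([jx, jy], axis=-1)), psi


def cdi_roundtrip_benchmark(levels=(64, 128, 256)) -> dict:
    """J -> B_z (stream function) -> single-component recovery, with the
    refinement slope of the round-trip error."""
    errs = {}
    for n in levels:
        J, _ = _gaussian_stream_current(n)
        bz = fieldsim.bz_from_current_2d(J)
        Jr = cdirecon.recover_current_bz(bz)
        errs[n] = float(np.linalg.norm(Jr.J - J.J) / np.linalg.norm(J.J))
    ns = np.array(sorted(errs))
    ev = np.array([errs[n] for n in ns])
    slope = float(np.polyfit(np.log(1.0 / ns), np.log(ev), 1)[0])
    return {"rel_l2": errs, "slope": slope}


def loop_current(n: int = 32, fov: float = 24e-3, r0: float = 7e-3,
                 width: float = 1.0e-3):
    """Azimuthal loop current (a smooth solenoid sheet): the curl of a
    plateau stream function, 1 inside the ring and 0 outside, so the ideal
    B_z is a uniform plateau inside the loop."""
    grid = Grid.square(n, fov, origin=(-fov / 2, -fov / 2))
    x, y = grid.coords()
    r = np.hypot(x, y)
    z = np.clip((r - r0) / width, -40.0, 40.0)
    psi = 1.0 / (1.0 + np.exp(z))
    with np.errstate(invalid="ignore", divide="ignore"):
        dpsi_dr = -np.exp(z) * psi ** 2 / width
        jx = np.where(r > 0, dpsi_dr * y / r, 0.0)
        jy = np.where(r > 0, -dpsi_dr * x / r, 0.0)
    return CurrentDensityField(grid=grid, J=np.stack([jx, jy], axis=-1))


def biot_savart_benchmark(n: int = 32, thickness: float = 0.2,
                          r0: float = 7e-3, width: float = 1.0e-3) -> dict:
    """Slab Biot-Savart summation vs the planar stream-function synthesis
    on a loop-current phantom, away from the current-carrying ring (more
    than 3 ring-widths from the sheet radius)."""
    J = loop_current(n, r0=r0, width=width)
    ideal = fieldsim.bz_from_current_2d(J)
    slab = fieldsim.bz_biot_savart_slab(J, thickness=thickness)
    x, y = J.grid.coords()
    away = np.abs(np.hypot(x, y) - r0) > 3 * width
    err = float(np.linalg.norm(slab.bz[away] - ideal.bz[away])
                / np.linalg.norm(ideal.bz[away]))
    return {"rel_l2_away": err, "n": n, "thickness": thickness}


def _direct_inverse_crime(spec, grid, sigma_init=0.1, tol=0.01, max_iter=50):
    sigma_true, electrodes = build_phantom(spec, grid)
    u = forward.solve_potential(sigma_true, electrodes)
    j_true = forward.current_density(sigma_true, u)
    cfg = ReconstructionConfig(sigma_init=sigma_init, tol=tol,
                               max_iter=max_iter)
    result = jsubstitution.jsub_reconstruct(j_true, electrodes, cfg,
                                            mask=sigma_true.mask)
    excl = electrode_exclusion_mask(grid, electrodes, 2e-3)
    roi = sigma_true.mask & ~excl
    return sigma_true, electrodes, result, roi


def two_region_spec_64() -> tuple:
    """Two-tissue phantom matched to a 64x64 / 30 mm imaging window."""
    spec = PhantomSpec.tumor_liver_region(
        sample_diameter_mm=24.0, electrode_spacing_mm=12.0,
        electrode_radius_mm=0.5, voltage=2100.0)
    grid = Grid.square(64, 30e-3)
    return spec, grid


def sigma_recovery_benchmark() -> dict:
    """Inverse-crime conductivity recovery at 64x64: homogeneous disc and
    the two-tissue (0.4 / 0.05 S/m) phantom, noiseless forward-model data,
    0.01 stopping rule."""
    out = {}
    spec = PhantomSpec.homogeneous_disc(sigma=0.1, voltage=1000.0)
    grid = Grid.square(64, 30e-3)
    sigma_true, _, result, roi = _direct_inverse_crime(
        spec, grid, sigma_init=0.05)
    err = np.abs(result.sigma_mreit.sigma[roi] - sigma_true.sigma[roi]) \
        / sigma_true.sigma[roi]
    out["homogeneous"] = {
        "median_rel_err": float(np.median(err)),
        "iterations": result.iterations,
        "converged": bool(result.converged),
    }
    spec, grid = two_region_spec_64()
    sigma_true, _, result, roi = _direct_inverse_crime(spec, grid)
    labels = region_labels_tumor_liver(spec, grid)
    regions = {}
    for rid, name in ((1, "tumor"), (2, "liver")):
        sel = roi & (labels == rid)
        regions[name] = float(np.median(
            np.abs(result.sigma_mreit.sigma[sel] - sigma_true.sigma[sel])
            / sigma_true.sigma[sel]))
    out["two_region"] = {
        "median_rel_err": regions,
        "iterations": result.iterations,
        "converged": bool(result.converged),
    }
    return out


def efield_agreement_benchmark() -> dict:
    """|E_MREIT| vs |E*| along the inter-electrode line for the two
    in-silico presets (noiseless, full measurement channel)."""
    out = {}
    for name in ("insilico_tumor_1700V", "insilico_tumor_liver_2100V"):
        cfg = pipeline.get_preset(name)
        metrics = pipeline.run_experiment(cfg)
        out[name] = {
            "profile_rel_l2": metrics.profile_rel_l2,
            "roi_rel_l2": metrics.rel_l2,
            "iterations": metrics.iterations,
            "n": cfg.n,
        }
    return out


def conservation_suite() -> dict:
    """Discrete conservation laws and channel identities on the ex vivo
    disc phantom: interior div J, electrode current balance, Eq-3 gauge
    invariance, linearity in the applied voltage, phase encode/decode."""
    spec = PhantomSpec.homogeneous_disc(sigma=0.1, voltage=1000.0)
    grid = Grid.square(64, 30e-3)
    sigma_map, electrodes = build_phantom(spec, grid)
    u = forward.solve_potential(sigma_map, electrodes)
    J = forward.current_density(sigma_map, u)
    jmax = float(J.magnitude().max())
    div = forward.flux_divergence(J)
    interior = u.labels == 0
    h = grid.spacing[0]
    div_rel = float(np.abs(div[interior]).max() * h / jmax)

    i_a = forward.electrode_current(J, electrodes, 1)
    i_c = forward.electrode_current(J, electrodes, 2)
    balance = float(abs(i_a + i_c) / abs(i_a))

    bz = fieldsim.bz_from_current_2d(J, sources=[
        (electrodes.anode.center[:2], i_a, electrodes.anode.radius),
        (electrodes.cathode.center[:2], -i_a, electrodes.cathode.radius)])
    J1 = cdirecon.recover_current_bz(bz)
    shifted = fieldsim.BzMap(grid=grid, bz=bz.bz + float(np.abs(bz.bz).max()))
    J2 = cdirecon.recover_current_bz(shifted)
    gauge = float(np.abs(J2.J - J1.J).max() / np.abs(J1.J).max())

    electrodes2 = ElectrodeConfig(electrodes.electrodes,
                                  2 * electrodes.voltage)
    u2 = forward.solve_potential(sigma_map, electrodes2)
    lin = float(np.abs(u2.u - 2 * u.u).max() / np.abs(u.u).max())

    acq = AcquisitionParams()
    phi = fieldsim.encode_phase(bz, acq)
    back = fieldsim.decode_phase(phi, acq)
    enc = float(np.abs(back.bz - bz.bz).max() / np.abs(bz.bz).max())
    return {"div_rel": div_rel, "current_balance": balance,
            "gauge_invariance": gauge, "voltage_linearity": lin,
            "encode_decode": enc}


def noise_robustness(seed: int = 0,
                     snrs=(1e6, 1e4, 1e2, 30.0, 10.0)) -> dict:
    """Reconstruction errors across decreasing phase SNR with the Spearman
    rank correlation of error against noise level (1/snr)."""
    from scipy.stats import spearmanr
    sig_errs, e_errs = [], []
    for k, snr in enumerate(snrs):
        cfg = pipeline.get_preset("exvivo_1000V_pair12",
                                  snr=float(snr), seed=seed + k,
                                  field_dependent=None)
        m = pipeline.run_experiment(cfg)
        sig_errs.append(m.sigma_median_rel_err)
        e_errs.append(m.rel_l2)
    noise = [1.0 / s for s in snrs]
    rho_sigma = float(spearmanr(noise, sig_errs).statistic)
    rho_e = float(spearmanr(noise, e_errs).statistic)
    return {"snrs": list(snrs), "sigma_median_rel_err": sig_errs,
            "e_rel_l2": e_errs, "spearman_sigma": rho_sigma,
            "spearman_e": rho_e}
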