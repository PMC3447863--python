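"""J-substitution reconstruction of conductivity and electric field.

The inverse solver alternates a forward Laplace solve under the current
conductivity iterate with a multiplicative update by the ratio of measured
to modelled current-density magnitudes,

    sigma_{k+1} = sigma_k * |J_CDI| / |J_k|,

until the change between successive conductivities falls below the stopping
threshold (0.01, relative max-norm over the region of interest by default).
Because the electrode voltages enter the forward solve as absolute Dirichlet
data, the reconstructed conductivity is absolute, not merely relative.

The electric field then follows from Ohm's law, E = J_CDI / sigma_MREIT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .geometry import ConductivityMap, ElectrodeConfig, Grid, ParameterError
from . import forward
from .forward import CurrentDensityField, EFieldMap

__all__ = [
    "NonConvergenceError",
    "ReconstructionConfig",
    "ReconstructionResult",
    "update_conductivity",
    "jsub_reconstruct",
    "reconstruct_efield",
]


class NonConvergenceError(RuntimeError):
    """Iteration diverged; carries the change history for diagnosis."""

    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = list(history)


@dataclass
class ReconstructionConfig:
    """Settings of the J-substitution iteration.

    Parameters
    ----------
    sigma_init
        Starting conductivity: a uniform value (S/m) spread over the sample
        mask, or a full ConductivityMap.  Default 0.1 S/m.
    tol
        Stopping threshold on the change between successive conductivities
        (default 0.01; relative max-norm unless ``change_norm="absolute"``).
    max_iter
        Iteration cap.
    sigma_floor, sigma_cap
        Positivity clamps (S/m) applied after each update.
    roi_mask
        Cells over which convergence is assessed; defaults to the update
        region (or the sample mask).
    update_mask
        Cells where the multiplicative update is applied.  Defaults to the
        whole sample mask; measured data warrant restricting it to the
        interior away from the sample rim and the electrodes, where CDI
        sensitivity and field distortions corrupt |J_CDI| — iterating on
        those cells drags an otherwise convergent reconstruction
        (semi-convergence).  Cells of the mask outside the update region
        are filled with the value of the nearest updated cell after each
        sweep when ``extend_fill`` is set.
    extend_fill
        Nearest-neighbor extension of sigma into the non-updated rim
        (default True; ignored without an ``update_mask``).
    keep_best
        Measured |J_CDI| with systematic artifacts makes the iteration
        semi-convergent: it first fits the bulk conductivity, then slowly
        fits the artifacts.  With ``keep_best`` the iterate with the
        smallest inter-iteration change is retained and returned instead
        of raising on sustained growth (converged stays False unless the
        stopping rule fired).
    change_norm
        How the change between successive conductivities is measured over
        the ROI: "relative" -> max |ds|/sigma (the default reading of the
        stopping rule); "relative_l2" -> ||ds|| / ||sigma|| (robust to
        isolated boundary-cell flicker in measured data); "absolute" ->
        max |ds| in S/m; "absolute_l2" -> ||ds|| / sqrt(N) in S/m.
    """

    sigma_init: Union[float, ConductivityMap] = 0.1
    tol: float = 0.01
    max_iter: int = 50
    sigma_floor: float = 1e-4
    sigma_cap: float = 10.0
    roi_mask: Optional[np.ndarray] = None
    update_mask: Optional[np.ndarray] = None
    extend_fill: bool = True
    keep_best: bool = False
    change_norm: str = "relative"

    def __post_init__(self):
        if not 0 < self.sigma_floor < self.sigma_cap:
            raise ParameterError("need 0 < sigma_floor < sigma_cap")
        if self.tol <= 0 or self.max_iter < 1:
            raise ParameterError("tol must be > 0 and max_iter >= 1")
        if self.change_norm not in ("relative", "relative_l2",
                                    "absolute", "absolute_l2"):
            raise ParameterError("unknown change_norm")


@dataclass
class ReconstructionResult:
    """Outcome of a J-substitution run."""

    sigma_mreit: ConductivityMap
    e_field: EFieldMap
    iterations: int
    history: list
    converged: bool
    residual_history: list = field(default_factory=list)
    best_iteration: Optional[int] = None
    best_change: Optional[float] = None


def update_conductivity(sigma_k: ConductivityMap, j_cdi_mag: np.ndarray,
                        j_k_mag: np.ndarray, sigma_floor: float = 1e-4,
                        sigma_cap: float = 10.0,
                        eps: float = 1e-6) -> ConductivityMap:
    """One multiplicative J-substitution update on the sample mask.

    Cells where the modelled |J_k| is vanishing (< eps * max|J_k|) carry no
    information and are left unchanged; the result is clamped to
    [sigma_floor, sigma_cap].
    """
    j_cdi_mag = np.asarray(j_cdi_mag, dtype=float)
    j_k_mag = np.asarray(j_k_mag, dtype=float)
    if (j_cdi_mag.shape != sigma_k.grid.shape
            or j_k_mag.shape != sigma_k.grid.shape):
        raise ParameterError("magnitude fields must match the sigma grid")
    sigma = sigma_k.sigma.copy()
    floor = eps * float(j_k_mag.max()) if j_k_mag.size else 0.0
    upd = sigma_k.mask & (j_k_mag > floor)
    sigma[upd] = np.clip(sigma[upd] * (j_cdi_mag[upd] / j_k_mag[upd]),
                         sigma_floor, sigma_cap)
    return ConductivityMap(sigma_k.grid, sigma, sigma_k.mask)


def _change(sig_new: np.ndarray, sig_old: np.ndarray, roi: np.ndarray,
            norm: str) -> float:
    d = np.abs(sig_new[roi] - sig_old[roi])
    old = sig_old[roi]
    if norm == "relative":
        return float(np.max(d / old))
    if norm == "relative_l2":
        return float(np.linalg.norm(d) / np.linalg.norm(old))
    if norm == "absolute":
        return float(np.max(d))
    return float(np.linalg.norm(d) / np.sqrt(d.size))


def jsub_reconstruct(j_cdi: CurrentDensityField, electrodes: ElectrodeConfig,
                     cfg: ReconstructionConfig,
                     mask: Optional[np.ndarray] = None,
                     solver_tol: float = 1e-10) -> ReconstructionResult:
    """Run the J-substitution iteration on measured current-density data.

    Parameters
    ----------
    j_cdi
        CDI-recovered (or forward-simulated) current density on the phantom
        grid; only its magnitude enters the update, its vector form enters
        the final Ohm's-law field.
    electrodes
        Electrode layout with the applied voltage (the absolute boundary
        data anchoring the conductivity scale).
    cfg
        Iteration settings.
    mask
        Sample body; required when ``cfg.sigma_init`` is a scalar (a
        ConductivityMap initializer carries its own mask).

    Raises
    ------
    NonConvergenceError
        If the change grows over 5 consecutive iterations.
    """
    grid = j_cdi.grid
    if isinstance(cfg.sigma_init, ConductivityMap):
        sigma_map = cfg.sigma_init.copy()
    else:
        if mask is None:
            raise ParameterError("mask required with a scalar sigma_init")
        sigma = np.full(grid.shape, float(cfg.sigma_init))
        sigma_map = ConductivityMap(grid, sigma, np.asarray(mask, dtype=bool))
    upd_region = cfg.update_mask
    fill_idx = None
    if upd_region is not None:
        upd_region = np.asarray(upd_region, dtype=bool) & sigma_map.mask
        if not upd_region.any():
            raise ParameterError("empty update region")
        if cfg.extend_fill:
            from scipy.ndimage import distance_transform_edt
            _, fill_idx = distance_transform_edt(~upd_region,
                                                 return_indices=True)
    roi = cfg.roi_mask
    if roi is None:
        roi = upd_region if upd_region is not None else sigma_map.mask
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ParameterError("empty convergence ROI")

    j_cdi_mag = j_cdi.magnitude()
    history, res_history = [], []
    converged = False
    grow = 0
    iterations = 0
    best_sigma, best_change, best_iter = None, np.inf, None
    for _ in range(cfg.max_iter):
        u = forward.solve_potential(sigma_map, electrodes, tol=solver_tol)
        jk = forward.current_density(sigma_map, u)
        jk_mag = jk.magnitude()
        res_history.append(float(np.linalg.norm(j_cdi_mag - jk_mag)))
        sigma_next = update_conductivity(sigma_map, j_cdi_mag, jk_mag,
                                         cfg.sigma_floor, cfg.sigma_cap)
        if upd_region is not None:
            s = sigma_map.sigma.copy()
            s[upd_region] = sigma_next.sigma[upd_region]
            if fill_idx is not None:
                rim = sigma_map.mask & ~upd_region
                s[rim] = s[tuple(fill_idx)][rim]
            sigma_next = ConductivityMap(grid, s, sigma_map.mask)
        change = _change(sigma_next.sigma, sigma_map.sigma, roi,
                         cfg.change_norm)
        history.append(change)
        iterations += 1
        sigma_map = sigma_next
        if change < best_change:
            best_change, best_iter = change, iterations
            if cfg.keep_best:
                best_sigma = sigma_map.sigma.copy()
        if change < cfg.tol:
            converged = True
            break
        # genuine divergence: sustained growth, not boundary-cell flicker
        if len(history) >= 2 and change > 1.05 * history[-2]:
            grow += 1
            if grow >= 5:
                if cfg.keep_best:
                    break  # semi-convergence: roll back to the best iterate
                raise NonConvergenceError(
                    "conductivity change grew for 5 consecutive iterations",
                    history)
        else:
            grow = 0

    if cfg.keep_best and not converged and best_sigma is not None:
        sigma_map = ConductivityMap(grid, best_sigma, sigma_map.mask)
    e_field = reconstruct_efield(j_cdi, sigma_map,
                                 sigma_floor=cfg.sigma_floor)
    return ReconstructionResult(sigma_mreit=sigma_map, e_field=e_field,
                                iterations=iterations, history=history,
                                converged=converged,
                                residual_history=res_history,
                                best_iteration=best_iter,
                                best_change=float(best_change))


def reconstruct_efield(j: CurrentDensityField, sigma: ConductivityMap,
                       sigma_floor: float = 1e-4) -> EFieldMap:
    """Ohm's-law electric field E = J / sigma (componentwise; magnitude
    |J|/sigma attached).  Exterior cells are zero."""
    if j.grid.shape != sigma.grid.shape:
        raise ParameterError("J and sigma live on different grids")
    inside = sigma.mask
    if np.any(sigma.sigma[inside] < sigma_floor):
        raise ParameterError("sigma below floor inside the sample mask")
    E = np.zeros_like(j.J)
    E[inside] = j.J[inside] / sigma.sigma[inside][..., None]
    return EFieldMap(grid=j.grid, E=E)
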