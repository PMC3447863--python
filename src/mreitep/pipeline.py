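"""End-to-end experiments: phantom -> forward -> B_z -> phase -> CDI ->
J-substitution -> electric field, with evaluation metrics and artifacts.

Two families of presets are provided:

* ``exvivo_*`` — the liver-sample configuration: 20 mm disc, four 1 mm
  needle electrodes, 64 x 64 imaging matrix over a 30 mm field of view,
  four 100 us pulses at 1000 V or 1500 V on pairs 1-2 or 1-3.  These runs
  enable the field-dependent conductivity option, emulating the
  electroporation-induced conductivity rise between the active electrodes.
* ``insilico_*`` — idealized 2D mid-plane sections of the deep-seated
  tumor model: homogeneous tumor (0.4 S/m, 1700 V across pair "3-4") and
  tumor-liver (0.4 / 0.05 S/m with a sigmoid transition, 2100 V across
  pair "4-6") on a 128 x 128 grid over 60 mm, evaluated along the
  inter-electrode line against the forward-model truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dfield, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from . import cdirecon, fieldsim, forward, io as mio, jsubstitution
from .fieldsim import AcquisitionParams
from .geometry import (ConductivityMap, ElectrodeConfig, GeometryError, Grid,
                       ParameterError, PhantomSpec, build_phantom,
                       region_labels_tumor_liver)
from .jsubstitution import ReconstructionConfig

__all__ = [
    "ExperimentConfig",
    "ProfileSeries",
    "MetricsReport",
    "run_experiment",
    "apply_field_dependent_sigma",
    "equilibrate_field_dependent_sigma",
    "extract_profile",
    "compare_fields",
    "electrode_exclusion_mask",
    "get_preset",
    "PRESET_NAMES",
    "load_config",
]

log = logging.getLogger("mreitep")

_MM = 1e-3

#: default field-dependent conductivity mechanism (see docs): conductivity
#: rises smoothly from its baseline below the reversible electroporation
#: threshold toward ``factor`` times baseline above the irreversible one.
DEFAULT_FIELD_DEPENDENT = {"E_rev": 4.0e4, "E_irrev": 8.0e4, "factor": 2.0}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Full description of one simulated MREIT experiment."""

    name: str
    phantom: PhantomSpec
    n: int = 64                      # imaging matrix (n x n)
    fov: float = 30e-3               # field of view (m)
    acq: AcquisitionParams = dfield(default_factory=AcquisitionParams)
    recon: ReconstructionConfig = dfield(default_factory=ReconstructionConfig)
    snr: Optional[float] = None      # phase SNR; None = noiseless
    seed: int = 0
    n_profile: int = 64              # samples along the evaluation line
    exclusion_mm: float = 2.0        # electrode-adjacent metric exclusion
    field_dependent: Optional[dict] = None
    eval_line: Optional[tuple] = None  # ((x0,y0),(x1,y1)) m; None = auto

    def __post_init__(self):
        if self.n_profile < 16:
            raise ParameterError("need at least 16 profile samples")

    def grid(self) -> Grid:
        return Grid.square(self.n, self.fov)

    def canonical_dict(self) -> dict:
        d = {
            "name": self.name,
            "phantom": {"preset": self.phantom.preset,
                        "params": {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in self.phantom.params.items()
                                   if not isinstance(v, np.ndarray)}},
            "n": self.n, "fov": self.fov,
            "acq": {"n_pulses": self.acq.n_pulses,
                    "pulse_duration": self.acq.pulse_duration,
                    "gamma": self.acq.gamma},
            "recon": {"sigma_init": (self.recon.sigma_init
                                     if np.isscalar(self.recon.sigma_init)
                                     else "map"),
                      "tol": self.recon.tol, "max_iter": self.recon.max_iter,
                      "sigma_floor": self.recon.sigma_floor,
                      "sigma_cap": self.recon.sigma_cap,
                      "change_norm": self.recon.change_norm},
            "snr": self.snr, "seed": self.seed,
            "n_profile": self.n_profile, "exclusion_mm": self.exclusion_mm,
            "field_dependent": self.field_dependent,
            "eval_line": ([list(p) for p in self.eval_line]
                          if self.eval_line else None),
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ProfileSeries:
    """|E| sampled along a line: arc-length positions (m), the MREIT value
    and, when available, the forward-model truth (V/m)."""

    positions: np.ndarray
    e_mreit: np.ndarray
    e_true: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.e_mreit = np.asarray(self.e_mreit, dtype=float)
        if len(self.positions) != len(self.e_mreit):
            raise ParameterError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ParameterError("positions must be strictly increasing")
        if self.e_true is not None:
            self.e_true = np.asarray(self.e_true, dtype=float)
            if len(self.e_true) != len(self.positions):
                raise ParameterError("truth series length mismatch")

    def rel_l2(self) -> float:
        if self.e_true is None:
            raise ParameterError("no truth series attached")
        return float(np.linalg.norm(self.e_mreit - self.e_true)
                     / np.linalg.norm(self.e_true))


@dataclass
class MetricsReport:
    """Evaluation summary of one reconstruction."""

    rel_l2: float
    max_rel: float
    region_medians: dict = dfield(default_factory=dict)
    iterations: Optional[int] = None
    converged: Optional[bool] = None
    profile_rel_l2: Optional[float] = None
    sigma_median_rel_err: Optional[float] = None
    sigma_region_medians: dict = dfield(default_factory=dict)
    config_hash: Optional[str] = None
    extras: dict = dfield(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


# ---------------------------------------------------------------------------
# Field-dependent conductivity (electroporation emulation)
# ---------------------------------------------------------------------------

def apply_field_dependent_sigma(sigma0: ConductivityMap, e_mag: np.ndarray,
                                params: dict) -> ConductivityMap:
    """Scale a baseline conductivity by a smooth function of |E|.

    The multiplier rises sigmoidally from 1 below the reversible threshold
    ``E_rev`` toward ``factor`` above the irreversible threshold
    ``E_irrev`` (both V/m), emulating the conductivity increase of
    electroporated tissue.  Always applied to the baseline ``sigma0``, so
    repeated application is idempotent at a fixed field.
    """
    E_rev, E_irrev = params["E_rev"], params["E_irrev"]
    factor = params["factor"]
    if not 0 < E_rev < E_irrev:
        raise ParameterError("need 0 < E_rev < E_irrev")
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    e = np.asarray(e_mag, dtype=float)
    mid = 0.5 * (E_rev + E_irrev)
    rate = 8.0 / (E_irrev - E_rev)
    s = 1.0 / (1.0 + np.exp(np.clip(-rate * (e - mid), -60, 60)))
    sigma = sigma0.sigma * (1.0 + (factor - 1.0) * s)
    return ConductivityMap(sigma0.grid, sigma, sigma0.mask)


def equilibrate_field_dependent_sigma(sigma0: ConductivityMap,
                                      electrodes: ElectrodeConfig,
                                      params: dict, tol: float = 0.01,
                                      max_rounds: int = 20,
                                      relax: float = 0.5,
                                      solver_tol: float = 1e-10):
    """Fixed point of the field-dependent conductivity with the forward
    solve: iterate sigma -> E(sigma) -> sigma0 * m(E) until the map changes
    by less than ``tol`` (relative max-norm).  Returns the equilibrated map.

    ``relax`` under-relaxes the update (the bare map can flip-flop across
    the permeabilization threshold where higher conductivity lowers the
    local field and vice versa).
    """
    sigma_map = sigma0.copy()
    history = []
    for _ in range(max_rounds):
        u = forward.solve_potential(sigma_map, electrodes, tol=solver_tol)
        e_mag = forward.electric_field(u).magnitude
        target = apply_field_dependent_sigma(sigma0, e_mag, params)
        m = sigma_map.mask
        blended = sigma_map.sigma + relax * (target.sigma - sigma_map.sigma)
        change = float(np.max(np.abs(blended[m] - sigma_map.sigma[m])
                              / sigma_map.sigma[m]))
        history.append(change)
        sigma_map = ConductivityMap(sigma_map.grid, blended, sigma_map.mask)
        if change < tol:
            return sigma_map
    raise jsubstitution.NonConvergenceError(
        "field-dependent conductivity fixed point did not settle", history)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def extract_profile(field: forward.EFieldMap, line, n: int) -> ProfileSeries:
    """Sample |E| by bilinear interpolation at n evenly spaced points of a
    line segment ((x0, y0), (x1, y1)) given in meters."""
    grid = field.grid
    (x0, y0), (x1, y1) = line
    for (x, y) in ((x0, y0), (x1, y1)):
        if not (grid.origin[0] <= x <= grid.origin[0] + grid.extent[0]
                and grid.origin[1] <= y <= grid.origin[1] + grid.extent[1]):
            raise GeometryError("profile endpoint outside the grid window")
    t = np.linspace(0.0, 1.0, n)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    ix = (xs - grid.origin[0]) / grid.spacing[0] - 0.5
    iy = (ys - grid.origin[1]) / grid.spacing[1] - 0.5
    vals = map_coordinates(field.magnitude, np.vstack([ix, iy]), order=1,
                           mode="nearest")
    positions = t * float(np.hypot(x1 - x0, y1 - y0))
    return ProfileSeries(positions=positions, e_mreit=vals)


def compare_fields(recon: forward.EFieldMap, truth: forward.EFieldMap,
                   roi: np.ndarray,
                   region_labels: Optional[np.ndarray] = None,
                   rel_floor: float = 1e-2) -> MetricsReport:
    """Relative L2 and max relative |E| errors over a region of interest.

    The max relative error is taken over ROI cells whose true magnitude
    exceeds ``rel_floor`` times the ROI maximum (cells with near-zero truth
    carry no meaningful relative error).  Per-region medians of the
    relative error are reported when integer region labels are supplied.
    """
    if recon.grid.shape != truth.grid.shape:
        raise ParameterError("fields live on different grids")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ParameterError("empty ROI")
    r = recon.magnitude[roi]
    t = truth.magnitude[roi]
    rel_l2 = float(np.linalg.norm(r - t) / np.linalg.norm(t))
    strong = t > rel_floor * t.max()
    max_rel = float(np.max(np.abs(r[strong] - t[strong]) / t[strong]))
    region_medians = {}
    if region_labels is not None:
        lab = np.asarray(region_labels)
        for rid in np.unique(lab[roi & (lab > 0)]):
            sel = roi & (lab == rid)
            tt = truth.magnitude[sel]
            rr = recon.magnitude[sel]
            ok = tt > 0
            region_medians[int(rid)] = float(
                np.median(np.abs(rr[ok] - tt[ok]) / tt[ok]))
    return MetricsReport(rel_l2=rel_l2, max_rel=max_rel,
                         region_medians=region_medians)


def electrode_exclusion_mask(grid: Grid, electrodes: ElectrodeConfig,
                             margin: float, active_only: bool = True
                             ) -> np.ndarray:
    """Cells within ``margin`` (m) of an electrode surface — excluded from
    error metrics, where field distortions around the needles dominate."""
    x, y = grid.coords()[:2]
    out = np.zeros(grid.shape, dtype=bool)
    for e in electrodes.electrodes:
        if active_only and e.role == "inactive":
            continue
        if e.cells is not None:
            from scipy.ndimage import binary_dilation
            it = max(1, int(np.ceil(margin / min(grid.spacing[:2]))))
            out |= binary_dilation(e.cells, iterations=it)
            continue
        r = np.sqrt((x - e.center[0]) ** 2 + (y - e.center[1]) ** 2)
        out |= (r >= e.radius - margin if e.invert
                else r <= e.radius + margin)
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _exvivo(voltage: float, pair: tuple) -> ExperimentConfig:
    name = f"exvivo_{int(voltage)}V_pair{pair[0]}{pair[1]}"
    return ExperimentConfig(
        name=name,
        phantom=PhantomSpec.exvivo_liver_4electrode(
            voltage=voltage, active_pair=pair),
        n=64, fov=30e-3,
        recon=ReconstructionConfig(change_norm="relative_l2"),
        field_dependent=dict(DEFAULT_FIELD_DEPENDENT),
    )


def _insilico_tumor() -> ExperimentConfig:
    return ExperimentConfig(
        name="insilico_tumor_1700V",
        phantom=PhantomSpec.tumor_region(voltage=1700.0),
        n=128, fov=60e-3,
        recon=ReconstructionConfig(change_norm="relative_l2"),
    )


def _insilico_tumor_liver() -> ExperimentConfig:
    return ExperimentConfig(
        name="insilico_tumor_liver_2100V",
        phantom=PhantomSpec.tumor_liver_region(voltage=2100.0),
        n=128, fov=60e-3,
        recon=ReconstructionConfig(change_norm="relative_l2"),
    )


_PRESETS = {
    "exvivo_1000V_pair12": lambda: _exvivo(1000.0, (1, 2)),
    "exvivo_1500V_pair12": lambda: _exvivo(1500.0, (1, 2)),
    "exvivo_1000V_pair13": lambda: _exvivo(1000.0, (1, 3)),
    "exvivo_1500V_pair13": lambda: _exvivo(1500.0, (1, 3)),
    "insilico_tumor_1700V": _insilico_tumor,
    "insilico_tumor_liver_2100V": _insilico_tumor_liver,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def get_preset(name: str, **overrides) -> ExperimentConfig:
    """Instantiate a named experiment preset, optionally overriding
    top-level config fields (e.g. ``snr=100, seed=3``)."""
    if name not in _PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    cfg = _PRESETS[name]()
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ParameterError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load an ExperimentConfig from YAML.

    Supported keys: ``preset`` (with optional overrides), or a full config
    with ``phantom: {preset, params}`` in mm-based units, ``n``, ``fov_mm``,
    ``acq: {n_pulses, pulse_duration_us, gamma}``, ``recon: {...}``,
    ``snr``, ``seed``, ``field_dependent``.
    """
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "preset" in raw:
        over = {k: v for k, v in raw.items() if k != "preset"}
        if "fov_mm" in over:
            over["fov"] = over.pop("fov_mm") * _MM
        if "acq" in over:
            a = over.pop("acq")
            over["acq"] = AcquisitionParams(
                n_pulses=a.get("n_pulses", 4),
                pulse_duration=a.get("pulse_duration_us", 100.0) * 1e-6,
                gamma=a.get("gamma", fieldsim.GAMMA_PROTON))
        if "recon" in over:
            over["recon"] = ReconstructionConfig(**over.pop("recon"))
        return get_preset(raw["preset"], **over)
    factory = getattr(PhantomSpec, raw["phantom"]["preset"])
    phantom = factory(**raw["phantom"].get("params", {}))
    acq_raw = raw.get("acq", {})
    acq = AcquisitionParams(
        n_pulses=acq_raw.get("n_pulses", 4),
        pulse_duration=acq_raw.get("pulse_duration_us", 100.0) * 1e-6,
        gamma=acq_raw.get("gamma", fieldsim.GAMMA_PROTON))
    recon = ReconstructionConfig(**raw.get("recon", {}))
    return ExperimentConfig(
        name=raw.get("name", "custom"), phantom=phantom,
        n=raw.get("n", 64), fov=raw.get("fov_mm", 30.0) * _MM,
        acq=acq, recon=recon, snr=raw.get("snr"), seed=raw.get("seed", 0),
        field_dependent=raw.get("field_dependent"))


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

def _auto_eval_line(electrodes: ElectrodeConfig, margin: float):
    """Inter-electrode line, trimmed by ``margin`` beyond each electrode
    surface so that the needle-adjacent distortion zone is excluded."""
    a = np.asarray(electrodes.anode.center[:2])
    c = np.asarray(electrodes.cathode.center[:2])
    d = c - a
    length = float(np.linalg.norm(d))
    unit = d / length
    start = a + (electrodes.anode.radius + margin) * unit
    end = c - (electrodes.cathode.radius + margin) * unit
    return (tuple(start), tuple(end))


def run_experiment(cfg: ExperimentConfig,
                   out_dir: Optional[Path] = None) -> MetricsReport:
    """Execute the full simulated-measurement/reconstruction chain.

    Writes, when ``out_dir`` is given: ``fields.h5`` (phantom, forward
    truth, CDI channel and reconstruction), NIfTI maps of sigma_MREIT and
    |E_MREIT|, the line-profile CSV and a JSON metrics report.  Fully
    deterministic for a fixed config (the report carries the config hash).
    """
    t0 = time.perf_counter()
    grid = cfg.grid()
    stage = "phantom"
    try:
        sigma_true, electrodes = build_phantom(cfg.phantom, grid)
        if cfg.field_dependent:
            stage = "field_dependent_sigma"
            sigma_true = equilibrate_field_dependent_sigma(
                sigma_true, electrodes, cfg.field_dependent)
        stage = "forward"
        u = forward.solve_potential(sigma_true, electrodes)
        j_true = forward.current_density(sigma_true, u)
        e_true = forward.electric_field(u)
        log.info("%s: forward solve done (%.2f s), residual %.1e",
                 cfg.name, time.perf_counter() - t0, u.residual)

        stage = "bz_synthesis"
        elec_mask = np.zeros(grid.shape, dtype=bool)
        for e in electrodes.electrodes:
            if e.role != "inactive":
                elec_mask |= e.rasterize(grid)
        # the generator-measured pulse current and the known needle
        # positions fix the monopole flow that B_z cannot see
        i_total = forward.electrode_current(j_true, electrodes,
                                            electrodes.anode.id)
        sources = [(electrodes.anode.center[:2], i_total,
                    electrodes.anode.radius),
                   (electrodes.cathode.center[:2], -i_total,
                    electrodes.cathode.radius)]
        bz = fieldsim.bz_from_current_2d(j_true, electrode_mask=elec_mask,
                                         sources=sources)

        stage = "phase"
        phi = fieldsim.encode_phase(bz, cfg.acq, wrap=False)
        if cfg.snr is not None:
            phi = fieldsim.add_phase_noise(phi, cfg.snr, cfg.seed)
        bz_meas = fieldsim.decode_phase(phi, cfg.acq)

        stage = "cdi"
        j_cdi = cdirecon.recover_current_bz(bz_meas, mask=sigma_true.mask,
                                            sources=sources)

        stage = "jsubstitution"
        recon_cfg = cfg.recon
        if recon_cfg.update_mask is None:
            # CDI data are unreliable in the sample rim (sensitivity
            # floor) and next to the needles (field distortion): update
            # sigma only in the interior and extend outward
            from scipy.ndimage import binary_erosion
            interior = (binary_erosion(sigma_true.mask, iterations=2)
                        & ~electrode_exclusion_mask(grid, electrodes, 1e-3))
            recon_cfg = ReconstructionConfig(
                sigma_init=recon_cfg.sigma_init, tol=recon_cfg.tol,
                max_iter=recon_cfg.max_iter,
                sigma_floor=recon_cfg.sigma_floor,
                sigma_cap=recon_cfg.sigma_cap,
                roi_mask=recon_cfg.roi_mask, update_mask=interior,
                keep_best=True, change_norm=recon_cfg.change_norm)
        result = jsubstitution.jsub_reconstruct(
            j_cdi, electrodes, recon_cfg, mask=sigma_true.mask)
        log.info("%s: J-substitution %s in %d iterations", cfg.name,
                 "converged" if result.converged else "stopped",
                 result.iterations)

        stage = "evaluation"
        margin = cfg.exclusion_mm * _MM
        excl = electrode_exclusion_mask(grid, electrodes, margin)
        roi = sigma_true.mask & ~excl
        labels = None
        if cfg.phantom.preset == "tumor_liver_region":
            labels = region_labels_tumor_liver(cfg.phantom, grid)
        metrics = compare_fields(result.e_field, e_true, roi,
                                 region_labels=labels)
        line = cfg.eval_line or _auto_eval_line(electrodes, margin)
        prof_m = extract_profile(result.e_field, line, cfg.n_profile)
        prof_t = extract_profile(e_true, line, cfg.n_profile)
        profile = ProfileSeries(prof_m.positions, prof_m.e_mreit,
                                prof_t.e_mreit)
        metrics.profile_rel_l2 = profile.rel_l2()
        metrics.iterations = result.iterations
        metrics.converged = result.converged
        sig_rel = (np.abs(result.sigma_mreit.sigma[roi]
                          - sigma_true.sigma[roi]) / sigma_true.sigma[roi])
        metrics.sigma_median_rel_err = float(np.median(sig_rel))
        if labels is not None:
            for rid in (1, 2):
                sel = roi & (labels == rid)
                metrics.sigma_region_medians[int(rid)] = float(np.median(
                    np.abs(result.sigma_mreit.sigma[sel]
                           - sigma_true.sigma[sel]) / sigma_true.sigma[sel]))
        metrics.config_hash = cfg.config_hash()
        metrics.extras["eval_line_m"] = [list(line[0]), list(line[1])]
        log.info("%s: finished in %.2f s", cfg.name,
                 time.perf_counter() - t0)

        if out_dir is not None:
            stage = "artifacts"
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            import h5py
            with h5py.File(out / "fields.h5", "w") as h5:
                mio.write_field(h5, "/phantom/sigma", sigma_true.sigma, grid,
                                "S/m")
                mio.write_field(h5, "/phantom/mask",
                                sigma_true.mask.astype(np.uint8), grid, "")
                mio.write_field(h5, "/forward/u", u.u, grid, "V")
                mio.write_field(h5, "/forward/J", j_true.J, grid, "A/m^2")
                mio.write_field(h5, "/forward/E", e_true.E, grid, "V/m")
                mio.write_field(h5, "/cdi/bz", bz_meas.bz, grid, "T")
                mio.write_field(h5, "/cdi/phi", phi.phi, grid, "rad")
                mio.write_field(h5, "/cdi/J_cdi", j_cdi.J, grid, "A/m^2")
                mio.write_field(h5, "/recon/sigma", result.sigma_mreit.sigma,
                                grid, "S/m")
                mio.write_field(h5, "/recon/E", result.e_field.E, grid, "V/m")
                mio.write_field(h5, "/recon/history",
                                np.asarray(result.history), grid, "")
            mio.write_nifti(out / "sigma_mreit.nii.gz",
                            result.sigma_mreit.sigma, grid)
            mio.write_nifti(out / "e_mreit_mag.nii.gz",
                            result.e_field.magnitude, grid)
            mio.write_profile_csv(out / "profile.csv", profile.positions,
                                  profile.e_mreit, profile.e_true)
            (out / "metrics.json").write_text(metrics.to_json())
        return metrics
    except Exception as err:
        if isinstance(err, (ParameterError, GeometryError)):
            raise
        raise RuntimeError(f"experiment {cfg.name!r} failed at stage "
                           f"{stage!r}: {err}") from err


def extrude_planar_bz(bz2d: fieldsim.BzMap, nz: int) -> tuple:
    """Thin-slab 3D field from a planar B_z: B = (0, 0, B_z(x, y)) extruded
    along z.  For z-invariant planar currents the in-plane components
    vanish, so this is the slab-mode input to the full Ampere recovery."""
    if nz < 8:
        raise ParameterError("slab needs at least 8 cells along z")
    g2 = bz2d.grid
    grid3 = Grid(shape=(*g2.shape, nz),
                 spacing=(*g2.spacing, g2.spacing[0]),
                 origin=(*g2.origin, 0.0))
    bz3 = np.repeat(bz2d.bz[:, :, None], nz, axis=2)
    zeros = np.zeros(grid3.shape)
    return zeros, zeros.copy(), bz3, grid3
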