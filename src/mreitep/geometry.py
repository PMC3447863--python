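"""Grids, conductivity phantoms and electrode layouts.

The phantoms emulate the two study configurations used throughout the
package: a cylindrical liver sample (20 mm diameter) with four 1 mm needle
electrodes, and idealized 2D sections of a deep-seated liver tumor with a
homogeneous tumor conductivity ``sigma_T = 0.4 S/m`` embedded in liver
tissue at ``sigma_L = 0.05 S/m``, joined by a sigmoid conductivity
transition.

Conventions
-----------
* SI units internally (meters, S/m, volts); preset factories accept ``*_mm``
  keyword arguments for convenience.
* Fields are stored as ``(nx, ny)`` (or ``(nx, ny, nz)``) arrays: axis 0 is
  x, axis 1 is y. Cell-centered, 0-based indexing; the world coordinate of
  cell ``i`` along an axis is ``origin + (i + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "ResolutionError",
    "ParameterError",
    "Grid",
    "ConductivityMap",
    "Electrode",
    "ElectrodeConfig",
    "PhantomSpec",
    "sigmoid_transition",
    "build_phantom",
    "PRESETS",
]


class GeometryError(ValueError):
    """Electrode placement inconsistent with the sample geometry."""


class ResolutionError(ValueError):
    """Grid too coarse to resolve a geometric feature."""


class ParameterError(ValueError):
    """Invalid phantom or operation parameter."""


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Regular cell-centered grid in 2D or 3D.

    Parameters
    ----------
    shape
        Number of cells per axis, each >= 8.
    spacing
        Cell size per axis in meters (isotropic per axis).
    origin
        World coordinate of the lower corner of the first cell, meters.
    """

    shape: tuple
    spacing: tuple
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ParameterError("grid must be 2D or 3D")
        if any(n < 8 for n in shape):
            raise ParameterError("grid needs at least 8 cells per axis")
        spacing = self.spacing
        if np.isscalar(spacing):
            spacing = (float(spacing),) * len(shape)
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != len(shape):
            raise ParameterError("spacing length must match shape")
        if any(s <= 0 for s in spacing):
            raise ParameterError("spacing must be positive")
        object.__setattr__(self, "spacing", spacing)
        origin = self.origin
        if origin is None:
            origin = (0.0,) * len(shape)
        origin = tuple(float(o) for o in origin)
        if len(origin) != len(shape):
            raise ParameterError("origin length must match shape")
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent(self) -> tuple:
        """Physical size per axis (m)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center(self) -> tuple:
        return tuple(o + 0.5 * e for o, e in zip(self.origin, self.extent))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Cell-center coordinates along one axis (m)."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def coords(self):
        """Broadcastable cell-center coordinate arrays, one per axis."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(self.ndim)),
                           indexing="ij")

    def refine(self, factor: int = 2) -> "Grid":
        """Same physical window at ``factor``-times finer resolution."""
        return Grid(
            shape=tuple(n * factor for n in self.shape),
            spacing=tuple(s / factor for s in self.spacing),
            origin=self.origin,
        )

    @classmethod
    def square(cls, n: int, fov: float, origin: Optional[tuple] = None) -> "Grid":
        """2D square grid of ``n`` x ``n`` cells over a field of view ``fov`` (m)."""
        if origin is None:
            origin = (0.0, 0.0)
        return cls(shape=(n, n), spacing=(fov / n, fov / n), origin=origin)


# ---------------------------------------------------------------------------
# Conductivity map and electrodes
# ---------------------------------------------------------------------------

@dataclass
class ConductivityMap:
    """Scalar conductivity field sigma (S/m) on a grid with a sample mask.

    Cells outside ``mask`` are insulating (treated as sigma = 0); inside the
    mask sigma must be positive and finite.
    """

    grid: Grid
    sigma: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.sigma.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ParameterError("sigma/mask shape must match grid shape")
        inside = self.sigma[self.mask]
        if inside.size and (not np.all(np.isfinite(inside)) or np.any(inside <= 0)):
            raise ParameterError("sigma must be positive and finite inside the mask")

    @property
    def effective(self) -> np.ndarray:
        """sigma with exterior cells zeroed."""
        return np.where(self.mask, self.sigma, 0.0)

    def copy(self) -> "ConductivityMap":
        return ConductivityMap(self.grid, self.sigma.copy(), self.mask.copy())


@dataclass(frozen=True)
class Electrode:
    """A needle electrode, rasterized as a filled disk (2D) or cylinder (3D).

    ``invert=True`` makes the electrode occupy ``r >= radius`` instead — used
    for the outer ring contact of the annulus oracle phantom.  ``cells`` may
    carry an explicit boolean rasterization that overrides the analytic disk
    (used for slab-edge contacts in tests); geometric boundary corrections
    are skipped for such electrodes.
    """

    id: int
    center: tuple
    radius: float
    role: str = "inactive"  # anode | cathode | inactive
    invert: bool = False
    cells: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.role not in ("anode", "cathode", "inactive"):
            raise ParameterError(f"unknown electrode role {self.role!r}")
        if self.cells is None and self.radius <= 0:
            raise ParameterError("electrode radius must be positive")

    def rasterize(self, grid: Grid) -> np.ndarray:
        """Boolean array of cells covered by this electrode."""
        if self.cells is not None:
            cells = np.asarray(self.cells, dtype=bool)
            if cells.shape != grid.shape:
                raise ParameterError("explicit electrode cells must match grid shape")
            return cells
        coords = grid.coords()
        # needles run along z in 3D: in-plane distance only
        r2 = sum((coords[a] - self.center[a]) ** 2 for a in range(min(grid.ndim, 2)))
        disk = r2 <= self.radius ** 2
        return ~disk if self.invert else disk

    def axis_distance_to_surface(self, point: Sequence[float], axis: int,
                                 step: float) -> Optional[float]:
        """Distance from ``point`` along ``axis`` to the electrode circle.

        Returns the first crossing t in (0, |step|] of the circle
        ``|p + t*e_axis - center| = radius`` (in-plane), or None when the
        segment between the cell centers does not cross the surface (or the
        electrode has no analytic shape).  Used for the sub-cell Dirichlet
        boundary correction in the forward solver.
        """
        if self.cells is not None or axis >= 2:
            return None
        d = [point[a] - self.center[a] for a in range(2)]
        sgn = 1.0 if step > 0 else -1.0
        # |d + t*sgn*e|^2 = R^2, t in (0, |step|]
        a = 1.0
        b = 2.0 * sgn * d[axis]
        c = d[0] ** 2 + d[1] ** 2 - self.radius ** 2
        disc = b * b - 4 * a * c
        if disc < 0:
            return None
        roots = sorted([(-b - np.sqrt(disc)) / 2, (-b + np.sqrt(disc)) / 2])
        for t in roots:
            if 0.0 < t <= abs(step) + 1e-15:
                return float(t)
        return None


@dataclass
class ElectrodeConfig:
    """Electrode layout and the applied inter-electrode voltage U_el (V).

    Exactly one anode and one cathode must be active; the anode is driven at
    ``voltage`` and the cathode is the 0 V reference.
    """

    electrodes: list
    voltage: float

    def __post_init__(self):
        roles = [e.role for e in self.electrodes]
        if roles.count("anode") != 1 or roles.count("cathode") != 1:
            raise ParameterError("exactly one anode and one cathode required")
        if self.voltage <= 0:
            raise ParameterError("applied voltage must be positive")
        ids = [e.id for e in self.electrodes]
        if len(set(ids)) != len(ids):
            raise ParameterError("electrode ids must be unique")

    def get(self, eid: int) -> Electrode:
        for e in self.electrodes:
            if e.id == eid:
                return e
        raise KeyError(f"no electrode with id {eid}")

    @property
    def anode(self) -> Electrode:
        return next(e for e in self.electrodes if e.role == "anode")

    @property
    def cathode(self) -> Electrode:
        return next(e for e in self.electrodes if e.role == "cathode")

    def with_active_pair(self, anode_id: int, cathode_id: int,
                         voltage: Optional[float] = None) -> "ElectrodeConfig":
        """Return a copy with a different active pair."""
        new = []
        for e in self.electrodes:
            role = ("anode" if e.id == anode_id
                    else "cathode" if e.id == cathode_id else "inactive")
            new.append(replace(e, role=role))
        return ElectrodeConfig(new, self.voltage if voltage is None else voltage)

    def electrode_voltage(self, e: Electrode) -> float:
        return self.voltage if e.role == "anode" else 0.0


# ---------------------------------------------------------------------------
# Sigmoid tissue transition
# ---------------------------------------------------------------------------

def sigmoid_transition(signed_distance, width, sigma_a, sigma_b):
    """Smooth conductivity interpolation across a tissue boundary.

    A logistic curve in the signed distance from the interface: returns
    ``sigma_a`` far on the negative side and ``sigma_b`` far on the positive
    side, with ``(sigma_a + sigma_b) / 2`` exactly at the interface.  The
    ``width`` parameter is the 12-88 % transition width (the logistic rate is
    ``4 / width``).

    Parameters
    ----------
    signed_distance
        Distance from the interface (m), negative on the ``sigma_a`` side.
    width
        Transition width (m), > 0.
    sigma_a, sigma_b
        Plateau conductivities (S/m).
    """
    if width <= 0:
        raise ParameterError("transition width must be positive")
    d = np.asarray(signed_distance, dtype=float)
    # clip the exponent to avoid overflow at extreme distances
    z = np.clip(4.0 * d / width, -60.0, 60.0)
    s = 1.0 / (1.0 + np.exp(-z))
    return sigma_a + (sigma_b - sigma_a) * s


# ---------------------------------------------------------------------------
# Phantom presets
# ---------------------------------------------------------------------------

_MM = 1e-3

PRESETS = (
    "homogeneous_disc",
    "exvivo_liver_4electrode",
    "tumor_region",
    "tumor_liver_region",
    "annulus",
    "custom",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Named phantom preset with its parameters (SI units).

    Use the classmethod factories (which accept ``*_mm`` lengths) rather
    than the raw constructor.
    """

    preset: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ParameterError(f"unknown preset {self.preset!r}")

    # -- factories ---------------------------------------------------------

    @classmethod
    def homogeneous_disc(cls, sigma: float = 0.1, diameter_mm: float = 20.0,
                         electrode_spacing_mm: float = 10.0,
                         electrode_radius_mm: float = 0.5,
                         voltage: float = 1000.0,
                         with_electrodes: bool = True) -> "PhantomSpec":
        """Uniform disc, optionally with an axial needle-electrode pair."""
        return cls("homogeneous_disc", dict(
            sigma=sigma, diameter=diameter_mm * _MM,
            electrode_spacing=electrode_spacing_mm * _MM,
            electrode_radius=electrode_radius_mm * _MM,
            voltage=voltage, with_electrodes=with_electrodes))

    @classmethod
    def exvivo_liver_4electrode(cls, sigma: float = 0.1,
                                diameter_mm: float = 20.0,
                                electrode_square_mm: float = 8.0,
                                electrode_radius_mm: float = 0.5,
                                active_pair: tuple = (1, 2),
                                voltage: float = 1000.0) -> "PhantomSpec":
        """Liver sample: 20 mm disc, four 1 mm needles on a square.

        Electrodes are numbered 1-4 counter-clockwise starting lower-left;
        the deliverable pulse pairs are 1-2 (adjacent) and 1-3 (diagonal).
        """
        if tuple(active_pair) not in ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)):
            raise ParameterError("active_pair must name two of electrodes 1-4")
        return cls("exvivo_liver_4electrode", dict(
            sigma=sigma, diameter=diameter_mm * _MM,
            electrode_square=electrode_square_mm * _MM,
            electrode_radius=electrode_radius_mm * _MM,
            active_pair=tuple(active_pair), voltage=voltage))

    @classmethod
    def tumor_region(cls, sigma_tumor: float = 0.4,
                     diameter_mm: float = 36.0,
                     electrode_spacing_mm: float = 20.0,
                     electrode_radius_mm: float = 0.9,
                     voltage: float = 1700.0) -> "PhantomSpec":
        """Homogeneous tumor section with the pulse pair spanning it."""
        return cls("tumor_region", dict(
            sigma=sigma_tumor, diameter=diameter_mm * _MM,
            electrode_spacing=electrode_spacing_mm * _MM,
            electrode_radius=electrode_radius_mm * _MM,
            voltage=voltage))

    @classmethod
    def tumor_liver_region(cls, sigma_tumor: float = 0.4,
                           sigma_liver: float = 0.05,
                           sample_diameter_mm: float = 48.0,
                           transition_width_mm: float = 1.0,
                           electrode_spacing_mm: float = 20.0,
                           electrode_radius_mm: float = 0.9,
                           orientation: str = "margin",
                           voltage: float = 2100.0) -> "PhantomSpec":
        """Two-tissue region: tumor and liver joined by a sigmoid transition.

        ``orientation`` places the needle pair relative to the (locally
        planar) tumor-liver interface:

        * ``"margin"`` (default) — the pair lies along the interface, the
          arrangement used to secure field coverage of the tumor margin.
          Conductivity contrast is then transverse to the pulse current,
          the direction in which single-direction MREIT data determine it.
        * ``"crossing"`` — the pair straddles the interface, so the current
          crosses it in series.  In this orientation the interior current
          magnitude from one pulse direction does not determine the
          conductivity split (the single-direction non-uniqueness); kept to
          demonstrate that limitation.
        """
        if orientation not in ("margin", "crossing"):
            raise ParameterError("orientation must be 'margin' or 'crossing'")
        return cls("tumor_liver_region", dict(
            sigma_tumor=sigma_tumor, sigma_liver=sigma_liver,
            sample_diameter=sample_diameter_mm * _MM,
            transition_width=transition_width_mm * _MM,
            electrode_spacing=electrode_spacing_mm * _MM,
            electrode_radius=electrode_radius_mm * _MM,
            orientation=orientation, voltage=voltage))

    @classmethod
    def annulus(cls, sigma: float = 0.1, inner_radius_mm: float = 2.0,
                outer_radius_mm: float = 10.0,
                voltage: float = 1.0) -> "PhantomSpec":
        """Coaxial phantom: center disk anode, outer ring cathode.

        The potential has the closed form U ln(b/r)/ln(b/a); used as the
        forward-solver oracle.
        """
        return cls("annulus", dict(
            sigma=sigma, inner_radius=inner_radius_mm * _MM,
            outer_radius=outer_radius_mm * _MM, voltage=voltage))

    @classmethod
    def custom(cls, sigma: np.ndarray, mask: np.ndarray,
               electrodes: list, voltage: float) -> "PhantomSpec":
        return cls("custom", dict(sigma=sigma, mask=mask,
                                  electrodes=electrodes, voltage=voltage))


def _check_electrodes(sigma_map: ConductivityMap, config: ElectrodeConfig,
                      grid: Grid) -> None:
    rasters = []
    for e in config.electrodes:
        cells = e.rasterize(grid)
        if e.invert:
            cells = cells & sigma_map.mask  # ring contact: in-sample part
        if not cells.any():
            raise ResolutionError(
                f"electrode {e.id} is not resolved by the grid "
                f"(radius {e.radius:g} m vs spacing {max(grid.spacing):g} m)")
        if e.cells is None and not e.invert:
            if min(grid.spacing[:2]) > e.radius:
                raise ResolutionError(
                    f"electrode {e.id} needs >= 2 cells across its diameter")
        if not np.all(sigma_map.mask[cells]):
            raise GeometryError(f"electrode {e.id} extends outside the sample")
        rasters.append(cells)
    for i in range(len(rasters)):
        for j in range(i + 1, len(rasters)):
            if np.any(rasters[i] & rasters[j]):
                raise GeometryError(
                    f"electrodes {config.electrodes[i].id} and "
                    f"{config.electrodes[j].id} overlap")


def build_phantom(spec: PhantomSpec, grid: Grid):
    """Rasterize a phantom preset onto a grid.

    Returns
    -------
    (ConductivityMap, ElectrodeConfig)

    Raises
    ------
    GeometryError
        If an electrode lies outside the sample or electrodes overlap.
    ResolutionError
        If the grid cannot resolve an electrode.
    """
    p = dict(spec.params)
    cx, cy = grid.center[0], grid.center[1]
    coords = grid.coords()
    r = np.sqrt((coords[0] - cx) ** 2 + (coords[1] - cy) ** 2)

    if spec.preset == "custom":
        sigma_map = ConductivityMap(grid, p["sigma"], p["mask"])
        config = ElectrodeConfig(list(p["electrodes"]), p["voltage"])
        _check_electrodes(sigma_map, config, grid)
        return sigma_map, config

    if spec.preset == "annulus":
        a, b = p["inner_radius"], p["outer_radius"]
        if not 0 < a < b:
            raise ParameterError("annulus needs 0 < inner < outer radius")
        dx = max(grid.spacing[:2])
        mask = r <= b + 2.0 * dx  # the outer-ring contact is part of the sample
        sigma = np.full(grid.shape, p["sigma"])
        electrodes = [
            Electrode(1, (cx, cy), a, "anode"),
            Electrode(2, (cx, cy), b, "cathode", invert=True),
        ]
        config = ElectrodeConfig(electrodes, p["voltage"])
        sigma_map = ConductivityMap(grid, sigma, mask)
        _check_electrodes(sigma_map, config, grid)
        return sigma_map, config

    if spec.preset in ("homogeneous_disc", "tumor_region"):
        radius = p["diameter"] / 2
        mask = r <= radius
        sigma = np.full(grid.shape, p["sigma"])
        electrodes = []
        if p.get("with_electrodes", True):
            half = p["electrode_spacing"] / 2
            electrodes = [
                Electrode(1, (cx - half, cy), p["electrode_radius"], "anode"),
                Electrode(2, (cx + half, cy), p["electrode_radius"], "cathode"),
            ]
        if not electrodes:
            # a buildable phantom still needs a driven pair for the solver;
            # callers wanting geometry only can ignore the config
            electrodes = [
                Electrode(1, (cx - radius / 2, cy), max(grid.spacing[:2]), "anode"),
                Electrode(2, (cx + radius / 2, cy), max(grid.spacing[:2]), "cathode"),
            ]
        config = ElectrodeConfig(electrodes, p["voltage"])
        sigma_map = ConductivityMap(grid, sigma, mask)
        _check_electrodes(sigma_map, config, grid)
        return sigma_map, config

    if spec.preset == "exvivo_liver_4electrode":
        radius = p["diameter"] / 2
        mask = r <= radius
        sigma = np.full(grid.shape, p["sigma"])
        half = p["electrode_square"] / 2
        # 1: lower-left, 2: lower-right, 3: upper-right, 4: upper-left
        centers = {1: (cx - half, cy - half), 2: (cx + half, cy - half),
                   3: (cx + half, cy + half), 4: (cx - half, cy + half)}
        an, ca = p["active_pair"]
        electrodes = [
            Electrode(i, centers[i], p["electrode_radius"],
                      "anode" if i == an else "cathode" if i == ca else "inactive")
            for i in (1, 2, 3, 4)
        ]
        config = ElectrodeConfig(electrodes, p["voltage"])
        sigma_map = ConductivityMap(grid, sigma, mask)
        _check_electrodes(sigma_map, config, grid)
        return sigma_map, config

    if spec.preset == "tumor_liver_region":
        radius = p["sample_diameter"] / 2
        mask = r <= radius
        half = p["electrode_spacing"] / 2
        if p["orientation"] == "margin":
            # interface along x at y = cy: tumor below, liver above;
            # needles inserted along the margin line
            signed = coords[1] - cy  # negative on the tumor side
            sigma = sigmoid_transition(signed, p["transition_width"],
                                       p["sigma_tumor"], p["sigma_liver"])
            electrodes = [
                Electrode(1, (cx - half, cy), p["electrode_radius"], "anode"),
                Electrode(2, (cx + half, cy), p["electrode_radius"], "cathode"),
            ]
        else:  # crossing: pair straddles the interface at x = cx
            signed = coords[0] - cx
            sigma = sigmoid_transition(signed, p["transition_width"],
                                       p["sigma_tumor"], p["sigma_liver"])
            electrodes = [
                Electrode(1, (cx - half, cy), p["electrode_radius"], "anode"),
                Electrode(2, (cx + half, cy), p["electrode_radius"], "cathode"),
            ]
        config = ElectrodeConfig(electrodes, p["voltage"])
        sigma_map = ConductivityMap(grid, sigma, mask)
        _check_electrodes(sigma_map, config, grid)
        return sigma_map, config

    raise ParameterError(f"unknown preset {spec.preset!r}")  # pragma: no cover


def region_labels_tumor_liver(spec: PhantomSpec, grid: Grid) -> np.ndarray:
    """Integer labels for the two-tissue phantom: 1 = tumor plateau,
    2 = liver plateau, 0 = transition zone / exterior."""
    if spec.preset != "tumor_liver_region":
        raise ParameterError("labels defined for the tumor_liver_region preset")
    p = spec.params
    cx, cy = grid.center[0], grid.center[1]
    coords = grid.coords()
    r = np.sqrt((coords[0] - cx) ** 2 + (coords[1] - cy) ** 2)
    signed = (coords[1] - cy) if p["orientation"] == "margin" else (coords[0] - cx)
    w = p["transition_width"]
    inside = r <= p["sample_diameter"] / 2
    labels = np.zeros(grid.shape, dtype=int)
    labels[inside & (signed <= -2 * w)] = 1  # tumor plateau
    labels[inside & (signed >= 2 * w)] = 2   # liver plateau
    return labels
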