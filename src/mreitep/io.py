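"""File exchange: HDF5 field archives, NIfTI volumes, CSV profiles, YAML.

HDF5 layout
-----------
/phantom/sigma, /phantom/mask      conductivity phantom (S/m)
/forward/u, /forward/J, /forward/E forward-model truth
/cdi/bz, /cdi/phi, /cdi/J_cdi      measurement channel
/recon/sigma, /recon/E, /recon/history  reconstruction outputs

Grid geometry (shape, spacing, origin) and units are stored as attributes
on each dataset.  NIfTI volumes are written float32 with the grid spacing
in mm in the header, one file per scalar field or vector component.
"""

from __future__ import annotations

from typing import Optional

import h5py
import numpy as np

from .geometry import Grid

__all__ = [
    "write_field",
    "read_field",
    "read_grid",
    "write_nifti",
    "read_nifti",
    "write_profile_csv",
]


def _set_grid_attrs(ds, grid: Grid, units: str):
    ds.attrs["spacing_m"] = np.asarray(grid.spacing)
    ds.attrs["origin_m"] = np.asarray(grid.origin)
    ds.attrs["units"] = units


def write_field(h5: h5py.File, path: str, data: np.ndarray, grid: Grid,
                units: str = ""):
    if path in h5:
        del h5[path]
    ds = h5.create_dataset(path, data=np.asarray(data))
    _set_grid_attrs(ds, grid, units)
    return ds


def read_field(h5: h5py.File, path: str) -> np.ndarray:
    return np.asarray(h5[path])


def read_grid(h5: h5py.File, path: str) -> Grid:
    ds = h5[path]
    shape = ds.shape
    spacing = tuple(float(s) for s in ds.attrs["spacing_m"])
    origin = tuple(float(o) for o in ds.attrs["origin_m"])
    # vector datasets carry the component axis last
    if len(shape) == len(spacing) + 1:
        shape = shape[:-1]
    return Grid(shape=tuple(shape), spacing=spacing, origin=origin)


def write_nifti(path, data: np.ndarray, grid: Grid):
    """Write a scalar volume as NIfTI-1, float32, spacing in mm."""
    import nibabel as nib
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
        spacing = (*grid.spacing, grid.spacing[0])
    else:
        spacing = grid.spacing
    affine = np.diag([*(s * 1e3 for s in spacing[:3]), 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(s * 1e3 for s in spacing[:3]))
    nib.save(img, str(path))


def read_nifti(path) -> np.ndarray:
    import nibabel as nib
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def write_profile_csv(path, positions_m: np.ndarray, e_mreit: np.ndarray,
                      e_true: Optional[np.ndarray] = None):
    """Line-profile CSV: position_m, E_mreit_Vpm[, E_true_Vpm]."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if e_true is None:
            w.writerow(["position_m", "E_mreit_Vpm"])
            for p, e in zip(positions_m, e_mreit):
                w.writerow([f"{p:.12g}", f"{e:.12g}"])
        else:
            w.writerow(["position_m", "E_mreit_Vpm", "E_true_Vpm"])
            for p, e, t in zip(positions_m, e_mreit, e_true):
                w.writerow([f"{p:.12g}", f"{e:.12g}", f"{t:.12g}"])
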