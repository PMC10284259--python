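"""NIfTI and tabular input/output helpers."""

from __future__ import annotations

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import BoldRun, Grid

__all__ = [
    "save_bold_run",
    "load_bold_run",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_timecourses",
    "load_timecourses",
]


def save_bold_run(run: BoldRun, path) -> None:
    """Write a BOLD run as 4D NIfTI-1 (x, y, z, t)."""
    vol = run.data.T.reshape(run.grid.shape + (run.n_volumes,))
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), run.grid.affine)
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, path)


def load_bold_run(path, subject_id: str, run_id: str, tr: float | None = None) -> BoldRun:
    img = nib.load(path)
    vol = np.asarray(img.get_fdata(), dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a 4D BOLD image")
    grid = Grid(vol.shape[:3], affine=np.asarray(img.affine))
    data = vol.reshape(-1, vol.shape[3]).T
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BoldRun(data=data, tr=tr, grid=grid, subject_id=subject_id, run_id=run_id)


def save_volume(flat_or_vol: np.ndarray, grid: Grid, path) -> None:
    """Write a 3D scalar map (flattened or grid-shaped) as NIfTI-1."""
    vol = np.asarray(flat_or_vol, dtype=np.float32)
    if vol.ndim == 1:
        vol = grid.unflatten(vol)
    nib.save(nib.Nifti1Image(vol, grid.affine), path)


def load_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(path)
    vol = np.asarray(img.get_fdata(), dtype=float)
    return vol, Grid(vol.shape, affine=np.asarray(img.affine))


def save_mask(mask: np.ndarray, grid: Grid, path) -> None:
    vol = np.asarray(mask)
    if vol.ndim == 1:
        vol = grid.unflatten(vol)
    nib.save(nib.Nifti1Image(vol.astype(np.uint8), grid.affine), path)


def load_mask(path) -> tuple[np.ndarray, Grid]:
    vol, grid = load_volume(path)
    return vol > 0.5, grid


def save_timecourses(tc: np.ndarray, path, prefix: str = "component") -> None:
    """Write a (time, component) array as CSV with labelled columns."""
    cols = [f"{prefix}_{i}" for i in range(tc.shape[1])]
    pd.DataFrame(tc, columns=cols).to_csv(path, index=False, float_format="%.10g")


def load_timecourses(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)
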