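"""NIfTI and delimited-table I/O.

Runs and 3D maps travel as NIfTI-1 (via nibabel) with the voxel size in
the header zooms and, for 4D runs, the TR in the fourth zoom.  Tables are
tab-separated text with a header row and an optional leading comment line
carrying the pipeline configuration hash, so outputs are diffable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import BoldRun, BrainMask

__all__ = [
    "read_bold", "write_bold", "read_mask", "write_mask",
    "read_map", "write_map", "read_table", "write_table",
]


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def write_bold(run: BoldRun, path: str | Path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), _affine(run.voxel_size))
    img.header.set_zooms((*run.voxel_size, run.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold(path: str | Path, tr: float | None = None) -> BoldRun:
    """Read a 4D run; the TR comes from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D run, got {data.ndim}D")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    tr = tr if tr is not None else header_tr
    if tr <= 0:
        raise ValueError(f"{path}: no usable TR in header; pass tr=")
    return BoldRun(data=data, voxel_size=tuple(float(z) for z in zooms[:3]),
                   tr=tr, provenance=[f"read: {path}"])


def write_mask(mask: BrainMask, path: str | Path,
               voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(mask.inside.astype(np.uint8), _affine(voxel_size))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    unique = np.unique(data)
    if not np.isin(unique, (0.0, 1.0)).all():
        warnings.warn(f"{path}: non-binary mask values coerced with > 0.5",
                      stacklevel=2)
    return BrainMask(data > 0.5)


def write_map(values: np.ndarray, path: str | Path,
              voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a 3D statistical map (NaN allowed outside the mask)."""
    if values.ndim != 3:
        raise ValueError("map must be 3D")
    img = nib.Nifti1Image(values.astype(np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def read_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got {data.ndim}D")
    return data


def write_table(frame: pd.DataFrame, path: str | Path,
                config_hash: str | None = None, index: bool = True) -> None:
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", float_format="%.6f", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
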