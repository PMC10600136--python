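"""File I/O: delimited tables, HDF5 containers, optional NIfTI volumes."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .hb_signal import DEFAULT_FRAME_RATE

__all__ = [
    "read_table",
    "write_table",
    "read_hdf5_pair",
    "write_hdf5_pair",
    "read_nifti",
]


def read_table(path) -> np.ndarray:
    """Read a frames x voxels matrix from TSV/CSV (header row = voxel ids)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    return df.to_numpy(dtype=float)


def write_table(path, matrix: np.ndarray, voxel_ids=None) -> None:
    """Write a frames x voxels matrix as TSV/CSV with a voxel-id header."""
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix))
    if voxel_ids is None:
        voxel_ids = [f"v{j}" for j in range(matrix.shape[1])]
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(matrix, columns=voxel_ids).to_csv(path, sep=sep, index=False)


def read_hdf5_pair(path) -> Tuple[np.ndarray, np.ndarray, float]:
    """Read datasets ``oxy``/``deoxy`` and attribute ``frame_rate``."""
    import h5py

    with h5py.File(path, "r") as f:
        oxy = np.asarray(f["oxy"], dtype=float)
        deoxy = np.asarray(f["deoxy"], dtype=float)
        frame_rate = float(f.attrs.get("frame_rate", DEFAULT_FRAME_RATE))
    return oxy, deoxy, frame_rate


def write_hdf5_pair(path, oxy: np.ndarray, deoxy: np.ndarray,
                    frame_rate: float = DEFAULT_FRAME_RATE) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("oxy", data=np.asarray(oxy, dtype=float))
        f.create_dataset("deoxy", data=np.asarray(deoxy, dtype=float))
        f.attrs["frame_rate"] = frame_rate


def read_nifti(path, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Flatten a 4D NIfTI volume to a frames x voxels matrix.

    ``mask`` is a boolean 3D array selecting voxel columns; without it all
    voxels are kept.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match volume")
        flat = data[mask, :]          # (n_voxels, n_frames)
    else:
        flat = data.reshape(-1, data.shape[3])
    return flat.T
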