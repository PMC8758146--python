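"""MRC volume and CSV table I/O with explicit unit conventions.

All internal lengths are nanometers; MRC headers carry Angstroms. Volumes are
indexed ``(z, y, x)``, 0-based, with the physical coordinate of a voxel equal
to ``index * voxel_size_nm`` at the voxel center. Only isotropic voxels are
supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import mrcfile
import numpy as np
import pandas as pd

DENSITY_DARK = "density_dark"
DENSITY_BRIGHT = "density_bright"

#: MRC2014 modes accepted on read (int8, int16, float32, uint16).
_SUPPORTED_MODES = {0, 1, 2, 6}


@dataclass
class GrayVolume:
    """A 3D scalar grid with voxel size metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Gray values, indexed ``(z, y, x)``.
    voxel_size_nm : float
        Isotropic edge length of one voxel in nm.
    polarity : str
        ``"density_dark"`` for raw tomograms (protein = low gray value) or
        ``"density_bright"`` for subvolume-average style data.
    """

    data: np.ndarray
    voxel_size_nm: float
    polarity: str = DENSITY_DARK

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if not self.voxel_size_nm > 0:
            raise ValueError(f"voxel_size_nm must be > 0, got {self.voxel_size_nm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.polarity not in (DENSITY_DARK, DENSITY_BRIGHT):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer label grid sharing shape and indexing with its GrayVolume.

    0 is background; labels are non-negative.
    """

    labels: np.ndarray
    voxel_size_nm: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label map, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {self.labels.dtype}")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _voxel_size_nm_from_header(mrc, path) -> float:
    vs = mrc.voxel_size
    sizes = np.array([float(vs.x), float(vs.y), float(vs.z)])
    if np.any(sizes <= 0):
        raise ValueError(
            f"{path}: MRC header voxel_size (cella/mx,my,mz) is missing or zero: {sizes}"
        )
    if not np.allclose(sizes, sizes[0], rtol=1e-3):
        raise ValueError(f"{path}: anisotropic voxel size not supported: {sizes} A")
    return float(sizes[0]) / 10.0  # A -> nm


def read_volume(path, polarity: str = DENSITY_DARK) -> GrayVolume:
    """Read an MRC2014 volume; voxel size converted from Angstrom to nm."""
    path = Path(path)
    with mrcfile.open(path, permissive=True) as mrc:
        mode = int(mrc.header.mode)
        if mode not in _SUPPORTED_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        data = np.asarray(mrc.data).copy()
        voxel_size_nm = _voxel_size_nm_from_header(mrc, path)
    return GrayVolume(data=data, voxel_size_nm=voxel_size_nm, polarity=polarity)


def write_volume(volume: GrayVolume, path) -> None:
    """Write a GrayVolume as MRC2014 mode 2 (float32), voxel size in Angstrom."""
    with mrcfile.new(Path(path), overwrite=True) as mrc:
        mrc.set_data(np.asarray(volume.data, dtype=np.float32))
        mrc.voxel_size = volume.voxel_size_nm * 10.0


def read_labels(path) -> LabelVolume:
    """Read an integer label map from MRC."""
    path = Path(path)
    with mrcfile.open(path, permissive=True) as mrc:
        data = np.asarray(mrc.data)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise ValueError(f"{path}: label map contains non-integer values")
            data = rounded.astype(np.int32)
        voxel_size_nm = _voxel_size_nm_from_header(mrc, path)
    return LabelVolume(labels=data.astype(np.int32, copy=True), voxel_size_nm=voxel_size_nm)


def write_labels(labels: LabelVolume, path) -> None:
    """Write a label map as MRC mode 1 (int16)."""
    arr = labels.labels
    if arr.max(initial=0) > np.iinfo(np.int16).max:
        raise ValueError("label values exceed int16 range of the MRC mode-1 format")
    with mrcfile.new(Path(path), overwrite=True) as mrc:
        mrc.set_data(arr.astype(np.int16))
        mrc.voxel_size = labels.voxel_size_nm * 10.0


def write_table(records: Sequence, path) -> None:
    """Write keyed measurement records as a UTF-8, comma-separated CSV.

    Records may be dicts or dataclass-like objects sharing one schema; an empty
    list yields a header-only file when the schema is known (empty DataFrame).
    """
    rows = []
    schema = None
    for rec in records:
        if hasattr(rec, "as_record"):
            row = rec.as_record()
        elif isinstance(rec, dict):
            row = dict(rec)
        else:
            raise TypeError(f"unsupported record type {type(rec)!r}")
        keys = tuple(row.keys())
        if schema is None:
            schema = keys
        elif keys != schema:
            raise ValueError(f"heterogeneous record schemas: {schema} vs {keys}")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(schema) if schema else None)
    df.to_csv(Path(path), index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
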