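"""Volumes, label images and resampling.

All arrays use (z, y, x) axis order internally (2D images are (y, x));
voxel sizes are per-axis in nanometres. Supported on-disk formats: MRC2014,
HDF5 (default dataset keys ``raw`` / ``labels``) and TIFF (voxel size kept
in the image description tag as JSON).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import _mrc

__all__ = [
    "Volume",
    "InstanceSegmentation",
    "read_volume",
    "write_volume",
    "resample_volume",
]


def _as_voxel_size(voxel_size, ndim: int) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=np.float64), (ndim,)).copy()
    if not np.all(np.isfinite(vs)) or np.any(vs <= 0):
        raise ValueError(f"voxel_size must be strictly positive, got {vs}")
    return vs


@dataclass
class Volume:
    """Scalar intensity volume (3D) or image (2D) with voxel size in nm."""

    data: np.ndarray
    voxel_size: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D data, got ndim={self.data.ndim}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume data contains non-finite values")
        self.voxel_size = _as_voxel_size(self.voxel_size, self.data.ndim)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class InstanceSegmentation:
    """Non-negative integer label image; 0 is background."""

    labels: np.ndarray
    voxel_size: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D labels, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = _as_voxel_size(self.voxel_size, self.labels.ndim)

    @property
    def ndim(self) -> int:
        return self.labels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _format_of(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".mrc", ".rec", ".st"):
        return "mrc"
    if ext in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if ext in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer format from extension {ext!r} ({path})")


def read_volume(
    path,
    dataset_key: str | None = None,
    voxel_size=None,
    labels: bool = False,
):
    """Read a volume or label image from MRC / HDF5 / TIFF.

    Parameters
    ----------
    path:
        Input file; format inferred from the extension.
    dataset_key:
        HDF5 dataset key (default ``"labels"`` when ``labels`` else ``"raw"``).
    voxel_size:
        Per-axis voxel size in nm; required when the file carries none.
    labels:
        Return an :class:`InstanceSegmentation` instead of a :class:`Volume`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    fmt = _format_of(path)
    file_voxel = None
    if fmt == "mrc":
        data, file_voxel = _mrc.read_mrc(path)
        if np.any(~np.isfinite(file_voxel)):
            file_voxel = None
    elif fmt == "hdf5":
        import h5py

        key = dataset_key or ("labels" if labels else "raw")
        with h5py.File(path, "r") as fh:
            if key not in fh:
                raise KeyError(f"{path}: no dataset {key!r}")
            ds = fh[key]
            data = ds[()]
            if "voxel_size_nm" in ds.attrs:
                file_voxel = np.asarray(ds.attrs["voxel_size_nm"], dtype=np.float64)
    else:
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
        try:
            meta = json.loads(desc)
            file_voxel = np.asarray(meta["voxel_size_nm"], dtype=np.float64)
        except (ValueError, KeyError, TypeError):
            file_voxel = None

    if voxel_size is not None:
        vs = voxel_size
    elif file_voxel is not None:
        vs = file_voxel[-data.ndim :]
    else:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass voxel_size explicitly"
        )
    if labels:
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"{path}: requested labels but dtype is {data.dtype}")
        return InstanceSegmentation(data, vs, provenance=str(path))
    return Volume(data, vs, provenance=str(path))


def write_volume(vol, path, dataset_key: str | None = None):
    """Write a Volume or InstanceSegmentation; round-trips with read_volume."""
    is_labels = isinstance(vol, InstanceSegmentation)
    data = vol.labels if is_labels else vol.data
    fmt = _format_of(path)
    if fmt == "mrc":
        _mrc.write_mrc(path, data, vol.voxel_size)
    elif fmt == "hdf5":
        import h5py

        key = dataset_key or ("labels" if is_labels else "raw")
        with h5py.File(path, "a") as fh:
            if key in fh:
                del fh[key]
            ds = fh.create_dataset(key, data=data, compression="gzip")
            ds.attrs["voxel_size_nm"] = np.asarray(vol.voxel_size, dtype=np.float64)
    else:
        import tifffile

        desc = json.dumps({"voxel_size_nm": list(map(float, vol.voxel_size))})
        tifffile.imwrite(str(path), data, description=desc)
    return path


def resample_volume(vol, target_voxel_size, mode: str | None = None):
    """Resample to a target voxel size (nm per axis).

    Intensity volumes use linear interpolation, labels nearest-neighbour.
    The output shape is ``round(shape * input_voxel / target_voxel)`` per
    axis; factor-k binning is the special case target = k * input.
    """
    is_labels = isinstance(vol, InstanceSegmentation)
    if mode is None:
        mode = "labels" if is_labels else "intensity"
    if mode not in ("intensity", "labels"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    data = vol.labels if is_labels else vol.data
    if data.size == 0:
        raise ValueError("cannot resample an empty volume")
    target = _as_voxel_size(target_voxel_size, data.ndim)
    factors = vol.voxel_size / target
    out_shape = tuple(int(round(s * f)) for s, f in zip(data.shape, factors))
    if min(out_shape) < 1:
        raise ValueError(f"target voxel size {target} collapses the volume")
    if out_shape == data.shape:
        out = data.copy()
    else:
        zoom = [o / s for o, s in zip(out_shape, data.shape)]
        order = 0 if mode == "labels" else 1
        out = ndi.zoom(data, zoom, order=order, mode="nearest", grid_mode=True)
        out = out[tuple(slice(0, o) for o in out_shape)]
    if is_labels:
        return InstanceSegmentation(out.astype(data.dtype), target, vol.provenance)
    return Volume(out, target, vol.provenance)


def bin_volume(vol, factor: int):
    """Integer binning by a factor (target voxel = factor * input voxel)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("binning factor must be a positive integer")
    return resample_volume(vol, np.asarray(vol.voxel_size) * int(factor))
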