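"""Minimal MRC2014 reader/writer.

Supports the modes needed for tomograms and label volumes (int8, int16,
float32, uint16) with the standard 1024-byte header. Pixel spacing is
stored in the CELLA fields in Angstrom and exposed in nm. Data are stored
C-contiguous with x the fastest axis, i.e. numpy shape (nz, ny, nx).
"""

from __future__ import annotations

import struct

import numpy as np

_MODE_TO_DTYPE = {
    0: np.dtype("int8"),
    1: np.dtype("int16"),
    2: np.dtype("float32"),
    6: np.dtype("uint16"),
}
_DTYPE_TO_MODE = {v: k for k, v in _MODE_TO_DTYPE.items()}

HEADER_SIZE = 1024


def _choose_mode(data: np.ndarray) -> tuple[int, np.ndarray]:
    dt = data.dtype
    if dt in _DTYPE_TO_MODE:
        return _DTYPE_TO_MODE[dt], data
    if np.issubdtype(dt, np.integer):
        lo, hi = int(data.min(initial=0)), int(data.max(initial=0))
        if 0 <= lo and hi <= np.iinfo(np.uint16).max:
            return 6, data.astype(np.uint16)
        raise ValueError(
            f"integer data with range [{lo}, {hi}] does not fit any supported MRC mode"
        )
    if np.issubdtype(dt, np.floating):
        return 2, data.astype(np.float32)
    raise ValueError(f"unsupported dtype for MRC: {dt}")


def write_mrc(path, data: np.ndarray, voxel_size_nm) -> None:
    """Write a 2D or 3D array with per-axis voxel size (nm, z-first order)."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
        voxel_size_nm = (1.0, *tuple(np.atleast_1d(voxel_size_nm)[-2:]))
    if data.ndim != 3:
        raise ValueError("MRC supports 2D or 3D data")
    vs = np.broadcast_to(np.asarray(voxel_size_nm, dtype=np.float64), (3,))
    mode, out = _choose_mode(np.ascontiguousarray(data))
    nz, ny, nx = out.shape
    # CELLA in Angstrom; axis order in header is (x, y, z)
    cella = (nx * vs[2] * 10.0, ny * vs[1] * 10.0, nz * vs[0] * 10.0)
    header = bytearray(HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart/nystart/nzstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    dmin, dmax = float(out.min(initial=0)), float(out.max(initial=0))
    struct.pack_into("<3f", header, 76, dmin, dmax, float(np.mean(out)) if out.size else 0.0)
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(np.std(out)) if out.size else 0.0)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(out.astype(out.dtype.newbyteorder("<"), copy=False).tobytes())


def read_mrc(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an MRC file; returns (data (nz,ny,nx), voxel_size_nm (z,y,x))."""
    with open(path, "rb") as fh:
        header = fh.read(HEADER_SIZE)
        if len(header) < HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        cella = struct.unpack_from("<3f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        if mode not in _MODE_TO_DTYPE:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) <= 0:
            raise ValueError(f"{path}: invalid dimensions {(nx, ny, nz)}")
        fh.seek(HEADER_SIZE + max(nsymbt, 0))
        dtype = _MODE_TO_DTYPE[mode].newbyteorder("<")
        data = np.frombuffer(fh.read(nx * ny * nz * dtype.itemsize), dtype=dtype)
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data block")
    data = data.reshape(nz, ny, nx)
    # voxel size per MRC2014: cella / grid size, Angstrom -> nm
    with np.errstate(invalid="ignore"):
        vs_xyz = np.array(cella, dtype=np.float64) / np.array([nx, ny, nz]) / 10.0
    voxel = vs_xyz[::-1].copy()
    if not np.all(np.isfinite(voxel)) or np.any(voxel <= 0):
        voxel = np.full(3, np.nan)
    return np.ascontiguousarray(data), voxel
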