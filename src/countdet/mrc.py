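"""Minimal MRC2014 reader/writer for counted movie stacks.

Supports the integer modes counting cameras actually emit (0: int8,
1: int16, 6: uint16) plus float32 (mode 2).  Unsigned 8-bit data are
written as mode 0 with the IMOD unsigned-byte stamp, the de-facto
convention for "8-bit MRC" movies.  Only little-endian files are handled.

This is deliberately a small, strict codec: headers it did not write are
validated field by field and rejected with an error naming the offending
field rather than guessed at.
"""

from __future__ import annotations

import os
import struct
from typing import Optional

import numpy as np

__all__ = ["read_mrc", "write_mrc", "MrcFormatError"]

HEADER_SIZE = 1024
MAP_MAGIC = b"MAP "
# little-endian machine stamp (first two bytes are what matter in practice)
MACHST_LE = b"\x44\x44\x00\x00"
IMOD_STAMP = 1146047817  # present => imodFlags is meaningful
IMOD_FLAG_UNSIGNED_BYTES = 1

_MODE_DTYPES = {
    0: np.dtype("i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


class MrcFormatError(ValueError):
    """Raised when an MRC file violates the subset of MRC2014 we support."""


def _dtype_to_mode(dtype: np.dtype) -> int:
    dtype = np.dtype(dtype)
    if dtype == np.uint8:
        return 0  # written with the IMOD unsigned stamp
    for mode, dt in _MODE_DTYPES.items():
        if dt == dtype:
            return mode
    raise MrcFormatError(f"no MRC mode for dtype {dtype}")


def write_mrc(path: str | os.PathLike, data: np.ndarray,
              voxel_size: Optional[float] = None) -> None:
    """Write a 2-D image or 3-D stack as a little-endian MRC2014 file.

    Parameters
    ----------
    data:
        int8/uint8/int16/uint16/float32 array, shape (nz, ny, nx) or (ny, nx).
    voxel_size:
        Sampling pitch in Angstrom per sample along x and y (z cell length
        is left at nz, i.e. unit spacing: frames are time, not depth).
    """
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise MrcFormatError("data must be 2-D or 3-D")
    mode = _dtype_to_mode(data.dtype)
    unsigned8 = data.dtype == np.uint8
    nz, ny, nx = data.shape
    px = float(voxel_size) if voxel_size else 1.0

    stats = data.astype(np.float64, copy=False)
    dmin, dmax, dmean = float(stats.min()), float(stats.max()), float(stats.mean())
    rms = float(stats.std())

    header = bytearray(HEADER_SIZE)
    struct.pack_into("<10i", header, 0,
                     nx, ny, nz,          # NX NY NZ
                     mode,                # MODE
                     0, 0, 0,             # NXSTART..
                     nx, ny, nz)          # MX MY MZ
    struct.pack_into("<6f", header, 40, nx * px, ny * px, float(nz),
                     90.0, 90.0, 90.0)    # CELLA, CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)          # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", header, 88, 0, 0)             # ISPG (stack), NSYMBT
    header[104:108] = b"MRCO"                             # EXTTYP (none follows)
    struct.pack_into("<i", header, 108, 20140)            # NVERSION
    if unsigned8:
        struct.pack_into("<2i", header, 152, IMOD_STAMP,
                         IMOD_FLAG_UNSIGNED_BYTES)
    header[208:212] = MAP_MAGIC
    header[212:216] = MACHST_LE
    struct.pack_into("<f", header, 216, rms)
    label = b"countdet: counted movie stack"
    struct.pack_into("<i", header, 220, 1)                # NLABL
    header[224:224 + len(label)] = label

    raw = data.view(np.int8) if unsigned8 else data
    raw = np.ascontiguousarray(raw.astype(raw.dtype.newbyteorder("<"),
                                          copy=False))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(raw.tobytes())


def read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, dict]:
    """Read an MRC file written by this codec or by compatible software.

    Returns
    -------
    data:
        Array of shape (nz, ny, nx), dtype per the file mode (uint8 when
        the IMOD unsigned-byte stamp is present on mode 0).
    header:
        Dict with nx/ny/nz, mode, voxel_size, dmin/dmax/dmean.
    """
    size = os.path.getsize(path)
    if size < HEADER_SIZE:
        raise MrcFormatError(f"file too small for an MRC header ({size} bytes)")
    with open(path, "rb") as fh:
        header = fh.read(HEADER_SIZE)
        if header[208:212] != MAP_MAGIC:
            raise MrcFormatError("bad MAP magic at header word 53 "
                                 f"(got {header[208:212]!r})")
        if header[212] not in (0x44,):
            raise MrcFormatError("unsupported MACHST (big-endian file?)")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        for name, val in (("NX", nx), ("NY", ny), ("NZ", nz)):
            if not 0 < val < 2 ** 31:
                raise MrcFormatError(f"invalid {name}={val}")
        if mode not in _MODE_DTYPES:
            raise MrcFormatError(f"unsupported MODE={mode}")
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        if nsymbt < 0:
            raise MrcFormatError(f"invalid NSYMBT={nsymbt}")
        mx = struct.unpack_from("<i", header, 28)[0]
        cella_x = struct.unpack_from("<f", header, 40)[0]
        voxel_size = cella_x / mx if mx > 0 and cella_x > 0 else None
        dmin, dmax, dmean = struct.unpack_from("<3f", header, 76)
        imod_stamp, imod_flags = struct.unpack_from("<2i", header, 152)

        dtype = _MODE_DTYPES[mode]
        n_items = nx * ny * nz
        expected = HEADER_SIZE + nsymbt + n_items * dtype.itemsize
        if size < expected:
            raise MrcFormatError(
                f"truncated file: NX*NY*NZ={n_items} items of mode {mode} "
                f"need {expected} bytes, file has {size}")
        fh.seek(HEADER_SIZE + nsymbt)
        data = np.frombuffer(fh.read(n_items * dtype.itemsize), dtype=dtype)
    data = data.reshape(nz, ny, nx)
    if mode == 0 and imod_stamp == IMOD_STAMP and \
            (imod_flags & IMOD_FLAG_UNSIGNED_BYTES):
        data = data.view(np.uint8)
    return data.copy(), {
        "nx": nx, "ny": ny, "nz": nz, "mode": mode,
        "voxel_size": voxel_size,
        "dmin": dmin, "dmax": dmax, "dmean": dmean,
    }
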