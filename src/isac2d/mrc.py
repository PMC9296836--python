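"""Minimal MRC2014 image-stack reader/writer.

Covers the interchange subset needed for particle stacks and class
averages: mode-2 (float32) writing, and reading of modes 0 (int8),
1 (int16), 2 (float32) and 6 (uint16), promoted to float on read.
Little-endian files only (the MRC2014 interchange default); the machine
stamp is checked and big-endian files are byte-swapped.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np

HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


class MRCFormatError(ValueError):
    pass


def read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, float | None]:
    """Read an MRC stack; returns (data as (nz, ny, nx) float32, pixel size).

    Pixel size is taken from cella / mx when present, else None.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise MRCFormatError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        swap = False
        stamp = header[212:214]
        if stamp == b"\x11\x11":  # big-endian machine stamp
            nx, ny, nz, mode = struct.unpack(">4i", header[:16])
            swap = True
        if mode not in _MODE_DTYPES:
            raise MRCFormatError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) < 1:
            raise MRCFormatError(f"{path}: bad dimensions {(nx, ny, nz)}")
        (nsymbt,) = struct.unpack("<i" if not swap else ">i", header[92:96])
        mx = struct.unpack("<i" if not swap else ">i", header[28:32])[0]
        cella_x = struct.unpack("<f" if not swap else ">f", header[40:44])[0]
        pixel = cella_x / mx if mx > 0 and cella_x > 0 else None
        if nsymbt:
            fh.seek(nsymbt, os.SEEK_CUR)
        dtype = np.dtype(_MODE_DTYPES[mode])
        if swap:
            dtype = dtype.newbyteorder(">")
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size != count:
            raise MRCFormatError(f"{path}: data block shorter than header promises")
    return data.reshape(nz, ny, nx).astype(np.float32), pixel


def write_mrc(
    path: str | os.PathLike,
    data: np.ndarray,
    pixel_size: float | None = None,
) -> None:
    """Write a (n, b, b) float stack as a mode-2 MRC2014 file."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise MRCFormatError("expected a (n, ny, nx) image stack")
    nz, ny, nx = data.shape
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    apix = float(pixel_size) if pixel_size else 1.0
    header = bytearray(HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * apix, ny * apix, nz * apix)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 1)
    label = b"isac2d particle stack"
    header[224 : 224 + len(label)] = label
    with open(path, "wb") as fh:
        fh.write(header)
        data.tofile(fh)
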