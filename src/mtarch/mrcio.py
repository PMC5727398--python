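"""MRC2014 read/write for density grids.

Volumes and images are exchanged as mode-2 (32-bit float) MRC maps through
gemmi, with the voxel size recorded in the cell header so external viewers
display correct physical dimensions.  Internally lengths are nm; MRC headers
are Angstrom-based, and the conversion lives here and in :mod:`mtarch.units`.

The exact pixel size and the 2D axis convention are additionally recorded in
an MRC text label (header labels are part of MRC2014 and ignored by
viewers), so a write/read round trip through this module reproduces
``pixel_nm`` bit-exactly even when the Angstrom cell dimensions are not
exactly representable in the header's 32-bit floats.
"""

from __future__ import annotations

import struct

import numpy as np

from .grid import DensityGrid
from .units import NM_TO_ANGSTROM

__all__ = ["read_mrc", "write_mrc", "MrcFormatError"]

_LABEL_PREFIX = "mtarch"
_NLABL_OFFSET = 220
_LABELS_OFFSET = 224
_LABEL_SIZE = 80


class MrcFormatError(ValueError):
    """Raised for files that are not valid MRC2014 maps."""


def write_mrc(grid: DensityGrid, path: str) -> None:
    """Write a density grid as a mode-2 MRC2014 map.

    2D grids are stored as single-section volumes; the original axis
    convention is recorded in a header label and restored on read.
    """
    import gemmi

    values = grid.values
    if values.ndim == 2:
        vol = values[None, :, :]  # one section
    else:
        vol = values
    nz, ny, nx = vol.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    pix_a = grid.pixel_nm * NM_TO_ANGSTROM
    g.set_unit_cell(gemmi.UnitCell(nx * pix_a, ny * pix_a, nz * pix_a, 90, 90, 90))
    np.array(g, copy=False)[...] = np.ascontiguousarray(vol.T, dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(path)

    label = f"{_LABEL_PREFIX} axes={grid.axes} pixel_nm={grid.pixel_nm!r}"
    raw = label.encode()[:_LABEL_SIZE].ljust(_LABEL_SIZE)
    with open(path, "r+b") as fh:
        fh.seek(_NLABL_OFFSET)
        fh.write(struct.pack("<i", 1))
        fh.seek(_LABELS_OFFSET)
        fh.write(raw)


def _parse_label(path: str) -> dict[str, str]:
    with open(path, "rb") as fh:
        header = fh.read(1024)
    if len(header) < 1024 or header[208:212] not in (b"MAP ", b"MAP\x00"):
        raise MrcFormatError(f"{path}: not an MRC2014 file (missing MAP tag)")
    out: dict[str, str] = {}
    (nlabl,) = struct.unpack("<i", header[_NLABL_OFFSET : _NLABL_OFFSET + 4])
    for i in range(max(0, min(nlabl, 10))):
        raw = header[_LABELS_OFFSET + i * _LABEL_SIZE :][:_LABEL_SIZE]
        text = raw.decode("ascii", errors="replace").strip()
        if text.startswith(_LABEL_PREFIX):
            for token in text.split()[1:]:
                if "=" in token:
                    key, val = token.split("=", 1)
                    out[key] = val
    return out


def read_mrc(path: str) -> DensityGrid:
    """Read an MRC2014 map into a density grid (values in file order z,y,x)."""
    import gemmi

    meta = _parse_label(path)
    try:
        m = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as err:
        raise MrcFormatError(f"{path}: {err}") from err
    vol = np.array(m.grid, copy=True).T  # (nx,ny,nz) -> (nz,ny,nx)
    if "pixel_nm" in meta:
        pixel_nm = float(meta["pixel_nm"])
    else:
        pixel_nm = float(m.grid.unit_cell.a / m.grid.nu) / NM_TO_ANGSTROM
    axes = meta.get("axes", "zyx")
    if axes in ("zy", "yx"):
        if vol.shape[0] != 1:
            raise MrcFormatError(
                f"{path}: labelled 2D ({axes}) but holds {vol.shape[0]} sections"
            )
        return DensityGrid(values=vol[0], pixel_nm=pixel_nm, axes=axes)
    return DensityGrid(values=vol, pixel_nm=pixel_nm, axes="zyx")
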