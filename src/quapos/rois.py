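"""Minimal reader/writer for the ImageJ ROI file dialect (.roi, .zip).

Only the outline types that occur in manual region selection are supported:
polygon, freehand, traced, and rectangle (converted to a 4-vertex polygon).
Coordinates follow the ImageJ convention: vertex values are pixel-corner
coordinates with x along columns and y along rows (y down).

The binary layout mirrors ImageJ's RoiDecoder: a 64-byte big-endian header
("Iout" magic, version, type byte, bounding box, vertex count) followed by
``n`` int16 x-offsets relative to ``left`` and ``n`` int16 y-offsets relative
to ``top``.  Files with the sub-pixel-resolution option additionally carry
float32 coordinates, which take precedence on read.
"""

from __future__ import annotations

import io
import struct
import zipfile
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath

_MAGIC = b"Iout"
_HEADER_SIZE = 64
_VERSION = 226

# ImageJ ROI type codes
_TYPE_POLYGON = 0
_TYPE_RECT = 1
_TYPE_FREEHAND = 7
_TYPE_TRACED = 8
_POLYGONAL_TYPES = {_TYPE_POLYGON, _TYPE_FREEHAND, _TYPE_TRACED}

_OPT_SUBPIXEL = 128


@dataclass
class PolygonRoi:
    """A named closed polygonal region; vertices as (n, 2) float array (x, y)."""

    name: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask on an image of ``shape`` (rows, cols).

        A pixel belongs to the ROI iff its centre ``(col + 0.5, row + 0.5)``
        lies inside the polygon.
        """
        h, w = shape
        x0 = max(int(np.floor(self.vertices[:, 0].min())) - 1, 0)
        x1 = min(int(np.ceil(self.vertices[:, 0].max())) + 1, w)
        y0 = max(int(np.floor(self.vertices[:, 1].min())) - 1, 0)
        y1 = min(int(np.ceil(self.vertices[:, 1].max())) + 1, h)
        mask = np.zeros(shape, dtype=bool)
        if x1 <= x0 or y1 <= y0:
            return mask
        cols, rows = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        centers = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])
        ring = np.vstack([self.vertices, self.vertices[:1]])
        codes = np.full(len(ring), MplPath.LINETO, dtype=np.uint8)
        codes[0] = MplPath.MOVETO
        codes[-1] = MplPath.CLOSEPOLY
        inside = MplPath(ring, codes).contains_points(centers)
        mask[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
        return mask


def decode_roi(data: bytes, name: str = "roi") -> PolygonRoi:
    """Decode one .roi byte blob into a polygon."""
    if len(data) < _HEADER_SIZE or data[:4] != _MAGIC:
        raise ValueError(f"{name}: not an ImageJ ROI file")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">h", data[16:18])[0]
    options = struct.unpack(">h", data[50:52])[0]

    if roi_type == _TYPE_RECT:
        verts = np.array(
            [[left, top], [right, top], [right, bottom], [left, bottom]], dtype=float
        )
        return PolygonRoi(name=name, vertices=verts)
    if roi_type not in _POLYGONAL_TYPES:
        raise ValueError(f"{name}: unsupported ROI type code {roi_type}")
    if n < 3:
        raise ValueError(f"{name}: polygon with {n} vertices")

    base = _HEADER_SIZE
    if options & _OPT_SUBPIXEL and len(data) >= base + 4 * n + 8 * n:
        off = base + 4 * n
        xs = np.frombuffer(data, dtype=">f4", count=n, offset=off)
        ys = np.frombuffer(data, dtype=">f4", count=n, offset=off + 4 * n)
        verts = np.column_stack([xs, ys]).astype(float)
    else:
        xs = np.frombuffer(data, dtype=">i2", count=n, offset=base).astype(float) + left
        ys = np.frombuffer(data, dtype=">i2", count=n, offset=base + 2 * n).astype(float) + top
        verts = np.column_stack([xs, ys])
    return PolygonRoi(name=name, vertices=verts)


def encode_roi(roi: PolygonRoi) -> bytes:
    """Encode a polygon as an integer-coordinate .roi blob."""
    verts = np.rint(roi.vertices).astype(int)
    left, top = verts[:, 0].min(), verts[:, 1].min()
    right, bottom = verts[:, 0].max(), verts[:, 1].max()
    n = len(verts)
    header = bytearray(_HEADER_SIZE)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = _TYPE_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = (verts[:, 0] - left).astype(">i2").tobytes() + (
        verts[:, 1] - top
    ).astype(">i2").tobytes()
    return bytes(header) + body


def read_roi(path: str | FsPath) -> PolygonRoi:
    path = FsPath(path)
    return decode_roi(path.read_bytes(), name=path.stem)


def write_roi(roi: PolygonRoi, path: str | FsPath) -> None:
    FsPath(path).write_bytes(encode_roi(roi))


def read_roi_zip(path: str | FsPath) -> dict[str, PolygonRoi]:
    """Read a .zip archive of ROIs; keys are the entry stems."""
    out: dict[str, PolygonRoi] = {}
    with zipfile.ZipFile(path) as zf:
        for info in sorted(zf.infolist(), key=lambda i: i.filename):
            if not info.filename.lower().endswith(".roi"):
                continue
            name = FsPath(info.filename).stem
            out[name] = decode_roi(zf.read(info), name=name)
    if not out:
        raise ValueError(f"{path}: no .roi entries found")
    return out


def write_roi_zip(rois: dict[str, PolygonRoi], path: str | FsPath) -> None:
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, roi in rois.items():
            zf.writestr(f"{name}.roi", encode_roi(roi))


def load_rois(path: str | FsPath) -> dict[str, PolygonRoi]:
    """Load either a single .roi file or a .zip archive, by extension."""
    path = FsPath(path)
    if path.suffix.lower() == ".zip":
        return read_roi_zip(path)
    roi = read_roi(path)
    return {roi.name: roi}


def rectangle_roi(name: str, top: int, left: int, bottom: int, right: int) -> PolygonRoi:
    """Convenience constructor for an axis-aligned rectangular ROI."""
    verts = np.array(
        [[left, top], [right, top], [right, bottom], [left, bottom]], dtype=float
    )
    return PolygonRoi(name=name, vertices=verts)
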