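"""ImageJ/Fiji ``.roi`` polygon codec and ``roi.zip`` archive handling.

Each segmented cell (COI) carries one 2D contour polygon stored in the
ImageJ ROI binary format: a 64-byte big-endian header (magic ``Iout``,
version, type code, integer bounding box, vertex count, stack position)
followed by the vertex coordinates as signed 16-bit offsets relative to
the bounding box corner.  Only the polygon-like types (polygon, freehand,
traced) are supported — cells are closed contours, never lines or points.

Coordinates are 0-based, origin top-left, x = column, y = row.
"""

from __future__ import annotations

import io
import re
import struct
import warnings
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, IntegrityError, RoiOverflowError, UnsupportedRoiTypeError

MAGIC = b"Iout"
VERSION = 228

#: ImageJ ROI type codes (byte at offset 6).
ROI_TYPE_POLYGON = 0
ROI_TYPE_FREEHAND = 7
ROI_TYPE_TRACED = 8
_POLYGONAL_TYPES = {ROI_TYPE_POLYGON, ROI_TYPE_FREEHAND, ROI_TYPE_TRACED}

_HEADER_SIZE = 64
# header field offsets (big-endian)
_OFF_VERSION = 4
_OFF_TYPE = 6
_OFF_TOP = 8
_OFF_LEFT = 10
_OFF_BOTTOM = 12
_OFF_RIGHT = 14
_OFF_N_COORDS = 16
_OFF_POSITION = 56
_OFF_HEADER2 = 60
# header2 field offsets, relative to the header2 block start
_H2_OFF_Z_POSITION = 8

_INT16_MAX = 32767


@dataclass
class RoiPolygon:
    """A single cell contour: simple polygon in original-image pixel space.

    Attributes
    ----------
    coi_id : int
        Identifier linking the contour to its row in the results table.
    slice : int
        1-based index of the cell's central optical section.
    vertices : ndarray of shape (n, 2)
        Integer ``(x, y)`` pixel coordinates, ordered along the contour.
    """

    coi_id: int
    slice: int
    vertices: np.ndarray
    bounds: tuple[int, int, int, int] = field(default=None)  # top, left, bottom, right

    def __post_init__(self):
        v = np.asarray(self.vertices)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a polygon needs at least 3 (x, y) vertices")
        self.vertices = np.rint(v).astype(np.int64)
        if self.bounds is None:
            x, y = self.vertices[:, 0], self.vertices[:, 1]
            self.bounds = (int(y.min()), int(x.min()), int(y.max()), int(x.max()))
        if self.slice < 1:
            raise ValueError("slice indices are 1-based")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def scaled(self, factor: float) -> "RoiPolygon":
        """Return a copy with vertices multiplied by ``factor`` and rounded."""
        return RoiPolygon(self.coi_id, self.slice,
                          np.rint(self.vertices * factor).astype(np.int64))

    def __eq__(self, other):
        if not isinstance(other, RoiPolygon):
            return NotImplemented
        return (self.coi_id == other.coi_id and self.slice == other.slice
                and np.array_equal(self.vertices, other.vertices))


@dataclass
class RoiSet:
    """All cell contours of one image, keyed by COI id (one polygon per cell)."""

    rois: dict[int, RoiPolygon] = field(default_factory=dict)

    def __len__(self):
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois.values())

    def __getitem__(self, coi_id: int) -> RoiPolygon:
        return self.rois[coi_id]

    def __contains__(self, coi_id: int) -> bool:
        return coi_id in self.rois

    def __eq__(self, other):
        if not isinstance(other, RoiSet):
            return NotImplemented
        return self.rois == other.rois

    @property
    def ids(self) -> list[int]:
        return sorted(self.rois)

    def add(self, roi: RoiPolygon) -> None:
        if roi.coi_id in self.rois:
            raise IntegrityError(f"duplicate COI id {roi.coi_id} in ROI set")
        self.rois[roi.coi_id] = roi

    def check_against_ids(self, coi_ids) -> None:
        """Warn when the contour ids and the table ids do not coincide."""
        table = set(int(i) for i in coi_ids)
        mine = set(self.rois)
        if table != mine:
            missing = sorted(table - mine)[:5]
            extra = sorted(mine - table)[:5]
            warnings.warn(
                f"ROI set and table ids differ (missing contours for {missing}, "
                f"contours without rows for {extra})", stacklevel=2)


def encode_roi(roi: RoiPolygon) -> bytes:
    """Serialize a polygon to the ImageJ ``.roi`` binary layout.

    The stack position field is set to the polygon's slice so that
    ImageJ-compatible readers restore the contour on the right optical
    section.
    """
    v = roi.vertices
    top, left = int(v[:, 1].min()), int(v[:, 0].min())
    bottom, right = int(v[:, 1].max()), int(v[:, 0].max())
    if right - left > _INT16_MAX or bottom - top > _INT16_MAX:
        raise RoiOverflowError(
            f"polygon extent {(right - left, bottom - top)} exceeds the signed "
            "16-bit relative coordinate range of the .roi format")
    xs = (v[:, 0] - left).astype(">i2")
    ys = (v[:, 1] - top).astype(">i2")

    header = bytearray(_HEADER_SIZE)
    header[0:4] = MAGIC
    struct.pack_into(">h", header, _OFF_VERSION, VERSION)
    header[_OFF_TYPE] = ROI_TYPE_POLYGON
    struct.pack_into(">hhhh", header, _OFF_TOP, top, left, bottom, right)
    struct.pack_into(">H", header, _OFF_N_COORDS, len(v))
    struct.pack_into(">i", header, _OFF_POSITION, roi.slice)
    struct.pack_into(">i", header, _OFF_HEADER2, 0)
    return bytes(header) + xs.tobytes() + ys.tobytes()


def decode_roi(payload: bytes, coi_id: int = 0) -> RoiPolygon:
    """Parse an ImageJ ``.roi`` byte block into a :class:`RoiPolygon`.

    Accepts polygon, freehand and traced ROI types; anything else (line,
    oval, point, ...) raises :class:`UnsupportedRoiTypeError` naming the
    type code.  The slice is taken from the stack position field when set,
    from the header2 z-position as a fallback, else 1.
    """
    if len(payload) < _HEADER_SIZE:
        raise FormatError(f"payload too short for a .roi header ({len(payload)} bytes)")
    if payload[0:4] != MAGIC:
        raise FormatError(f"bad magic {payload[0:4]!r}; expected {MAGIC!r}")
    roi_type = payload[_OFF_TYPE]
    if roi_type not in _POLYGONAL_TYPES:
        raise UnsupportedRoiTypeError(roi_type)
    top, left, bottom, right = struct.unpack_from(">hhhh", payload, _OFF_TOP)
    (n,) = struct.unpack_from(">H", payload, _OFF_N_COORDS)
    if n < 3:
        raise FormatError(f"polygon ROI with {n} vertices")
    need = _HEADER_SIZE + 4 * n
    if len(payload) < need:
        raise FormatError(f"truncated .roi payload: {len(payload)} < {need} bytes")
    xs = np.frombuffer(payload, dtype=">i2", count=n, offset=_HEADER_SIZE)
    ys = np.frombuffer(payload, dtype=">i2", count=n, offset=_HEADER_SIZE + 2 * n)
    vertices = np.stack([xs.astype(np.int64) + left, ys.astype(np.int64) + top], axis=1)

    (position,) = struct.unpack_from(">i", payload, _OFF_POSITION)
    if position <= 0:
        (h2,) = struct.unpack_from(">i", payload, _OFF_HEADER2)
        if h2 > 0 and len(payload) >= h2 + _H2_OFF_Z_POSITION + 4:
            (z,) = struct.unpack_from(">i", payload, h2 + _H2_OFF_Z_POSITION)
            position = z
    return RoiPolygon(coi_id=coi_id, slice=position if position > 0 else 1,
                      vertices=vertices)


def _entry_name(coi_id: int) -> str:
    return f"{coi_id:04d}.roi"


_INT_RE = re.compile(r"\d+")


def write_roi_archive(roi_set: RoiSet, path) -> str:
    """Write a ``roi.zip`` archive with one ``.roi`` entry per COI.

    Entries are named by zero-padded COI id and stored uncompressed with a
    fixed timestamp so identical sets produce byte-identical archives.
    """
    if len(roi_set) == 0:
        warnings.warn("writing an empty ROI archive", stacklevel=2)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for coi_id in roi_set.ids:
            info = zipfile.ZipInfo(_entry_name(coi_id), date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, encode_roi(roi_set[coi_id]))
    return str(path)


def read_roi_archive(path) -> RoiSet:
    """Read a ``roi.zip`` archive into a :class:`RoiSet`.

    COI ids are parsed from entry names (a single integer in the name is the
    id; Fiji's auto-names with several number groups fall back to the entry
    order, with a warning).  Entries that fail to decode are reported via
    warnings and skipped, never silently dropped.
    """
    roi_set = RoiSet()
    with zipfile.ZipFile(path, "r") as zf:
        names = [n for n in zf.namelist() if n.lower().endswith(".roi")]
        if not names:
            warnings.warn(f"ROI archive {path} contains no .roi entries", stacklevel=2)
            return roi_set
        for order, name in enumerate(names, start=1):
            ints = _INT_RE.findall(name.rsplit("/", 1)[-1])
            if len(ints) == 1:
                coi_id = int(ints[0])
            else:
                warnings.warn(f"cannot parse a COI id from entry {name!r}; "
                              f"using entry order {order}", stacklevel=2)
                coi_id = order
            try:
                roi = decode_roi(zf.read(name), coi_id=coi_id)
            except (FormatError, ValueError) as exc:
                warnings.warn(f"skipping undecodable entry {name!r}: {exc}",
                              stacklevel=2)
                continue
            roi_set.add(roi)
    return roi_set


def read_roi_bytes_archive(data: bytes) -> RoiSet:
    """Like :func:`read_roi_archive` but from an in-memory zip blob."""
    return read_roi_archive(io.BytesIO(data))
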