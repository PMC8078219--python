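"""Membrane-ring measurement from labeled nucleus stacks.

Cells are segmented in 3D as labeled nuclei.  All 2D measurements happen on
each cell's *central slice* — the optical section where its nucleus shows
the largest cross-sectional area.  There, a ring approximating the cell
membrane is built by morphological dilation of the nucleus (``inner_margin``
pixels of cytoplasm skipped, then ``thickness`` pixels of ring), the mean of
every channel inside the ring is recorded as that cell's intensity, and the
ring's outer boundary is traced into the polygon stored in ``roi.zip``.

In dense tissue neighbouring rings would overlap; each background pixel is
assigned to the territory of its nearest nucleus (Euclidean distance
transform) so a pixel contributes to exactly one cell's ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from skimage.measure import find_contours
from skimage.morphology import dilation, disk

from .errors import DimensionError
from .image_stack import ImageStack, to_8bit
from .roi_io import RoiPolygon, RoiSet
from .tabular_io import CoiTable


@dataclass
class NucleusLabels:
    """3D labeled nucleus volume, ``[slice][y][x]``; 0 is background and
    label k becomes COI id k downstream (26-connected objects)."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionError(
                f"expected a (slice, y, x) label volume; got shape {self.labels.shape}")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def ids(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]


@dataclass
class RingSpec:
    """Ring geometry: ``inner_margin`` px skipped outward from the nucleus
    boundary, then a ring ``thickness`` px wide.  Defaults (1, 3) place a
    3-px ring starting one pixel off the nucleus."""

    inner_margin: int = 1
    thickness: int = 3

    def __post_init__(self):
        if self.inner_margin < 0:
            raise ValueError("inner_margin must be >= 0")
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1")

    @property
    def outer_radius(self) -> int:
        return self.inner_margin + self.thickness


def _as_labels(labels) -> np.ndarray:
    return labels.labels if isinstance(labels, NucleusLabels) else np.asarray(labels)


def central_slice(labels) -> dict[int, int]:
    """Per cell, the 1-based slice maximizing its nucleus cross-section.

    Ties go to the lowest slice index.
    """
    vol = _as_labels(labels)
    max_label = int(vol.max()) if vol.size else 0
    if max_label == 0:
        return {}
    counts = np.zeros((vol.shape[0], max_label + 1), dtype=np.int64)
    for s in range(vol.shape[0]):
        counts[s] = np.bincount(vol[s].ravel(), minlength=max_label + 1)
    best = np.argmax(counts, axis=0)  # argmax returns the first (lowest) maximum
    present = counts.sum(axis=0) > 0
    return {int(k): int(best[k]) + 1 for k in range(1, max_label + 1) if present[k]}


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask.copy()
    return dilation(mask, disk(radius)).astype(bool)


def nearest_nucleus_territory(slice_labels: np.ndarray) -> np.ndarray:
    """Label each pixel with the id of its nearest nucleus (EDT-based)."""
    background = slice_labels == 0
    _, (iy, ix) = ndimage.distance_transform_edt(background, return_indices=True)
    return slice_labels[iy, ix]


def _trace_outer_polygon(outer_mask: np.ndarray, coi_id: int,
                         slice_index: int) -> RoiPolygon:
    contours = find_contours(outer_mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask has no boundary to trace")
    contour = max(contours, key=len)  # (row, col) sub-pixel boundary
    verts = np.rint(contour[:, ::-1]).astype(np.int64)  # -> (x, y)
    keep = np.any(np.diff(verts, axis=0, append=verts[:1]) != 0, axis=1)
    verts = verts[keep]
    if len(verts) >= 3 and Polygon(verts).is_simple:
        return RoiPolygon(coi_id, slice_index, verts)
    # rounding occasionally produces a pinched contour; fall back to the hull
    ys, xs = np.nonzero(outer_mask)
    hull = MultiPoint(np.stack([xs, ys], axis=1)).convex_hull
    verts = np.rint(np.asarray(hull.exterior.coords)[:-1]).astype(np.int64)
    return RoiPolygon(coi_id, slice_index, verts)


def membrane_ring(labels, coi_id: int, slice_index: int,
                  spec: RingSpec = RingSpec(),
                  territory: np.ndarray | None = None):
    """Build the membrane ring mask and outer polygon of one cell.

    Returns ``(ring_mask, outer_polygon)``.  The ring is the outer dilation
    minus the inner dilation of the nucleus, restricted to the cell's own
    territory so neighbouring rings never share pixels.  An empty ring (cell
    squeezed by neighbours) triggers a warning; its intensities become NaN.
    """
    vol = _as_labels(labels)
    plane = vol[slice_index - 1]
    mask = plane == coi_id
    if not mask.any():
        raise ValueError(f"COI {coi_id} has no pixels on slice {slice_index}")
    if territory is None:
        territory = nearest_nucleus_territory(plane)
    outer = _dilate(mask, spec.outer_radius)
    inner = _dilate(mask, spec.inner_margin)
    ring = outer & ~inner & (territory == coi_id)
    if not ring.any():
        warnings.warn(f"degenerate ring for COI {coi_id} on slice {slice_index}; "
                      "intensities will be missing", stacklevel=2)
    polygon = _trace_outer_polygon(outer, coi_id, slice_index)
    return ring, polygon


def measure_coi(stack: ImageStack, ring_mask: np.ndarray,
                slice_index: int) -> dict[str, float]:
    """Mean intensity of every channel inside the ring, on the 0-255 scale
    (16-bit planes are rescaled by 255/65535 first).  Empty ring -> NaN."""
    out: dict[str, float] = {}
    empty = not ring_mask.any()
    for ch in range(1, stack.n_channels + 1):
        label = stack.legend.label_of(ch)
        if empty:
            out[label] = float("nan")
        else:
            plane = to_8bit(stack.plane(slice_index, ch))
            out[label] = float(plane[ring_mask].mean())
    return out


def morphology(polygon: RoiPolygon) -> tuple[float, float, float]:
    """``(area, circularity, solidity)`` of a cell contour.

    Area by the shoelace formula (px²); circularity = 4·pi·area/perimeter²,
    clamped to <= 1 (1 for a perfect circle); solidity = area / convex-hull
    area (1 for convex shapes).
    """
    verts = polygon.vertices if isinstance(polygon, RoiPolygon) else np.asarray(polygon)
    if len(verts) < 3:
        raise ValueError("morphology needs a polygon with at least 3 vertices")
    poly = Polygon(verts)
    area = poly.area
    perimeter = poly.exterior.length
    if area <= 0 or perimeter <= 0:
        raise ValueError("degenerate polygon with zero area or perimeter")
    circularity = min(1.0, 4.0 * np.pi * area / perimeter ** 2)
    solidity = area / poly.convex_hull.area
    return float(area), float(circularity), float(min(1.0, solidity))


def run_measurement(stack: ImageStack, labels, spec: RingSpec = RingSpec()
                    ) -> tuple[CoiTable, RoiSet]:
    """Full measurement stage: one table row and one outer polygon per cell.

    Columns: ``ID``, one intensity column per legend label, centroid ``X``/
    ``Y`` (nucleus pixels on the central slice), ``Z`` (the central slice),
    ``Area``, ``Circ.``, ``Solidity``.
    """
    vol = _as_labels(labels)
    if vol.shape[0] != stack.n_slices or vol.shape[1:] != (stack.height, stack.width):
        raise DimensionError(
            f"label volume {vol.shape} does not match image "
            f"({stack.n_slices}, {stack.height}, {stack.width})")
    centers = central_slice(vol)
    roi_set = RoiSet()
    rows = []
    territories: dict[int, np.ndarray] = {}
    for coi_id in sorted(centers):
        s = centers[coi_id]
        if s not in territories:
            territories[s] = nearest_nucleus_territory(vol[s - 1])
        ring, poly = membrane_ring(vol, coi_id, s, spec, territory=territories[s])
        intensities = measure_coi(stack, ring, s)
        ys, xs = np.nonzero(vol[s - 1] == coi_id)
        area, circ, sol = morphology(poly)
        row = {"ID": coi_id, **intensities,
               "X": float(xs.mean()), "Y": float(ys.mean()), "Z": float(s),
               "Area": area, "Circ.": circ, "Solidity": sol}
        rows.append(row)
        roi_set.add(poly)
    columns = (["ID"] + list(stack.legend.labels)
               + ["X", "Y", "Z", "Area", "Circ.", "Solidity"])
    df = pd.DataFrame(rows, columns=columns)
    roles = {"id": "ID", "x": "X", "y": "Y", "z": "Z", "slice": "Z",
             "area": "Area", "circularity": "Circ.", "solidity": "Solidity"}
    intensity_cols = {lbl: lbl for lbl in stack.legend.labels}
    return CoiTable(df, roles, intensity_cols), roi_set
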