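"""Spatial analysis: dense-region detection, cell-cell interaction flags,
and mapping a drawn image region back to the cells inside it.

Dense regions (e.g. an area of intense proliferation) are found by DBSCAN
over cell centroids in the 2D plane of the central slices: a *core* point
has at least ``min_pts`` neighbours within ``eps`` (itself included);
clusters are cores connected through eps-reachability plus their border
points; everything else is noise.  Membership becomes the binary
``ROI_DBSCAN`` column of the results table.

Interaction with a partner population (e.g. phagocytes) is flagged per cell
when its outer contour, dilated by ``contact_dist`` pixels, overlaps at
least one partner-mask pixel on the cell's own optical section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from sklearn.neighbors import KDTree

from .errors import DimensionError, IntegrityError
from .roi_io import RoiSet
from .tabular_io import CoiTable

DEFAULT_EPS = 50.0   # px; arbitrary default, tune to the tissue and scale
DEFAULT_MIN_PTS = 5

REGION_COLUMN = "ROI_DBSCAN"


@dataclass
class RegionLabeling:
    """DBSCAN result: per-point cluster id (−1 = noise) and the derived
    binary in-region flag (1 iff the point belongs to any cluster)."""

    eps: float
    min_pts: int
    labels: np.ndarray
    ids: np.ndarray | None = None

    @property
    def flags(self) -> np.ndarray:
        return (self.labels >= 0).astype(np.int64)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if self.labels.size else 0

    def flag_of(self) -> dict[int, int]:
        if self.ids is None:
            raise ValueError("labeling carries no COI ids")
        return {int(i): int(f) for i, f in zip(self.ids, self.flags)}


def dbscan_regions(points, eps: float = DEFAULT_EPS, min_pts: int = DEFAULT_MIN_PTS,
                   ids=None) -> RegionLabeling:
    """Classic DBSCAN over 2D centroids.

    Points are processed in ascending order (input order, which callers keep
    sorted by COI id) so border points reachable from two clusters land
    deterministically in the first cluster discovered.  Neighbour queries use
    a KD-tree; semantics are the textbook algorithm.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    n = len(pts)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return RegionLabeling(eps, min_pts, labels,
                              None if ids is None else np.asarray(ids, dtype=np.int64))
    tree = KDTree(pts)
    neighborhoods = tree.query_radius(pts, r=eps)  # closed ball, self included
    core = np.array([len(nb) >= min_pts for nb in neighborhoods])
    visited = np.zeros(n, dtype=bool)
    cluster = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        # expand a new cluster from this seed core point
        stack = [i]
        visited[i] = True
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in neighborhoods[j]:
                if labels[k] == -1:
                    labels[k] = cluster  # border or yet-unvisited core
                if core[k] and not visited[k]:
                    visited[k] = True
                    stack.append(k)
        cluster += 1
    return RegionLabeling(eps, min_pts, labels,
                          None if ids is None else np.asarray(ids, dtype=np.int64))


def assign_region_flag(table: CoiTable, labeling: RegionLabeling) -> CoiTable:
    """Set the binary ``ROI_DBSCAN`` column from a labeling keyed by COI id."""
    if labeling.ids is None:
        if len(labeling.labels) != len(table):
            raise IntegrityError("labeling length does not match the table")
        flags = labeling.flags
    else:
        mapping = labeling.flag_of()
        missing = [i for i in table.ids if int(i) not in mapping]
        if missing:
            raise IntegrityError(f"labeling lacks ids {missing[:10]}")
        flags = np.array([mapping[int(i)] for i in table.ids], dtype=np.int64)
    return table.with_column(REGION_COLUMN, flags, role="region")


def label_regions_from_table(table: CoiTable, eps: float = DEFAULT_EPS,
                             min_pts: int = DEFAULT_MIN_PTS) -> tuple[CoiTable, RegionLabeling]:
    """Convenience: DBSCAN over the table's centroids, flag column attached."""
    order = np.argsort(table.ids, kind="stable")
    pts = np.stack([table.column("x"), table.column("y")], axis=1)[order]
    labeling = dbscan_regions(pts, eps, min_pts, ids=table.ids[order])
    return assign_region_flag(table, labeling), labeling


def partner_mask_from_stack(stack, channel: int, threshold: float) -> np.ndarray:
    """Binary partner mask per slice from one channel at a display-scale
    threshold (0-255)."""
    from .image_stack import to_8bit
    planes = [to_8bit(stack.plane(s, channel)) >= threshold
              for s in range(1, stack.n_slices + 1)]
    return np.stack(planes)


def detect_interactions(rois: RoiSet, partner_mask: np.ndarray,
                        contact_dist: float = 0.0) -> dict[int, int]:
    """Flag cells whose contour, dilated by ``contact_dist`` px, touches the
    partner mask on the cell's slice.  Flags are monotone in ``contact_dist``.
    """
    mask = np.asarray(partner_mask)
    if mask.ndim == 2:
        mask = mask[None]
    if mask.ndim != 3:
        raise DimensionError(f"partner mask must be (slice, y, x); got {mask.shape}")
    if contact_dist < 0:
        raise ValueError("contact_dist must be >= 0")
    n_slices, h, w = mask.shape
    flags: dict[int, int] = {}
    for roi in rois:
        if roi.slice > n_slices:
            raise DimensionError(
                f"COI {roi.coi_id} lies on slice {roi.slice} but the partner "
                f"mask has {n_slices} slice(s)")
        poly = Polygon(roi.vertices)
        if contact_dist > 0:
            poly = poly.buffer(contact_dist)
        x0, y0, x1, y1 = poly.bounds
        r0, r1 = max(0, int(np.floor(y0))), min(h - 1, int(np.ceil(y1)))
        c0, c1 = max(0, int(np.floor(x0))), min(w - 1, int(np.ceil(x1)))
        hit = 0
        if r0 <= r1 and c0 <= c1:
            window = mask[roi.slice - 1, r0:r1 + 1, c0:c1 + 1]
            ys, xs = np.nonzero(window)
            if len(ys):
                pts = shapely.points(xs + c0, ys + r0)
                hit = int(shapely.covers(poly, pts).any())
        flags[roi.coi_id] = hit
    return flags


def assign_interaction_flag(table: CoiTable, flags: dict[int, int],
                            column: str = "Interaction") -> CoiTable:
    missing = [i for i in table.ids if int(i) not in flags]
    if missing:
        raise IntegrityError(f"interaction flags lack ids {missing[:10]}")
    vals = np.array([flags[int(i)] for i in table.ids], dtype=np.int64)
    return table.with_column(column, vals, role="interaction")


def cells_in_region(table: CoiTable, region_polygon, slice_filter: int | None = None
                    ) -> list[int]:
    """Ids of cells whose centroid lies inside or on the boundary of a drawn
    image region ("Image to Plot"), optionally restricted to one slice."""
    verts = np.asarray(region_polygon, dtype=float).reshape(-1, 2)
    if len(verts) < 3:
        raise ValueError("a region polygon needs at least 3 vertices")
    poly = Polygon(verts)
    if poly.area == 0 and poly.length == 0:
        raise ValueError("degenerate region polygon")
    xs = np.asarray(table.column("x"), dtype=float)
    ys = np.asarray(table.column("y"), dtype=float)
    inside = shapely.covers(poly, shapely.points(xs, ys))
    if slice_filter is not None:
        inside &= np.asarray(table.column("slice"), dtype=float) == slice_filter
    return [int(i) for i, ok in zip(table.ids, inside) if ok]
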