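"""DBSCAN regions, interaction flags and image-region selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import DBSCAN as SkDBSCAN

import histocyto as hc
from histocyto.errors import DimensionError, IntegrityError
from _oracles import brute_dbscan, point_in_polygon


def _table_from_points(pts):
    df = pd.DataFrame({"ID": np.arange(1, len(pts) + 1),
                       "X": pts[:, 0], "Y": pts[:, 1],
                       "Z": np.ones(len(pts))})
    return hc.CoiTable(df, {"id": "ID", "x": "X", "y": "Y", "z": "Z",
                            "slice": "Z"}, {})


def test_dbscan_matches_brute_force_closure():
    """Exact label agreement with the from-definition oracle across random
    geometries, densities and parameters."""
    rng = np.random.default_rng(0)
    for trial in range(25):
        n = int(rng.integers(1, 200))
        if trial % 3 == 0:
            centers = rng.uniform(0, 400, (3, 2))
            pts = centers[rng.integers(0, 3, n)] + rng.normal(0, 12, (n, 2))
        else:
            pts = rng.uniform(0, 300, (n, 2))
        eps = float(rng.uniform(5, 60))
        min_pts = int(rng.integers(1, 8))
        ours = hc.dbscan_regions(pts, eps, min_pts).labels
        assert np.array_equal(ours, brute_dbscan(pts, eps, min_pts))


def test_dbscan_core_and_noise_match_sklearn():
    """Independent reference: core/noise partition agrees with sklearn."""
    rng = np.random.default_rng(1)
    pts = np.vstack([rng.normal(0, 10, (40, 2)), rng.normal(150, 10, (40, 2)),
                     rng.uniform(-200, 350, (15, 2))])
    ours = hc.dbscan_regions(pts, eps=15, min_pts=5)
    ref = SkDBSCAN(eps=15, min_samples=5).fit(pts)
    assert np.array_equal(ours.labels == -1, ref.labels_ == -1)
    # same partition up to relabeling
    for lab in set(ours.labels) - {-1}:
        members = ours.labels == lab
        assert len(set(ref.labels_[members])) == 1


def test_dbscan_two_separated_blobs():
    rng = np.random.default_rng(2)
    eps = 10.0
    a = rng.uniform(0, 20, (30, 2))
    b = a + (200, 0)  # 10*eps away
    labeling = hc.dbscan_regions(np.vstack([a, b]), eps=eps, min_pts=4)
    assert labeling.n_clusters == 2
    assert (labeling.labels >= 0).all()
    assert set(labeling.labels[:30]) == {0} and set(labeling.labels[30:]) == {1}


def test_dbscan_degenerate_cases():
    assert hc.dbscan_regions([(5.0, 5.0)], eps=1, min_pts=2).labels.tolist() == [-1]
    same = hc.dbscan_regions([(1.0, 1.0)] * 6, eps=1, min_pts=6)
    assert same.n_clusters == 1 and (same.labels == 0).all()
    assert hc.dbscan_regions(np.zeros((0, 2)), eps=1, min_pts=1).labels.size == 0


def test_region_flags_and_permutation_invariance():
    rng = np.random.default_rng(3)
    pts = np.vstack([rng.normal(50, 5, (20, 2)), rng.uniform(200, 400, (6, 2))])
    table = _table_from_points(pts)
    labeling = hc.dbscan_regions(pts, eps=20, min_pts=4, ids=table.ids)
    flagged = hc.assign_region_flag(table, labeling)
    assert flagged.resolve("region") == "ROI_DBSCAN"
    flags = dict(zip(flagged.ids, flagged.column("region")))
    # reorder the points: per-id flags must not change
    perm = rng.permutation(len(pts))
    labeling2 = hc.dbscan_regions(pts[perm], eps=20, min_pts=4,
                                  ids=table.ids[perm])
    assert labeling2.flag_of() == {int(i): int(flags[i]) for i in table.ids}


def test_region_flag_all_noise_and_id_mismatch():
    pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
    table = _table_from_points(pts)
    labeling = hc.dbscan_regions(pts, eps=5, min_pts=2, ids=table.ids)
    assert hc.assign_region_flag(table, labeling).column("region").tolist() == [0, 0, 0]
    bad = hc.dbscan_regions(pts[:2], eps=5, min_pts=2, ids=[1, 2])
    with pytest.raises(IntegrityError):
        hc.assign_region_flag(table, bad)


def _gap_scene():
    """A square cell contour and a partner pixel one pixel of gap away."""
    rois = hc.RoiSet()
    rois.add(hc.RoiPolygon(1, 1, [(5, 5), (10, 5), (10, 10), (5, 10)]))
    mask = np.zeros((1, 20, 20), bool)
    mask[0, 7, 12] = True  # column 12; polygon ends at column 10 -> gap at 11
    return rois, mask


def test_interaction_dilation_bridges_gap():
    rois, mask = _gap_scene()
    assert hc.detect_interactions(rois, mask, contact_dist=0.0) == {1: 0}
    assert hc.detect_interactions(rois, mask, contact_dist=2.0) == {1: 1}


def test_interaction_monotone_in_contact_distance():
    rng = np.random.default_rng(5)
    rois = hc.RoiSet()
    for i in range(1, 9):
        cx, cy = rng.integers(15, 85, 2)
        rois.add(hc.RoiPolygon(i, 1, [(cx - 4, cy - 4), (cx + 4, cy - 4),
                                      (cx + 4, cy + 4), (cx - 4, cy + 4)]))
    mask = rng.uniform(size=(1, 100, 100)) > 0.995
    prev = np.zeros(8, int)
    for dist in (0.0, 1.0, 3.0, 6.0, 12.0):
        flags = hc.detect_interactions(rois, mask, dist)
        cur = np.array([flags[i] for i in range(1, 9)])
        assert (cur >= prev).all()  # flags only turn 0 -> 1 as distance grows
        prev = cur


def test_interaction_slice_out_of_range():
    rois = hc.RoiSet()
    rois.add(hc.RoiPolygon(1, 5, [(0, 0), (3, 0), (0, 3)]))
    with pytest.raises(DimensionError):
        hc.detect_interactions(rois, np.zeros((2, 10, 10), bool), 1.0)


def test_cells_in_region_whole_image_and_empty():
    rng = np.random.default_rng(6)
    pts = rng.uniform(10, 90, (40, 2))
    table = _table_from_points(pts)
    everything = [(0, 0), (100, 0), (100, 100), (0, 100)]
    assert hc.cells_in_region(table, everything) == [int(i) for i in table.ids]
    nothing = [(200, 200), (201, 200), (201, 201)]
    assert hc.cells_in_region(table, nothing) == []
    with pytest.raises(ValueError):
        hc.cells_in_region(table, [(0, 0), (1, 1)])


def test_cells_in_region_matches_ray_casting_oracle():
    rng = np.random.default_rng(7)
    for _ in range(15):
        pts = rng.uniform(0, 100, (80, 2))
        table = _table_from_points(pts)
        angles = np.sort(rng.uniform(0, 2 * np.pi, int(rng.integers(3, 10))))
        radii = rng.uniform(15, 45, len(angles))
        poly = np.stack([50 + radii * np.cos(angles),
                         50 + radii * np.sin(angles)], axis=1)
        ours = hc.cells_in_region(table, poly)
        oracle = [int(i) for i, (x, y) in zip(table.ids, pts)
                  if point_in_polygon(x, y, poly)]
        assert ours == oracle
        # invariance under polygon vertex rotation
        assert hc.cells_in_region(table, np.roll(poly, 3, axis=0)) == ours


def test_cells_in_region_slice_filter():
    pts = np.array([[10.0, 10.0], [20.0, 20.0]])
    df = pd.DataFrame({"ID": [1, 2], "X": pts[:, 0], "Y": pts[:, 1],
                       "Z": [1.0, 2.0]})
    table = hc.CoiTable(df, {"id": "ID", "x": "X", "y": "Y", "slice": "Z"}, {})
    box = [(0, 0), (50, 0), (50, 50), (0, 50)]
    assert hc.cells_in_region(table, box) == [1, 2]
    assert hc.cells_in_region(table, box, slice_filter=2) == [2]
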