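"""Filtering, gating, shape classes, statistics, persistence, annotation."""

import numpy as np
import pytest

import histocyto as hc
from histocyto.errors import SchemaVersionError
from conftest import make_table
from _oracles import point_in_polygon, summarize


def test_filter_full_range_keeps_all():
    table = make_table(np.random.default_rng(0), 50)
    ids = hc.apply_filter(table, hc.FilterSpec(["A"], [(0, 255)]))
    assert ids == [int(i) for i in table.ids]


def test_filter_region_flag_selects_exactly_flagged_cells():
    """Filtering the binary region column to [1, 1] reproduces the use-case
    step of keeping only cells inside the dense proliferation area."""
    rng = np.random.default_rng(1)
    table = make_table(rng, 60)
    flags = rng.integers(0, 2, 60)
    table = table.with_column("ROI_DBSCAN", flags, role="region")
    ids = hc.apply_filter(table, hc.FilterSpec(["ROI_DBSCAN"], [(1, 1)]))
    assert ids == [int(i) for i, f in zip(table.ids, flags) if f == 1]


def test_filter_two_parameters_matches_row_scan():
    rng = np.random.default_rng(2)
    table = make_table(rng, 300)
    spec = hc.FilterSpec(["A", "B"], [(50, 150), (20, 200)])
    ours = hc.apply_filter(table, spec)
    oracle = [int(i) for i, a, b in zip(table.ids, table.column("A"),
                                        table.column("B"))
              if 50 <= a <= 150 and 20 <= b <= 200]
    assert ours == oracle


def test_filter_unknown_column():
    table = make_table(np.random.default_rng(3), 5)
    with pytest.raises(KeyError):
        hc.apply_filter(table, hc.FilterSpec(["Nope"], [(0, 1)]))


def _random_lasso(rng):
    angles = np.sort(rng.uniform(0, 2 * np.pi, int(rng.integers(3, 12))))
    radii = rng.uniform(20, 120, len(angles))
    return np.stack([128 + radii * np.cos(angles),
                     128 + radii * np.sin(angles)], axis=1)


def test_gates_match_brute_force_oracle():
    """Rectangle, lasso and quadrant membership vs per-row oracles."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        table = make_table(rng, int(rng.integers(5, 400)))
        ids = [int(i) for i in table.ids]
        a, b = table.column("A"), table.column("B")

        x0, x1 = np.sort(rng.uniform(0, 255, 2))
        y0, y1 = np.sort(rng.uniform(0, 255, 2))
        rect = hc.Gate("rectangle", "A", "B", [x0, x1 + 1, y0, y1 + 1])
        got = hc.apply_gate(table, ids, rect).member_ids
        want = [i for i, x, y in zip(ids, a, b)
                if x0 <= x <= x1 + 1 and y0 <= y <= y1 + 1]
        assert got == want

        lasso = hc.Gate("lasso", "A", "B", _random_lasso(rng).tolist())
        got = hc.apply_gate(table, ids, lasso).member_ids
        want = [i for i, x, y in zip(ids, a, b)
                if point_in_polygon(x, y, lasso.geometry)]
        assert got == want

        xt, yt = rng.uniform(0, 255, 2)
        for which in ("LL", "LR", "UL", "UR"):
            gate = hc.Gate("quadrant", "A", "B", [xt, yt, which])
            got = set(hc.apply_gate(table, ids, gate).member_ids)
            want = {i for i, x, y in zip(ids, a, b)
                    if ((x >= xt) == (which in ("LR", "UR"))
                        and (y >= yt) == (which in ("UL", "UR")))}
            assert got == want


def test_multiple_selection_is_sorted_union():
    table = make_table(np.random.default_rng(5), 100)
    ids = [int(i) for i in table.ids]
    g1 = hc.Gate("rectangle", "A", "B", [0, 80, 0, 255], name="low")
    g2 = hc.Gate("rectangle", "A", "B", [170, 255, 0, 255], name="high")
    union = hc.apply_gate(table, ids, [g1, g2])
    m1 = set(hc.apply_gate(table, ids, g1).member_ids)
    m2 = set(hc.apply_gate(table, ids, g2).member_ids)
    assert union.member_ids == sorted(m1 | m2)
    assert not (m1 & m2)


def test_lasso_around_everything():
    table = make_table(np.random.default_rng(6), 40)
    ids = [int(i) for i in table.ids]
    hull = hc.Gate("lasso", "A", "B", [[-1, -1], [300, -1], [300, 300], [-1, 300]])
    assert hc.apply_gate(table, ids, hull).member_ids == ids


def test_quadrants_partition_filtered_set():
    rng = np.random.default_rng(7)
    for _ in range(10):
        table = make_table(rng, int(rng.integers(1, 300)))
        ids = [int(i) for i in table.ids][: int(rng.integers(1, len(table) + 1))]
        xt, yt = rng.uniform(0, 255, 2)
        quads = hc.quadrant_split(table, ids, "A", "B", xt, yt)
        members = [i for q in quads.values() for i in q.member_ids]
        assert sorted(members) == sorted(ids)      # everything exactly once
        assert len(members) == len(set(members))


def test_quadrant_boundary_goes_upper_right():
    table = make_table(np.random.default_rng(8), 3)
    table.df.loc[0, ["A", "B"]] = (100.0, 100.0)  # exactly at both thresholds
    quads = hc.quadrant_split(table, [1, 2, 3], "A", "B", 100.0, 100.0)
    assert 1 in quads["UR"].member_ids
    low = hc.quadrant_split(table, [1, 2, 3], "A", "B", -1.0, -1.0)
    assert low["UR"].count == 3  # thresholds below the data: everything UR


def test_filter_gate_composition():
    """Gating a filtered set equals gate-on-full-table intersected with the
    filter set."""
    rng = np.random.default_rng(9)
    table = make_table(rng, 250)
    filtered = hc.apply_filter(table, hc.FilterSpec(["C"], [(40, 180)]))
    gate = hc.Gate("rectangle", "A", "B", [30, 200, 30, 200])
    on_filtered = hc.apply_gate(table, filtered, gate).member_ids
    on_full = hc.apply_gate(table, [int(i) for i in table.ids], gate).member_ids
    assert set(on_filtered) == set(on_full) & set(filtered)


def test_mixture_recovery_on_well_separated_populations():
    """Quadrant gating at the midpoint recovers >=99% of planted memberships
    on well-separated mixtures.  Two-axis recovery is (1 - PHI(-s/2))^2 for a
    per-axis separation of s SDs, so the 99% guarantee needs s >= ~5.2; this
    exercises it at 6 SD."""
    rng = np.random.default_rng(10)
    n = 1000
    sd = 10.0
    is_t = rng.uniform(size=n) < 0.5
    a = np.where(is_t, rng.normal(150, sd, n), rng.normal(90, sd, n))  # 6 SD
    b = np.where(is_t, rng.normal(90, sd, n), rng.normal(150, sd, n))
    table = make_table(rng, n)
    table.df["A"], table.df["B"] = a, b
    quads = hc.quadrant_split(table, [int(i) for i in table.ids],
                              "A", "B", 120.0, 120.0)
    planted_t = set(np.flatnonzero(is_t) + 1)
    planted_b = set(np.flatnonzero(~is_t) + 1)
    hits = (len(planted_t & set(quads["LR"].member_ids))
            + len(planted_b & set(quads["UL"].member_ids)))
    assert hits / n >= 0.99


def test_classify_shapes_interaction_threshold():
    rng = np.random.default_rng(11)
    table = make_table(rng, 30)
    flags = rng.integers(0, 2, 30)
    table = table.with_column("Interaction", flags, role="interaction")
    ids = [int(i) for i in table.ids]
    classes = hc.classify_shapes(table, ids, hc.ShapeRule("Interaction", 1.0))
    assert all((classes[i] == "circle") == bool(f) for i, f in zip(ids, flags))
    # threshold above the data maximum: everything in the first class
    all_low = hc.classify_shapes(table, ids, hc.ShapeRule("A", 1000.0))
    assert set(all_low.values()) == {"triangle"}
    # invariant under id reordering
    rev = hc.classify_shapes(table, ids[::-1], hc.ShapeRule("Interaction", 1.0))
    assert rev == classes


def test_population_stats_against_independent_summary():
    rng = np.random.default_rng(12)
    table = make_table(rng, 120)
    ids = [int(i) for i in table.ids]
    quads = hc.quadrant_split(table, ids, "A", "B", 128.0, 128.0)
    stats = hc.population_stats(table, list(quads.values()), parent_ids=ids)
    assert stats.summary["percent_of_parent"].sum() == pytest.approx(100.0)
    for _, row in stats.summary.iterrows():
        res = quads[row["population"]]
        if not res.count:
            continue
        sub = table.rows_for(res.member_ids)
        for col in ("A", "B", "C"):
            ref = summarize(sub[col].to_numpy())
            for stat, val in ref.items():
                assert row[f"{col}_{stat}"] == pytest.approx(val)


def test_population_stats_single_gate_and_empty_gate():
    table = make_table(np.random.default_rng(13), 25)
    ids = [int(i) for i in table.ids]
    full = hc.GateResult("all", ids)
    empty = hc.GateResult("none", [])
    stats = hc.population_stats(table, [full, empty], parent_ids=ids)
    assert stats.summary.loc[0, "count"] == 25
    assert stats.summary.loc[0, "percent_of_parent"] == 100.0
    assert stats.summary.loc[1, "count"] == 0          # zero row kept
    assert np.isnan(stats.summary.loc[1, "A_mean"])


def test_gate_persistence_roundtrip(tmp_path):
    gates = [hc.Gate("rectangle", "A", "B", [0.0, 10.0, 0.0, 10.0], name="r"),
             hc.Gate("lasso", "A", "B", [[0, 0], [5, 0], [5, 5]], name="l"),
             hc.Gate("quadrant", "A", "B", [100.0, 100.0, "LR"], name="q")]
    filters = [hc.FilterSpec(["Area"], [(40.0, 200.0)])]
    rules = [hc.ShapeRule("Interaction", 1.0)]
    path = tmp_path / "gates.json"
    hc.save_gates(path, gates, filters, rules)
    g2, f2, r2 = hc.load_gates(path)
    assert [g.kind for g in g2] == ["rectangle", "lasso", "quadrant"]
    assert g2[0].geometry == [0.0, 10.0, 0.0, 10.0]
    assert g2[2].geometry[2] == "LR"
    assert f2[0].params == ["Area"] and f2[0].bounds == [(40.0, 200.0)]
    assert r2[0].threshold == 1.0


def test_gate_persistence_minimal_json_and_version_check(tmp_path):
    path = tmp_path / "hand.json"
    path.write_text('{"schema_version": 1, "gates": [{"kind": "rectangle", '
                    '"x_param": "LT", "y_param": "LB", '
                    '"geometry": [0, 100, 0, 100]}]}')
    gates, filters, rules = hc.load_gates(path)
    assert len(gates) == 1 and gates[0].x_param == "LT"
    assert filters == [] and rules == []

    newer = tmp_path / "newer.json"
    newer.write_text('{"schema_version": 99, "gates": []}')
    with pytest.raises(SchemaVersionError):
        hc.load_gates(newer)


def test_degenerate_gate_geometry_rejected():
    with pytest.raises(ValueError):
        hc.Gate("rectangle", "A", "B", [5, 5, 0, 10])
    with pytest.raises(ValueError):
        hc.Gate("lasso", "A", "B", [[0, 0], [1, 1]])
    with pytest.raises(ValueError):
        hc.Gate("quadrant", "A", "B", [np.inf, 0, "UR"])


def test_annotate_involution_and_identity():
    table = make_table(np.random.default_rng(14), 10)
    original = table.copy()
    edited, log = hc.annotate(table, [hc.AnnotationEdit(3, "A", 7.5)])
    assert float(edited.rows_for([3])["A"].iloc[0]) == 7.5
    reverted, _ = hc.annotate(edited, [hc.AnnotationEdit(3, "A", log[0].old_value)])
    assert reverted == original
    untouched, empty_log = hc.annotate(table, [])
    assert untouched == table and empty_log == []


def test_annotate_conflict_last_wins_with_warning():
    table = make_table(np.random.default_rng(15), 5)
    edits = [hc.AnnotationEdit(2, "A", 1.0), hc.AnnotationEdit(2, "A", 2.0)]
    with pytest.warns(UserWarning, match="conflicting"):
        edited, log = hc.annotate(table, edits)
    assert float(edited.rows_for([2])["A"].iloc[0]) == 2.0
    assert len(log) == 2


def test_annotate_changes_downstream_statistics():
    table = make_table(np.random.default_rng(16), 20)
    ids = [int(i) for i in table.ids]
    before = hc.population_stats(table, [hc.GateResult("all", ids)], ids)
    edited, _ = hc.annotate(table, [hc.AnnotationEdit(1, "A", 250.0)])
    after = hc.population_stats(edited, [hc.GateResult("all", ids)], ids)
    expect = summarize(edited.rows_for(ids)["A"].to_numpy())["mean"]
    assert after.summary.loc[0, "A_mean"] == pytest.approx(expect)
    assert after.summary.loc[0, "A_mean"] != before.summary.loc[0, "A_mean"]
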