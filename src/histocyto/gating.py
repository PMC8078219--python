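"""The "Plot to Image" engine: filters, gates, symbol-shape classes,
population statistics, gate persistence and annotation edits.

Selection follows flow-cytometry practice applied to per-cell image
measurements: a coarse *filter* on one or two parameters removes badly
segmented cells first, then *gates* (quadrants, rectangles, lassos, in
single or multiple selection mode) carve the filtered cells into
populations on a two-parameter scatterplot, and a third parameter can split
every point into two symbol-shape classes at a user threshold.

One boundary convention everywhere: intervals are closed, and a value
exactly at a threshold goes to the upper/right/second class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import SchemaVersionError
from .tabular_io import CoiTable

GATE_SCHEMA_VERSION = 1


@dataclass
class FilterSpec:
    """Range filter on one parameter or rectangle filter on two.

    ``params`` holds 1-2 column names; ``bounds`` one closed ``[lo, hi]``
    interval per parameter.
    """

    params: list[str]
    bounds: list[tuple[float, float]]

    def __post_init__(self):
        if not 1 <= len(self.params) <= 2 or len(self.params) != len(self.bounds):
            raise ValueError("a filter takes 1 or 2 parameters, one bound each")
        for lo, hi in self.bounds:
            if lo > hi:
                raise ValueError(f"filter bound [{lo}, {hi}] has lo > hi")

    @property
    def mode(self) -> str:
        return "range" if len(self.params) == 1 else "rectangle"


@dataclass
class Gate:
    """Declarative scatterplot selection geometry.

    ``kind`` is ``rectangle`` (geometry ``[x0, x1, y0, y1]``), ``lasso``
    (geometry: vertex list, >=3) or ``quadrant`` (geometry
    ``[x_thr, y_thr, which]`` with ``which`` in LL/LR/UL/UR).
    """

    kind: str
    x_param: str
    y_param: str
    geometry: list
    name: str = ""

    def __post_init__(self):
        if self.kind == "rectangle":
            x0, x1, y0, y1 = map(float, self.geometry)
            if x0 >= x1 or y0 >= y1:
                raise ValueError(f"degenerate rectangle {self.geometry}")
        elif self.kind == "lasso":
            if len(self.geometry) < 3:
                raise ValueError("a lasso needs at least 3 vertices")
        elif self.kind == "quadrant":
            x_thr, y_thr, which = self.geometry
            if which not in ("LL", "LR", "UL", "UR"):
                raise ValueError(f"unknown quadrant {which!r}")
            if not (np.isfinite(x_thr) and np.isfinite(y_thr)):
                raise ValueError("quadrant thresholds must be finite")
        else:
            raise ValueError(f"unknown gate kind {self.kind!r}")


@dataclass
class ShapeRule:
    """Third-parameter display split: values below ``threshold`` take the
    first marker class, values at or above it the second."""

    param: str
    threshold: float
    classes: tuple[str, str] = ("triangle", "circle")

    def __post_init__(self):
        if len(self.classes) != 2:
            raise ValueError("a shape rule defines exactly two classes")


@dataclass
class GateResult:
    """Members selected by one gate, plus how they were selected."""

    name: str
    member_ids: list[int]
    provenance: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.member_ids)


def apply_filter(table: CoiTable, spec: FilterSpec) -> list[int]:
    """Ids whose values lie inside the closed bounds of every filtered
    parameter, in table order."""
    keep = np.ones(len(table), dtype=bool)
    for param, (lo, hi) in zip(spec.params, spec.bounds):
        vals = np.asarray(table.column(param), dtype=float)
        keep &= (vals >= lo) & (vals <= hi)
    return [int(i) for i in table.ids[keep]]


def _membership(table: CoiTable, ids: list[int], gate: Gate) -> np.ndarray:
    sub = table.rows_for(ids)
    x = sub[table.resolve(gate.x_param)].to_numpy(dtype=float)
    y = sub[table.resolve(gate.y_param)].to_numpy(dtype=float)
    if gate.kind == "rectangle":
        x0, x1, y0, y1 = map(float, gate.geometry)
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if gate.kind == "lasso":
        poly = Polygon(np.asarray(gate.geometry, dtype=float))
        return shapely.covers(poly, shapely.points(x, y))
    x_thr, y_thr, which = gate.geometry
    hi_x, hi_y = x >= float(x_thr), y >= float(y_thr)
    return {"LL": ~hi_x & ~hi_y, "LR": hi_x & ~hi_y,
            "UL": ~hi_x & hi_y, "UR": hi_x & hi_y}[which]


def apply_gate(table: CoiTable, ids, gate) -> GateResult:
    """Select members of ``gate`` among the filtered ``ids``.

    Passing a list of gates applies multiple-selection mode: the union of
    the member sets, ascending id order, duplicates removed.
    """
    ids = [int(i) for i in ids]
    if isinstance(gate, (list, tuple)):
        members: set[int] = set()
        for g in gate:
            members.update(apply_gate(table, ids, g).member_ids)
        name = "+".join(g.name or g.kind for g in gate)
        return GateResult(name, sorted(members),
                          {"mode": "multiple", "gates": len(gate)})
    mask = _membership(table, ids, gate)
    members = [i for i, m in zip(ids, mask) if m]
    return GateResult(gate.name or gate.kind, members,
                      {"mode": "single", "kind": gate.kind,
                       "x_param": gate.x_param, "y_param": gate.y_param})


def quadrant_split(table: CoiTable, ids, x_param: str, y_param: str,
                   x_thr: float, y_thr: float) -> dict[str, GateResult]:
    """Partition the filtered ids into the four scatterplot quadrants.

    At-threshold values go up/right, so every id lands in exactly one
    quadrant: LL (x<thr, y<thr), LR (x>=thr, y<thr), UL, UR.
    """
    out = {}
    for which in ("LL", "LR", "UL", "UR"):
        gate = Gate("quadrant", x_param, y_param, [x_thr, y_thr, which], name=which)
        out[which] = apply_gate(table, ids, gate)
    return out


def classify_shapes(table: CoiTable, ids, rule: ShapeRule) -> dict[int, str]:
    """Two-way symbol-shape split of the selected ids at the rule threshold."""
    ids = [int(i) for i in ids]
    vals = table.rows_for(ids)[table.resolve(rule.param)].to_numpy(dtype=float)
    return {i: rule.classes[1] if v >= rule.threshold else rule.classes[0]
            for i, v in zip(ids, vals)}


@dataclass
class PopulationStats:
    """Per-population summary plus the per-member rows (the downloadable
    statistics tables)."""

    summary: pd.DataFrame
    members: pd.DataFrame

    def to_csv(self, summary_path, members_path) -> tuple[str, str]:
        self.summary.to_csv(summary_path, index=False)
        self.members.to_csv(members_path, index=False)
        return str(summary_path), str(members_path)


def population_stats(table: CoiTable, results, parent_ids=None) -> PopulationStats:
    """Counts, percent of the filtered parent, and per-column mean/median/
    min/max for each gated population.  Empty populations keep their zero
    row rather than being dropped."""
    if parent_ids is None:
        parent_count = len(table)
    else:
        parent_count = len(list(parent_ids))
    numeric = [c for c in table.parameter_columns
               if pd.api.types.is_numeric_dtype(table.df[c])]
    summary_rows = []
    member_frames = []
    for res in results:
        row = {"population": res.name, "count": res.count,
               "percent_of_parent": (100.0 * res.count / parent_count
                                     if parent_count else float("nan"))}
        if res.count:
            sub = table.rows_for(res.member_ids)
            for c in numeric:
                vals = sub[c].astype(float)
                row[f"{c}_mean"] = vals.mean()
                row[f"{c}_median"] = vals.median()
                row[f"{c}_min"] = vals.min()
                row[f"{c}_max"] = vals.max()
            block = sub.reset_index(drop=True).copy()
            block.insert(0, "population", res.name)
            member_frames.append(block)
        else:
            for c in numeric:
                for stat in ("mean", "median", "min", "max"):
                    row[f"{c}_{stat}"] = float("nan")
        summary_rows.append(row)
    members = (pd.concat(member_frames, ignore_index=True) if member_frames
               else pd.DataFrame(columns=["population"] + list(table.df.columns)))
    return PopulationStats(pd.DataFrame(summary_rows), members)


# ---------------------------------------------------------------------------
# gate persistence

def _gate_to_json(g: Gate) -> dict:
    geometry = g.geometry
    if g.kind == "lasso":
        geometry = [[float(x), float(y)] for x, y in geometry]
    elif g.kind == "quadrant":
        geometry = [float(geometry[0]), float(geometry[1]), geometry[2]]
    else:
        geometry = [float(v) for v in geometry]
    return {"kind": g.kind, "x_param": g.x_param, "y_param": g.y_param,
            "geometry": geometry, "name": g.name}


def save_gates(path, gates=(), filters=(), shape_rules=()) -> str:
    """Persist gates, filters and shape rules as versioned JSON.

    Geometry is stored in data units (not pixels), so saved gates transfer
    across images of the same panel.
    """
    doc = {
        "schema_version": GATE_SCHEMA_VERSION,
        "gates": [_gate_to_json(g) for g in gates],
        "filters": [{"params": list(f.params),
                     "bounds": [[float(lo), float(hi)] for lo, hi in f.bounds]}
                    for f in filters],
        "shape_rules": [{"param": r.param, "threshold": float(r.threshold),
                         "classes": list(r.classes)} for r in shape_rules],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
    return str(path)


def load_gates(path) -> tuple[list[Gate], list[FilterSpec], list[ShapeRule]]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version is None or int(version) > GATE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"gate file schema version {version!r} is newer than the supported "
            f"version {GATE_SCHEMA_VERSION}")
    gates = [Gate(d["kind"], d["x_param"], d["y_param"], d["geometry"],
                  d.get("name", "")) for d in doc.get("gates", [])]
    filters = [FilterSpec(d["params"], [tuple(b) for b in d["bounds"]])
               for d in doc.get("filters", [])]
    rules = [ShapeRule(d["param"], d["threshold"], tuple(d.get("classes",
                                                               ("triangle", "circle"))))
             for d in doc.get("shape_rules", [])]
    return gates, filters, rules


# ---------------------------------------------------------------------------
# annotation

@dataclass
class AnnotationEdit:
    """One manual correction: set ``column`` of cell ``coi_id`` to
    ``new_value``; ``old_value`` is filled in when the edit is applied."""

    coi_id: int
    column: str
    new_value: object
    old_value: object = None
    timestamp: str = ""


def annotate(table: CoiTable, edits) -> tuple[CoiTable, list[AnnotationEdit]]:
    """Apply manual edits in order; return the edited table and the audit log.

    Conflicting edits to the same cell and column resolve last-wins, with a
    warning.  Applying an edit and then its inverse restores the original.
    """
    out = table.copy()
    id_col = out.roles["id"]
    index = pd.Index(out.df[id_col])
    log: list[AnnotationEdit] = []
    seen: set[tuple[int, str]] = set()
    for e in edits:
        col = out.resolve(e.column)
        pos = index.get_indexer([e.coi_id])
        if pos[0] < 0:
            raise KeyError(f"no cell with id {e.coi_id}")
        key = (int(e.coi_id), col)
        if key in seen:
            warnings.warn(f"conflicting edits to cell {e.coi_id}, column {col!r}; "
                          "keeping the last one", stacklevel=2)
        seen.add(key)
        old = out.df.at[pos[0], col]
        out.df.at[pos[0], col] = e.new_value
        log.append(AnnotationEdit(
            int(e.coi_id), col, e.new_value, old_value=old,
            timestamp=e.timestamp or datetime.now(timezone.utc).isoformat()))
    return out, log
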