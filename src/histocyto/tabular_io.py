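"""Segmentation result tables and channel legends.

The results CSV carries one row per segmented cell (COI): per-channel mean
membrane intensities in arbitrary units bounded by [0, 255], centroid
coordinates, morphology (area, circularity, solidity) and binary flags
(interaction with a partner cell, membership of a dense region).  The
legend CSV maps channel headers ``Ch1..ChN`` to human-readable labels
(e.g. ``Ch1 -> LT``).

Column names follow Fiji export conventions and are matched
case-insensitively with synonyms, so tables produced by different macros
load without editing.  The original header names and order are preserved
so a read → write round trip is the identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

INTENSITY_MIN = 0.0
INTENSITY_MAX = 255.0

#: canonical role -> accepted (lower-cased) header spellings
_ROLE_SYNONYMS = {
    "id": ("id", "coi_id", "coi", "label", "cell_id", "unnamed: 0"),
    "x": ("x", "xm", "x_centroid", "centroid_x"),
    "y": ("y", "ym", "y_centroid", "centroid_y"),
    "z": ("z",),
    "slice": ("slice",),
    "area": ("area",),
    "circularity": ("circ", "circ.", "circularity", "round", "roundness"),
    "solidity": ("solidity",),
    "interaction": ("interaction", "interact"),
    "region": ("roi_dbscan", "region", "in_region"),
}

_CH_HEADER_RE = re.compile(r"^ch(\d+)$", re.IGNORECASE)


def _norm(name: str) -> str:
    return str(name).strip().lower()


@dataclass
class Legend:
    """Ordered mapping from channel header (``Ch1``...) to channel label."""

    entries: dict[str, str]

    def __post_init__(self):
        numbers = []
        for header in self.entries:
            m = _CH_HEADER_RE.match(str(header).strip())
            if not m:
                raise FormatError(f"legend header {header!r} is not of the form ChN")
            numbers.append(int(m.group(1)))
        if numbers != list(range(1, len(numbers) + 1)):
            raise FormatError(
                f"legend headers must be Ch1..Ch{len(numbers)} consecutive; got {numbers}")

    def __len__(self):
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return list(self.entries.values())

    @property
    def n_channels(self) -> int:
        return len(self.entries)

    def label_of(self, channel_index: int) -> str:
        """Label of the 1-based channel index."""
        return self.labels[channel_index - 1]


def read_legend(path) -> Legend:
    """Read the legend CSV (headers ``Ch1..ChN``, one row of labels)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[0] < 1:
        raise FormatError("legend file has no label row")
    return Legend(dict(zip(df.columns, df.iloc[0].astype(str))))


def write_legend(legend: Legend, path) -> str:
    pd.DataFrame([legend.entries]).to_csv(path, index=False)
    return str(path)


@dataclass
class CoiTable:
    """Tabular record of every cell of interest.

    ``df`` holds the data with the original column names and order
    (the id column included); ``roles`` maps canonical roles (``x``, ``y``,
    ``area``, ...) to the actual column names; ``intensity_columns`` maps
    legend labels to the columns holding that channel's intensity.
    """

    df: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    intensity_columns: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        if not isinstance(other, CoiTable):
            return NotImplemented
        if list(self.df.columns) != list(other.df.columns):
            return False
        if len(self.df) != len(other.df):
            return False
        if len(self.df) == 0:
            return True
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True), other.df.reset_index(drop=True),
                check_dtype=False, check_exact=False, rtol=0, atol=1e-9)
            return True
        except AssertionError:
            return False

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def parameter_columns(self) -> list[str]:
        """All columns except the id column (the 'parameters' of a COI)."""
        id_col = self.roles.get("id")
        return [c for c in self.df.columns if c != id_col]

    @property
    def ids(self) -> np.ndarray:
        return self.df[self.roles["id"]].to_numpy(dtype=np.int64)

    def column(self, name_or_role: str) -> np.ndarray:
        """Values of a column, addressed by role, exact name or synonym."""
        col = self.resolve(name_or_role)
        return self.df[col].to_numpy()

    def resolve(self, name_or_role: str) -> str:
        if name_or_role in self.roles:
            return self.roles[name_or_role]
        if name_or_role in self.df.columns:
            return name_or_role
        lowered = {_norm(c): c for c in self.df.columns}
        if _norm(name_or_role) in lowered:
            return lowered[_norm(name_or_role)]
        raise KeyError(f"unknown column or role {name_or_role!r}; "
                       f"available: {list(self.df.columns)}")

    def rows_for(self, coi_ids) -> pd.DataFrame:
        idx = self.df.set_index(self.roles["id"], drop=False)
        return idx.loc[list(coi_ids)]

    def with_column(self, name: str, values, role: str | None = None) -> "CoiTable":
        """Return a copy with ``name`` set (appended when new)."""
        df = self.df.copy()
        df[name] = values
        roles = dict(self.roles)
        if role:
            roles[role] = name
        return CoiTable(df, roles, dict(self.intensity_columns))

    def copy(self) -> "CoiTable":
        return CoiTable(self.df.copy(), dict(self.roles), dict(self.intensity_columns))


def _map_roles(columns, legend: Legend | None):
    roles: dict[str, str] = {}
    intensity: dict[str, str] = {}
    labels = {_norm(lbl): lbl for lbl in (legend.labels if legend else [])}
    headers = {f"ch{i}": lbl for i, lbl in enumerate(legend.labels, 1)} if legend else {}
    for col in columns:
        key = _norm(col)
        if key in labels and labels[key] not in intensity:
            intensity[labels[key]] = col
            continue
        if key in headers and headers[key] not in intensity:
            intensity[headers[key]] = col
            continue
        for role, synonyms in _ROLE_SYNONYMS.items():
            if key in synonyms and role not in roles:
                roles[role] = col
                break
    # Fiji "Results" exports carry an unnamed leading index column; treat it
    # as the id when no explicit id column exists.
    if "id" not in roles:
        first = columns[0] if len(columns) else None
        if first is not None and (_norm(first).startswith("unnamed") or first == ""):
            roles["id"] = first
    # z doubles as the slice when no explicit slice column is present
    if "slice" not in roles and "z" in roles:
        roles["slice"] = roles["z"]
    return roles, intensity


def _validate(df: pd.DataFrame, roles, intensity, n_slices=None):
    problems = []
    id_col = roles.get("id")
    if id_col is not None and len(df):
        ids = df[id_col]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise IntegrityError(
                f"duplicate coi_id values: {sorted(set(dup.tolist()))[:10]}")
    for label, col in intensity.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(vals < INTENSITY_MIN) | (vals > INTENSITY_MAX)]
        for i in bad:
            problems.append((int(i) + 2, col,  # +2: header line + 1-based rows
                             f"intensity {df.at[i, col]} outside [0, 255]"))
    for role, lo, hi in (("circularity", 0.0, 1.0), ("solidity", 0.0, 1.0)):
        if role in roles:
            vals = pd.to_numeric(df[roles[role]], errors="coerce")
            bad = df.index[(vals < lo) | (vals > hi)]
            for i in bad:
                problems.append((int(i) + 2, roles[role],
                                 f"{role} {df.at[i, roles[role]]} outside [{lo}, {hi}]"))
    if "slice" in roles and n_slices is not None and len(df):
        vals = pd.to_numeric(df[roles["slice"]], errors="coerce")
        bad = df.index[(vals < 1) | (vals > n_slices)]
        for i in bad:
            problems.append((int(i) + 2, roles["slice"],
                             f"slice {df.at[i, roles['slice']]} outside [1, {n_slices}]"))
    if problems:
        lines = "; ".join(f"line {r}, column {c}: {m}" for r, c, m in problems[:20])
        raise ValidationError(f"{len(problems)} invalid value(s): {lines}",
                              details=problems)


def read_results(path, legend: Legend | None = None, *, n_slices: int | None = None,
                 validate: bool = True) -> CoiTable:
    """Read a segmentation results CSV into a :class:`CoiTable`.

    Intensity columns are matched to the legend labels (or ``ChN`` headers);
    unknown numeric columns are kept as extra parameters.  Validation
    reports every offending line and column in one error.
    """
    df = pd.read_csv(path)
    if len(df.columns) and all(_looks_numeric(c) for c in df.columns):
        raise FormatError(f"{path}: first line looks like data, not a header row")
    if len(df.columns) < 2:
        raise FormatError(f"{path}: a results table needs at least two columns")
    roles, intensity = _map_roles(list(df.columns), legend)
    if "id" not in roles:
        df.insert(0, "ID", np.arange(1, len(df) + 1, dtype=np.int64))
        roles["id"] = "ID"
    if validate:
        _validate(df, roles, intensity, n_slices=n_slices)
    return CoiTable(df, roles, intensity)


def _looks_numeric(token) -> bool:
    try:
        float(str(token))
        return True
    except ValueError:
        return False


def write_results(table: CoiTable, path) -> str:
    """Write the table back to CSV, preserving column names and order."""
    table.df.to_csv(path, index=False)
    return str(path)
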