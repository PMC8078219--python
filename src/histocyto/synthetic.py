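"""Synthetic four-file bundles (image.tif, roi.zip, results.csv, legend.csv)
with ground truth, emulating a stimulated lymphoid-tissue acquisition.

The default preset mirrors the structure of a spectral confocal use case:
176 cells of interest over 12 optical slices and 6 channels, a planted
T/B-cell intensity mixture on the membrane channels, a planted dense
proliferation region (for DBSCAN), and planted phagocyte contacts — so
every downstream module is testable without any real acquisition.

Nuclei are integer-radius spheres at integer centres, which guarantees a
strictly largest cross-section on the central slice (the lattice points at
distance exactly r exist only there).  Membranes are painted as shells that
cover the entire measurement ring, so with zero noise the measured ring
means equal the planted values exactly.

One pseudo-random stream (seeded from ``SceneSpec.seed``) is consumed in a
fixed order — population assembly, cluster membership, radii, placement,
axial position, intensities, contacts, noise — so identical seeds give
byte-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PackingError
from .gating import FilterSpec, ShapeRule, apply_filter, classify_shapes, quadrant_split
from .image_stack import ImageStack, load_stack, save_stack
from .measure import NucleusLabels, RingSpec, run_measurement
from .roi_io import read_roi_archive, write_roi_archive
from .spatial import (REGION_COLUMN, assign_interaction_flag, assign_region_flag,
                      dbscan_regions, detect_interactions, partner_mask_from_stack)
from .tabular_io import CoiTable, Legend, read_legend, read_results, write_legend, write_results

USECASE_LEGEND = Legend({"Ch1": "Ki67", "Ch2": "LB", "Ch3": "LT",
                         "Ch4": "Phago", "Ch5": "LTact", "Ch6": "DAPI"})


@dataclass
class PopulationSpec:
    """One planted cell population: its size, membrane intensity per channel
    label (mean, SD — arbitrary units in [0, 255]) and nucleus radius range
    (px, inclusive)."""

    label: str
    count: int
    intensity: dict[str, tuple[float, float]]
    radius_range: tuple[int, int] = (3, 5)


@dataclass
class ClusterSpec:
    """Planted dense region: a disk holding ``member_fraction`` of all cells
    packed at the global minimum spacing; the rest are scattered outside,
    isolated enough to read as background density."""

    radius: float = 300.0
    center: tuple[float, float] | None = None  # defaults to the image centre
    member_fraction: float = 0.65


@dataclass
class SceneSpec:
    """Everything the generator needs to build one reproducible bundle."""

    size: tuple[int, int] = (1024, 1024)        # (X, Y)
    n_slices: int = 12
    legend: Legend = field(default_factory=lambda: USECASE_LEGEND)
    populations: list[PopulationSpec] = field(default_factory=list)
    cluster: ClusterSpec | None = None
    contact_fraction: float = 0.25
    noise_sd: float = 5.0
    min_spacing: float = 34.0                   # px between cell centres
    ring: RingSpec = field(default_factory=RingSpec)
    contact_dist: float = 2.0
    table_channels: tuple[str, ...] = ("LT", "LB")
    partner_channel: str = "Phago"
    partner_value: float = 200.0
    partner_threshold: float = 80.0
    blob_radius: int = 4
    nucleus_channel: str = "Ki67"
    nucleus_value: float = 220.0
    counterstain_channel: str = "DAPI"
    counterstain_value: float = 180.0
    seed: int = 0
    max_attempts: int = 1000

    @property
    def n_cells(self) -> int:
        return sum(p.count for p in self.populations)

    @property
    def eps(self) -> float:
        """DBSCAN radius used downstream: twice the planted spacing."""
        return 2.0 * self.min_spacing

    @property
    def min_pts(self) -> int:
        return 4

    def quadrant_thresholds(self) -> tuple[float, float]:
        """Midpoints between the extreme planted means on the two scatter
        channels — the natural gate position for well-separated mixtures."""
        thr = []
        for label in self.table_channels[:2]:
            means = [p.intensity[label][0] for p in self.populations
                     if label in p.intensity]
            thr.append((max(means) + min(means)) / 2.0)
        return thr[0], thr[1]

    def expected_quadrant(self, population: PopulationSpec) -> str:
        x_thr, y_thr = self.quadrant_thresholds()
        x_label, y_label = self.table_channels[:2]
        hi_x = population.intensity.get(x_label, (0, 0))[0] >= x_thr
        hi_y = population.intensity.get(y_label, (0, 0))[0] >= y_thr
        return {(False, False): "LL", (True, False): "LR",
                (False, True): "UL", (True, True): "UR"}[(hi_x, hi_y)]


def usecase_spec(seed: int = 0, noise_sd: float = 5.0) -> SceneSpec:
    """The default preset: 176 cells (80 T, 70 B, 26 uncharacterized),
    6 channels, 12 slices, planted dense region and phagocyte contacts."""
    populations = [
        PopulationSpec("T", 80, {"LT": (180.0, 10.0), "LB": (30.0, 10.0)}),
        PopulationSpec("B", 70, {"LT": (30.0, 10.0), "LB": (180.0, 10.0)}),
        PopulationSpec("unchar", 26, {"LT": (30.0, 10.0), "LB": (30.0, 10.0)}),
    ]
    return SceneSpec(populations=populations, cluster=ClusterSpec(),
                     noise_sd=noise_sd, seed=seed)


@dataclass
class GroundTruth:
    """What was planted, per cell, plus the spec that planted it."""

    spec: SceneSpec
    df: pd.DataFrame

    def __len__(self):
        return len(self.df)


# ---------------------------------------------------------------------------
# placement

def _sample_positions(spec: SceneSpec, rng, radii, in_cluster) -> np.ndarray:
    X, Y = spec.size
    margin = max(radii, default=0) + spec.ring.outer_radius + spec.blob_radius * 2 + 4
    placed: list[tuple[float, float]] = []
    if spec.cluster is not None:
        cx0, cy0 = spec.cluster.center or (X / 2.0, Y / 2.0)
        R = spec.cluster.radius
        exclusion = R + spec.eps  # keeps outsiders unreachable from the cluster
    positions = np.zeros((len(radii), 2))
    for i in range(len(radii)):
        ok = False
        for _ in range(spec.max_attempts):
            if spec.cluster is not None and in_cluster[i]:
                r = R * math.sqrt(rng.uniform())
                a = rng.uniform(0, 2 * math.pi)
                x, y = cx0 + r * math.cos(a), cy0 + r * math.sin(a)
                if not (margin <= x <= X - margin and margin <= y <= Y - margin):
                    continue
            else:
                x = rng.uniform(margin, X - margin)
                y = rng.uniform(margin, Y - margin)
                if spec.cluster is not None:
                    if math.hypot(x - cx0, y - cy0) < exclusion:
                        continue
            x, y = round(x), round(y)
            good = True
            for j, (px, py) in enumerate(placed):
                d = math.hypot(x - px, y - py)
                if d < spec.min_spacing:
                    good = False
                    break
                # keep scattered background cells mutually farther than eps so
                # they stay DBSCAN noise by construction
                if (spec.cluster is not None and not in_cluster[i]
                        and not in_cluster[j] and d < spec.eps + 1):
                    good = False
                    break
            if good:
                placed.append((x, y))
                positions[i] = (x, y)
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place cell {i + 1}/{len(radii)} after "
                f"{spec.max_attempts} attempts; reduce counts or spacing")
    return positions


# ---------------------------------------------------------------------------
# painting

def _paint_scene(spec: SceneSpec, rng, cells: pd.DataFrame):
    X, Y = spec.size
    S, C = spec.n_slices, len(spec.legend)
    labels = np.zeros((S, Y, X), dtype=np.int32)
    image = np.zeros((S, C, Y, X), dtype=np.float32)
    ch_index = {lbl: k for k, lbl in enumerate(spec.legend.labels)}

    for cell in cells.itertuples():
        r = int(cell.radius)
        cx, cy, cz = int(cell.cx), int(cell.cy), int(cell.cz)
        half = r + spec.ring.outer_radius + 2
        y0, y1 = cy - half, cy + half + 1
        x0, x1 = cx - half, cx + half + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        for dz in range(-r, r + 1):
            z = cz + dz
            if not 1 <= z <= S:
                continue
            rad2 = r * r - dz * dz
            nucleus = d2 <= rad2
            labels[z - 1, y0:y1, x0:x1][nucleus] = cell.ID
            image[z - 1, ch_index[spec.nucleus_channel], y0:y1, x0:x1][nucleus] = \
                spec.nucleus_value
            image[z - 1, ch_index[spec.counterstain_channel], y0:y1, x0:x1][nucleus] = \
                spec.counterstain_value
        # membrane shell on the central slice, covering the whole ring zone
        shell_r = r + spec.ring.outer_radius + 1.5
        shell = (d2 > r * r) & (d2 <= shell_r * shell_r)
        for label in spec.table_channels:
            value = getattr(cell, f"{label}_true")
            image[cz - 1, ch_index[label], y0:y1, x0:x1][shell] = value
        if cell.contact:
            theta = cell.contact_angle
            bx = int(round(cx + (r + spec.ring.outer_radius + spec.blob_radius - 1)
                           * math.cos(theta)))
            by = int(round(cy + (r + spec.ring.outer_radius + spec.blob_radius - 1)
                           * math.sin(theta)))
            b = spec.blob_radius
            byy, bxx = np.mgrid[by - b:by + b + 1, bx - b:bx + b + 1]
            blob = (bxx - bx) ** 2 + (byy - by) ** 2 <= b * b
            image[cz - 1, ch_index[spec.partner_channel],
                  by - b:by + b + 1, bx - b:bx + b + 1][blob] = spec.partner_value

    if spec.noise_sd > 0:
        for s in range(S):
            for c in range(C):
                image[s, c] += rng.normal(0.0, spec.noise_sd, (Y, X))
    return NucleusLabels(np.ascontiguousarray(labels)), \
        np.rint(np.clip(image, 0, 255)).astype(np.uint8)


# ---------------------------------------------------------------------------
# bundle generation

def generate(spec: SceneSpec, out_dir) -> tuple[dict[str, str], GroundTruth]:
    """Build a full bundle on disk and return its paths plus ground truth.

    Files written: ``image.tif``, ``roi.zip``, ``results.csv``,
    ``legend.csv``, ``ground_truth.csv`` and the label volume
    ``labels.tif`` (input of the measurement stage).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells

    pop_labels = [p.label for p in spec.populations for _ in range(p.count)]
    pop_of = {p.label: p for p in spec.populations}
    in_cluster = np.zeros(n, dtype=bool)
    if spec.cluster is not None and n:
        k = int(round(spec.cluster.member_fraction * n))
        in_cluster[rng.choice(n, size=k, replace=False)] = True
    radii = np.array([int(rng.integers(pop_of[lbl].radius_range[0],
                                       pop_of[lbl].radius_range[1] + 1))
                      for lbl in pop_labels], dtype=int)
    positions = _sample_positions(spec, rng, list(radii), in_cluster)
    cz = np.empty(n, dtype=int)
    for i in range(n):
        lo = min(int(radii[i]) + 1, spec.n_slices)
        hi = max(spec.n_slices - int(radii[i]), 1)
        if lo > hi:
            lo = hi = (spec.n_slices + 1) // 2
        cz[i] = int(rng.integers(lo, hi + 1))
    values = {}
    for label in spec.table_channels:
        col = np.zeros(n)
        for i, lbl in enumerate(pop_labels):
            mean, sd = pop_of[lbl].intensity.get(label, (0.0, 0.0))
            col[i] = float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, 0, 255))
        values[f"{label}_true"] = col
    contact = np.zeros(n, dtype=bool)
    if n:
        m = int(round(spec.contact_fraction * n))
        contact[rng.choice(n, size=m, replace=False)] = True
    contact_angle = rng.uniform(0, 2 * math.pi, size=n)

    truth_df = pd.DataFrame({
        "ID": np.arange(1, n + 1, dtype=np.int64),
        "population": pop_labels,
        "cx": positions[:, 0], "cy": positions[:, 1], "cz": cz,
        "radius": radii,
        "in_cluster": in_cluster.astype(int),
        "contact": contact.astype(int),
        "contact_angle": contact_angle,
        **values,
    })
    truth = GroundTruth(spec, truth_df)

    labels, pixels = _paint_scene(spec, rng, truth_df)
    stack = ImageStack(pixels=pixels, legend=spec.legend, scale=1.0)

    meas_table, roi_set = run_measurement(stack, labels, spec.ring)
    partner = partner_mask_from_stack(stack, spec.legend.labels.index(
        spec.partner_channel) + 1, spec.partner_threshold)
    flags = detect_interactions(roi_set, partner, spec.contact_dist)
    if n:
        centroids = np.stack([meas_table.column("x"), meas_table.column("y")], axis=1)
        labeling = dbscan_regions(centroids, spec.eps, spec.min_pts,
                                  ids=meas_table.ids)
    else:
        labeling = dbscan_regions(np.zeros((0, 2)), spec.eps, spec.min_pts,
                                  ids=np.zeros(0, dtype=np.int64))
    table = meas_table
    # keep only the scatterplot channels among the measured intensities
    drop = [c for lbl, c in table.intensity_columns.items()
            if lbl not in spec.table_channels]
    table = CoiTable(table.df.drop(columns=drop), dict(table.roles),
                     {lbl: c for lbl, c in table.intensity_columns.items()
                      if lbl in spec.table_channels})
    table = assign_interaction_flag(table, flags)
    table = assign_region_flag(table, labeling)

    paths = {
        "image": str(out / "image.tif"),
        "roi": str(out / "roi.zip"),
        "results": str(out / "results.csv"),
        "legend": str(out / "legend.csv"),
        "ground_truth": str(out / "ground_truth.csv"),
        "labels": str(out / "labels.tif"),
    }
    save_stack(stack, paths["image"])
    save_stack(labels.labels.astype(np.uint16)[:, None], paths["labels"])
    write_roi_archive(roi_set, paths["roi"])
    write_results(table, paths["results"])
    write_legend(spec.legend, paths["legend"])
    truth_df.to_csv(paths["ground_truth"], index=False)
    return paths, truth


def load_bundle(paths_or_dir):
    """Read a bundle back: ``(stack, table, roi_set, legend)``."""
    if isinstance(paths_or_dir, (str, Path)):
        d = Path(paths_or_dir)
        paths = {"image": d / "image.tif", "roi": d / "roi.zip",
                 "results": d / "results.csv", "legend": d / "legend.csv"}
    else:
        paths = paths_or_dir
    legend = read_legend(paths["legend"])
    table = read_results(paths["results"], legend)
    roi_set = read_roi_archive(paths["roi"])
    stack = load_stack(paths["image"], legend)
    return stack, table, roi_set, legend


def end_to_end_check(paths_or_dir, truth: GroundTruth) -> dict:
    """Run the analysis pipeline on a generated bundle and score it against
    the planted ground truth.

    Reproduces the use-case workflow: filter to the dense region, split the
    filtered cells into quadrants on the two membrane channels at the
    planted midpoints, and classify symbols by the interaction flag — then
    reports identity / region / contact recovery over the whole scene.
    """
    spec = truth.spec
    stack, table, roi_set, _ = load_bundle(paths_or_dir)
    report: dict = {"n_cells": len(table)}
    if len(table) == 0:
        return report
    tdf = truth.df.set_index("ID")
    ids = [int(i) for i in table.ids]

    # identity recovery via quadrant gating over all cells
    x_label, y_label = spec.table_channels[:2]
    x_thr, y_thr = spec.quadrant_thresholds()
    quadrants = quadrant_split(table, ids, x_label, y_label, x_thr, y_thr)
    report["quadrant_counts"] = {k: v.count for k, v in quadrants.items()}
    expected = {p.label: spec.expected_quadrant(p) for p in spec.populations}
    tb_pops = {lbl for lbl, q in expected.items() if q in ("LR", "UL")}
    measured_quadrant = {}
    for which, res in quadrants.items():
        for i in res.member_ids:
            measured_quadrant[i] = which
    tb_ids = [i for i in ids if tdf.at[i, "population"] in tb_pops]
    recovered = sum(measured_quadrant[i] == expected[tdf.at[i, "population"]]
                    for i in tb_ids)
    report["tb_total"] = len(tb_ids)
    report["tb_recovered"] = int(recovered)
    report["tb_identity_recovery_pct"] = 100.0 * recovered / max(1, len(tb_ids))

    # region membership vs the planted cluster
    region = np.asarray(table.column("region"), dtype=int)
    planted = np.array([tdf.at[i, "in_cluster"] for i in ids], dtype=int)
    report["region_agreement_pct"] = float(100.0 * np.mean(region == planted))

    # contact flags vs the planted contacts
    inter = np.asarray(table.column("interaction"), dtype=int)
    planted_c = np.array([tdf.at[i, "contact"] for i in ids], dtype=int)
    report["contact_accuracy_pct"] = float(100.0 * np.mean(inter == planted_c))

    # the narrative workflow: filter to the region, gate, classify shapes
    filtered = apply_filter(table, FilterSpec([REGION_COLUMN], [(1, 1)]))
    report["n_filtered"] = len(filtered)
    fq = quadrant_split(table, filtered, x_label, y_label, x_thr, y_thr)
    report["filtered_quadrant_counts"] = {k: v.count for k, v in fq.items()}
    t_like = [lbl for lbl, q in expected.items() if q == "LR"]
    if t_like:
        shapes = classify_shapes(table, fq["LR"].member_ids,
                                 ShapeRule("interaction", 1.0))
        report["gated_T_interacting"] = sum(1 for v in shapes.values()
                                            if v == "circle")
    # intensity recovery per population (mean abs error of planted vs measured)
    errs = []
    for i in ids:
        for label in spec.table_channels:
            meas = float(table.rows_for([i])[table.intensity_columns[label]].iloc[0])
            errs.append(abs(meas - float(tdf.at[i, f"{label}_true"])))
    report["intensity_mae"] = float(np.mean(errs))
    return report
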