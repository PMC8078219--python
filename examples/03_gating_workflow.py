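"""Scatterplot gating: filter -> quadrant split -> shape classes -> stats.

Reproduces the canonical histo-cytometry workflow on the example bundle:
keep well-measured cells, split them into T/B/uncharacterized quadrants on
the two membrane channels, highlight phagocyte-interacting cells as a
symbol-shape class, and export population statistics.
"""

from pathlib import Path

import histocyto as hc

BUNDLE = Path("example_output/bundle")
if not BUNDLE.exists():
    raise SystemExit("run examples/01_generate_bundle.py first")

_, table, _, _ = hc.load_bundle(BUNDLE)

# 1. filter: drop cells with implausible area (badly segmented doublets)
filtered = hc.apply_filter(table, hc.FilterSpec(["Area"], [(10.0, 500.0)]))
print(f"filter kept {len(filtered)}/{len(table)} cells (Area in [10, 500] px^2)")

# 2. quadrant gate on the two membrane channels at the mixture midpoint
quadrants = hc.quadrant_split(table, filtered, "LT", "LB", 105.0, 105.0)
for name, label in [("LR", "T cells (LT-high)"), ("UL", "B cells (LB-high)"),
                    ("LL", "uncharacterized"), ("UR", "double-positive")]:
    print(f"  {name}: {quadrants[name].count:3d}  {label}")

# 3. symbol-shape class: circles for phagocyte-interacting cells
shapes = hc.classify_shapes(table, quadrants["LR"].member_ids,
                            hc.ShapeRule("Interaction", 1.0))
n_touch = sum(1 for s in shapes.values() if s == "circle")
print(f"of the gated T cells, {n_touch} interact with a phagocyte (circles)")

# 4. downloadable statistics
stats = hc.population_stats(table, list(quadrants.values()), parent_ids=filtered)
out = Path("example_output")
stats.to_csv(out / "population_summary.csv", out / "population_members.csv")
print(stats.summary[["population", "count", "percent_of_parent",
                     "LT_mean", "LB_mean"]].round(1).to_string(index=False))
print("Percentages are relative to the filtered parent; quadrant rows always")
print("sum to 100% because the split is a partition.")

# 5. gates are saveable for later sessions
hc.save_gates(out / "gates.json",
              gates=[hc.Gate("quadrant", "LT", "LB", [105.0, 105.0, "LR"],
                             name="T cells")],
              filters=[hc.FilterSpec(["Area"], [(10.0, 500.0)])],
              shape_rules=[hc.ShapeRule("Interaction", 1.0)])
print(f"gate set saved to {out / 'gates.json'}")
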