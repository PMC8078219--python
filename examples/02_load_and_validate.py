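"""Load and validate a four-file bundle.

Reads the channel legend, the per-cell results table, the .roi contour
archive and the multi-channel TIFF, cross-checks them against each other,
and prints what a quick QC pass would look at.
"""

from pathlib import Path

import histocyto as hc

BUNDLE = Path("example_output/bundle")
if not BUNDLE.exists():
    raise SystemExit("run examples/01_generate_bundle.py first")

stack, table, rois, legend = hc.load_bundle(BUNDLE)
rois.check_against_ids(table.ids)  # warns if contours and rows disagree

print(f"legend : {len(legend)} channels -> {', '.join(legend.labels)}")
print(f"image  : {stack.width}x{stack.height} px, {stack.n_slices} slices, "
      f"{stack.n_channels} channels, resize scale {stack.scale:g}")
print(f"table  : {len(table)} cells x {len(table.parameter_columns)} parameters "
      f"({', '.join(table.parameter_columns)})")
print(f"rois   : {len(rois)} contours, slices "
      f"{min(r.slice for r in rois)}..{max(r.slice for r in rois)}")

lt = table.column("LT")
print(f"LT intensity range [{lt.min():.1f}, {lt.max():.1f}] "
      "(bounded by the 0-255 convention).")
print("A mismatch between contour ids and table rows, an intensity outside")
print("[0, 255], or a slice beyond the stack would have raised here.")
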