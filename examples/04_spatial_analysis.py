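"""Spatial analysis: DBSCAN dense regions, interaction flags, and selecting
the cells inside a drawn image region ("Image to Plot").
"""

from pathlib import Path

import numpy as np

import histocyto as hc

BUNDLE = Path("example_output/bundle")
if not BUNDLE.exists():
    raise SystemExit("run examples/01_generate_bundle.py first")

stack, table, rois, legend = hc.load_bundle(BUNDLE)

# 1. density-based regions over the cell centroids
flagged, labeling = hc.label_regions_from_table(table, eps=68.0, min_pts=4)
n_in = int(flagged.column("region").sum())
print(f"DBSCAN (eps=68 px, min_pts=4): {labeling.n_clusters} dense region(s), "
      f"{n_in}/{len(table)} cells inside (ROI_DBSCAN=1)")

# 2. interaction with the phagocyte channel: threshold it into a mask, then
#    flag cells whose contour (dilated by 2 px) touches it
phago = legend.labels.index("Phago") + 1
mask = hc.partner_mask_from_stack(stack, phago, threshold=80.0)
flags = hc.detect_interactions(rois, mask, contact_dist=2.0)
print(f"interaction flags: {sum(flags.values())}/{len(flags)} cells touch the "
      "thresholded phagocyte signal")

# 3. draw a region on the image and pull its cells onto the scatterplot
half = [(0, 0), (stack.width // 2, 0), (stack.width // 2, stack.height),
        (0, stack.height)]
inside = hc.cells_in_region(table, half)
lt = table.rows_for(inside)["LT"].to_numpy(float) if inside else np.array([])
print(f"left image half contains {len(inside)} cells; "
      f"their mean LT intensity is {lt.mean():.1f}" if len(lt)
      else "left image half contains no cells")
print("Any polygon drawn on the image maps to a cell subset this way; paired")
print("with two table columns it becomes the Image-to-Plot scatter selection.")
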