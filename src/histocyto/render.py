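"""Map gated selections back into the image: contour overlays with optional
id labels, and per-cell crops for annotation.

Rendering is fully deterministic — identical inputs give byte-identical
output — and strictly local: an overlay touches only pixels within the
stroke thickness of member contours plus the id label boxes; everything
else is bit-identical to the plain composed view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk

from .image_stack import ImageStack, RgbImage, compose
from .roi_io import RoiPolygon, RoiSet

DEFAULT_CONTOUR_COLOR = (255, 0, 255)  # magenta, distinct from the channel cycle

# 3x5 bitmap digit font (rows of 3 bits, top to bottom) for id labels
_FONT = {
    "0": ("111", "101", "101", "101", "111"),
    "1": ("010", "110", "010", "010", "111"),
    "2": ("111", "001", "111", "100", "111"),
    "3": ("111", "001", "111", "001", "111"),
    "4": ("101", "101", "111", "001", "001"),
    "5": ("111", "100", "111", "001", "111"),
    "6": ("111", "100", "111", "101", "111"),
    "7": ("111", "001", "010", "010", "010"),
    "8": ("111", "101", "111", "101", "111"),
    "9": ("111", "101", "111", "001", "111"),
}
GLYPH_W, GLYPH_H, GLYPH_GAP = 3, 5, 1
LABEL_OFFSET = 2  # px right of the contour bounding box


@dataclass
class OverlaySpec:
    """How to draw a selection: which slice/channels/gain to compose, the
    contour stroke thickness (px), whether to print ids, and the stroke
    color (RGB 0-255)."""

    slice: int = 1
    channels: tuple = (1,)
    gain: float = 1.0
    thickness: int = 1
    show_ids: bool = False
    color: tuple = DEFAULT_CONTOUR_COLOR

    def __post_init__(self):
        if self.thickness < 1:
            raise ValueError("contour thickness must be >= 1")


def _contour_raster(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Closed midpoint-line rasterization of the polygon boundary."""
    mask = np.zeros(shape, dtype=bool)
    v = roi.vertices
    h, w = shape
    for a, b in zip(v, np.roll(v, -1, axis=0)):
        rr, cc = _draw_line(int(a[1]), int(a[0]), int(b[1]), int(b[0]))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True
    return mask


def _label_mask(text: str, top: int, left: int, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    x = left
    for ch in text:
        glyph = _FONT.get(ch)
        if glyph is None:
            x += GLYPH_W + GLYPH_GAP
            continue
        for dy, row in enumerate(glyph):
            for dx, bit in enumerate(row):
                if bit == "1":
                    r, c = top + dy, x + dx
                    if 0 <= r < shape[0] and 0 <= c < shape[1]:
                        mask[r, c] = True
        x += GLYPH_W + GLYPH_GAP
    return mask


def selection_mask(rois: RoiSet, members, spec: OverlaySpec,
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(stroke mask, label mask) for the members drawn on ``spec.slice``."""
    stroke = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=bool)
    drawn_boxes = []
    for coi_id in members:
        if coi_id not in rois:
            warnings.warn(f"COI {coi_id} has no contour; skipped", stacklevel=2)
            continue
        roi = rois[coi_id]
        if roi.slice != spec.slice:
            continue
        stroke |= _contour_raster(roi, shape)
        if spec.show_ids:
            top, _, _, right = roi.bounds
            box = (top, right + LABEL_OFFSET)
            if any(abs(box[0] - b[0]) < GLYPH_H and abs(box[1] - b[1]) < 4 * GLYPH_W
                   for b in drawn_boxes):
                warnings.warn(f"id label for COI {coi_id} overlaps another label",
                              stacklevel=2)
            drawn_boxes.append(box)
            labels |= _label_mask(str(coi_id), box[0], box[1], shape)
    if spec.thickness > 1:
        stroke = dilation(stroke, disk(spec.thickness - 1)).astype(bool)
    return stroke, labels


def overlay_selection(stack: ImageStack, rois: RoiSet, members,
                      spec: OverlaySpec) -> RgbImage:
    """Compose the display image and stroke the member contours on top.

    Only contours whose central slice equals ``spec.slice`` are drawn, so
    scrolling through slices shows each selected cell on its own optical
    section.  Members without a contour are warned about and skipped.
    """
    base = compose(stack, spec.slice, spec.channels, spec.gain)
    stroke, labels = selection_mask(rois, members, spec,
                                    (stack.height, stack.width))
    out = base.pixels.copy()
    color = np.asarray(spec.color, dtype=np.uint8)
    out[stroke | labels] = color
    return RgbImage(out, provenance={**base.provenance,
                                     "members": [int(m) for m in members],
                                     "thickness": spec.thickness,
                                     "show_ids": spec.show_ids})


def crop_cell(stack: ImageStack, roi: RoiPolygon, magnification: float = 1.0,
              spec: OverlaySpec | None = None, margin: int = 0) -> RgbImage:
    """Magnified crop of one cell for visual annotation.

    The contour's bounding box, padded by ``margin`` px and clipped to the
    image, is cut from the composed view and magnified by integer pixel
    replication.  Channel/gain/slice rules are those of :func:`compose`.
    """
    if magnification < 1:
        raise ValueError("magnification must be >= 1")
    spec = spec or OverlaySpec()
    top, left, bottom, right = roi.bounds
    if bottom < 0 or right < 0 or top >= stack.height or left >= stack.width:
        raise ValueError(f"contour of COI {roi.coi_id} lies outside the image")
    r0, r1 = max(0, top - margin), min(stack.height - 1, bottom + margin)
    c0, c1 = max(0, left - margin), min(stack.width - 1, right + margin)
    base = compose(stack, spec.slice, spec.channels, spec.gain)
    crop = base.pixels[r0:r1 + 1, c0:c1 + 1]
    factor = max(1, int(round(magnification)))
    if factor > 1:
        crop = np.repeat(np.repeat(crop, factor, axis=0), factor, axis=1)
    return RgbImage(np.ascontiguousarray(crop),
                    provenance={**base.provenance, "coi_id": roi.coi_id,
                                "bbox": (r0, c0, r1, c1), "magnification": factor})


def save_png(image: RgbImage, path) -> str:
    iio.imwrite(path, image.pixels, extension=".png")
    return str(path)
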