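"""Multi-channel / multi-slice TIFF loading, the 1024-px resize rule, and
RGB display composition.

Large acquisitions are resized proportionally on load so that the longest
spatial dimension is at most 1024 px (a 2048 x 1536 image becomes
1024 x 768); per-cell geometry must be rescaled with
:func:`rescale_geometry` to stay registered with the resized pixels.
Slices and channels are 1-based throughout, matching the table convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

from .errors import DimensionError, FormatError
from .roi_io import RoiPolygon, RoiSet
from .tabular_io import CoiTable, Legend

MAX_DIM = 1024

#: default display colors cycled over channels: red, green, blue, magenta,
#: yellow, cyan (unit RGB vectors).
DEFAULT_COLORS = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (1.0, 0.0, 1.0),
    (1.0, 1.0, 0.0),
    (0.0, 1.0, 1.0),
)


@dataclass
class ImageStack:
    """Pixel data as ``[slice][channel][y][x]`` plus its channel legend.

    ``scale`` records the proportional resize factor applied on load
    (1.0 when the image was already within the 1024-px bound);
    ``original_size`` is the pre-resize ``(X, Y)``.
    """

    pixels: np.ndarray
    legend: Legend
    scale: float = 1.0
    original_size: tuple[int, int] = None

    def __post_init__(self):
        if self.pixels.ndim != 4:
            raise DimensionError(
                f"expected a (slice, channel, y, x) array; got shape {self.pixels.shape}")
        if self.pixels.dtype not in (np.uint8, np.uint16):
            raise FormatError(f"unsupported bit depth {self.pixels.dtype}; "
                              "8- and 16-bit images are supported")
        if self.n_channels != len(self.legend):
            raise DimensionError(
                f"{self.n_channels} channels in the image but {len(self.legend)} "
                "legend entries")
        if self.original_size is None:
            self.original_size = (self.width, self.height)

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[2]

    @property
    def width(self) -> int:
        return self.pixels.shape[3]

    def plane(self, slice_index: int, channel_index: int) -> np.ndarray:
        """One 2D plane; both indices 1-based."""
        if not 1 <= slice_index <= self.n_slices:
            raise IndexError(f"slice {slice_index} outside [1, {self.n_slices}]")
        if not 1 <= channel_index <= self.n_channels:
            raise IndexError(f"channel {channel_index} outside [1, {self.n_channels}]")
        return self.pixels[slice_index - 1, channel_index - 1]


@dataclass
class RgbImage:
    """8-bit RGB rendering plus how it was produced (slice, channels, gain)."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def resize_factor(width: int, height: int, max_dim: int = MAX_DIM) -> float:
    """Proportional factor so the longest dimension becomes ``max_dim``
    (1.0 when already within bounds)."""
    return min(1.0, max_dim / max(width, height))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _resize_planes(pixels: np.ndarray, scale: float) -> np.ndarray:
    s, c, h, w = pixels.shape
    new_h, new_w = _round_half_up(h * scale), _round_half_up(w * scale)
    out = np.empty((s, c, new_h, new_w), dtype=pixels.dtype)
    for i in range(s):
        for j in range(c):
            # area-averaging (anti-aliased) downsampling preserves mean
            # intensities better than nearest-neighbour
            plane = _sk_resize(pixels[i, j], (new_h, new_w),
                               anti_aliasing=True, preserve_range=True)
            out[i, j] = np.rint(plane).astype(pixels.dtype)
    return out


def _arrange_pages(arr: np.ndarray, n_channels: int, order: str) -> np.ndarray:
    """Normalize a tifffile array to (slice, channel, y, x)."""
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        pages = arr.shape[0]
        if pages == n_channels:
            arr = arr[None]  # single slice, one page per channel
        elif pages % n_channels == 0:
            n_slices = pages // n_channels
            if order == "slice_major":
                arr = arr.reshape(n_slices, n_channels, *arr.shape[1:])
            else:
                arr = arr.reshape(n_channels, n_slices, *arr.shape[1:])
                arr = arr.transpose(1, 0, 2, 3)
        else:
            raise DimensionError(
                f"{pages} TIFF pages are not divisible by {n_channels} channels")
    elif arr.ndim == 4:
        if arr.shape[1] == n_channels:
            pass  # (Z, C, Y, X)
        elif arr.shape[0] == n_channels:
            arr = arr.transpose(1, 0, 2, 3)  # (C, Z, Y, X)
        else:
            raise DimensionError(
                f"cannot locate a {n_channels}-channel axis in shape {arr.shape}")
    else:
        raise DimensionError(f"unsupported TIFF dimensionality {arr.ndim}")
    return arr


def load_stack(path, legend: Legend, *, order: str = "slice_major",
               max_dim: int = MAX_DIM) -> ImageStack:
    """Load a multi-channel TIFF and apply the proportional resize rule.

    ``order`` resolves ambiguous multi-page layouts: ``slice_major`` means
    pages iterate channels fastest (s1c1, s1c2, ..., s2c1, ...);
    ``channel_major`` the converse.
    """
    arr = np.asarray(tifffile.imread(path))
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"unsupported bit depth {arr.dtype}; expected 8- or 16-bit")
    arr = _arrange_pages(arr, len(legend), order)
    h, w = arr.shape[2], arr.shape[3]
    scale = resize_factor(w, h, max_dim)
    if scale < 1.0:
        arr = _resize_planes(arr, scale)
    return ImageStack(pixels=np.ascontiguousarray(arr), legend=legend,
                      scale=scale, original_size=(w, h))


def save_stack(stack_or_array, path) -> str:
    """Write a (slice, channel, y, x) array as a multi-page TIFF."""
    arr = stack_or_array.pixels if isinstance(stack_or_array, ImageStack) else stack_or_array
    tifffile.imwrite(path, arr, photometric="minisblack")
    return str(path)


def rescale_geometry(rois: RoiSet, table: CoiTable, scale: float) -> tuple[RoiSet, CoiTable]:
    """Scale per-cell geometry to match a resized image.

    Vertices and centroid columns are multiplied by ``scale`` (rounded for
    vertices), areas by ``scale**2``.  The inputs are left untouched so the
    original-coordinate objects stay available for export; ``scale == 1``
    returns equal copies.
    """
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1]; got {scale}")
    new_rois = RoiSet({i: r.scaled(scale) for i, r in rois.rois.items()})
    new_table = table.copy()
    for role in ("x", "y"):
        if role in table.roles:
            col = table.roles[role]
            new_table.df[col] = table.df[col].astype(float) * scale
    if "area" in table.roles:
        col = table.roles["area"]
        new_table.df[col] = table.df[col].astype(float) * scale * scale
    return new_rois, new_table


def channel_color(channel_index: int, colors=DEFAULT_COLORS) -> tuple[float, float, float]:
    """Display color of a 1-based channel index (fixed cycle, overridable)."""
    return colors[(channel_index - 1) % len(colors)]


def to_8bit(plane: np.ndarray) -> np.ndarray:
    """Map a plane to the 0-255 display range (16-bit scaled by 255/65535)."""
    if plane.dtype == np.uint16:
        return plane.astype(np.float64) * (255.0 / 65535.0)
    return plane.astype(np.float64)


def compose(stack: ImageStack, slice_index: int, channels, gain: float = 1.0,
            colors=DEFAULT_COLORS) -> RgbImage:
    """Blend selected channels of one slice into an 8-bit RGB view.

    Each channel is mapped to its display color, the colored planes are
    summed, multiplied by ``gain`` and clipped to [0, 255].
    """
    channels = list(channels)
    if not channels:
        raise ValueError("at least one channel must be selected")
    if gain < 0:
        raise ValueError("gain must be >= 0")
    out = np.zeros((stack.height, stack.width, 3), dtype=np.float64)
    for ch in channels:
        plane = to_8bit(stack.plane(slice_index, ch))
        color = channel_color(ch, colors)
        for k in range(3):
            if color[k]:
                out[..., k] += plane * color[k]
    out = np.clip(out * gain, 0.0, 255.0)
    return RgbImage(np.rint(out).astype(np.uint8),
                    provenance={"slice": slice_index, "channels": channels,
                                "gain": gain})
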