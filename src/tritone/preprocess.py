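"""Slice extraction, white-matter masking and lobe rasterization.

The diagnostic workflow keeps one lateral slice per brain (the 30th from
the top by default, 58-60 mm deep at 2 mm spacing), removes white matter
and background by an intensity threshold at 45% of the maximum allowable
intensity, and rasterizes the straight-line lobe boundaries into a label
map with one label per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import ParameterError, SegmentationError
from .io_voxels import BoundaryConfig, SliceGrid, VoxelVolume

DEFAULT_MASK_FRACTION = 0.45
DEFAULT_SLICE_ORDINAL = 30


class Region(IntEnum):
    """Labels of the rasterized lobe map."""

    OUTSIDE = 0
    FRONTAL = 1
    PARIETAL = 2
    SENSORIMOTOR = 3


#: Region label for each boundary-file region name.
REGION_LABELS = {
    "frontal": Region.FRONTAL,
    "parietal": Region.PARIETAL,
    "sensorimotor": Region.SENSORIMOTOR,
}


@dataclass(frozen=True)
class MaskParams:
    """Masking threshold parameters: a fraction of the bit-depth maximum."""

    fraction: float = DEFAULT_MASK_FRACTION
    bit_depth: int = 15

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise ParameterError(
                f"mask fraction must be in (0, 1), got {self.fraction}"
            )
        if self.bit_depth < 1:
            raise ParameterError(f"bit_depth must be positive, got {self.bit_depth}")


def mask_threshold(params: MaskParams) -> float:
    """Intensity threshold ``fraction * (2**bit_depth - 1)``, unrounded.

    At the defaults (45%, 15 bits) this is 14,745.15 out of a maximum
    allowable value of 32,767.
    """
    return params.fraction * ((1 << params.bit_depth) - 1)


def extract_slice(volume: VoxelVolume, ordinal_from_top: int) -> SliceGrid:
    """Extract the ``ordinal_from_top``-th lateral plane (1-based, from the
    top face) as a :class:`SliceGrid` with an all-true mask."""
    nz = volume.dims[2]
    if not (1 <= ordinal_from_top <= nz):
        raise IndexError(
            f"slice ordinal {ordinal_from_top} out of range 1..{nz}"
        )
    idx = ordinal_from_top - 1
    return SliceGrid(
        values=volume.values[:, :, idx].copy(),
        bit_depth=volume.bit_depth,
        slice_index=idx,
    )


def apply_mask(slice_grid: SliceGrid, threshold: float) -> SliceGrid:
    """Mask pixels whose intensity fell below ``threshold``.

    A pixel survives iff ``value >= threshold`` (strictly below means
    masked; exact equality is not "below" and is retained).  The result's
    mask is the conjunction with any pre-existing mask; values are
    unchanged.  Idempotent for a fixed threshold.
    """
    if not (0.0 <= threshold <= slice_grid.max_value):
        raise ParameterError(
            f"threshold {threshold} outside [0, {slice_grid.max_value}]"
        )
    surviving = slice_grid.values >= threshold
    return SliceGrid(
        values=slice_grid.values,
        bit_depth=slice_grid.bit_depth,
        slice_index=slice_grid.slice_index,
        mask=slice_grid.mask & surviving,
    )


def rasterize_polygon(
    points: "np.ndarray | list[tuple[float, float]]", dims: tuple[int, int]
) -> np.ndarray:
    """Pixels of a ``dims`` grid whose integer centers lie inside a polygon.

    Even-odd crossing test with a half-open convention: an edge counts when
    it crosses strictly above the pixel's y (``y0 > y`` differs across the
    edge) and the pixel's x is strictly left of the crossing.  A pixel
    center exactly on a shared boundary therefore belongs to the region
    whose interior lies on its higher-coordinate side, so adjacent regions
    rasterize without gaps or overlaps.  An axis-aligned rectangle with
    corners (x0, y0) and (x1, y1) covers exactly (x1-x0)*(y1-y0) pixels.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ParameterError("polygon needs at least 2 (x, y) points")
    nx, ny = dims
    px = np.arange(nx, dtype=float)[:, None]
    py = np.arange(ny, dtype=float)[None, :]
    inside = np.zeros((nx, ny), dtype=bool)
    x0s, y0s = pts[:, 0], pts[:, 1]
    x1s, y1s = np.roll(pts[:, 0], -1), np.roll(pts[:, 1], -1)
    for x0, y0, x1, y1 in zip(x0s, y0s, x1s, y1s):
        if y0 == y1:  # horizontal edge never crosses a scanline
            continue
        crosses = (y0 > py) != (y1 > py)
        x_int = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < x_int)
    return inside


def segment_lobes(slice_grid: SliceGrid, boundaries: BoundaryConfig) -> np.ndarray:
    """Rasterize the three lobe boundaries into a region label map.

    Returns an int8 array over the slice dims with values from
    :class:`Region`; pixels in no region are ``Region.OUTSIDE``.  Regions
    whose polygons overlap after rasterization raise
    :class:`~tritone.errors.SegmentationError` reporting the overlap size.
    """
    dims = slice_grid.dims
    boundaries.validate(dims)
    labels = np.zeros(dims, dtype=np.int8)
    claimed = np.zeros(dims, dtype=bool)
    overlap = 0
    for name, pts in boundaries.regions().items():
        region_mask = rasterize_polygon(pts, dims)
        overlap += int((claimed & region_mask).sum())
        claimed |= region_mask
        labels[region_mask] = REGION_LABELS[name]
    if overlap:
        raise SegmentationError(
            f"region polygons overlap on {overlap} pixel(s) after rasterization"
        )
    return labels
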