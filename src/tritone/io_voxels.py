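"""Readers and writers for the voxel text dialect, boundary files and images.

The voxel text dialect is the line-oriented format emitted by the clinical
pre-processing step: one voxel per line, four numeric fields
``x y z value`` (whitespace- or comma-delimited).  Boundary files carry the
straight-line lobe segmentation as a region name header followed by one
``x y`` pair per line.  A 2-D greyscale PNG can stand in for the 3-D
projection screen capture.  All readers produce the common in-memory types
:class:`VoxelVolume` and :class:`SliceGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, ParseError, RangeError

#: Default volume geometry: 86 x 100 x 86 voxels at 2 mm isotropic spacing,
#: 15-bit intensities (the spatially normalized clinical layout).
DEFAULT_DIMS = (86, 100, 86)
DEFAULT_SPACING_MM = (2.0, 2.0, 2.0)
DEFAULT_BIT_DEPTH = 15

#: Sentinel slice index for grids that did not come from a volume
#: (e.g. projection images).
SLICE_NA = -1

REGION_NAMES = ("frontal", "parietal", "sensorimotor")


@dataclass
class VoxelVolume:
    """A 3-D grid of non-negative integer intensities.

    Values are indexed ``values[x, y, z]`` with z counted from the top face
    of the head. Every value must lie in ``[0, 2**bit_depth - 1]``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    bit_depth: int = DEFAULT_BIT_DEPTH

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ConfigError(f"volume values must be 3-D, got {self.values.ndim}-D")
        if min(self.values.shape) < 1:
            raise ConfigError(f"volume dims must all be >= 1, got {self.values.shape}")
        if self.bit_depth < 1:
            raise ConfigError(f"bit_depth must be positive, got {self.bit_depth}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigError(f"spacing must be positive, got {self.spacing_mm}")
        if self.values.size and (
            self.values.min() < 0 or self.values.max() > self.max_value
        ):
            raise RangeError(
                f"values outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Maximum allowable intensity, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1


@dataclass
class SliceGrid:
    """A 2-D lateral slice (or projection image) with a sonification mask.

    ``mask`` marks the pixels that participate in regional averaging; it
    starts all-true and is narrowed by intensity thresholding.
    """

    values: np.ndarray
    bit_depth: int = DEFAULT_BIT_DEPTH
    slice_index: int = SLICE_NA
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ConfigError(f"slice values must be 2-D, got {self.values.ndim}-D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ConfigError("mask shape does not match values shape")
        if self.values.size and (
            self.values.min() < 0 or self.values.max() > self.max_value
        ):
            raise RangeError(
                f"values outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )

    @property
    def dims(self) -> tuple[int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class BoundaryConfig:
    """Straight-line region boundaries on a slice, in pixel coordinates.

    Each region is an ordered list of (x, y) vertices interpreted as a
    closed polygon. Regions must rasterize to pairwise-disjoint pixel sets.
    """

    frontal: list[tuple[float, float]]
    parietal: list[tuple[float, float]]
    sensorimotor: list[tuple[float, float]]

    def regions(self) -> dict[str, list[tuple[float, float]]]:
        return {
            "frontal": self.frontal,
            "parietal": self.parietal,
            "sensorimotor": self.sensorimotor,
        }

    def validate(self, dims: tuple[int, int] | None = None) -> None:
        """Check point counts and, if ``dims`` is given, coordinate bounds.

        Vertices may lie on the far edge (x == nx or y == ny): the half-open
        rasterization rule means such a polygon still covers only in-bounds
        pixels.
        """
        for name, pts in self.regions().items():
            if len(pts) < 2:
                raise ConfigError(
                    f"region '{name}' needs at least 2 points, got {len(pts)}"
                )
            if dims is not None:
                nx, ny = dims
                for x, y in pts:
                    if not (0 <= x <= nx and 0 <= y <= ny):
                        raise ConfigError(
                            f"region '{name}' point ({x}, {y}) outside slice "
                            f"dims {dims}"
                        )


def _parse_number(token: str, line_no: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {line_no}: non-numeric {what} {token!r}") from None


def _parse_int(token: str, line_no: int, what: str) -> int:
    value = _parse_number(token, line_no, what)
    if value != int(value):
        raise ParseError(f"line {line_no}: {what} {token!r} is not an integer")
    return int(value)


def read_voxel_text(
    path: str | Path,
    bit_depth: int = DEFAULT_BIT_DEPTH,
    dims: tuple[int, int, int] | None = None,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
) -> VoxelVolume:
    """Read a voxel text file into a :class:`VoxelVolume`.

    Each non-empty, non-comment line holds ``x y z value`` (whitespace or
    comma delimited).  Unless ``dims`` overrides them, the volume dims are
    the tight bounding box implied by the maximum coordinates plus one
    (coordinates are 0-based).  Unlisted voxels default to 0.  A value above
    ``2**bit_depth - 1`` is a :class:`~tritone.errors.RangeError`, never
    clamped; a duplicate coordinate with a conflicting value is a
    :class:`~tritone.errors.ParseError`.
    """
    path = Path(path)
    xs: list[int] = []
    ys: list[int] = []
    zs: list[int] = []
    vals: list[int] = []
    max_value = (1 << bit_depth) - 1
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.replace(",", " ").strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"line {line_no}: expected 4 fields, got {len(fields)}"
                )
            x = _parse_int(fields[0], line_no, "x-location")
            y = _parse_int(fields[1], line_no, "y-location")
            z = _parse_int(fields[2], line_no, "z-location")
            v = _parse_int(fields[3], line_no, "value")
            if x < 0 or y < 0 or z < 0:
                raise ParseError(f"line {line_no}: negative coordinate")
            if not (0 <= v <= max_value):
                raise RangeError(
                    f"line {line_no}: value {v} outside [0, {max_value}] "
                    f"for bit depth {bit_depth}"
                )
            xs.append(x)
            ys.append(y)
            zs.append(z)
            vals.append(v)

    if dims is None:
        if not xs:
            raise ParseError(f"{path}: no voxel data lines and no dims override")
        dims = (max(xs) + 1, max(ys) + 1, max(zs) + 1)
    coords = np.array([xs, ys, zs], dtype=np.int64).T.reshape(-1, 3)
    values_arr = np.asarray(vals, dtype=np.int64)
    if coords.size and (coords >= np.asarray(dims)).any():
        raise ParseError(f"{path}: coordinates exceed declared dims {dims}")

    grid = np.zeros(dims, dtype=np.int32)
    if coords.size:
        lin = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), dims)
        order = np.argsort(lin, kind="stable")
        lin_sorted = lin[order]
        val_sorted = values_arr[order]
        dup = lin_sorted[1:] == lin_sorted[:-1]
        if dup.any():
            conflict = dup & (val_sorted[1:] != val_sorted[:-1])
            if conflict.any():
                bad = np.unravel_index(lin_sorted[1:][conflict][0], dims)
                raise ParseError(
                    f"duplicate coordinate {tuple(int(c) for c in bad)} "
                    "with conflicting values"
                )
        grid[coords[:, 0], coords[:, 1], coords[:, 2]] = values_arr
    return VoxelVolume(values=grid, spacing_mm=spacing_mm, bit_depth=bit_depth)


def write_voxel_text(volume: VoxelVolume, path: str | Path) -> None:
    """Write one ``x y z value`` line per nonzero voxel, x-major order."""
    path = Path(path)
    nonzero = np.argwhere(volume.values != 0)  # C order: x-major, then y, then z
    with open(path, "w") as fh:
        for x, y, z in nonzero:
            fh.write(f"{x} {y} {z} {volume.values[x, y, z]}\n")


def read_boundary_file(path: str | Path) -> BoundaryConfig:
    """Read the boundary coordinates text file.

    Format: a region header line (``frontal``, ``parietal`` or
    ``sensorimotor``, case-insensitive) followed by one ``x y`` pair per
    line.  All three regions must be present with at least 2 points each.
    """
    path = Path(path)
    regions: dict[str, list[tuple[float, float]]] = {}
    current: list[tuple[float, float]] | None = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.replace(",", " ").strip()
            if not line or line.startswith("#"):
                continue
            name = line.lower()
            if name in REGION_NAMES:
                if name in regions:
                    raise ParseError(f"line {line_no}: region '{name}' repeated")
                current = []
                regions[name] = current
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"line {line_no}: expected region name or 'x y' pair, "
                    f"got {raw.strip()!r}"
                )
            if current is None:
                raise ParseError(f"line {line_no}: coordinates before a region name")
            x = _parse_number(fields[0], line_no, "x coordinate")
            y = _parse_number(fields[1], line_no, "y coordinate")
            current.append((x, y))

    missing = [name for name in REGION_NAMES if name not in regions]
    if missing:
        raise ConfigError(f"boundary file missing region(s): {', '.join(missing)}")
    config = BoundaryConfig(
        frontal=regions["frontal"],
        parietal=regions["parietal"],
        sensorimotor=regions["sensorimotor"],
    )
    config.validate()
    return config


def write_boundary_file(config: BoundaryConfig, path: str | Path) -> None:
    """Write a boundary configuration in the text format read back by
    :func:`read_boundary_file`."""
    config.validate()
    with open(path, "w") as fh:
        for name, pts in config.regions().items():
            fh.write(f"{name}\n")
            for x, y in pts:
                fh.write(f"{_fmt_coord(x)} {_fmt_coord(y)}\n")


def _fmt_coord(c: float) -> str:
    return str(int(c)) if float(c) == int(c) else repr(float(c))


def read_projection_image(path: str | Path) -> SliceGrid:
    """Read an 8-bit greyscale projection image into a :class:`SliceGrid`.

    The image stands in for the screen-captured 3-D projection view, with
    extraneous elements (axes, labels, whitespace) already cropped.  A
    multi-channel image is accepted only if all channels are identical.
    The returned grid uses ``slice_index = SLICE_NA`` and is indexed
    ``values[x, y]`` like slices extracted from a volume.
    """
    from PIL import Image

    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop an opaque alpha channel
            if not (arr[:, :, 3] == arr[0, 0, 3]).all():
                raise ConfigError(f"{path}: image has a non-uniform alpha channel")
            arr = arr[:, :, :3]
        if not (arr == arr[:, :, :1]).all():
            raise ConfigError(f"{path}: multi-channel image with unequal channels")
        arr = arr[:, :, 0]
    if arr.dtype != np.uint8:
        raise ConfigError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    # PIL arrays are (row, col) = (y, x); transpose to (x, y).
    return SliceGrid(values=arr.T.astype(np.int32), bit_depth=8, slice_index=SLICE_NA)


def read_dicom_series(paths: Sequence[str | Path]) -> VoxelVolume:
    """Convert a sorted DICOM image series to a :class:`VoxelVolume`.

    Convenience import only: slices are stacked along z in the given order
    after sorting by InstanceNumber when available.  No RTSTRUCT handling;
    boundary coordinates always come from the text file.
    """
    import pydicom

    datasets = [pydicom.dcmread(str(p)) for p in paths]
    if not datasets:
        raise ConfigError("empty DICOM series")

    def _key(ds):  # top of head first when InstanceNumber is present
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_key)
    planes = []
    for ds in datasets:
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ConfigError("only single-frame 2-D DICOM images are supported")
        planes.append(arr.T)  # (row, col) -> (x, y)
    values = np.stack(planes, axis=2).astype(np.int32)
    bit_depth = int(getattr(datasets[0], "BitsStored", DEFAULT_BIT_DEPTH))
    spacing = getattr(datasets[0], "PixelSpacing", None)
    thickness = float(getattr(datasets[0], "SliceThickness", 0) or DEFAULT_SPACING_MM[2])
    if spacing is not None:
        spacing_mm = (float(spacing[1]), float(spacing[0]), thickness)
    else:
        spacing_mm = DEFAULT_SPACING_MM
    return VoxelVolume(values=values, spacing_mm=spacing_mm, bit_depth=bit_depth)
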