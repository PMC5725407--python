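"""Synthetic, pre-normalized brain phantoms with known regional statistics.

Clinical PET volumes cannot ship with the package, so the phantom
generator builds volumes whose ground truth is known by construction: a
gray-matter ellipsoidal shell (above the 45% masking threshold) over a
white-matter core (below it), with three straight-line-bounded lobe
regions painted into the diagnostic slice.  Gray matter in the frontal
and parietal regions is reduced by configurable hypometabolism fractions,
so the pipeline's recovered relative deviations should equal those
fractions (exactly when noise-free, up to integer rounding).

The geometry is deliberately schematic — only the statistical contract
(known regional means, known mask membership) matters for validating the
sonification pipeline.  Severity presets are calibration points spanning
clearly audible beat-rate differences; they are synthetic values, not
clinical estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, ParameterError
from .io_voxels import (
    DEFAULT_BIT_DEPTH,
    DEFAULT_DIMS,
    DEFAULT_SPACING_MM,
    BoundaryConfig,
    VoxelVolume,
)
from .preprocess import DEFAULT_MASK_FRACTION, DEFAULT_SLICE_ORDINAL, rasterize_polygon

#: Per-severity (hypo_FL, hypo_PL) fractional gray-matter reductions.
#: Synthetic calibration points, monotone in severity.
PHANTOM_HYPO = {
    "normal": (0.0, 0.02),
    "mild": (0.05, 0.10),
    "moderate": (0.12, 0.20),
    "severe": (0.25, 0.35),
}

#: Region footprints as fractions of the slice dims (x0, x1, y0, y1).
_REGION_FRACTIONS = {
    "frontal": (0.26, 0.74, 0.12, 0.30),
    "sensorimotor": (0.26, 0.74, 0.36, 0.56),
    "parietal": (0.26, 0.74, 0.62, 0.84),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic volume.

    ``gm_level`` and ``wm_level`` default to 0.8 and 0.3 of the bit-depth
    maximum; ``hypo_FL``/``hypo_PL`` are the fractional reductions applied
    to gray matter in the frontal/parietal regions; ``noise_sd`` is the
    standard deviation of additive Gaussian noise in intensity units
    (rounded and truncated to the valid range).  Well-posedness requires
    white matter below and hypometabolic gray matter above the masking
    threshold.
    """

    dims: tuple[int, int, int] = DEFAULT_DIMS
    bit_depth: int = DEFAULT_BIT_DEPTH
    gm_level: float | None = None
    wm_level: float | None = None
    hypo_FL: float = 0.0
    hypo_PL: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    slice_ordinal: int = DEFAULT_SLICE_ORDINAL
    mask_fraction: float = DEFAULT_MASK_FRACTION

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def gm(self) -> float:
        return 0.8 * self.max_value if self.gm_level is None else self.gm_level

    @property
    def wm(self) -> float:
        return 0.3 * self.max_value if self.wm_level is None else self.wm_level

    def validate(self) -> None:
        if min(self.dims) < 8:
            raise ConfigError(f"phantom dims too small: {self.dims}")
        if not (1 <= self.slice_ordinal <= self.dims[2]):
            raise ConfigError(
                f"slice ordinal {self.slice_ordinal} outside 1..{self.dims[2]}"
            )
        for name, h in (("hypo_FL", self.hypo_FL), ("hypo_PL", self.hypo_PL)):
            if not (0.0 <= h < 1.0):
                raise ConfigError(f"{name} must be in [0, 1), got {h}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        threshold = self.mask_fraction * self.max_value
        worst_gm = self.gm * (1.0 - max(self.hypo_FL, self.hypo_PL))
        if not (self.wm < threshold <= worst_gm):
            raise ConfigError(
                "ill-posed phantom: need wm_level < threshold <= "
                f"gm_level*(1-max hypo); got wm={self.wm:.1f}, "
                f"threshold={threshold:.2f}, surviving gm={worst_gm:.1f}"
            )


def severity_preset(severity: str, **overrides) -> PhantomSpec:
    """Phantom spec for one severity category.

    Hypometabolism fractions come from :data:`PHANTOM_HYPO`; noise defaults
    to 1% of the maximum allowable intensity.  Keyword overrides replace
    any spec field (e.g. ``noise_sd=0`` for exact-recovery checks).
    """
    if severity not in PHANTOM_HYPO:
        raise ParameterError(
            f"unknown severity {severity!r}; expected one of {tuple(PHANTOM_HYPO)}"
        )
    hypo_fl, hypo_pl = PHANTOM_HYPO[severity]
    spec = PhantomSpec(hypo_FL=hypo_fl, hypo_PL=hypo_pl)
    spec = replace(spec, noise_sd=0.01 * spec.max_value)
    if overrides:
        spec = replace(spec, **overrides)
    spec.validate()
    return spec


def default_boundaries(dims: tuple[int, int] = DEFAULT_DIMS[:2]) -> BoundaryConfig:
    """Rectangular lobe boundaries used by the phantom, scaled to ``dims``.

    Corners are integer pixel coordinates; under the half-open
    rasterization rule each rectangle covers exactly
    ``(x1-x0) * (y1-y0)`` pixels and the three regions are disjoint.
    """
    nx, ny = dims
    regions = {}
    for name, (fx0, fx1, fy0, fy1) in _REGION_FRACTIONS.items():
        x0, x1 = round(fx0 * nx), round(fx1 * nx)
        y0, y1 = round(fy0 * ny), round(fy1 * ny)
        regions[name] = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    return BoundaryConfig(
        frontal=regions["frontal"],
        parietal=regions["parietal"],
        sensorimotor=regions["sensorimotor"],
    )


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, BoundaryConfig]:
    """Generate a synthetic volume and its matching boundary configuration.

    Construction: background 0; an outer ellipsoid of white matter with a
    gray-matter shell; the three lobe rectangles painted at gray-matter
    level (reduced by the hypo fractions for frontal/parietal) in a thin
    slab of slices around the diagnostic slice, using the same rasterizer
    the pipeline segments with.  Seeded noise is added to brain voxels,
    then everything is rounded to integers and clipped to the valid
    range.  Deterministic for a fixed seed.
    """
    spec.validate()
    nx, ny, nz = spec.dims
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]

    def ellipsoid(scale: float) -> np.ndarray:
        ax, ay, az = scale * nx / 2.0, scale * ny / 2.0, scale * nz / 2.0
        return (
            ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        ) <= 1.0

    outer = ellipsoid(0.94)
    inner = ellipsoid(0.60)
    vol = np.zeros(spec.dims, dtype=float)
    vol[outer] = spec.gm  # gray-matter shell ...
    vol[inner] = spec.wm  # ... over a white-matter core

    boundaries = default_boundaries((nx, ny))
    z0 = spec.slice_ordinal - 1
    slab = slice(max(0, z0 - 2), min(nz, z0 + 3))
    levels = {
        "frontal": spec.gm * (1.0 - spec.hypo_FL),
        "parietal": spec.gm * (1.0 - spec.hypo_PL),
        "sensorimotor": spec.gm,
    }
    for name, pts in boundaries.regions().items():
        footprint = rasterize_polygon(pts, (nx, ny))
        vol[footprint, slab] = levels[name]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        brain = vol > 0
        vol[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
    values = np.clip(np.rint(vol), 0, spec.max_value).astype(np.int32)
    volume = VoxelVolume(
        values=values, spacing_mm=DEFAULT_SPACING_MM, bit_depth=spec.bit_depth
    )
    return volume, boundaries


def render_projection_png(
    volume: VoxelVolume, path: str | Path, slice_ordinal: int = DEFAULT_SLICE_ORDINAL
) -> np.ndarray:
    """Export the diagnostic slice as an 8-bit greyscale PNG, emulating the
    cropped screen-capture projection view.  Intensities are rescaled from
    the volume's bit depth to 8 bits.  Returns the written 8-bit (x, y)
    pixel buffer for comparison against a re-read of the file."""
    from PIL import Image

    plane = volume.values[:, :, slice_ordinal - 1].astype(float)
    pixels = np.rint(plane * 255.0 / volume.max_value).astype(np.uint8)
    Image.fromarray(pixels.T, mode="L").save(str(path))  # (x, y) -> (row, col)
    return pixels
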