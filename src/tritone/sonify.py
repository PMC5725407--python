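"""Triple-tone frequency mapping of regional metabolic activity.

The triple-tone sonification (TTS) assigns one oscillator per lobe.  The
sensorimotor cortex (SMC), typically unaffected by Alzheimer's disease,
anchors the base frequency f_default = 440 Hz.  The frontal and parietal
oscillators are detuned from it in proportion to the relative deviation of
each lobe's mean (masked) intensity from the SMC mean:

    delta  = |av_region - av_SMC| / av_SMC
    f_FL   = f_default * (1 + DF * |delta_FL|)
    f_PL   = f_default * (1 - DF * |delta_PL|)

where DF is the severity-dependent detune factor.  The frontal tone is
forced above and the parietal tone below the base frequency so that equal
frontal and parietal deviations cannot collapse into a single beating
pair.  Mixing the three tones produces amplitude beating whose rates are
exactly f_default * DF * |delta|; faster, more complex beating signals a
larger metabolic deviation, i.e. more severe disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyRegionError,
    FrequencyCollapseError,
    ParameterError,
    ReferenceError_,
)
from .io_voxels import BoundaryConfig, SliceGrid, VoxelVolume
from .preprocess import (
    DEFAULT_MASK_FRACTION,
    DEFAULT_SLICE_ORDINAL,
    MaskParams,
    Region,
    apply_mask,
    extract_slice,
    mask_threshold,
    segment_lobes,
)

DEFAULT_BASE_FREQUENCY = 440.0

#: Detune factor per severity category.
DETUNE_FACTORS = {
    "normal": 0.05,
    "mild": 0.10,
    "moderate": 0.15,
    "severe": 0.20,
}

SEVERITIES = tuple(DETUNE_FACTORS)


def severity_to_detune(severity: str) -> float:
    """Detune factor for a severity category (normal, mild, moderate, severe)."""
    try:
        return DETUNE_FACTORS[severity]
    except KeyError:
        raise ParameterError(
            f"unknown severity {severity!r}; expected one of {SEVERITIES}"
        ) from None


@dataclass(frozen=True)
class RegionStats:
    """Per-lobe masked mean intensities and surviving-pixel counts."""

    av_FL: float
    av_PL: float
    av_SMC: float
    n_FL: int
    n_PL: int
    n_SMC: int


@dataclass(frozen=True)
class TTSParams:
    """Triple-tone mapping parameters.

    Exactly one of ``severity`` (table lookup) or ``detune_factor``
    (explicit DF, for data-driven experimentation) selects DF.
    ``parietal_positive`` is a compatibility switch that applies the
    parietal detuning upward like the frontal one, defeating the
    anti-collapse sign rule; it exists only for comparison and is off by
    default.
    """

    f_default: float = DEFAULT_BASE_FREQUENCY
    detune_factor: float | None = None
    severity: str | None = None
    parietal_positive: bool = False

    def __post_init__(self) -> None:
        if self.f_default <= 0:
            raise ParameterError(f"f_default must be positive, got {self.f_default}")
        if (self.detune_factor is None) == (self.severity is None):
            raise ParameterError(
                "exactly one of severity or detune_factor must be given"
            )
        if self.detune_factor is not None and self.detune_factor <= 0:
            raise ParameterError(
                f"detune factor must be positive, got {self.detune_factor}"
            )
        if self.severity is not None:
            severity_to_detune(self.severity)  # validate the label

    def resolve_detune(self) -> float:
        if self.detune_factor is not None:
            return self.detune_factor
        return severity_to_detune(self.severity)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ToneSet:
    """The three oscillator frequencies and the deviations behind them."""

    f_SMC: float
    f_FL: float
    f_PL: float
    delta_FL: float
    delta_PL: float

    @property
    def frequencies(self) -> tuple[float, float, float]:
        return (self.f_SMC, self.f_FL, self.f_PL)

    @property
    def beat_rate_FL(self) -> float:
        """Beating rate of the frontal tone against the base tone, Hz."""
        return abs(self.f_FL - self.f_SMC)

    @property
    def beat_rate_PL(self) -> float:
        """Beating rate of the parietal tone against the base tone, Hz."""
        return abs(self.f_SMC - self.f_PL)


def region_average(
    slice_grid: SliceGrid, labels: np.ndarray, region: Region
) -> tuple[float, int]:
    """Mean intensity and pixel count over unmasked pixels of one region."""
    if labels.shape != slice_grid.dims:
        raise ParameterError(
            f"label map shape {labels.shape} != slice dims {slice_grid.dims}"
        )
    sel = (labels == int(region)) & slice_grid.mask
    count = int(sel.sum())
    if count == 0:
        raise EmptyRegionError(
            f"region {Region(region).name} has no surviving pixels; "
            "mean intensity is undefined"
        )
    return float(slice_grid.values[sel].mean()), count


def compute_region_stats(slice_grid: SliceGrid, labels: np.ndarray) -> RegionStats:
    """Masked means and counts for the three lobes."""
    av_fl, n_fl = region_average(slice_grid, labels, Region.FRONTAL)
    av_pl, n_pl = region_average(slice_grid, labels, Region.PARIETAL)
    av_smc, n_smc = region_average(slice_grid, labels, Region.SENSORIMOTOR)
    return RegionStats(
        av_FL=av_fl, av_PL=av_pl, av_SMC=av_smc, n_FL=n_fl, n_PL=n_pl, n_SMC=n_smc
    )


def relative_deviation(av_region: float, av_SMC: float) -> float:
    """Dimensionless deviation ``|av_region - av_SMC| / av_SMC``."""
    if av_SMC <= 0:
        raise ReferenceError_(
            f"sensorimotor reference mean must be positive, got {av_SMC}"
        )
    return abs(av_region - av_SMC) / av_SMC


def tts_frequencies(stats: RegionStats, params: TTSParams) -> ToneSet:
    """Map regional statistics to the three oscillator frequencies.

    The base tone sits at ``f_default``; the frontal tone is detuned up by
    ``DF * |delta_FL|`` and the parietal tone down by ``DF * |delta_PL|``
    (up as well when ``parietal_positive`` is set).  Scale-invariant in the
    intensities: rescaling all three means leaves the tones unchanged.
    """
    df = params.resolve_detune()
    delta_fl = relative_deviation(stats.av_FL, stats.av_SMC)
    delta_pl = relative_deviation(stats.av_PL, stats.av_SMC)
    f_fl = params.f_default * (1.0 + df * delta_fl)
    if params.parietal_positive:
        f_pl = params.f_default * (1.0 + df * delta_pl)
    else:
        if df * delta_pl >= 1.0:
            raise FrequencyCollapseError(
                f"DF * |delta_PL| = {df * delta_pl:.3f} >= 1 would make the "
                "parietal frequency non-positive"
            )
        f_pl = params.f_default * (1.0 - df * delta_pl)
    return ToneSet(
        f_SMC=params.f_default,
        f_FL=f_fl,
        f_PL=f_pl,
        delta_FL=delta_fl,
        delta_PL=delta_pl,
    )


def sonification_report(
    stats: RegionStats, tones: ToneSet, params: TTSParams, **extra
) -> dict:
    """Machine-readable summary of one sonification run (JSON-serializable)."""
    report = {
        "av_FL": stats.av_FL,
        "av_PL": stats.av_PL,
        "av_SMC": stats.av_SMC,
        "n_FL": stats.n_FL,
        "n_PL": stats.n_PL,
        "n_SMC": stats.n_SMC,
        "delta_FL": tones.delta_FL,
        "delta_PL": tones.delta_PL,
        "detune_factor": params.resolve_detune(),
        "severity": params.severity,
        "f_default_hz": params.f_default,
        "f_SMC_hz": tones.f_SMC,
        "f_FL_hz": tones.f_FL,
        "f_PL_hz": tones.f_PL,
        "beat_rate_FL_hz": tones.beat_rate_FL,
        "beat_rate_PL_hz": tones.beat_rate_PL,
    }
    report.update(extra)
    return report


def sonify_slice(
    slice_grid: SliceGrid,
    boundaries: BoundaryConfig,
    params: TTSParams,
    mask_fraction: float = DEFAULT_MASK_FRACTION,
) -> tuple[RegionStats, ToneSet, dict]:
    """Threshold, segment and tone-map one slice; returns stats, tones and
    the sonification report."""
    threshold = mask_threshold(
        MaskParams(fraction=mask_fraction, bit_depth=slice_grid.bit_depth)
    )
    masked = apply_mask(slice_grid, threshold)
    labels = segment_lobes(masked, boundaries)
    stats = compute_region_stats(masked, labels)
    tones = tts_frequencies(stats, params)
    report = sonification_report(
        stats,
        tones,
        params,
        mask_fraction=mask_fraction,
        mask_threshold=threshold,
        bit_depth=slice_grid.bit_depth,
        slice_index=slice_grid.slice_index,
        masked_fraction=float(1.0 - masked.mask.mean()),
    )
    return stats, tones, report


def sonify_volume(
    volume: VoxelVolume,
    boundaries: BoundaryConfig,
    params: TTSParams,
    slice_ordinal: int = DEFAULT_SLICE_ORDINAL,
    mask_fraction: float = DEFAULT_MASK_FRACTION,
) -> tuple[RegionStats, ToneSet, dict]:
    """Full analysis of one volume: extract the diagnostic slice (30th from
    the top by default) and run :func:`sonify_slice` on it."""
    slice_grid = extract_slice(volume, slice_ordinal)
    stats, tones, report = sonify_slice(
        slice_grid, boundaries, params, mask_fraction=mask_fraction
    )
    report["slice_ordinal_from_top"] = slice_ordinal
    return stats, tones, report
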