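# Methods

## Pipeline model and assumptions

`tritone` assumes its input volume is already spatially normalized to a
standard brain layout — nominally 86 × 100 × 86 voxels at 2 mm isotropic
spacing with 15-bit intensities — so that one fixed lateral slice cuts
through representative frontal, parietal and sensorimotor tissue in every
subject. Normalization itself (vendor-software warping) is out of scope;
the package consumes the line-oriented voxel text export (`x y z value`
per line) and a separate boundary-coordinates text file. Boundary
coordinates are taken as given: automatic lobe segmentation is not
attempted, and the contours are interpreted as straight-line polygons in
slice pixel coordinates.

The diagnostic slice defaults to the 30th plane counted ordinally from
the top face (internal index 29), i.e. the 58–60 mm depth window at 2 mm
spacing. Indices and coordinates are 0-based internally; only the CLI's
`--slice` flag speaks the ordinal convention.

## Masking

Gray matter carries the diagnostically relevant metabolic signal; white
matter and background are excluded by intensity. The threshold is a
fraction (default 0.45) of the maximum allowable intensity
`2^bit_depth − 1`, kept unrounded: 14,745.15 at 15 bits, 114.75 at
8 bits. "Fell below" is read literally: a pixel is masked iff
`value < threshold`, so exact equality survives. With the non-integer
threshold on 15-bit integer data equality is unreachable and the choice
is inert there, but it must be fixed for settings where the threshold
lands on an integer (e.g. fraction 0.2 at 8 bits gives 51, which integer
data can tie). Masking is applied before regional averaging, and
projection images are thresholded with the same fraction at their own
bit depth (8), which keeps the deviation ratios comparable because the
tone mapping is scale-invariant.

## Lobe rasterization

Region polygons are rasterized with an even-odd crossing test on integer
pixel centers using a half-open convention: an edge counts when it
crosses strictly above the pixel's y, and the pixel must lie strictly
left of the crossing. Consequently a pixel center exactly on a shared
boundary belongs to the region whose interior lies on its
higher-coordinate side — adjacent regions tile without gaps or double
claims, and an axis-aligned rectangle with corners (x0, y0), (x1, y1)
covers exactly (x1−x0)·(y1−y0) pixels. Any overlap between the three
regions after rasterization is an error reporting the number of
double-claimed pixels. Pixels in no region are labelled OUTSIDE and never
sonified. The test suite checks this rasterizer against an independent
winding-number implementation (matplotlib's `Path.contains_points`) on
randomly placed triangles.

## Tone mapping

Each lobe's masked mean intensity is compared to the sensorimotor mean
through the relative deviation `Δ = |av_region − av_SMC| / av_SMC`
(dimensionless, absolute value). The sensorimotor oscillator sits at
`f_default` (440 Hz); the frontal oscillator is detuned up and the
parietal down by `DF·|Δ|` of the base frequency, where the detune factor
DF comes from the severity table {normal 0.05, mild 0.10, moderate 0.15,
severe 0.20} or is given explicitly. The opposed signs keep equal frontal
and parietal deviations from collapsing into a single beating pair; a
compatibility flag (`parietal_positive`) exposes the variant that detunes
both lobes upward, but it defeats the anti-collapse property and is off
by default. Selecting DF by severity label reproduces the
ground-truth-driven usage of the original workflow; the explicit-DF path
exists for data-driven experimentation. `DF·|Δ_PL| ≥ 1` would drive the
parietal frequency non-positive and raises an error rather than clamping.

Beat rates follow in closed form: mixing tones at f and f+δ modulates the
envelope at exactly δ Hz, so the render beats at `f_default·DF·|Δ_FL|`
and `f_default·DF·|Δ_PL|` against the base tone (and at their sum between
the outer tones).

## Synthesis

Each tone drives an ideal (naive) triangle oscillator
`tri(x) = (2/π)·arcsin(sin(x))`, zero-valued and rising at t = 0 with
zero phase. The waveform is deliberately not band-limited: its harmonics
fall off as 1/k², so at fundamentals of a few hundred Hz rendered at
44.1 kHz the aliased energy is negligible, and the closed form makes the
waveform exactly testable. The three oscillators mix at equal amplitude
(1/3 each, zero initial phase — phase only shifts beating in time, never
removes it) and the mix is peak-normalized to at most full scale. Output
is offline 16-bit PCM mono WAV (samples scaled by 32767 and rounded
half-away-from-zero), 30 s at 44.1 kHz by default, replacing the original
live-synthesis playback path. Deterministic: fixed tones, duration and
rate give bit-identical buffers and files.

Analysis utilities exist mainly so tests can close the loop on the audio
itself: Hann-windowed FFT peak picking (accurate to one bin), a
Hilbert-transform amplitude envelope whose spectrum exposes the beat
rates, and a modulation-depth measure (smoothed-envelope
(max−min)/(max+min), edges trimmed). A steady three-equal-tone render
measures below 1% modulation depth; a severe-case render exceeds 50%.

## Synthetic phantom

The phantom generator emulates only the statistical contract of a
normalized PET volume: a gray-matter ellipsoidal shell (0.8 of the
intensity maximum) over a white-matter core (0.3 of the maximum, safely
below the 45% threshold), with the three lobe rectangles painted into a
5-slice slab around the diagnostic slice using the same rasterizer the
pipeline segments with. Frontal and parietal gray matter is reduced by
the hypometabolism fractions `hypo_FL`, `hypo_PL`; seeded Gaussian noise
(rounded to integers, truncated to the valid range) is added to brain
voxels only. Well-posedness — white matter below the threshold, the most
hypometabolic gray matter still above it — is validated before
generation. Because the painted levels are integer-rounded, a noise-free
phantom recovers its generative fractions to within about `1/gm_level`
(≈4·10⁻⁵ relative at 15 bits), and that bound is what the exact-recovery
tests assert.

Severity presets — hypo (FL, PL) = normal (0, 0.02), mild (0.05, 0.10),
moderate (0.12, 0.20), severe (0.25, 0.35), noise 1% of the maximum — are
synthetic calibration points chosen to span clearly audible beat-rate
differences at the tabulated detune factors (1.8 to 30.8 Hz at DF 0.20);
they are not clinical estimates. What the phantom does **not** model:
anatomy, partial-volume effects, scanner point-spread, inter-subject
variability in the reference region, or any correlation structure in the
noise. Passing the recovery tests therefore shows the pipeline computes
its defined statistics correctly, not that the method separates clinical
severity grades on real scans — that question was answered by listener
studies outside the scope of this package.

## Numerical choices and degenerate inputs

- Thresholds are never rounded; comparisons use the exact float.
- Region means are plain arithmetic means in float64 over surviving
  pixels; an empty region (everything masked) is an error naming the
  region rather than a NaN.
- The voxel text reader accepts whitespace and comma delimiters, requires
  integer coordinates/values, rejects out-of-range values (no clamping)
  and conflicting duplicate coordinates, and is order-independent.
- Acceptance-style checks run on full-size (86 × 100 × 86) phantoms;
  generation is vectorized and takes ~30 ms each, so the 20-replicate
  monotonicity suite uses full-size volumes throughout. Spectral and
  envelope checks render 10 s of audio (0.1 Hz FFT resolution — an order
  of magnitude finer than the 5% beat-rate tolerance requires).

## Known limitations

- The detune factor is an input (severity label or number), not estimated
  from the data; mapping DF to a data feature is future work.
- The boundary-file syntax is this package's own plumbing; the original
  workflow's file format is undocumented.
- Naive triangle synthesis would alias audibly for base frequencies far
  above the default 440 Hz.
- The DICOM reader is a convenience importer for plain image series; it
  performs no normalization and no RTSTRUCT contour extraction.
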