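# tritone

Triple-tone sonification of PET-derived brain volumes: regional
hypometabolism rendered as audible frequency beating.

Alzheimer's disease shows up on FDG-PET as reduced metabolic activity
(hypometabolism) in the parietal — and, in severe cases, frontal — lobes,
while the sensorimotor cortex (SMC) is typically spared. Visual severity
grading of these scans is subject to intra-reader variability, which has
motivated auditory displays as a supportive channel. `tritone` implements
such a display: it turns one diagnostic slice of a spatially normalized
PET volume into a 30-second, three-oscillator audio rendering whose
beating pattern encodes how far frontal and parietal metabolic activity
deviates from the sensorimotor reference. It is written for researchers in
auditory display and quantitative neuroimaging who want a reproducible,
scriptable reference implementation of the method, complete with a
synthetic phantom generator for validation without any clinical data.

## The method

For the selected lateral slice (the 30th from the top by default, 58–60 mm
deep at 2 mm spacing), voxels below 45% of the maximum allowable intensity
(14,745.15 for 15-bit data) are masked out as white matter/background.
Straight-line boundaries segment the remainder into frontal lobe (FL),
parietal lobe (PL) and sensorimotor cortex (SMC), and the masked mean
intensity of each region is computed. The SMC anchors a triangular-wave
oscillator at f_default = 440 Hz; the other two lobes are detuned from it
by their relative deviation

&nbsp;&nbsp;&nbsp;&nbsp;Δ = |av_region − av_SMC| / av_SMC

scaled by a severity-dependent detune factor DF:

&nbsp;&nbsp;&nbsp;&nbsp;f_FL = f_default · (1 + DF·|Δ_FL|)
&nbsp;&nbsp;&nbsp;&nbsp;f_PL = f_default · (1 − DF·|Δ_PL|)

with DF ∈ {normal: 0.05, mild: 0.10, moderate: 0.15, severe: 0.20}. The
frontal tone is forced above and the parietal tone below the base
frequency so equal deviations cannot collapse into a single beating pair.
Mixing the three triangle waves produces amplitude beating at exactly
f_default·DF·|Δ| Hz per lobe: the larger the metabolic deviation, the
faster and more complex the beating.

## Worked example

Generate a synthetic "severe" phantom (frontal gray matter reduced 25%,
parietal 35%, 1% additive noise) and sonify it:

```sh
tritone phantom --severity severe --seed 11 \
    --out-volume severe_vol.txt --out-boundaries severe_bnd.txt
tritone sonify --volume severe_vol.txt --boundaries severe_bnd.txt \
    --severity severe --wav severe.wav
```

The second command writes `severe.wav` (30 s, 44.1 kHz mono) and prints
the sonification report:

```json
{
  "av_FL": 19663.0291005291,
  "av_PL": 17040.655844155845,
  "av_SMC": 26218.614285714284,
  "beat_rate_FL_hz": 22.003126862834506,
  "beat_rate_PL_hz": 30.804844758603906,
  "delta_FL": 0.25003553253221017,
  "delta_PL": 0.35005505407504417,
  "detune_factor": 0.2,
  "f_FL_hz": 462.0031268628345,
  "f_PL_hz": 409.1951552413961,
  "f_SMC_hz": 440.0,
  "mask_threshold": 14745.15,
  "n_FL": 756, "n_PL": 924, "n_SMC": 840,
  "slice_ordinal_from_top": 30
}
```

Reading the numbers: the pipeline recovered the phantom's generative
deviations (Δ_FL ≈ 0.25, Δ_PL ≈ 0.35) from the masked regional means, and
at DF = 0.20 mapped them to 462.0 Hz (frontal, above the base) and
409.2 Hz (parietal, below it). The rendered mix therefore beats at about
22 Hz and 30.8 Hz against the 440 Hz reference — the rapid, rough texture
that signals a severe case. A healthy phantom (`--hypo-fl 0 --hypo-pl 0
--noise-sd 0`) reports all three frequencies at exactly 440 Hz: a steady
tone with no beating.

`tritone analyze` prints the same report without rendering audio, and
also accepts an 8-bit greyscale projection image via `--image`.

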