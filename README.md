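# microcirc

Image analysis for two-photon and wide-field recordings of the blood
microcirculation visualized with fluorescent plasma tracers — the
setting where blood plasma is bright, unlabeled red blood cells (RBCs)
cast dark shadows, and the questions are *how fast is the blood
moving*, *how much does a vessel dilate on sensory stimulation*, and
*how good is the tracer*.

The package provides, as an importable library with a thin CLI:

* **Velocimetry** — capillary RBC speed from two points on the same
  capillary via the z-scored, unbiased cross-correlogram
  `C(τ) = 1/(N−|τ|)·Σ_t z1(t)·z2(t+τ)`, with sub-frame peak
  interpolation; plus kymograph (space × time) extraction.
* **Vessel dynamics** — per-frame vessel diameter as the full width at
  half maximum (FWHM) of a line-intensity profile; baseline
  normalization to the 2-s pre-stimulus window; per-stimulus peak
  percent dilation and time-to-peak (functional hyperemia).
* **Segmentation** — global Otsu thresholding of whole image stacks
  for vascular areas; adaptive local-mean thresholding for cells;
  masked means; eroded-complement parenchymal masks.
* **Tracer metrics** — photostability decay curves normalized to a
  reference time point; SNR `(vessel − parenchyma)/parenchyma`;
  Shannon entropy of the probability-normalized image; the
  extracellular/cytosolic secretion ratio of cell cultures.
* **Synthetic data** — seeded generators for every acquisition
  geometry above (fast capillary movies, stimulus-locked dilation
  movies, two-channel decay series, branching macroscope fields, cell
  fields), each emitting ground truth beside the data, so the whole
  pipeline is testable without raw recordings.

## Worked example

Simulate a 10-s, 200 Hz capture of a single 5 μm capillary with 30%
hematocrit and a ground-truth speed of 1.1 mm/s, then re-measure the
speed from two points 20 μm apart
(`python examples/velocimetry_example.py`):

```
ground-truth speed : 1.100 mm/s
estimated speed    : 1.053 mm/s (p1->p2)
peak lag           : +3.80 frames over 20 um
peak correlation   : 0.625
```

The correlogram peaks at +3.80 frames: RBC shadows need ≈ 19 ms to
travel the 20 μm between the points, giving 1.05 mm/s — within 5% of
the configured truth — and the positive lag identifies the flow
direction (p1 → p2). The peak correlation of 0.63 sits far above the
≈ 0.02 noise floor of a 2000-frame correlogram, marking a reliable
measurement.

Functional hyperemia under the awake whisker air-puff protocol (two
5-s stimuli at 30 s and 65 s; configured dilations 15% and 12%;
`python examples/hyperemia_example.py`):

```
baseline diameter  : 20.01 um (truth 20.00 um)
stimulus at   30 s : peak dilation 15.13% (configured 15%), time to peak 1.75 s
stimulus at   65 s : peak dilation 12.08% (configured 12%), time to peak 1.40 s
```

The other examples (`photostability_example.py`,
`image_quality_example.py`, `secretion_example.py`) cover decay
curves, SNR/entropy ranking of wide-field probes, and cell-culture
secretion ratios the same way: build a small synthetic input, run the
measurement, print what it means.

The same stages run from the shell:

```sh
microcirc simulate --config sim.yaml --outdir out --seed 1
microcirc velocity out/kymograph.tif --p1 30 9 --p2 70 9 \
    --frame-interval 0.005 --pixel-size 0.5 --outdir out
microcirc diameter out/hyperemia.tif --p0 30 0 --p1 30 119 \
    --onset 30 --onset 65 --frame-interval 0.05 --pixel-size 0.5 --outdir out
```

Each stage writes CSV tables with units in the column names and a
provenance header (package version, config hash, seed); identical
config and seed reproduce identical numbers.

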