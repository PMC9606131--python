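# Methods

`microcirc` implements the image-analysis computations used to
characterize the cerebral microcirculation from two-photon and
wide-field fluorescence recordings of plasma-labeled blood vessels:
capillary red-blood-cell (RBC) velocimetry, vessel-diameter and
functional-hyperemia quantification, tracer photostability curves,
vascular/cellular segmentation, and wide-field image-quality metrics.
A seeded synthetic-data generator reproduces the statistical structure
each stage assumes, with machine-readable ground truth, so every
estimator is validated end-to-end without raw imaging data.

Units are fixed throughout: seconds for time, micrometers for lengths,
mm/s for speeds, arbitrary units (a.u.) for intensities. Pixel
coordinates are 0-based `(x, y)`.

## Two-point cross-correlogram velocimetry

In a plasma-labeled capillary, unlabeled RBCs appear as dark shadows
moving through bright plasma. Intensity time courses are sampled at two
points along the capillary axis (per-frame mean over a disc, default
radius 1 px for noise robustness), z-scored with the *population* SD
(so the zero-lag autocorrelation of identical traces is exactly 1), and
cross-correlated with the unbiased normalization

    C(τ) = 1/(N−|τ|) · Σ_t z1(t) z2(t+τ),   τ ∈ [−max_lag, +max_lag]

which removes the triangular bias of the raw estimator. Positive τ
means the second point lags the first (flow p1 → p2). The transit lag
τ\* is refined to sub-frame resolution by 3-point parabolic
interpolation around the integer argmax (ties break toward smaller
|τ|), and speed = separation / (|τ\*| · Δt). Default `max_lag` is N/4;
a peak on the correlogram boundary or at τ\* = 0 is an error, not a
number.

**Accuracy and its limits.** The correlogram near its peak is the trace
autocorrelation shifted by the true transit lag. The autocorrelation's
main-lobe half-width is the shadow transit time over one point,
`rbc_length / v`, in frame units. Two regimes follow:

* transit time ≳ 1 frame interval (e.g. 1.1 mm/s, 6 μm shadows,
  200 Hz ⇒ 1.09 frames): the three points around the argmax sample the
  lobe's flanks and the parabola resolves the fractional lag. Because
  the lobe is triangular rather than parabolic, a small systematic bias
  remains (≈ −4 to −5% under these conditions).
* transit time ≪ 1 frame interval (e.g. 5.2 mm/s ⇒ 0.23 frames): the
  peak occupies a single integer lag, its neighbors carry only ringing
  and noise, and **no** 3-point interpolation can recover the
  fractional part — estimates quantize toward `Δx/(k·Δt)` for integer
  k. Over 24 seeded conditions spanning 0.5–8 mm/s at 200 Hz the median
  |relative error| stays below 5%, but individual high-speed captures
  near this resolution limit can be off by tens of percent. In
  practice: increase the frame rate, enlarge the point separation (the
  relative error of a fixed fractional-lag error shrinks with the lag),
  or treat speeds implying sub-frame transit with suspicion.

Traces are not detrended before z-scoring; the stationary simulator
needs none, and on real data any slow drift common to both points
inflates the peak rather than shifting it.

## Vessel diameter and functional hyperemia

The diameter of a vessel crossed by a (manually chosen) line is the
full width at half maximum (FWHM) of the bilinear line-intensity
profile: from the profile's global maximum — not the line midpoint, so
off-center lines still work — walk left and right to the first samples
below `min + 0.5·(max − min)` and place each edge by linear
interpolation between the bracketing samples. FWHM is scale-invariant
(any affine intensity rescaling leaves it unchanged) and, for edges
blurred by a symmetric PSF, unbiased for the underlying width.
A flat profile, a maximum at a profile endpoint, or a missing crossing
raises "no vessel edges found"; in a time series such frames are stored
as NaN, never interpolated, and more than 50% failures marks the line
as not intersecting a vessel.

Functional hyperemia is read from the baseline-normalized trace
`N(t) = D(t) / mean(D over [onset₁ − 2 s, onset₁))` (2-s pre-stimulus
window per the standard protocol, configurable; failed frames excluded
from the mean, with ≥ 50% of baseline frames required). Per stimulus,
the peak percent change `100·(max N − 1)` and the time-to-peak are
measured in a window from onset to 10 s past stimulus end (windows
reaching past the movie end are truncated with a warning). All stimuli
are normalized to the *first* onset's baseline, matching a protocol in
which the session starts with a dedicated baseline period; per-stimulus
baselines can be obtained by calling the normalizer per epoch.

Because the peak is a maximum over a few hundred noisy frames, noise in
the per-frame diameter biases it upward by roughly
`σ_N · sqrt(2 ln n_frames)`; with per-frame diameter jitter below ~0.5%
of baseline (the regime the generator's defaults emulate, see below)
this bias stays within the 1-percentage-point accuracy the recovery
tests assert, across amplitudes from 2% to 40%.

## Segmentation

* **Otsu (vascular areas).** One global threshold per acquisition,
  maximizing between-class variance over a 256-bin histogram spanning
  `[min, max]` of *all* voxels of the stack (the whole 3-D stack, not
  per frame; per-frame thresholds are an option). Voxels strictly above
  the threshold are vascular; ties at the threshold go to background.
  Implementation: `skimage.filters.threshold_otsu`; the test suite
  re-derives the threshold by exhaustive search in exact rational
  arithmetic, because the float variance curve has near-ties (and, with
  empty bins between modes, exactly tied maximizers) that make bin
  identity ill-defined while the segmentation itself is unique.
* **Adaptive (cellular areas).** Foreground iff
  `pixel > local_mean · (1 + k)` with `k = 0.5·(0.5 − sensitivity)`,
  where the local mean is Gaussian-weighted over an odd window with
  reflective borders (σ = radius/3, kernel truncated at the window
  edge). Masks grow monotonically with sensitivity. Dark objects use
  the mirrored rule `pixel < local_mean · (1 − k)` rather than image
  inversion, which would map a bright background to ≈ 0 where a
  multiplicative margin is meaningless. At sensitivity 0.5 the margin
  is zero and half of a flat noisy background exceeds its own local
  mean — use ≲ 0.25 on fields with large uniform regions.
* **Parenchyma (background for SNR).** Complement of the vascular mask
  eroded by a 2-px disk, keeping boundary bleed out of the background
  estimate; the image border does not erode.

## Tracer-quality metrics

* **Photostability.** Per channel and time point, the mean intensity
  over the vascular mask, divided by the reference time point (default
  the first). Normalized curves are invariant to per-channel gain. A
  dye with half-life `T½` follows `2^(−(t−t₀)/T½)`.
* **SNR.** `(mean_vessel − mean_parenchyma) / mean_parenchyma`;
  invariant to multiplicative rescaling, deliberately *not* to additive
  offsets.
* **Shannon entropy.** The image is converted to a probability matrix
  `p_ij = I_ij / Σ I` and `H = −Σ p_ij log2 p_ij` (with `0·log 0 := 0`),
  in bits — computed on raw intensity probabilities, not on a gray-level
  histogram; the two differ. H is maximal, `log2(#pixels)`, for a flat
  image and decreases as intensity concentrates in sparse vessels, so
  for vascular images *lower* entropy means better contrast. The base
  only fixes the unit; comparisons between probes are base-independent.
* **Secretion ratio.** Mean intensity outside the cell mask over the
  mean inside; > 1 indicates a secreted construct. Group statistics
  across animals/wells are exported as tables for standard statistical
  tools rather than reimplemented.

## Synthetic data generator

Each generator draws all randomness from `numpy.random.default_rng(seed)`
(fixed seed ⇒ bitwise-identical output), adds Gaussian noise clipped at
zero (detectors report nonnegative counts), and emits a
`SimulationTruth` (scalars in YAML, masks/arrays as sidecar TIFFs) that
round-trips losslessly.

* **Kymograph movies** — a straight horizontal capillary; dark shadows
  of length `rbc_length` translate at `rbc_speed`. Shadow start
  positions form a stationary stream with exponential (Poisson) gaps of
  mean `rbc_length·(1−h)/h`, which makes the expected dark fraction
  equal the hematocrit `h`; the stream covers the whole span swept
  during the movie, so the signal is stationary *and aperiodic*. (A
  periodic wrap at the field edges was rejected: it makes the two-point
  traces periodic with period `L/v` — ≈ 11 frames under the default
  fast-capture conditions — duplicating the correlogram peak at every
  multiple of the period and letting noise select the wrong copy.)
  The box shadow profile is blurred along the flow axis by a 1-px
  Gaussian PSF evaluated analytically via the error function — small
  against a 4–6 μm capillary; walls are sharp in y. Defaults: 200 Hz
  (within the 116–220 Hz fast-capture range), 0.5 μm/px, 60 μm field,
  5 μm bore, plasma 100 / shadow 20 a.u.
* **Hyperemia movies** — a straight vessel whose true diameter follows
  `D*(t) = D₀·(1 + Σ_k a_k·g(t − onset_k))`, `g` a rise/decay
  double-exponential (τ_rise = 1 s, τ_decay = 3 s, unit peak normalized
  analytically, so each `a_k` is the fractional peak dilation; the
  sampled truth reaches the peak to O((Δt)²)). Defaults follow the
  awake whisker air-puff protocol: 5-s stimuli at 30 s and 65 s in a
  100-s session. Vessel edges carry the 1-px Gaussian PSF so half-max
  edges are localizable to sub-pixel precision, as on real data.
  Imaging defaults (20 Hz, noise 2 a.u. ≈ 2% of the 90 a.u. vessel
  contrast) emulate the modest-noise, frame-averaged recordings that
  diameter analyses are run on in practice; per-frame diameter jitter
  is then ≈ 0.2% of baseline, keeping the max-statistic bias of the
  peak estimator within the tested 1-percentage-point band.
* **Decay movies** — per time point, a two-channel vessel field;
  channel "stable" constant, channel "decaying" scaled by
  `2^(−(t−t₀)/half_life)`. Defaults mirror an acute-dye comparison at
  10/60/120 min with a 30-min half-life.
* **Macroscope images** — a meandering trunk with three branches,
  rasterized as a centerline; the vessel mask is the set of pixels
  within a distance cutoff chosen as the `vessel_fraction` quantile of
  the distance transform, so coverage matches the request to within a
  quantile step. Two intensity levels plus noise, no PSF — so the truth
  masks reproduce the configured SNR exactly at zero noise.
* **Cell fields** — non-overlapping discs (cytosolic level) placed by
  seeded rejection sampling on a uniform extracellular background;
  infeasible packings are rejected after bounded retries.

**What the generator does not emulate** — and hence what passing tests
do not certify on real data: depth-dependent attenuation and
scattering, photon (Poisson) noise, heartbeat pulsatility and
stochastic flow fluctuations, RBC deformation and size dispersion,
vessel curvature and bifurcating networks, motion artifacts, and
intra-frame scan-time structure. In particular, real capillary traces
carry slow flux fluctuations that broaden the correlogram peak, so
real-data velocimetry near the resolution limit may behave somewhat
better than the worst-case analysis above — but the frame-rate limit
itself is physical and remains.

## Numerical choices and degenerate inputs

* Otsu: 256 bins over `[min, max]`; constant data raise "degenerate
  histogram". Strictly-above masking affects only bin-boundary voxels.
* Correlograms are computed by FFT-based correlation and agree with the
  direct double-loop sum to < 1e-9; means under masks accumulate in
  float64 even for float32 frames.
* Parabolic peak offsets are clipped to ±0.5 frames; a degenerate
  (zero-curvature) neighborhood falls back to the integer lag.
* Bilinear sampling uses `scipy.ndimage.map_coordinates(order=1)`;
  line endpoints are inclusive and must lie in bounds.
* Edge crossings are linearly interpolated between bracketing samples;
  the FWHM threshold uses the profile's own min/max, making it
  affine-invariant but sensitive to single-pixel outliers on very noisy
  profiles (average frames first in that regime).
* Baseline normalization requires the first onset at least one baseline
  length into the movie and ≥ 50% valid baseline frames.
* Simulated frames are float32 (levels carry ~1e-7 relative rounding);
  the CLI stores acquisitions as 16-bit unsigned TIFF (rounded,
  clipped), while in-memory float stacks round-trip bitwise through
  `write_stack`/`read_stack`.

## Problem sizes used in the test and acceptance runs

Velocity recovery uses 2000-frame (10 s at 200 Hz) single-capillary
movies; the speed-sweep property uses 24 such movies across 0.5–8 mm/s.
Hyperemia recovery uses 100-s sessions at 20 Hz (2000 frames) for each
of five amplitudes; decay curves use three time points of 3-frame
64×64 stacks; segmentation properties use 8×8×2 stacks (50–30 random
draws); quality metrics use 256×256 fields. These sizes put every
estimator comfortably in its asymptotic regime while keeping a full
verification run in well under a minute per module.

## Known limitations

* Sub-frame lag recovery degrades sharply once the shadow transit time
  drops below one frame interval (quantified above); the estimator
  reports a number there rather than failing, because the peak is still
  well-defined — inspect `peak_correlation` and the implied transit
  time before trusting high-speed estimates.
* The FWHM diameter assumes a single bright vessel on the line; two
  vessels closer than their blur widths merge into one crossing pair.
* Adaptive segmentation with a window smaller than the objects hollows
  them out (the local mean tracks the object); choose windows ≥ 2–3×
  the object diameter.
* The entropy metric is intensity-weighted, so saturated pixels
  dominate; it is meaningful only for images acquired under identical
  excitation and exposure, as in the macroscope comparisons it serves.
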