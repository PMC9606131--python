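"""Synthetic two-photon imaging data with machine-readable ground truth.

Every generator emulates one of the acquisition geometries the analysis
stages expect, and returns a :class:`SimulationTruth` next to the data so
downstream estimators can be validated without real recordings:

``make_kymograph_movie``
    a high-frame-rate movie of a single straight plasma-labeled capillary
    in which unlabeled red blood cells (RBCs) cast dark shadows that
    translate at a configured speed,
``make_hyperemia_movie``
    a vessel whose width follows a stimulus-locked double-exponential
    dilation time course (functional hyperemia),
``make_decay_movie``
    two-channel vessel fields at successive time points, one channel
    photostable and one decaying exponentially (tracer photostability),
``make_macroscope_image``
    a wide-field image of a branching surface vessel on parenchymal
    background (SNR / entropy benchmarks),
``make_cell_field``
    a cell-culture field with distinct cytosolic and extracellular
    fluorescence levels (secretion-ratio benchmarks).

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed gives bitwise-identical output.  Noise is additive Gaussian, clipped
at zero (detectors report nonnegative counts).
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.special import erf

from .stack import Image, ImageStack

__all__ = [
    "KymographSimConfig",
    "HyperemiaSimConfig",
    "DecaySimConfig",
    "SimulationTruth",
    "make_kymograph_movie",
    "make_hyperemia_movie",
    "make_decay_movie",
    "make_macroscope_image",
    "make_cell_field",
]

#: std. dev. of the 1-D optical blur applied to shadow/vessel edges, in pixels
PSF_SIGMA_PX = 1.0


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid parameter '{name}': {msg}")


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Ground-truth parameters and masks emitted beside every dataset.

    ``params`` holds scalar/labeled values (speed, half-life, seed, ...);
    ``arrays`` holds array-valued truth (masks, per-frame diameter).
    ``save``/``load`` round-trip losslessly: scalars via YAML, arrays via
    sidecar TIFFs referenced from the YAML.
    """

    params: dict
    arrays: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        """Write truth to ``path`` (a ``.yaml`` file); arrays go to
        ``<stem>.<name>.tif`` next to it.  Returns the YAML path."""
        import tifffile

        path = Path(path)
        doc: dict = {"params": _plainify(self.params), "arrays": {}}
        for name, arr in self.arrays.items():
            arr = np.asarray(arr)
            tif = path.with_suffix(f".{name}.tif")
            data = arr.astype(np.uint8) if arr.dtype == bool else arr
            tifffile.imwrite(tif, data)
            doc["arrays"][name] = {"file": tif.name, "dtype": str(arr.dtype)}
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SimulationTruth":
        import tifffile

        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        arrays = {}
        for name, meta in doc.get("arrays", {}).items():
            arr = tifffile.imread(path.parent / meta["file"])
            if meta["dtype"] == "bool":
                arr = arr.astype(bool)
            else:
                arr = arr.astype(meta["dtype"])
            arrays[name] = arr
        return cls(params=doc["params"], arrays=arrays)


def _plainify(obj):
    """Convert numpy scalars/arrays in a params tree to plain Python."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, numbers.Integral):
        return int(obj)
    if isinstance(obj, numbers.Real):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# capillary kymograph movies
# ---------------------------------------------------------------------------


@dataclass
class KymographSimConfig:
    """Single-capillary fast-imaging movie parameters.

    The capillary is a straight horizontal tube; dark RBC shadows of
    length ``rbc_length`` translate along +x at ``rbc_speed``.  The
    defaults describe a 200 Hz capture of a 5 μm cerebral capillary at
    0.5 μm/pixel.
    """

    n_frames: int = 2000
    frame_rate: float = 200.0          # Hz
    pixel_size: float = 0.5            # μm / pixel
    capillary_length: float = 60.0     # μm (field of view along the flow axis)
    capillary_diameter: float = 5.0    # μm
    rbc_speed: float = 1.0             # mm/s
    hematocrit: float = 0.3            # dark fraction of the capillary, [0, 1)
    rbc_length: float = 6.0            # μm
    plasma_intensity: float = 100.0    # a.u.
    rbc_intensity: float = 20.0        # a.u. (< plasma_intensity)
    noise_sd: float = 5.0              # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_frames >= 2, "n_frames", "need at least 2 frames")
        _require(self.frame_rate > 0, "frame_rate", "must be > 0 Hz")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0 μm/pixel")
        _require(self.capillary_length > 0, "capillary_length", "must be > 0 μm")
        _require(self.capillary_diameter > 0, "capillary_diameter", "must be > 0 μm")
        _require(self.rbc_speed >= 0, "rbc_speed", "must be ≥ 0 mm/s")
        _require(0 <= self.hematocrit < 1, "hematocrit", "must lie in [0, 1)")
        _require(self.rbc_length > 0, "rbc_length", "must be > 0 μm")
        _require(
            self.rbc_intensity < self.plasma_intensity,
            "rbc_intensity",
            "RBC shadows must be darker than plasma",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be ≥ 0")


def make_kymograph_movie(config: KymographSimConfig) -> tuple[ImageStack, SimulationTruth]:
    """Simulate a plasma-labeled capillary with translating RBC shadows.

    RBC placement is a stationary stream: shadow start positions are laid
    down with exponential (Poisson) gaps whose mean, ``rbc_length · (1 −
    h) / h``, makes the expected dark fraction equal the hematocrit
    ``h``.  The stream covers the whole span swept during the movie, so
    the signal at any point is stationary and aperiodic.  The box shadow
    profile is blurred along the flow axis by a Gaussian PSF of
    ``PSF_SIGMA_PX`` pixels (evaluated analytically via the error
    function); capillary walls are sharp in y.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    nx = max(4, round(c.capillary_length / c.pixel_size))
    n_rows = max(1, round(c.capillary_diameter / c.pixel_size))
    margin = 4
    ny = n_rows + 2 * margin
    dt = 1.0 / c.frame_rate
    v_um_s = c.rbc_speed * 1000.0
    duration = (c.n_frames - 1) * dt
    sigma = PSF_SIGMA_PX * c.pixel_size

    x_centers = (np.arange(nx) + 0.5) * c.pixel_size

    # RBC shadow start positions over the full swept span (stream moves +x)
    starts = np.empty(0)
    if c.hematocrit > 0:
        pad = c.rbc_length + 6 * sigma
        lo = -v_um_s * duration - pad
        hi = c.capillary_length + pad
        mean_gap = c.rbc_length * (1 - c.hematocrit) / c.hematocrit
        span = hi - lo
        n_expect = int(span / (c.rbc_length + mean_gap) * 1.5) + 16
        gaps = rng.exponential(mean_gap, size=n_expect)
        pos = lo + rng.uniform(0, c.rbc_length + mean_gap) + np.cumsum(
            np.concatenate([[0.0], (c.rbc_length + gaps)[:-1]])
        )
        while pos[-1] < hi:  # pragma: no cover - top-up for unlucky draws
            extra = rng.exponential(mean_gap, size=n_expect)
            pos = np.concatenate(
                [pos, pos[-1] + c.rbc_length + extra[0] + np.cumsum(
                    np.concatenate([[0.0], (c.rbc_length + extra[1:])]))]
            )
        starts = pos[pos < hi]

    inv = 1.0 / (np.sqrt(2.0) * sigma)
    contrast = c.plasma_intensity - c.rbc_intensity

    profiles = np.empty((c.n_frames, nx), dtype=np.float64)
    for i in range(c.n_frames):
        t = i * dt
        occ = np.zeros(nx)
        if starts.size:
            a = starts + v_um_s * t            # shadow leading edges now
            b = a + c.rbc_length
            vis = (b > x_centers[0] - 4 * sigma) & (a < x_centers[-1] + 4 * sigma)
            for aa, bb in zip(a[vis], b[vis]):
                occ += 0.5 * (erf((x_centers - aa) * inv) - erf((x_centers - bb) * inv))
        profiles[i] = c.plasma_intensity - contrast * occ

    frames = np.zeros((c.n_frames, ny, nx), dtype=np.float32)
    frames[:, margin : margin + n_rows, :] = profiles[:, None, :]
    if c.noise_sd > 0:
        frames += rng.normal(0.0, c.noise_sd, size=frames.shape).astype(np.float32)
        np.clip(frames, 0.0, None, out=frames)

    capillary_mask = np.zeros((ny, nx), dtype=bool)
    capillary_mask[margin : margin + n_rows, :] = True

    truth = SimulationTruth(
        params={
            "generator": "kymograph",
            "rbc_speed_mm_per_s": c.rbc_speed,
            "frame_rate_hz": c.frame_rate,
            "pixel_size_um": c.pixel_size,
            "hematocrit": c.hematocrit,
            "rbc_length_um": c.rbc_length,
            "capillary_rows": [margin, margin + n_rows],
            "plasma_intensity": c.plasma_intensity,
            "rbc_intensity": c.rbc_intensity,
            "noise_sd": c.noise_sd,
            "seed": c.seed,
        },
        arrays={"capillary_mask": capillary_mask},
    )
    stack = ImageStack(frames, frame_interval=dt, pixel_size=c.pixel_size,
                       channel="plasma")
    return stack, truth


# ---------------------------------------------------------------------------
# functional hyperemia movies
# ---------------------------------------------------------------------------


@dataclass
class HyperemiaSimConfig:
    """Vessel-field movie with stimulus-locked dilation.

    The true diameter follows

    ``D*(t) = baseline_diameter · (1 + Σ_k a_k · g(t − onset_k))``

    with ``g`` a rise/decay double exponential normalized to unit peak,
    so each ``a_k`` is the fractional peak dilation of stimulus ``k``.
    Defaults follow the awake whisker air-puff protocol: two 5-s stimuli
    at 30 s and 65 s in a 100-s session, imaged at 20 Hz.
    """

    n_frames: int = 2000
    frame_rate: float = 20.0                 # Hz
    pixel_size: float = 0.5                  # μm / pixel
    baseline_diameter: float = 20.0          # μm
    dilation_amplitudes: tuple = (0.15, 0.12)  # fractional peak change per stimulus
    stimulus_onsets: tuple = (30.0, 65.0)    # s
    stimulus_duration: float = 5.0           # s
    rise_tau: float = 1.0                    # s
    decay_tau: float = 3.0                   # s
    vessel_intensity: float = 100.0          # a.u.
    background_intensity: float = 10.0       # a.u.
    noise_sd: float = 2.0                    # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_frames >= 2, "n_frames", "need at least 2 frames")
        _require(self.frame_rate > 0, "frame_rate", "must be > 0 Hz")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0 μm/pixel")
        _require(self.baseline_diameter > 0, "baseline_diameter", "must be > 0 μm")
        _require(self.rise_tau > 0 and self.decay_tau > 0, "rise_tau/decay_tau",
                 "time constants must be > 0 s")
        self.dilation_amplitudes = tuple(float(a) for a in self.dilation_amplitudes)
        self.stimulus_onsets = tuple(float(o) for o in self.stimulus_onsets)
        _require(len(self.dilation_amplitudes) == len(self.stimulus_onsets),
                 "dilation_amplitudes", "need one amplitude per stimulus onset")
        _require(all(a > -1 for a in self.dilation_amplitudes),
                 "dilation_amplitudes", "amplitudes must be > −1")
        duration = (self.n_frames - 1) / self.frame_rate
        _require(all(0 <= o <= duration for o in self.stimulus_onsets),
                 "stimulus_onsets", f"onsets must lie within the movie (0–{duration:g} s)")
        _require(self.vessel_intensity > self.background_intensity,
                 "vessel_intensity", "vessel must be brighter than background")
        _require(self.noise_sd >= 0, "noise_sd", "must be ≥ 0")


def hyperemia_impulse(s: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak rise/decay double-exponential response, zero for s < 0."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    pos = s > 0
    if rise_tau == decay_tau:
        tau = rise_tau
        out[pos] = (s[pos] / tau) * np.exp(1.0 - s[pos] / tau)
        return out
    raw = np.exp(-s[pos] / decay_tau) - np.exp(-s[pos] / rise_tau)
    s_peak = np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    peak = np.exp(-s_peak / decay_tau) - np.exp(-s_peak / rise_tau)
    out[pos] = raw / peak
    return out


def hyperemia_diameter_truth(config: HyperemiaSimConfig) -> np.ndarray:
    """Per-frame ground-truth diameter D*(t) in μm."""
    c = config
    t = np.arange(c.n_frames) / c.frame_rate
    mod = np.ones(c.n_frames)
    for a, onset in zip(c.dilation_amplitudes, c.stimulus_onsets):
        mod += a * hyperemia_impulse(t - onset, c.rise_tau, c.decay_tau)
    return c.baseline_diameter * mod


def make_hyperemia_movie(config: HyperemiaSimConfig) -> tuple[ImageStack, SimulationTruth]:
    """Simulate a straight horizontal vessel whose width follows D*(t).

    Vessel edges are Gaussian-blurred (PSF ``PSF_SIGMA_PX`` px) so that
    half-maximum edge detection can localize them with sub-pixel
    precision, as it does on real data.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    d_star = hyperemia_diameter_truth(c)

    height_um = 2.5 * c.baseline_diameter * (1 + max(max(c.dilation_amplitudes, default=0.0), 0.0))
    ny = int(round(height_um / c.pixel_size))
    nx = max(16, int(round(1.5 * c.baseline_diameter / c.pixel_size)))
    sigma = PSF_SIGMA_PX * c.pixel_size
    inv = 1.0 / (np.sqrt(2.0) * sigma)

    y = (np.arange(ny) + 0.5) * c.pixel_size
    cy = ny * c.pixel_size / 2.0
    e1 = cy - d_star / 2.0   # upper edge per frame (μm)
    e2 = cy + d_star / 2.0
    inside = 0.5 * (
        erf((y[None, :] - e1[:, None]) * inv) - erf((y[None, :] - e2[:, None]) * inv)
    )
    profile = c.background_intensity + (c.vessel_intensity - c.background_intensity) * inside

    frames = np.repeat(profile[:, :, None], nx, axis=2).astype(np.float32)
    if c.noise_sd > 0:
        frames += rng.normal(0.0, c.noise_sd, size=frames.shape).astype(np.float32)
        np.clip(frames, 0.0, None, out=frames)

    truth = SimulationTruth(
        params={
            "generator": "hyperemia",
            "baseline_diameter_um": c.baseline_diameter,
            "dilation_amplitudes": list(c.dilation_amplitudes),
            "stimulus_onsets_s": list(c.stimulus_onsets),
            "stimulus_duration_s": c.stimulus_duration,
            "rise_tau_s": c.rise_tau,
            "decay_tau_s": c.decay_tau,
            "frame_rate_hz": c.frame_rate,
            "pixel_size_um": c.pixel_size,
            "vessel_center_y_um": cy,
            "noise_sd": c.noise_sd,
            "seed": c.seed,
        },
        arrays={"diameter_um": d_star},
    )
    stack = ImageStack(frames, frame_interval=1.0 / c.frame_rate,
                       pixel_size=c.pixel_size, channel="plasma")
    return stack, truth


# ---------------------------------------------------------------------------
# two-channel photostability movies
# ---------------------------------------------------------------------------


@dataclass
class DecaySimConfig:
    """Two-channel vessel fields at successive time points.

    Channel ``stable`` keeps a constant vascular intensity; channel
    ``decaying`` starts at ``decaying_channel_initial`` and halves every
    ``half_life`` minutes: ``I(t) = I₀ · 2^(−(t − t₀)/half_life)`` with
    ``t₀`` the first time point.  Defaults mirror an acute-dye
    comparison imaged at 10, 60 and 120 min.
    """

    time_points: tuple = (10.0, 60.0, 120.0)   # minutes
    stable_channel_intensity: float = 100.0    # a.u.
    decaying_channel_initial: float = 100.0    # a.u.
    half_life: float = 30.0                    # minutes
    vessel_fraction_rows: float = 0.3          # fraction of field height that is vessel
    background_intensity: float = 10.0         # a.u.
    noise_sd: float = 2.0                      # a.u.
    frames_per_stack: int = 3
    field_size: int = 64                       # pixels (square field)
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_points = tuple(float(t) for t in self.time_points)
        _require(len(self.time_points) >= 2, "time_points", "need at least 2 time points")
        _require(all(b > a for a, b in zip(self.time_points, self.time_points[1:])),
                 "time_points", "must be strictly increasing")
        _require(self.half_life > 0, "half_life", "must be > 0 minutes")
        _require(self.noise_sd >= 0, "noise_sd", "must be ≥ 0")
        _require(self.frames_per_stack >= 1, "frames_per_stack", "must be ≥ 1")
        _require(0 < self.vessel_fraction_rows < 1, "vessel_fraction_rows",
                 "must lie in (0, 1)")


def make_decay_movie(config: DecaySimConfig) -> tuple[list[dict[str, ImageStack]], SimulationTruth]:
    """Simulate per-time-point two-channel vessel stacks.

    Returns one ``{"stable": ImageStack, "decaying": ImageStack}`` mapping
    per time point, plus truth (vessel mask, half-life, expected
    normalized curve).
    """
    c = config
    rng = np.random.default_rng(c.seed)
    n = c.field_size
    band = max(1, int(round(c.vessel_fraction_rows * n)))
    y0 = (n - band) // 2
    vessel_mask = np.zeros((n, n), dtype=bool)
    vessel_mask[y0 : y0 + band, :] = True

    t0 = c.time_points[0]
    expected = [2.0 ** (-(t - t0) / c.half_life) for t in c.time_points]

    stacks: list[dict[str, ImageStack]] = []
    for t, frac in zip(c.time_points, expected):
        levels = {"stable": c.stable_channel_intensity,
                  "decaying": c.decaying_channel_initial * frac}
        entry: dict[str, ImageStack] = {}
        for name, level in levels.items():
            frames = np.full((c.frames_per_stack, n, n), c.background_intensity,
                             dtype=np.float32)
            frames[:, vessel_mask] = level
            if c.noise_sd > 0:
                frames += rng.normal(0.0, c.noise_sd, size=frames.shape).astype(np.float32)
                np.clip(frames, 0.0, None, out=frames)
            entry[name] = ImageStack(frames, frame_interval=1.0, channel=name)
        stacks.append(entry)

    truth = SimulationTruth(
        params={
            "generator": "decay",
            "time_points_min": list(c.time_points),
            "half_life_min": c.half_life,
            "stable_channel_intensity": c.stable_channel_intensity,
            "decaying_channel_initial": c.decaying_channel_initial,
            "expected_decaying_normalized": expected,
            "background_intensity": c.background_intensity,
            "noise_sd": c.noise_sd,
            "seed": c.seed,
        },
        arrays={"vessel_mask": vessel_mask},
    )
    return stacks, truth


# ---------------------------------------------------------------------------
# wide-field macroscope images
# ---------------------------------------------------------------------------


def make_macroscope_image(
    vessel_intensity: float = 200.0,
    background_intensity: float = 100.0,
    vessel_fraction: float = 0.15,
    noise_sd: float = 5.0,
    size: int = 256,
    seed: int = 0,
) -> tuple[Image, SimulationTruth]:
    """Simulate a wide-field image of branching surface vessels.

    A meandering trunk with a few branches is rasterized as a centerline;
    the vessel mask is the set of pixels nearest to the centerline, with
    the distance cutoff chosen as the ``vessel_fraction`` quantile of the
    distance transform so the mask covers ≈ ``vessel_fraction`` of the
    field.  Intensities are two-level (vessel over background) plus
    Gaussian noise; truth stores the exact mask.
    """
    _require(0 < vessel_fraction < 1, "vessel_fraction", "must lie in (0, 1)")
    _require(size >= 16, "size", "field must be at least 16 px")
    _require(noise_sd >= 0, "noise_sd", "must be ≥ 0")
    from scipy.ndimage import distance_transform_edt, gaussian_filter1d

    rng = np.random.default_rng(seed)
    centerline = np.zeros((size, size), dtype=bool)

    def draw_path(r0: float, c0: float, drdc: float, length: int) -> None:
        wander = gaussian_filter1d(rng.normal(0.0, 1.0, length), 8, mode="nearest")
        r = r0 + np.cumsum(np.full(length, drdc) + 0.6 * wander)
        cc = c0 + np.arange(length, dtype=float)
        ok = (r >= 0) & (r < size) & (cc >= 0) & (cc < size)
        centerline[r[ok].astype(int), cc[ok].astype(int)] = True

    draw_path(size * rng.uniform(0.3, 0.7), 0.0, 0.0, size)          # trunk
    for _ in range(3):                                               # branches
        start = rng.integers(size // 8, 7 * size // 8)
        rows, cols = np.nonzero(centerline)
        pick = np.argmin(np.abs(cols - start))
        draw_path(float(rows[pick]), float(cols[pick]),
                  rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.2),
                  rng.integers(size // 4, size // 2))

    dist = distance_transform_edt(~centerline)
    cutoff = np.quantile(dist, vessel_fraction)
    mask = dist <= cutoff

    pixels = np.where(mask, vessel_intensity, background_intensity).astype(np.float64)
    if noise_sd > 0:
        pixels += rng.normal(0.0, noise_sd, size=pixels.shape)
        np.clip(pixels, 0.0, None, out=pixels)

    truth = SimulationTruth(
        params={
            "generator": "macroscope",
            "vessel_intensity": vessel_intensity,
            "background_intensity": background_intensity,
            "vessel_fraction": vessel_fraction,
            "achieved_fraction": float(mask.mean()),
            "noise_sd": noise_sd,
            "seed": seed,
        },
        arrays={"vessel_mask": mask},
    )
    return Image(pixels), truth


# ---------------------------------------------------------------------------
# cell-culture fields
# ---------------------------------------------------------------------------


def make_cell_field(
    cytosolic_intensity: float = 40.0,
    extracellular_intensity: float = 80.0,
    n_cells: int = 12,
    cell_radius: int = 8,
    noise_sd: float = 1.0,
    size: int = 256,
    seed: int = 0,
) -> tuple[Image, SimulationTruth]:
    """Simulate a cell-culture field with secreted extracellular signal.

    Non-overlapping discs (cells, cytosolic level) are placed by seeded
    rejection sampling on a uniform extracellular background; infeasible
    packings are rejected after bounded retries.  Truth stores the cell
    mask.
    """
    _require(n_cells >= 0, "n_cells", "must be ≥ 0")
    _require(cell_radius >= 1, "cell_radius", "must be ≥ 1 px")
    _require(size > 2 * cell_radius, "size", "field too small for the cell radius")
    _require(noise_sd >= 0, "noise_sd", "must be ≥ 0")

    rng = np.random.default_rng(seed)
    centers: list[tuple[int, int]] = []
    max_tries = 400 * max(n_cells, 1)
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"invalid parameter 'n_cells': could not place {n_cells} "
                f"non-overlapping cells of radius {cell_radius} in a {size}px field"
            )
        r = rng.integers(cell_radius, size - cell_radius)
        c = rng.integers(cell_radius, size - cell_radius)
        if all((r - r2) ** 2 + (c - c2) ** 2 > (2 * cell_radius + 1) ** 2
               for r2, c2 in centers):
            centers.append((int(r), int(c)))

    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    for r, c in centers:
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= cell_radius**2

    pixels = np.where(mask, cytosolic_intensity, extracellular_intensity).astype(np.float64)
    if noise_sd > 0:
        pixels += rng.normal(0.0, noise_sd, size=pixels.shape)
        np.clip(pixels, 0.0, None, out=pixels)

    truth = SimulationTruth(
        params={
            "generator": "cell_field",
            "cytosolic_intensity": cytosolic_intensity,
            "extracellular_intensity": extracellular_intensity,
            "n_cells": n_cells,
            "cell_radius_px": cell_radius,
            "cell_centers": [list(c) for c in centers],
            "noise_sd": noise_sd,
            "seed": seed,
        },
        arrays={"cell_mask": mask},
    )
    return Image(pixels), truth
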