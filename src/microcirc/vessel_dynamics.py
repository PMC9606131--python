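"""Vessel diameter from line intensity profiles and functional hyperemia.

Diameter is measured as the full width at half maximum (FWHM) of the
intensity profile along a line crossing the vessel: from the profile's
global maximum, walk outward to the first crossings below
``min + 0.5·(max − min)`` and refine each crossing by linear
interpolation between the bracketing samples.  The per-frame diameter
trace is normalized to the mean diameter over a pre-stimulus baseline
window (2 s by default), and functional hyperemia is quantified per
stimulus as the peak percent change of the normalized trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .stack import Image, ImageStack

__all__ = [
    "LineProfile",
    "DiameterTrace",
    "HyperemiaResult",
    "sample_line_profile",
    "profile_diameter",
    "diameter_timeseries",
    "normalize_to_baseline",
    "hyperemia_metrics",
]


@dataclass
class LineProfile:
    """Intensity profile along a line; positions in μm starting at 0."""

    positions: np.ndarray
    intensities: np.ndarray
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    spacing: float  # requested sampling step, pixels

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if self.positions[0] != 0 or np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must start at 0 and strictly increase")


@dataclass
class DiameterTrace:
    """Per-frame vessel diameter (μm) with optional baseline normalization.

    ``diameters`` holds NaN for frames where edge detection failed;
    failed frames are never interpolated.  ``normalized`` is
    ``D(t) / baseline mean`` once :func:`normalize_to_baseline` ran.
    """

    diameters: np.ndarray          # μm, NaN where undefined
    frame_interval: float          # s
    normalized: np.ndarray | None = None
    baseline_window: tuple[float, float] | None = None   # (start, end) s
    stimulus_onsets: tuple = ()
    stimulus_duration: float | None = None               # s
    vessel_label: str | None = None

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=np.float64)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        valid = self.diameters[~np.isnan(self.diameters)]
        if valid.size and np.any(valid <= 0):
            raise ValueError("diameters must be positive where defined")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.diameters.size) * self.frame_interval


@dataclass
class HyperemiaResult:
    """Per-stimulus peak dilation and latency."""

    peak_percent_change: np.ndarray   # % relative to baseline, one per stimulus
    time_to_peak: np.ndarray          # s relative to onset
    stimulus_onsets: np.ndarray       # s
    vessel_label: str | None = None


def sample_line_profile(image: Image | np.ndarray, p0: tuple[float, float],
                        p1: tuple[float, float], spacing: float = 1.0) -> LineProfile:
    """Bilinear intensity profile along the segment p0 → p1 (inclusive).

    ``p0``/``p1`` are ``(x, y)`` pixel coordinates; samples sit at evenly
    spaced positions from p0 to p1 with a step as close to ``spacing``
    pixels as divides the segment.  Positions are reported in μm when the
    image carries a pixel size, else in pixels.
    """
    if isinstance(image, Image):
        pixels, pixel_size = image.pixels, image.pixel_size
    else:
        pixels, pixel_size = np.asarray(image), None
    (x0, y0), (x1, y1) = p0, p1
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0:
        raise ValueError("degenerate line: endpoints coincide")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ny, nx = pixels.shape
    for x, y in (p0, p1):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError(f"endpoint ({x}, {y}) outside the {nx}×{ny} image")

    n = max(2, int(round(length / spacing)) + 1)
    ts = np.linspace(0.0, length, n)
    xs = x0 + (x1 - x0) * ts / length
    ys = y0 + (y1 - y0) * ts / length
    vals = map_coordinates(pixels.astype(np.float64), np.vstack([ys, xs]), order=1)
    scale = pixel_size if pixel_size is not None else 1.0
    return LineProfile(positions=ts * scale, intensities=vals,
                       endpoints=(tuple(p0), tuple(p1)), spacing=spacing)


def profile_diameter(profile: LineProfile) -> tuple[float, tuple[float, float]]:
    """Vessel diameter as the FWHM of a line profile.

    From the global maximum (an interior sample), walk left and right to
    the first samples below ``min + 0.5 · (max − min)`` and place each
    edge by linear interpolation between the bracketing samples.

    Returns
    -------
    (diameter, (left_edge, right_edge))
        In the units of ``profile.positions``.

    Raises
    ------
    ValueError
        "no vessel edges found" for a flat profile, a maximum at an
        endpoint, or a missing crossing on either side.
    """
    v, p = profile.intensities, profile.positions
    vmax, vmin = v.max(), v.min()
    if vmax == vmin:
        raise ValueError("no vessel edges found: flat profile")
    imax = int(np.argmax(v))
    if imax == 0 or imax == v.size - 1:
        raise ValueError("no vessel edges found: maximum at profile endpoint")
    half = vmin + 0.5 * (vmax - vmin)

    def cross(i_from: int, step: int) -> float:
        i = i_from + step
        while 0 <= i < v.size:
            if v[i] < half:
                inner = i - step           # sample still ≥ half
                frac = (v[inner] - half) / (v[inner] - v[i])
                return float(p[inner] + frac * (p[i] - p[inner]))
            i += step
        raise ValueError("no vessel edges found: profile does not drop below half max")

    left = cross(imax, -1)
    right = cross(imax, +1)
    return right - left, (left, right)


def diameter_timeseries(stack: ImageStack, p0: tuple[float, float],
                        p1: tuple[float, float], spacing: float = 1.0,
                        vessel_label: str | None = None) -> DiameterTrace:
    """Per-frame FWHM diameter along a fixed line.

    Frames where edge detection fails are recorded as NaN (never
    interpolated).  If more than half of the frames fail, the line is
    deemed not to intersect a vessel and an error is raised.
    """
    diameters = np.full(stack.n_frames, np.nan)
    for i in range(stack.n_frames):
        profile = sample_line_profile(stack.frame(i), p0, p1, spacing)
        try:
            diameters[i], _ = profile_diameter(profile)
        except ValueError:
            pass
    if np.isnan(diameters).mean() > 0.5:
        raise ValueError("line does not intersect a vessel (edge detection failed on >50% of frames)")
    return DiameterTrace(diameters=diameters, frame_interval=stack.frame_interval,
                         vessel_label=vessel_label)


def normalize_to_baseline(trace: DiameterTrace, stimulus_onsets,
                          baseline_seconds: float = 2.0,
                          stimulus_duration: float = 5.0) -> DiameterTrace:
    """Normalize a diameter trace to its pre-stimulus baseline mean.

    ``N(t) = D(t) / mean(D over [onset₁ − baseline_seconds, onset₁))``.
    Failed (NaN) frames are excluded from the baseline mean; at least
    half of the baseline frames must be valid.  Normalization is
    idempotent: renormalizing an already-normalized trace with the same
    arguments returns the same result.
    """
    onsets = tuple(float(o) for o in np.atleast_1d(stimulus_onsets))
    if not onsets:
        raise ValueError("at least one stimulus onset is required")
    if baseline_seconds <= 0:
        raise ValueError("baseline_seconds must be positive")
    first = min(onsets)
    if first < baseline_seconds:
        raise ValueError(
            f"first onset at {first:g} s leaves no {baseline_seconds:g}-s baseline window"
        )
    t = trace.times
    window = (first - baseline_seconds, first)
    in_window = (t >= window[0]) & (t < window[1])
    if not in_window.any():
        raise ValueError("no frames fall inside the baseline window")
    base = trace.diameters[in_window]
    n_valid = np.sum(~np.isnan(base))
    if n_valid < 0.5 * base.size or n_valid == 0:
        raise ValueError("insufficient valid pre-stimulus frames for the baseline")
    mean_d = float(np.nanmean(base))
    return replace(trace, normalized=trace.diameters / mean_d,
                   baseline_window=window, stimulus_onsets=onsets,
                   stimulus_duration=stimulus_duration)


def hyperemia_metrics(trace: DiameterTrace, post_stimulus_window: float = 10.0) -> HyperemiaResult:
    """Peak percent dilation and time-to-peak per stimulus.

    For each onset the response is searched in
    ``[onset, onset + stimulus_duration + post_stimulus_window]``; a
    window reaching past the movie end is truncated with a warning.
    Peak percent change = ``100 · (max N − 1)``.
    """
    if trace.normalized is None or not trace.stimulus_onsets:
        raise ValueError("hyperemia_metrics needs a baseline-normalized trace with stimulus onsets")
    duration = trace.stimulus_duration if trace.stimulus_duration is not None else 5.0
    t = trace.times
    peaks, latencies = [], []
    for onset in trace.stimulus_onsets:
        end = onset + duration + post_stimulus_window
        if end > t[-1]:
            warnings.warn(
                f"response window for onset {onset:g} s truncated at movie end ({t[-1]:g} s)",
                stacklevel=2,
            )
            end = t[-1]
        sel = (t >= onset) & (t <= end)
        seg = trace.normalized[sel]
        if not np.any(~np.isnan(seg)):
            raise ValueError(f"no valid frames in the response window after onset {onset:g} s")
        k = int(np.nanargmax(seg))
        peaks.append(100.0 * (seg[k] - 1.0))
        latencies.append(float(t[sel][k] - onset))
    return HyperemiaResult(peak_percent_change=np.array(peaks),
                           time_to_peak=np.array(latencies),
                           stimulus_onsets=np.array(trace.stimulus_onsets),
                           vessel_label=trace.vessel_label)
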