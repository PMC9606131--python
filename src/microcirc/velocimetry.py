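"""Capillary RBC velocimetry from two-point cross-correlation.

The estimator follows the two-point scheme used for plasma-labeled
capillaries: intensity time courses are sampled at two locations along
the same capillary, z-scored (population SD, so the zero-lag
autocorrelation of identical traces is exactly 1), and cross-correlated
with the *unbiased* normalization

    C(τ) = (1 / (N − |τ|)) Σ_t z1(t) · z2(t + τ)

which removes the triangular bias of the raw estimator.  The transit
time between the two points is the (sub-frame, parabolically
interpolated) lag of the correlogram peak, and speed = separation /
transit time, reported in mm/s.  Positive lag means the downstream point
``p2`` lags ``p1`` (flow p1 → p2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import map_coordinates

from .stack import ImageStack

__all__ = [
    "IntensityTrace",
    "Correlogram",
    "VelocityEstimate",
    "extract_point_trace",
    "zscore_trace",
    "unbiased_crosscorrelogram",
    "estimate_velocity",
    "extract_kymograph",
]


@dataclass
class IntensityTrace:
    """Per-frame mean intensity over a small disc at one point."""

    values: np.ndarray
    frame_interval: float          # s
    point: tuple[float, float]     # (x, y) pixels
    radius: float                  # pixels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 16:
            raise ValueError("IntensityTrace needs a 1-D series of ≥ 16 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class Correlogram:
    """Cross-correlogram values over symmetric integer lags."""

    lags: np.ndarray       # frames, −L … +L
    values: np.ndarray     # dimensionless
    n_frames: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal length")
        if 0 not in self.lags:
            raise ValueError("lag 0 must be present")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlogram contains non-finite values")


@dataclass
class VelocityEstimate:
    """Result of one two-point capillary measurement."""

    speed: float             # mm/s (≥ 0)
    lag: float               # frames, signed, sub-frame resolution
    separation: float        # μm between the two points
    peak_correlation: float  # dimensionless
    direction: str           # "p1->p2" or "p2->p1"


def _disc_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dx**2 + dy**2 <= radius**2
    return dy[keep], dx[keep]


def extract_point_trace(stack: ImageStack, point: tuple[float, float],
                        radius: float = 1.0) -> IntensityTrace:
    """Per-frame mean intensity over the disc of ``radius`` px at ``point``.

    ``point`` is ``(x, y)`` in 0-based pixels; ``radius`` 0 gives the raw
    single-pixel series.  The disc must lie inside the frame.
    """
    x, y = point
    xi, yi = int(round(x)), int(round(y))
    dy, dx = _disc_offsets(radius)
    ys, xs = yi + dy, xi + dx
    ny, nx = stack.frame_shape
    if ys.min() < 0 or xs.min() < 0 or ys.max() >= ny or xs.max() >= nx:
        raise ValueError(
            f"point ({x}, {y}) with radius {radius} reaches outside the {nx}×{ny} frame"
        )
    values = stack.frames[:, ys, xs].mean(axis=1)
    return IntensityTrace(values, stack.frame_interval, (x, y), radius)


def zscore_trace(trace: IntensityTrace | np.ndarray) -> np.ndarray:
    """Standardize a trace to mean 0, population SD 1.

    Raises ``ValueError("flat trace")`` for zero-variance input.
    """
    x = trace.values if isinstance(trace, IntensityTrace) else np.asarray(trace, float)
    sd = x.std()  # population SD
    if sd == 0:
        raise ValueError("flat trace")
    return (x - x.mean()) / sd


def unbiased_crosscorrelogram(z1: np.ndarray, z2: np.ndarray,
                              max_lag: int) -> Correlogram:
    """Unbiased cross-correlogram of two equal-length series.

    ``C(τ) = (1/(N−|τ|)) Σ_t z1(t) z2(t+τ)`` for τ in ``[−max_lag,
    max_lag]``; positive τ means ``z2`` lags ``z1``.
    """
    z1 = np.asarray(z1, dtype=np.float64)
    z2 = np.asarray(z2, dtype=np.float64)
    if z1.ndim != 1 or z2.ndim != 1 or z1.size != z2.size:
        raise ValueError("z1 and z2 must be 1-D series of equal length")
    n = z1.size
    if not 1 <= max_lag <= n // 2:
        raise ValueError(f"max_lag must lie in [1, N/2] = [1, {n // 2}], got {max_lag}")

    # full cross-correlation: index (n-1)+τ holds Σ_t z1(t) z2(t+τ)
    full = signal.correlate(z2, z1, mode="full", method="auto")
    lags = np.arange(-max_lag, max_lag + 1)
    sums = full[(n - 1) + lags]
    values = sums / (n - np.abs(lags))
    return Correlogram(lags=lags, values=values, n_frames=n)


def _parabolic_peak(corr: Correlogram) -> tuple[float, float]:
    """Sub-frame peak lag via 3-point parabolic interpolation.

    Ties in the argmax break toward smaller |τ|.  Raises if the peak sits
    on the correlogram boundary.
    """
    v, lags = corr.values, corr.lags
    top = np.flatnonzero(v == v.max())
    k = top[np.argmin(np.abs(lags[top]))]
    if k == 0 or k == v.size - 1:
        raise ValueError("peak outside search window")
    cm, c0, cp = v[k - 1], v[k], v[k + 1]
    denom = cm - 2 * c0 + cp
    delta = 0.0 if denom == 0 else 0.5 * (cm - cp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(lags[k] + delta), float(c0)


def estimate_velocity(stack: ImageStack, p1: tuple[float, float],
                      p2: tuple[float, float], radius: float = 1.0,
                      max_lag: int | None = None) -> VelocityEstimate:
    """Estimate capillary RBC speed from two points on the same capillary.

    Parameters
    ----------
    stack:
        High-frame-rate movie with ``frame_interval`` (s) and
        ``pixel_size`` (μm/px) set.
    p1, p2:
        Distinct ``(x, y)`` pixel locations on the capillary.
    radius:
        Sampling-disc radius in pixels (default 1 px for noise
        robustness).
    max_lag:
        Correlogram half-width in frames; default ``N // 4``.

    Returns
    -------
    VelocityEstimate
        Speed in mm/s, signed sub-frame lag, point separation in μm,
        peak correlation and flow direction.
    """
    if stack.pixel_size is None:
        raise ValueError("stack.pixel_size (μm/pixel) is required for velocimetry")
    if tuple(p1) == tuple(p2):
        raise ValueError("p1 and p2 must be distinct points")
    n = stack.n_frames
    if max_lag is None:
        max_lag = max(1, n // 4)

    z1 = zscore_trace(extract_point_trace(stack, p1, radius))
    z2 = zscore_trace(extract_point_trace(stack, p2, radius))
    corr = unbiased_crosscorrelogram(z1, z2, max_lag)
    lag, peak = _parabolic_peak(corr)
    if abs(lag) < 1e-9:
        raise ValueError("unresolvable lag (points too close or flow too fast)")

    dx_px = np.hypot(p2[0] - p1[0], p2[1] - p1[1])
    separation_um = dx_px * stack.pixel_size
    transit_s = abs(lag) * stack.frame_interval
    speed_mm_s = (separation_um / 1000.0) / transit_s
    direction = "p1->p2" if lag > 0 else "p2->p1"
    return VelocityEstimate(speed=speed_mm_s, lag=lag, separation=separation_um,
                            peak_correlation=peak, direction=direction)


def extract_kymograph(stack: ImageStack, line: tuple[tuple[float, float], tuple[float, float]],
                      spacing: float = 1.0) -> np.ndarray:
    """Space × time matrix sampled along a line in every frame.

    ``line`` is ``((x0, y0), (x1, y1))`` in pixels; samples are bilinear
    interpolations at ``spacing``-pixel steps from p0 to p1 inclusive.
    Moving RBC shadows appear as sloped dark stripes.
    """
    (x0, y0), (x1, y1) = line
    length = np.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("zero-length line")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n_samples = int(np.floor(length / spacing)) + 1
    ts = np.linspace(0.0, length, n_samples)
    xs = x0 + (x1 - x0) * ts / length
    ys = y0 + (y1 - y0) * ts / length
    ny, nx = stack.frame_shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > nx - 1 or ys.max() > ny - 1:
        raise ValueError("line reaches outside the frame")

    out = np.empty((n_samples, stack.n_frames), dtype=np.float64)
    coords = np.vstack([ys, xs])
    for i in range(stack.n_frames):
        out[:, i] = map_coordinates(stack.frames[i].astype(np.float64), coords, order=1)
    return out
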