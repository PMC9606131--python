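"""Plasma-tracer quality statistics.

* ``decay_curves`` — photostability: per-channel vascular mean intensity
  across time points, normalized to a reference time point (so a
  perfectly stable tracer reads 1 throughout and an exponentially
  cleared dye follows ``2^(−Δt/half-life)``).
* ``compute_snr`` — ``(vessel − parenchyma) / parenchyma`` contrast of a
  wide-field image.
* ``shannon_entropy`` — entropy (bits) of the image normalized to a
  probability matrix ``p_ij = I_ij / Σ I``; flat images score high,
  images with signal concentrated in sparse vessels score low, so lower
  entropy indicates better vascular contrast.
* ``secretion_ratio`` — extracellular / cytosolic mean fluorescence of a
  cell-culture field, the readout for secreted tracer constructs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .segmentation import masked_mean, parenchyma_mask
from .stack import Image, ImageStack, Mask

__all__ = [
    "DecayCurve",
    "QualityMetrics",
    "decay_curves",
    "compute_snr",
    "shannon_entropy",
    "secretion_ratio",
]


@dataclass
class DecayCurve:
    """Vascular mean intensity vs time for one channel."""

    time_points: np.ndarray     # minutes
    raw_means: np.ndarray       # a.u.
    normalized: np.ndarray      # dimensionless; 1 at the reference index
    reference_index: int
    channel: str | None = None

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=np.float64)
        self.raw_means = np.asarray(self.raw_means, dtype=np.float64)
        self.normalized = np.asarray(self.normalized, dtype=np.float64)
        if not (self.time_points.shape == self.raw_means.shape == self.normalized.shape):
            raise ValueError("time_points, raw_means and normalized must share length")


@dataclass
class QualityMetrics:
    """SNR and Shannon entropy for one wide-field image."""

    snr: float
    entropy_bits: float
    source: str | None = None


def decay_curves(stacks: Sequence[Mapping[str, ImageStack]],
                 vessel_mask: Mask | np.ndarray,
                 reference_index: int = 0,
                 time_points: Sequence[float] | None = None) -> dict[str, DecayCurve]:
    """Per-channel normalized vascular intensity across time points.

    Parameters
    ----------
    stacks:
        One mapping ``channel name → ImageStack`` per acquisition time
        point (all time points must provide the same channels).
    vessel_mask:
        Vascular mask (typically from ``segmentation.otsu_mask`` of the
        reference acquisition), applied to every frame.
    reference_index:
        Time point whose mean defines 1 for each channel.
    time_points:
        Acquisition times in minutes; defaults to 0, 1, 2, ...
    """
    if len(stacks) < 2:
        raise ValueError("need at least two time points")
    if not 0 <= reference_index < len(stacks):
        raise ValueError(f"reference_index {reference_index} outside 0..{len(stacks) - 1}")
    channels = list(stacks[0].keys())
    if not channels:
        raise ValueError("no channels present")
    for i, entry in enumerate(stacks):
        missing = set(channels) - set(entry.keys())
        if missing:
            raise ValueError(f"time point {i} is missing channel(s) {sorted(missing)}")
    t = (np.asarray(time_points, dtype=float) if time_points is not None
         else np.arange(len(stacks), dtype=float))
    if t.size != len(stacks):
        raise ValueError("time_points length must match the number of stacks")

    curves: dict[str, DecayCurve] = {}
    for ch in channels:
        raw = np.array([float(np.mean(masked_mean(entry[ch], vessel_mask)))
                        for entry in stacks])
        ref = raw[reference_index]
        if ref == 0:
            raise ValueError(f"zero reference mean for channel {ch!r}")
        curves[ch] = DecayCurve(time_points=t, raw_means=raw, normalized=raw / ref,
                                reference_index=reference_index, channel=ch)
    return curves


def compute_snr(image: Image | np.ndarray, vessel_mask: Mask | np.ndarray,
                parenchyma: Mask | np.ndarray | None = None) -> float:
    """Signal-to-noise ratio ``(mean_vessel − mean_parenchyma) / mean_parenchyma``.

    When no parenchymal mask is supplied, the eroded complement of the
    vascular mask is used (2-px erosion keeps boundary bleed out).  The
    two masks must be nonempty and disjoint.
    """
    vm = vessel_mask.pixels if isinstance(vessel_mask, Mask) else np.asarray(vessel_mask, bool)
    if parenchyma is None:
        parenchyma = parenchyma_mask(vm)
    pm = parenchyma.pixels if isinstance(parenchyma, Mask) else np.asarray(parenchyma, bool)
    if np.logical_and(vm, pm).any():
        raise ValueError("vessel and parenchyma masks overlap")
    mean_vessel = masked_mean(image, vm)
    mean_par = masked_mean(image, pm)
    if mean_par == 0:
        raise ValueError("zero parenchymal mean; SNR undefined")
    return float((mean_vessel - mean_par) / mean_par)


def shannon_entropy(image: Image | np.ndarray) -> float:
    """Shannon entropy (bits) of the intensity-probability matrix.

    The image is converted to probabilities ``p_ij = I_ij / Σ I`` and
    ``H = −Σ p_ij log2 p_ij`` with ``0·log 0 := 0``.  Bounded by
    ``log2(pixel count)`` (uniform image).
    """
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image, dtype=float)
    if np.any(pixels < 0):
        raise ValueError("negative intensities; entropy undefined")
    total = pixels.sum()
    if total == 0:
        raise ValueError("all-zero image; entropy undefined")
    p = pixels / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def secretion_ratio(image: Image | np.ndarray, cell_mask: Mask | np.ndarray) -> float:
    """Extracellular / cytosolic mean fluorescence ratio.

    ``cell_mask`` marks cytosolic (cell) pixels; the ratio is the mean
    intensity outside the mask divided by the mean inside.  Values > 1
    indicate the tracer is predominantly secreted.
    """
    m = cell_mask.pixels if isinstance(cell_mask, Mask) else np.asarray(cell_mask, bool)
    if not m.any():
        raise ValueError("empty cell mask; no cells detected")
    if m.all():
        raise ValueError("cell mask covers the whole frame; no extracellular region")
    inside = masked_mean(image, m)
    outside = masked_mean(image, ~m)
    if inside == 0:
        raise ValueError("zero cytosolic mean; ratio undefined")
    return float(outside / inside)
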