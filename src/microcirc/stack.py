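"""Core in-memory containers for imaging data.

Conventions used throughout the package:

* pixel coordinates are 0-based and given as ``(x, y)`` tuples,
* physical units are fixed at the boundary: seconds for time,
  micrometers for lengths, mm/s for speeds,
* an :class:`ImageStack` stores its frames as a single ``(t, y, x)``
  array; a single :class:`Image` is a ``(y, x)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image", "ImageStack", "Mask"]


@dataclass
class Image:
    """A single 2-D intensity image (arbitrary units, nonnegative).

    Parameters
    ----------
    pixels:
        2-D array of finite, nonnegative intensities.
    pixel_size:
        Physical pixel size in μm/pixel, or ``None`` when unknown.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"Image pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("Image contains negative intensities")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ImageStack:
    """A time-ordered stack of 2-D frames with acquisition metadata.

    Parameters
    ----------
    frames:
        ``(t, y, x)`` array of intensities; at least one frame.
    frame_interval:
        Time between consecutive frames in seconds (> 0).
    pixel_size:
        μm/pixel, or ``None`` when unknown (stages that need physical
        units raise a configuration error in that case).
    channel:
        Optional channel label (e.g. ``"green"``).
    """

    frames: np.ndarray
    frame_interval: float = 1.0
    pixel_size: float | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, ...]
        if self.frames.ndim != 3:
            raise ValueError(
                f"ImageStack frames must be (t, y, x), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("ImageStack needs at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("ImageStack contains non-finite intensities")
        if self.frame_interval is None or self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (seconds)")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (μm/pixel)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def frame_rate(self) -> float:
        """Frames per second."""
        return 1.0 / self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, index: int) -> Image:
        return Image(self.frames[index], pixel_size=self.pixel_size)


@dataclass
class Mask:
    """A boolean mask with provenance.

    ``pixels`` is boolean and either 2-D (one frame / single image) or
    3-D (per-frame masks of a stack).  ``method`` records how the mask
    was produced; ``threshold`` the intensity threshold if one was used.
    """

    pixels: np.ndarray
    method: str
    threshold: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            raise ValueError("Mask pixels must be boolean")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("Mask must be 2-D or 3-D")
        if not self.method:
            raise ValueError("Mask must record the method that produced it")

    @property
    def n_selected(self) -> int:
        return int(self.pixels.sum())

    def frame(self, index: int) -> "Mask":
        if self.pixels.ndim != 3:
            raise ValueError("frame() only applies to per-frame (3-D) masks")
        return Mask(self.pixels[index], method=self.method, threshold=self.threshold)
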