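"""Vascular and cellular segmentation by global and adaptive thresholding.

``otsu_mask`` reproduces the classic global-threshold procedure: a single
threshold maximizing between-class variance over a 256-bin histogram of
*all* voxels of the stack (one threshold for the whole acquisition), with
voxels strictly above the threshold marked as vascular.  ``adaptive_mask``
detects cellular areas against a slowly varying background by comparing
each pixel with a Gaussian-weighted local mean scaled by a sensitivity
knob.  ``masked_mean`` computes the masked mean intensities that the
tracer metrics are built on.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .stack import Image, ImageStack, Mask

__all__ = ["otsu_mask", "adaptive_mask", "masked_mean", "parenchyma_mask"]

OTSU_NBINS = 256


def _data_of(obj) -> np.ndarray:
    if isinstance(obj, ImageStack):
        return obj.frames
    if isinstance(obj, Image):
        return obj.pixels
    return np.asarray(obj)


def otsu_mask(stack: ImageStack | Image, per_frame: bool = False,
              nbins: int = OTSU_NBINS) -> tuple[Mask, float]:
    """Global Otsu threshold over all voxels of a stack (or one image).

    The histogram uses ``nbins`` bins spanning ``[min, max]`` of the
    data.  The mask marks voxels *strictly above* the returned threshold;
    ties at the threshold go to background.  With ``per_frame=True`` a
    separate threshold is computed for every frame (the returned scalar
    is then the mean threshold and per-frame values are stored in
    ``mask.extra['thresholds']``).

    Raises
    ------
    ValueError
        If the data contain fewer than two distinct values
        ("degenerate histogram").
    """
    data = _data_of(stack)
    if per_frame and isinstance(stack, ImageStack):
        thresholds = []
        masks = []
        for i, frame in enumerate(data):
            if frame.min() == frame.max():
                raise ValueError(f"degenerate histogram: frame {i} is constant")
            thr = float(threshold_otsu(frame, nbins=nbins))
            thresholds.append(thr)
            masks.append(frame > thr)
        mask = Mask(np.stack(masks), method="otsu-per-frame",
                    threshold=float(np.mean(thresholds)),
                    extra={"thresholds": thresholds})
        return mask, mask.threshold

    if data.min() == data.max():
        raise ValueError("degenerate histogram: all voxels share one intensity")
    thr = float(threshold_otsu(data.ravel(), nbins=nbins))
    return Mask(data > thr, method="otsu", threshold=thr), thr


def adaptive_mask(image: Image | np.ndarray, window: int = 25,
                  sensitivity: float = 0.5, polarity: str = "bright") -> Mask:
    """Adaptive (local Gaussian mean) threshold detection.

    A pixel is foreground iff its intensity exceeds the Gaussian-weighted
    local mean of a ``window``-sized neighborhood (reflective borders)
    scaled by ``1 + k`` with ``k = 0.5 · (0.5 − sensitivity)``.  Higher
    sensitivity lowers the bar, so masks grow monotonically with
    sensitivity.  ``polarity="dark"`` detects objects darker than their
    surround with the mirrored rule ``pixel < local_mean · (1 − k)``.

    At sensitivity 0.5 the margin ``k`` is zero and half of a flat noisy
    background sits above its own local mean; pick a sensitivity below
    0.5 (e.g. 0.25) when the field has large uniform regions.

    Raises
    ------
    ValueError
        If ``window`` is even or < 3, or sensitivity outside [0, 1].
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and ≥ 3, got {window}")
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError(f"sensitivity must lie in [0, 1], got {sensitivity}")
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")

    pixels = _data_of(image).astype(np.float64)
    if pixels.ndim != 2:
        raise ValueError("adaptive_mask expects a single 2-D image")

    radius = (window - 1) // 2
    sigma = max(radius / 3.0, 0.5)   # kernel support ≈ the requested window
    local_mean = ndimage.gaussian_filter(pixels, sigma=sigma, mode="reflect",
                                         truncate=radius / sigma)
    k = 0.5 * (0.5 - sensitivity)
    if polarity == "bright":
        fg = pixels > local_mean * (1.0 + k)
    else:
        fg = pixels < local_mean * (1.0 - k)
    return Mask(fg, method=f"adaptive-{polarity}", threshold=None,
                extra={"window": window, "sensitivity": sensitivity})


def masked_mean(image_or_stack, mask: Mask | np.ndarray):
    """Mean intensity under a mask; per-frame vector for a stack.

    A 2-D mask applied to a stack is broadcast over frames; a 3-D mask
    must match the stack shape exactly.

    Raises
    ------
    ValueError
        For an empty mask ("no pixels selected") or mismatched shapes.
    """
    m = mask.pixels if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    data = _data_of(image_or_stack)
    if not m.any():
        raise ValueError("no pixels selected")

    if data.ndim == 2:
        if m.shape != data.shape:
            raise ValueError(f"mask shape {m.shape} does not match image {data.shape}")
        return float(data[m].mean(dtype=np.float64))

    if m.ndim == 2:
        if m.shape != data.shape[1:]:
            raise ValueError(f"mask shape {m.shape} does not match frames {data.shape[1:]}")
        return data[:, m].mean(axis=1, dtype=np.float64)
    if m.shape != data.shape:
        raise ValueError(f"mask shape {m.shape} does not match stack {data.shape}")
    if not m.reshape(m.shape[0], -1).any(axis=1).all():
        raise ValueError("no pixels selected in at least one frame")
    flat = data.reshape(data.shape[0], -1).astype(np.float64)
    mf = m.reshape(m.shape[0], -1)
    return (flat * mf).sum(axis=1) / mf.sum(axis=1)


def parenchyma_mask(vessel_mask: Mask | np.ndarray, erosion_radius: int = 2) -> Mask:
    """Extra-vascular (parenchymal) mask for SNR computations.

    Complement of the vascular mask eroded by ``erosion_radius`` pixels,
    which keeps boundary bleed out of the background estimate.
    """
    m = vessel_mask.pixels if isinstance(vessel_mask, Mask) else np.asarray(vessel_mask, bool)
    if m.ndim != 2:
        raise ValueError("parenchyma_mask expects a 2-D vessel mask")
    background = ~m
    if erosion_radius > 0:
        # border_value=1: the image boundary does not erode the background
        background = ndimage.binary_erosion(background, structure=disk(erosion_radius),
                                            border_value=1)
    return Mask(background, method="eroded-complement",
                extra={"erosion_radius": erosion_radius})
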