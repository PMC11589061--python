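"""Anatomically weighted loss masks from HU thresholding and distance transforms.

The brain set is the open HU interval (0, 80). Every pixel gets the Euclidean
distance D(r), in pixel units, to the nearest pixel *inside* that set (0 on
brain pixels themselves). The distance is truncated and power-normalized into
a weight in [0, 1]:

    D_trunc(r) = 1           if D(r) > d
               = (D(r)/d)^p  otherwise

so D_sharp = D_trunc saturates to 1 deep in bone/air while D_smooth =
1 - D_trunc equals 1 throughout the brain, with a monotone transition of
width d pixels across the boundary. The smooth/sharp loss terms are blended
by these weights, which avoids boundary discontinuities between the two
regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import CTImage

__all__ = ["MaskParams", "WeightMask", "brain_mask", "distance_map", "compute_weight_masks"]


@dataclass
class MaskParams:
    """HU band and transition shape for the weighting masks.

    ``d`` is the transition width in pixels, ``p`` the transition power
    (p = 3 gives the default cubic transition).
    """

    hu_low: float = 0.0
    hu_high: float = 80.0
    d: float = 7.0
    p: float = 3.0

    def __post_init__(self) -> None:
        if self.hu_high <= self.hu_low:
            raise ValueError("HU upper bound must exceed the lower bound")
        if self.d < 1:
            raise ValueError("transition width d must be >= 1 pixel")
        if self.p < 1:
            raise ValueError("transition power p must be >= 1")


@dataclass
class WeightMask:
    """Distance map and derived per-pixel loss weights."""

    distance: np.ndarray   # D(r), pixels; +inf if the brain set is empty
    d_trunc: np.ndarray
    d_sharp: np.ndarray
    d_smooth: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.distance < 0):
            raise ValueError("distances must be non-negative")
        for w in (self.d_trunc, self.d_sharp, self.d_smooth):
            if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
                raise ValueError("weights must lie in [0, 1]")


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, CTImage) else np.asarray(image, dtype=float)


def brain_mask(image, params: MaskParams | None = None) -> np.ndarray:
    """Boolean grid, true exactly where hu_low < HU < hu_high (open interval)."""
    params = params or MaskParams()
    pix = _as_pixels(image)
    if not np.all(np.isfinite(pix)):
        raise ValueError("image contains non-finite HU values")
    return (pix > params.hu_low) & (pix < params.hu_high)


def distance_map(brain: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance (pixels) to the nearest brain-set pixel.

    Zero on brain pixels. If the brain set is empty every distance is +inf and
    a warning is issued; downstream weighting then degenerates to all-sharp.
    """
    brain = np.asarray(brain, dtype=bool)
    if brain.size == 0:
        raise ValueError("degenerate empty grid")
    if not brain.any():
        warnings.warn("brain mask is empty; distances are infinite (all-sharp weighting)",
                      stacklevel=2)
        return np.full(brain.shape, np.inf)
    # distance to the nearest zero of the input -> zeros must be brain pixels
    return ndimage.distance_transform_edt(~brain)


def compute_weight_masks(image, params: MaskParams | None = None) -> WeightMask:
    """Threshold, distance-transform and normalize into a :class:`WeightMask`."""
    params = params or MaskParams()
    dist = distance_map(brain_mask(image, params))
    with np.errstate(invalid="ignore"):
        d_trunc = np.where(dist > params.d, 1.0, (dist / params.d) ** params.p)
    d_sharp = d_trunc
    return WeightMask(distance=dist, d_trunc=d_trunc,
                      d_sharp=d_sharp, d_smooth=1.0 - d_trunc)
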