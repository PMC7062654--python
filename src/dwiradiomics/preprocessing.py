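"""ROI gray-level normalization.

Before any histogram, co-occurrence, run-length or autoregressive feature is
computed, the ROI's dynamics are limited to mu +/- 3 sigma (mean and population
standard deviation of the masked pixels) and the clipped values are quantized
linearly to integer gray levels 1..Ng.  This makes those features invariant to
positive affine rescaling of the input intensities (scanner gain/offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidRoiError
from .io_formats import AnnotatedImage, RoiMask

#: Width of the dynamics window in units of sigma.  Fixed by the method.
CLIP_K = 3.0

#: Default number of quantization levels (6 bits).
DEFAULT_N_LEVELS = 64


@dataclass(frozen=True)
class NormalizationParams:
    """The mu +/- 3 sigma window and level count used for one ROI."""

    mu: float
    sigma: float
    n_levels: int

    @property
    def lower(self) -> float:
        return self.mu - CLIP_K * self.sigma

    @property
    def upper(self) -> float:
        return self.mu + CLIP_K * self.sigma


@dataclass(frozen=True)
class QuantizedRoi:
    """ROI pixels mapped to integer levels 1..Ng.

    ``level_image`` is a full-grid int array with 0 outside the mask so that
    spatial neighbourhood features (GLCM, RLM, AR model) keep the geometry;
    ``levels`` gives the masked values in row-major coordinate order.
    """

    level_image: np.ndarray
    mask: np.ndarray
    n_levels: int
    params: NormalizationParams

    @property
    def levels(self) -> np.ndarray:
        return self.level_image[self.mask]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _as_mask_array(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)


def _as_pixel_array(image) -> np.ndarray:
    return image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image, dtype=float)


def normalize_roi(image, mask, n_levels: int = DEFAULT_N_LEVELS) -> QuantizedRoi:
    """Limit ROI dynamics to mu +/- 3 sigma and quantize to ``n_levels`` levels.

    The mapping is ``level = 1 + floor((x_clip - lower) / (upper - lower) * Ng)``
    with half-open bins and the top edge closed, so ``x = upper`` maps to Ng and
    exactly Ng levels are reachable.  Sigma is the population standard
    deviation (divisor N).  A constant ROI (sigma = 0) maps entirely to level 1
    so that downstream matrices stay well defined.
    """
    px = _as_pixel_array(image)
    m = _as_mask_array(mask)
    if px.shape != m.shape:
        raise InvalidRoiError(f"mask shape {m.shape} does not match image shape {px.shape}")
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    values = px[m]
    if values.size == 0:
        raise InvalidRoiError("empty mask")
    mu = float(values.mean())
    sigma = float(values.std())  # population (divisor N)
    if values.max() == values.min():
        sigma = 0.0  # bitwise-constant ROI: ignore rounding residue in std
    params = NormalizationParams(mu=mu, sigma=sigma, n_levels=int(n_levels))

    level_image = np.zeros(px.shape, dtype=np.int32)
    if sigma == 0.0:
        level_image[m] = 1
        return QuantizedRoi(level_image, m.copy(), int(n_levels), params)

    lower, upper = params.lower, params.upper
    clipped = np.clip(values, lower, upper)
    lv = 1 + np.floor((clipped - lower) / (upper - lower) * n_levels).astype(np.int64)
    np.clip(lv, 1, n_levels, out=lv)  # closes the top edge: x = upper -> Ng
    level_image[m] = lv
    return QuantizedRoi(level_image, m.copy(), int(n_levels), params)
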