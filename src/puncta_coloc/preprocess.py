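"""Optional per-channel noise reduction and brightness normalization.

These operations modify the pixel data that thresholding will see, so they
are OFF by default and should be applied consistently across all images of
one experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk


@dataclass
class PreprocessParams:
    """Noise-reduction and brightness-normalization settings.

    ``rolling_radius`` is the structuring-element radius (pixels) of the
    background estimate, ``blur_sigma`` the Gaussian smoothing scale
    (pixels), and ``saturated_fraction`` the fraction of pixels driven to
    255 by brightness normalization.
    """

    subtract_background: bool = False
    rolling_radius: float = 50.0
    blur_sigma: float = 1.0
    normalize_brightness: bool = False
    saturated_fraction: float = 0.0035

    def __post_init__(self) -> None:
        if self.rolling_radius <= 0:
            raise ValueError("rolling_radius must be > 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not (0 <= self.saturated_fraction < 1):
            raise ValueError("saturated_fraction must be in [0, 1)")


def subtract_background(plane: np.ndarray, rolling_radius: float) -> np.ndarray:
    """Rolling-ball style background subtraction.

    The background is estimated by grayscale morphological opening with a
    disk structuring element of the given radius and subtracted from the
    plane, clipped at zero.  A constant plane is pure background and maps
    to all zeros.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got {plane.ndim}-D")
    if rolling_radius <= 0:
        raise ValueError("rolling_radius must be > 0")
    footprint = disk(int(round(rolling_radius)))
    background = ndimage.grey_opening(plane, footprint=footprint)
    out = plane.astype(np.int64) - background.astype(np.int64)
    np.clip(out, 0, None, out=out)
    return out.astype(plane.dtype)


def gaussian_blur(plane: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel (reflective boundary).

    ``sigma = 0`` returns the input unchanged.  Output is floating point so
    no intensity mass is lost to premature rounding.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got {plane.ndim}-D")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return plane
    return ndimage.gaussian_filter(plane.astype(np.float64), sigma=sigma, mode="reflect")


def normalize_brightness(plane: np.ndarray, saturated_fraction: float) -> np.ndarray:
    """Rescale so a fixed fraction of pixels saturates at 255.

    Linearly maps ``[min(plane), q]`` onto ``[0, 255]`` where ``q`` is the
    ``1 - saturated_fraction`` quantile (lower order statistic); values above
    ``q`` clip to 255.  Constant planes map to all zeros.  Applying the same
    fraction to every image of an experiment equalizes the percentage of
    saturated pixels across images.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got {plane.ndim}-D")
    if not (0 <= saturated_fraction < 1):
        raise ValueError("saturated_fraction must be in [0, 1)")
    lo = float(plane.min())
    q = float(np.quantile(plane, 1.0 - saturated_fraction, method="lower"))
    if q <= lo:
        return np.zeros(plane.shape, dtype=np.uint8)
    scaled = (plane.astype(np.float64) - lo) / (q - lo) * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def preprocess_plane(plane: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Apply the configured preprocessing chain to one channel plane."""
    out = plane
    if params.subtract_background:
        out = subtract_background(out, params.rolling_radius)
        if params.blur_sigma > 0:
            blurred = gaussian_blur(out, params.blur_sigma)
            out = np.clip(np.floor(blurred + 0.5), 0, 255).astype(np.uint8)
    if params.normalize_brightness:
        out = normalize_brightness(out, params.saturated_fraction)
    return np.asarray(out, dtype=np.uint8)
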