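"""Preprocessing: CLAHE, illumination equalization, and the local-contrast
stretch used before exudate detection.

All operations take and return images in [0, 1].  The local-contrast stretch
(``local_contrast_stretch``) is defined on the 8-bit scale — g = 9*f - 9*f̄_3x3 + 90
with f in [0, 255] — because its constants are 8-bit constants; the result
is clipped to [0, 255] and returned renormalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = ["EnhanceParams", "clahe", "illumination_equalize", "local_contrast_stretch"]


@dataclass(frozen=True)
class EnhanceParams:
    """Tunables for preprocessing.

    clahe_clip : normalized CLAHE clip limit (fraction of tile pixel count).
    clahe_tiles : contextual tile grid (rows, cols).
    bg_sigma : Gaussian sigma in pixels for the illumination-field estimate.
    stretch_window : odd window size of the local mean in the contrast stretch.
    """

    clahe_clip: float = 0.01
    clahe_tiles: Tuple[int, int] = (8, 8)
    bg_sigma: float = 30.0
    stretch_window: int = 3

    def __post_init__(self) -> None:
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")
        if self.bg_sigma <= 0:
            raise ValueError("bg_sigma must be > 0")
        if self.stretch_window < 3 or self.stretch_window % 2 == 0:
            raise ValueError("stretch_window must be odd and >= 3")


def _check(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    return image


def clahe(image: np.ndarray, params: EnhanceParams = EnhanceParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, output in [0, 1]."""
    image = _check(image)
    ptp = image.max() - image.min()
    if ptp < 1e-6:
        # constant image: nothing to equalize
        return np.clip(image, 0.0, 1.0)
    rows, cols = params.clahe_tiles
    kernel = (
        max(1, image.shape[0] // rows),
        max(1, image.shape[1] // cols),
    )
    out = exposure.equalize_adapthist(
        np.clip(image, 0.0, 1.0), kernel_size=kernel, clip_limit=params.clahe_clip
    )
    return np.clip(out, 0.0, 1.0)


def illumination_equalize(
    image: np.ndarray, params: EnhanceParams = EnhanceParams()
) -> np.ndarray:
    """Flatten slowly varying background illumination.

    Subtracts a large-sigma Gaussian estimate of the illumination field and
    restores the global mean, so vignetting and linear shading are removed
    while local structure is untouched.
    """
    image = _check(image)
    background = ndimage.gaussian_filter(image, params.bg_sigma, mode="nearest")
    out = image - background + image.mean()
    return np.clip(out, 0.0, 1.0)


def local_contrast_stretch(
    green: np.ndarray, params: EnhanceParams = EnhanceParams()
) -> np.ndarray:
    """Local-mean contrast stretch of the green channel.

    On the 8-bit scale: g(i,j) = 9*f(i,j) - 9*f̄_w(i,j) + 90, where f̄_w is
    the mean over an stretch_window × stretch_window neighborhood (mirror-padded
    borders, the center pixel included).  g is clipped to [0, 255] and the
    result returned on [0, 1].  Accepts input on either the [0, 1] or the
    [0, 255] scale.
    """
    green = _check(green)
    f = green * 255.0 if green.max() <= 1.0 else green
    local_mean = ndimage.uniform_filter(f, size=params.stretch_window, mode="mirror")
    g = 9.0 * f - 9.0 * local_mean + 90.0
    return np.clip(g, 0.0, 255.0) / 255.0
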