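"""Exudate segmentation on color fundus images.

Exudates are bright yellow lipid deposits, best seen on the color
photograph.  The detector works on the green channel: local-mean contrast
stretch (``enhance.local_contrast_stretch``), curvelet bright-object amplification
(fifth-power band-magnitude map), thresholding (Otsu restricted to
above-mean pixels), then removal of candidate regions touching the
(dilated) optic disc, which would otherwise be the largest bright region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from . import curvelet
from .enhance import EnhanceParams, local_contrast_stretch
from .optic_disc import OpticDisc, amplify_bright

__all__ = ["ExudateResult", "ExudateParams", "detect_exudates"]


@dataclass(frozen=True)
class ExudateParams:
    amplify_power: float = 5.0
    od_dilation: int = 5  # px, absorbs the disc's boundary halo
    min_region: int = 5  # px, salt-noise guard
    smooth_sigma: float = 1.0  # pre-smoothing of the green channel
    # absolute floor on the contrast-stretched image (whose scale is fixed:
    # flat background maps to 90/255); noise-driven Otsu splits cannot pass
    # it on lesion-free images
    stretch_gate: float = 0.5


@dataclass
class ExudateResult:
    mask: np.ndarray
    total_area: int
    n_regions: int
    od_removed: bool


def detect_exudates(
    color: np.ndarray,
    od: Optional[OpticDisc],
    params: ExudateParams = ExudateParams(),
    enhance_params: EnhanceParams = EnhanceParams(),
) -> ExudateResult:
    """Segment exudates from a preprocessed RGB fundus image.

    ``od`` may be None, in which case no disc masking is applied and the
    result is flagged ``od_removed=False``.
    """
    color = np.asarray(color, dtype=float)
    if color.ndim != 3 or color.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (h, w, 3)")
    green = ndimage.gaussian_filter(color[..., 1], params.smooth_sigma)

    stretched = local_contrast_stretch(green, enhance_params)
    amplified = amplify_bright(stretched, params.amplify_power)

    # threshold: Otsu over the bright half only — the dark background would
    # otherwise dominate the histogram and drag the split down
    above_mean = amplified[amplified > amplified.mean()]
    if above_mean.size < 2 or above_mean.max() - above_mean.min() < 1e-9:
        mask = np.zeros(green.shape, dtype=bool)
    else:
        mask = amplified > threshold_otsu(above_mean)
    # the contrast stretch responds at lesion boundaries (a flat interior
    # cancels against its local mean), so gate on its absolute scale, fill
    # the enclosed interiors and restore the outer half of the edge band
    # with a 1-px dilation
    mask &= stretched > params.stretch_gate
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_dilation(mask, structure=disk(1))

    od_removed = False
    if od is not None:
        od_zone = ndimage.binary_dilation(od.mask, structure=disk(params.od_dilation))
        # drop whole candidate regions that touch the disc zone, then make
        # the exclusion exact
        labels = measure.label(mask, connectivity=2)
        for region_label in np.unique(labels[od_zone]):
            if region_label > 0:
                mask[labels == region_label] = False
        mask &= ~od_zone
        od_removed = True

    # size gate
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = counts >= params.min_region
    keep[0] = False
    mask = keep[labels]

    n_regions = int(measure.label(mask, connectivity=2).max())
    return ExudateResult(
        mask=mask,
        total_area=int(mask.sum()),
        n_regions=n_regions,
        od_removed=od_removed,
    )
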