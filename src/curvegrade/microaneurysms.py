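"""Microaneurysm (MA) detection on FFA angiograms.

MAs are the earliest retinopathy lesion: small saccular capillary
dilations that show as bright dots a few pixels across on the angiogram.
The detector removes the segmented vessels from the image, dilates, derives
a retinal background by grayscale erosion, maps the background's zero
pixels onto the dilated image and subtracts the background, enhances small
bright structures with a white top-hat, and thresholds at one tenth of the
maximum intensity (26 on the 8-bit scale).  Surviving components pass a
dot-likeness gate (1-50 px, bounded eccentricity); counts are reported
overall and within the (dilated) FAZ boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import disk

from .faz import FazResult
from .optic_disc import OpticDisc

__all__ = ["MaResult", "MaParams", "detect_mas", "ma_threshold"]


@dataclass(frozen=True)
class MaParams:
    vessel_dilation: int = 1  # exclusion margin around the vessel mask
    dilation_radius: int = 2  # grayscale dilation before background estimate
    background_radius: int = 10  # erosion element; exceeds the MA diameter
    tophat_radius: int = 3  # white top-hat for small bright structures
    threshold_frac: float = 0.1  # of the maximum of the enhanced image
    # absolute floor on the enhanced contrast (fraction of full scale);
    # guards the relative threshold when no true lesion sets the maximum
    min_contrast: float = 0.05
    od_dilation: int = 5  # exclusion margin around the optic disc
    min_area: int = 1
    max_area: int = 50
    max_eccentricity: float = 0.95  # dot-likeness gate
    # source-image dot gate: the bright structure containing a candidate
    # (local Otsu in a window around it) must not extend farther than this —
    # fragments of faint vessels fail it, isolated dots pass
    max_source_extent: float = 16.0
    source_window: int = 15  # half-width of the local window
    faz_margin: int = 10  # px dilation of the FAZ mask for "in FAZ" counts


@dataclass
class MaResult:
    centers: np.ndarray  # (n, 2) float centroids (row, col)
    total_count: int
    count_in_faz: int
    mask: np.ndarray


def ma_threshold(bit_depth: int = 8, frac: float = 0.1) -> int:
    """Detection threshold on an integer scale: ceil(frac * max intensity).

    For 8-bit images this evaluates to 26.
    """
    return ceil(frac * (2**bit_depth - 1))


def _source_extent(
    ffa: np.ndarray, centroid: Tuple[float, float], params: MaParams
) -> float:
    """Extent (major axis, px) of the bright structure containing the
    candidate in the source image, measured by local Otsu in a window."""
    from skimage.filters import threshold_otsu

    h, w = ffa.shape
    r0, c0 = int(round(centroid[0])), int(round(centroid[1]))
    hw = params.source_window
    r1, r2 = max(0, r0 - hw), min(h, r0 + hw + 1)
    c1, c2 = max(0, c0 - hw), min(w, c0 + hw + 1)
    window = ffa[r1:r2, c1:c2]
    if window.max() - window.min() < 1e-9:
        return 0.0
    local = window > threshold_otsu(window)
    labels = measure.label(local, connectivity=2)
    label_here = labels[r0 - r1, c0 - c1]
    if label_here == 0:
        return 0.0
    region = next(p for p in measure.regionprops(labels) if p.label == label_here)
    return float(region.axis_major_length)


def detect_mas(
    ffa: np.ndarray,
    vessel_mask: np.ndarray,
    faz: Optional[FazResult] = None,
    od: Optional[OpticDisc] = None,
    params: MaParams = MaParams(),
) -> MaResult:
    """Detect microaneurysms on a preprocessed FFA image.

    ``faz`` may be None, in which case ``count_in_faz`` is 0.  When ``od``
    is given, the (dilated) disc region is excluded — the bright disc rim
    otherwise survives the background subtraction.
    """
    ffa = np.asarray(ffa, dtype=float)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != ffa.shape:
        raise ValueError("vessel mask shape must match the image")

    vessel_zone = ndimage.binary_dilation(
        vessel_mask, structure=disk(params.vessel_dilation)
    )
    if od is not None:
        vessel_zone |= ndimage.binary_dilation(
            od.mask, structure=disk(params.od_dilation)
        )
    devesseled = np.where(vessel_zone, 0.0, ffa)

    dilated = ndimage.grey_dilation(devesseled, footprint=disk(params.dilation_radius))
    background = ndimage.grey_erosion(dilated, footprint=disk(params.background_radius))
    # map the background's zero pixels onto the dilated image, then remove
    # the background itself
    dilated = np.where(background == 0.0, 0.0, dilated)
    residual = np.clip(dilated - background, 0.0, None)

    enhanced = ndimage.white_tophat(residual, footprint=disk(params.tophat_radius))

    # threshold on the 8-bit-rescaled enhancement: ceil(0.1 * 255) = 26,
    # with an absolute contrast floor for the lesion-free case
    peak = enhanced.max()
    if peak <= 0:
        mask = np.zeros(ffa.shape, dtype=bool)
    else:
        scaled = enhanced / peak * 255.0
        mask = scaled >= ma_threshold(8, params.threshold_frac)
        mask &= enhanced >= params.min_contrast
    mask &= ~vessel_zone

    centers: List[Tuple[float, float]] = []
    labels = measure.label(mask, connectivity=2)
    final = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        if region.eccentricity > params.max_eccentricity:
            continue
        extent = _source_extent(ffa, region.centroid, params)
        if not (0.0 < extent <= params.max_source_extent):
            # no bright structure at the candidate (morphology artifact) or
            # an elongated one (vessel fragment) — either way not a dot
            continue
        final[labels == region.label] = True
        centers.append(region.centroid)
    centers_arr = np.asarray(centers, dtype=float).reshape(-1, 2)

    count_in_faz = 0
    if faz is not None and faz.mask.any() and len(centers) > 0:
        faz_zone = ndimage.binary_dilation(faz.mask, structure=disk(params.faz_margin))
        rows = np.clip(np.round(centers_arr[:, 0]).astype(int), 0, ffa.shape[0] - 1)
        cols = np.clip(np.round(centers_arr[:, 1]).astype(int), 0, ffa.shape[1] - 1)
        count_in_faz = int(faz_zone[rows, cols].sum())

    return MaResult(
        centers=centers_arr,
        total_count=len(centers),
        count_in_faz=count_in_faz,
        mask=final,
    )
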