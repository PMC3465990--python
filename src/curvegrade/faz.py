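"""Foveal avascular zone (FAZ) segmentation.

The macula sits 2.5 optic-disc diameters from the disc center, which fixes a
circular region of interest (ROI).  Two independent delineations of the
avascular zone are intersected:

* endpoint path — skeletonize the vessel mask, mark skeleton pixels whose
  3x3 neighborhood sums to 2 (a tip: the pixel plus exactly one neighbor),
  drop endpoints farther from the endpoint centroid than the mean distance,
  and fill the convex hull of the survivors;
* intensity path — suppress vessel pixels in the angiogram, apply a
  grayscale morphological closing, and keep the darkest quartile inside the
  ROI (the avascular zone is hypofluorescent).

The final mask is the logical AND, restricted to the ROI disk.  Area,
centroid, ordered boundary points and the variance of boundary-to-centroid
distances (the shape-regularity feature) are measured on the final mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk, skeletonize

from .optic_disc import OpticDisc

__all__ = [
    "RoiSpec",
    "FazResult",
    "FazParams",
    "RoiOutOfBoundsError",
    "InsufficientEndpointsError",
    "define_roi",
    "find_endpoints",
    "filter_endpoints",
    "segment_faz",
]


class RoiOutOfBoundsError(RuntimeError):
    """The macular ROI falls entirely outside the image."""


class InsufficientEndpointsError(RuntimeError):
    """Fewer than three vessel endpoints were found in the ROI."""


@dataclass(frozen=True)
class FazParams:
    roi_radius_factor: float = 2.5  # ROI radius in units of the OD radius
    closing_radius: int = 8  # disk radius for the intensity-path closing
    # endpoint hulls smaller than this fraction of the dark region are
    # treated as degenerate and the intensity path is used alone
    min_hull_fraction: float = 0.75
    n_boundary_points: int = 64


@dataclass(frozen=True)
class RoiSpec:
    """Macular region of interest anchored on the optic disc."""

    center: Tuple[float, float]
    radius: float
    od_reference: OpticDisc

    def contains(self, point: Tuple[float, float]) -> bool:
        return np.hypot(point[0] - self.center[0], point[1] - self.center[1]) <= self.radius

    def disk_mask(self, shape: Tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.hypot(rr - self.center[0], cc - self.center[1]) <= self.radius


@dataclass
class FazResult:
    mask: np.ndarray
    area: int
    centroid: Tuple[float, float]
    boundary_points: np.ndarray  # ordered (n, 2) along the boundary
    distance_variance: float
    endpoint_fallback: bool = False


def define_roi(
    od: OpticDisc,
    image_shape: Tuple[int, int],
    side_hint: str = "auto",
    params: FazParams = FazParams(),
) -> RoiSpec:
    """Place the macular ROI 2.5 disc diameters from the disc center.

    The ROI center lies on the horizontal line through the disc center.
    ``side_hint``: "auto" moves toward the image-center side (tie broken
    toward the right), "left"/"right" force the direction.
    """
    h, w = image_shape
    row, col = od.center
    offset = 2.5 * od.diameter
    if side_hint == "auto":
        direction = 1.0 if col <= w / 2 else -1.0
    elif side_hint == "right":
        direction = 1.0
    elif side_hint == "left":
        direction = -1.0
    else:
        raise ValueError("side_hint must be 'left', 'right' or 'auto'")
    center = (row, col + direction * offset)
    radius = params.roi_radius_factor * od.radius
    if (
        center[1] + radius < 0
        or center[1] - radius >= w
        or center[0] + radius < 0
        or center[0] - radius >= h
    ):
        raise RoiOutOfBoundsError(f"ROI centered at {center} lies outside the image")
    return RoiSpec(center=center, radius=radius, od_reference=od)


def find_endpoints(vessel_mask: np.ndarray, roi: RoiSpec) -> List[Tuple[int, int]]:
    """Vessel-tip pixels inside the ROI.

    The mask is skeletonized first (the 3x3 sum rule assumes 1-px-wide
    curves); a skeleton pixel is a tip when its 3x3 neighborhood sums to
    exactly 2 — itself plus one neighbor.  Sums of 1 are isolated pixels,
    3 or more lie within or at junctions of vessel runs.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    skel = skeletonize(vessel_mask)
    sums = ndimage.correlate(skel.astype(int), np.ones((3, 3), dtype=int), mode="constant")
    tips = skel & (sums == 2)
    roi_mask = roi.disk_mask(vessel_mask.shape)
    rows, cols = np.nonzero(tips & roi_mask)
    return list(zip(rows.tolist(), cols.tolist()))


def filter_endpoints(
    points: List[Tuple[float, float]], roi: Optional[RoiSpec] = None
) -> List[Tuple[float, float]]:
    """Keep endpoints no farther from the endpoint centroid than the mean
    endpoint-to-centroid distance (discards stray tips outside the FAZ rim).
    """
    if len(points) < 3:
        raise InsufficientEndpointsError(f"need >= 3 endpoints, got {len(points)}")
    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    dists = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    keep = dists <= dists.mean()
    return [tuple(p) for p in pts[keep]]


def _hull_mask(points: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Filled convex hull of the given (row, col) points."""
    from skimage.morphology import convex_hull_image

    canvas = np.zeros(shape, dtype=bool)
    rows = np.clip(np.round(points[:, 0]).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.round(points[:, 1]).astype(int), 0, shape[1] - 1)
    canvas[rows, cols] = True
    if canvas.sum() < 3:
        return canvas
    return convex_hull_image(canvas)


def _boundary_and_variance(
    mask: np.ndarray, n_points: int
) -> Tuple[Tuple[float, float], np.ndarray, float]:
    """Centroid, ordered boundary points and boundary-distance variance."""
    centroid_rc = ndimage.center_of_mass(mask)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return centroid_rc, np.zeros((0, 2)), 0.0
    contour = max(contours, key=len)
    idx = np.linspace(0, len(contour) - 1, min(n_points, len(contour))).astype(int)
    boundary = contour[idx]
    dists = np.hypot(boundary[:, 0] - centroid_rc[0], boundary[:, 1] - centroid_rc[1])
    return centroid_rc, boundary, float(np.var(dists))


def segment_faz(
    vessel_mask: np.ndarray,
    ffa: np.ndarray,
    roi: RoiSpec,
    params: FazParams = FazParams(),
) -> FazResult:
    """Segment the FAZ inside the ROI by intersecting the endpoint-hull and
    dark-region delineations.

    When fewer than three endpoints are found, the intensity path alone is
    used and ``endpoint_fallback`` is set.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    ffa = np.asarray(ffa, dtype=float)
    if vessel_mask.shape != ffa.shape:
        raise ValueError("vessel mask and image shapes differ")
    roi_mask = roi.disk_mask(ffa.shape)

    # intensity path: suppress vessels, close (fills the dark vessel gaps
    # with their bright surroundings), keep pixels darker than the global
    # mean of the closed image — the avascular zone is hypofluorescent.
    # The threshold is global on purpose: the FAZ can fill most of the ROI,
    # in which case any ROI-local split degenerates.
    suppressed = ffa.copy()
    suppressed[vessel_mask] = 0.0
    closed = ndimage.grey_closing(suppressed, footprint=disk(params.closing_radius))
    # the avascular zone is by definition vessel-free, so vessel pixels can
    # never belong to it
    dark = (closed <= closed.mean()) & roi_mask & ~vessel_mask

    fallback = False
    try:
        endpoints = find_endpoints(vessel_mask, roi)
        kept = filter_endpoints(endpoints, roi)
        hull = _hull_mask(np.asarray(kept, dtype=float), ffa.shape) & roi_mask
        if hull.sum() < params.min_hull_fraction * dark.sum():
            # endpoint evidence degenerate (truncated tip ring): the hull
            # cannot plausibly contain the avascular zone, so trust the
            # intensity path alone, as when endpoints are missing outright
            fallback = True
            final = dark
        else:
            final = hull & dark
    except InsufficientEndpointsError:
        fallback = True
        final = dark

    area = int(final.sum())
    if area == 0:
        return FazResult(
            mask=final, area=0, centroid=roi.center,
            boundary_points=np.zeros((0, 2)), distance_variance=0.0,
            endpoint_fallback=fallback,
        )
    centroid, boundary, dist_var = _boundary_and_variance(final, params.n_boundary_points)
    return FazResult(
        mask=final,
        area=area,
        centroid=centroid,
        boundary_points=boundary,
        distance_variance=dist_var,
        endpoint_fallback=fallback,
    )
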