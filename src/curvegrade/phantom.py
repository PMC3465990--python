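"""Seeded synthetic retina phantoms with full ground truth.

``render_pair`` draws a paired FFA angiogram + color fundus image containing
the structures the segmentation pipeline assumes: a dark vignetted
background, a bright vessel-crossed optic disc, a branching vessel tree with
Gaussian cross-section profile, a vessel-free foveal avascular zone (FAZ) at
the macula (2.5 disc diameters temporal to the disc), small bright
microaneurysm dots on the angiogram and bright-yellow exudate blobs on the
color image.  Every planted object is recorded in a :class:`PhantomTruth`
(the pre-noise renders are retained for oracle tests).

``sample_feature_cohort`` draws six-feature vectors per severity grade from
log-normal class-conditional distributions around fixed per-grade mean
feature values, for exercising the grading cascade without images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "render_pair",
    "grade_presets",
    "sample_feature_cohort",
    "COHORT_FEATURE_MEANS",
]

#: Per-grade mean feature vectors (F1 exudate area px, F2 microaneurysms in
#: FAZ, F3 total microaneurysms, F4 vessel area px, F5 FAZ area px, F6 FAZ
#: boundary-distance variance px^2) used as class centers by the cohort
#: sampler.  Severity trends: exudate load and FAZ area/irregularity grow
#: with grade while vessel area declines as capillaries drop out.
COHORT_FEATURE_MEANS: Dict[int, Tuple[float, ...]] = {
    1: (15.0, 0.0, 0.94, 52567.14, 3498.25, 12.93),
    2: (450.0, 13.8, 110.0, 45654.0, 5773.0, 27.07),
    3: (2987.0, 15.04, 73.76, 29521.0, 13624.0, 110.84),
}

#: Features whose values are counts and get rounded to integers.
_COUNT_FEATURES = (1, 2)  # F2, F3 (0-based indices)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast parameters of one synthetic retina pair.

    ``faz_center`` defaults to 2.5 optic-disc diameters from the disc center
    along the horizontal toward the image center (the macula's anatomical
    position).  The FAZ disk is kept vessel-free by construction.
    """

    shape: Tuple[int, int] = (576, 720)
    od_center: Tuple[float, float] = (288.0, 150.0)
    od_radius: float = 40.0
    n_vessels: int = 12
    vessel_sigma: float = 2.0
    vessel_contrast: float = 0.5
    vessel_length_scale: float = 1.0
    faz_center: Optional[Tuple[float, float]] = None
    faz_radius: float = 30.0
    n_mas: int = 0
    ma_radius: float = 2.0
    ma_contrast: float = 0.35
    ma_near_faz_frac: float = 0.5
    n_exs: int = 0
    ex_area_range: Tuple[float, float] = (60.0, 200.0)
    ex_contrast: float = 0.5
    background_vignette_strength: float = 0.3
    noise_sigma: float = 0.01
    seed: int = 0
    grade: int = 1

    def resolved_faz_center(self) -> Tuple[float, float]:
        if self.faz_center is not None:
            return self.faz_center
        row, col = self.od_center
        direction = 1.0 if col <= self.shape[1] / 2 else -1.0
        return (row, col + direction * 2.5 * 2.0 * self.od_radius)

    def validate(self) -> None:
        h, w = self.shape
        r, c = self.od_center
        if not (self.od_radius < r < h - self.od_radius and self.od_radius < c < w - self.od_radius):
            raise ValueError("optic disc extends outside the image")
        fr, fc = self.resolved_faz_center()
        if not (self.faz_radius < fr < h - self.faz_radius and self.faz_radius < fc < w - self.faz_radius):
            raise ValueError("FAZ extends outside the image")
        if self.n_vessels < 0 or self.n_mas < 0 or self.n_exs < 0:
            raise ValueError("object counts must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth for one rendered pair (plus pre-noise renders for tests)."""

    vessel_mask: np.ndarray
    od_center: Tuple[float, float]
    od_radius: float
    faz_center: Tuple[float, float]
    faz_radius: float
    faz_polygon: np.ndarray  # (n, 2) boundary points, (row, col)
    faz_area: float
    ma_centers: np.ndarray  # (n, 2) float (row, col)
    ex_mask: np.ndarray
    ex_area: int
    grade: int
    clean_ffa: np.ndarray = field(repr=False, default=None)
    clean_color: np.ndarray = field(repr=False, default=None)


# ----------------------------------------------------------------------------
# vessel tree


def _walk(
    rng: np.random.Generator,
    start: Tuple[float, float],
    heading: float,
    n_steps: int,
    shape: Tuple[int, int],
    faz_center: Tuple[float, float],
    keepout: float,
    wobble: float = 0.06,
) -> np.ndarray:
    """Bounded-curvature random walk steered away from the FAZ keep-out disk.

    Returns the visited (row, col) points; stops at the image margin.
    """
    h, w = shape
    pts = []
    r, c = start
    for _ in range(n_steps):
        pts.append((r, c))
        heading += rng.normal(0.0, wobble)
        nr = r + 2.0 * np.sin(heading)
        nc = c + 2.0 * np.cos(heading)
        dr, dc = nr - faz_center[0], nc - faz_center[1]
        dist = np.hypot(dr, dc)
        if dist < keepout:
            # steer along the tangent that moves away from the keep-out disk
            away = np.arctan2(dr, dc)
            delta = (away - heading + np.pi) % (2 * np.pi) - np.pi
            heading += np.clip(delta, -0.5, 0.5)
            nr = r + 2.0 * np.sin(heading)
            nc = c + 2.0 * np.cos(heading)
            if np.hypot(nr - faz_center[0], nc - faz_center[1]) < keepout:
                break
        if not (8 <= nr < h - 8 and 8 <= nc < w - 8):
            break
        r, c = nr, nc
    return np.asarray(pts, dtype=float)


def _vessel_centerlines(spec: PhantomSpec, rng: np.random.Generator) -> List[np.ndarray]:
    h, w = spec.shape
    faz_c = spec.resolved_faz_center()
    keepout = spec.faz_radius + 2.0 * spec.vessel_sigma + 1.0
    paths: List[np.ndarray] = []
    # arcade vessels fanning out from inside the optic disc
    for i in range(spec.n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        rr = rng.uniform(0.0, 0.5) * spec.od_radius
        start = (spec.od_center[0] + rr * np.sin(ang), spec.od_center[1] + rr * np.cos(ang))
        heading = ang + rng.normal(0.0, 0.3)
        n_steps = spec.vessel_length_scale * rng.integers(150, 300)
        path = _walk(rng, start, heading, int(n_steps), spec.shape, faz_c, keepout)
        if len(path) > 5:
            paths.append(path)
            # one branch per arcade, and a shorter grandchild off the branch
            for depth in range(2):
                parent = paths[-1]
                if len(parent) < 30:
                    break
                k = rng.integers(len(parent) // 3, len(parent) - 5)
                seg = parent[k + 1] - parent[k - 1]
                bh = np.arctan2(seg[0], seg[1]) + rng.choice([-1, 1]) * rng.uniform(0.4, 0.8)
                child = _walk(
                    rng, tuple(parent[k]), bh, int(n_steps // (2 * (depth + 1))),
                    spec.shape, faz_c, keepout,
                )
                if len(child) > 5:
                    paths.append(child)
                else:
                    break
    # perifoveal vessels converging radially on the FAZ rim (they terminate
    # there, which is what the endpoint-based FAZ segmentation relies on)
    n_radial = 16
    for i in range(n_radial):
        ang = 2 * np.pi * i / n_radial + rng.normal(0.0, 0.1)
        r0 = 3.2 * spec.faz_radius
        start = (faz_c[0] + r0 * np.sin(ang), faz_c[1] + r0 * np.cos(ang))
        start = (
            float(np.clip(start[0], 9, h - 9)),
            float(np.clip(start[1], 9, w - 9)),
        )
        heading = ang + np.pi  # inward
        path = _walk(rng, start, heading, 200, spec.shape, faz_c, keepout, wobble=0.03)
        if len(path) > 5:
            paths.append(path)
    # short perifoveal capillary segments scattered through the macular
    # annulus — their free tips populate the endpoint statistics the way a
    # real capillary plexus does; higher-grade dropout thins them
    n_cap = int(round(56 * spec.vessel_length_scale))
    outer = spec.faz_radius + 85.0  # fixed-width annulus: constant density
    for _ in range(n_cap):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(spec.faz_radius + 6.0, outer)
        start = (faz_c[0] + rad * np.sin(ang), faz_c[1] + rad * np.cos(ang))
        if not (9 <= start[0] < h - 9 and 9 <= start[1] < w - 9):
            continue
        path = _walk(
            rng, start, rng.uniform(0, 2 * np.pi), int(rng.integers(14, 30)),
            spec.shape, faz_c, keepout, wobble=0.05,
        )
        if len(path) > 5:
            paths.append(path)
    return paths


def _rasterize_centerlines(paths: Sequence[np.ndarray], shape: Tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for path in paths:
        # dense resampling so 2-px steps leave no gaps
        for a, b in zip(path[:-1], path[1:]):
            n = int(np.ceil(np.hypot(*(b - a)))) + 1
            rr = np.linspace(a[0], b[0], n).round().astype(int)
            cc = np.linspace(a[1], b[1], n).round().astype(int)
            mask[rr, cc] = True
    return mask


# ----------------------------------------------------------------------------
# rendering


def _radial_grid(shape: Tuple[int, int], center: Tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1])


def render_pair(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Render (ffa, color, truth); deterministic for a given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    faz_c = spec.resolved_faz_center()

    # vessel layer: unit-peak Gaussian cross-section around the centerlines
    paths = _vessel_centerlines(spec, rng)
    centerline = _rasterize_centerlines(paths, spec.shape)
    vessel_layer = ndimage.gaussian_filter(centerline.astype(float), spec.vessel_sigma)
    # normalize so a single straight vessel has unit peak (line of unit
    # impulses blurred with a 2D Gaussian peaks at 1/(sqrt(2*pi)*sigma));
    # crossings exceed 1 and are clipped at render time
    vessel_layer *= np.sqrt(2.0 * np.pi) * spec.vessel_sigma
    vessel_layer = np.clip(vessel_layer, 0.0, 1.0)
    vessel_mask = ndimage.binary_dilation(
        centerline, structure=disk(int(round(2 * spec.vessel_sigma)))
    )
    # enforce the avascular zone exactly in the truth
    faz_dist = _radial_grid(spec.shape, faz_c)
    vessel_mask &= faz_dist > spec.faz_radius

    # optic disc: bright plateau with a soft rim
    od_dist = _radial_grid(spec.shape, spec.od_center)
    od_layer = 1.0 / (1.0 + np.exp((od_dist - spec.od_radius) / 1.5))

    # vignetted background
    rr, cc = np.mgrid[0:h, 0:w]
    rho2 = ((rr - h / 2) / (h / 2)) ** 2 + ((cc - w / 2) / (w / 2)) ** 2
    vignette = 1.0 - spec.background_vignette_strength * rho2 / 2.0

    # perfusion glow: perfused retina fluoresces diffusely on FFA while the
    # avascular zone stays dark; approximated by blurred vessel density
    glow = ndimage.gaussian_filter(vessel_layer, 12.0)
    if glow.max() > 0:
        glow = glow / glow.max()
    ffa = (
        0.18 * vignette
        + 0.12 * glow
        + spec.vessel_contrast * vessel_layer
        + 0.45 * od_layer
    )

    # microaneurysms: small bright dots away from vessels and the disc
    ma_centers = _place_mas(spec, rng, vessel_mask, od_dist, faz_dist)
    for r0, c0 in ma_centers:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        ffa += spec.ma_contrast * np.exp(-d2 / (2.0 * (spec.ma_radius / 1.4) ** 2))

    # color fundus: dark-red background, pale disc, yellow exudates
    color = np.stack(
        [0.45 * vignette, 0.20 * vignette, 0.08 * vignette], axis=-1
    )
    color[..., 0] += 0.40 * od_layer
    color[..., 1] += 0.38 * od_layer
    color[..., 2] += 0.18 * od_layer
    color[..., 1] -= 0.08 * vessel_layer  # vessels faintly visible in color

    ex_mask = _place_exudates(spec, rng, od_dist)
    ex_soft = ndimage.gaussian_filter(ex_mask.astype(float), 1.0)
    color[..., 0] += spec.ex_contrast * ex_soft
    color[..., 1] += 0.9 * spec.ex_contrast * ex_soft

    clean_ffa = np.clip(ffa, 0.0, 1.0)
    clean_color = np.clip(color, 0.0, 1.0)
    ffa_noisy = np.clip(clean_ffa + rng.normal(0.0, spec.noise_sigma, spec.shape), 0.0, 1.0)
    color_noisy = np.clip(
        clean_color + rng.normal(0.0, spec.noise_sigma, clean_color.shape), 0.0, 1.0
    )

    angles = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    polygon = np.stack(
        [faz_c[0] + spec.faz_radius * np.sin(angles), faz_c[1] + spec.faz_radius * np.cos(angles)],
        axis=1,
    )
    truth = PhantomTruth(
        vessel_mask=vessel_mask,
        od_center=spec.od_center,
        od_radius=spec.od_radius,
        faz_center=faz_c,
        faz_radius=spec.faz_radius,
        faz_polygon=polygon,
        faz_area=float(np.pi * spec.faz_radius**2),
        ma_centers=np.asarray(ma_centers, dtype=float).reshape(-1, 2),
        ex_mask=ex_mask,
        ex_area=int(ex_mask.sum()),
        grade=spec.grade,
        clean_ffa=clean_ffa,
        clean_color=clean_color,
    )
    return ffa_noisy, color_noisy, truth


def _place_mas(
    spec: PhantomSpec,
    rng: np.random.Generator,
    vessel_mask: np.ndarray,
    od_dist: np.ndarray,
    faz_dist: np.ndarray,
) -> List[Tuple[float, float]]:
    if spec.n_mas == 0:
        return []
    h, w = spec.shape
    clearance = ndimage.distance_transform_edt(~vessel_mask)
    centers: List[Tuple[float, float]] = []
    n_near = int(round(spec.ma_near_faz_frac * spec.n_mas))
    faz_c = spec.resolved_faz_center()
    for i in range(spec.n_mas):
        for _ in range(2000):
            if i < n_near:
                # perifoveal: microaneurysms arise on capillaries, which the
                # avascular zone lacks, so sample the annulus around the FAZ
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(spec.faz_radius + 5.0, 1.9 * spec.faz_radius + 10.0)
                r0 = faz_c[0] + rad * np.sin(ang)
                c0 = faz_c[1] + rad * np.cos(ang)
            else:
                r0 = rng.uniform(25, h - 25)
                c0 = rng.uniform(25, w - 25)
            ri, ci = int(round(r0)), int(round(c0))
            if not (0 <= ri < h and 0 <= ci < w):
                continue
            if clearance[ri, ci] < 6 * spec.vessel_sigma:
                continue
            if od_dist[ri, ci] < spec.od_radius + 12:
                continue
            if centers and min(np.hypot(r0 - a, c0 - b) for a, b in centers) < 6 * spec.ma_radius:
                continue
            centers.append((r0, c0))
            break
    return centers


def _place_exudates(
    spec: PhantomSpec, rng: np.random.Generator, od_dist: np.ndarray
) -> np.ndarray:
    h, w = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_exs):
        for _ in range(300):
            r0 = rng.uniform(40, h - 40)
            c0 = rng.uniform(40, w - 40)
            if od_dist[int(r0), int(c0)] < spec.od_radius + 25:
                continue
            area = rng.uniform(*spec.ex_area_range)
            ratio = rng.uniform(0.7, 1.3)
            a = np.sqrt(area / np.pi * ratio)
            b = np.sqrt(area / np.pi / ratio)
            phi = rng.uniform(0, np.pi)
            dr, dc = rr - r0, cc - c0
            x = dr * np.cos(phi) + dc * np.sin(phi)
            y = -dr * np.sin(phi) + dc * np.cos(phi)
            blob = (x / a) ** 2 + (y / b) ** 2 <= 1.0
            if (mask & ndimage.binary_dilation(blob, structure=disk(6))).any():
                continue  # keep blobs separated so region counts are exact
            mask |= blob
            break
    return mask


# ----------------------------------------------------------------------------
# presets and feature-space cohorts


def grade_presets(grade: int, seed: int = 0) -> PhantomSpec:
    """Phantom parameters emulating the three severity groups.

    Grade 1 (no retinopathy): lesion-free, small circular FAZ, dense vessels.
    Grade 2 (mild/moderate): moderate microaneurysm/exudate load, enlarged
    FAZ.  Grade 3 (severe/proliferative): heavy exudate load, large FAZ,
    reduced vessel density.  FAZ radius increases and vessel count decreases
    with grade, matching the severity trends of the mean feature table.
    """
    if grade == 1:
        return PhantomSpec(n_vessels=14, faz_radius=28.0, n_mas=0, n_exs=0, seed=seed, grade=1)
    if grade == 2:
        return PhantomSpec(
            n_vessels=10, vessel_length_scale=0.8, faz_radius=38.0, n_mas=12,
            n_exs=3, ex_area_range=(60.0, 150.0), seed=seed, grade=2,
        )
    if grade == 3:
        return PhantomSpec(
            n_vessels=7, vessel_length_scale=0.6, faz_radius=50.0, n_mas=15,
            n_exs=6, ex_area_range=(150.0, 350.0), seed=seed, grade=3,
        )
    raise ValueError("grade must be 1, 2 or 3")


def sample_feature_cohort(
    n_per_grade: Tuple[int, int, int] = (30, 25, 15),
    cv: float = 0.10,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw a synthetic feature-space cohort around the per-grade means.

    Each feature is drawn independently from a log-normal distribution with
    the class-mean expectation and coefficient of variation ``cv`` (zero
    means stay exactly zero; count features are rounded).  Returns
    ``(features, labels)`` with shapes (n, 6) and (n,).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows: List[np.ndarray] = []
    labels: List[int] = []
    for grade, n in zip((1, 2, 3), n_per_grade):
        means = np.asarray(COHORT_FEATURE_MEANS[grade], dtype=float)
        for _ in range(n):
            if cv == 0:
                # degenerate draw: every vector equals the class mean exactly
                fv = means.copy()
            else:
                sigma2 = np.log1p(cv**2)
                mu = np.where(means > 0, np.log(np.where(means > 0, means, 1.0)) - sigma2 / 2, 0.0)
                draw = np.exp(rng.normal(mu, np.sqrt(sigma2)))
                fv = np.where(means > 0, draw, 0.0)
                fv[list(_COUNT_FEATURES)] = np.round(fv[list(_COUNT_FEATURES)])
            rows.append(fv)
            labels.append(grade)
    return np.asarray(rows), np.asarray(labels, dtype=int)
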