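"""Shared fixtures: phantom renders and segmentation products are cached at
session scope because rendering and segmenting a 576 x 720 retina phantom
costs seconds and many tests share the same inputs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from curvegrade.phantom import PhantomSpec, grade_presets, render_pair
from curvegrade.vessels import segment_vessels


@pytest.fixture(scope="session")
def clean_retina():
    """Lesion-free retina pair (grade-1 preset, seed 1) with truth."""
    return render_pair(grade_presets(1, seed=1))


@pytest.fixture(scope="session")
def clean_vessels(clean_retina):
    ffa, _, _ = clean_retina
    return segment_vessels(ffa, with_exclusion=True)


@pytest.fixture(scope="session")
def ma_retina():
    """Retina with 20 scattered off-vessel microaneurysm dots (seed 9)."""
    spec = dataclasses.replace(
        grade_presets(1, seed=9), n_mas=20, ma_near_faz_frac=0.0
    )
    return render_pair(spec)


@pytest.fixture(scope="session")
def ma_vessels(ma_retina):
    ffa, _, _ = ma_retina
    return segment_vessels(ffa, with_exclusion=True)


@pytest.fixture(scope="session")
def faz30_retina():
    """Retina with a radius-30 vessel-free FAZ disk (seed 11)."""
    spec = dataclasses.replace(grade_presets(1, seed=11), faz_radius=30.0)
    return render_pair(spec)


@pytest.fixture(scope="session")
def ex3_retina():
    """Color phantom with 3 planted exudate blobs off the disc (seed 7)."""
    spec = dataclasses.replace(grade_presets(2, seed=7), n_exs=3)
    return render_pair(spec)


@pytest.fixture(scope="session")
def small_disk_phantom():
    """Simple bright vessel-crossed disk phantom for optic-disc unit tests.

    A single disk (center (120, 200), radius 25) on a dark background,
    crossed by two vessel lines, with mild noise; the matching vessel mask
    covers the lines.
    """
    rng = np.random.default_rng(0)
    h, w = 576, 720
    rr, cc = np.mgrid[0:h, 0:w]
    img = np.full((h, w), 0.15)
    d = np.hypot(rr - 120, cc - 200)
    img += 0.55 / (1.0 + np.exp((d - 25) / 1.5))
    vessel_mask = np.zeros((h, w), dtype=bool)
    for slope in (0.3, -0.6):
        dist = np.abs((rr - 120) - slope * (cc - 200)) / np.hypot(1, slope)
        img += 0.4 * np.exp(-(dist**2) / (2 * 2.0**2))
        vessel_mask |= dist <= 4
    img = np.clip(img + rng.normal(0, 0.01, (h, w)), 0, 1)
    return img, vessel_mask
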