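"""Curvelet transform: reconstruction, linearity, energy, band editing."""

import numpy as np
import pytest

from curvegrade.curvelet import (
    fdct,
    ifdct,
    modify_bands,
    identity_rule,
    power_rule,
    highpass_amplify_rule,
    zero_rule,
    default_n_scales,
    save_coefficients,
    load_coefficients,
)


@pytest.mark.parametrize("shape,n_scales", [((64, 64), 3), ((128, 96), 4)])
def test_round_trip_is_exact(shape, n_scales):
    rng = np.random.default_rng(7)
    x = rng.random(shape)
    y = ifdct(fdct(x, n_scales))
    assert np.abs(y - x).max() < 1e-6


def test_zero_image_gives_zero_bands():
    coeffs = fdct(np.zeros((64, 64)), 4)
    assert all(np.abs(b).max() == 0 for b in coeffs.bands.values())


def test_coarsest_scale_has_one_wedge():
    coeffs = fdct(np.random.default_rng(0).random((64, 64)), 4)
    counts = coeffs.wedge_counts()
    assert counts[0] == 1
    assert counts[-1] == 1  # isotropic band at the finest scale too
    assert counts[1] == 16


def test_energy_conservation():
    rng = np.random.default_rng(3)
    x = rng.random((64, 64))
    coeffs = fdct(x, 3)
    assert abs(coeffs.energy() - np.sum(x**2)) / np.sum(x**2) < 0.01


def test_linearity():
    rng = np.random.default_rng(5)
    x, y = rng.random((64, 64)), rng.random((64, 64))
    ca, cb, cab = fdct(x, 3), fdct(y, 3), fdct(2.0 * x + 3.0 * y, 3)
    for key in cab.bands:
        np.testing.assert_allclose(
            cab.bands[key], 2.0 * ca.bands[key] + 3.0 * cb.bands[key], atol=1e-8
        )


def test_image_too_small_raises():
    with pytest.raises(ValueError):
        fdct(np.zeros((16, 16)), 6)


def test_bad_angle_count_raises():
    with pytest.raises(ValueError):
        fdct(np.zeros((64, 64)), 3, n_angles_coarse=6)


def test_default_scale_count():
    assert default_n_scales((64, 64)) == 3
    assert default_n_scales((576, 720)) == 7


def test_identity_rule_is_bit_identical():
    coeffs = fdct(np.random.default_rng(1).random((64, 64)), 3)
    out = modify_bands(coeffs, identity_rule)
    for key in coeffs.bands:
        assert np.array_equal(out.bands[key], coeffs.bands[key])


def test_zero_rule_reconstructs_zero():
    coeffs = fdct(np.random.default_rng(2).random((64, 64)), 3)
    rec = ifdct(modify_bands(coeffs, zero_rule))
    assert np.abs(rec).max() < 1e-12


def test_power_rule_p1_is_identity_up_to_roundoff():
    x = np.random.default_rng(4).random((64, 64))
    rec = ifdct(modify_bands(fdct(x, 3), power_rule(1.0)))
    assert np.abs(rec - x).max() < 1e-6


def test_modify_bands_preserves_phase():
    coeffs = fdct(np.random.default_rng(6).random((64, 64)), 3)
    out = modify_bands(coeffs, power_rule(5.0))
    for key in coeffs.bands:
        c, m = coeffs.bands[key], out.bands[key]
        both = (np.abs(c) > 1e-12) & (np.abs(m) > 1e-12)
        phase_diff = np.angle(c[both]) - np.angle(m[both])
        assert np.abs(np.angle(np.exp(1j * phase_diff))).max() < 1e-9


def test_zero_coarse_of_constant_reconstructs_near_zero():
    const = np.full((64, 64), 0.7)
    coeffs = fdct(const, 3)

    def drop_coarse(scale, wedge, mag):
        return np.zeros_like(mag) if scale == 0 else mag

    rec = ifdct(modify_bands(coeffs, drop_coarse))
    assert np.abs(rec).max() < 1e-3 * 0.7


def test_power5_amplifies_bright_structures():
    """Fifth-power band magnitudes raise the bright-region (top-decile)
    mean relative to the global mean in the renormalized reconstruction
    (bright-object amplification on a disk phantom)."""
    rng = np.random.default_rng(0)
    rr, cc = np.mgrid[0:128, 0:128]
    disk = np.hypot(rr - 64, cc - 64) < 18
    img = np.clip(0.15 + 0.5 * disk + 0.01 * rng.standard_normal((128, 128)), 0, 1)
    rec = ifdct(modify_bands(fdct(img), power_rule(5.0)))
    rec = (rec - rec.min()) / (rec.max() - rec.min())
    top = np.quantile(img, 0.9)
    ratio_before = img[img >= top].mean() / img.mean()
    ratio_after = rec[img >= top].mean() / rec.mean()
    assert ratio_after > ratio_before


def test_highpass_rule_zeroes_coarse_and_scales_rest():
    coeffs = fdct(np.random.default_rng(8).random((64, 64)), 3)
    out = modify_bands(coeffs, highpass_amplify_rule(2.0))
    assert np.abs(out.bands[(0, 0)]).max() == 0
    for (s, w), c in coeffs.bands.items():
        if s > 0:
            np.testing.assert_allclose(np.abs(out.bands[(s, w)]), 2.0 * np.abs(c), atol=1e-12)


def test_nonfinite_rule_raises():
    coeffs = fdct(np.random.default_rng(9).random((64, 64)), 3)
    with pytest.raises(FloatingPointError), np.errstate(divide="ignore"):
        modify_bands(coeffs, lambda s, w, m: m / 0.0)


def test_serialization_round_trip(tmp_path):
    coeffs = fdct(np.random.default_rng(10).random((64, 64)), 3)
    path = tmp_path / "coeffs.npz"
    save_coefficients(coeffs, path)
    loaded = load_coefficients(path)
    assert loaded.source_shape == tuple(coeffs.source_shape)
    for key in coeffs.bands:
        np.testing.assert_array_equal(loaded.bands[key], coeffs.bands[key])
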