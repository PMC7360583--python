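"""Pixel-level primitives: filters, thresholds, morphology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from angioquant.raster import (
    DegenerateImageError,
    auto_threshold,
    binary_morphology,
    disk_footprint,
    fft_bandpass,
    flatfield_correct,
    log_enhance,
    subtract_modal,
    variance_filter,
)


def test_flatfield_of_constant_is_one():
    img = np.full((32, 32), 7.5)
    out = flatfield_correct(img, sigma=5)
    assert np.allclose(out, 1.0)


def test_flatfield_removes_smooth_gradient():
    # flat texture times a smooth multiplicative ramp: correction should
    # recover the texture (normalized to mean 1) within 5%
    rng = np.random.default_rng(0)
    texture = 1.0 + 0.05 * rng.standard_normal((128, 128))
    ramp = np.linspace(0.6, 1.4, 128)[None, :] * np.ones((128, 1))
    out = flatfield_correct(texture * ramp, sigma=10)
    expected = texture / texture.mean()
    inner = (slice(16, -16), slice(16, -16))
    assert np.all(np.abs(out[inner] - expected[inner]) / expected[inner] < 0.05)


def test_flatfield_rejects_all_zero_image():
    with pytest.raises(DegenerateImageError):
        flatfield_correct(np.zeros((32, 32)), sigma=4)


def test_variance_of_constant_is_zero():
    out = variance_filter(np.full((24, 24), 3.0), radius=2)
    assert np.allclose(out, 0.0)


def test_variance_single_bright_pixel_matches_hand_computation():
    # 13-pixel circular neighborhood of radius 2; any window containing
    # the lone bright pixel has variance 12 v^2 / 169
    v = 5.0
    img = np.zeros((21, 21))
    img[10, 10] = v
    out = variance_filter(img, radius=2)
    expected = 12.0 * v * v / 169.0
    assert out[10, 10] == pytest.approx(expected)
    assert out.max() == pytest.approx(expected)
    assert out[10, 14] == pytest.approx(0.0)  # window excludes the pixel


def test_variance_ridge_along_step_edge():
    img = np.zeros((20, 20))
    img[:, 10:] = 1.0
    out = variance_filter(img, radius=2)
    assert out[10, 10] > 0.1
    assert out[10, 2] == pytest.approx(0.0)
    assert out[10, 17] == pytest.approx(0.0)


def test_log_enhance_is_monotone_and_finite_at_zero():
    out = log_enhance(np.tile([0.0, 1.0, 10.0, 100.0], (16, 4)))
    row = out[0, :4]
    assert np.all(np.isfinite(out))
    assert row[1] < row[2] < row[3]
    # concavity: the slope between successive inputs decreases
    assert (row[2] - row[1]) / 9.0 > (row[3] - row[2]) / 90.0


def test_bandpass_requires_ordered_cutoffs():
    with pytest.raises(ValueError):
        fft_bandpass(np.ones((32, 32)), v1=5, v2=5)


def test_bandpass_constant_goes_to_zero():
    out = fft_bandpass(np.full((64, 64), 3.0), v1=2, v2=16)
    assert np.allclose(out, 0.0, atol=1e-9)


@pytest.mark.parametrize("wavelength,expect_pass", [(20.0, True), (400.0, False)])
def test_bandpass_sinusoid_amplitude(wavelength, expect_pass):
    # v1=4, v2=100: mid-band wavelengths survive, structures much larger
    # than v2 are suppressed below 20%
    x = np.arange(600)
    img = 1.0 + 0.5 * np.sin(2 * np.pi * x / wavelength)
    img = np.tile(img, (32, 1))
    out = fft_bandpass(img, v1=4, v2=100)
    amp = 0.5 * (out[16, 150:450].max() - out[16, 150:450].min())
    ratio = amp / 0.5
    if expect_pass:
        assert ratio > 0.8
    else:
        assert ratio < 0.2


def test_bandpass_linearity(rng):
    a = rng.random((48, 48))
    b = rng.random((48, 48))
    lhs = fft_bandpass(2.0 * a + 3.0 * b, 2, 12)
    rhs = 2.0 * fft_bandpass(a, 2, 12) + 3.0 * fft_bandpass(b, 2, 12)
    assert np.allclose(lhs, rhs, atol=1e-9)


def test_subtract_modal_zeroes_background():
    img = np.full((20, 20), 7.0)
    img[5:8, 5:8] = 200.0
    out = subtract_modal(img)
    assert out[0, 0] == pytest.approx(0.0, abs=1.0)
    assert out[6, 6] == pytest.approx(193.0, abs=1.0)


def test_subtract_modal_noise_has_zero_mode(rng):
    out = subtract_modal(rng.uniform(10, 20, size=(64, 64)))
    assert np.all(out >= 0)
    counts, edges = np.histogram(out, bins=64)
    assert np.argmax(counts) == 0


def test_mean_and_isodata_threshold_two_level_image():
    img = np.zeros((20, 20))
    img[:, 10:] = 200.0
    img[:, :10] = 10.0
    for method in ("mean", "isodata"):
        mask, t = auto_threshold(img, method, return_threshold=True)
        assert t == pytest.approx(105.0)
        assert mask.sum() == 200 and mask[:, 10:].all()


def test_minimum_threshold_finds_intermode_valley(rng):
    lo = rng.normal(50, 8, size=4000)
    hi = rng.normal(180, 8, size=4000)
    img = np.concatenate([lo, hi]).reshape(80, 100)
    _, t = auto_threshold(img, "minimum", return_threshold=True)
    assert 50 + 0.4 * 130 <= t <= 50 + 0.6 * 130


def test_minimum_threshold_rejects_flat_histogram():
    with pytest.raises(ValueError):
        auto_threshold(np.full((20, 20), 3.0), "minimum")


@given(st.integers(0, 1000))
@settings(max_examples=25, deadline=None)
def test_mean_isodata_invariant_to_affine_rescale(seed):
    rng = np.random.default_rng(seed)
    img = rng.random((24, 24)) * 100
    a, b = 2.5, 17.0
    for method in ("mean", "isodata"):
        m1 = auto_threshold(img, method)
        m2 = auto_threshold(a * img + b, method)
        assert np.array_equal(m1, m2)


def test_fill_holes_closes_interior():
    mask = disk_footprint(8).copy()
    mask[7:10, 7:10] = False
    out = binary_morphology(mask, "fill_holes")
    assert np.array_equal(out, disk_footprint(8))


@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_morphology_idempotence_and_duality(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((28, 28)) > 0.6
    for op in ("open", "close", "fill_holes"):
        once = binary_morphology(mask, op)
        assert np.array_equal(binary_morphology(once, op), once)
    # dilation of the mask = complement of erosion of the complement
    dil = binary_morphology(mask, "dilate")
    dual = ~ndi.binary_erosion(~mask, np.ones((3, 3), bool), border_value=1)
    assert np.array_equal(dil, dual)


def test_dilate_disk_grows_by_annulus_area():
    mask = np.zeros((40, 40), dtype=bool)
    yy, xx = np.mgrid[0:40, 0:40]
    mask[(yy - 20) ** 2 + (xx - 20) ** 2 <= 100] = True
    grown = binary_morphology(mask, "maximum_filter", radius=2)
    # compare effective (area-equivalent) radii: dilation by a disk of
    # radius 2 should grow the radius by 2, up to discretization
    r_before = np.sqrt(mask.sum() / np.pi)
    r_after = np.sqrt(grown.sum() / np.pi)
    assert r_after - r_before == pytest.approx(2.0, rel=0.10)
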