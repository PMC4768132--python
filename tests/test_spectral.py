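"""Averaged PSDF estimator: analytic oracles and invariances."""

import math

import numpy as np
import pytest

import helixpsd as h
from helixpsd.scene import HeightMap
from helixpsd.spectral import peak_snr

BOX = h.BoxSelection(0, 8, 0, 128, "rows")


def _map(lines: np.ndarray, px: float = 1.0) -> HeightMap:
    return HeightMap(np.asarray(lines, dtype=float), px)


def test_constant_lines_zero_power():
    res = h.averaged_psdf(_map(np.full((8, 128), 3.7)), BOX)
    assert np.all(res.power == 0.0)
    assert res.wavenumbers[0] == pytest.approx(res.dk)


def test_pure_cosine_single_bin_and_parseval():
    n, a, period = 128, 0.8, 8  # period divides n: zero leakage
    x = np.arange(n)
    lines = np.tile(a * np.cos(2 * np.pi * x / period), (8, 1))
    res = h.averaged_psdf(_map(lines), BOX)
    i = res.nearest_bin(2 * np.pi / period)
    assert res.wavenumbers[i] == pytest.approx(2 * np.pi / period, rel=1e-12)
    mask = np.ones(res.power.size, bool)
    mask[i] = False
    assert np.all(res.power[mask] < 1e-20)
    # Parseval: total power integrates to the line variance a^2/2
    assert np.sum(res.power) * res.dk == pytest.approx(a * a / 2, rel=1e-12)


def test_offgrid_sinusoid_peaks_at_nearest_bin():
    n = 128
    k_true = 2 * np.pi * 10.3 / n  # between bins 10 and 11 (px = 1)
    x = np.arange(n)
    lines = np.tile(np.sin(k_true * x), (8, 1))
    res = h.averaged_psdf(_map(lines), BOX)
    i_expect = res.nearest_bin(k_true)
    assert int(np.argmax(res.power)) == i_expect


def test_parseval_on_arbitrary_data():
    rng = np.random.default_rng(21)
    lines = rng.normal(size=(8, 128)) + rng.normal(size=(8, 1))
    res = h.averaged_psdf(_map(lines), BOX)
    var = ((lines - lines.mean(axis=1, keepdims=True)) ** 2).mean(axis=1).mean()
    assert abs(np.sum(res.power) * res.dk - var) < 1e-9


def test_hann_window_preserves_broadband_power():
    rng = np.random.default_rng(22)
    lines = rng.normal(size=(64, 512))
    hm = _map(lines)
    box = h.BoxSelection(0, 64, 0, 512, "rows")
    plain = h.averaged_psdf(hm, box)
    hann = h.averaged_psdf(hm, box, window="hann")
    assert np.sum(hann.power) == pytest.approx(np.sum(plain.power), rel=0.05)


def test_white_noise_floor_level():
    # white noise of variance s^2 has a flat one-sided PSDF at s^2 / k_nyq
    rng = np.random.default_rng(23)
    s = 0.12
    lines = rng.normal(scale=s, size=(512, 256))
    res = h.averaged_psdf(_map(lines, px=0.5), h.BoxSelection(0, 512, 0, 256, "rows"))
    expect = s * s / res.k_nyquist
    assert np.median(res.power) == pytest.approx(expect, rel=0.05)


def test_offset_and_line_order_invariance():
    rng = np.random.default_rng(24)
    lines = rng.normal(size=(8, 128))
    a = h.averaged_psdf(_map(lines), BOX)
    b = h.averaged_psdf(_map(lines + 100.0), BOX)
    c = h.averaged_psdf(_map(lines[::-1]), BOX)
    assert np.allclose(a.power, b.power, atol=1e-9)
    assert np.allclose(a.power, c.power, atol=1e-12)


def test_column_direction_transposes():
    rng = np.random.default_rng(25)
    vals = rng.normal(size=(128, 8))
    res_c = h.averaged_psdf(_map(vals), h.BoxSelection(0, 128, 0, 8, "columns"))
    res_r = h.averaged_psdf(_map(vals.T), BOX)
    assert np.allclose(res_c.power, res_r.power, atol=1e-12)


def test_box_validation():
    with pytest.raises(ValueError, match="at least"):
        h.BoxSelection(0, 2, 0, 128, "rows")  # too few lines
    with pytest.raises(ValueError, match="at least"):
        h.BoxSelection(0, 8, 0, 8, "rows")  # lines too short
    with pytest.raises(ValueError):
        h.BoxSelection(4, 4, 0, 128, "rows")  # empty range
    with pytest.raises(ValueError):
        h.BoxSelection(0, 8, 0, 128, "diagonal")
    with pytest.raises(ValueError, match="outside image"):
        h.averaged_psdf(_map(np.zeros((4, 64))), BOX)


def test_peak_snr_flat_spectrum_is_one():
    lines = np.random.default_rng(26).normal(size=(2048, 64))
    res = h.averaged_psdf(_map(lines), h.BoxSelection(0, 2048, 0, 64, "rows"))
    snrs = [peak_snr(res, i) for i in range(5, res.power.size - 5)]
    assert np.median(snrs) == pytest.approx(1.0, abs=0.1)


def _ripple_map(k: float, where: str, rng) -> HeightMap:
    """200x128 map with a k-ripple in rows 0:8 ('signal'), 100:108 too if 'both'."""
    vals = rng.normal(scale=0.1, size=(200, 128))
    x = np.arange(128)
    ripple = 0.5 * np.cos(k * x)
    vals[0:8] += ripple
    if where == "both":
        vals[100:108] += ripple
    return HeightMap(vals, 1.0)


def test_compare_background_flags():
    k = 2 * np.pi * 16 / 128
    rng = np.random.default_rng(27)
    hm = _ripple_map(k, "signal", rng)
    sig = h.averaged_psdf(hm, h.BoxSelection(0, 8, 0, 128, "rows"))
    bg = h.averaged_psdf(hm, h.BoxSelection(100, 108, 0, 128, "rows"))
    assert h.compare_background(sig, bg, [k])[k] == "signal-specific"
    # identical boxes: everything is in the background by construction
    assert h.compare_background(sig, sig, [k])[k] == "also-in-background"
    # ripple present in both boxes
    hm2 = _ripple_map(k, "both", rng)
    sig2 = h.averaged_psdf(hm2, h.BoxSelection(0, 8, 0, 128, "rows"))
    bg2 = h.averaged_psdf(hm2, h.BoxSelection(100, 108, 0, 128, "rows"))
    assert h.compare_background(sig2, bg2, [k])[k] == "also-in-background"


def test_compare_background_grid_mismatch():
    rng = np.random.default_rng(28)
    a = h.averaged_psdf(_map(rng.normal(size=(8, 128))), BOX)
    b = h.averaged_psdf(
        _map(rng.normal(size=(8, 64))), h.BoxSelection(0, 8, 0, 64, "rows")
    )
    with pytest.raises(ValueError, match="grid"):
        h.compare_background(a, b, [0.5])


def test_optimize_box_improves_and_is_fixed_point():
    rng = np.random.default_rng(29)
    k = 2 * np.pi * 16 / 128
    hm = _ripple_map(k, "signal", rng)
    seed_box = h.BoxSelection(0, 30, 0, 128, "rows")  # mostly noise lines
    best = h.optimize_box(hm, seed_box, k)

    def snr_of(box):
        res = h.averaged_psdf(hm, box)
        return peak_snr(res, res.nearest_bin(k))

    assert snr_of(best) >= snr_of(seed_box)
    again = h.optimize_box(hm, best, k)
    assert again == best  # local maximum is stable
    assert best.within(hm.shape)
    with pytest.raises(ValueError, match="resolvable band"):
        h.optimize_box(hm, seed_box, 10 * math.pi)
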