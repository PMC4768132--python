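"""Synthetic scene generator: exact geometry, noise statistics, channels."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

import helixpsd as h

BARE = h.SceneSpec(
    helix=h.HelixParameters(length_nm=200.0),
    corrugation_amplitude_nm=0.0,
    substrate_rms_nm=0.0,
    aggregate_density_per_um2=0.0,
    image_size_px=(512, 512),
    pixel_size_nm=0.5,
)


def test_bare_cylinder_apparent_height_exact():
    hm = h.render_scene(BARE, seed=0)
    assert hm.values.max() == pytest.approx(14.0, abs=1e-12)
    # substrate exactly flat at zero
    assert hm.values.min() == 0.0


def test_default_scene_height_near_14(noiseless_map):
    # corrugation (amplitude 0.2 nm) rides on the 14 nm crest
    assert noiseless_map.values.max() == pytest.approx(14.0, abs=0.3)


def test_cylinder_profile_shape():
    hm = h.render_scene(BARE, seed=0)
    # transverse profile through the crest is the z-compressed circle
    nrows, ncols = hm.values.shape
    crest_col = int(np.argmax(hm.values.mean(axis=0)))
    row = nrows // 2
    t = (np.arange(ncols) - ncols // 2) * BARE.pixel_size_nm
    expect = np.where(
        np.abs(t) <= 9.0,
        (9.0 + np.sqrt(np.clip(81.0 - t**2, 0, None))) * (14.0 / 18.0),
        0.0,
    )
    assert np.allclose(hm.values[row], expect, atol=1e-9)
    assert crest_col == ncols // 2


def test_substrate_rms():
    spec = replace(BARE, substrate_rms_nm=0.4)
    hm = h.render_scene(spec, seed=5)
    off = hm.values[:, :150]  # far from the vertical virion footprint
    assert off.std() == pytest.approx(0.4, rel=0.05)


def test_aggregates_only_off_virion():
    spec = replace(BARE, aggregate_density_per_um2=60.0)
    hm = h.render_scene(spec, seed=2)
    base = h.render_scene(BARE, seed=2)
    diff = hm.values - base.values
    ncols = hm.values.shape[1]
    t = np.abs((np.arange(ncols) - ncols // 2) * spec.pixel_size_nm)
    on_virion = t <= 9.0
    assert np.all(diff[:, on_virion] == 0.0)
    assert diff.max() > 2.0  # at least one aggregate cap landed


def test_add_noise_zero_is_identity(noiseless_map):
    out = h.add_noise(noiseless_map, h.NoiseSpec())
    assert np.array_equal(out.values, noiseless_map.values)


def test_add_noise_white_rms_and_determinism():
    flat = h.HeightMap(np.zeros((256, 256)), 0.5)
    spec = h.NoiseSpec(white_rms_nm=0.12, seed=9)
    a = h.add_noise(flat, spec)
    b = h.add_noise(flat, spec)
    c = h.add_noise(flat, replace(spec, seed=10))
    assert a.values.std() == pytest.approx(0.12, rel=0.05)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_add_noise_line_offsets_constant_per_row():
    flat = h.HeightMap(np.zeros((64, 64)), 0.5)
    out = h.add_noise(flat, h.NoiseSpec(line_offset_rms_nm=0.05, seed=1))
    assert np.allclose(out.values.std(axis=1), 0.0, atol=1e-12)
    assert out.values.std() > 0


def test_render_determinism(noiseless_map):
    again = h.render_scene(h.scene_preset("noiseless"), seed=0)
    assert np.array_equal(again.values, noiseless_map.values)


def test_make_channels_zero_noise_identical():
    zero = h.NoiseSpec()
    topo, mode2 = h.make_channels(BARE, zero, zero, scene_seed=0)
    assert np.array_equal(topo.values, mode2.values)
    assert topo.channel_label == "topography"
    assert mode2.channel_label == "mode2-like"


def test_make_channels_jitter_ordering_enforced():
    with pytest.raises(ValueError, match="jitter"):
        h.make_channels(
            BARE,
            h.NoiseSpec(axial_jitter_rms_nm=0.1),
            h.NoiseSpec(axial_jitter_rms_nm=2.0),
            scene_seed=0,
        )


def test_render_jitter_decorrelates_lines():
    spec = replace(BARE, corrugation_amplitude_nm=0.2)
    calm = h.render_scene(spec, seed=0)
    jittered = h.render_scene(spec, seed=0, axial_jitter_rms_nm=2.0, jitter_seed=4)
    ncols = calm.values.shape[1]
    crest = ncols // 2
    # the crest column differs once the corrugation phase jitters per sample
    assert not np.array_equal(calm.values[:, crest], jittered.values[:, crest])
    # but the underlying cylinder (corrugation-free regions) is untouched
    assert np.array_equal(calm.values[:, 0], jittered.values[:, 0])


def test_crest_periodicities(noiseless_map):
    """Both lattice periodicities are present along the crest line; the
    three-turn repeat (6.9 nm) dominates the autocorrelation and the
    single-turn pitch (2.3 nm, k = 2.73 1/nm) shows as a spectral local
    maximum."""
    vals = noiseless_map.values
    crest = vals[:, vals.shape[1] // 2]
    x = crest - crest.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    ac /= ac[0]
    px = noiseless_map.pixel_size_nm
    lag_min = int(round(3.0 / px))  # skip the zero-lag peak's shoulder
    lag_max = int(round(20.0 / px))
    best_lag = lag_min + int(np.argmax(ac[lag_min : lag_max + 1]))
    assert best_lag * px == pytest.approx(6.9, abs=px)

    spec = np.abs(np.fft.rfft(x)) ** 2
    k = np.arange(spec.size) * 2 * np.pi / (x.size * px)
    i = int(np.argmin(np.abs(k - h.wavenumber_of(2.3))))
    assert spec[i] > spec[i - 2] and spec[i] > spec[i + 2]


def test_scene_validation():
    with pytest.raises(ValueError, match="Nyquist"):
        h.SceneSpec(pixel_size_nm=1.2)
    with pytest.raises(ValueError, match="apparent height"):
        h.SceneSpec(apparent_height_nm=19.0)
    with pytest.raises(ValueError):
        h.NoiseSpec(white_rms_nm=-0.1)


def test_clipping_warns():
    spec = replace(BARE, helix=h.HelixParameters(length_nm=400.0))
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        with pytest.raises(UserWarning, match="clipping"):
            h.render_scene(spec, seed=0)
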