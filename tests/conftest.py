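"""Shared fixtures: expensive renders are built once per session."""

from __future__ import annotations

import warnings
from dataclasses import replace

import pytest

import helixpsd as h


@pytest.fixture(scope="session")
def noiseless_map():
    """Noiseless default vertical virion (no substrate roughness/aggregates)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return h.render_scene(h.scene_preset("noiseless"), seed=0)


@pytest.fixture(scope="session")
def noiseless_dilated(noiseless_map):
    """Noiseless scene imaged with a 2 nm spherical tip."""
    tip = h.build_tip("sphere", 2.0, noiseless_map.pixel_size_nm)
    return h.dilate(noiseless_map, tip)


@pytest.fixture(scope="session")
def seed0_channels():
    """(topography, mode2-like) default channels, scene seed 0, pipeline seeds."""
    spec = h.scene_preset("paper-default")
    topo_noise = replace(h.TOPO_NOISE, seed=1)
    mode2_noise = replace(h.MODE2_NOISE, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return h.make_channels(spec, topo_noise, mode2_noise, scene_seed=0)
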