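"""Frozen scene and noise presets.

The channel noise levels emulate the empirical contrast between channels:
the topography channel carries strong line-to-line phase jitter of the
surface corrugation (masking the lattice periodicity) plus ordinary
measurement noise, while the second-mode-like channel is nearly jitter-free
with a low white floor, so the three-turn repeat is detectable there and
not in topography.  The levels were calibrated once against the default
scene and are frozen here; they are study conditions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import replace

from .helix import HelixParameters
from .scene import NoiseSpec, SceneSpec

__all__ = [
    "DEFAULT_HELIX",
    "DEFAULT_SCENE",
    "TOPO_NOISE",
    "MODE2_NOISE",
    "scene_preset",
    "noise_presets",
]

DEFAULT_HELIX = HelixParameters(length_nm=380.0)

#: default synthetic scene: vertical virion spanning a 360 x 128 nm frame
#: (no end caps inside the frame, so axis-aligned analysis lines carry no
#: step edges), 0.5 nm pixels, TMV-like corrugation
DEFAULT_SCENE = SceneSpec(
    helix=DEFAULT_HELIX,
    orientation_deg=90.0,
    image_size_px=(720, 256),
)

#: topography channel: high corrugation phase jitter + white noise
TOPO_NOISE = NoiseSpec(white_rms_nm=0.12, line_offset_rms_nm=0.05, axial_jitter_rms_nm=2.0, seed=0)

#: second-mode-like channel: low jitter, low white floor
MODE2_NOISE = NoiseSpec(white_rms_nm=0.08, line_offset_rms_nm=0.0, axial_jitter_rms_nm=0.1, seed=0)


def scene_preset(name: str) -> SceneSpec:
    """Named scene presets used by the CLI and the pipeline."""
    if name in ("paper-default", "default", "vertical"):
        return DEFAULT_SCENE
    if name == "horizontal":
        return replace(
            DEFAULT_SCENE,
            orientation_deg=0.0,
            image_size_px=(256, 720),
        )
    if name == "noiseless":
        return replace(DEFAULT_SCENE, substrate_rms_nm=0.0, aggregate_density_per_um2=0.0)
    raise ValueError(f"unknown scene preset {name!r}")


def noise_presets(name: str) -> tuple[NoiseSpec, NoiseSpec]:
    """(topography, mode2-like) noise presets for a named scene preset."""
    if name == "noiseless":
        z = NoiseSpec()
        return z, z
    return TOPO_NOISE, MODE2_NOISE
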