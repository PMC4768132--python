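"""End-to-end orchestration: simulate or load, analyse, report.

Coordinate convention everywhere: row-major, origin top-left, 0-based,
half-open box ranges.  Topography maps are analysed unflattened; computing
a spectrum on a line-flattened map is refused, since per-line flattening
removes exactly the per-line periodic content the analysis looks for.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .helix import HelixParameters
from .io import read_heightmap, write_heightmap
from .model import SurfacePeriodicity
from .presets import noise_presets, scene_preset
from .scene import HeightMap, make_channels
from .spectral import BoxSelection
from .tip import build_tip, dilate

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("helixpsd")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (flat key=value file)."""

    preset: str = "paper-default"  # simulation preset, or "file" to load
    input_path: str = ""  # height-map file when preset == "file"
    seed: int = 0
    channel: str = "mode2-like"  # topography | mode2-like
    signal_box: str = "auto"  # "r0:r1,c0:c1" or "auto"
    background_box: str = "auto"
    line_direction: str = "auto"  # rows | columns | auto
    window: str = "none"
    snr_threshold: float = 3.0
    max_harmonic: int = 4
    tip_model: str = "none"  # none | sphere | paraboloid | point
    tip_radius_nm: float = 0.0
    pitch_nm: float = 2.3
    subunits_per_three_turns: int = 49
    outer_radius_nm: float = 9.0
    output_dir: str = "helixpsd_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        ftypes = {f.name: f.type for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in ftypes:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            typ = ftypes[key]
            if typ in ("int", int):
                kwargs[key] = int(val)
            elif typ in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_text(self) -> str:
        lines = [f"{k} = {v}" for k, v in sorted(asdict(self).items())]
        return "\n".join(lines) + "\n"

    @property
    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        lines = [
            f"{k} = {v}" for k, v in sorted(asdict(self).items()) if k != "output_dir"
        ]
        return hashlib.sha256("\n".join(lines).encode()).hexdigest()[:16]

    def helix(self) -> HelixParameters:
        return HelixParameters(
            pitch_nm=self.pitch_nm,
            subunits_per_three_turns=self.subunits_per_three_turns,
            outer_radius_nm=self.outer_radius_nm,
        )


def _parse_box(text: str, direction: str) -> BoxSelection | None:
    if text == "auto":
        return None
    try:
        rows, cols = text.split(",")
        r0, r1 = (int(v) for v in rows.split(":"))
        c0, c1 = (int(v) for v in cols.split(":"))
    except ValueError as exc:
        raise ValueError(f"bad box spec {text!r}; expected r0:r1,c0:c1") from exc
    return BoxSelection(r0, r1, c0, c1, direction)


def _acquire(config: RunConfig) -> HeightMap:
    if config.preset == "file":
        if not config.input_path:
            raise PipelineError("input stage: preset 'file' needs input_path")
        hm = read_heightmap(config.input_path)
        if str(hm.metadata.get("flattened", "")).lower() in ("1", "true", "line"):
            raise PipelineError(
                "input stage: refusing to analyse a line-flattened map -- "
                "flattening removes the per-line periodic content"
            )
        return hm
    spec = scene_preset(config.preset)
    topo_noise, mode2_noise = noise_presets(config.preset)
    from dataclasses import replace

    topo_noise = replace(topo_noise, seed=config.seed * 2 + 1)
    mode2_noise = replace(mode2_noise, seed=config.seed * 2 + 2)
    topo, mode2 = make_channels(spec, topo_noise, mode2_noise, scene_seed=config.seed)
    if config.channel == "topography":
        return topo
    if config.channel == "mode2-like":
        return mode2
    raise PipelineError(f"input stage: unknown channel {config.channel!r}")


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    log.info("acquiring input (preset=%s seed=%d)", config.preset, config.seed)
    hm = _acquire(config)

    if config.tip_model != "none":
        log.info("dilating with %s tip R=%g nm", config.tip_model, config.tip_radius_nm)
        try:
            hm = dilate(hm, build_tip(config.tip_model, config.tip_radius_nm, hm.pixel_size_nm))
        except ValueError as exc:
            raise PipelineError(f"tip stage: {exc}") from exc

    direction = None if config.line_direction == "auto" else config.line_direction
    try:
        model = SurfacePeriodicity(
            hm,
            signal_box=_parse_box(config.signal_box, direction or "rows"),
            background_box=_parse_box(config.background_box, direction or "rows"),
            helix=config.helix(),
            line_direction=direction,
        )
        result = model.fit(
            snr_threshold=config.snr_threshold,
            window=config.window,
            max_harmonic=config.max_harmonic,
        )
    except ValueError as exc:
        raise PipelineError(f"analysis stage: {exc}") from exc

    sig_box = result.psdf.box
    report = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "channel": hm.channel_label,
        "coordinate_convention": "row-major, origin top-left, 0-based, half-open ranges",
        "signal_box": [sig_box.row0, sig_box.row1, sig_box.col0, sig_box.col1],
        "background_box": [
            result.background_psdf.box.row0,
            result.background_psdf.box.row1,
            result.background_psdf.box.col0,
            result.background_psdf.box.col1,
        ],
        "line_direction": sig_box.line_direction,
        "window": config.window,
        "snr_threshold": config.snr_threshold,
        "dk_inv_nm": result.psdf.dk,
        "peaks": [
            {
                "k_inv_nm": pk.wavenumber_inv_nm,
                "distance_nm": pk.distance_nm,
                "power_nm3": pk.power,
                "snr": pk.snr,
                "flag": result.flags.get(pk.wavenumber_inv_nm, "unchecked"),
                "harmonic_m": result.harmonics.assigned.get(pk),
            }
            for pk in result.peaks.peaks
        ],
        "harmonics": {
            "fundamental_k_inv_nm": result.harmonics.fundamental_k,
            "missing": list(result.harmonics.missing),
            "power_ratios": {str(m): r for m, r in result.harmonics.harmonic_power_ratios.items()},
        },
        "correlation_length_nm": result.correlation_length_nm,
        "correlation_fit_error": result.slope_fit_error,
        "predicted_peaks": [
            {
                "source": p.source,
                "k_inv_nm": p.wavenumber_inv_nm,
                "distance_nm": p.distance_nm,
                "visibility": p.visibility_weight,
            }
            for p in result.predicted
        ],
    }

    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash: {config.config_hash}\n# seed: {config.seed}\n"
        spectrum = pd.DataFrame(
            {"k_inv_nm": result.psdf.wavenumbers, "power": result.psdf.power}
        )
        with open(out / "spectrum_signal.csv", "w") as fh:
            fh.write(header)
            spectrum.to_csv(fh, index=False)
        bg = pd.DataFrame(
            {
                "k_inv_nm": result.background_psdf.wavenumbers,
                "power": result.background_psdf.power,
            }
        )
        with open(out / "spectrum_background.csv", "w") as fh:
            fh.write(header)
            bg.to_csv(fh, index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "config.resolved").write_text(
            f"# config_hash: {config.config_hash}\n" + config.to_text()
        )
        with open(out / "predicted_vs_observed.csv", "w") as fh:
            fh.write(header)
            result.prediction_table().to_csv(fh, index=False)
        write_heightmap(hm, out / "input_map.tif")
        log.info("wrote outputs to %s", out)
    return report
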