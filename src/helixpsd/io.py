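"""Raster I/O for height maps.

Two text-friendly on-disk forms:
  * 32-bit float TIFF plus a JSON sidecar (same stem, ``.json``) carrying
    pixel size, channel label, seed and generator settings;
  * a plain-text matrix with ``#``-prefixed header lines, of which
    ``# pixel_size_nm: <value>`` is mandatory.

A missing pixel size is a hard error: a physical scale is never guessed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .scene import HeightMap

__all__ = ["read_heightmap", "write_heightmap"]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_TEXT_SUFFIXES = {".txt", ".asc", ".dat", ".xyz"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_heightmap(heightmap: HeightMap, path: str | Path) -> Path:
    """Write a height map; the format follows the file suffix."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, heightmap.values.astype(np.float32))
        meta = {
            "pixel_size_nm": heightmap.pixel_size_nm,
            "channel_label": heightmap.channel_label,
            **{k: _jsonable(v) for k, v in heightmap.metadata.items()},
        }
        _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    elif path.suffix.lower() in _TEXT_SUFFIXES:
        header = [
            f"# pixel_size_nm: {heightmap.pixel_size_nm!r}",
            f"# channel_label: {heightmap.channel_label}",
        ]
        for k, v in sorted(heightmap.metadata.items()):
            header.append(f"# {k}: {_jsonable(v)}")
        body = "\n".join(
            " ".join(f"{v:.9g}" for v in row) for row in heightmap.values
        )
        path.write_text("\n".join(header) + "\n" + body + "\n")
    else:
        raise ValueError(f"unsupported height-map format {path.suffix!r}")
    return path


def read_heightmap(path: str | Path) -> HeightMap:
    """Read a height map written by :func:`write_heightmap` (or compatible)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        side = _sidecar(path)
        if not side.exists():
            raise ValueError(
                f"TIFF {path} has no JSON sidecar {side.name}; pixel size unknown "
                "(a physical scale is never guessed)"
            )
        meta = json.loads(side.read_text())
        if "pixel_size_nm" not in meta:
            raise ValueError(f"sidecar {side} lacks pixel_size_nm")
        values = tifffile.imread(path)
        px = float(meta.pop("pixel_size_nm"))
        label = str(meta.pop("channel_label", "topography"))
        return HeightMap(values, px, label, meta)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return _read_text_matrix(path)
    raise ValueError(f"unsupported height-map format {path.suffix!r}")


def _read_text_matrix(path: Path) -> HeightMap:
    px = None
    label = "topography"
    meta: dict = {}
    rows: list[list[float]] = []
    width = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key == "pixel_size_nm":
                    try:
                        px = float(val)
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: bad pixel_size_nm {val!r}"
                        ) from exc
                elif key == "channel_label":
                    label = val
                else:
                    meta[key] = val
            continue
        try:
            row = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed matrix row") from exc
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(
                f"{path}:{lineno}: row has {len(row)} values, expected {width}"
            )
        rows.append(row)
    if px is None:
        raise ValueError(f"{path}: missing '# pixel_size_nm:' header")
    if not rows:
        raise ValueError(f"{path}: no matrix data")
    return HeightMap(np.array(rows), px, label, meta)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (bool, int, float, str)) or v is None:
        return v
    return str(v)
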