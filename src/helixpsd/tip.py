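"""Probe broadening of a surface by greyscale morphological dilation.

An AFM height map is (to first order) the dilation of the true surface by
the reflected tip: imaged(x) = max_u [ surface(x+u) + tip_profile(u) ] with
the tip profile non-positive and zero at the apex.  A blunt tip bridges over
narrow valleys, which drains power from the high harmonics of a periodic
corrugation -- the sharper the tip, the richer the harmonic content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scene import HeightMap

__all__ = ["TipShape", "build_tip", "dilate", "erode"]

# fill value marking pixels outside the tip support; far below any height
# difference that can occur in nm-scale maps, so it never wins the max
_OUTSIDE = -1.0e9


@dataclass(frozen=True)
class TipShape:
    """Radial tip profile on a pixel grid.

    ``profile`` holds heights of the (reflected) tip surface relative to the
    apex: non-positive, 0 at the center pixel, ``_OUTSIDE`` beyond the
    finite support.  Grids are odd-sized and apex-centered.
    """

    profile: np.ndarray
    pixel_size_nm: float
    radius_nm: float
    model: str

    def __post_init__(self) -> None:
        p = np.asarray(self.profile)
        if p.ndim != 2 or p.shape[0] % 2 == 0 or p.shape[1] % 2 == 0:
            raise ValueError("tip profile must be a 2D odd-sized grid")
        c = (p.shape[0] // 2, p.shape[1] // 2)
        if p[c] != 0.0:
            raise ValueError("tip apex value must be 0 at the center")
        if np.any(p > 0):
            raise ValueError("tip profile must be non-positive everywhere")

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of pixels inside the finite tip support."""
        return self.profile > _OUTSIDE / 2


def build_tip(model: str, radius_nm: float, pixel_size_nm: float) -> TipShape:
    """Construct a parametric tip profile.

    sphere      : profile(r) = -(R - sqrt(R^2 - r^2)), support r <= R
    paraboloid  : profile(r) = -r^2 / (2R), support truncated at r = 2R
    point       : single-pixel ideal tip (identity element of dilation)
    """
    if radius_nm < 0:
        raise ValueError("radius_nm must be >= 0")
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    if model == "point" or radius_nm == 0:
        return TipShape(np.zeros((1, 1)), pixel_size_nm, 0.0, "point")

    if model == "sphere":
        r_sup = radius_nm
    elif model == "paraboloid":
        r_sup = 2.0 * radius_nm
    else:
        raise ValueError(f"unknown tip model {model!r}")

    n = int(math.floor(r_sup / pixel_size_nm))
    ax = np.arange(-n, n + 1) * pixel_size_nm
    rr = np.hypot(ax[:, None], ax[None, :])
    prof = np.full(rr.shape, _OUTSIDE)
    inside = rr <= r_sup + 1e-12
    if model == "sphere":
        arg = np.clip(radius_nm**2 - rr[inside] ** 2, 0.0, None)
        prof[inside] = -(radius_nm - np.sqrt(arg))
    else:
        prof[inside] = -(rr[inside] ** 2) / (2.0 * radius_nm)
    prof[n, n] = 0.0
    return TipShape(prof, pixel_size_nm, radius_nm, model)


def _check_compat(heightmap: HeightMap, tip: TipShape) -> None:
    if not math.isclose(heightmap.pixel_size_nm, tip.pixel_size_nm, rel_tol=1e-9):
        raise ValueError(
            f"pixel size mismatch: map {heightmap.pixel_size_nm} nm vs "
            f"tip {tip.pixel_size_nm} nm"
        )
    if (
        tip.profile.shape[0] > heightmap.values.shape[0]
        or tip.profile.shape[1] > heightmap.values.shape[1]
    ):
        raise ValueError("tip support larger than the image")


def dilate(heightmap: HeightMap, tip: TipShape) -> HeightMap:
    """Image a surface with a tip: greyscale dilation, edge replication.

    Output is pointwise >= input (the probe can only broaden, never dig).
    """
    _check_compat(heightmap, tip)
    if tip.profile.shape == (1, 1):
        out = heightmap.values.copy()
    else:
        out = ndimage.grey_dilation(
            heightmap.values, structure=tip.profile, mode="nearest"
        )
        # guard against the sentinel leaking through (cannot happen while the
        # apex pixel is 0, but cheap to assert)
        np.maximum(out, heightmap.values, out=out)
    return heightmap.with_values(
        out, metadata_update={"tip_model": tip.model, "tip_radius_nm": tip.radius_nm}
    )


def erode(heightmap: HeightMap, tip: TipShape) -> HeightMap:
    """Certainty-map style inverse: erosion by the same tip.

    ``erode(dilate(s))`` lower-bounds the true surface; provided as an
    optional reconstruction check only, not a pipeline stage.
    """
    _check_compat(heightmap, tip)
    if tip.profile.shape == (1, 1):
        out = heightmap.values.copy()
    else:
        out = ndimage.grey_erosion(
            heightmap.values, structure=tip.profile, mode="nearest"
        )
        np.minimum(out, heightmap.values, out=out)
    return heightmap.with_values(
        out,
        metadata_update={
            "tip_model": tip.model,
            "tip_radius_nm": tip.radius_nm,
            "eroded": True,
        },
    )
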