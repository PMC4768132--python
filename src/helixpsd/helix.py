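"""Geometry of a helical coat-protein lattice on a cylindrical virion.

TMV-like parameters: one helix turn rises 2.3 nm and carries 16.33 proteins,
so 49 subunits complete exactly three turns and the shortest truly axial
lattice translation is the three-turn repeat, 3 x 2.3 = 6.9 nm.  Vectors
joining a protein to its nearest partner after n turns are only *near*-axial
for n not divisible by 3; their off-axis angle controls how strongly each
repeat distance shows up in a power spectrum taken along the virion axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HelixParameters",
    "RepeatVector",
    "PeakPrediction",
    "subunit_lattice",
    "repeat_vector",
    "wavenumber_of",
    "distance_of",
    "predicted_peaks",
]


@dataclass(frozen=True)
class HelixParameters:
    """Parameters of the helical lattice and the cylinder that carries it.

    Attributes
    ----------
    pitch_nm : axial rise per helix turn.
    subunits_per_three_turns : integer count of coat proteins completing
        exactly three turns (49 for TMV; per-turn count is this / 3).
    outer_radius_nm : cylinder radius carrying the protein centers as seen
        from outside (9 nm for the 18 nm virion diameter).
    channel_radius_nm : inner channel radius (informational).
    length_nm : virion length.
    handedness : +1 or -1, sense of azimuthal advance per subunit.
    """

    pitch_nm: float = 2.3
    subunits_per_three_turns: int = 49
    outer_radius_nm: float = 9.0
    channel_radius_nm: float = 2.0
    length_nm: float = 300.0
    handedness: int = 1

    def __post_init__(self) -> None:
        if self.pitch_nm <= 0:
            raise ValueError("pitch_nm must be positive")
        if self.subunits_per_three_turns < 3:
            raise ValueError("subunits_per_three_turns must be >= 3")
        if not self.outer_radius_nm > self.channel_radius_nm >= 0:
            raise ValueError("need outer_radius_nm > channel_radius_nm >= 0")
        if self.handedness not in (1, -1):
            raise ValueError("handedness must be +1 or -1")

    @property
    def subunits_per_turn(self) -> float:
        return self.subunits_per_three_turns / 3.0

    @property
    def axial_rise_per_subunit_nm(self) -> float:
        return self.pitch_nm / self.subunits_per_turn

    @property
    def azimuth_step_deg(self) -> float:
        return 360.0 / self.subunits_per_turn

    @property
    def three_turn_repeat_nm(self) -> float:
        """Shortest truly axial lattice translation (6.9 nm for TMV)."""
        return 3.0 * self.pitch_nm


@dataclass(frozen=True)
class RepeatVector:
    """Near-axial lattice vector after ``n_turns`` helix turns."""

    n_turns: int
    partner_index: int
    axial_distance_nm: float
    offaxis_angle_deg: float
    arc_offset_nm: float

    def __post_init__(self) -> None:
        if self.axial_distance_nm <= 0:
            raise ValueError("axial_distance_nm must be positive")
        if abs(self.offaxis_angle_deg) >= 90:
            raise ValueError("off-axis angle must satisfy |angle| < 90 deg")

    @property
    def offaxis_angle_rounded(self) -> int:
        return int(round(self.offaxis_angle_deg))


@dataclass(frozen=True)
class PeakPrediction:
    """Predicted spectral peak for an axis-aligned line-averaged spectrum."""

    wavenumber_inv_nm: float
    distance_nm: float
    visibility_weight: float
    source: str = ""

    def __post_init__(self) -> None:
        if not math.isclose(
            self.wavenumber_inv_nm, 2 * math.pi / self.distance_nm, rel_tol=1e-9
        ):
            raise ValueError("wavenumber and distance are inconsistent (k = 2*pi/l)")
        if not 0 <= self.visibility_weight <= 1:
            raise ValueError("visibility_weight must lie in [0, 1]")


def subunit_lattice(params: HelixParameters, n_subunits: int) -> np.ndarray:
    """Coordinates of the first ``n_subunits`` coat proteins.

    Returns a structured array with fields ``axial_nm``, ``azimuth_deg`` and
    ``xyz`` (a 3-point on the outer cylinder, z along the virion axis).
    Subunit ``j`` sits at axial position ``j * pitch / s`` and azimuth
    ``j * (360 / s) * handedness`` (mod 360), ``s`` subunits per turn.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    j = np.arange(n_subunits)
    axial = j * params.axial_rise_per_subunit_nm
    azim = np.mod(j * params.azimuth_step_deg * params.handedness, 360.0)
    phi = np.deg2rad(azim)
    r = params.outer_radius_nm
    out = np.zeros(
        n_subunits,
        dtype=[("axial_nm", float), ("azimuth_deg", float), ("xyz", float, 3)],
    )
    out["axial_nm"] = axial
    out["azimuth_deg"] = azim
    out["xyz"][:, 0] = r * np.cos(phi)
    out["xyz"][:, 1] = r * np.sin(phi)
    out["xyz"][:, 2] = axial
    return out


def repeat_vector(params: HelixParameters, n_turns: int) -> RepeatVector:
    """Vector from a subunit to its nearest lattice partner after ``n_turns``.

    The partner is the subunit whose index is closest to ``n_turns * s``; the
    leftover azimuthal offset, taken as an arc on the outer cylinder, tilts
    the vector off the axis.  Sign convention: positive when the partner lags
    in azimuth (TMV: +27 deg for one turn, -14 deg for two, 0 for three...).
    """
    if n_turns < 1:
        raise ValueError("n_turns must be >= 1")
    s = params.subunits_per_turn
    partner = int(round(n_turns * s))
    axial = partner * params.axial_rise_per_subunit_nm
    dphi_deg = (partner - n_turns * s) * params.azimuth_step_deg
    arc = params.outer_radius_nm * math.radians(dphi_deg)
    angle = math.degrees(math.atan(abs(arc) / axial))
    if dphi_deg > 0:
        angle = -angle
    return RepeatVector(
        n_turns=n_turns,
        partner_index=partner,
        axial_distance_nm=axial,
        offaxis_angle_deg=angle,
        arc_offset_nm=arc,
    )


def wavenumber_of(distance_nm: float) -> float:
    """Wavenumber k = 2*pi / l for a real-space distance l (nm -> 1/nm)."""
    if distance_nm <= 0:
        raise ValueError("distance must be positive")
    return 2.0 * math.pi / distance_nm


def distance_of(wavenumber_inv_nm: float) -> float:
    """Real-space distance l = 2*pi / k for a wavenumber k (1/nm -> nm)."""
    if wavenumber_inv_nm <= 0:
        raise ValueError("wavenumber must be positive")
    return 2.0 * math.pi / wavenumber_inv_nm


def predicted_peaks(
    params: HelixParameters,
    max_turns: int = 6,
    attenuation_deg: float = 10.0,
) -> list[PeakPrediction]:
    """Predicted peaks for an axis-aligned line-averaged power spectrum.

    One prediction per near-axial repeat (n = 1..max_turns) with a Gaussian
    visibility in the off-axis angle, ``exp(-(theta/attenuation_deg)**2)`` --
    a vector tilted away from the analysis axis decoheres across scan lines.
    The width is a free scale: only the ordering of weights is physical.
    Harmonics of the three-turn axial repeat (m * k(3*pitch)) are appended
    with unit weight; their true intensities depend on how sharply the probe
    resolves the repeating building block, which is not modelled here.
    """
    if max_turns < 1:
        raise ValueError("max_turns must be >= 1")
    if attenuation_deg <= 0:
        raise ValueError("attenuation_deg must be positive")
    preds: list[PeakPrediction] = []
    for n in range(1, max_turns + 1):
        rv = repeat_vector(params, n)
        w = math.exp(-((rv.offaxis_angle_deg / attenuation_deg) ** 2))
        preds.append(
            PeakPrediction(
                wavenumber_inv_nm=wavenumber_of(rv.axial_distance_nm),
                distance_nm=rv.axial_distance_nm,
                visibility_weight=w,
                source=f"n_turns={n}",
            )
        )
    k0 = wavenumber_of(params.three_turn_repeat_nm)
    for m in range(1, max_turns + 1):
        preds.append(
            PeakPrediction(
                wavenumber_inv_nm=m * k0,
                distance_nm=distance_of(m * k0),
                visibility_weight=1.0,
                source=f"harmonic={m}",
            )
        )
    preds.sort(key=lambda p: p.wavenumber_inv_nm)
    return preds
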