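"""Peak detection, harmonic assignment and correlation-length extraction.

A strictly periodic surface built from one repeating axial building block
(6.9 nm for TMV) produces a fundamental plus integer harmonics; which
harmonics survive reflects how sharply the probe resolves the block's inner
structure.  A rough-but-aperiodic surface instead shows two power-law
regimes in the log-log spectrum whose transition wavenumber defines a
correlation length l = 2*pi/k_break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .helix import distance_of
from .scene import HeightMap
from .spectral import BoxSelection, PSDFResult, peak_snr

__all__ = [
    "Peak",
    "PeakSet",
    "HarmonicModel",
    "SlopeFit",
    "DegenerateFitError",
    "detect_peaks",
    "assign_harmonics",
    "correlation_length",
    "estimate_axis",
]


class DegenerateFitError(RuntimeError):
    """Raised when a two-slope fit finds no knee (near-identical slopes)."""


@dataclass(frozen=True)
class Peak:
    wavenumber_inv_nm: float
    power: float
    snr: float
    distance_nm: float
    bin_index: int


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks of one spectrum, sorted by wavenumber."""

    peaks: tuple[Peak, ...]
    snr_threshold: float
    dk: float  # bin spacing of the source spectrum
    noise_floor: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ks = [p.wavenumber_inv_nm for p in self.peaks]
        if any(b < a for a, b in zip(ks, ks[1:])):
            raise ValueError("peaks must be sorted by wavenumber")
        if any(p.snr < self.snr_threshold for p in self.peaks):
            raise ValueError("all retained peaks must satisfy the SNR threshold")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.array([p.wavenumber_inv_nm for p in self.peaks])

    def strongest_in(self, k_lo: float, k_hi: float) -> Peak | None:
        cands = [p for p in self.peaks if k_lo <= p.wavenumber_inv_nm <= k_hi]
        return max(cands, key=lambda p: p.power) if cands else None


@dataclass(frozen=True)
class HarmonicModel:
    """Assignment of detected peaks to harmonics of a fundamental."""

    fundamental_k: float
    assigned: dict  # Peak -> harmonic integer m
    missing: tuple[int, ...]
    harmonic_power_ratios: dict  # m -> power(m)/power(m_ref)
    tolerance_k: float

    def harmonic_of(self, m: int) -> Peak | None:
        for pk, mm in self.assigned.items():
            if mm == m:
                return pk
        return None


@dataclass(frozen=True)
class SlopeFit:
    """Two-slope log-log fit with a knee."""

    breakpoint_k: float
    slopes: tuple[float, float]
    intercepts: tuple[float, float]
    correlation_length_nm: float
    residual: float
    k_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.k_range[0] < self.breakpoint_k < self.k_range[1]:
            raise ValueError("breakpoint must lie strictly inside the fitted range")


def detect_peaks(psdf: PSDFResult, snr_threshold: float = 3.0) -> PeakSet:
    """Local spectral maxima whose local-median SNR reaches the threshold.

    Maxima closer than one bin are merged keeping the higher-power bin; each
    peak carries its real-space distance 2*pi/k.
    """
    if snr_threshold <= 1:
        raise ValueError("snr_threshold must exceed 1")
    p = psdf.power
    idx, _ = sps.find_peaks(p)
    floor = np.array([p[i] / peak_snr(psdf, i) if peak_snr(psdf, i) > 0 else 0.0 for i in range(p.size)]) if p.size else np.array([])

    kept: list[int] = []
    for i in idx:
        if peak_snr(psdf, i) >= snr_threshold:
            if kept and i - kept[-1] <= 1:
                if p[i] > p[kept[-1]]:
                    kept[-1] = i
            else:
                kept.append(i)
    peaks = tuple(
        Peak(
            wavenumber_inv_nm=float(psdf.wavenumbers[i]),
            power=float(p[i]),
            snr=float(peak_snr(psdf, i)),
            distance_nm=distance_of(float(psdf.wavenumbers[i])),
            bin_index=i,
        )
        for i in kept
    )
    return PeakSet(peaks=peaks, snr_threshold=snr_threshold, dk=psdf.dk, noise_floor=floor)


def assign_harmonics(
    peaks: PeakSet, fundamental_k: float, max_m: int, tolerance_k: float | None = None
) -> HarmonicModel:
    """Assign each peak the integer m minimising |k - m*k0| within tolerance.

    The default tolerance is one spectral bin -- the physical resolution of
    the averaged spectrum.  Harmonics up to ``max_m`` with no assigned peak
    are reported missing.
    """
    if fundamental_k <= 0:
        raise ValueError("fundamental_k must be positive")
    if max_m < 1:
        raise ValueError("max_m must be >= 1")
    tol = peaks.dk if tolerance_k is None else tolerance_k
    assigned: dict[Peak, int] = {}
    best_for_m: dict[int, Peak] = {}
    for pk in peaks.peaks:
        m = int(round(pk.wavenumber_inv_nm / fundamental_k))
        if 1 <= m <= max_m and abs(pk.wavenumber_inv_nm - m * fundamental_k) <= tol + 1e-12:
            prev = best_for_m.get(m)
            if prev is None or abs(pk.wavenumber_inv_nm - m * fundamental_k) < abs(
                prev.wavenumber_inv_nm - m * fundamental_k
            ):
                best_for_m[m] = pk
    assigned = {pk: m for m, pk in best_for_m.items()}
    missing = tuple(m for m in range(1, max_m + 1) if m not in best_for_m)
    ratios: dict[int, float] = {}
    ref = best_for_m.get(min(best_for_m)) if best_for_m else None
    if ref is not None and ref.power > 0:
        ratios = {m: pk.power / ref.power for m, pk in sorted(best_for_m.items())}
    return HarmonicModel(
        fundamental_k=fundamental_k,
        assigned=assigned,
        missing=missing,
        harmonic_power_ratios=ratios,
        tolerance_k=tol,
    )


def correlation_length(
    psdf: PSDFResult,
    k_range: tuple[float, float] | None = None,
    min_slope_diff: float = 0.25,
) -> SlopeFit:
    """Two-slope least-squares fit in (log k, log power) with a free knee.

    The knee is found by exhaustively splitting the selected bins into two
    segments of at least 4 bins each, fitting a line to each and keeping the
    split with the smallest total squared residual; the reported breakpoint
    is the intersection of the two lines and the correlation length is
    2*pi/k_break.  The DC-adjacent first bin and bins beyond 0.8x Nyquist
    are always excluded (leakage and pixelation contaminate the extremes).
    """
    k = psdf.wavenumbers
    p = psdf.power
    sel = (np.arange(k.size) >= 1) & (k <= 0.8 * psdf.k_nyquist) & (p > 0)
    if k_range is not None:
        sel &= (k >= k_range[0]) & (k <= k_range[1])
    k, p = k[sel], p[sel]
    if k.size < 8:
        raise ValueError("need at least 8 usable bins for a two-slope fit")
    lk, lp = np.log(k), np.log(p)

    best = None
    for split in range(4, k.size - 3):
        r_tot = 0.0
        fits = []
        for seg in (slice(0, split), slice(split, k.size)):
            A = np.vstack([lk[seg], np.ones(lk[seg].size)]).T
            coef, res, *_ = np.linalg.lstsq(A, lp[seg], rcond=None)
            r = float(res[0]) if res.size else float(np.sum((A @ coef - lp[seg]) ** 2))
            fits.append(coef)
            r_tot += r
        if best is None or r_tot < best[0]:
            best = (r_tot, fits, split)

    r_tot, (c1, c2), _ = best
    s1, b1 = float(c1[0]), float(c1[1])
    s2, b2 = float(c2[0]), float(c2[1])
    if abs(s1 - s2) < min_slope_diff:
        raise DegenerateFitError(
            f"slopes {s1:.3f} and {s2:.3f} nearly identical; no knee in the spectrum"
        )
    lk_break = (b2 - b1) / (s1 - s2)
    k_break = float(np.exp(lk_break))
    if not k[0] < k_break < k[-1]:
        raise DegenerateFitError(
            f"fitted slope intersection k = {k_break:.3g} 1/nm falls outside the "
            f"fitted range [{k[0]:.3g}, {k[-1]:.3g}]"
        )
    return SlopeFit(
        breakpoint_k=k_break,
        slopes=(s1, s2),
        intercepts=(b1, b2),
        correlation_length_nm=2.0 * math.pi / k_break,
        residual=r_tot,
        k_range=(float(k[0]), float(k[-1])),
    )


def estimate_axis(heightmap: HeightMap, box: BoxSelection | None = None) -> float:
    """Orientation of an elongated object, degrees vs horizontal in [-90, 90).

    Thresholds the box at the midpoint between the background median and the
    maximum, then takes the principal axis of the second central moments of
    the mask.
    """
    vals = heightmap.values
    if box is not None:
        vals = vals[box.row0 : box.row1, box.col0 : box.col1]
    med = float(np.median(vals))
    thr = med + 0.5 * (float(vals.max()) - med)
    ys, xs = np.nonzero(vals > thr)
    if ys.size == 0:
        raise ValueError("no pixels above the background threshold")
    x = xs - xs.mean()
    y = -(ys - ys.mean())  # image rows grow downward; flip to math convention
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    ang = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    if ang >= 90.0:
        ang -= 180.0
    elif ang < -90.0:
        ang += 180.0
    return ang
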