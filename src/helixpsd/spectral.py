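"""Line-averaged power spectral density of height-map boxes.

The estimator: inside a rectangular box, take every scan line, remove its
mean, Fourier-transform it, square the magnitude (discarding phase) and
average over lines.  Averaging many lines lifts periodic components above
the noise while incoherent content averages to a smooth floor.

Conventions (fixed throughout the package):
  * wavenumber k = 2*pi / wavelength, bins at m * 2*pi/(L*dx);
  * one-sided spectrum, DC excluded from outputs;
  * normalisation such that sum(power) * dk equals the mean per-line
    variance (Parseval), so power carries units of nm^3;
  * no window by default (peak-position fidelity over sidelobe
    suppression); a Hann window is available and is renormalised to keep
    the Parseval convention for broadband content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .scene import HeightMap

__all__ = [
    "BoxSelection",
    "PSDFResult",
    "averaged_psdf",
    "peak_snr",
    "compare_background",
    "optimize_box",
]

MIN_LINES = 4
MIN_SAMPLES = 16


@dataclass(frozen=True)
class BoxSelection:
    """Axis-aligned box: half-open, 0-based row/column ranges.

    ``line_direction`` says which way the analysis lines run; lines along
    "columns" are used for a vertically oriented virion.
    """

    row0: int
    row1: int
    col0: int
    col1: int
    line_direction: str = "rows"

    def __post_init__(self) -> None:
        if self.line_direction not in ("rows", "columns"):
            raise ValueError("line_direction must be 'rows' or 'columns'")
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError("box ranges must be non-empty (half-open)")
        if min(self.row0, self.col0) < 0:
            raise ValueError("box ranges must be non-negative")
        if self.n_lines < MIN_LINES:
            raise ValueError(f"box must contain at least {MIN_LINES} lines")
        if self.line_length < MIN_SAMPLES:
            raise ValueError(f"lines must contain at least {MIN_SAMPLES} samples")

    @property
    def n_lines(self) -> int:
        return (self.row1 - self.row0) if self.line_direction == "rows" else (self.col1 - self.col0)

    @property
    def line_length(self) -> int:
        return (self.col1 - self.col0) if self.line_direction == "rows" else (self.row1 - self.row0)

    def within(self, shape: tuple[int, int]) -> bool:
        return self.row1 <= shape[0] and self.col1 <= shape[1]

    def extract_lines(self, values: np.ndarray) -> np.ndarray:
        """(n_lines, line_length) array of scan lines."""
        block = values[self.row0 : self.row1, self.col0 : self.col1]
        return block if self.line_direction == "rows" else block.T


@dataclass(frozen=True)
class PSDFResult:
    """One-sided averaged power spectrum of a box (DC bin excluded)."""

    wavenumbers: np.ndarray  # 1/nm, strictly increasing
    power: np.ndarray  # nm^3
    n_lines_averaged: int
    line_length_samples: int
    pixel_size_nm: float
    box: BoxSelection
    source_channel: str = ""

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")

    @property
    def dk(self) -> float:
        """Bin spacing 2*pi/(L*dx) -- the physical spectral resolution."""
        return 2.0 * math.pi / (self.line_length_samples * self.pixel_size_nm)

    @property
    def k_nyquist(self) -> float:
        return math.pi / self.pixel_size_nm

    def nearest_bin(self, k: float) -> int:
        return int(np.argmin(np.abs(self.wavenumbers - k)))

    def same_grid(self, other: "PSDFResult") -> bool:
        return (
            self.line_length_samples == other.line_length_samples
            and math.isclose(self.pixel_size_nm, other.pixel_size_nm, rel_tol=1e-9)
        )


def averaged_psdf(
    heightmap: HeightMap, box: BoxSelection, window: str = "none"
) -> PSDFResult:
    """Per-line FFT -> squared magnitude -> average over the box's lines."""
    if not box.within(heightmap.shape):
        raise ValueError(f"box {box} outside image of shape {heightmap.shape}")
    lines = np.asarray(box.extract_lines(heightmap.values), dtype=float)
    n_lines, n = lines.shape
    lines = lines - lines.mean(axis=1, keepdims=True)

    if window == "hann":
        w = np.hanning(n)
        w = w / math.sqrt(np.mean(w**2))  # preserve broadband Parseval
        lines = lines * w
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")

    spec = np.fft.rfft(lines, axis=1)
    p2 = (np.abs(spec) ** 2).mean(axis=0)

    dx = heightmap.pixel_size_nm
    dk = 2.0 * math.pi / (n * dx)
    # one-sided: double every bin except DC and (for even n) Nyquist, then
    # normalise so sum(power)*dk = mean per-line variance
    weights = np.full(p2.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    power = weights * p2 / (n**2 * dk)
    k = np.arange(p2.size) * dk

    return PSDFResult(
        wavenumbers=k[1:],
        power=power[1:],
        n_lines_averaged=n_lines,
        line_length_samples=n,
        pixel_size_nm=dx,
        box=box,
        source_channel=heightmap.channel_label,
    )


def peak_snr(psdf: PSDFResult, index: int) -> float:
    """SNR of a bin: its power over the median of the surrounding window.

    The window is the 9 bins centred on the peak minus the 3 central bins
    (the peak and its direct neighbours, which carry its leakage skirt),
    clipped at the spectrum edges.
    """
    p = psdf.power
    lo, hi = max(index - 4, 0), min(index + 5, p.size)
    neigh = np.concatenate([p[lo : max(index - 1, lo)], p[min(index + 2, hi) : hi]])
    if neigh.size == 0:
        return math.inf if p[index] > 0 else 0.0
    floor = float(np.median(neigh))
    if floor == 0.0:
        return math.inf if p[index] > 0 else 0.0
    return float(p[index] / floor)


def compare_background(
    signal: PSDFResult,
    background: PSDFResult,
    peak_ks,
    snr_threshold: float = 3.0,
) -> dict[float, str]:
    """Flag each peak wavenumber as signal-specific or also-in-background.

    A peak is *signal-specific* when its SNR in the signal box reaches the
    threshold while the SNR at the same wavenumber in the background box
    stays below it.  Both spectra must share the bin grid.
    """
    if not signal.same_grid(background):
        raise ValueError("signal and background spectra have incompatible bin grids")
    flags: dict[float, str] = {}
    for k in peak_ks:
        i = signal.nearest_bin(k)
        s = peak_snr(signal, i)
        b = peak_snr(background, background.nearest_bin(k))
        flags[float(k)] = (
            "signal-specific" if (s >= snr_threshold and b < snr_threshold) else "also-in-background"
        )
    return flags


def _snr_at_target(heightmap: HeightMap, box: BoxSelection, target_k: float, window: str) -> float:
    psdf = averaged_psdf(heightmap, box, window=window)
    return peak_snr(psdf, psdf.nearest_bin(target_k))


def optimize_box(
    heightmap: HeightMap,
    seed_box: BoxSelection,
    target_k: float,
    window: str = "none",
    step: int = 2,
    max_iter: int = 200,
) -> BoxSelection:
    """Greedy box-edge search maximising the SNR of the bin nearest target_k.

    Deterministic coordinate ascent: each iteration tries moving every edge
    by +-step and +-1 pixels and keeps the single best strictly improving
    move; stops at a local maximum.  Box invariants (minimum lines/samples,
    image bounds) are never violated.
    """
    if target_k <= 0 or target_k > math.pi / heightmap.pixel_size_nm:
        raise ValueError("target_k must lie within the resolvable band")
    if not seed_box.within(heightmap.shape):
        raise ValueError("seed box outside image")

    best = seed_box
    best_snr = _snr_at_target(heightmap, best, target_k, window)
    deltas = sorted({1, step}) if step > 0 else [1]
    for _ in range(max_iter):
        candidate, cand_snr = None, best_snr
        for edge in ("row0", "row1", "col0", "col1"):
            for d in deltas:
                for sign in (-1, 1):
                    fields = {
                        "row0": best.row0,
                        "row1": best.row1,
                        "col0": best.col0,
                        "col1": best.col1,
                    }
                    fields[edge] += sign * d
                    try:
                        nb = BoxSelection(line_direction=best.line_direction, **fields)
                    except ValueError:
                        continue
                    if not nb.within(heightmap.shape):
                        continue
                    snr = _snr_at_target(heightmap, nb, target_k, window)
                    if snr > cand_snr:
                        candidate, cand_snr = nb, snr
        if candidate is None:
            break
        best, best_snr = candidate, cand_snr
    return best
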