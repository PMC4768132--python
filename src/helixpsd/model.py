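"""Model/results interface for single-particle surface-periodicity analysis.

`SurfacePeriodicity` wraps one height map plus analysis choices (boxes,
line direction, helix parameters); `fit()` runs the spectral chain --
line-averaged power spectrum, background comparison, peak detection,
harmonic assignment against the three-turn axial repeat, and a two-slope
correlation-length fit -- and returns a `SurfacePeriodicityResult` with the
estimates and a `summary()` table.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .helix import HelixParameters, predicted_peaks, wavenumber_of
from .peaks import (
    DegenerateFitError,
    HarmonicModel,
    PeakSet,
    SlopeFit,
    assign_harmonics,
    correlation_length,
    detect_peaks,
    estimate_axis,
)
from .scene import HeightMap
from .spectral import BoxSelection, PSDFResult, averaged_psdf, compare_background, optimize_box

__all__ = ["SurfacePeriodicity", "SurfacePeriodicityResult", "auto_boxes"]


def auto_boxes(
    heightmap: HeightMap,
    line_direction: str,
    half_width_nm: float = 1.5,
) -> tuple[BoxSelection, BoxSelection]:
    """Crest-centred signal box and same-shape substrate background box.

    The signal box runs along the virion crest (the line with the highest
    mean height) with the given half-width across it; the background box is
    the same shape placed over the lowest-mean region at least one virion
    radius away from the crest.
    """
    vals = heightmap.values if line_direction == "rows" else heightmap.values.T
    n_lines, _ = vals.shape
    profile = vals.mean(axis=1)
    crest = int(np.argmax(profile))
    w = max(2, int(round(half_width_nm / heightmap.pixel_size_nm)))
    lo = max(crest - w, 0)
    hi = min(crest + w + 1, n_lines)
    if hi - lo < 4:
        lo, hi = max(0, hi - 4), min(n_lines, lo + 4)

    margin = int(round(12.0 / heightmap.pixel_size_nm))  # > virion radius
    width = hi - lo
    best_start, best_mean = None, math.inf
    for start in range(0, n_lines - width + 1):
        if abs(start + width // 2 - crest) <= margin:
            continue
        m = float(profile[start : start + width].mean())
        if m < best_mean:
            best_start, best_mean = start, m
    if best_start is None:
        raise ValueError("no background region available outside the virion")

    def mkbox(a: int, b: int) -> BoxSelection:
        if line_direction == "rows":
            return BoxSelection(a, b, 0, heightmap.shape[1], "rows")
        return BoxSelection(0, heightmap.shape[0], a, b, "columns")

    return mkbox(lo, hi), mkbox(best_start, best_start + width)


@dataclass
class SurfacePeriodicityResult:
    """Fitted surface-periodicity estimates for one height map."""

    model: "SurfacePeriodicity"
    psdf: PSDFResult
    background_psdf: PSDFResult | None
    peaks: PeakSet
    flags: dict
    harmonics: HarmonicModel
    slope_fit: SlopeFit | None
    slope_fit_error: str | None
    predicted: list

    @property
    def correlation_length_nm(self) -> float | None:
        return None if self.slope_fit is None else self.slope_fit.correlation_length_nm

    def peak_table(self) -> pd.DataFrame:
        rows = []
        for pk in self.peaks.peaks:
            m = self.harmonics.assigned.get(pk)
            rows.append(
                {
                    "k_inv_nm": pk.wavenumber_inv_nm,
                    "distance_nm": pk.distance_nm,
                    "power_nm3": pk.power,
                    "snr": pk.snr,
                    "flag": self.flags.get(pk.wavenumber_inv_nm, "unchecked"),
                    "harmonic_m": m if m is not None else pd.NA,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["k_inv_nm", "distance_nm", "power_nm3", "snr", "flag", "harmonic_m"],
        )

    def prediction_table(self) -> pd.DataFrame:
        det_ks = self.peaks.wavenumbers
        rows = []
        for p in self.predicted:
            match = None
            if det_ks.size:
                i = int(np.argmin(np.abs(det_ks - p.wavenumber_inv_nm)))
                if abs(det_ks[i] - p.wavenumber_inv_nm) <= self.peaks.dk:
                    match = float(det_ks[i])
            rows.append(
                {
                    "source": p.source,
                    "k_pred_inv_nm": p.wavenumber_inv_nm,
                    "distance_nm": p.distance_nm,
                    "visibility": p.visibility_weight,
                    "k_observed_inv_nm": match if match is not None else pd.NA,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        buf = _io.StringIO()
        hm = self.model.heightmap
        print("Surface periodicity analysis", file=buf)
        print("=" * 64, file=buf)
        print(
            f"channel: {hm.channel_label}   image: {hm.shape[0]}x{hm.shape[1]} px "
            f"@ {hm.pixel_size_nm} nm", file=buf)
        b = self.psdf.box
        print(
            f"signal box rows [{b.row0}:{b.row1}) cols [{b.col0}:{b.col1}) "
            f"lines along {b.line_direction}; {self.psdf.n_lines_averaged} lines x "
            f"{self.psdf.line_length_samples} samples, dk = {self.psdf.dk:.4f} 1/nm",
            file=buf,
        )
        print("-" * 64, file=buf)
        tab = self.peak_table()
        if len(tab):
            print(tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"), file=buf)
        else:
            print("no peaks above threshold", file=buf)
        print("-" * 64, file=buf)
        print(
            f"harmonic fundamental k0 = {self.harmonics.fundamental_k:.4f} 1/nm "
            f"({2 * math.pi / self.harmonics.fundamental_k:.2f} nm); "
            f"missing harmonics: {list(self.harmonics.missing) or 'none'}",
            file=buf,
        )
        if self.slope_fit is not None:
            sf = self.slope_fit
            print(
                f"two-slope fit: slopes ({sf.slopes[0]:.2f}, {sf.slopes[1]:.2f}), "
                f"knee k = {sf.breakpoint_k:.3f} 1/nm -> correlation length "
                f"{sf.correlation_length_nm:.2f} nm",
                file=buf,
            )
        else:
            print(f"two-slope fit: {self.slope_fit_error}", file=buf)
        return buf.getvalue()

    def plot_psdf(self, ax=None):
        """Log-log spectrum with detected peaks and lattice predictions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.psdf.wavenumbers, self.psdf.power, label="signal box")
        if self.background_psdf is not None:
            ax.loglog(
                self.background_psdf.wavenumbers,
                self.background_psdf.power,
                alpha=0.6,
                label="background box",
            )
        for pk in self.peaks.peaks:
            ax.axvline(pk.wavenumber_inv_nm, color="k", ls=":", lw=0.8)
        for p in self.predicted:
            if p.visibility_weight > 0.3:
                ax.axvline(p.wavenumber_inv_nm, color="r", ls="--", lw=0.6, alpha=0.5)
        ax.set_xlabel("k (1/nm)")
        ax.set_ylabel("power (nm$^3$)")
        ax.legend()
        return ax


@dataclass
class SurfacePeriodicity:
    """Surface-periodicity model for one height map.

    Boxes and line direction default to automatic selection: the virion
    orientation is estimated from image moments, analysis lines are taken
    along the virion axis, and crest/background boxes are placed from the
    height profile.
    """

    heightmap: HeightMap
    signal_box: BoxSelection | None = None
    background_box: BoxSelection | None = None
    helix: HelixParameters = field(default_factory=HelixParameters)
    line_direction: str | None = None

    def __post_init__(self) -> None:
        if self.line_direction is None:
            if self.signal_box is not None:
                self.line_direction = self.signal_box.line_direction
            else:
                angle = estimate_axis(self.heightmap)
                self.line_direction = "columns" if abs(angle) > 45 else "rows"
        if self.signal_box is None or self.background_box is None:
            sig, bg = auto_boxes(self.heightmap, self.line_direction)
            self.signal_box = self.signal_box or sig
            self.background_box = self.background_box or bg

    def fit(
        self,
        snr_threshold: float = 3.0,
        window: str = "none",
        max_harmonic: int = 4,
        optimize_signal_box: bool = False,
        corr_k_range: tuple[float, float] | None = None,
        attenuation_deg: float = 10.0,
    ) -> SurfacePeriodicityResult:
        k0 = wavenumber_of(self.helix.three_turn_repeat_nm)
        sig_box = self.signal_box
        if optimize_signal_box:
            sig_box = optimize_box(self.heightmap, sig_box, k0, window=window)
        psdf = averaged_psdf(self.heightmap, sig_box, window=window)
        bg = averaged_psdf(self.heightmap, self.background_box, window=window)

        pks = detect_peaks(psdf, snr_threshold=snr_threshold)
        flags = (
            compare_background(psdf, bg, pks.wavenumbers, snr_threshold=snr_threshold)
            if len(pks.peaks)
            else {}
        )
        harm = assign_harmonics(pks, k0, max_m=max_harmonic)
        sfit, err = None, None
        try:
            sfit = correlation_length(psdf, k_range=corr_k_range)
        except (DegenerateFitError, ValueError) as exc:
            err = str(exc)
        pred = predicted_peaks(self.helix, max_turns=6, attenuation_deg=attenuation_deg)
        return SurfacePeriodicityResult(
            model=self,
            psdf=psdf,
            background_psdf=bg,
            peaks=pks,
            flags=flags,
            harmonics=harm,
            slope_fit=sfit,
            slope_fit_error=err,
            predicted=pred,
        )
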