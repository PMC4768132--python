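"""Peak detection, harmonic assignment, two-slope fits, axis estimation."""

import math

import numpy as np
import pytest

import helixpsd as h
from helixpsd.peaks import Peak
from helixpsd.scene import HeightMap

N, PX = 720, 0.5
DK = 2 * math.pi / (N * PX)
_BOX = h.BoxSelection(0, 8, 0, N, "rows")


def make_psdf(power: np.ndarray) -> h.PSDFResult:
    k = (np.arange(power.size) + 1) * DK
    return h.PSDFResult(
        wavenumbers=k,
        power=np.asarray(power, dtype=float),
        n_lines_averaged=8,
        line_length_samples=N,
        pixel_size_nm=PX,
        box=_BOX,
    )


def spikes(floor: float, at: dict[int, float], nbins: int = 360) -> h.PSDFResult:
    p = np.full(nbins, floor)
    for i, v in at.items():
        p[i] = v
    return make_psdf(p)


def test_flat_spectrum_no_peaks():
    ps = h.detect_peaks(make_psdf(np.ones(360)), snr_threshold=3.0)
    assert ps.peaks == ()


def test_spike_detection_and_harmonics():
    res = spikes(1.0, {9: 100.0, 29: 40.0})
    ps = h.detect_peaks(res, snr_threshold=3.0)
    assert [p.bin_index for p in ps.peaks] == [9, 29]
    assert ps.peaks[0].snr == pytest.approx(100.0)
    k0 = 10 * DK
    harm = h.assign_harmonics(ps, k0, max_m=3)
    assert sorted(harm.assigned.values()) == [1, 3]
    assert harm.missing == (2,)
    assert harm.harmonic_power_ratios[3] == pytest.approx(0.4)
    assert harm.harmonic_of(2) is None
    assert harm.harmonic_of(1).bin_index == 9


def test_subthreshold_spike_not_detected():
    res = spikes(1.0, {9: 2.5})
    assert h.detect_peaks(res, snr_threshold=3.0).peaks == ()


def test_adjacent_maxima_merge_keeps_stronger():
    res = spikes(1.0, {9: 50.0, 10: 80.0})
    ps = h.detect_peaks(res, snr_threshold=3.0)
    assert [p.bin_index for p in ps.peaks] == [10]


def _peak(i: int, power: float = 10.0) -> Peak:
    k = (i + 1) * DK
    return Peak(k, power, 10.0, 2 * math.pi / k, i)


def test_assignment_tolerance_one_bin():
    ps = h.PeakSet(peaks=(_peak(11),), snr_threshold=3.0, dk=DK)  # 2 bins off m=1
    harm = h.assign_harmonics(ps, 10 * DK, max_m=2)
    assert harm.assigned == {}
    assert harm.missing == (1, 2)
    # explicit wider tolerance rescues it
    harm2 = h.assign_harmonics(ps, 10 * DK, max_m=2, tolerance_k=2.5 * DK)
    assert list(harm2.assigned.values()) == [1]


def test_closest_candidate_wins():
    ps = h.PeakSet(peaks=(_peak(8, 99.0), _peak(9, 5.0)), snr_threshold=3.0, dk=DK)
    harm = h.assign_harmonics(ps, 10 * DK, max_m=1)
    assert harm.harmonic_of(1).bin_index == 9  # closer beats stronger


def test_empty_peakset_all_missing():
    ps = h.PeakSet(peaks=(), snr_threshold=3.0, dk=DK)
    harm = h.assign_harmonics(ps, 10 * DK, max_m=4)
    assert harm.missing == (1, 2, 3, 4)
    assert harm.harmonic_power_ratios == {}


def test_peakset_invariants():
    with pytest.raises(ValueError, match="sorted"):
        h.PeakSet(peaks=(_peak(9), _peak(5)), snr_threshold=3.0, dk=DK)
    with pytest.raises(ValueError, match="threshold"):
        h.PeakSet(peaks=(Peak(DK, 1.0, 1.5, 2 * math.pi / DK, 0),), snr_threshold=3.0, dk=DK)


def knee_power(k: np.ndarray, kc: float, s_lo: float = -0.5, s_hi: float = -3.5):
    """Piecewise power law continuous at the knee kc."""
    p = np.where(k <= kc, (k / kc) ** s_lo, (k / kc) ** s_hi)
    return p


def test_correlation_length_recovers_constructed_knee():
    kc = 1.25  # knee -> correlation length 2*pi/1.25 ~ 5.0 nm
    res = make_psdf(knee_power((np.arange(360) + 1) * DK, kc))
    fit = h.correlation_length(res)
    assert fit.breakpoint_k == pytest.approx(kc, rel=0.10)
    assert fit.correlation_length_nm == pytest.approx(2 * math.pi / kc, rel=0.10)
    assert fit.slopes[0] > fit.slopes[1]  # steeper decay past the knee


def test_correlation_length_monte_carlo_median():
    kc = 1.25
    k = (np.arange(360) + 1) * DK
    clean = knee_power(k, kc)
    rng = np.random.default_rng(31)
    estimates = []
    for _ in range(100):
        noisy = clean * rng.gamma(8.0, 1 / 8.0, size=clean.size)
        try:
            estimates.append(h.correlation_length(make_psdf(noisy)).breakpoint_k)
        except h.DegenerateFitError:
            pass
    assert len(estimates) >= 95
    assert np.median(estimates) == pytest.approx(kc, rel=0.10)


def test_pure_power_law_raises_degenerate():
    k = (np.arange(360) + 1) * DK
    res = make_psdf(k**-2.0)
    with pytest.raises(h.DegenerateFitError, match="identical"):
        h.correlation_length(res)


def test_knee_outside_requested_range_raises():
    kc = 1.25
    k = (np.arange(360) + 1) * DK
    res = make_psdf(knee_power(k, kc))
    with pytest.raises((h.DegenerateFitError, ValueError)):
        h.correlation_length(res, k_range=(2.0, 5.0))


def test_estimate_axis_orientations():
    vals = np.zeros((64, 64))
    vals[30:34, :] = 10.0  # horizontal bar
    assert abs(h.estimate_axis(HeightMap(vals, 1.0))) < 5.0
    vert = np.zeros((64, 64))
    vert[:, 30:34] = 10.0  # vertical bar
    assert abs(h.estimate_axis(HeightMap(vert, 1.0))) > 85.0
    with pytest.raises(ValueError, match="threshold"):
        h.estimate_axis(HeightMap(np.zeros((16, 16)), 1.0))
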