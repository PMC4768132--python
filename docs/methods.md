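# Methods note

This note records the model behind `helixpsd`, the parameter defaults and
their rationale, the numerical choices, and the limits of the synthetic
image generator.

## 1. Lattice model

A helical virion is modelled as a cylinder of outer radius R = 9 nm
carrying one coat protein per lattice site. With pitch p = 2.3 nm per turn
and N₃ = 49 subunits per three turns (s = N₃/3 = 16.33 per turn), subunit
*j* sits at axial position *j*·(3p/N₃) and azimuth *j*·(360°/s)·handedness.
The axial rise per subunit is 3·2.3/49 = 0.1408 nm; the shortest truly
axial lattice translation is the three-turn repeat L₃ = 3p = 6.9 nm.

**Repeat vectors.** After *n* turns the nearest lattice partner of a
subunit has index round(*n*·s). The leftover azimuthal offset
Δφ = (round(*n*·s) − *n*·s)·(360°/s), taken as an arc R·Δφ on the cylinder,
tilts the joining vector off the axis by atan(|arc| / axial). The sign is
positive when the partner lags in azimuth. For the TMV parameters this
gives, for n = 1…6: +27.12°, −13.95°, 0°, +7.19°, −5.71°, 0° (rounded: 27,
−14, 0, 7, −6, 0) at axial distances 2.25, 4.65, 6.9, 9.15, 11.55,
13.8 nm.

**Predicted spectrum.** All wavenumbers use k = 2π/l. An axis-aligned
line-averaged spectrum is predicted to contain (a) one peak per near-axial
repeat, with a Gaussian visibility exp(−(θ/θ₀)²) in the off-axis angle θ
(θ₀ = 10° by default; a tilted repeat decoheres across scan lines, and only
the ordering of the weights is physical, not the scale), and (b) integer
harmonics m·k(L₃) of the three-turn repeat, whose true intensities depend
on how sharply the probe resolves the repeating block and are therefore
listed with unit weight. Key values: k(6.9) = 0.91 nm⁻¹, k(9.2) =
0.68 nm⁻¹, k(2.3) = 2.73 nm⁻¹; the m = 2 harmonic corresponds to
6.9/2 = 3.45 nm.

## 2. Synthetic scene generator

The generator emulates the *statistical* structure of ambient-air AFM
images of TMV on gold; it is not a physical simulation of cantilever
dynamics.

| parameter | default | units | rationale |
|---|---|---|---|
| pitch | 2.3 | nm | TMV lattice |
| subunits per 3 turns | 49 | – | TMV lattice |
| outer radius | 9.0 | nm | 18 nm virion diameter |
| virion length | 380 (default scene) | nm | longer than the 360 nm frame so axis-aligned analysis lines carry no end-cap steps (clipping warns) |
| apparent height | 14.0 | nm | empirical tip–sample compression of the 18 nm rod; applied as an affine z-scale |
| corrugation amplitude | 0.2 | nm | free parameter of the emulation; puts the single-turn harmonic just above the low-noise channel's detection limit |
| corrugation σ (axial) | 0.85 | nm | see §2.1 |
| corrugation aspect (lateral/axial) | 1.47 | – | see §2.1 |
| substrate RMS roughness | 0.4 | nm | evaporated-gold figure; correlation length 1 nm |
| aggregate density / diameter | 30 µm⁻² / 18 | – / nm | coat-protein disk aggregates on the substrate; heights in multiples of 2.3 nm (stacked disks) |
| pixel size | 0.5 | nm | satisfies Nyquist for k = 2.73 nm⁻¹ (limit: < π/2.73 ≈ 1.15 nm) |
| image size (default scene) | 720 × 256 | px | 720-sample lines give bin spacing Δk = 2π/360 = 0.0175 nm⁻¹ ≤ 0.02 nm⁻¹ |

The virion is a z-compressed lying-cylinder silhouette; the grid is
integer-pixel centred so one sample line runs exactly along the crest (the
bare cylinder's maximum is then exactly the apparent height). Substrate
roughness is Gaussian noise filtered to a 1 nm correlation length and
rescaled to exact RMS; it is rendered **off the virion footprint only** — a
rigid 300 nm rod does not conform to sub-nm substrate roughness, and this
keeps the noiseless virion box truly noiseless. Aggregates are rejected
from the virion footprint and composited by pointwise maximum.

### 2.1 Corrugation model and anisotropy

Each protein contributes an anisotropic Gaussian bump on the cylinder
surface, projected to the image plane and tapered by cos(azimuth); only the
upper half-cylinder is visible. The bump is sharper along the axis
(σ_a = 0.85 nm; inter-turn grooves) than along the turn (σ_t = 1.47·σ_a ≈
1.25 nm; neighbouring proteins blend into a quasi-continuous helical
ridge).

The anisotropy is load-bearing. Closed-form structure factors of the crest
bump train (harmonic weights cₘ = 1 + 2w₁₆cos(32πm/49) + 2w₁₇cos(34πm/49)
with lateral Gaussian weights w for the two neighbouring helical strands,
times an axial envelope exp(−(m·k₀·σ_a)²/2)) show that an *isotropic* bump
of width ~1 nm makes the m = 2 harmonic **stronger** than m = 3 — the
opposite of what helical-ridge packing produces physically. Ridge-like
anisotropy suppresses m = 2 below the noise floor while keeping m = 3
(2.73 nm⁻¹) detectable. The exact values (0.85 nm, aspect 1.47) were fixed
in a single calibration pass together with the channel noise presets and
are frozen in `SceneSpec`; they are study conditions, not fitting knobs.

### 2.2 Two-channel noise model

Each scene yields two co-registered channels with the same geometry and
independent noise (`presets.py`, calibrated once and frozen):

- **topography**: white 0.12 nm RMS, per-line offsets 0.05 nm RMS, axial
  phase jitter 2.0 nm RMS;
- **mode2-like**: white 0.08 nm RMS, no line offsets, jitter 0.1 nm RMS.

The jitter is per-recorded-sample positional noise of the corrugation
phase, applied at render time: each pixel reads the lattice at an axial
position perturbed by N(0, σ²). With σ = 2 nm the coherent power of the
0.91 nm⁻¹ fundamental is suppressed by exp(−k²σ²) ≈ 0.036, dropping its
SNR below the detection threshold — this emulates the empirical fact that
standard topography hides the lattice that second-mode channels reveal.
Per-sample (rather than per-scan-line) jitter is required so that masking
works for any virion orientation; a whole-line shift would leave in-line
periodicity intact for a virion lying along the fast scan, and the PSDF
discards phase. `add_noise` additionally offers a per-line lateral jitter
(sub-pixel line shifts via interpolation) as generic measurement noise.

## 3. Tip convolution

An AFM image is, to first order, the greyscale morphological dilation of
the surface by the reflected tip: imaged(x) = max_u [surface(x+u) +
tip(u)], with the tip profile non-positive and zero at the apex. Tips:
sphere (profile −(R−√(R²−r²)), support r ≤ R), paraboloid (−r²/2R,
truncated at 2R), and ideal point (identity). Dilation is extensive
(imaged ≥ true), monotone, and commutes with constant offsets; erosion by
the same tip gives the standard reconstruction lower bound. The
implementation uses `scipy.ndimage.grey_dilation` with edge replication
and is tested for exact agreement with a brute-force double loop.

Blunter tips bridge narrow valleys and drain power from high harmonics, so
P(2.73)/P(0.91) falls with tip radius. One subtlety: this monotonicity
holds on the *apex* scan lines. Off-apex lines acquire laterally-mixed
bump rows under a small tip's lateral contact with the curved crest (the
neighbouring helical strands are axially staggered), which can *raise* the
measured ratio slightly for small tips — a real property of dilation near
a curved crest, and the reason the tip-suppression check uses a narrow
(±1 nm) apex box.

## 4. Spectral estimation

Within a box, each line is mean-removed and transformed with an FFT; the
squared magnitudes are averaged over lines. Conventions, fixed everywhere:

- wavenumber k = 2π/λ, bins at m·2π/(N·Δx), DC excluded;
- one-sided spectrum normalised so Σ power·Δk = mean per-line variance
  (Parseval; power in nm³), exact to 1e−9 in tests;
- no window by default — peak-*position* fidelity matters more than
  sidelobe suppression for line spectra; a Hann window (renormalised to
  preserve broadband Parseval) is available for slope work;
- peak SNR = bin power / median of the surrounding 9-bin window minus the
  3 central bins (the peak and its leakage skirt); detection threshold 3;
- a peak is *signal-specific* when its SNR reaches threshold in the signal
  box and not at the same bin of a same-grid background box;
- harmonic assignment: m = round(k/k₀), accepted within one spectral bin
  (the physical resolution) of m·k₀; unfilled m ≤ m_max are reported
  missing. A missing harmonic is only meaningful against a noise floor: in
  a strictly noiseless spectrum, any nonzero line is "detected" because
  its own leakage skirt sets the local median.

**Correlation length.** Aperiodic roughness shows two power-law regimes in
log-log; the knee is found by exhaustively splitting the usable bins (first
bin and k > 0.8·Nyquist excluded) into two segments of ≥ 4 bins, fitting a
line to each, and intersecting the best pair; the correlation length is
2π/k_break. Near-identical slopes or an out-of-range intersection raise
`DegenerateFitError` — degenerate fits never return silently.

**Box selection.** The default signal box runs along the crest (highest
mean line) with a 1.5 nm half-width; the background box is the same shape
over the lowest-mean region ≥ 12 nm from the crest. `optimize_box`
performs deterministic greedy coordinate ascent on the four edges,
maximising the SNR at a target wavenumber.

## 5. Pipeline and reproducibility

`helixpsd run` resolves a flat `key = value` config, renders or loads a
map, optionally applies a tip, and runs the model. All randomness flows
from explicit seeds (scene seed and per-channel noise seeds); reports carry
a config hash (output location excluded) and no timestamps, so repeated
runs are byte-identical. Line-flattened input maps are refused: per-line
flattening removes exactly the per-line periodic content being analysed.
A missing physical pixel size is a hard error — scale is never guessed.

## 6. Limits of the emulation

- No cantilever dynamics: the "mode2-like" channel is a statistical stand-in
  (low positional jitter, low white floor), not a model of multifrequency
  force transduction; channel noise levels are frozen presets, not physics.
- Geometric dilation only: no elastic deformation, no adhesion, no feedback
  overshoot; the 14 nm apparent height is imposed, not derived.
- The corrugation amplitude (0.2 nm) and bump widths are free parameters
  chosen once; real corrugation contrast depends on imaging regime.
- The substrate is stationary Gaussian roughness plus disk aggregates;
  real gold terraces and contamination are more structured.
- Scan artifacts beyond line offsets and positional jitter (creep,
  thermal drift, skew) are not modelled.
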