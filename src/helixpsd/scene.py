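"""Synthetic scanning-probe scenes of a helical virion on a rough substrate.

Emulates the statistical structure of ambient-air AFM images of TMV: a
~300 x 18 nm rod lying on gold (0.4 nm RMS roughness), apparent height
compressed to ~14 nm, surface corrugation from the 49-subunits-per-three-
turns coat-protein helix, 18 nm disk aggregates in the background, and two
co-registered read-out channels -- a "topography" channel whose strong
phase jitter masks the lattice periodicity and a low-noise "mode2-like"
channel that preserves it.  Scan lines are horizontal (rows); the map value
unit is nm throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .helix import HelixParameters, wavenumber_of

__all__ = ["HeightMap", "SceneSpec", "NoiseSpec", "render_scene", "add_noise", "make_channels"]

# highest wavenumber the analysis must resolve: the single-turn pitch peak
K_MAX_NEEDED_INV_NM = wavenumber_of(2.3)


@dataclass
class HeightMap:
    """A raster of heights (nm) with physical pixel size and a channel tag."""

    values: np.ndarray
    pixel_size_nm: float
    channel_label: str = "topography"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("height map must be a 2D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("height map contains non-finite values")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, metadata_update: dict | None = None) -> "HeightMap":
        meta = dict(self.metadata)
        if metadata_update:
            meta.update(metadata_update)
        return HeightMap(values, self.pixel_size_nm, self.channel_label, meta)


@dataclass(frozen=True)
class SceneSpec:
    """What is on the surface and how it is sampled.

    The corrugation is a Gaussian bump per coat protein, anisotropic on the
    cylinder surface: sharper along the axis (inter-turn grooves) than along
    the turn, where neighbouring proteins blend into a quasi-continuous
    helical ridge.  Amplitude and widths are free parameters of the
    emulation (no real corrugation amplitude is established for TMV under
    attractive-regime imaging); defaults put the single-turn harmonic just
    above the detection limit of the low-noise channel.
    """

    helix: HelixParameters = field(default_factory=HelixParameters)
    orientation_deg: float = 90.0  # virion axis vs fast-scan (horizontal)
    apparent_height_nm: float = 14.0
    corrugation_amplitude_nm: float = 0.2
    corrugation_sigma_nm: float = 0.85  # axial (along virion) bump sigma
    corrugation_aspect: float = 1.47  # lateral sigma = aspect * axial sigma
    substrate_rms_nm: float = 0.4
    substrate_correlation_nm: float = 1.0
    aggregate_density_per_um2: float = 30.0
    aggregate_diameter_nm: float = 18.0
    image_size_px: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_size_nm: float = 0.5

    def __post_init__(self) -> None:
        if self.apparent_height_nm > 2 * self.helix.outer_radius_nm:
            raise ValueError("apparent height cannot exceed the virion diameter")
        if self.pixel_size_nm >= math.pi / K_MAX_NEEDED_INV_NM:
            raise ValueError(
                f"pixel size {self.pixel_size_nm} nm violates Nyquist for "
                f"k = {K_MAX_NEEDED_INV_NM:.2f} 1/nm (need < "
                f"{math.pi / K_MAX_NEEDED_INV_NM:.2f} nm)"
            )
        if self.corrugation_amplitude_nm < 0 or self.corrugation_sigma_nm <= 0:
            raise ValueError("corrugation amplitude must be >= 0 and sigma > 0")

    @property
    def z_compression(self) -> float:
        """Affine z-scaling mapping the 18 nm rod to its apparent height."""
        return self.apparent_height_nm / (2.0 * self.helix.outer_radius_nm)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for one read-out channel.

    white_rms_nm       : i.i.d. per-pixel noise.
    line_offset_rms_nm : constant additive offset per fast-scan line.
    axial_jitter_rms_nm: random axial shift of the corrugation phase per
                         recorded sample (positional noise of the signal).
    """

    white_rms_nm: float = 0.0
    line_offset_rms_nm: float = 0.0
    axial_jitter_rms_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.white_rms_nm, self.line_offset_rms_nm, self.axial_jitter_rms_nm) < 0:
            raise ValueError("noise RMS values must be >= 0")


def _axis_frames(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel virion-frame coordinates (axial a, transverse t), in nm."""
    nrows, ncols = spec.image_size_px
    px = spec.pixel_size_nm
    # integer-pixel center so one sample row/column sits exactly on the crest
    y = (np.arange(nrows) - nrows // 2) * px  # rows: slow scan
    x = (np.arange(ncols) - ncols // 2) * px  # cols: fast scan
    xx = np.broadcast_to(x[None, :], (nrows, ncols))
    yy = np.broadcast_to(y[:, None], (nrows, ncols))
    th = math.radians(spec.orientation_deg)
    a = xx * math.cos(th) + yy * math.sin(th)
    t = -xx * math.sin(th) + yy * math.cos(th)
    return a, t


def _corrugation_grid(spec: SceneSpec, a_min: float, a_max: float) -> tuple[np.ndarray, float, float]:
    """Corrugation field on a regular (axial, transverse) grid.

    Returns (field, a0, t0): field[i, j] at axial a0 + i*px and transverse
    t0 + j*px.  One anisotropic Gaussian bump per coat protein on the upper
    half of the cylinder, projected to the image plane, amplitude tapered by
    cos(azimuth) (the bump normal tilts away from vertical off the crest).
    """
    px = spec.pixel_size_nm
    hel = spec.helix
    R = hel.outer_radius_nm
    sig_a = spec.corrugation_sigma_nm
    sig_t = spec.corrugation_sigma_nm * spec.corrugation_aspect
    pad = 4.0 * sig_a
    a0 = a_min - pad
    t0 = -R
    na = int(math.ceil((a_max - a_min + 2 * pad) / px)) + 1
    nt = int(math.ceil(2 * R / px)) + 1
    fielda = np.zeros((na, nt))
    if spec.corrugation_amplitude_nm == 0:
        return fielda, a0, t0

    rise = hel.axial_rise_per_subunit_nm
    j_lo = int(math.floor((a0 - pad) / rise))
    j_hi = int(math.ceil((a0 + (na - 1) * px + pad) / rise))
    j = np.arange(j_lo, j_hi + 1)
    a_j = j * rise
    phi_j = np.mod(j * hel.azimuth_step_deg * hel.handedness + 180.0, 360.0) - 180.0
    vis = np.abs(phi_j) < 90.0
    a_j, phi_j = a_j[vis], phi_j[vis]
    t_j = R * np.sin(np.deg2rad(phi_j))
    amp_j = spec.corrugation_amplitude_nm * np.cos(np.deg2rad(phi_j))

    wa = int(math.ceil(4.0 * sig_a / px))
    wt = int(math.ceil(4.0 * sig_t / px))
    a_ax = np.arange(na) * px + a0
    t_ax = np.arange(nt) * px + t0
    for ac, tc, amp in zip(a_j, t_j, amp_j):
        ia = int(round((ac - a0) / px))
        it = int(round((tc - t0) / px))
        ia0, ia1 = max(ia - wa, 0), min(ia + wa + 1, na)
        it0, it1 = max(it - wt, 0), min(it + wt + 1, nt)
        if ia0 >= ia1 or it0 >= it1:
            continue
        da = (a_ax[ia0:ia1] - ac) / sig_a
        dt = (t_ax[it0:it1] - tc) / sig_t
        fielda[ia0:ia1, it0:it1] += amp * np.exp(
            -0.5 * (da[:, None] ** 2 + dt[None, :] ** 2)
        )
    return fielda, a0, t0


def render_scene(
    spec: SceneSpec,
    seed: int = 0,
    *,
    axial_jitter_rms_nm: float = 0.0,
    jitter_seed: int | None = None,
    channel_label: str = "topography",
) -> HeightMap:
    """Render the scene to a height map.  Deterministic for fixed seeds.

    ``seed`` drives substrate roughness and aggregate placement (the static
    scene); ``axial_jitter_rms_nm`` optionally shifts the axial position at
    which each recorded pixel samples the corrugation by a random amount
    drawn with ``jitter_seed``, emulating positional/phase noise of the
    recorded contrast channel.
    """
    nrows, ncols = spec.image_size_px
    px = spec.pixel_size_nm
    hel = spec.helix
    R = hel.outer_radius_nm
    half_len = hel.length_nm / 2.0
    a, t = _axis_frames(spec)

    frame_a = max(np.abs(a[0, 0]), np.abs(a[-1, -1]), np.abs(a[0, -1]), np.abs(a[-1, 0]))
    if half_len > frame_a:
        warnings.warn("virion does not fit in the frame; clipping", stacklevel=2)

    footprint = (np.abs(t) <= R) & (np.abs(a) <= half_len)

    # --- virion body: lying cylinder silhouette, z-compressed -------------
    virion = np.zeros((nrows, ncols))
    tt = t[footprint]
    virion[footprint] = (R + np.sqrt(np.clip(R**2 - tt**2, 0.0, None))) * spec.z_compression

    # --- coat-protein corrugation -----------------------------------------
    if spec.corrugation_amplitude_nm > 0:
        a_lo = max(a[footprint].min(), -half_len) if footprint.any() else 0.0
        a_hi = min(a[footprint].max(), half_len) if footprint.any() else 0.0
        grid, a0, t0 = _corrugation_grid(spec, a_lo, a_hi)
        a_s = a.copy()
        if axial_jitter_rms_nm > 0:
            # per-sample positional noise of the recorded corrugation phase:
            # each recorded pixel reads the lattice at a randomly shifted
            # axial position, so the periodicity decoheres along the analysis
            # direction whatever the virion orientation
            rng_j = np.random.default_rng(jitter_seed if jitter_seed is not None else seed + 1)
            a_s += rng_j.normal(0.0, axial_jitter_rms_nm, size=(nrows, ncols))
        coords = np.vstack([((a_s - a0) / px)[footprint], ((t - t0) / px)[footprint]])
        corr = ndimage.map_coordinates(grid, coords, order=1, mode="constant", cval=0.0)
        virion[footprint] += corr

    # --- substrate roughness and aggregates (static scene randomness) -----
    rng = np.random.default_rng(seed)
    background = np.zeros((nrows, ncols))
    if spec.substrate_rms_nm > 0:
        rough = rng.standard_normal((nrows, ncols))
        sig_px = spec.substrate_correlation_nm / px
        if sig_px > 0:
            rough = ndimage.gaussian_filter(rough, sig_px, mode="wrap")
        rough *= spec.substrate_rms_nm / rough.std()
        background += rough

    if spec.aggregate_density_per_um2 > 0:
        area_um2 = (nrows * px * 1e-3) * (ncols * px * 1e-3)
        n_agg = rng.poisson(spec.aggregate_density_per_um2 * area_um2)
        r_agg = spec.aggregate_diameter_nm / 2.0
        yc = (np.arange(nrows) - nrows // 2) * px
        xc = (np.arange(ncols) - ncols // 2) * px
        placed = 0
        attempts = 0
        while placed < n_agg and attempts < 20 * max(n_agg, 1):
            attempts += 1
            cy = rng.uniform(yc[0], yc[-1])
            cx = rng.uniform(xc[0], xc[-1])
            h_agg = 2.3 * rng.integers(1, 4)  # 1-3 stacked 17-protein disks
            th = math.radians(spec.orientation_deg)
            a_c = cx * math.cos(th) + cy * math.sin(th)
            t_c = -cx * math.sin(th) + cy * math.cos(th)
            # keep aggregates off the virion footprint (they sit on gold)
            if abs(t_c) <= R + r_agg + 2.0 and abs(a_c) <= half_len + r_agg + 2.0:
                continue
            rr2 = (yc[:, None] - cy) ** 2 + (xc[None, :] - cx) ** 2
            cap = h_agg * np.sqrt(np.clip(1.0 - rr2 / r_agg**2, 0.0, None))
            mask = cap > 0
            background[mask] = np.maximum(background[mask], cap[mask])
            placed += 1

    values = np.where(footprint, virion, background)
    meta = {
        "seed": seed,
        "orientation_deg": spec.orientation_deg,
        "pitch_nm": hel.pitch_nm,
        "subunits_per_three_turns": hel.subunits_per_three_turns,
        "apparent_height_nm": spec.apparent_height_nm,
        "axial_jitter_rms_nm": axial_jitter_rms_nm,
    }
    return HeightMap(values, px, channel_label, meta)


def add_noise(heightmap: HeightMap, noise: NoiseSpec) -> HeightMap:
    """Add measurement noise; reproducible for a fixed ``noise.seed``.

    White noise is i.i.d. per pixel; line offsets are constant within each
    fast-scan line (row); the jitter term shifts each line along the fast
    scan by a random sub-pixel amount (linear interpolation).  All-zero RMS
    returns values identical to the input.
    """
    rng = np.random.default_rng(noise.seed)
    vals = heightmap.values.copy()
    nrows, ncols = vals.shape
    if noise.axial_jitter_rms_nm > 0:
        shifts = rng.normal(0.0, noise.axial_jitter_rms_nm / heightmap.pixel_size_nm, nrows)
        xi = np.arange(ncols)
        for r in range(nrows):
            vals[r] = np.interp(xi + shifts[r], xi, vals[r])
    if noise.line_offset_rms_nm > 0:
        vals += rng.normal(0.0, noise.line_offset_rms_nm, nrows)[:, None]
    if noise.white_rms_nm > 0:
        vals += rng.normal(0.0, noise.white_rms_nm, vals.shape)
    return heightmap.with_values(vals, metadata_update={"noise_seed": noise.seed})


def make_channels(
    spec: SceneSpec,
    topo_noise: NoiseSpec,
    mode2_noise: NoiseSpec,
    scene_seed: int = 0,
) -> tuple[HeightMap, HeightMap]:
    """Two co-registered channels of one scene.

    Same geometry, substrate and aggregates; independent noise.  The
    "topography" channel carries high phase jitter of the corrugation
    (masking the lattice periodicity, as in standard AM-AFM), the
    "mode2-like" channel low jitter (periodicity visible).  The jitter acts
    on the corrugation's axial phase at render time, per recorded sample.
    """
    if mode2_noise.axial_jitter_rms_nm > topo_noise.axial_jitter_rms_nm:
        raise ValueError("mode2 channel jitter must not exceed topography jitter")

    def one(noise: NoiseSpec, label: str) -> HeightMap:
        m = render_scene(
            spec,
            scene_seed,
            axial_jitter_rms_nm=noise.axial_jitter_rms_nm,
            jitter_seed=noise.seed + 1,
            channel_label=label,
        )
        post = replace(noise, axial_jitter_rms_nm=0.0)  # jitter consumed at render
        return add_noise(m, post)

    return one(topo_noise, "topography"), one(mode2_noise, "mode2-like")
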