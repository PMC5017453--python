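"""Synthetic fixtures with known ground truth.

Three generators emulate the study conditions of a fiber-bundle
hyperspectral endoscope:

* :func:`render_honeycomb` — imprints the quasi-periodic honeycomb pattern
  of a hexagonal fiber-core lattice onto any scene.  Each lattice site
  integrates the scene over its core disc and re-emits a Gaussian-profile
  bright core over darker cladding.  Because a fiber funnels the light it
  collects over its whole cell through the much smaller core, core centers
  overshoot the pattern-free scene while cladding undershoots it — the
  same above/below modulation seen in recorded honeycomb spectra, where
  filtering darkens center pixels and brightens ring pixels.
* :func:`make_usaf_scene` — a USAF-style resolution chart (groups of three
  dark bars on a bright field, bar width equal to gap width), together
  with the homogeneous region and bar-crossing line profiles the quality
  metrics need.
* :func:`make_two_tissue_cube` — a larynx-like 30-band cube: two tissues
  with distinct smooth reflectance spectra, an elliptical lesion, a
  multiplicative illumination gradient, band-dependent Gaussian noise
  (strongest in the two lowest-wavelength bands) and optional saturated
  specular blobs recorded in an exclusion mask.

All generators are deterministic for a fixed seed, and every rendered
fixture returns its exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .io import HSCube
from .metrics import MetricRegions

__all__ = [
    "HoneycombSpec",
    "SceneSpec",
    "render_honeycomb",
    "make_usaf_scene",
    "make_two_tissue_cube",
    "default_reflectances",
]


@dataclass
class HoneycombSpec:
    """Geometry and gains of the emulated fiber bundle.

    pitch : center-to-center fiber spacing in px.
    core_radius : core disc radius in px (< pitch / 2).
    core_gain, cladding_gain : transmission factors in [0, 1],
        core_gain > cladding_gain.
    lattice_angle : lattice orientation in degrees (kept off-axis by
        default so peaks do not align with the FFT grid axes).
    jitter : per-fiber positional noise sd in px.
    conserve_flux : scale each core's peak by (lattice cell area) /
        (effective Gaussian core area) so the emitted flux matches the
        collected flux; this produces the bright-dot overshoot of real
        fiber images.
    """

    pitch: float = 8.0
    core_radius: float = 3.0
    core_gain: float = 0.9
    cladding_gain: float = 0.35
    lattice_angle: float = 10.0
    jitter: float = 0.15
    seed: int = 0
    conserve_flux: bool = True

    def __post_init__(self):
        if not (0 < self.core_radius < self.pitch / 2):
            raise ValueError("need 0 < core_radius < pitch/2")
        for g in (self.core_gain, self.cladding_gain):
            if not (0 <= g <= 1):
                raise ValueError("gains must lie in [0, 1]")
        if self.core_gain <= self.cladding_gain:
            raise ValueError("core_gain must exceed cladding_gain")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")

    @property
    def profile_sigma(self) -> float:
        """Gaussian core profile width (core_radius / 2)."""
        return self.core_radius / 2.0

    @property
    def flux_boost(self) -> float:
        if not self.conserve_flux:
            return 1.0
        cell = (math.sqrt(3) / 2.0) * self.pitch ** 2
        return cell / (2.0 * math.pi * self.profile_sigma ** 2)


def _lattice_centers(shape, spec: HoneycombSpec) -> np.ndarray:
    h, w = shape
    th = math.radians(spec.lattice_angle)
    a1 = spec.pitch * np.array([math.sin(th), math.cos(th)])
    a2 = spec.pitch * np.array([math.sin(th + math.pi / 3), math.cos(th + math.pi / 3)])
    m = int(math.ceil((h + w) / spec.pitch)) + 2
    ii, jj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    centers = ii[..., None] * a1 + jj[..., None] * a2
    centers = centers.reshape(-1, 2)
    pad = spec.pitch
    keep = ((centers[:, 0] > -pad) & (centers[:, 0] < h + pad)
            & (centers[:, 1] > -pad) & (centers[:, 1] < w + pad))
    centers = centers[keep]
    rng = np.random.default_rng(spec.seed)
    if spec.jitter > 0:
        centers = centers + rng.normal(0.0, spec.jitter, centers.shape)
    return centers


def _core_splats(shape, centers, sigma):
    """Flattened pixel indices, Gaussian weights and fiber ids of every
    core's splat footprint (radius 3 sigma)."""
    h, w = shape
    reach = max(int(math.ceil(3 * sigma)), 1)
    idx_parts, w_parts, id_parts = [], [], []
    for fid, (cr, cc) in enumerate(centers):
        r0, r1 = int(math.floor(cr)) - reach, int(math.floor(cr)) + reach + 1
        c0, c1 = int(math.floor(cc)) - reach, int(math.floor(cc)) + reach + 1
        r0, r1 = max(r0, 0), min(r1, h)
        c0, c1 = max(c0, 0), min(c1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc2 = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        d2 = (rr - cr) ** 2 + (cc2 - cc) ** 2
        prof = np.exp(-d2 / (2 * sigma ** 2)).ravel()
        idx_parts.append((rr * w + cc2).ravel())
        w_parts.append(prof)
        id_parts.append(np.full(prof.size, fid, dtype=np.int64))
    return (np.concatenate(idx_parts), np.concatenate(w_parts),
            np.concatenate(id_parts))


def _disc_kernel(radius: float) -> np.ndarray:
    r = max(int(math.ceil(radius)), 1)
    ax = np.arange(-r, r + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    k = (d2 <= radius ** 2).astype(float)
    return k / k.sum()


def render_honeycomb(scene, spec: HoneycombSpec | None = None):
    """Imprint the honeycomb pattern onto a scene (2D image, (B, H, W)
    stack or :class:`HSCube`).

    Returns ``(rendered, ground_truth)``; the ground truth is the input
    scene itself, unchanged.  For a cube input the same jittered lattice is
    used for every band (the bundle does not move between bands).
    """
    spec = spec or HoneycombSpec()
    if isinstance(scene, HSCube):
        rendered, truth = render_honeycomb(scene.bands, spec)
        return (HSCube(bands=rendered, wavelengths_nm=scene.wavelengths_nm,
                       masks=dict(scene.masks)), truth)
    scene = np.asarray(scene, dtype=float)
    single = scene.ndim == 2
    stack = scene[None] if single else scene
    if stack.ndim != 3:
        raise ValueError("scene must be 2D or (B, H, W)")
    h, w = stack.shape[1:]
    centers = _lattice_centers((h, w), spec)
    sigma = spec.profile_sigma
    idx, weights, fiber_ids = _core_splats((h, w), centers, sigma)
    coverage = np.zeros(h * w)
    np.add.at(coverage, idx, weights)
    coverage = np.clip(coverage, 0.0, 1.0).reshape(h, w)
    disc = _disc_kernel(spec.core_radius)
    ci = np.clip(np.round(centers[:, 0]).astype(int), 0, h - 1)
    cj = np.clip(np.round(centers[:, 1]).astype(int), 0, w - 1)
    boost = spec.flux_boost
    out = np.empty_like(stack)
    for b, band in enumerate(stack):
        local_mean = fftconvolve(band, disc, mode="same")
        samples = local_mean[ci, cj]
        cores = np.zeros(h * w)
        np.add.at(cores, idx, weights * samples[fiber_ids])
        cores = cores.reshape(h, w)
        out[b] = (band * spec.cladding_gain * (1.0 - coverage)
                  + spec.core_gain * boost * cores)
    out = np.clip(out, 0.0, None)
    truth = scene.copy()
    return (out[0] if single else out), truth


def make_usaf_scene(groups=(16, 8, 4), shape=(512, 512), background=0.9,
                    bar_value=0.0):
    """USAF-style chart: per group, three dark vertical bars of width equal
    to the gap width, descending sizes.  Returns ``(scene, regions)`` with
    the homogeneous-area mask and one bar-crossing profile per group."""
    groups = tuple(groups)
    if not groups or any(g <= 0 for g in groups):
        raise ValueError("bar sizes must be positive")
    if any(a <= b for a, b in zip(groups[1:], groups)):
        pass  # descending recommended but not essential
    h, w = shape
    scene = np.full((h, w), float(background))
    col0 = max(w // 8, 8)
    row = max(h // 16, 8)
    profiles = []
    for g in groups:
        height = 5 * g
        span = 5 * g  # 3 bars + 2 gaps
        if col0 + span >= w or row + height >= h:
            raise ValueError(f"bar group of size {g} exceeds the canvas")
        for k in range(3):
            c = col0 + 2 * k * g
            scene[row:row + height, c:c + g] = bar_value
        prow = row + height // 2
        profiles.append(((float(prow), float(max(col0 - g, 0))),
                         (float(prow), float(min(col0 + span + g, w - 1)))))
        row += height + max(h // 20, 12)
    homog = np.zeros((h, w), dtype=bool)
    homog[h // 4: 3 * h // 4, w - w // 3: w - max(w // 16, 8)] = True
    regions = MetricRegions(homogeneous_region=homog, line_profiles=profiles)
    return scene, regions


def default_reflectances(wavelengths_nm):
    """Two smooth, distinct tissue reflectance curves in [0, 1].

    Tissue A (healthy mucosa): rising toward red with a mild hemoglobin
    dip; tissue B (lesion): flatter, darker, with a shifted absorption
    feature.  These are phenomenological shapes, not measured spectra.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    a = 0.30 + 0.35 / (1 + np.exp(-(wl - 580.0) / 30.0)) \
        - 0.12 * np.exp(-((wl - 545.0) / 25.0) ** 2)
    b = 0.40 + 0.10 / (1 + np.exp(-(wl - 600.0) / 40.0)) \
        - 0.18 * np.exp(-((wl - 470.0) / 40.0) ** 2)
    return np.clip(a, 0.02, 0.98), np.clip(b, 0.02, 0.98)


@dataclass
class SceneSpec:
    """Parameters of the two-tissue larynx-like cube generator."""

    kind: str = "two_tissue"
    shape: tuple = (128, 128)
    n_bands: int = 30
    wavelength_start: float = 390.0
    wavelength_step: float = 10.0
    reflectance_a: np.ndarray | None = None
    reflectance_b: np.ndarray | None = None
    illumination_range: tuple = (0.5, 1.0)
    intensity_scale: float = 2000.0
    noise_sd: float = 8.0
    low_band_noise_sd: float = 40.0
    n_noisy_low_bands: int = 2
    lesion_center: tuple = (0.62, 0.58)   # relative (row, col)
    lesion_axes: tuple = (0.18, 0.13)     # relative semi-axes
    lesion_angle: float = 25.0
    specular_blobs: list = field(default_factory=lambda: [(0.30, 0.72, 4.0),
                                                          (0.75, 0.25, 3.0)])
    saturation_value: float = 4095.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.low_band_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.wavelength_start + self.wavelength_step * np.arange(self.n_bands)


def _illumination(shape, lo, hi):
    h, w = shape
    rr, cc = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    ramp = 0.55 * cc + 0.25 * rr
    bump = 0.20 * np.exp(-(((rr - 0.45) ** 2 + (cc - 0.4) ** 2) / 0.18))
    t = ramp + bump
    t = (t - t.min()) / np.ptp(t)
    return lo + (hi - lo) * t


def _ellipse_mask(shape, center_rel, axes_rel, angle_deg):
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cr, ccn = center_rel[0] * h, center_rel[1] * w
    ar, ac = axes_rel[0] * h, axes_rel[1] * w
    th = math.radians(angle_deg)
    dr, dc = rr - cr, cc - ccn
    u = dr * math.cos(th) + dc * math.sin(th)
    v = -dr * math.sin(th) + dc * math.cos(th)
    return (u / ar) ** 2 + (v / ac) ** 2 <= 1.0


def make_two_tissue_cube(spec: SceneSpec | None = None):
    """Larynx-like two-tissue cube with full ground truth.

    Band image = illumination(x, y) * intensity_scale * reflectance(band)
    per tissue, plus zero-mean Gaussian noise (sd ``low_band_noise_sd`` in
    the ``n_noisy_low_bands`` lowest bands, ``noise_sd`` elsewhere).  The
    elliptical lesion carries the tissue-B spectrum.  Specular blobs are
    saturated in every band and recorded in the SR mask.

    Returns ``(cube, lesion_mask, sr_mask)``; the masks are also attached
    to ``cube.masks`` under ``"lesion"`` and ``"specular"``.
    """
    spec = spec or SceneSpec()
    h, w = spec.shape
    wl = spec.wavelengths_nm
    ra, rb = spec.reflectance_a, spec.reflectance_b
    if ra is None or rb is None:
        da, db = default_reflectances(wl)
        ra = da if ra is None else np.asarray(ra, float)
        rb = db if rb is None else np.asarray(rb, float)
    ra, rb = np.asarray(ra, float), np.asarray(rb, float)
    if ra.shape != (spec.n_bands,) or rb.shape != (spec.n_bands,):
        raise ValueError("reflectance vectors must have one entry per band")
    if np.min(ra) < 0 or np.max(ra) > 1 or np.min(rb) < 0 or np.max(rb) > 1:
        raise ValueError("reflectances must lie in [0, 1]")
    lesion = _ellipse_mask((h, w), spec.lesion_center, spec.lesion_axes,
                           spec.lesion_angle)
    illum = _illumination((h, w), *spec.illumination_range)
    rng = np.random.default_rng(spec.seed)
    bands = np.empty((spec.n_bands, h, w))
    for b in range(spec.n_bands):
        refl = np.where(lesion, rb[b], ra[b])
        img = illum * spec.intensity_scale * refl
        sd = (spec.low_band_noise_sd if b < spec.n_noisy_low_bands
              else spec.noise_sd)
        if sd > 0:
            img = img + rng.normal(0.0, sd, (h, w))
        bands[b] = img
    sr = np.zeros((h, w), dtype=bool)
    for (r_rel, c_rel, radius) in spec.specular_blobs:
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        blob = (rr - r_rel * h) ** 2 + (cc - c_rel * w) ** 2 <= radius ** 2
        sr |= blob
    bands[:, sr] = spec.saturation_value
    bands = np.clip(bands, 0.0, None)
    cube = HSCube(bands=bands, wavelengths_nm=wl,
                  masks={"lesion": lesion, "specular": sr})
    return cube, lesion, sr
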