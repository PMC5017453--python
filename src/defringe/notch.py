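"""Adaptive windowed notch filters in the Fourier domain.

For each detected interference peak the affected spectral neighborhood is
measured by a strict-descent flood fill; its maximum Euclidean radius ``d``
sets the edge length of a square filter window, ``n = 2*ceil(d*a) + 1``,
where ``a`` is a scaling factor.  The ``n x n`` neighborhood of the peak is
then multiplied element-wise by a radial filter matrix ``G`` with gain 0 at
the peak rising to 1 at the window edge, in one of six designs:

==============  ==========================================================
gaussian        ``1 - exp(-r^2 / (2 sigma^2))``, sigma = 0.3
super_gaussian  ``1 - exp(-(r / kappa)^b)``, kappa = 0.3, b = 6.0
hanning         ``1 - 0.5 (cos(pi r) + 1)`` for r <= 1, else 1
bartlett        ``r`` for r <= 1, else 1
ideal           ``0`` for r <= 1, else 1
smoothed_ideal  ideal convolved with a 9 x 9 Gaussian kernel
==============  ==========================================================

with ``r`` the window-normalized radius from the center (``r = 1`` at the
mid-edge points, ``sqrt(2)`` at the corners).  Each window is mirrored
through DC so the spectrum stays Hermitian; DC itself is never attenuated.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .fourier import (FourierSpectrum, forward_fft, hermitian_partner,
                      inverse_fft, log_magnitude, mirror_spectrum)
from .peaks import Peak, PeakDetectionParams, detect_peaks

__all__ = [
    "SizingParams",
    "NotchWindow",
    "FILTER_DESIGNS",
    "affected_extent",
    "window_size",
    "make_filter",
    "apply_notch",
    "remove_honeycomb",
    "HoneycombNotchFilter",
]

_NEIGHBORS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))

FILTER_DESIGNS = ("gaussian", "super_gaussian", "hanning", "bartlett",
                  "ideal", "smoothed_ideal")


@dataclass
class SizingParams:
    """Window sizing: ``n = 2*ceil(d * scale_a) + 1``.

    ``max_fraction`` caps ``n`` at that fraction of the smaller spectrum
    dimension (rounded down to odd) so a runaway extent cannot notch out a
    large part of the spectrum.
    """

    scale_a: float = 1.0
    max_fraction: float = 0.25

    def __post_init__(self):
        if self.scale_a <= 0:
            raise ValueError("scale_a must be positive")
        if not (0 < self.max_fraction <= 1):
            raise ValueError("max_fraction must be in (0, 1]")


@dataclass
class NotchWindow:
    """Per-peak square filter region: the peak, its size and gain matrix."""

    peak: Peak
    size_n: int
    design: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.size_n < 3 or self.size_n % 2 == 0:
            raise ValueError("size_n must be odd and >= 3")
        if self.matrix.shape != (self.size_n, self.size_n):
            raise ValueError("matrix shape does not match size_n")
        if self.matrix.min() < 0 or self.matrix.max() > 1:
            raise ValueError("matrix values must lie in [0, 1]")


def affected_extent(surface, peak) -> tuple:
    """Strict-descent flood region of a peak and its maximum radius ``d``.

    Starting at the peak, an 8-connected region grows by path-monotone
    descent: a neighbor joins iff its value is strictly less than the value
    of the pixel it is reached from.  Returns ``(region, d)`` where
    ``region`` is a boolean raster and ``d`` the largest Euclidean distance
    from the peak to any region pixel (0 when nothing descends).
    """
    s = np.asarray(surface, dtype=float)
    h, w = s.shape
    pos = peak.pos if isinstance(peak, Peak) else tuple(peak)
    r0, c0 = pos
    region = np.zeros((h, w), dtype=bool)
    region[r0, c0] = True
    queue = deque([(r0, c0)])
    d2max = 0
    while queue:
        r, c = queue.popleft()
        v = s[r, c]
        for dr, dc in _NEIGHBORS8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not region[nr, nc] and s[nr, nc] < v:
                region[nr, nc] = True
                queue.append((nr, nc))
                d2 = (nr - r0) ** 2 + (nc - c0) ** 2
                if d2 > d2max:
                    d2max = d2
    return region, math.sqrt(d2max)


def window_size(d: float, params: SizingParams, spectrum_shape=None) -> int:
    """Odd window edge length for extent radius ``d``.

    ``n = 2*ceil(d*a) + 1``, clamped to at least 3 and (when a shape is
    given) to ``max_fraction * min(H, W)`` rounded down to odd.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    n = 2 * math.ceil(d * params.scale_a) + 1
    n = max(n, 3)
    if spectrum_shape is not None:
        cap = int(params.max_fraction * min(spectrum_shape))
        if cap % 2 == 0:
            cap -= 1
        if cap >= 3:
            n = min(n, cap)
    return n


def _radius_grid(n: int) -> np.ndarray:
    half = (n - 1) / 2.0
    ax = (np.arange(n) - half) / half
    return np.hypot(ax[:, None], ax[None, :])


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def make_filter(design: str, n: int, sigma: float = 0.3, kappa: float = 0.3,
                b: float = 6.0, smooth_kernel_size: int = 9,
                smooth_sigma: float = 1.8) -> np.ndarray:
    """Radial ``n x n`` gain matrix for one of the six designs.

    All designs are 0 at the center and rise to 1; ``smoothed_ideal`` is
    the ideal disc convolved with a normalized Gaussian kernel
    (``smooth_kernel_size`` square, sigma ``smooth_sigma`` px), treating
    everything outside the window as pass-band (gain 1), then clipped to
    [0, 1].
    """
    if n < 3 or n % 2 == 0:
        raise ValueError("n must be odd and >= 3")
    r = _radius_grid(n)
    if design == "gaussian":
        return 1.0 - np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    if design == "super_gaussian":
        return 1.0 - np.exp(-((r / kappa) ** b))
    if design == "hanning":
        return np.where(r <= 1.0, 1.0 - 0.5 * (np.cos(np.pi * r) + 1.0), 1.0)
    if design == "bartlett":
        return np.where(r <= 1.0, r, 1.0)
    if design == "ideal":
        return np.where(r <= 1.0, 0.0, 1.0)
    if design == "smoothed_ideal":
        ideal = np.where(r <= 1.0, 0.0, 1.0)
        kernel = _gaussian_kernel(smooth_kernel_size, smooth_sigma)
        # pad with pass-band so the border of the window is not darkened
        sm = ndimage.convolve(ideal, kernel, mode="constant", cval=1.0)
        return np.clip(sm, 0.0, 1.0)
    raise ValueError(f"unknown filter design {design!r}; choose from {FILTER_DESIGNS}")


def _place(gain: np.ndarray, matrix: np.ndarray, center) -> None:
    """Multiply ``matrix`` (odd square) into ``gain`` centered at ``center``,
    clipped to the in-bounds overlap."""
    h, w = gain.shape
    n = matrix.shape[0]
    half = n // 2
    r0, c0 = center[0] - half, center[1] - half
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + n, h), min(c0 + n, w)
    if rs >= re or cs >= ce:
        return
    gain[rs:re, cs:ce] *= matrix[rs - r0:re - r0, cs - c0:ce - c0]


def notch_gain(shape, window: NotchWindow) -> np.ndarray:
    """Full-spectrum gain field of one notch window plus its Hermitian
    mirror, with the DC coefficient forced to unit gain."""
    h, w = shape
    dc = (h // 2, w // 2)
    gain = np.ones((h, w))
    pr, pc = window.peak.pos
    _place(gain, window.matrix, (pr, pc))
    mirror_center = hermitian_partner((pr, pc), (h, w))
    _place(gain, window.matrix[::-1, ::-1], mirror_center)
    # exact symmetrization guards against border clipping asymmetries
    gain = np.minimum(gain, mirror_spectrum(gain))
    if gain[dc] < 1.0:
        warnings.warn("notch window covers DC; DC gain forced to 1")
        gain[dc] = 1.0
    return gain


def apply_notch(spectrum: FourierSpectrum, window: NotchWindow) -> FourierSpectrum:
    """Hadamard-multiply one notch window (and its conjugate mirror) into
    the spectrum.  DC is never attenuated; out-of-bounds parts of the
    window are clipped."""
    gain = notch_gain(spectrum.shape, window)
    return FourierSpectrum(spectrum.coeffs * gain)


def remove_honeycomb(image, detection: PeakDetectionParams | None = None,
                     sizing: SizingParams | None = None,
                     design: str = "super_gaussian", **filter_kwargs):
    """Full single-image pipeline: FFT -> peak detection -> per-peak window
    sizing -> notch filtering -> inverse FFT.

    Returns ``(filtered, report)`` where ``report`` is a list of dicts with
    each surviving peak's position, amplitude, extent radius ``d`` and
    window size ``n``.  The output raster is real with negatives clipped to
    zero (intensities are physical).
    """
    detection = detection or PeakDetectionParams()
    sizing = sizing or SizingParams()
    if design not in FILTER_DESIGNS:
        raise ValueError(f"unknown filter design {design!r}")
    image = np.asarray(image, dtype=float)
    spec = forward_fft(image)
    surf = log_magnitude(spec)
    peaks = detect_peaks(surf, detection)
    gain = np.ones(spec.shape)
    report = []
    for pk in peaks:  # descending amplitude
        _, d = affected_extent(surf, pk)
        n = window_size(d, sizing, spec.shape)
        matrix = make_filter(design, n, **filter_kwargs)
        win = NotchWindow(peak=pk, size_n=n, design=design, matrix=matrix)
        gain *= notch_gain(spec.shape, win)
        report.append({"row": pk.pos[0], "col": pk.pos[1],
                       "amplitude": pk.amplitude, "d": d, "n": n})
    filtered = inverse_fft(FourierSpectrum(spec.coeffs * gain))
    return np.clip(filtered, 0.0, None), report


class HoneycombNotchFilter(BaseEstimator, TransformerMixin):
    """Adaptive Fourier notch filter for fiber-bundle honeycomb patterns.

    A stateless scikit-learn transformer: :meth:`fit` only validates,
    :meth:`transform` runs the full detection/sizing/filtering pipeline on
    each band independently (peak locations vary within and between cubes,
    so nothing learned from one band transfers to another).

    Parameters mirror the functional API: detection (``tolerance_t``,
    ``tolerance_fraction``, ``dc_exclusion_radius``, ``border_margin``,
    ``max_peaks``), sizing (``scale_a``, ``max_fraction``) and the filter
    ``design`` with its shape constants.

    Attributes
    ----------
    reports_ : list of per-band peak reports from the last transform.
    """

    def __init__(self, design="super_gaussian", tolerance_t=None,
                 tolerance_fraction=0.10, dc_exclusion_radius=10.0,
                 border_margin=4, max_peaks=None, scale_a=1.0,
                 max_fraction=0.25, sigma=0.3, kappa=0.3, b=6.0):
        self.design = design
        self.tolerance_t = tolerance_t
        self.tolerance_fraction = tolerance_fraction
        self.dc_exclusion_radius = dc_exclusion_radius
        self.border_margin = border_margin
        self.max_peaks = max_peaks
        self.scale_a = scale_a
        self.max_fraction = max_fraction
        self.sigma = sigma
        self.kappa = kappa
        self.b = b

    def _params(self):
        det = PeakDetectionParams(
            tolerance_t=self.tolerance_t,
            tolerance_fraction=self.tolerance_fraction,
            dc_exclusion_radius=self.dc_exclusion_radius,
            border_margin=self.border_margin,
            max_peaks=self.max_peaks,
        )
        siz = SizingParams(scale_a=self.scale_a, max_fraction=self.max_fraction)
        return det, siz

    def fit(self, X, y=None):
        self._params()  # validate
        if self.design not in FILTER_DESIGNS:
            raise ValueError(f"unknown filter design {self.design!r}")
        self.is_fitted_ = True
        return self

    def transform(self, X):
        """Filter a 2D image or a (B, H, W) stack; band order is kept."""
        self.fit(X)
        det, siz = self._params()
        kw = dict(sigma=self.sigma, kappa=self.kappa, b=self.b)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            out, rep = remove_honeycomb(X, det, siz, self.design, **kw)
            self.reports_ = [rep]
            return out
        if X.ndim == 3:
            out = np.empty_like(X)
            reports = []
            for i, band in enumerate(X):
                out[i], rep = remove_honeycomb(band, det, siz, self.design, **kw)
                reports.append(rep)
            self.reports_ = reports
            return out
        raise ValueError("X must be a 2D image or a (B, H, W) stack")
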