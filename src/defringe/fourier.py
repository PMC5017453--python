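"""Centered 2D Fourier transforms and magnitude views.

Quasi-periodic interference such as the fiber-bundle honeycomb pattern
appears in the Fourier domain as isolated bursts of energy ("peaks").
Detection and notch filtering both operate on a centered spectrum: the DC
component sits at ``(H // 2, W // 2)`` after the shift, and real images have
Hermitian-symmetric coefficients about that point, which every mutation in
this package is required to preserve so that the inverse transform stays
real.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FourierSpectrum",
    "forward_fft",
    "inverse_fft",
    "log_magnitude",
    "hermitian_partner",
    "SymmetryWarning",
]


class SymmetryWarning(UserWarning):
    """Raised/emitted when a spectrum modification broke Hermitian symmetry."""


@dataclass
class FourierSpectrum:
    """Centered complex 2D spectrum of a single band image."""

    coeffs: np.ndarray

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.ndim != 2 or self.coeffs.size == 0:
            raise ValueError("coeffs must be a non-empty 2D complex array")

    @property
    def height(self) -> int:
        return self.coeffs.shape[0]

    @property
    def width(self) -> int:
        return self.coeffs.shape[1]

    @property
    def shape(self) -> tuple:
        return self.coeffs.shape

    @property
    def dc_pos(self) -> tuple:
        """(row, col) of the DC coefficient under the centered convention."""
        return (self.height // 2, self.width // 2)


def hermitian_partner(pos, shape) -> tuple:
    """Index of the conjugate-symmetric coefficient of ``pos``.

    With the centered convention this is the point reflection through the
    DC index ``N // 2`` along each axis, ``(2 * (N // 2) - s) % N``; DC
    maps to itself.
    """
    return ((2 * (shape[0] // 2) - pos[0]) % shape[0],
            (2 * (shape[1] // 2) - pos[1]) % shape[1])


def mirror_spectrum(arr: np.ndarray) -> np.ndarray:
    """Point-reflect a centered-spectrum-shaped array through DC."""
    h, w = arr.shape
    return np.roll(arr[::-1, ::-1], (1 - h % 2, 1 - w % 2), axis=(0, 1))


def forward_fft(image) -> FourierSpectrum:
    """Centered 2D FFT of a band image."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D raster")
    return FourierSpectrum(np.fft.fftshift(np.fft.fft2(image)))


def inverse_fft(spectrum: FourierSpectrum, rel_tol: float = 1e-6,
                on_asymmetry: str = "raise") -> np.ndarray:
    """Inverse transform back to a real raster.

    The imaginary residual left by Hermitian-symmetric modifications is
    discarded.  A residual above ``rel_tol`` of the dynamic range signals an
    asymmetric modification; depending on ``on_asymmetry`` this raises,
    warns, or is ignored.
    """
    if on_asymmetry not in ("raise", "warn", "ignore"):
        raise ValueError(f"unknown on_asymmetry mode {on_asymmetry!r}")
    img = np.fft.ifft2(np.fft.ifftshift(spectrum.coeffs))
    real = img.real
    # near-constant outputs have ptp ~ float noise; fall back to magnitude
    scale = max(np.ptp(real), np.max(np.abs(real)), 1e-12)
    resid = np.max(np.abs(img.imag)) / scale
    if resid > rel_tol and on_asymmetry != "ignore":
        msg = (f"imaginary residual {resid:.3g} of dynamic range exceeds "
               f"{rel_tol:g}: spectrum was modified asymmetrically")
        if on_asymmetry == "raise":
            raise ValueError(msg)
        warnings.warn(msg, SymmetryWarning)
    return real


def log_magnitude(spectrum: FourierSpectrum) -> np.ndarray:
    """Detection surface ``log(1 + |F|)``.

    Peaks are detected on the log magnitude rather than the raw magnitude:
    DC exceeds the artifact peaks by orders of magnitude, and the flood
    tolerance needs a bounded dynamic range to be meaningful.
    """
    return np.log1p(np.abs(spectrum.coeffs))
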