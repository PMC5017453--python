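"""Hyperspectral cube and mask I/O.

A hyperspectral (HS) cube is an ordered stack of co-registered grayscale
band images of the same scene at successive wavelengths.  The reference
acquisition geometry is a 1388 x 1040 px, 12-bit camera sweeping 390-680 nm
in 10 nm steps (30 bands); this module is agnostic to size and band count.

On-disk dialect: multi-page TIFF, one page per band, 16-bit unsigned samples
holding 12-bit data without rescaling.  Masks are single-page images with
nonzero meaning "inside".  Wavelength metadata travels in a plain-text
sidecar (``<stack>.wavelengths.txt``, one value per line) when not supplied
explicitly.

Coordinate convention used throughout the package: (row, col), 0-based,
row 0 at the top.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
import imageio.v3 as iio

__all__ = ["HSCube", "read_cube", "write_cube", "drop_bands", "read_mask", "write_mask"]

#: default wavelength grid of the acquisition system (nm)
DEFAULT_WAVELENGTH_START = 390.0
DEFAULT_WAVELENGTH_STEP = 10.0


@dataclass
class HSCube:
    """Ordered stack of co-registered band images plus wavelength metadata.

    Parameters
    ----------
    bands : ndarray, shape (B, H, W)
        Per-band intensity rasters, non-negative.
    wavelengths_nm : ndarray, shape (B,)
        Strictly increasing band-center wavelengths.
    masks : dict of str -> ndarray (H, W) of bool
        Optional named binary rasters (ROI, specular-reflection exclusion,
        annotation, ...).
    """

    bands: np.ndarray
    wavelengths_nm: np.ndarray
    masks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3 or self.bands.shape[0] == 0:
            raise ValueError("bands must be a non-empty (B, H, W) stack")
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.wavelengths_nm.shape != (self.bands.shape[0],):
            raise ValueError(
                f"wavelength count {self.wavelengths_nm.size} != band count "
                f"{self.bands.shape[0]}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if np.min(self.bands) < 0:
            raise ValueError("intensities must be non-negative")
        for name, m in self.masks.items():
            m = np.asarray(m).astype(bool)
            if m.shape != self.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != cube shape {self.shape}")
            self.masks[name] = m

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def height(self) -> int:
        return self.bands.shape[1]

    @property
    def width(self) -> int:
        return self.bands.shape[2]

    @property
    def shape(self) -> tuple:
        """Spatial shape (H, W)."""
        return self.bands.shape[1:]


def _default_wavelengths(n: int) -> np.ndarray:
    return DEFAULT_WAVELENGTH_START + DEFAULT_WAVELENGTH_STEP * np.arange(n)


def _sidecar_path(path) -> str:
    base, _ = os.path.splitext(os.fspath(path))
    return base + ".wavelengths.txt"


def read_cube(path, wavelengths=None) -> HSCube:
    """Read a multi-page grayscale stack into an :class:`HSCube`.

    Values are preserved bit-exactly.  ``wavelengths`` defaults to the
    sidecar file next to ``path`` if present, else to 390 + 10*i nm.
    """
    pages = tifffile.imread(os.fspath(path))
    pages = np.asarray(pages)
    if pages.size == 0:
        raise ValueError(f"{path}: stack contains no pages")
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {pages.shape}")
    if wavelengths is None:
        sidecar = _sidecar_path(path)
        if os.path.exists(sidecar):
            wavelengths = np.loadtxt(sidecar, ndmin=1)
        else:
            wavelengths = _default_wavelengths(pages.shape[0])
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != pages.shape[0]:
        raise ValueError(
            f"{path}: {wavelengths.size} wavelengths for {pages.shape[0]} pages"
        )
    return HSCube(bands=pages, wavelengths_nm=wavelengths)


def write_cube(cube: HSCube, path) -> None:
    """Write a cube as a multi-page TIFF plus a wavelength sidecar.

    Integer cubes round-trip bit-exactly through :func:`read_cube`.
    """
    if not isinstance(cube, HSCube):
        raise TypeError("write_cube expects an HSCube")
    # one grayscale page per band (3-band cubes must not become RGB)
    tifffile.imwrite(os.fspath(path), cube.bands, photometric="minisblack")
    np.savetxt(_sidecar_path(path), cube.wavelengths_nm, fmt="%.6g")


def drop_bands(cube: HSCube, indices) -> HSCube:
    """Return a cube without the listed band positions (and wavelengths).

    The default pipeline drops bands 0 and 1 (390 and 400 nm), where the
    combination of the fiber pattern and strong white noise leaves too low a
    signal-to-noise ratio for correction.
    """
    indices = list(indices)
    for i in indices:
        if not (-cube.n_bands <= i < cube.n_bands):
            raise IndexError(f"band index {i} out of range for {cube.n_bands} bands")
    drop = {i % cube.n_bands for i in indices}
    keep = [i for i in range(cube.n_bands) if i not in drop]
    if not keep:
        raise ValueError("dropping all bands would leave an empty cube")
    return HSCube(
        bands=cube.bands[keep],
        wavelengths_nm=cube.wavelengths_nm[keep],
        masks=dict(cube.masks),
    )


def read_mask(path) -> np.ndarray:
    """Read a single-page image as a boolean mask (nonzero = inside)."""
    arr = np.asarray(iio.imread(os.fspath(path)))
    if arr.ndim == 3:  # collapse any color/alpha channels
        arr = arr.max(axis=-1)
    return arr != 0


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit single-page image."""
    iio.imwrite(os.fspath(path), (np.asarray(mask, bool) * np.uint8(255)))
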