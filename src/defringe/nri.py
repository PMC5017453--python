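"""Normalized ratio index (NRI) features.

The larynx geometry and the light source leave the mucosa unevenly lit.  A
spectrally homogeneous object under varying illumination yields spectra
that are linear rescalings of one another, so classification on raw
intensities keys on brightness rather than tissue.  The NRI of a band pair,

    nri(l1, l2) = (I_l1 - I_l2) / (I_l1 + I_l2),   l1 > l2,

cancels any positive per-pixel illumination factor.  Building it for all
ordered band pairs of a B-band cube yields B*(B-1)/2 features per pixel
(378 for the 28 bands spanning 410-680 nm after the two noisiest bands are
dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["NRICube", "nri_pair", "build_nri_cube", "apply_exclusion_mask",
           "NRITransform", "nri_pairs_table"]


def nri_pair(i1, i2) -> np.ndarray:
    """Element-wise ``(i1 - i2) / (i1 + i2)``; 0 where both are 0."""
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if np.min(i1) < 0 or np.min(i2) < 0:
        raise ValueError("intensities must be non-negative")
    denom = i1 + i2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (i1 - i2) / np.where(denom > 0, denom, 1.0), 0.0)
    return out


@dataclass
class NRICube:
    """Per-pixel NRI feature planes with their band-pair index.

    ``features`` has shape (P, H, W); ``pair_index[p]`` is the wavelength
    pair ``(l1, l2)`` with ``l1 > l2`` of plane ``p``.  Pairs are ordered
    lexicographically by ``(l2, l1)`` ascending; classifier reproducibility
    depends on this order, so it is fixed here once.
    """

    features: np.ndarray
    pair_index: list = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 3:
            raise ValueError("features must have shape (P, H, W)")
        if len(self.pair_index) != self.features.shape[0]:
            raise ValueError("pair_index length must match feature count")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def shape(self) -> tuple:
        return self.features.shape[1:]

    def as_table(self) -> np.ndarray:
        """(H*W, P) feature table in row-major pixel order."""
        p, h, w = self.features.shape
        return self.features.reshape(p, h * w).T


def nri_pairs_table(n_bands: int) -> list:
    """Band-index pairs ``(i1, i2)`` with ``i1 > i2`` in the canonical
    (l2, l1)-lexicographic order."""
    return [(i1, i2) for i2 in range(n_bands) for i1 in range(i2 + 1, n_bands)]


def build_nri_cube(cube) -> NRICube:
    """All-pairs NRI of a cube (``HSCube`` or (B, H, W) array).

    The intended input has its two noisiest low-wavelength bands already
    dropped; the construction itself works for any cube with >= 2 bands.
    """
    bands = np.asarray(getattr(cube, "bands", cube), dtype=float)
    wl = getattr(cube, "wavelengths_nm", None)
    if bands.ndim != 3:
        raise ValueError("cube must have shape (B, H, W)")
    nb = bands.shape[0]
    if nb < 2:
        raise ValueError("need at least 2 bands to form a pair")
    if wl is None:
        wl = np.arange(nb, dtype=float)
    pairs = nri_pairs_table(nb)
    features = np.empty((len(pairs),) + bands.shape[1:])
    for p, (i1, i2) in enumerate(pairs):
        features[p] = nri_pair(bands[i1], bands[i2])
    pair_index = [(float(wl[i1]), float(wl[i2])) for i1, i2 in pairs]
    return NRICube(features=features, pair_index=pair_index)


def apply_exclusion_mask(nri: NRICube, mask) -> tuple:
    """Drop masked pixels (e.g. specular reflections) from the feature set.

    ``mask`` is boolean with True = excluded.  Returns
    ``(table, retained_flat_index)`` where ``table`` is the
    (n_retained, P) feature table and the index maps rows back to
    row-major pixel positions for map rendering.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != nri.shape:
        raise ValueError(f"mask shape {mask.shape} != feature shape {nri.shape}")
    retained = np.flatnonzero(~mask.ravel())
    if retained.size == 0:
        raise ValueError("mask excludes every pixel")
    return nri.as_table()[retained], retained


class NRITransform(BaseEstimator, TransformerMixin):
    """Stateless transformer: band intensities -> all-pairs NRI features.

    ``X`` is a (n_pixels, B) table of non-negative band intensities; the
    output is (n_pixels, B*(B-1)/2) in the canonical pair order, ready for
    downstream clustering or similarity mapping.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (n_pixels, B) with B >= 2")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        self.fit(X)
        X = np.asarray(X, dtype=float)
        pairs = nri_pairs_table(X.shape[1])
        out = np.empty((X.shape[0], len(pairs)))
        for p, (i1, i2) in enumerate(pairs):
            out[:, p] = nri_pair(X[:, i1], X[:, i2])
        return out
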