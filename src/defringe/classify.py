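"""Tissue classification on NRI features.

Unsupervised: a Gaussian mixture model with full covariance matrices,

    p(x) = sum_k alpha_k N(x | mu_k, Sigma_k),

fitted by expectation-maximization (k-means initialization from a given
seed; iterations stop at a relative log-likelihood improvement threshold).
Default k = 10 clusters.  High-dimensional full covariances need many
pixels, so fitting optionally subsamples to a pixel budget with a fixed
seed.

Supervised: a per-pixel Pearson correlation map against a mean reference
NRI spectrum drawn from randomly selected pixels of an annotated region.
Pearson correlation responds to spectral shape but not brightness or
offset, which is exactly the invariance wanted for tissue similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

__all__ = [
    "GMMModel",
    "LabelMap",
    "CorrelationMap",
    "gmm_fit",
    "gmm_predict",
    "reference_spectrum",
    "correlation_map",
    "GaussianMixtureTissueModel",
    "PearsonSimilarityMap",
]

EXCLUDED_LABEL = -1


@dataclass
class GMMModel:
    """Fitted mixture: weights, means, full covariances and the EM
    log-likelihood trace (mean per-sample log-likelihood, non-decreasing)."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: list
    seed: int
    converged: bool
    _gm: GaussianMixture = field(repr=False, default=None)


@dataclass
class LabelMap:
    """Per-pixel cluster labels; excluded pixels carry ``EXCLUDED_LABEL``."""

    labels: np.ndarray
    k: int


@dataclass
class CorrelationMap:
    """Per-pixel Pearson coefficients in [-1, 1]; zero-variance pixels are
    NaN and flagged in ``undefined``."""

    values: np.ndarray
    undefined: np.ndarray
    reference_provenance: dict = field(default_factory=dict)


def gmm_fit(features, k: int, seed: int = 0, tol: float = 1e-6,
            max_iter: int = 500, subsample: int | None = 20000,
            reg_scale: float = 1e-6) -> GMMModel:
    """EM fit of a full-covariance GMM with an explicit likelihood trace.

    The covariance diagonal is floored at ``reg_scale`` times the mean
    per-feature variance, which keeps Sigma_k positive-definite even for
    degenerate (constant) features.  EM stops when the relative improvement
    of the mean log-likelihood drops below ``tol`` or after ``max_iter``
    steps.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a (n_pixels, n_features) table")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} rows cannot support k={k} components")
    rng = np.random.default_rng(seed)
    fit_X = X
    if subsample is not None and X.shape[0] > subsample:
        idx = rng.choice(X.shape[0], size=subsample, replace=False)
        fit_X = X[idx]
    var = float(np.mean(np.var(fit_X, axis=0)))
    if var == 0.0:
        warnings.warn("all features are constant; covariance floored")
    reg = max(reg_scale * var, 1e-12)
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         reg_covar=reg, init_params="kmeans",
                         random_state=int(seed) % (2 ** 31),
                         max_iter=1, warm_start=True, tol=0.0)
    trace: list[float] = []
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(fit_X)  # one EM step per call under warm_start
            ll = float(gm.score(fit_X))
            if trace:
                prev = trace[-1]
                rel = abs(ll - prev) / max(abs(prev), 1e-300)
                trace.append(ll)
                if rel < tol:
                    converged = True
                    break
            else:
                trace.append(ll)
    return GMMModel(n_components=k, weights=gm.weights_.copy(),
                    means=gm.means_.copy(), covariances=gm.covariances_.copy(),
                    log_likelihood=trace, seed=seed, converged=converged,
                    _gm=gm)


def gmm_predict(model: GMMModel, features, excluded=None) -> LabelMap:
    """Maximum-posterior component labels for each retained pixel.

    ``features`` is (n_pixels, P); ``excluded`` an optional boolean vector
    marking pixels to label as excluded instead of classifying.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension does not match the fitted model")
    labels = model._gm.predict(X)
    if excluded is not None:
        excluded = np.asarray(excluded, dtype=bool)
        labels = np.where(excluded, EXCLUDED_LABEL, labels)
    return LabelMap(labels=labels, k=model.n_components)


def reference_spectrum(features, mask, n_pixels: int = 100, seed: int = 0):
    """Mean feature vector of ``n_pixels`` pixels sampled uniformly without
    replacement from a marked region (e.g. annotated cancerous tissue).

    ``features`` may be an :class:`~defringe.nri.NRICube` or a (P, H, W)
    array.  A region smaller than ``n_pixels`` is used whole, with a
    warning.
    """
    planes = np.asarray(getattr(features, "features", features), dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != planes.shape[1:]:
        raise ValueError("mask shape does not match feature planes")
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValueError("reference mask is empty")
    if idx.size < n_pixels:
        warnings.warn(f"mask has only {idx.size} pixels < n_pixels={n_pixels}; "
                      "using all of them")
        chosen = idx
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(idx, size=n_pixels, replace=False)
    table = planes.reshape(planes.shape[0], -1).T
    return table[chosen].mean(axis=0)


def correlation_map(features, reference) -> CorrelationMap:
    """Per-pixel Pearson correlation against a reference spectrum.

    The correlation is computed across the feature dimension, so it
    measures spectral shape similarity and ignores per-pixel brightness
    (scale) and offset.  Pixels with constant feature vectors are
    undefined (NaN) and flagged.
    """
    planes = np.asarray(getattr(features, "features", features), dtype=float)
    ref = np.asarray(reference, dtype=float).ravel()
    if planes.shape[0] != ref.size:
        raise ValueError("reference length does not match feature count")
    rc = ref - ref.mean()
    ref_norm = np.linalg.norm(rc)
    if ref_norm == 0:
        raise ValueError("reference spectrum is constant")
    p = planes.shape[0]
    flat = planes.reshape(p, -1)
    xc = flat - flat.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(xc, axis=0)
    undefined = norms == 0
    safe = np.where(undefined, 1.0, norms)
    corr = (rc @ xc) / (safe * ref_norm)
    corr = np.where(undefined, np.nan, np.clip(corr, -1.0, 1.0))
    shape = planes.shape[1:]
    return CorrelationMap(values=corr.reshape(shape),
                          undefined=undefined.reshape(shape))


class GaussianMixtureTissueModel(BaseEstimator, ClusterMixin):
    """scikit-learn estimator facade over :func:`gmm_fit`/:func:`gmm_predict`.

    Parameters
    ----------
    n_components : number of clusters (default 10).
    random_state : seed for k-means initialization and subsampling.
    tol, max_iter : EM stopping rule (relative log-likelihood improvement).
    subsample : pixel budget for fitting; None fits on everything.
    """

    def __init__(self, n_components: int = 10, random_state: int = 0,
                 tol: float = 1e-6, max_iter: int = 500,
                 subsample: int | None = 20000, reg_scale: float = 1e-6):
        self.n_components = n_components
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter
        self.subsample = subsample
        self.reg_scale = reg_scale

    def fit(self, X, y=None):
        model = gmm_fit(X, k=self.n_components, seed=self.random_state,
                        tol=self.tol, max_iter=self.max_iter,
                        subsample=self.subsample, reg_scale=self.reg_scale)
        self.model_ = model
        self.weights_ = model.weights
        self.means_ = model.means
        self.covariances_ = model.covariances
        self.log_likelihood_trace_ = model.log_likelihood
        self.converged_ = model.converged
        self.labels_ = self.predict(X)
        return self

    def predict(self, X):
        return gmm_predict(self.model_, X).labels

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class PearsonSimilarityMap(BaseEstimator):
    """Supervised similarity mapper: fit stores a mean reference spectrum,
    predict returns per-pixel Pearson correlations.

    ``fit(X)`` expects reference spectra as rows (e.g. the sampled pixels
    of an annotated region) and stores their mean; ``predict(X)`` scores
    arbitrary (n_pixels, P) tables.
    """

    def __init__(self):
        pass

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_features)")
        self.reference_ = X.mean(axis=0)
        if np.ptp(self.reference_) == 0:
            raise ValueError("mean reference spectrum is constant")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        cm = correlation_map(X.T[:, :, None], self.reference_)
        return cm.values.ravel()
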