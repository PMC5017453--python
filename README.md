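# defringe

Honeycomb-pattern removal and tissue classification for fiber-bundle
hyperspectral endoscopy.

Flexible endoscopes transmit their image through a coherent bundle of
thousands of hexagonally packed optical fibers. Each fiber's bright core
and dark cladding imprint a quasi-periodic "honeycomb" pattern on every
recorded image — strong enough to dominate the small spectral contrasts
that hyperspectral (HS) cancer detection depends on, so it must be removed
with minimal loss of image detail. `defringe` implements an adaptive
Fourier-domain notch filter for this: the hexagonal lattice concentrates
into a handful of isolated peaks in the 2-D spectrum (six symmetric
first-order peaks around DC), and attenuating individually sized windows
around exactly those peaks removes the pattern while passing everything
else.

The package is aimed at researchers processing fiberscopic HS cubes
(stacks of co-registered band images, e.g. 390–680 nm in 10 nm steps) and
at anyone removing quasi-periodic interference from images. It provides:

* **Adaptive notch filtering** — per band: local-maxima detection on
  `log(1+|F|)`, flood-fill prominence screening (an adaptation of the
  ImageJ maxima detector), DC/border cleaning, per-peak affected-extent
  measurement by strict-descent flood fill, window size `n = 2·ceil(d·a)+1`,
  and one of six radial filter designs (Gaussian, super-Gaussian, Hanning,
  Bartlett, ideal, smoothed ideal) applied Hermitian-symmetrically.
* **Baselines** — spatial-domain Gaussian smoothing and a star-shaped
  Fourier low-pass built from the six first-order peaks.
* **Quality metrics** — variance-based smoothness `s`, bar-chart line
  separation `r`, and the weighted quality `q = γ·s + (1−γ)·r`.
* **Illumination-invariant features** — the normalized ratio index
  `nri(λ1, λ2) = (I_λ1 − I_λ2)/(I_λ1 + I_λ2)` for all band pairs.
* **Classification** — unsupervised Gaussian-mixture clustering (full
  covariances, EM) and supervised Pearson-correlation similarity mapping
  against a sampled reference spectrum.
* **Synthetic data** — seeded generators for honeycomb renderings, a
  USAF-style resolution chart, and a two-tissue larynx-like cube, each
  with exact ground truth.

Filters and classifiers are scikit-learn estimators
(`HoneycombNotchFilter`, `SpatialGaussianFilter`, `StarLowpassFilter`,
`NRITransform`, `GaussianMixtureTissueModel`, `PearsonSimilarityMap`) and
compose with sklearn pipelines; plain functions wrap them for one-off use.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from defringe import (HoneycombSpec, SceneSpec, make_two_tissue_cube,
                      render_honeycomb, remove_honeycomb, smoothness_s,
                      HoneycombNotchFilter, HSCube, drop_bands,
                      build_nri_cube, reference_spectrum, correlation_map)

# 1. larynx-like two-tissue cube, then imprint the fiber-bundle pattern
cube, lesion, specular = make_two_tissue_cube(SceneSpec(shape=(256, 256), seed=3))
noisy, truth = render_honeycomb(cube.bands, HoneycombSpec(seed=1))

# 2. adaptive notch filtering of one band
band = noisy[15]  # 540 nm
filtered, report = remove_honeycomb(band, design="super_gaussian")
print(f"peaks notched: {len(report)}")
print(f"smallest windows (first-order peaks): {sorted(r['n'] for r in report)[:6]}")
print(f"MAE vs ground truth: {np.abs(band - truth[15]).mean():.1f} -> "
      f"{np.abs(filtered - truth[15]).mean():.1f} counts")
region = np.zeros((256, 256), bool); region[40:90, 20:70] = True
print(f"smoothness s over a homogeneous patch: "
      f"{smoothness_s(filtered, band, region):.3f}")

# 3. defringe the whole cube, build NRI features, map lesion similarity
clean = HoneycombNotchFilter(design="super_gaussian").transform(noisy)
work = drop_bands(HSCube(bands=clean, wavelengths_nm=cube.wavelengths_nm), [0, 1])
nri = build_nri_cube(work)
ref = reference_spectrum(nri, lesion & ~specular, n_pixels=100, seed=5)
cm = correlation_map(nri, ref)
print(f"NRI features per pixel: {nri.n_features}")
print(f"mean Pearson correlation to the lesion reference: "
      f"lesion {np.nanmean(cm.values[lesion]):.3f}, "
      f"healthy {np.nanmean(cm.values[~lesion & ~specular]):.3f}")
```

Output:

```
peaks notched: 24
smallest windows (first-order peaks): [19, 19, 21, 21, 23, 23]
MAE vs ground truth: 262.6 -> 88.9 counts
smoothness s over a homogeneous patch: 0.825
NRI features per pixel: 378
mean Pearson correlation to the lesion reference: lesion 0.983, healthy 0.450
```

Reading the numbers: the detector found and notched 24 interference peaks
in the 540 nm band (the six first-order peaks received 19–23 px windows);
filtering cut the mean absolute error to the pattern-free ground truth
from 262.6 to 88.9 counts and flattened a homogeneous patch to `s = 0.825`
(0 would mean no change, 1 a perfectly flat patch). On the defringed cube,
the 378 band-pair NRI features make lesion pixels correlate at 0.983 with
the lesion reference spectrum, against 0.450 for healthy mucosa — the
separation the supervised classifier thresholds on.

## Command line

```sh
defringe simulate --scene two-tissue --size 256 --seed 1 --out cube.tif
defringe defringe cube.tif --design super-gaussian --report peaks.tsv --out clean.tif
defringe peaks cube.tif --out peaks.tsv
defringe baseline cube.tif --method sd-gaussian --kernel-size 17 --out blur.tif
defringe nri clean.tif --out nri.tif --pairs-out pairs.tsv
defringe classify clean.tif --mode gmm --k 10 --seed 1 --out labels.tsv
defringe run --config pipeline.yaml --out-dir out/
```

`run` drives the whole pipeline (simulate → defringe → metrics → NRI →
classify) from one YAML config; a single seed fans out deterministically
to every stage, and unknown config keys are rejected before any
computation.

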