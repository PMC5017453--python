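# Methods

## Problem setting

A flexible endoscope transmits its image through a coherent bundle of
thousands of hexagonally packed optical fibers. Each fiber has a
transmitting core and non-transmitting cladding, so every recorded image
carries a quasi-periodic "honeycomb" modulation: bright circular cores
surrounded by dark rings. For hyperspectral (HS) imaging — a stack of
co-registered band images, here 390–680 nm in 10 nm steps at 12-bit depth —
this pattern dominates small tissue-contrast variations and must be removed
before classification, while preserving as much image detail as possible.

In the Fourier domain the hexagonal lattice concentrates into isolated
peaks: six radially symmetric first-order peaks around DC plus weaker
higher orders. Attenuating small neighborhoods around exactly those peaks
removes the pattern and leaves the rest of the spectrum — and hence the
image detail — untouched. The core of this package is that adaptive notch
pipeline; around it sit the comparison baselines, objective quality
metrics, illumination-invariant features and tissue classification.

## Adaptive notch filtering

Per band image, independently (peak positions vary between bands and
cubes):

1. **Detection surface.** The centered 2-D FFT is reduced to
   `log(1 + |F|)`. Detection on the log magnitude rather than raw
   magnitude is a design choice: DC exceeds the artifact peaks by orders
   of magnitude, and the flood tolerance below needs a bounded dynamic
   range to be meaningful across bands.
2. **Local maxima.** Every pixel strictly greater than its in-bounds
   8-neighbors (3×3 moving window). Plateaus produce no maxima; ties in
   later stages are broken row-major for determinism.
3. **Prominence screening.** Candidates are flooded in descending
   amplitude order (an adaptation of the maxima detector in ImageJ). For a
   candidate of amplitude `m`, an 8-connected region grows over pixels `v`
   with `m − t ≤ v ≤ m`. The candidate is rejected if the flood touches a
   pixel claimed by a previously accepted peak, or reaches a pixel above
   `m`. Accepted peaks claim their region. The tolerance `t` defaults to
   10 % of the detection surface's dynamic range (the original value was
   determined empirically and never published); it is exposed as a
   parameter.
4. **Cleaning.** The DC peak and anything within `dc_exclusion_radius`
   (default 10 px) of DC is dropped, as are peaks within `border_margin`
   (default 4 px) of the spectrum edge. Near-DC and border responses mark
   the image mean and wrap-around periods, not the interference pattern;
   notching them blurs the image. The border/DC reading of "falsely
   identified peaks at back-to-back periods" is an interpretation, stated
   here once.
5. **Extent and window size.** From each surviving peak, a second
   8-connected flood grows by *path-monotone strict descent*: a neighbor
   joins iff its value is strictly below the value of the pixel it is
   reached from (the literal "less than the value of the current pixel"
   rule, not a comparison against the seed). `d` is the maximum Euclidean
   distance from the peak to a region pixel (Euclidean rather than
   Chebyshev, reading "distance between the peak and a pixel" literally).
   The window edge is `n = 2·ceil(d·a) + 1` with scaling factor `a`
   (default 1.0; `ceil` keeps `n` odd for non-integer `d·a`), clamped to
   `≥ 3` and to `max_fraction · min(H, W)` (default 0.25, rounded down to
   odd) so a runaway descent through a smooth spectral floor cannot notch
   out a large part of the spectrum.
6. **Filtering.** The `n × n` neighborhood of the peak is multiplied
   element-wise by a radial gain matrix `G(x, y)` with normalized radius
   `r = sqrt(((x−(n−1)/2)/((n−1)/2))² + ((y−(n−1)/2)/((n−1)/2))²)`:

   | design | gain |
   |---|---|
   | gaussian | `1 − exp(−r²/(2σ²))`, σ = 0.3 |
   | super-Gaussian | `1 − exp(−(r/κ)^b)`, κ = 0.3, b = 6.0 |
   | Hanning | `1 − 0.5(cos(πr) + 1)` for r ≤ 1, else 1 |
   | Bartlett | `r` for r ≤ 1, else 1 |
   | ideal | `0` for r ≤ 1, else 1 |
   | smoothed ideal | ideal convolved with a 9×9 Gaussian kernel |

   The super-Gaussian exponent composition is written ambiguously in its
   source; the implementation uses `(r/κ)^b` with κ = 0.3, b = 6.0, which
   produces the steep near-ideal profile the design is meant to have, and
   exposes both constants as parameters. The smoothed-ideal kernel size is
   fixed (9×9) but its width is not; σ = 1.8 px is used (≈ 5σ support in
   9 px), with the region outside the window treated as pass-band during
   the convolution so the window rim is not darkened.

   Every window is applied together with its point reflection through DC
   (matrix spatially reversed) in the same call, and the resulting gain
   field is symmetrized exactly, so the spectrum stays Hermitian and the
   inverse transform stays real even when detection kept only one member
   of a conjugate pair near a border. The DC coefficient is never
   attenuated (a window covering DC forces DC gain 1 with a warning).
   Overlapping windows compose multiplicatively; Hadamard products
   commute, so application order is irrelevant, but peaks are processed in
   descending amplitude for reporting determinism.
7. **Reconstruction.** Inverse FFT, real part, negatives clipped to 0
   (intensities are physical). An imaginary residual above 1e−6 of the
   dynamic range signals an asymmetric modification and raises (or warns,
   per configuration).

The extent flood (step 5) runs on the same log-magnitude surface as
detection — the source is silent on this; consistency is chosen.

## Baselines

**Spatial-domain Gaussian.** Convolution with an explicit normalized
square kernel; only the kernel sizes (3 and 17 in the published
comparison) are prescribed, so σ is tied to size as `size/5`. Borders by
reflection, preserving mean intensity.

**Star-shaped Fourier low-pass.** The original star geometry is not fully
specified; the reconstruction here is documented and only
qualitative/ordering properties are asserted for it. From the six
first-order peak positions (validated to form three conjugate pairs), a
12-vertex star polygon centered at DC is built: convex corners at the
angular midpoints between adjacent peak directions at the peak radius,
concave vertices along the peak directions at half that radius, so all
six peaks fall in the stop region. The rasterized polygon is smoothed
with a 9×9 Gaussian kernel, then symmetrized exactly about DC so the
filtered image is real.

## Quality metrics

The published comparison uses a variance-based smoothness `s` and a
Rayleigh-based line-separation criterion `r` whose exact formulas live in
an earlier work and are not reproduced; the operational definitions here
satisfy every stated constraint (range [0, 1], `s = 0` for the unfiltered
reference, higher = smoother / crisper):

* `s = clamp(1 − σ_f/σ_u, 0, 1)` over a homogeneous region, with
  `σ_u = 0 → s = 0` by convention.
* `r`: intensity profiles crossing bar triplets of a USAF-style chart are
  split at mid-range into bright/dark runs; each dark gap between two
  bright runs scores the Michelson-style contrast
  `(Īmax − Imin)/(Īmax + Imin)` with `Īmax` the mean of the two adjacent
  run maxima; `r` is the mean gap contrast. A crisp chart with black bars
  scores exactly 1; a profile blurred flat scores 0. Profiles with fewer
  than two detectable bright runs are skipped with a warning (an exactly
  flat profile contributes 0 instead, matching the blurred-flat limit).
* `q = γ·s + (1 − γ)·r`, γ ∈ [0, 1] weighting smoothness against detail.

Cube scoring averages per-band values; across-band spread uses the
population standard deviation (a single band reports 0). Published
absolute `s`/`r` values for the recorded USAF cube are not reproducible
without that cube; the package asserts the algebraic recombination of `q`
from the published means and the ordering properties on synthetic data
(e.g. super-Gaussian notch `s` above star-shaped `s`; unfiltered `r`
above all filtered `r`).

## Illumination-invariant features and classification

The larynx geometry illuminates the mucosa unevenly; a spectrally
homogeneous object under varying illumination yields linearly rescaled
spectra. The normalized ratio index
`nri(λ1, λ2) = (I_λ1 − I_λ2)/(I_λ1 + I_λ2)`, λ1 > λ2, cancels any
positive per-pixel illumination factor. It is built for all ordered band
pairs of the cube after the two lowest-wavelength bands (390, 400 nm) are
dropped — the combination of the pattern and strong white noise there
precludes satisfactory correction — giving 378 features for 28 bands.
`0/0 → 0` keeps dark pixels finite and in range. Pair order is fixed
lexicographically by (λ2, λ1) ascending, since classifier reproducibility
depends on it.

**Unsupervised.** A Gaussian mixture `p(x) = Σ_k α_k N(x | μ_k, Σ_k)` with
full covariances, fitted by EM (k = 10 by default). Initialization,
convergence threshold and any subsampling were not published; here EM is
initialized by seeded k-means, stops at relative log-likelihood
improvement < 1e−6 (max 500 iterations), and floors covariance diagonals
at 1e−6 times the mean feature variance. Because 378-dimensional full
covariances need many pixels, fitting subsamples to a configurable budget
(default 20 000 pixels) with a fixed seed. The EM engine is
scikit-learn's `GaussianMixture`, driven one step at a time so the
non-decreasing log-likelihood trace is part of the fitted model.
Specular-reflection pixels (masks are inputs; their detection is an
external pre-processing concern) are excluded from fitting and flagged in
the label map. Attributing clusters to tissue is a reporting step: the
pipeline reports per-cluster overlap fractions with any provided
annotation mask rather than claiming a diagnosis.

**Supervised.** The mean NRI spectrum of 100 randomly selected pixels
(uniform, without replacement, seeded) inside an annotated region serves
as reference; each pixel is scored by Pearson correlation across the
feature dimension — responsive to spectral shape, invariant to brightness
and offset. Constant pixel vectors are undefined (NaN) and flagged.

## Synthetic data

The generators define the test conditions; they emulate phenomenology,
not fiber optics (no modal coupling, crosstalk, or camera PSF).

**Honeycomb.** A hexagonal lattice (default pitch 8 px, orientation 10°
off-axis so peaks avoid the FFT grid axes, per-fiber positional jitter
sd 0.15 px) is imprinted on any scene. Each fiber samples the scene mean
over its core disc (radius 3 px) and re-emits a Gaussian-profile core
(σ = core_radius/2) over cladding at `cladding_gain` (0.35); the core
peak is `sample · core_gain · B` with `core_gain` 0.9 and `B` the
flux-concentration factor (lattice cell area over effective Gaussian core
area, ≈ 3.9 at the defaults). The factor makes core centers overshoot the
pattern-free scene while cladding undershoots it — the modulation
observed in recorded honeycomb spectra, where filtering darkens center
pixels and brightens ring pixels. Without it the modulation would be
one-sided (everywhere ≤ the true scene) and no DC-preserving filter could
reduce the mean absolute error to ground truth, since for one-sided
modulation `E|m − 1| = |E[m] − 1|`. The generator returns its input scene
unchanged as ground truth; 12-bit quantization is optional (float by
default) so invariants are not masked by rounding.

**USAF-style chart.** Groups of three dark vertical bars (bar width =
gap width) on a bright field, emitted together with the homogeneous-area
mask and bar-crossing profile segments the metrics need; the clean chart
scores `r = 1` by construction.

**Two-tissue cube.** 30 bands, default 128×128 px (desk-scale rather than
the instrument's 1388×1040; full size by configuration). Band image =
illumination(x, y) · intensity_scale · reflectance(band), with two
smooth, distinct phenomenological reflectance curves (not measured
spectra), an elliptical lesion carrying the second spectrum, a
multiplicative illumination field spanning 0.5–1.0, Gaussian noise of
sd 8 counts (40 in the two lowest bands, emulating the strong short-
wavelength white noise), and optional saturated specular blobs recorded
in an exclusion mask. All ground truth (lesion mask, SR mask, spectra,
illumination) is returned.

What passing tests on these fixtures do **not** show: robustness to real
inter-band misregistration (heartbeat motion), wavelength-dependent fiber
transmission, chromatic aberration, real tissue texture, or clinically
meaningful separability — the two-tissue phantom is linearly separable by
construction once illumination is cancelled.

A related caveat: the emulated honeycomb is identical in every band and
acts almost multiplicatively per pixel, so the NRI features alone already
cancel most of it — on the phantom, classification of the raw honeycombed
cube is not worse than after defringing. The classification benefit of
pattern removal on recorded data rests on pattern properties the phantom
does not emulate (band-incoherence, inter-band shifts, noise coupling at
low signal). What the phantom does demonstrate quantitatively is the
per-band restoration quality: peak-power suppression, error to ground
truth, and the smoothness/detail metrics.

## Numerical choices and conventions

* Pixel coordinates are (row, col), 0-based, row 0 at top, everywhere.
* Centered spectra put DC at `(H//2, W//2)`; the Hermitian partner of a
  shifted index `s` is `(2·(N//2) − s) mod N` per axis (point reflection
  through DC, valid for odd and even sizes).
* Cubes are multi-page TIFF, 16-bit samples holding 12-bit data without
  rescaling; masks are single-page images, nonzero = inside; wavelengths
  travel in a plain-text sidecar. The on-disk dialect of the original
  acquisition software is unknown; multi-page TIFF is a compatibility
  choice.
* The pipeline's single seed fans out per stage as
  `CRC32(stage name) XOR seed mod 2³¹`, so stages are independently
  reproducible; reruns with identical config are bit-identical for
  integer outputs.

## Known limitations

* Higher-order interference peaks weaker than the flood tolerance
  survive filtering; on strongly textured scenes the descent-based extent
  can under- or overestimate the affected region.
* The star-mask geometry is a documented reconstruction, not the original.
* `s` and `r` are operationalizations; absolute values are comparable
  within this package, not across implementations.
* GMM label identities are arbitrary (cluster matching is up to the
  caller), and the EM trace is per-step mean log-likelihood on the
  (sub)sampled fitting set.
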