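# Methods

## Model

The package estimates a continuous, georeferenced sample property s from a
vis–NIR spectrum and a planar location **u** with the spatially varying
linear model

    s = β₀(u) + Σᵢ₌₁..m βᵢ(u) wᵢ + ε,    ε ~ N(0, σ²),

where w₁…w_m are wavelet-domain features of the spectrum (a multiresolution
component value at a specific scale and wavelength) chosen by the selection
procedure below. The assumptions are those of any GWR: the error is
homoskedastic Gaussian, the coefficient surfaces vary smoothly enough to be
estimated by kernel-local least squares, and distances are Euclidean on
projected planar coordinates (a lon/lat input must be projected first).

## Preprocessing

Reflectance R ∈ (0, 1] is converted to apparent absorbance log₁₀(1/R).
Profiles sampled at several depth intervals are collapsed to one value per
site by thickness-weighted averaging (weights = depth_bottom − depth_top).
Right-skewed properties may be natural-log transformed before modelling;
every reported metric is computed after back-transforming predictions by
plain exponentiation (no smearing correction — the convention kept
deliberately simple so that train and test are treated identically).
Outlier screening removes values more than k standard deviations from the
mean (default k = 2.5) in a single non-iterated pass on the raw scale,
before any transform; mean and sd come from the full input once, so the
screen is order-independent and reproducible.

## Multiresolution analysis

Spectra are decomposed with a maximal-overlap (undecimated) discrete
wavelet transform into detail series D₁…D_J at dyadic scales λᵢ = 2ⁱ
samples plus a smooth S, all full length and aligned to the wavelength
grid, so that S + ΣD = spectrum exactly. Defaults: Daubechies extremal
phase filter with 4 vanishing moments (filter length 8), J = 6 (scales
2…64 nm on a 1 nm grid). Boundaries are handled by mirroring the spectrum
to twice its length and treating the result as circular; the first N points
of each component are kept. The implementation composes each component's
pyramid cascade with its adjoint in the frequency domain, which makes every
component an exactly zero-phase circular filter; the test suite checks this
against a literal time-domain pyramid (brute-force circular convolution),
and reconstruction error on random signals is at machine precision. The
undecimated variant is required because downstream stages correlate
component values per wavelength at every scale; a decimated pyramid would
not provide them.

## Feature selection

1. **Ranking.** Every (scale, wavelength) column is scored by |R|, the
   absolute Pearson correlation with the response, computed on training
   rows only. Zero-variance columns score 0. Ties break by column order
   (scale-major, then wavelength), making the ranking deterministic.
2. **Collinearity filter.** Walking the ranked list, a candidate joins the
   accepted set only if the maximum variance inflation factor of the
   tentative set stays below 10. VIFs are the diagonal of the inverse
   correlation matrix of the accepted set, updated candidate-by-candidate
   with the bordered-inverse identity — algebraically identical to the
   regress-each-column definition but O(k²) per candidate, which matters
   when 15 057 columns are offered. An optional cap on the accepted-set
   size (pipeline default 40) keeps the next stage well posed when n is
   small; the greedy rule itself is unchanged.
3. **Subset sizing.** The survivors are added one at a time, in rank
   order, to an OLS fitted inside each fold of a seeded ten-fold
   cross-validation; k* maximises the mean held-out R² (ties go to the
   smaller k). Mean training R² is non-decreasing in k by OLS nesting —
   a useful internal consistency check; held-out R² is not, and its peak
   is the whole point of the stage.

Selection runs on the 70% training split only, so the held-out 30% never
influences feature choice.

## Geographically weighted regression

At each fit location the coefficients solve weighted least squares with
Gaussian kernel weights w = exp(−½ (d/b)²); the adaptive bandwidth b is
the distance to the q-th nearest training point (excluding a zero-distance
self match, which still receives weight 1). The neighbour count q is an
integer tuned by golden-section search over [m+3, n] on the AICc

    AICc = n ln σ̂² + n ln 2π + n (n + tr S) / (n − 2 − tr S),

with tr S the hat-matrix trace (effective parameters) and σ̂² = RSS/n; the
final bracket is swept exhaustively because the profile can be mildly
non-unimodal, and a saturated smoother (denominator ≤ 0) scores +∞ so the
search avoids it. A flat-kernel flag gives the infinite-bandwidth limit, in
which every local fit equals global OLS and tr S = m + 1; the OLS/linear
AICc used for the comparator models (k = intercept + slopes + variance)
is algebraically identical to the GWR formula in that limit, so relative
likelihoods η = exp((AICc_min − AICc)/2) are comparable across model
families. Predictions at unseen locations recompute adaptive weights
against the training locations at the fitted q and solve a fresh local fit;
a prediction at a training location therefore reproduces its fitted value.

Spatial non-stationarity is tested by Monte-Carlo randomisation: locations
are reassigned to observations uniformly at random, the GWR refit at the
same q, and the variability of each coefficient surface (variance, and
|CV| as a secondary statistic) compared with the observed one;
p = (1 + #{perm ≥ obs}) / (n_perm + 1), n_perm default 99. Under a
stationary truth the rows are exchangeable, so the test is exact for any
fixed q — the calibration check in the acceptance suite exploits exactly
this property.

## Comparator models

**PLSR** uses univariate NIPALS on the column-centred full absorbance
spectra (2151 predictors), with the component count A ≤ 20 minimising mean
RMSE over a seeded ten-fold cross-validation; centring happens inside each
fold, so no information leaks from held-out rows. A configuration flag
switches the PLSR input to the wavelet feature matrix instead of raw
spectra for sensitivity analyses. **WLR** is OLS with intercept on the
selected wavelet features — exactly the flat-kernel limit of the WGWR on
the same design, which the tests assert to 1e−8.

## Validation protocol

A seeded uniform 70/30 split (no spatial stratification — with spatially
autocorrelated data this makes test metrics somewhat optimistic for all
models equally; the package reports it rather than "fixing" it). Metrics:
R² = 1 − SSE/SST, MAE, RMSE, all on the back-transformed scale when a
transform was configured; AICc from the training fit; pairwise percent
changes reported at 1 d.p. and metrics at full precision in the JSON
report. Reports are byte-identical across reruns of the same (config,
seed).

## Synthetic data

The generator inverts the model the method assumes. Spectra are a smooth
increasing absorbance baseline (offset 1.0, slope 0.6 over the grid) plus
three Gaussian absorption bands at 700, 1415 and 2205 nm whose depths scale
with independent standard-normal latent drivers, plus three noise layers:
white detector noise (sd 0.002 absorbance), per-sample offset/tilt wander
(sd 0.05), and a pink (1/f-power) component (sd 0.03). The pink layer is
what makes the recovery problem honest: white noise alone leaves coarse
wavelet scales almost noise-free, so weakly leaked band energy at the wrong
scale would out-correlate the true scale; pink noise carries equal energy
per octave and thus gives every detail level a comparable noise floor —
the dominant wavelength-correlated behaviour of real scatter and drift.
Band widths (1.5, 3.0, 1.5 nm) put each band's energy maximally into a
single detail level (D3/D4/D3), and amplitudes (0.04 absorbance per driver
sd) set the planted column's signal-to-noise near the point where the true
scale separates best from its neighbours in correlation.

Properties are s = β₀(u) + Σ βᵢ(u) fᵢ + ε with fᵢ the planted component
values of the *clean* spectra, ε Gaussian (sd 0.8), and coefficient
surfaces constant (`stationary`), linear in the normalised coordinates
(`drift`, ±45% across the domain), a central Gaussian bump (`patchy`), or
zero (`null`). Defaults — n = 200 samples uniform on a 300 × 300 km domain,
2151-point grid — mimic a regional survey of a few hundred georeferenced
soils. Noise levels were fixed once so that the `drift` preset yields
held-out R² in the 0.4–0.7 band typical of regional spectroscopic soil
models, which lets the comparative ordering (WGWR ≥ WLR) be exercised
without pretending to reproduce any particular survey.

What the generator does **not** emulate: variogram-structured latent
fields (coefficient surfaces are parametric), instrument splice artefacts,
multiplicative scatter, or spatially clustered sampling designs. Passing
tests therefore demonstrate correctness of the machinery and its behaviour
under the stated regimes, not performance claims about any real survey.

## Numerical choices and edge cases

* Weighted local fits use a QR-based least-squares solve on √w-scaled
  rows, never an explicit inverse; batched fits solve the per-location
  normal systems with LAPACK's batched solver after forming them by
  einsum (m ≤ ~10, where the normal equations are benign).
* VIF of an exactly collinear set is +∞, not an exception; a single
  feature has VIF 1 by convention.
* Ties in CV subset sizing and in bandwidth AICc go to the smaller
  k / q (parsimony); ranking ties go to column order.
* A coincident q-th neighbour (zero bandwidth) raises an error suggesting
  jitter; coincident training points within a window are fine (weight 1).
* Degenerate CV folds with constant held-out response are dropped from the
  fold average (NaN-mean).
* The golden-section bandwidth search memoises AICc values and finishes
  with an exhaustive sweep of the final bracket of width ≤ 4.
* Skewness is the adjusted Fisher–Pearson coefficient; sd uses n−1.
* The problem sizes used by the test suite and acceptance script
  (n = 100–400 samples, 20 seeds for ordering/recovery rates, 200
  replicates for test calibration) were chosen as the smallest sizes at
  which the checked properties are statistically decisive.

## Known limitations

* One bandwidth for all coefficients (no multiscale GWR), no robust or
  ridge-regularised local fits.
* The adaptive kernel is Gaussian (a bisquare option exists but is off by
  default); truncation is never applied, so every training point carries
  positive weight.
* Back-transformation is naive exponentiation; log-scale models therefore
  predict medians, not means, on the original scale.
* The 70/30 split ignores spatial autocorrelation; reported test metrics
  are internal validation, not a substitute for spatially blocked CV.
* PLSR is univariate-response only.
* The PLSR AICc counts the latent components (plus intercept and variance)
  as its parameters. When cross-validation chooses many components on
  high-dimensional spectra, this understates the model's effective
  complexity and the training RSS can approach zero, making the PLSR AICc
  — and hence its relative likelihood — optimistic. AICc/η comparisons
  are most meaningful between WLR and WGWR, which share the same design
  matrix and constant conventions.
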