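# Methods

## The measurement problem

Fluoro-Gold (FG, hydroxystilbamidine) is a retrograde neuronal tracer whose
optimal one-photon excitation lies in the ultraviolet, outside the laser
lines of standard confocal systems. Two-photon excitation (2PE) microscopy
reaches it with near-infrared light and, combined with fluorescence lifetime
imaging (FLIM), can separate FG from broadband lipofuscin-like tissue
autofluorescence by decay rate rather than color. `fgflim` implements the
computational side of that characterization: TCSPC decay fitting with
instrument-response convolution, per-pixel lifetime mapping and contrast,
relative 2PE cross-section correction against a reference dye, quadratic
power-dependence verification, and volumetric cell-body counting — all
testable against a synthetic-data generator with known ground truth.

## Decay model

TCSPC histograms record photon arrival times over one laser repetition
period (default 12.5 ns, the 80 MHz Ti:Sapphire convention, in 256 bins of
~48.8 ps). Because excitation is a pulse train, a slow component's tail
folds into the following period; the forward model is therefore the
steady-state *wrapped* multi-exponential

    d(t) = sum_i a_i exp(-t / tau_i) / (1 - exp(-T / tau_i)),   t in [0, T)

circularly convolved with the instrument response function (IRF) and scaled:

    E(t) = A * (d (*) IRF)(t - s) + b

with amplitude fractions `a_i` summing to one, lifetimes `tau_i` in ns, a
photon budget `A`, a per-bin baseline `b`, and an IRF "color shift" `s`
treated as a bounded nuisance parameter (±5 bins). Convolution is done with
FFTs on the periodic grid; the decay is sampled at bin centers and
normalized to unit sum, so `sum E = A + n_bins * b` holds to float precision
(photon conservation).

The IRF is Gaussian by default, parameterized by its FWHM (100 ps, the
duration of the characterized system); a measured kernel can be substituted
via `irf_from_histogram`. Kernels narrower than half a bin are rejected
rather than silently degenerating to a delta; `delta_irf` provides the
idealized single-bin response explicitly.

## Fitting

`fit_monoexponential` / `fit_biexponential` minimize either

* Pearson-weighted residuals `(obs - E) / sqrt(max(E, 1))` (default; the
  scheme of commercial TCSPC software), or
* signed square-root Poisson deviance residuals, whose least-squares optimum
  is the exact Poisson maximum-likelihood estimate,

with `scipy.optimize.least_squares` (TRF, bounds on all parameters).
Initialization: the long lifetime from a weighted log-slope fit of the tail,
the short lifetime at 0.05 ns, amplitudes from the estimated intensity split
between tail and head, baseline from the histogram minimum; all overridable.
Components are returned in canonical ascending-lifetime order (swapped with
their amplitudes if the optimizer crosses). A two-component fit whose
lifetimes collapse within 2% falls back to a mono fit, recorded in metadata.
Fits with a lifetime pinned at its bound or with the decay amplitude
collapsed to zero (e.g. a flat histogram) are flagged non-converged — never
returned silently.

Goodness of fit is the reduced chi-squared over bins whose expected counts
reach a floor of 1 (to keep empty tail bins from dividing by near-zero),
with `n_free = n_used_bins - n_parameters`. On correctly specified Poisson
data at 10^6 photons this statistic calibrates to 1.00 (mean over seeds).

Two mean-lifetime summaries are provided: amplitude-weighted
`sum a_i tau_i / sum a_i` and intensity-weighted
`sum a_i tau_i^2 / sum a_i tau_i`. The intensity-weighted form is the
package default because it is the one consistent with a dominant-amplitude
sub-100 ps component and a 2.3 ns minor component producing a 1.4 ns
apparent mean: solving the weighted-mean equation for tau = (0.1, 2.3) ns
and a 1.4 ns mean gives amplitude fractions a1 ≈ 0.94, a2 ≈ 0.06
(`amplitudes_for_intensity_mean`), whereas the amplitude-weighted mean of
such a decay would be ~0.23 ns. Whether "high-/low-intensity" component
labels refer to amplitude or integrated-intensity fractions is ambiguous in
common usage, so `FitResult` reports both.

## Synthetic data: what it emulates, what it does not

The generator defines the study conditions:

| quantity | default | rationale |
|---|---|---|
| FG short lifetime | 0.09 ns | known only to lie strictly below 100 ps; default sits just under that bound |
| FG long lifetime | 2.3 ns | printed component value |
| FG amplitude split | solved | intensity-weighted mean pinned to 1.4 ns exactly |
| background lifetime | 1.35 ns | lipofuscin-like autofluorescence |
| IRF | Gaussian, 100 ps FWHM | stated system duration; shape unspecified, Gaussian is standard TCSPC practice |
| window | 12.5 ns / 256 bins | 80 MHz repetition convention |
| photon budget | 10^6 per histogram; 5000 per pixel | solution-measurement vs. imaging scale |
| wavelength grid | 720–1000 nm, 10 nm | stated scan range |
| cell phantoms | axis-aligned ellipsoids, ~10–15 µm radius at 1 µm/voxel | motoneuron scale; simplest testable geometry |
| spectral noise | multiplicative Gaussian CV | detector gain noise dominates at these rates |

Counting noise is Poisson per bin (variance = mean, verified at 3σ over
1000 seeded repeats); fixing the seed fixes every output bit-for-bit.
Deliberately *not* modeled: optical aberration, depth-dependent scattering
and attenuation, refractive-index mismatch, detector afterpulsing and
dead-time. Passing tests therefore demonstrate correctness of the estimators
and pipeline plumbing under ideal counting statistics, not robustness to
instrument pathologies in real tissue data.

## Per-pixel mapping and contrast

`fit_pixels` sums each pixel's histogram over a (2b+1)² in-plane
neighborhood (default b = 1, i.e. 3×3, nearest-edge padding), drops pixels
below a photon threshold (default 500), and fits each surviving pixel
(biexponential by default, with the mono fallback above). Masked-out pixels
carry NaN everywhere and never enter histograms or contrast statistics.

"Lifetime contrast" has no standard definition; both
`absolute = |tau_fg - tau_bg|` (ns) and
`normalized = |tau_fg - tau_bg| / (tau_fg + tau_bg)` are implemented
(default absolute, recorded in output metadata), computed on *median*
mean-lifetimes over the two masks — medians because per-pixel biexponential
fits at a few thousand photons have heavy-tailed errors.
`contrast_spectrum` evaluates one dataset per excitation wavelength and
reports the argmax; exact ties resolve to the shorter wavelength and are
flagged. With phantoms the masks come from ground truth; on real data Otsu
thresholding of the photon-count image is the intended route.

## Relative cross-section correction

With the reference dye's known spectrum `sigma_R`, the correction curve
`f_c = F_R / sigma_R` absorbs every wavelength-dependent instrument factor,
and `sigma_S = (F_S / f_c) * (C_R / C_S)` yields the sample's relative
cross-section. Because both dyes share `f_c`, the laser-power term cancels
even without explicit power normalization; `normalize_by_power` (default
exponent 2, the 2PE scaling; configurable to 1) is still provided for
series measured under varying power that are consumed individually.
Design points: mismatched wavelength grids are an error, never silently
resampled; wavelengths where `sigma_R = 0` are dropped and reported;
background subtraction floors at zero with the floored wavelengths flagged
so peak calls can exclude them. `spectral_peak` flags boundary maxima —
the FG situation, where the true 2PE maximum lies below the 720 nm edge of
the tuning range — and breaks exact ties toward the shorter wavelength.
Absolute cross-sections (GM units) are out of scope: they additionally
require detector spectral-sensitivity and quantum-yield corrections.

`power_exponent` checks the quadratic intensity dependence of 2PE by
ordinary least squares on (log P, log F), reporting the slope with a
t-based 95% CI.

## Segmentation

The cell-body counter is a deterministic classical pipeline (the original
workflow used a trained commercial random-forest pixel classifier, which is
not reproducible from a description): Gaussian smoothing (sigma in µm,
scaled per axis by voxel size) → Otsu or fixed threshold → optional lifetime
gate → hole filling → 26-connected components → minimum-volume filter
(µm³) → optional distance-transform watershed (anisotropy-aware) to split
touching somata. Counts are invariant to positive intensity rescaling under
Otsu on noise-free phantoms, and monotone non-increasing in the
minimum-volume parameter. On seeded ellipsoid phantoms at SNR ≥ 10 the
default settings achieve recall and precision ≥ 0.95. The minimum-volume
and smoothing defaults are phantom-calibrated choices, not values taken
from any instrument protocol.

## Numerical choices and degenerate inputs

* Circular FFT convolution; fractional IRF shifts applied as Fourier phase
  ramps; negative roundoff clipped at zero.
* chi-squared floor 1 count; identifiability tolerance 2% relative;
  `least_squares` tolerances 1e-14 (noiseless recovery is exact to ~1e-12).
* Flat or empty histograms: flagged non-converged (`tau_at_bound` /
  `amplitude_collapsed`), total-count minimum 1000 by default.
* Histograms with fewer than the minimum counts, overlapping contrast
  masks, empty pixel selections, mismatched grids: explicit errors; empty
  *volumes* segment to zero objects (a legitimate result, not an error).
* Tie-breaks are always toward the shorter lifetime/wavelength and flagged.

## Problem sizes

The bundled tests and the acceptance script run entirely on generated data:
100-seed ensembles at 10^6 photons for solution-scale decay fitting, a
64×64-pixel FLIM phantom at 5000 photons/pixel for the mapping pipeline,
and ~60³-voxel volumes with 10–20 ellipsoidal cells for segmentation.
These sizes give Monte-Carlo errors comfortably inside the stated
tolerances while keeping a full run in the minutes range on one CPU.

## Known limitations

* No triple-exponential or stretched-exponential models; no global
  multi-histogram fitting; no phasor analysis.
* FLIM TIFF exchange covers single-plane (2-D + time) stacks; multi-plane
  FLIM lives in memory only.
* No readers for proprietary TCSPC container formats (.sdt/.ptu); the
  TSV/TIFF/JSON contract is the exchange layer.
* The short component sits at the IRF width, where its estimator is
  intrinsically noisy: its bias bound (<25% at 10^6 photons) is much looser
  than the long component's (<2%), and recovery degrades as the IRF widens
  (verified monotone in the tests).
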