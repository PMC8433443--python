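# fgflim

Analysis tools for two-photon excitation (2PE) imaging of **Fluoro-Gold**
(FG, hydroxystilbamidine), the widely used retrograde neuronal tracer — aimed
at microscopists and neuroanatomists who want to image FG-labeled neurons
deep in tissue and separate the tracer from lipofuscin-like autofluorescence
by fluorescence lifetime rather than color.

The package covers the computational stages of that workflow:

* **TCSPC decay fitting** (`fgflim.decay_fit`) — mono- and bi-exponential
  models convolved with the instrument response function (IRF) over the
  periodic laser repetition window:
  `E(t) = A·[Σᵢ aᵢ e^(−t/τᵢ)] ⊛ IRF(t−s) + b`, with Poisson (Pearson) or
  exact Poisson-MLE weighting, reduced χ², and both amplitude-weighted
  (Σaᵢτᵢ/Σaᵢ) and intensity-weighted (Σaᵢτᵢ²/Σaᵢτᵢ) mean lifetimes.
* **FLIM mapping** (`fgflim.flim_map`) — per-pixel fits with spatial
  binning and photon thresholds, lifetime distributions, and lifetime
  contrast (|τ_fg − τ_bg|, or normalized) between labeled cells and
  background across excitation wavelengths.
* **Relative 2PE spectra** (`fgflim.spectra`) — reference-dye correction
  `f_c(λ) = F_R(λ)/σ_R(λ)`, `σ_S(λ) = F_S(λ)/f_c(λ)·C_R/C_S`, power
  normalization, background subtraction, boundary-aware peak calls, and the
  quadratic power-dependence check (log–log slope ≈ 2 for 2PE).
* **Cell-body counting** (`fgflim.segmentation`) — a deterministic classical
  3-D pipeline (smooth → threshold → fill → 26-connected label → volume
  filter → optional watershed) for counting labeled somata in volumes.
* **Synthetic data** (`fgflim.synthetic_data`) — generators for every input
  above with known ground truth: FG-like two-component decays (90 ps /
  2.3 ns, intensity-weighted mean pinned at 1.4 ns), 1.35 ns
  mono-exponential background, Gaussian 100 ps IRF, Poisson counting,
  wavelength series over 720–1000 nm, and ellipsoidal cell phantoms.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate an FG-like decay at 10⁶ photons and fit it:

```python
import fgflim as fg

irf = fg.make_irf()                       # Gaussian, 100 ps FWHM, 256 bins
truth = fg.fg_decay_params()              # 90 ps / 2.3 ns, mean 1.4 ns
acq = fg.AcquisitionSettings(seed=7)      # 12.5 ns window, 1e6 photons
hist = fg.simulate_decay(truth, irf, acq)

result = fg.fit_biexponential(hist, irf)
print("lifetimes (ns):", [round(t, 4) for t in result.params.lifetimes_ns])
print("amplitudes:    ", [round(a, 4) for a in result.params.amplitudes])
print("mean lifetime: ", round(result.mean_lifetime("intensity"), 3), "ns")
print("reduced chi2:  ", round(result.chi2_reduced, 3))
```

prints

```
lifetimes (ns): [0.0904, 2.3026]
amplitudes:     [0.9461, 0.0539]
mean lifetime:  1.4 ns
reduced chi2:   1.025
```

— the fitter recovers the injected sub-100 ps and 2.3 ns components, their
~0.95/0.05 amplitude split, and the 1.4 ns intensity-weighted mean
lifetime; a reduced χ² near 1 says the Poisson noise model is consistent
with the residuals.

The same stages are scriptable from the shell:

```sh
fgflim simulate decay --seed 7 --out decay.tsv
fgflim fit decay --model biexp --out fit.json decay.tsv
fgflim simulate flim --seed 3 --out scene.tif
fgflim flim fit --out-prefix maps scene.tif
fgflim flim contrast --fg-labels scene.labels.tif --out contrast.json maps
```

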