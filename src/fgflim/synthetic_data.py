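"""Synthetic TCSPC, FLIM, spectral, and volumetric test data with known truth.

Every downstream stage of the pipeline (decay fitting, lifetime mapping,
relative cross-section correction, cell-body segmentation) can be exercised
on data generated here, with the injected ground truth returned alongside.

The defaults emulate the Fluoro-Gold (FG) imaging conditions the package was
built around:

* FG decay: two components, a short one of 90 ps (the short component is
  known only to lie below 100 ps, so the default sits just under that bound)
  and a long one of 2.3 ns, with amplitude fractions solved so the
  intensity-weighted mean lifetime is exactly 1.4 ns
  (:func:`fgflim.decay_fit.amplitudes_for_intensity_mean`).
* Background (lipofuscin-like) autofluorescence: mono-exponential, 1.35 ns.
* Instrument response: Gaussian, 100 ps FWHM.
* Acquisition: 12.5 ns window (80 MHz repetition), 256 bins, Poisson counting.
* Excitation wavelength grid: 720-1000 nm in 10 nm steps.
* Scene phantoms: ellipsoidal cell bodies (motoneuron scale, ~10-15 um radius
  at 1 um/voxel) over a uniform tissue background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    PS_PER_NS,
    _FWHM_TO_SIGMA,
    AcquisitionSettings,
    ConvolvedDecayModel,
    DecayHistogram,
    DecayModelParams,
    IRFKernel,
    measure_fwhm,
)
from .decay_fit import amplitudes_for_intensity_mean
from .spectra import CrossSectionCurve, SpectralSeries

logger = logging.getLogger("fgflim")

# --- study-condition constants ---------------------------------------------
FG_TAU_SHORT_NS = 0.09      # short FG component, strictly below 100 ps
FG_TAU_LONG_NS = 2.3        # long FG component
FG_MEAN_LIFETIME_NS = 1.4   # intensity-weighted mean of the FG decay
BACKGROUND_TAU_NS = 1.35    # lipofuscin-like tissue autofluorescence
IRF_FWHM_PS = 100.0         # instrument response duration
DEFAULT_IRF_CENTER_PS = 1250.0
WAVELENGTH_MIN_NM = 720.0
WAVELENGTH_MAX_NM = 1000.0
WAVELENGTH_STEP_NM = 10.0


def wavelength_grid() -> np.ndarray:
    """Excitation wavelengths in 10 nm steps over 720-1000 nm."""
    return np.arange(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM + 0.5,
                     WAVELENGTH_STEP_NM)


def fg_decay_params(baseline: float = 0.0) -> DecayModelParams:
    """FG bi-exponential truth: 90 ps / 2.3 ns with a 1.4 ns intensity mean."""
    a1, a2 = amplitudes_for_intensity_mean(FG_TAU_SHORT_NS, FG_TAU_LONG_NS,
                                           FG_MEAN_LIFETIME_NS)
    return DecayModelParams((a1, a2), (FG_TAU_SHORT_NS, FG_TAU_LONG_NS),
                            baseline)


def background_decay_params(baseline: float = 0.0) -> DecayModelParams:
    """Mono-exponential tissue-background truth at 1.35 ns."""
    return DecayModelParams.mono(BACKGROUND_TAU_NS, baseline)


# ---------------------------------------------------------------------------
# instrument response
# ---------------------------------------------------------------------------

def make_irf(fwhm: float = IRF_FWHM_PS, bin_width: float = 48.828125,
             n_bins: int = 256,
             center: float = DEFAULT_IRF_CENTER_PS) -> IRFKernel:
    """Gaussian instrument response kernel on a uniform time grid.

    Parameters
    ----------
    fwhm
        Full width at half maximum in ps.  Must be resolvable on the grid
        (``fwhm >= bin_width / 2``); an unresolvable request raises rather
        than silently degenerating to a delta.
    bin_width, n_bins
        Time grid the kernel will be convolved with (defaults match the
        256-bin / 12.5 ns acquisition window).
    center
        Peak position in ps from the window start.
    """
    if not fwhm > 0:
        raise ValueError("fwhm must be positive")
    if fwhm < bin_width / 2.0:
        raise ValueError(
            f"IRF fwhm {fwhm} ps is not resolvable on a {bin_width} ps grid "
            "(fwhm < bin_width/2); use a finer grid or delta_irf()")
    window = n_bins * bin_width
    if not (0.0 <= center <= window):
        raise ValueError(f"center {center} ps outside window [0, {window}]")
    t = (np.arange(n_bins) + 0.5) * bin_width
    sigma = fwhm * _FWHM_TO_SIGMA
    values = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    s = values.sum()
    if s <= 0:
        raise ValueError("IRF kernel vanished; center too close to the edge")
    return IRFKernel(values / s, bin_width, center, fwhm)


def delta_irf(bin_width: float, n_bins: int, center: float = 0.0) -> IRFKernel:
    """Idealized single-bin (delta) response at the bin nearest ``center``.

    The nominal fwhm is set to the bin width, the narrowest width the grid
    can represent.
    """
    values = np.zeros(n_bins)
    idx = min(n_bins - 1, max(0, int(round(center / bin_width - 0.5))))
    values[idx] = 1.0
    return IRFKernel(values, bin_width, (idx + 0.5) * bin_width, bin_width)


def irf_from_histogram(hist: DecayHistogram) -> IRFKernel:
    """Build a kernel from a measured IRF histogram (normalized to unit area)."""
    counts = hist.counts.astype(float)
    s = counts.sum()
    if s <= 0:
        raise ValueError("measured IRF histogram is empty")
    values = counts / s
    center = float((hist.time_axis - hist.t0) @ values)
    fwhm = measure_fwhm(values, hist.bin_width)
    return IRFKernel(values, hist.bin_width, center, fwhm)


# ---------------------------------------------------------------------------
# decay simulation
# ---------------------------------------------------------------------------

def expected_decay_counts(params: DecayModelParams, irf: IRFKernel,
                          total_photons: float) -> np.ndarray:
    """Noise-free expected counts/bin for a decay seen through ``irf``."""
    return ConvolvedDecayModel(irf).expected(params, total_photons)


def simulate_decay(params: DecayModelParams, irf: IRFKernel,
                   acq: AcquisitionSettings) -> DecayHistogram:
    """Poisson TCSPC histogram of an IRF-convolved multi-exponential decay.

    Expected counts are ``total_photons * (decay (*) IRF) + baseline``; the
    observed histogram draws each bin from a Poisson law with that mean.
    Deterministic under a fixed ``acq.seed``.
    """
    if irf.n_bins != acq.n_bins:
        raise ValueError(
            f"IRF has {irf.n_bins} bins but acquisition expects {acq.n_bins}")
    if abs(irf.bin_width - acq.bin_width_ps) > 1e-6 * acq.bin_width_ps:
        raise ValueError("IRF bin width does not match the acquisition window")
    expected = expected_decay_counts(params, irf, acq.total_photons)
    rng = np.random.default_rng(acq.seed)
    counts = rng.poisson(expected)
    meta = {
        "truth": _params_dict(params),
        "seed": acq.seed,
        "total_photons": acq.total_photons,
        "irf": {"fwhm_ps": irf.fwhm, "center_ps": irf.center},
    }
    return DecayHistogram(counts, acq.bin_width_ps, 0.0, meta)


def _params_dict(p: DecayModelParams) -> dict:
    return {
        "amplitudes": list(p.amplitudes),
        "lifetimes_ns": list(p.lifetimes_ns),
        "baseline": p.baseline,
    }


# ---------------------------------------------------------------------------
# scene phantoms and FLIM images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """One ellipsoidal cell body in a phantom scene."""

    center: tuple[float, float, float]       # (z, y, x), voxel units
    radii: tuple[float, float, float]        # (z, y, x) semi-axes, voxels
    decay: DecayModelParams
    brightness: float = 1.0                  # photon multiplier vs. nominal

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("cell radii must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be nonnegative")


@dataclass(frozen=True)
class ScenePhantom:
    """Ellipsoidal cell bodies over a uniform background volume.

    ``photons_per_pixel`` is the nominal expected photon count of a
    brightness-1 voxel; per-voxel expectations scale with the cell or
    background brightness.
    """

    shape: tuple[int, int, int] = (1, 64, 64)          # (z, y, x)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # um
    cells: tuple[CellSpec, ...] = ()
    background_decay: DecayModelParams = field(
        default_factory=lambda: DecayModelParams.mono(BACKGROUND_TAU_NS))
    background_brightness: float = 1.0
    photons_per_pixel: int = 5000

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError("phantom shape must be at least 1 voxel per axis")
        if self.background_brightness < 0 or self.photons_per_pixel < 0:
            raise ValueError("brightness and photon budget must be >= 0")
        for c in self.cells:
            if not all(0 <= c.center[i] < self.shape[i] for i in range(3)):
                raise ValueError(f"cell center {c.center} outside the volume")
        object.__setattr__(self, "cells", tuple(self.cells))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a simulated scene."""

    labels: np.ndarray                  # (z, y, x) uint16, 0 = background
    cell_specs: tuple[CellSpec, ...]
    mean_lifetime: np.ndarray           # (z, y, x) intensity-weighted, ns
    has_overlap: bool

    @property
    def n_cells(self) -> int:
        return len(self.cell_specs)


@dataclass
class FlimDataset:
    """Per-pixel TCSPC histograms plus the shared time axis and IRF."""

    data: np.ndarray                    # (..., n_bins) counts
    bin_width: float                    # ps
    irf: IRFKernel
    wavelength: float | None = None     # nm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim < 2:
            raise ValueError("FLIM data must have at least one spatial axis "
                             "plus the time axis")
        if np.any(d < 0):
            raise ValueError("FLIM counts must be nonnegative")
        if d.shape[-1] != self.irf.n_bins:
            raise ValueError("time axis length does not match the IRF")
        self.data = d

    @property
    def n_bins(self) -> int:
        return int(self.data.shape[-1])

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]


def phantom_labels(phantom: ScenePhantom) -> tuple[np.ndarray, bool]:
    """Rasterize cell ellipsoids into a uint16 label volume.

    Returns the labels (cells numbered 1..n in listing order; later cells
    overwrite earlier ones where they overlap) and an overlap flag.
    """
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in phantom.shape),
                             indexing="ij")
    labels = np.zeros(phantom.shape, dtype=np.uint16)
    hit_count = np.zeros(phantom.shape, dtype=np.uint8)
    for i, cell in enumerate(phantom.cells, start=1):
        cz, cy, cx = cell.center
        rz, ry, rx = cell.radii
        inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
                  + ((xx - cx) / rx) ** 2) <= 1.0
        labels[inside] = i
        hit_count[inside] += 1
    return labels, bool(np.any(hit_count > 1))


def simulate_flim_image(phantom: ScenePhantom, irf: IRFKernel,
                        acq: AcquisitionSettings
                        ) -> tuple[FlimDataset, PhantomTruth]:
    """Simulate a (z, y, x, t) FLIM stack from a scene phantom.

    Every voxel inside a cell ellipsoid carries that cell's decay; all other
    voxels carry the background decay.  Per-voxel expected photons are
    ``phantom.photons_per_pixel`` scaled by the local brightness;
    ``acq.total_photons`` is ignored here.  Overlapping cells are permitted
    but flagged in the returned truth and dataset metadata.
    """
    if irf.n_bins != acq.n_bins:
        raise ValueError("IRF bin count does not match the acquisition")
    labels, has_overlap = phantom_labels(phantom)
    if has_overlap:
        logger.warning("phantom contains overlapping cells")

    model = ConvolvedDecayModel(irf)
    from .decay_fit import mean_lifetime  # local import: avoids cycle at load

    # one expected curve per distinct region (background + each cell)
    curves = {0: model.expected(phantom.background_decay,
                                phantom.photons_per_pixel
                                * phantom.background_brightness)}
    tau_truth = {0: mean_lifetime(phantom.background_decay, "intensity")}
    for i, cell in enumerate(phantom.cells, start=1):
        curves[i] = model.expected(cell.decay,
                                   phantom.photons_per_pixel * cell.brightness)
        tau_truth[i] = mean_lifetime(cell.decay, "intensity")

    expected = np.empty(phantom.shape + (acq.n_bins,), dtype=float)
    truth_tau = np.empty(phantom.shape, dtype=float)
    for lab, curve in curves.items():
        mask = labels == lab
        expected[mask] = curve
        truth_tau[mask] = tau_truth[lab]

    rng = np.random.default_rng(acq.seed)
    data = rng.poisson(expected).astype(np.int64)
    meta = {
        "seed": acq.seed,
        "photons_per_pixel": phantom.photons_per_pixel,
        "n_cells": len(phantom.cells),
        "has_overlap": has_overlap,
        "background_truth": _params_dict(phantom.background_decay),
    }
    ds = FlimDataset(data, acq.bin_width_ps, irf, metadata=meta)
    return ds, PhantomTruth(labels, phantom.cells, truth_tau, has_overlap)


def simulate_volume(phantom: ScenePhantom, noise_sd: float = 0.0,
                    seed: int = 0) -> tuple[np.ndarray, PhantomTruth]:
    """Plain 3-D intensity volume (no decay axis) for segmentation tests.

    Voxel intensity is the local brightness times ``photons_per_pixel``,
    plus additive Gaussian noise of standard deviation ``noise_sd`` (same
    units).  Returns the volume and the phantom truth (truth mean-lifetime
    map included for lifetime-gated segmentation tests).
    """
    labels, has_overlap = phantom_labels(phantom)
    from .decay_fit import mean_lifetime

    intensity = np.full(phantom.shape,
                        phantom.background_brightness
                        * phantom.photons_per_pixel, dtype=float)
    truth_tau = np.full(phantom.shape,
                        mean_lifetime(phantom.background_decay, "intensity"))
    for i, cell in enumerate(phantom.cells, start=1):
        mask = labels == i
        intensity[mask] = cell.brightness * phantom.photons_per_pixel
        truth_tau[mask] = mean_lifetime(cell.decay, "intensity")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, phantom.shape)
    return intensity, PhantomTruth(labels, phantom.cells, truth_tau,
                                   has_overlap)


# ---------------------------------------------------------------------------
# spectral and power series
# ---------------------------------------------------------------------------

def fg_like_cross_section(wavelengths: np.ndarray | None = None
                          ) -> CrossSectionCurve:
    """Monotone-decreasing sample-dye curve peaking at the 720 nm grid edge.

    Mimics the shape of a two-photon excitation spectrum whose absolute
    maximum lies below the laser tuning range, so the sampled maximum sits on
    the grid boundary.
    """
    wl = wavelength_grid() if wavelengths is None else np.asarray(wavelengths,
                                                                  dtype=float)
    sigma = np.exp(-(wl - wl[0]) / 120.0)
    return CrossSectionCurve(wl, sigma)


def reference_like_cross_section(wavelengths: np.ndarray | None = None,
                                 peak_nm: float = 800.0,
                                 width_nm: float = 80.0) -> CrossSectionCurve:
    """Smooth single-bump reference-dye curve with an interior maximum."""
    wl = wavelength_grid() if wavelengths is None else np.asarray(wavelengths,
                                                                  dtype=float)
    sigma = 0.2 + np.exp(-0.5 * ((wl - peak_nm) / width_nm) ** 2)
    return CrossSectionCurve(wl, sigma)


def simulate_spectral_series(true_sigma_sample: CrossSectionCurve,
                             true_sigma_reference: CrossSectionCurve,
                             c_sample: float, c_reference: float,
                             laser_power: np.ndarray | float = 1.0,
                             instrument_factor: np.ndarray | float = 1.0,
                             noise_cv: float = 0.0, seed: int = 0
                             ) -> tuple[SpectralSeries, SpectralSeries]:
    """Fluorescence series for a sample and a reference dye on one grid.

    The two-photon signal model is

        F(lambda) = g(lambda) * sigma(lambda) * C * P(lambda)^2 * (1 + eps),

    with the same instrument factor g and laser power P applied to both dyes
    ("identical imaging conditions") and eps ~ Normal(0, noise_cv) drawn
    independently per wavelength and dye.
    """
    wl = true_sigma_sample.wavelengths
    if not np.array_equal(wl, true_sigma_reference.wavelengths):
        raise ValueError("sample and reference must share a wavelength grid")
    if c_sample <= 0 or c_reference <= 0:
        raise ValueError("concentrations must be positive")
    power = np.broadcast_to(np.asarray(laser_power, dtype=float), wl.shape)
    if np.any(power <= 0):
        raise ValueError("laser power must be positive")
    gain = np.broadcast_to(np.asarray(instrument_factor, dtype=float),
                           wl.shape)
    rng = np.random.default_rng(seed)

    def series(curve: CrossSectionCurve, conc: float) -> SpectralSeries:
        f = gain * curve.sigma * conc * power ** 2
        if noise_cv > 0:
            f = f * (1.0 + rng.normal(0.0, noise_cv, wl.shape))
        return SpectralSeries(wl, np.maximum(f, 0.0), power=power.copy(),
                              metadata={"noise_cv": noise_cv, "seed": seed,
                                        "concentration": conc})

    return series(true_sigma_sample, c_sample), series(true_sigma_reference,
                                                       c_reference)


def simulate_power_series(sigma: float, concentration: float,
                          powers: Sequence[float], exponent: float = 2.0,
                          noise_cv: float = 0.0, seed: int = 0):
    """(power, fluorescence) table following F = c P^exponent with CV noise.

    Used to verify the quadratic intensity dependence of two-photon
    excitation (exponent 2) against a linear one-photon control (exponent 1).
    """
    import pandas as pd

    p = np.asarray(powers, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("powers must be a non-empty 1-D sequence")
    if np.any(p <= 0):
        raise ValueError("powers must be positive")
    f = sigma * concentration * p ** exponent
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        f = f * (1.0 + rng.normal(0.0, noise_cv, p.shape))
    return pd.DataFrame({"power_mW": p, "intensity": np.maximum(f, 0.0)})
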