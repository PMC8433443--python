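"""Relative two-photon excitation spectra and power-dependence checks.

A sample dye's two-photon cross-section can be measured relative to a
reference dye of known spectrum without characterizing the laser or detection
path, provided both dyes are imaged under identical conditions.  The
reference measurement defines a per-wavelength correction curve

    f_c(lambda) = F_R(lambda) / sigma_R(lambda),

which absorbs every wavelength-dependent instrument factor; the sample's
relative cross-section then follows from its fluorescence series and the
molar concentration ratio:

    sigma_S(lambda) = F_S(lambda) / f_c(lambda) * C_R / C_S.

Only *relative* cross-sections are produced; converting to absolute GM units
would additionally require detector spectral sensitivity and quantum-yield
corrections, which are out of scope here.

The module also verifies the quadratic dependence of two-photon-excited
fluorescence on excitation power via a log-log regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger("fgflim")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class SpectralSeries:
    """Wavelength-indexed fluorescence measurements.

    ``power`` (mW) and ``background`` (same units as intensity) are optional
    per-wavelength companions.
    """

    wavelengths: np.ndarray
    intensity: np.ndarray
    power: np.ndarray | None = None
    background: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or wl.size != f.size:
            raise ValueError("wavelengths and intensity must be equal-length "
                             "1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.wavelengths, self.intensity = wl, f
        for name in ("power", "background"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != wl.shape:
                    raise ValueError(f"{name} must match the wavelength grid")
                setattr(self, name, v)


@dataclass
class CrossSectionCurve:
    """Relative two-photon cross-section per wavelength (arbitrary scale)."""

    wavelengths: np.ndarray
    sigma: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if wl.ndim != 1 or wl.size != s.size:
            raise ValueError("wavelengths and sigma must be equal-length "
                             "1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(s[np.isfinite(s)] < 0):
            raise ValueError("sigma must be nonnegative where defined")
        self.wavelengths, self.sigma = wl, s


@dataclass
class CorrectionCurve:
    """Per-wavelength instrument correction f_c = F_R / sigma_R."""

    wavelengths: np.ndarray
    values: np.ndarray
    dropped_wavelengths: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    metadata: dict = field(default_factory=dict)


@dataclass
class PeakResult:
    """Location of a sampled spectral maximum."""

    wavelength_nm: float
    value: float
    is_boundary: bool
    is_tie: bool = False


@dataclass
class PowerLawFit:
    """Log-log slope of fluorescence vs. excitation power."""

    slope: float
    stderr: float
    ci95: tuple[float, float]
    intercept: float
    n: int


def _require_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.allclose(a, b, rtol=0, atol=1e-9):
        raise ValueError("wavelength grids differ; measurements must share "
                         "one grid (no implicit resampling)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_by_power(s: SpectralSeries, exponent: float = 2.0
                       ) -> SpectralSeries:
    """Divide fluorescence by laser power to the given exponent.

    Two-photon signal scales as P^2, so the default exponent is 2; exponent 1
    is available for one-photon-style normalization.  Requires a positive
    power value at every wavelength.
    """
    if s.power is None:
        raise ValueError("series carries no power column")
    if np.any(s.power <= 0):
        raise ValueError("laser power must be positive at every wavelength")
    out = SpectralSeries(s.wavelengths.copy(),
                         s.intensity / s.power ** exponent,
                         background=None if s.background is None
                         else s.background / s.power ** exponent,
                         metadata=dict(s.metadata))
    out.metadata["power_normalized_exponent"] = exponent
    return out


def background_subtract(s: SpectralSeries, b: SpectralSeries
                        ) -> SpectralSeries:
    """Subtract a background series, flooring at zero.

    Wavelengths where the difference was floored are flagged in
    ``metadata["floored_wavelengths"]`` so downstream peak calls can exclude
    them rather than trusting a clipped zero.
    """
    _require_same_grid(s.wavelengths, b.wavelengths)
    diff = s.intensity - b.intensity
    floored = diff < 0
    out = SpectralSeries(s.wavelengths.copy(), np.maximum(diff, 0.0),
                         power=None if s.power is None else s.power.copy(),
                         metadata=dict(s.metadata))
    out.metadata["floored_wavelengths"] = s.wavelengths[floored].tolist()
    if floored.any():
        logger.warning("background subtraction floored %d wavelengths",
                       int(floored.sum()))
    return out


def correction_curve(f_r: SpectralSeries, sigma_r: CrossSectionCurve
                     ) -> CorrectionCurve:
    """Instrument correction from the reference dye: f_c = F_R / sigma_R.

    Wavelengths where the reference cross-section is zero (or undefined) are
    dropped from the curve and reported in ``dropped_wavelengths``.
    """
    _require_same_grid(f_r.wavelengths, sigma_r.wavelengths)
    ok = np.isfinite(sigma_r.sigma) & (sigma_r.sigma > 0)
    if not ok.any():
        raise ValueError("reference cross-section is zero everywhere")
    dropped = f_r.wavelengths[~ok]
    if dropped.size:
        logger.warning("correction curve undefined at %d wavelengths "
                       "(sigma_R = 0); dropped", dropped.size)
    return CorrectionCurve(f_r.wavelengths[ok],
                           f_r.intensity[ok] / sigma_r.sigma[ok],
                           dropped_wavelengths=dropped)


def relative_cross_section(f_s: SpectralSeries, f_c: CorrectionCurve,
                           c_reference: float, c_sample: float
                           ) -> CrossSectionCurve:
    """Sample cross-section: sigma_S = (F_S / f_c) * (C_R / C_S).

    The sample series is restricted to the correction curve's (possibly
    reduced) grid; the concentration ratio puts both dyes on a common
    per-molecule scale.  The result inherits whatever relative scale the
    reference spectrum was expressed in.
    """
    if c_reference <= 0 or c_sample <= 0:
        raise ValueError("concentrations must be positive")
    keep = np.isin(f_s.wavelengths, f_c.wavelengths)
    if keep.sum() != f_c.wavelengths.size:
        raise ValueError("sample grid does not cover the correction curve")
    sigma = (f_s.intensity[keep] / f_c.values) * (c_reference / c_sample)
    return CrossSectionCurve(
        f_s.wavelengths[keep], sigma,
        metadata={"c_reference": c_reference, "c_sample": c_sample,
                  "dropped_wavelengths": f_c.dropped_wavelengths.tolist()})


def spectral_peak(curve: CrossSectionCurve | SpectralSeries) -> PeakResult:
    """Argmax of a sampled spectrum, with boundary and tie flags.

    ``is_boundary`` marks a maximum at the first or last grid point — the
    situation where the true peak may lie outside the tuning range of the
    laser (as for Fluoro-Gold at 720 nm).  Exact ties resolve to the shorter
    wavelength and set ``is_tie``.
    """
    y = curve.sigma if isinstance(curve, CrossSectionCurve) else curve.intensity
    wl = curve.wavelengths
    finite = np.isfinite(y)
    if not finite.any():
        raise ValueError("spectrum has no finite values")
    vmax = np.max(y[finite])
    winners = np.flatnonzero(finite & (y == vmax))
    idx = int(winners[0])
    return PeakResult(float(wl[idx]), float(vmax),
                      is_boundary=idx in (0, wl.size - 1),
                      is_tie=winners.size > 1)


def power_exponent(powers: np.ndarray, intensities: np.ndarray
                   ) -> PowerLawFit:
    """Least-squares slope of log F vs. log P with its 95% CI.

    Two-photon-excited fluorescence should give a slope of 2; a slope near 1
    indicates one-photon (linear) signal.  Requires at least three strictly
    positive (P, F) pairs.
    """
    p = np.asarray(powers, dtype=float)
    f = np.asarray(intensities, dtype=float)
    if p.shape != f.shape or p.ndim != 1:
        raise ValueError("powers and intensities must be equal-length 1-D")
    if p.size < 3:
        raise ValueError("need at least 3 power levels")
    if np.any(p <= 0) or np.any(f <= 0):
        raise ValueError("powers and intensities must be strictly positive")
    res = stats.linregress(np.log(p), np.log(f))
    tcrit = stats.t.ppf(0.975, p.size - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return PowerLawFit(float(res.slope), float(res.stderr),
                       (float(ci[0]), float(ci[1])),
                       float(res.intercept), int(p.size))
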