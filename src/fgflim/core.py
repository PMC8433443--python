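"""Shared domain types and the periodic IRF-convolved decay forward model.

Time-correlated single photon counting (TCSPC) records a histogram of photon
arrival times over one laser repetition period.  The measured histogram is the
fluorophore's multi-exponential decay convolved with the instrument response
function (IRF).  Because excitation is a pulse *train*, the tail of a long
lifetime component folds into the next period; the forward model here is
therefore a circular (wrap-around) convolution of the steady-state wrapped
exponential with the IRF kernel, which is the physically correct picture for
pulsed excitation at a fixed repetition rate.

Conventions
-----------
* time axis in picoseconds (ps); lifetimes in nanoseconds (ns)
* histogram bins are uniform; values are sampled at bin centers
* IRF kernels carry unit area, so convolution conserves photon counts
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("fgflim")

PS_PER_NS = 1000.0

# Gaussian FWHM = 2 sqrt(2 ln 2) sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IRFKernel:
    """Instrument response function sampled on the acquisition time grid.

    Parameters
    ----------
    values
        Nonnegative weights per time bin, summing to one (unit area).
    bin_width
        Width of one time bin in ps.
    center
        Nominal kernel center in ps from the window start.
    fwhm
        Nominal full width at half maximum in ps.
    """

    values: np.ndarray
    bin_width: float
    center: float
    fwhm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("IRF values must be a 1-D array with >= 2 bins")
        if np.any(v < 0):
            raise ValueError("IRF values must be nonnegative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("IRF values must sum to 1 within 1e-9")
        if not self.fwhm > 0:
            raise ValueError("IRF fwhm must be positive")
        if not self.bin_width > 0:
            raise ValueError("IRF bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def time_axis(self) -> np.ndarray:
        """Bin-center times in ps."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class DecayModelParams:
    """Parameters of a mono- or bi-exponential fluorescence decay.

    ``amplitudes`` are fractional pre-exponential amplitudes summing to one;
    ``lifetimes_ns`` are the component lifetimes in ns, in canonical
    (ascending) order; ``baseline`` is a constant offset in counts per bin.
    """

    amplitudes: tuple[float, ...]
    lifetimes_ns: tuple[float, ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.amplitudes)
        t = tuple(float(x) for x in self.lifetimes_ns)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "lifetimes_ns", t)
        if len(a) != len(t) or len(a) not in (1, 2):
            raise ValueError("need 1 or 2 (amplitude, lifetime) pairs")
        if any(x < 0 for x in a):
            raise ValueError("amplitudes must be nonnegative")
        if abs(sum(a) - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1 within 1e-9")
        if any(x <= 0 for x in t):
            raise ValueError("lifetimes must be positive")
        if len(t) == 2 and t[0] > t[1]:
            raise ValueError("lifetimes must be in canonical ascending order "
                             "(use DecayModelParams.canonical)")
        if self.baseline < 0:
            raise ValueError("baseline must be nonnegative")

    @classmethod
    def mono(cls, tau_ns: float, baseline: float = 0.0) -> "DecayModelParams":
        return cls((1.0,), (float(tau_ns),), baseline)

    @classmethod
    def biexp(cls, a1: float, tau1_ns: float, tau2_ns: float,
              baseline: float = 0.0) -> "DecayModelParams":
        return cls.canonical((a1, 1.0 - a1), (tau1_ns, tau2_ns), baseline)

    @classmethod
    def canonical(cls, amplitudes: Sequence[float],
                  lifetimes_ns: Sequence[float],
                  baseline: float = 0.0) -> "DecayModelParams":
        """Build params with components sorted by ascending lifetime."""
        order = np.argsort(np.asarray(lifetimes_ns, dtype=float), kind="stable")
        a = tuple(float(amplitudes[i]) for i in order)
        t = tuple(float(lifetimes_ns[i]) for i in order)
        s = sum(a)
        if s <= 0:
            raise ValueError("amplitudes must have positive sum")
        return cls(tuple(x / s for x in a), t, baseline)

    @property
    def n_components(self) -> int:
        return len(self.amplitudes)

    @property
    def intensity_fractions(self) -> tuple[float, ...]:
        """Fraction of emitted photons per component, a_i tau_i / sum."""
        w = [a * t for a, t in zip(self.amplitudes, self.lifetimes_ns)]
        s = sum(w)
        return tuple(x / s for x in w)


@dataclass(frozen=True)
class AcquisitionSettings:
    """TCSPC acquisition window and photon budget.

    Defaults follow the 80 MHz Ti:Sapphire convention: a 12.5 ns repetition
    window divided into 256 bins (~48.8 ps/bin).
    """

    n_bins: int = 256
    period_ns: float = 12.5
    total_photons: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")
        if not self.period_ns > 0:
            raise ValueError("period must be positive")
        if self.total_photons < 0:
            raise ValueError("total_photons must be >= 0")

    @property
    def bin_width_ps(self) -> float:
        return self.period_ns * PS_PER_NS / self.n_bins

    @property
    def period_ps(self) -> float:
        return self.period_ns * PS_PER_NS


@dataclass
class DecayHistogram:
    """Binned photon arrival counts over one laser period."""

    counts: np.ndarray
    bin_width: float            # ps
    t0: float = 0.0             # ps, window start (bin left edge convention)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        self.counts = c
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def time_axis(self) -> np.ndarray:
        """Bin-center times in ps."""
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def time_edges(self) -> np.ndarray:
        """Bin left edges in ps (file exchange convention)."""
        return self.t0 + np.arange(self.n_bins) * self.bin_width

    @property
    def total(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def wrapped_multiexponential(params: DecayModelParams, n_bins: int,
                             bin_width_ps: float) -> np.ndarray:
    """Steady-state multi-exponential decay under pulse-train excitation.

    For repetition period T, the observable decay at time t in [0, T) is the
    superposition of the responses to all previous pulses,

        d(t) = sum_i a_i exp(-t/tau_i) / (1 - exp(-T/tau_i)),

    sampled at bin centers and normalized to unit sum so that convolution and
    photon scaling conserve counts exactly.
    """
    t = (np.arange(n_bins) + 0.5) * bin_width_ps
    period = n_bins * bin_width_ps
    d = np.zeros(n_bins)
    for a, tau_ns in zip(params.amplitudes, params.lifetimes_ns):
        tau = tau_ns * PS_PER_NS
        d += a * np.exp(-t / tau) / (1.0 - np.exp(-period / tau))
    s = d.sum()
    if s <= 0:
        raise ValueError("degenerate decay: zero total intensity")
    return d / s


def convolve_periodic(signal: np.ndarray, kernel: np.ndarray,
                      shift_bins: float = 0.0) -> np.ndarray:
    """Circular convolution of two equal-length sequences via the FFT.

    ``shift_bins`` applies an additional (possibly fractional) circular
    delay to the kernel, used as the "color shift" nuisance parameter when
    fitting.  Tiny negative values from roundoff are clipped to zero.
    """
    n = signal.size
    if kernel.size != n:
        raise ValueError(f"kernel length {kernel.size} != signal length {n}")
    f = np.fft.rfft(signal) * np.fft.rfft(kernel)
    if shift_bins != 0.0:
        freqs = np.arange(f.size)
        f *= np.exp(-2j * np.pi * freqs * shift_bins / n)
    out = np.fft.irfft(f, n)
    return np.where(out < 0, 0.0, out)


class ConvolvedDecayModel:
    """Expected TCSPC counts for a decay model seen through a fixed IRF.

    Precomputes the kernel FFT so repeated evaluations during fitting (or
    per-pixel mapping) are cheap.
    """

    def __init__(self, irf: IRFKernel):
        self.irf = irf
        self.n_bins = irf.n_bins
        self.bin_width = irf.bin_width
        self._kernel_fft = np.fft.rfft(irf.values)
        self._freqs = np.arange(self._kernel_fft.size)

    def expected(self, params: DecayModelParams, n_photons: float = 1.0,
                 shift_ps: float = 0.0) -> np.ndarray:
        """Expected counts/bin: n_photons * (decay (*) IRF) + baseline."""
        d = wrapped_multiexponential(params, self.n_bins, self.bin_width)
        f = np.fft.rfft(d) * self._kernel_fft
        if shift_ps != 0.0:
            shift_bins = shift_ps / self.bin_width
            f = f * np.exp(-2j * np.pi * self._freqs * shift_bins / self.n_bins)
        out = np.fft.irfft(f, self.n_bins)
        out = np.where(out < 0, 0.0, out)
        return n_photons * out + params.baseline


def measure_fwhm(values: np.ndarray, bin_width: float) -> float:
    """Full width at half maximum of a sampled peak, in time units.

    The two half-maximum crossings are located by linear interpolation
    between the bin-center samples bracketing each crossing.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 samples to measure a width")
    imax = int(np.argmax(v))
    half = v[imax] / 2.0
    t = (np.arange(v.size) + 0.5) * bin_width

    # walk left from the peak
    left = None
    for i in range(imax, 0, -1):
        if v[i - 1] < half <= v[i]:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    right = None
    for i in range(imax, v.size - 1):
        if v[i + 1] < half <= v[i]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    if left is None or right is None:
        raise ValueError("half-maximum crossings not found inside the window")
    return float(right - left)
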