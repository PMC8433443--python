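"""IRF-convolved mono- and bi-exponential fits to TCSPC decay histograms.

The measured histogram is modeled as

    E(t) = A * [ sum_i a_i exp(-t/tau_i) ] (*) IRF(t - shift) + baseline,

a periodic (wrap-around) convolution over the laser repetition window, with
the pre-exponential fractions a_i summing to one.  Two weighting schemes are
available:

* ``"pearson"`` (default): least squares with Poisson weights
  1/max(E, 1), the scheme used by commercial TCSPC fitting software.
* ``"deviance"``: signed square-root Poisson deviance residuals, whose least
  squares optimum is the exact Poisson maximum-likelihood estimate.

Goodness of fit is summarized by the reduced chi-squared over bins whose
expected counts exceed a floor (default 1 count, to avoid dividing by
near-zero tails), with degrees of freedom n_used_bins - n_parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .core import (
    PS_PER_NS,
    ConvolvedDecayModel,
    DecayHistogram,
    DecayModelParams,
    IRFKernel,
)

logger = logging.getLogger("fgflim")

__all__ = [
    "FitOptions", "FitResult", "model_decay", "fit_monoexponential",
    "fit_biexponential", "mean_lifetime", "reduced_chi_squared",
    "amplitudes_for_intensity_mean", "DecayHistogram",
]


# ---------------------------------------------------------------------------
# options and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    """Knobs for the decay fitters.

    Attributes
    ----------
    weighting
        "pearson" for Poisson-weighted least squares, "deviance" for the
        Poisson maximum-likelihood objective.
    min_total_counts
        Histograms with fewer total photons are rejected outright.
    fit_shift
        Treat the IRF temporal shift ("color shift") as a free nuisance
        parameter, bounded to +-``max_shift_bins`` bins.
    chi2_floor
        Expected-count floor for the chi-squared sum; bins whose expectation
        falls below it are excluded from the statistic.
    identifiability_rtol
        If a two-component fit converges with |tau2 - tau1| below this
        relative tolerance the fit is declared unidentifiable and collapses
        to a mono-exponential fit (recorded in metadata).
    tau_init_short_ns, init
        Initialization: the long lifetime comes from a log-slope fit of the
        tail, the short one starts at ``tau_init_short_ns``, amplitudes from
        the estimated intensity split; any entry can be overridden via
        ``init`` ({"tau1", "tau2", "a1", "baseline", "shift"}).
    """

    weighting: Literal["pearson", "deviance"] = "pearson"
    min_total_counts: int = 1000
    fit_shift: bool = True
    max_shift_bins: float = 5.0
    chi2_floor: float = 1.0
    identifiability_rtol: float = 0.02
    tau_init_short_ns: float = 0.05
    tau_bounds_ns: tuple[float, float] = (1e-3, 50.0)
    init: dict | None = None
    max_nfev: int = 2000


@dataclass
class FitResult:
    """Result of an IRF-convolved exponential fit.

    ``params`` holds canonical (ascending-lifetime) amplitudes, lifetimes and
    baseline; ``n_photons`` is the fitted decay amplitude (photons in the
    decay component, excluding baseline).  Both amplitude and intensity
    fractions are exposed because the field uses either convention for
    "component fraction".
    """

    params: DecayModelParams
    n_photons: float
    irf_shift_ps: float
    chi2_reduced: float
    residuals: np.ndarray
    n_free: int
    converged: bool
    covariance: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def amplitude_fractions(self) -> tuple[float, ...]:
        return self.params.amplitudes

    @property
    def intensity_fractions(self) -> tuple[float, ...]:
        return self.params.intensity_fractions

    def mean_lifetime(self, mode: str = "intensity") -> float:
        return mean_lifetime(self.params, mode)


# ---------------------------------------------------------------------------
# model and summary statistics
# ---------------------------------------------------------------------------

def model_decay(params: DecayModelParams, irf: IRFKernel,
                shift_ps: float = 0.0, n_photons: float = 1.0) -> np.ndarray:
    """Expected counts/bin for a decay model seen through ``irf``.

    Periodic convolution of the normalized multi-exponential with the IRF
    shifted by ``shift_ps``, scaled to ``n_photons`` and offset by the
    per-bin baseline.  The decay is sampled at bin centers; over one period
    the total equals ``n_photons + n_bins * baseline`` to float precision.
    """
    return ConvolvedDecayModel(irf).expected(params, n_photons, shift_ps)


def mean_lifetime(params: DecayModelParams,
                  mode: str = "intensity") -> float:
    """Mean lifetime of a multi-exponential decay, in ns.

    ``"amplitude"`` mode weights components by their pre-exponential
    amplitudes (sum a_i tau_i / sum a_i); ``"intensity"`` mode weights by
    emitted photons (sum a_i tau_i^2 / sum a_i tau_i).  Both lie between the
    smallest and largest component lifetime.
    """
    a = np.asarray(params.amplitudes)
    t = np.asarray(params.lifetimes_ns)
    if mode == "amplitude":
        return float((a * t).sum() / a.sum())
    if mode == "intensity":
        return float((a * t ** 2).sum() / (a * t).sum())
    raise ValueError(f"unknown mean-lifetime mode {mode!r}")


def amplitudes_for_intensity_mean(tau1_ns: float, tau2_ns: float,
                                  mean_ns: float) -> tuple[float, float]:
    """Amplitude fractions (a1, a2) whose intensity-weighted mean is given.

    Solves  (a1 tau1^2 + a2 tau2^2) / (a1 tau1 + a2 tau2) = mean  with
    a1 + a2 = 1.  For tau = (0.1, 2.3) ns and a 1.4 ns mean this gives
    a1 ~= 0.941, a2 ~= 0.059.
    """
    if not tau1_ns < mean_ns < tau2_ns:
        raise ValueError("mean must lie strictly between the two lifetimes")
    a2 = (tau1_ns * (mean_ns - tau1_ns)
          / (tau2_ns ** 2 - tau1_ns ** 2 - mean_ns * (tau2_ns - tau1_ns)))
    if not 0.0 < a2 < 1.0:
        raise ValueError("no valid amplitude split for these lifetimes")
    return 1.0 - a2, a2


def reduced_chi_squared(observed: np.ndarray, expected: np.ndarray,
                        n_free: int, floor: float = 1.0) -> float:
    """Pearson reduced chi-squared over bins with expectation >= ``floor``.

    chi2_red = sum (obs - exp)^2 / max(exp, floor) / n_free, restricted to
    bins whose expected counts reach the floor; the floor (default one
    count) keeps near-empty tail bins from dominating the statistic.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same shape")
    if n_free <= 0:
        raise ValueError("n_free must be positive")
    use = exp >= floor
    chi2 = float(((obs[use] - exp[use]) ** 2 / exp[use]).sum())
    return chi2 / n_free


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _tail_tau_estimate(hist: DecayHistogram, baseline0: float) -> float:
    """Long-lifetime starting value from the log-slope of the tail."""
    counts = hist.counts.astype(float)
    peak = int(np.argmax(counts))
    start = min(peak + max(3, hist.n_bins // 16), hist.n_bins - 4)
    idx = np.arange(start, hist.n_bins)
    y = counts[idx] - baseline0
    good = y > 5.0
    if good.sum() < 4:
        return 2.0
    t = idx[good] * hist.bin_width
    w = y[good]
    slope = np.polyfit(t, np.log(y[good]), 1, w=np.sqrt(w))[0]
    if slope >= 0:
        return 2.0
    return float(np.clip(-1.0 / slope / PS_PER_NS, 0.05, 40.0))


def _pearson_residuals(obs: np.ndarray, exp: np.ndarray) -> np.ndarray:
    return (obs - exp) / np.sqrt(np.maximum(exp, 1.0))


def _deviance_residuals(obs: np.ndarray, exp: np.ndarray) -> np.ndarray:
    exp = np.maximum(exp, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    dev = 2.0 * (exp - obs + term)
    return np.sign(obs - exp) * np.sqrt(np.maximum(dev, 0.0))


def _fit(hist: DecayHistogram, irf: IRFKernel, k: int,
         opts: FitOptions) -> FitResult:
    """Shared fitting core for k = 1 or 2 exponential components."""
    counts = hist.counts.astype(float)
    total = counts.sum()
    if total < opts.min_total_counts:
        raise ValueError(
            f"histogram has {total:.0f} counts, below the minimum of "
            f"{opts.min_total_counts}")
    if irf.n_bins != hist.n_bins:
        raise ValueError("IRF and histogram bin counts differ")

    model = ConvolvedDecayModel(irf)
    n = hist.n_bins
    init = dict(opts.init or {})

    baseline0 = float(init.get("baseline", max(counts.min(), 0.0)))
    amp0 = max(total - n * baseline0, 1.0)
    tau2_0 = float(init.get("tau2", _tail_tau_estimate(hist, baseline0)))
    lo, hi = opts.tau_bounds_ns
    tau2_0 = float(np.clip(tau2_0, lo * 1.01, hi * 0.99))
    shift0 = float(init.get("shift", 0.0))
    shift_hw = opts.max_shift_bins * hist.bin_width

    if k == 1:
        tau0 = float(init.get("tau1", tau2_0))
        x0 = [amp0, np.clip(tau0, lo * 1.01, hi * 0.99), baseline0, shift0]
        lower = [1e-6, lo, 0.0, -shift_hw]
        upper = [np.inf, hi, np.inf, shift_hw]

        def unpack(x):
            p = DecayModelParams.mono(x[1], x[2])
            return p, x[0], x[3]
    else:
        tau1_0 = float(np.clip(init.get("tau1", opts.tau_init_short_ns),
                               lo * 1.01, hi * 0.99))
        # intensity split estimate: photons in the extrapolated tail
        # component vs. the rest, converted to amplitude fractions
        f2 = 0.5
        tail_photons = _extrapolated_tail_photons(hist, baseline0, tau2_0)
        if amp0 > 0:
            f2 = float(np.clip(tail_photons / amp0, 0.05, 0.95))
        w1, w2 = (1.0 - f2) / tau1_0, f2 / tau2_0
        a1_0 = float(init.get("a1", w1 / (w1 + w2)))
        x0 = [amp0, np.clip(a1_0, 1e-3, 1 - 1e-3), tau1_0, tau2_0,
              baseline0, shift0]
        lower = [1e-6, 0.0, lo, lo, 0.0, -shift_hw]
        upper = [np.inf, 1.0, hi, hi, np.inf, shift_hw]

        def unpack(x):
            p = DecayModelParams.canonical((x[1], 1.0 - x[1]), (x[2], x[3]),
                                           x[4])
            return p, x[0], x[5]

    if not opts.fit_shift:
        lower[-1] = upper[-1] = 0.0
        x0[-1] = 0.0
        # least_squares needs lower < upper; drop the parameter instead
        lower = lower[:-1]
        upper = upper[:-1]
        x0 = x0[:-1]

        base_unpack = unpack

        def unpack(x):  # noqa: F811 - intentional rebinding
            p, a, _ = base_unpack(np.append(x, 0.0))
            return p, a, 0.0

    resid_fn = (_pearson_residuals if opts.weighting == "pearson"
                else _deviance_residuals)
    if opts.weighting not in ("pearson", "deviance"):
        raise ValueError(f"unknown weighting {opts.weighting!r}")

    def residuals(x):
        p, amp, shift = unpack(x)
        exp = model.expected(p, amp, shift)
        return resid_fn(counts, exp)

    sol = least_squares(residuals, x0, bounds=(lower, upper),
                        method="trf", x_scale="jac",
                        ftol=1e-14, xtol=1e-14, gtol=1e-14,
                        max_nfev=opts.max_nfev)

    params, amp, shift = unpack(sol.x)
    n_params = len(sol.x)
    expected = model.expected(params, amp, shift)
    n_used = int((expected >= opts.chi2_floor).sum())
    n_free = max(n_used - n_params, 1)
    chi2 = reduced_chi_squared(counts, expected, n_free, opts.chi2_floor)
    resid = _pearson_residuals(counts, expected)

    converged = bool(sol.success)
    meta: dict = {"weighting": opts.weighting, "nfev": int(sol.nfev),
                  "model": "mono" if k == 1 else "biexp"}
    # a lifetime pinned at its bound is not a trustworthy optimum
    taus = np.asarray(params.lifetimes_ns)
    if np.any(taus <= lo * 1.05) or np.any(taus >= hi * 0.95):
        converged = False
        meta["tau_at_bound"] = True
    # decay amplitude collapsed to ~0: baseline explains everything, the
    # lifetimes are meaningless (e.g. a flat histogram)
    if amp <= 1e-4 * total:
        converged = False
        meta["amplitude_collapsed"] = True

    cov = None
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        meta["covariance_failed"] = True

    result = FitResult(params, float(amp), float(shift), float(chi2),
                       resid, n_free, converged, cov, meta)

    if k == 2:
        t1, t2 = params.lifetimes_ns
        if abs(t2 - t1) <= opts.identifiability_rtol * t2:
            logger.warning("biexponential fit unidentifiable "
                           "(tau1 ~= tau2 = %.3f ns); collapsing to mono", t2)
            mono = _fit(hist, irf, 1, replace(opts, init={**init, "tau1": t2}))
            mono.metadata["collapsed_from_biexp"] = True
            mono.metadata["biexp_taus_ns"] = (t1, t2)
            return mono
    return result


def _extrapolated_tail_photons(hist: DecayHistogram, baseline0: float,
                               tau2_ns: float) -> float:
    """Rough photon count of the slow component, from the tail fit."""
    counts = hist.counts.astype(float)
    peak = int(np.argmax(counts))
    start = min(peak + max(3, hist.n_bins // 16), hist.n_bins - 4)
    tail = np.maximum(counts[start:] - baseline0, 0.0)
    if tail.sum() <= 0:
        return 0.0
    # photons before `start` that belong to the slow exponential
    tau_bins = tau2_ns * PS_PER_NS / hist.bin_width
    head = tail[0] * tau_bins  # integral of the exponential up to `start`
    return float(tail.sum() + min(head, counts[:start].sum()))


def fit_monoexponential(hist: DecayHistogram, irf: IRFKernel,
                        opts: FitOptions | None = None) -> FitResult:
    """Fit a single IRF-convolved exponential plus baseline.

    Non-convergence (including a lifetime pinned at its bound, e.g. when
    handed a flat histogram) is reported through ``FitResult.converged`` and
    metadata, never silently.
    """
    return _fit(hist, irf, 1, opts or FitOptions())


def fit_biexponential(hist: DecayHistogram, irf: IRFKernel,
                      opts: FitOptions | None = None) -> FitResult:
    """Fit a two-component IRF-convolved exponential decay plus baseline.

    Components are returned in canonical order (tau1 <= tau2, amplitudes
    swapped along with the lifetimes).  If the two lifetimes collapse within
    ``opts.identifiability_rtol`` the fit falls back to mono-exponential and
    records that in ``metadata["collapsed_from_biexp"]``.
    """
    return _fit(hist, irf, 2, opts or FitOptions())
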