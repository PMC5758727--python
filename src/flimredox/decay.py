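"""Two-component TCSPC decay model, simulation and fitting.

Fluorescence decays recorded by time-correlated single photon counting
(TCSPC) under pulsed excitation are modelled as a bi-exponential,

    I(t) = a1 * exp(-t / tau1) + a2 * exp(-t / tau2) + background,

convolved with the instrument response function (IRF).  Because the laser
repeats every ``period`` ns (12.5 ns at 80 MHz), long-lived components do
not fully decay between pulses; the model sums the tails of all preceding
pulses in closed form ("incomplete decay" handling), which amounts to a
periodic decay circularly convolved with the IRF over the record.

Amplitude fractions a1% = a1/(a1+a2) and a2% = a2/(a1+a2) remove overall
intensity from the parameters; the amplitude-weighted mean lifetime is
tau_m = tau1*a1% + tau2*a2%.  Fits maximise the Poisson likelihood by
default (appropriate for low-count pixels) with Neyman-weighted least
squares as an option, and report the Pearson reduced chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import optimize

logger = logging.getLogger("flimredox")

__all__ = [
    "TimeAxis",
    "IRFModel",
    "DecayHistogram",
    "BiExpParams",
    "FitResult",
    "FitOptions",
    "InsufficientPhotonsError",
    "model_decay",
    "simulate_decay",
    "fit_biexp",
    "fit_image",
    "reduced_chi2",
    "normalized_fractions",
    "amplitude_weighted_lifetime",
    "bin_spatial",
]

Channel = Literal["trp", "nadh", "fad"]

#: lifetimes this many times the laser period make the periodic sum degenerate
MAX_TAU_PERIODS = 50.0

#: two lifetimes closer than this (ns) are flagged effectively mono-exponential
DEGENERATE_TAU_GAP = 0.05


class InsufficientPhotonsError(ValueError):
    """Raised when a histogram holds fewer photons than the configured floor."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeAxis:
    """Discretisation of one laser excitation period.

    Parameters
    ----------
    n_bins
        Number of TCSPC time bins (ADC resolution), default 256.
    period
        Laser repetition period in ns; 12.5 ns corresponds to 80 MHz.
    bin_width
        Width of one bin in ns.  Defaults to ``period / n_bins`` so the
        record tiles the period exactly.
    """

    n_bins: int = 256
    period: float = 12.5
    bin_width: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_width is None:
            object.__setattr__(self, "bin_width", self.period / self.n_bins)
        if self.n_bins <= 0 or self.bin_width <= 0 or self.period <= 0:
            raise ValueError("TimeAxis fields must be strictly positive")
        if self.n_bins * self.bin_width > self.period + self.bin_width:
            raise ValueError(
                "record length n_bins*bin_width exceeds the excitation period"
            )

    @property
    def times(self) -> np.ndarray:
        """Bin start times in ns."""
        return np.arange(self.n_bins) * self.bin_width


@dataclass(frozen=True)
class IRFModel:
    """Instrument response function, Gaussian or measured.

    A Gaussian IRF is parameterised by its ``center`` and ``fwhm`` (both
    ns); a measured IRF is a non-negative per-bin curve, normalised to
    unit sum on discretisation.
    """

    shape: Literal["gaussian", "measured"] = "gaussian"
    center: float = 1.0
    fwhm: float = 0.2
    curve: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.shape == "gaussian":
            if self.fwhm <= 0:
                raise ValueError("gaussian IRF requires fwhm > 0")
        elif self.shape == "measured":
            if self.curve is None:
                raise ValueError("measured IRF requires a curve")
            curve = np.asarray(self.curve, dtype=float)
            if np.any(curve < 0) or curve.sum() <= 0:
                raise ValueError("measured IRF curve must be non-negative with positive sum")
            object.__setattr__(self, "curve", curve)
        else:
            raise ValueError(f"unknown IRF shape {self.shape!r}")

    def discretize(self, axis: TimeAxis) -> np.ndarray:
        """Per-bin IRF amplitudes on ``axis``, normalised to sum to 1."""
        if self.shape == "measured":
            if len(self.curve) != axis.n_bins:  # type: ignore[arg-type]
                raise ValueError("measured IRF length must match axis.n_bins")
            return self.curve / self.curve.sum()  # type: ignore[union-attr]
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        t = axis.times
        curve = np.exp(-0.5 * ((t - self.center) / sigma) ** 2)
        return curve / curve.sum()


@dataclass(frozen=True)
class BiExpParams:
    """Bi-exponential decay parameters (amplitudes in counts at t=0, lifetimes in ns)."""

    a1: float
    a2: float
    tau1: float
    tau2: float
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("lifetimes must be strictly positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    def canonicalize(self) -> "BiExpParams":
        """Return the component-ordered form with tau1 <= tau2."""
        if self.tau1 <= self.tau2:
            return self
        return replace(self, a1=self.a2, a2=self.a1, tau1=self.tau2, tau2=self.tau1)


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per time bin for one pixel, ROI or channel."""

    counts: np.ndarray
    axis: TimeAxis
    channel: Channel = "nadh"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or len(counts) != self.axis.n_bins:
            raise ValueError("counts length must equal axis.n_bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bi-exponential fit, canonicalised to tau1 <= tau2."""

    params: BiExpParams
    a1_pct: float
    a2_pct: float
    tau_m: float
    chi2_reduced: float
    n_photons: float
    converged: bool
    degenerate: bool = False  # |tau2 - tau1| below the resolvability gap


@dataclass(frozen=True)
class FitOptions:
    """Knobs for :func:`fit_biexp`.

    ``background=None`` fits a constant background as a free parameter
    (the periodic model makes pre-rise bins carry previous-pulse signal,
    so they cannot simply be read off as background); pass a float to fix
    it instead.  Bounds follow the free/bound lifetime ranges typical for
    cellular autofluorescence.
    """

    objective: Literal["mle", "neyman"] = "mle"
    min_photons: float = 300.0
    # disjoint component bounds keep the short/long labels identifiable:
    # overlapping ranges let the optimizer swap components along the flat
    # likelihood ridge when one component is photon-poor
    tau1_bounds: tuple[float, float] = (0.05, 0.8)
    tau2_bounds: tuple[float, float] = (0.8, 8.0)
    background: float | None = None
    chi2_floor: float = 1.0
    max_iter: int = 400


# ---------------------------------------------------------------------------
# elementary formulas
# ---------------------------------------------------------------------------


def normalized_fractions(a1: float, a2: float) -> tuple[float, float]:
    """Intensity-normalised amplitude fractions (a1%, a2%).

    a1% = a1/(a1+a2), a2% = a2/(a1+a2); invariant under rescaling both
    amplitudes, which removes the overall fluorescence intensity.
    """
    if a1 < 0 or a2 < 0:
        raise ValueError("amplitudes must be non-negative")
    total = a1 + a2
    if total == 0:
        raise ValueError("a1 + a2 must be positive")
    return a1 / total, a2 / total


def amplitude_weighted_lifetime(fit) -> float:
    """Amplitude-weighted mean lifetime tau_m = tau1*a1% + tau2*a2% (ns)."""
    if isinstance(fit, FitResult):
        return fit.params.tau1 * fit.a1_pct + fit.params.tau2 * fit.a2_pct
    a1_pct, a2_pct = normalized_fractions(fit.a1, fit.a2)
    return fit.tau1 * a1_pct + fit.tau2 * a2_pct


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _periodic_component(tau: float, amplitude: float, axis: TimeAxis) -> np.ndarray:
    # closed-form sum over all preceding excitation periods:
    #   sum_p exp(-(t + p*T)/tau) = exp(-t/tau) / (1 - exp(-T/tau))
    factor = 1.0 / (1.0 - np.exp(-axis.period / tau))
    return amplitude * factor * np.exp(-axis.times / tau)


def _circular_convolve(signal: np.ndarray, irf_curve: np.ndarray) -> np.ndarray:
    n = len(signal)
    return np.fft.irfft(np.fft.rfft(signal) * np.fft.rfft(irf_curve), n=n)


def model_decay(params: BiExpParams, irf: IRFModel, axis: TimeAxis) -> np.ndarray:
    """Expected counts per bin for a periodic bi-exponential decay.

    Each component's tails from all preceding pulses are summed in closed
    form, the periodic decay is circularly convolved with the normalised
    IRF, and the constant background is added.
    """
    for tau in (params.tau1, params.tau2):
        if tau >= MAX_TAU_PERIODS * axis.period:
            raise ValueError(
                f"lifetime {tau} ns >= {MAX_TAU_PERIODS}x the {axis.period} ns period; "
                "periodic model is numerically degenerate"
            )
    decay = _periodic_component(params.tau1, params.a1, axis)
    decay = decay + _periodic_component(params.tau2, params.a2, axis)
    out = _circular_convolve(decay, irf.discretize(axis)) + params.background
    # FFT round-off can leave tiny negative excursions below background
    return np.maximum(out, params.background)


def simulate_decay(
    params: BiExpParams,
    irf: IRFModel,
    axis: TimeAxis,
    total_photons: float,
    seed: int | np.random.Generator,
) -> DecayHistogram:
    """Draw a Poisson TCSPC histogram with expected total ``total_photons``."""
    if total_photons <= 0:
        raise ValueError("total_photons must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean = model_decay(params, irf, axis)
    mean = mean * (total_photons / mean.sum())
    counts = rng.poisson(mean)
    return DecayHistogram(counts=counts, axis=axis)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def reduced_chi2(
    hist: DecayHistogram,
    model: np.ndarray,
    n_free_params: int,
    floor: float = 1.0,
) -> float:
    """Pearson reduced chi-square of ``model`` against the histogram.

    Bins with expected counts below ``floor`` are excluded (the Pearson
    statistic is ill-behaved for near-empty bins); the sum of squared
    residuals over expected counts is divided by the remaining degrees of
    freedom.
    """
    model = np.asarray(model, dtype=float)
    include = model >= floor
    n_included = int(include.sum())
    if n_included <= n_free_params:
        raise ValueError(
            f"only {n_included} bins above the floor with {n_free_params} free "
            "parameters; reduced chi-square undefined"
        )
    resid = hist.counts[include] - model[include]
    chi2 = float(np.sum(resid * resid / model[include]))
    return chi2 / (n_included - n_free_params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _estimate_background(counts: np.ndarray, irf: IRFModel, axis: TimeAxis) -> float:
    """Median count in the pre-rise bins (before the IRF center)."""
    if irf.shape == "gaussian":
        rise_start = irf.center - 1.5 * irf.fwhm
    else:
        rise_start = axis.times[int(np.argmax(irf.curve))] - 2 * axis.bin_width
    pre = counts[axis.times < rise_start]
    if len(pre) < 3:
        return 0.0
    return float(np.median(pre))


def _tail_lifetime(counts: np.ndarray, axis: TimeAxis, background: float) -> float:
    """Log-linear slope fit to the last 40% of bins, for initialisation."""
    n_tail = max(int(0.4 * axis.n_bins), 4)
    y = counts[-n_tail:] - background
    t = axis.times[-n_tail:]
    pos = y > 0
    if pos.sum() < 4:
        return 2.5
    slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
    if slope >= -1e-9:
        return 2.5
    return float(-1.0 / slope)


def _basis(tau1: float, tau2: float, irf_curve: np.ndarray, axis: TimeAxis) -> np.ndarray:
    b1 = _circular_convolve(_periodic_component(tau1, 1.0, axis), irf_curve)
    b2 = _circular_convolve(_periodic_component(tau2, 1.0, axis), irf_curve)
    return np.column_stack([np.maximum(b1, 0.0), np.maximum(b2, 0.0)])


def fit_biexp(
    hist: DecayHistogram,
    irf: IRFModel,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit a two-component decay to a TCSPC histogram.

    The default objective is the Poisson negative log-likelihood of
    :func:`model_decay`; ``objective="neyman"`` minimises least squares
    weighted by 1/max(counts, 1).  The result is canonicalised to
    tau1 <= tau2 and carries the Pearson reduced chi-square.

    Raises
    ------
    InsufficientPhotonsError
        If the histogram holds fewer photons than ``options.min_photons``.
    """
    counts = hist.counts
    if not np.all(np.isfinite(counts)):
        raise ValueError("histogram contains non-finite counts")
    if hist.total_photons < options.min_photons:
        raise InsufficientPhotonsError(
            f"{hist.total_photons:.0f} photons < minimum {options.min_photons:.0f}"
        )

    axis = hist.axis
    irf_curve = irf.discretize(axis)
    fit_background = options.background is None
    # pre-rise median is only an upper-bound style starting guess: those
    # bins also hold the previous pulse's tail, which the model describes
    background = (
        min(_estimate_background(counts, irf, axis), float(counts.mean()))
        if fit_background
        else options.background
    )

    # deterministic initialisation: tail slope -> tau2, tau1 = tau2/5,
    # amplitudes by non-negative least squares given the lifetimes
    lo1, hi1 = options.tau1_bounds
    lo2, hi2 = options.tau2_bounds
    tau2_init = float(np.clip(_tail_lifetime(counts, axis, background), lo2, hi2))
    tau1_init = float(np.clip(tau2_init / 5.0, lo1, hi1))
    basis = _basis(tau1_init, tau2_init, irf_curve, axis)
    amps, _ = optimize.nnls(basis, np.maximum(counts - background, 0.0))
    a_floor = 1e-6 * max(hist.total_photons, 1.0)
    a1_init, a2_init = (max(a, a_floor) for a in amps)

    # amplitudes are rescaled to O(1) so every coordinate moves on a
    # comparable scale; the objective supplies its analytic gradient
    y = counts
    a_scale = max(float(counts.max()), 1.0)
    t = axis.times
    period = axis.period
    irf_fft = np.fft.rfft(irf_curve)
    n = axis.n_bins

    def _components(x: np.ndarray):
        u1, u2, t1, t2 = x[:4]
        mu = x[4] * a_scale if fit_background else background
        convs, dconvs = [], []
        for u, tau in ((u1, t1), (u2, t2)):
            e = np.exp(-t / tau)
            ew = np.exp(-period / tau)
            factor = 1.0 / (1.0 - ew)
            g = e * factor
            # d/dtau of the periodic unit component
            dg = e * (t / tau**2 * factor + factor * factor * ew * period / tau**2)
            conv_g = np.fft.irfft(np.fft.rfft(g) * irf_fft, n=n)
            conv_dg = np.fft.irfft(np.fft.rfft(dg) * irf_fft, n=n)
            mu = mu + u * a_scale * conv_g
            convs.append(conv_g)
            dconvs.append(conv_dg)
        return np.maximum(mu, 1e-12), convs, dconvs

    def _grad(x: np.ndarray, r: np.ndarray, convs, dconvs) -> np.ndarray:
        g = [
            a_scale * np.dot(r, convs[0]),
            a_scale * np.dot(r, convs[1]),
            x[0] * a_scale * np.dot(r, dconvs[0]),
            x[1] * a_scale * np.dot(r, dconvs[1]),
        ]
        if fit_background:
            g.append(a_scale * np.sum(r))
        return np.array(g)

    if options.objective == "mle":

        def objective(x: np.ndarray):
            mu, convs, dconvs = _components(x)
            r = 1.0 - y / mu  # d NLL / d mu
            return float(np.sum(mu - y * np.log(mu))), _grad(x, r, convs, dconvs)

    elif options.objective == "neyman":
        w = 1.0 / np.maximum(y, 1.0)

        def objective(x: np.ndarray):
            mu, convs, dconvs = _components(x)
            r = 2.0 * w * (mu - y)
            return float(np.sum(w * (y - mu) ** 2)), _grad(x, r, convs, dconvs)

    else:
        raise ValueError(f"unknown objective {options.objective!r}")

    a_hi = 100.0
    x0 = [a1_init / a_scale, a2_init / a_scale, tau1_init, tau2_init]
    bounds = [(0.0, a_hi), (0.0, a_hi), (lo1, hi1), (lo2, hi2)]
    if fit_background:
        x0.append(background / a_scale)
        bounds.append((0.0, float(counts.mean()) / a_scale))
    res = optimize.minimize(
        objective,
        x0=np.array(x0),
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"maxiter": options.max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    a1, a2, tau1, tau2 = res.x[:4]
    a1 *= a_scale
    a2 *= a_scale
    if fit_background:
        background = float(res.x[4] * a_scale)
    params = BiExpParams(
        a1=float(a1), a2=float(a2), tau1=float(tau1), tau2=float(tau2), background=background
    ).canonicalize()

    at_bound = (
        tau1 <= lo1 + 1e-9
        or tau1 >= hi1 - 1e-9
        or tau2 <= lo2 + 1e-9
        or tau2 >= hi2 - 1e-9
    )
    converged = bool(res.success) and res.nit < options.max_iter and not at_bound

    degenerate = abs(params.tau2 - params.tau1) < DEGENERATE_TAU_GAP
    if degenerate and params.a1 + params.a2 > 0:
        # effectively mono-exponential: fractions follow the canonical sort
        logger.debug("fit flagged effectively mono-exponential (tau gap < %g ns)", DEGENERATE_TAU_GAP)

    a1_pct, a2_pct = normalized_fractions(params.a1, params.a2)
    tau_m = params.tau1 * a1_pct + params.tau2 * a2_pct
    model = model_decay(params, irf, axis)
    chi2 = reduced_chi2(
        hist, model, n_free_params=5 if fit_background else 4, floor=options.chi2_floor
    )
    return FitResult(
        params=params,
        a1_pct=a1_pct,
        a2_pct=a2_pct,
        tau_m=tau_m,
        chi2_reduced=chi2,
        n_photons=hist.total_photons,
        converged=converged,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# image-level helpers
# ---------------------------------------------------------------------------

#: plane order of the per-pixel parameter maps produced by fit_image
MAP_PLANES = ("a1", "a2", "a1_pct", "a2_pct", "tau1", "tau2", "tau_m", "chi2", "photons", "converged")


def bin_spatial(cube: np.ndarray, kernel: int) -> np.ndarray:
    """Sum photon cubes over a square spatial kernel (SPCImage-style binning).

    ``cube`` is (time, y, x); each pixel's histogram becomes the sum over
    the (2*kernel+1)^2 neighbourhood, boundary-clipped.
    """
    if kernel <= 0:
        return cube
    from scipy.ndimage import uniform_filter

    size = 2 * kernel + 1
    out = uniform_filter(cube.astype(float), size=(1, size, size), mode="constant")
    return out * size * size


def fit_image(
    cube: np.ndarray,
    irf: IRFModel,
    axis: TimeAxis,
    options: FitOptions = FitOptions(),
    binning: int = 0,
) -> dict[str, np.ndarray]:
    """Fit every pixel of a (time, y, x) TCSPC cube independently.

    Returns a dict of 2-D float maps keyed by :data:`MAP_PLANES`; pixels
    below the photon floor are NaN (0 in the ``converged`` plane).  Pixel
    fits are independent, so results do not depend on traversal order.
    """
    if cube.ndim != 3 or cube.shape[0] != axis.n_bins:
        raise ValueError("cube must be (time, y, x) with time == axis.n_bins")
    work = bin_spatial(cube, binning)
    _, h, w = work.shape
    maps = {name: np.full((h, w), np.nan) for name in MAP_PLANES}
    maps["converged"] = np.zeros((h, w))
    photons = work.sum(axis=0)
    maps["photons"] = photons.astype(float)
    for iy, ix in zip(*np.nonzero(photons >= options.min_photons)):
        hist = DecayHistogram(counts=work[:, iy, ix], axis=axis)
        fit = fit_biexp(hist, irf, options)
        maps["a1"][iy, ix] = fit.params.a1
        maps["a2"][iy, ix] = fit.params.a2
        maps["a1_pct"][iy, ix] = fit.a1_pct
        maps["a2_pct"][iy, ix] = fit.a2_pct
        maps["tau1"][iy, ix] = fit.params.tau1
        maps["tau2"][iy, ix] = fit.params.tau2
        maps["tau_m"][iy, ix] = fit.tau_m
        maps["chi2"][iy, ix] = fit.chi2_reduced
        maps["converged"][iy, ix] = float(fit.converged)
    return maps
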