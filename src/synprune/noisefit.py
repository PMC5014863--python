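"""Response-noise estimation by Gaussian-with-offset least squares.

The noise in a population's spike response is quantified as the offset
``o_noise`` of the model

    G(x; a, mu, sigma, o) = a * exp(-(x - mu)**2 / (2 sigma**2)) + max(0, o)

fitted to the unit-area normalized response density over x = j/n by
nonlinear least squares (scipy ``curve_fit``).  The ``max(0, .)`` clamp
is part of the model the optimizer sees, so the offset can never go
negative.  Initial guesses: amplitude 1/(sigma_input*sqrt(2*pi)) (the
peak of a unit-area Gaussian of the input width), mu = circular mean of
the density, sigma = sigma_input, offset 0.

The model is a plain (non-circular) Gaussian fitted to circular data;
responses whose decoded center lies within 2*sigma_input of the wrap
seam are circularly rolled to center 0.5 before fitting and the fitted
mean rolled back, which keeps the fit well posed near 0/1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .coding import SIGMA_INPUT, UndefinedCircularMeanError, circular_mean

__all__ = [
    "FitFailureError",
    "GaussianFit",
    "gaussian_offset",
    "normalize_response",
    "fit_gaussian_offset",
]


class FitFailureError(RuntimeError):
    """Least-squares fit failed to converge; carries the initial guesses."""

    def __init__(self, message: str, p0):
        super().__init__(message)
        self.p0 = tuple(p0)


@dataclass(frozen=True)
class GaussianFit:
    """Fitted response model; ``o_noise`` is the headline noise metric."""

    a: float
    mu: float
    sigma: float
    o_noise: float

    def model(self, x):
        return gaussian_offset(x, self.a, self.mu, self.sigma, self.o_noise)


def gaussian_offset(x, a, mu, sigma, o):
    """The fitted model: Gaussian bump plus clamped nonnegative offset."""
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + np.maximum(0.0, o)


def normalize_response(spike_counts: np.ndarray) -> np.ndarray:
    """Rescale spike counts to a unit-area density on [0, 1).

    ``density[j] = counts[j] * n / sum(counts)`` so the discrete
    integral (mean value) is one; this makes the standard initial
    amplitude guess consistent for any total spike count.
    """
    counts = np.asarray(spike_counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total spike count must be positive")
    return counts * counts.shape[0] / total


def fit_gaussian_offset(
    density: np.ndarray, sigma_input: float = SIGMA_INPUT
) -> GaussianFit:
    """Fit the Gaussian-with-offset model to a normalized response density.

    Returns the converged parameters with ``sigma`` reported positive
    and ``o_noise`` clamped at zero.  On optimizer failure a coarse grid
    of alternative starts around the initial guesses is tried before
    raising :class:`FitFailureError`.
    """
    y = np.asarray(density, dtype=np.float64)
    n = y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to identify 4 parameters")
    if np.any(y < 0):
        raise ValueError("density must be nonnegative")
    x = np.arange(n) / n

    try:
        mu0 = circular_mean(y)
    except UndefinedCircularMeanError:
        mu0 = 0.5

    # Roll responses near the wrap seam to center 0.5.
    shift = 0
    if min(mu0, 1.0 - mu0) < 2.0 * sigma_input:
        shift = int(round((0.5 - mu0) * n))
        y = np.roll(y, shift)
        mu0 = (mu0 + shift / n) % 1.0

    a0 = 1.0 / (sigma_input * np.sqrt(2.0 * np.pi))
    p0 = (a0, mu0, sigma_input, 0.0)
    popt = _try_fits(x, y, p0)
    if popt is None:
        raise FitFailureError("Gaussian-with-offset fit did not converge", p0)

    a, mu, sigma, o = popt
    mu = (mu - shift / n) % 1.0
    return GaussianFit(a=float(a), mu=float(mu), sigma=float(abs(sigma)),
                       o_noise=float(max(0.0, o)))


def _try_fits(x, y, p0):
    """Primary fit plus a coarse fallback grid of starting points."""
    starts = [p0]
    a0, mu0, s0, _ = p0
    for fa in (0.5, 2.0):
        for fs in (0.5, 2.0):
            for o_start in (0.0, float(np.median(y))):
                starts.append((a0 * fa, mu0, s0 * fs, o_start))
    for start in starts:
        try:
            with warnings.catch_warnings():
                # the clamped offset often has a flat direction at the
                # optimum; the covariance estimate is not used
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    gaussian_offset, x, y, p0=start,
                    xtol=1e-8, ftol=1e-8, gtol=1e-8, maxfev=2000,
                )
        except RuntimeError:
            continue
        if np.all(np.isfinite(popt)) and abs(popt[2]) > 1e-6:
            return popt
    return None
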