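"""Population coding of circular scalar stimuli.

Stimuli live on the circular unit interval [0, 1).  A stimulus ``x`` is
encoded by a Gaussian rate bump over the input array (circular distance,
standard deviation 1/12 by default) which drives independent Poisson
spike trains; the value represented by a population is read out as the
circular mean of its activities, i.e. the angle of the complex resultant
sum_j a_j * exp(i * 2*pi*j/n) mapped back to [0, 1).  Neuron indices are
0-based everywhere; phases use j/n * 2*pi.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "UndefinedCircularMeanError",
    "circular_distance",
    "encode_stimulus",
    "sample_poisson",
    "circular_mean",
    "circular_error",
]

#: Default circular standard deviation of the input tuning curve.
SIGMA_INPUT = 1.0 / 12.0


class UndefinedCircularMeanError(ValueError):
    """The resultant vector vanishes, so the circular mean is undefined."""


def circular_distance(u, v):
    """Shortest distance on the unit circle, in [0, 0.5]."""
    d = np.abs(np.asarray(u, dtype=np.float64) - np.asarray(v, dtype=np.float64)) % 1.0
    return np.minimum(d, 1.0 - d)


def encode_stimulus(
    x: float, n: int, sigma: float = SIGMA_INPUT, r_max: float = 40.0
) -> np.ndarray:
    """Firing-rate profile (Hz) of the input population for stimulus ``x``.

    ``rates[j] = r_max * exp(-d(j/n, x)**2 / (2 sigma**2))`` with ``d``
    the circular distance, so the profile peaks at the neuron indexing
    the stimulus value and wraps around the array ends.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = circular_distance(np.arange(n) / n, float(x) % 1.0)
    return r_max * np.exp(-(d**2) / (2.0 * sigma**2))


def sample_poisson(
    rates: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of neurons spiking in one step of ``dt`` ms.

    Per-step Bernoulli approximation of a Poisson process: neuron ``j``
    spikes with probability ``rates[j] * dt`` (rates in Hz, dt in ms).
    """
    p = np.asarray(rates, dtype=np.float64) * (dt * 1e-3)
    if np.any(p >= 1.0):
        raise ValueError("rate * dt must stay below 1 for the Bernoulli step")
    return np.flatnonzero(rng.random(p.shape[0]) < p)


def circular_mean(activities: np.ndarray) -> float:
    """Decode a circular value from nonnegative population activities.

    Returns the angle of ``sum_j a_j * exp(i 2 pi j / n)`` divided by
    2*pi, in [0, 1).  Raises :class:`UndefinedCircularMeanError` when
    the resultant vanishes (all-zero or perfectly antipodal activity).
    """
    a = np.asarray(activities, dtype=np.float64)
    n = a.shape[0]
    total = a.sum()
    z = np.sum(a * np.exp(2j * np.pi * np.arange(n) / n))
    if total <= 0.0 or np.abs(z) <= 1e-9 * total:
        raise UndefinedCircularMeanError("resultant vector is (numerically) zero")
    return float(np.angle(z) / (2.0 * np.pi) % 1.0)


def circular_error(a: float, b: float) -> float:
    """Circular distance between two stimulus values, in [0, 0.5]."""
    return float(circular_distance(a, b))
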