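"""Deterministic toy-input generators for tests and documentation.

Synthetic spike responses with a controlled Gaussian-plus-offset
mixture, small connection matrices with known structure, and scripted
weight streams that exercise the structural-plasticity rules without
running the neuron simulator.  Everything here is a pure function of its
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structural import BookkeepingState, ConnectionMatrix

__all__ = [
    "SyntheticResponse",
    "make_response",
    "make_toy_matrix",
    "scripted_weight_stream",
    "run_scripted_bookkeeping",
]


@dataclass(frozen=True)
class SyntheticResponse:
    """Mixture description of a synthetic population spike response.

    A fraction ``offset_fraction`` of the ``total_spikes`` is uniform
    contamination; the rest follows a wrapped Gaussian at (``mu``,
    ``sigma``).  Counts are drawn multinomially so the total is fixed,
    which conditions fit-accuracy tests on the overall activity level.
    """

    n: int = 1600
    mu: float = 0.5
    sigma: float = 1.0 / 12.0
    offset_fraction: float = 0.0
    total_spikes: int = 10_000
    seed: int = 0


def _wrapped_gaussian(n: int, mu: float, sigma: float) -> np.ndarray:
    x = np.arange(n) / n
    d = np.abs(x - mu) % 1.0
    d = np.minimum(d, 1.0 - d)
    g = np.exp(-(d**2) / (2.0 * sigma**2))
    return g / g.sum()


def make_response(sr: SyntheticResponse, rng: np.random.Generator | None = None) -> np.ndarray:
    """Spike-count vector drawn from the mixture density."""
    if rng is None:
        rng = np.random.default_rng(sr.seed)
    density = ((1.0 - sr.offset_fraction) * _wrapped_gaussian(sr.n, sr.mu, sr.sigma)
               + sr.offset_fraction / sr.n)
    return rng.multinomial(sr.total_spikes, density)


def make_toy_matrix(
    pattern: str,
    n_src: int = 16,
    n_tgt: int = 16,
    rng: np.random.Generator | None = None,
    k: int = 2,
    w_max: float = 0.5,
) -> ConnectionMatrix:
    """Small named connection matrices for structural-plasticity tests.

    Patterns: ``diagonal`` (column j prefers source j*n_src/n_tgt,
    already sorted), ``reversed`` (same band mirrored), ``random``
    (``k`` synapses per column at random rows) and ``two-cluster``
    (synapses in two separated row bands).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    w = np.zeros((n_src, n_tgt))
    if pattern in ("diagonal", "reversed"):
        for j in range(n_tgt):
            center = int(round(j * n_src / n_tgt))
            if pattern == "reversed":
                center = (n_src - 1) - center
            for d in range(-(k // 2), k // 2 + 1):
                w[(center + d) % n_src, j] = w_max * (1.0 - abs(d) / (k // 2 + 1))
    elif pattern == "random":
        for j in range(n_tgt):
            rows = rng.choice(n_src, size=k, replace=False)
            w[rows, j] = rng.uniform(0.05 * w_max, w_max, size=k)
    elif pattern == "two-cluster":
        lo = n_src // 8
        hi = 5 * n_src // 8
        for j in range(n_tgt):
            w[(lo + j) % n_src, j] = w_max
            w[(hi + j) % n_src, j] = w_max
    else:
        raise ValueError(f"unknown pattern: {pattern!r}")
    mask = w > 0
    return ConnectionMatrix(w, mask, w_init_max=w_max, w_max=w_max,
                            tag=f"toy:{pattern}", plasticity="P+S")


def scripted_weight_stream(script):
    """Iterator over (evaluation, (row, col), weight) events, sorted by evaluation.

    Drives bookkeeping scenarios without simulation: before evaluation
    ``k`` all events scheduled at ``k`` are applied to the matrix.
    """
    return iter(sorted(script, key=lambda e: e[0]))


def run_scripted_bookkeeping(
    cm: ConnectionMatrix,
    bk: BookkeepingState,
    script,
    n_evals: int,
    mode: str = "bookkeeping",
    rng: np.random.Generator | None = None,
):
    """Apply ``n_evals`` structural-plasticity events under a weight script.

    Yields (evaluation index, per-column counts after the event).  The
    scripted weights are written immediately before each evaluation.
    """
    from .structural import apply_structural_plasticity

    if rng is None:
        rng = np.random.default_rng(0)
    events = list(scripted_weight_stream(script))
    pos = 0
    for k in range(n_evals):
        while pos < len(events) and events[pos][0] == k:
            _, (row, col), weight = events[pos]
            if cm.mask[row, col]:
                cm.w[row, col] = weight
            pos += 1
        apply_structural_plasticity(cm, bk, mode, rng)
        yield k, cm.col_counts()
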