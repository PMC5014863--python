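"""Nearest-spike, trace-based STDP.

Every plastic connection keeps one presynaptic trace ``r`` per source
neuron and one postsynaptic trace ``o`` per target neuron.  A trace is
set to 1 on the corresponding neuron's spike and decays exponentially
(``tau_r`` = 20 ms; ``tau_o`` = 40 ms for excitatory-to-excitatory
synapses, 20 ms for inhibitory-to-excitatory ones).  On a presynaptic
spike a synapse is depressed,

    w <- w - o * nu_pre * w**eta_pre,

and on a postsynaptic spike it is potentiated,

    w <- w + r * nu_post * o * (w_max - w)**eta_post,

where the ``o`` entering the potentiation is the decayed value: ``o`` is
set to 1 only *after* all of the neuron's synapses were updated, so the
very first postsynaptic spike never potentiates.  The weight-dependent
factors act as soft bounds; explicit clipping to [0, w_max] is kept as a
safety net.  If pre- and postsynaptic neurons spike in the same step the
depression is applied first, then the potentiation, then both traces are
set to 1.

Synaptic scaling (:func:`scale_columns`) is the homeostatic complement:
a multiplicative per-column normalization of a neuron's excitatory input
weights back to their column sum at initialization, applied at every
structural-plasticity interval.  As popular synapses potentiate, scaling
pushes the rest below the weakness threshold and thereby feeds the
structural rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StdpParams",
    "TraceState",
    "EE_STDP",
    "IE_STDP",
    "decay_traces",
    "on_pre_spike",
    "on_post_spike",
    "scale_columns",
]


@dataclass(frozen=True)
class StdpParams:
    """STDP rule parameters (times in ms)."""

    nu_pre: float = 0.0005
    nu_post: float = 0.0025
    eta_pre: float = 0.2
    eta_post: float = 0.2
    w_max: float = 0.5
    tau_o: float = 40.0
    tau_r: float = 20.0

    def __post_init__(self) -> None:
        if min(self.nu_pre, self.nu_post, self.eta_pre, self.eta_post) <= 0:
            raise ValueError("learning rates and exponents must be positive")
        if self.w_max <= 0 or self.tau_o <= 0 or self.tau_r <= 0:
            raise ValueError("w_max and trace time constants must be positive")


#: Stock rule for excitatory-to-excitatory synapses.
EE_STDP = StdpParams(tau_o=40.0)

#: Stock rule for inhibitory-to-excitatory synapses (same rates, faster o).
IE_STDP = StdpParams(tau_o=20.0)


@dataclass
class TraceState:
    """Trace vectors of one plastic connection: ``r`` per source, ``o`` per target."""

    r: np.ndarray
    o: np.ndarray

    @classmethod
    def zeros(cls, n_src: int, n_tgt: int) -> "TraceState":
        return cls(np.zeros(n_src, dtype=np.float64), np.zeros(n_tgt, dtype=np.float64))

    def copy(self) -> "TraceState":
        return TraceState(self.r.copy(), self.o.copy())


def decay_traces(tr: TraceState, dt: float, params: StdpParams) -> TraceState:
    """Exponentially decay both traces by ``dt`` ms, in place."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    tr.r *= np.exp(-dt / params.tau_r)
    tr.o *= np.exp(-dt / params.tau_o)
    return tr


def on_pre_spike(w, o_post, params: StdpParams):
    """Depression applied when the presynaptic neuron fires.

    Works elementwise on arrays or scalars; the caller sets ``r = 1``
    afterwards.  Result is clipped below at zero.
    """
    w = np.asarray(w, dtype=np.float64)
    out = w - np.asarray(o_post) * params.nu_pre * np.power(w, params.eta_pre)
    return np.maximum(out, 0.0)


def on_post_spike(w, r_pre, o_post, params: StdpParams):
    """Potentiation applied when the postsynaptic neuron fires.

    ``o_post`` must be the decayed (pre-update) trace value; the caller
    sets ``o = 1`` only after all synapses of the neuron were updated.
    Result is clipped above at ``w_max``.
    """
    w = np.asarray(w, dtype=np.float64)
    headroom = np.maximum(params.w_max - w, 0.0)
    out = w + np.asarray(r_pre) * params.nu_post * np.asarray(o_post) * np.power(
        headroom, params.eta_post
    )
    return np.minimum(out, params.w_max)


def scale_columns(cm, target_sums: np.ndarray) -> None:
    """Synaptic scaling: rescale every column of ``cm`` to its target sum.

    Multiplicative normalization of the target neuron's input weights,
    in place.  Columns whose current sum is zero are left alone; after
    scaling, weights are clipped at the connection's ``w_max``.
    """
    sums = cm.w.sum(axis=0)
    factors = np.ones_like(sums)
    nonzero = sums > 0
    factors[nonzero] = target_sums[nonzero] / sums[nonzero]
    cm.w *= factors[np.newaxis, :]
    np.minimum(cm.w, cm.w_max, out=cm.w)
    cm.w[~cm.mask] = 0.0
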