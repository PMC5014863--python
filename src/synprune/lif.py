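"""Conductance-based leaky integrate-and-fire populations.

Each neuron follows

    tau_v * dV/dt = (V_rest - V) + I_e + I_i,
    I_e = -V * g_e,                 (excitatory reversal at 0 mV)
    I_i = (E_inh - V) * g_i,        (E_inh = -85 mV)

with dimensionless conductances ``g_e``/``g_i`` that jump on afferent
spikes and decay exponentially with time constants ``tau_ge`` = 5 ms and
``tau_gi`` = 10 ms.  Potentials are in mV, time in ms.  The membrane is
integrated with forward Euler at the global step (0.5 ms by default);
conductance decay uses the exact exponential factor per step since the
linear decay has a closed form and this removes one source of dt
sensitivity.

Update order within a global step is fixed: (1) decay conductances,
(2) integrate V with the decayed conductances, (3) detect ``V >=
V_thresh``, report the spikes and reset those neurons to ``V_reset``,
(4) deliver spikes to their targets (conductance increments and
plasticity hooks), so a spike influences its targets from the *next*
step on (one-step axonal delay).  There is no refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "E_INH",
    "NeuronParams",
    "PopulationState",
    "EXC_PARAMS",
    "INH_PARAMS",
    "step_population",
    "inject_spikes",
]

#: Inhibitory reversal potential (mV).
E_INH = -85.0


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of one LIF neuron group (potentials in mV, times in ms)."""

    v_rest: float
    v_reset: float
    v_thresh: float
    tau_v: float
    tau_ge: float = 5.0
    tau_gi: float = 10.0
    e_inh: float = E_INH

    def __post_init__(self) -> None:
        if self.v_reset > self.v_thresh:
            raise ValueError("v_reset must not exceed v_thresh")
        if self.v_rest > self.v_thresh:
            raise ValueError("v_rest must not exceed v_thresh")
        if self.tau_v <= 0 or self.tau_ge <= 0 or self.tau_gi <= 0:
            raise ValueError("time constants must be positive")


#: Stock excitatory neuron group.
EXC_PARAMS = NeuronParams(v_rest=-65.0, v_reset=-65.0, v_thresh=-52.0, tau_v=20.0)

#: Stock inhibitory neuron group.
INH_PARAMS = NeuronParams(v_rest=-60.0, v_reset=-45.0, v_thresh=-40.0, tau_v=10.0)


@dataclass
class PopulationState:
    """Dynamic state of one LIF population.

    ``v`` holds membrane potentials (mV); ``g_e``/``g_i`` the
    dimensionless excitatory/inhibitory conductances.  All three share
    one length.
    """

    v: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray

    @classmethod
    def at_rest(cls, n: int, params: NeuronParams) -> "PopulationState":
        """A population of ``n`` neurons at rest with zero conductances."""
        return cls(
            v=np.full(n, params.v_rest, dtype=np.float64),
            g_e=np.zeros(n, dtype=np.float64),
            g_i=np.zeros(n, dtype=np.float64),
        )

    def __len__(self) -> int:
        return self.v.shape[0]

    def copy(self) -> "PopulationState":
        return PopulationState(self.v.copy(), self.g_e.copy(), self.g_i.copy())

    def reset(self, params: NeuronParams) -> None:
        """Return to rest in place (between evaluation and training contexts)."""
        self.v[:] = params.v_rest
        self.g_e[:] = 0.0
        self.g_i[:] = 0.0


def step_population(
    state: PopulationState, params: NeuronParams, dt: float
) -> tuple[PopulationState, np.ndarray]:
    """Advance a population by one step of ``dt`` ms, in place.

    Returns ``(state, spike_indices)`` where ``spike_indices`` are the
    neurons whose potential reached threshold this step (already reset
    to ``v_reset``).  Conductances decay first (exact exponential), then
    the membrane is integrated with forward Euler using the decayed
    conductances.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = state.v.shape[0]
    if state.g_e.shape[0] != n or state.g_i.shape[0] != n:
        raise ValueError("state vectors must share one length")

    state.g_e *= np.exp(-dt / params.tau_ge)
    state.g_i *= np.exp(-dt / params.tau_gi)

    i_e = -state.v * state.g_e
    i_i = (params.e_inh - state.v) * state.g_i
    state.v += dt * ((params.v_rest - state.v) + i_e + i_i) / params.tau_v

    spikes = np.flatnonzero(state.v >= params.v_thresh)
    state.v[spikes] = params.v_reset
    return state, spikes


def inject_spikes(state, weights, source_spikes, polarity: str):
    """Deliver ``source_spikes`` through ``weights`` into a population.

    For each target ``j`` the excitatory (``polarity='excitatory'``) or
    inhibitory (``'inhibitory'``) conductance is increased by the summed
    weights of the spiking sources.  ``weights`` is a
    :class:`~synprune.structural.ConnectionMatrix` (or a plain dense
    array with zeros at absent synapses) with rows = sources, columns =
    targets.
    """
    w = getattr(weights, "w", weights)
    if w.shape[1] != len(state):
        raise ValueError("weight column count must equal target population size")
    source_spikes = np.asarray(source_spikes, dtype=np.intp)
    if source_spikes.size == 0:
        return state
    if source_spikes.max(initial=-1) >= w.shape[0]:
        raise ValueError("spike index exceeds source population size")
    increments = w[source_spikes, :].sum(axis=0)
    if polarity == "excitatory":
        state.g_e += increments
    elif polarity == "inhibitory":
        state.g_i += increments
    else:
        raise ValueError(f"unknown polarity: {polarity!r}")
    return state
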