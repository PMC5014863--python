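"""Network construction: single-population and three-way topologies.

A computation population holds 1600 excitatory and 400 inhibitory LIF
neurons (scaled together by a ``scale`` factor, exc:inh ratio 4:1) with
all four recurrent connection types.  Inhibitory-to-excitatory synapses
are plastic ("P", STDP only); synapses between excitatory neurons —
recurrent, from input populations, and long-range between populations —
additionally undergo structural plasticity ("P+S").  Excitatory-to-
inhibitory and inhibitory-to-inhibitory synapses are static.

Initialization picks 10% of the possible synapses of every connection,
with the constraint that each column (target neuron) receives exactly
the same number, and draws weights uniformly between zero and a per-type
ceiling (single-population input->exc 1.0, three-way input->exc and
long-range 0.5, input->inh 0.2, exc->exc 0.2, exc->inh 0.2, inh->exc
1.0, inh->inh 0.4).

The three-way network wires three input populations X, Y, Z to
computation populations A, B, C; a fourth population H receives no
direct input and is coupled to each of A, B, C by long-range
excitatory connections that are bidirectional on the population level
but sampled independently per direction (so not neuron-to-neuron
bidirectional).  After training on triples satisfying A + B - C = 0
(mod 1) the network can infer a missing input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coding import UndefinedCircularMeanError, circular_mean
from .lif import EXC_PARAMS, INH_PARAMS, NeuronParams, PopulationState
from .stdp import EE_STDP, IE_STDP, StdpParams, TraceState
from .structural import BookkeepingState, ConnectionMatrix, StructuralParams

__all__ = [
    "CEILINGS",
    "NetworkSpec",
    "Connection",
    "Population",
    "Network",
    "init_connection_matrix",
    "build_single_population",
    "build_three_way",
    "sort_columns_by_preference",
    "sort_network",
]

#: Per-type maximum weights at initialization.
CEILINGS = {
    "input->exc:single": 1.0,
    "input->exc:threeway": 0.5,
    "input->inh": 0.2,
    "exc->exc": 0.2,
    "exc->inh": 0.2,
    "inh->exc": 1.0,
    "inh->inh": 0.4,
    "longrange": 0.5,
}

#: Fraction of w_max below which a synapse counts as weak.
THETA_W_FRACTION = 0.1


@dataclass(frozen=True)
class NetworkSpec:
    """Sizes, density and plasticity constants of a network.

    ``scale`` shrinks all populations together for desk-scale runs
    (densities unchanged, so per-column synapse counts shrink too).
    """

    scale: float = 1.0
    n_input: int = 1600
    n_exc: int = 1600
    n_inh: int = 400
    density: float = 0.1
    r_max: float = 4.0
    sigma_input: float = 1.0 / 12.0
    peripheral_cross_links: bool = False
    synaptic_scaling: bool = True
    structural: StructuralParams = field(default_factory=StructuralParams)

    @property
    def input_size(self) -> int:
        return max(1, int(round(self.n_input * self.scale)))

    @property
    def exc_size(self) -> int:
        return max(1, int(round(self.n_exc * self.scale)))

    @property
    def inh_size(self) -> int:
        return max(1, int(round(self.n_inh * self.scale)))


@dataclass
class Population:
    """One computation population: excitatory + inhibitory groups."""

    name: str
    exc: PopulationState
    inh: PopulationState
    exc_params: NeuronParams = EXC_PARAMS
    inh_params: NeuronParams = INH_PARAMS

    def reset(self) -> None:
        self.exc.reset(self.exc_params)
        self.inh.reset(self.inh_params)


@dataclass
class Connection:
    """One connection matrix plus its plasticity state.

    ``src``/``tgt`` are (population name, kind) with kind in
    {"input", "exc", "inh"}.  Plastic connections carry a TraceState;
    "P+S" connections also carry a BookkeepingState and the column sums
    at initialization (the synaptic-scaling targets).
    """

    name: str
    src: tuple[str, str]
    tgt: tuple[str, str]
    cm: ConnectionMatrix
    stdp: StdpParams | None = None
    trace: TraceState | None = None
    bk: BookkeepingState | None = None
    init_col_sums: np.ndarray | None = None


@dataclass
class Network:
    """Populations, input populations and connections of one model."""

    spec: NetworkSpec
    populations: dict[str, Population]
    inputs: dict[str, int]  # input population name -> size
    connections: list[Connection]
    kind: str = "single"  # "single" | "threeway"

    def connection(self, name: str) -> Connection:
        for c in self.connections:
            if c.name == name:
                return c
        raise KeyError(name)

    def plastic_connections(self) -> list[Connection]:
        return [c for c in self.connections if c.cm.plasticity in ("P", "P+S")]

    def ps_connections(self) -> list[Connection]:
        return [c for c in self.connections if c.cm.plasticity == "P+S"]

    def reset_dynamic_state(self) -> None:
        for pop in self.populations.values():
            pop.reset()
        for c in self.plastic_connections():
            c.trace.r[:] = 0.0
            c.trace.o[:] = 0.0

    def copy(self) -> "Network":
        pops = {
            name: Population(p.name, p.exc.copy(), p.inh.copy(), p.exc_params, p.inh_params)
            for name, p in self.populations.items()
        }
        conns = [
            Connection(
                c.name, c.src, c.tgt, c.cm.copy(), c.stdp,
                c.trace.copy() if c.trace is not None else None,
                c.bk.copy() if c.bk is not None else None,
                c.init_col_sums.copy() if c.init_col_sums is not None else None,
            )
            for c in self.connections
        ]
        return Network(self.spec, pops, dict(self.inputs), conns, self.kind)

    def total_synapses(self) -> int:
        return int(sum(c.cm.mask.sum() for c in self.connections))


def init_connection_matrix(
    n_src: int,
    n_tgt: int,
    density: float,
    w_ceiling: float,
    rng: np.random.Generator,
    w_max: float | None = None,
    tag: str = "",
    plasticity: str = "static",
) -> ConnectionMatrix:
    """Random sparse matrix with an equal synapse count per column.

    Each column receives exactly ``round(density * n_src)`` synapses at
    uniformly random rows, with weights uniform on (0, ``w_ceiling``).
    The equal-count constraint slightly stabilizes the network.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    k = max(1, int(round(density * n_src)))
    mask = np.zeros((n_src, n_tgt), dtype=bool)
    for col in range(n_tgt):
        rows = rng.choice(n_src, size=k, replace=False)
        mask[rows, col] = True
    w = np.zeros((n_src, n_tgt), dtype=np.float64)
    w[mask] = rng.uniform(0.0, w_ceiling, size=int(mask.sum()))
    if w_max is None:
        w_max = max(w_ceiling, 0.5)
    return ConnectionMatrix(w, mask, w_init_max=w_ceiling, w_max=w_max,
                            tag=tag, plasticity=plasticity)


def _structural_for(spec: NetworkSpec, w_max: float) -> StructuralParams:
    return replace(spec.structural, theta_w=THETA_W_FRACTION * w_max, w_new=None)


def _make_connection(
    spec, rng, name, src, tgt, ceiling_key, plasticity, n_src, n_tgt
) -> Connection:
    ceiling = CEILINGS[ceiling_key]
    w_max = max(ceiling, 0.5)
    cm = init_connection_matrix(
        n_src, n_tgt, spec.density, ceiling, rng,
        w_max=w_max, tag=ceiling_key, plasticity=plasticity,
    )
    conn = Connection(name=name, src=src, tgt=tgt, cm=cm)
    if plasticity == "P":
        conn.stdp = replace(IE_STDP, w_max=w_max)
        conn.trace = TraceState.zeros(n_src, n_tgt)
    elif plasticity == "P+S":
        conn.stdp = replace(EE_STDP, w_max=w_max)
        conn.trace = TraceState.zeros(n_src, n_tgt)
        conn.bk = BookkeepingState.for_matrix(cm, _structural_for(spec, w_max))
        conn.init_col_sums = cm.w.sum(axis=0)
    return conn


def _add_recurrent(spec, rng, conns, pop: str) -> None:
    ne, ni = spec.exc_size, spec.inh_size
    conns.append(_make_connection(
        spec, rng, f"{pop}.exc->{pop}.exc", (pop, "exc"), (pop, "exc"),
        "exc->exc", "P+S", ne, ne))
    conns.append(_make_connection(
        spec, rng, f"{pop}.exc->{pop}.inh", (pop, "exc"), (pop, "inh"),
        "exc->inh", "static", ne, ni))
    conns.append(_make_connection(
        spec, rng, f"{pop}.inh->{pop}.exc", (pop, "inh"), (pop, "exc"),
        "inh->exc", "P", ni, ne))
    conns.append(_make_connection(
        spec, rng, f"{pop}.inh->{pop}.inh", (pop, "inh"), (pop, "inh"),
        "inh->inh", "static", ni, ni))


def _add_input(spec, rng, conns, inp: str, pop: str, ceiling_key: str) -> None:
    n_in, ne, ni = spec.input_size, spec.exc_size, spec.inh_size
    conns.append(_make_connection(
        spec, rng, f"{inp}->{pop}.exc", (inp, "input"), (pop, "exc"),
        ceiling_key, "P+S", n_in, ne))
    conns.append(_make_connection(
        spec, rng, f"{inp}->{pop}.inh", (inp, "input"), (pop, "inh"),
        "input->inh", "static", n_in, ni))


def build_single_population(spec: NetworkSpec, rng: np.random.Generator) -> Network:
    """Input population X feeding one computation population P."""
    pops = {"P": Population("P",
                            PopulationState.at_rest(spec.exc_size, EXC_PARAMS),
                            PopulationState.at_rest(spec.inh_size, INH_PARAMS))}
    conns: list[Connection] = []
    _add_input(spec, rng, conns, "X", "P", "input->exc:single")
    _add_recurrent(spec, rng, conns, "P")
    return Network(spec=spec, populations=pops, inputs={"X": spec.input_size},
                   connections=conns, kind="single")


def build_three_way(spec: NetworkSpec, rng: np.random.Generator) -> Network:
    """Inputs X, Y, Z feeding A, B, C; hidden population H couples them."""
    pops = {
        name: Population(name,
                         PopulationState.at_rest(spec.exc_size, EXC_PARAMS),
                         PopulationState.at_rest(spec.inh_size, INH_PARAMS))
        for name in ("A", "B", "C", "H")
    }
    conns: list[Connection] = []
    for inp, pop in (("X", "A"), ("Y", "B"), ("Z", "C")):
        _add_input(spec, rng, conns, inp, pop, "input->exc:threeway")
    for pop in ("A", "B", "C", "H"):
        _add_recurrent(spec, rng, conns, pop)
    ne = spec.exc_size
    pairs = [("A", "H"), ("H", "A"), ("B", "H"), ("H", "B"), ("C", "H"), ("H", "C")]
    if spec.peripheral_cross_links:
        for a, b in (("A", "B"), ("B", "C"), ("A", "C")):
            pairs += [(a, b), (b, a)]
    for src, tgt in pairs:
        conns.append(_make_connection(
            spec, rng, f"{src}.exc->{tgt}.exc", (src, "exc"), (tgt, "exc"),
            "longrange", "P+S", ne, ne))
    return Network(spec=spec, populations=pops,
                   inputs={"X": spec.input_size, "Y": spec.input_size, "Z": spec.input_size},
                   connections=conns, kind="threeway")


def sort_columns_by_preference(cm: ConnectionMatrix) -> np.ndarray:
    """Permutation sorting target columns by preferred input stimulus.

    A column's preference is the circular mean of its input weight
    profile over the source index; columns are ordered by that value
    ascending (stable sort).
    """
    prefs = np.empty(cm.n_tgt, dtype=np.float64)
    for col in range(cm.n_tgt):
        try:
            prefs[col] = circular_mean(cm.w[:, col])
        except UndefinedCircularMeanError:
            prefs[col] = 0.0
    # A preference of exactly 0 can evaluate to 1 - eps through the
    # angle's floating-point sign; snap to 12 decimals so the seam is cut
    # deterministically at 0.
    prefs = np.round(prefs, 12) % 1.0
    return np.argsort(prefs, kind="stable")


def sort_network(net: Network) -> dict[str, np.ndarray]:
    """Sort each computation population by preference, before training.

    The permutation of a population's excitatory neurons is derived from
    its input connection matrix (for H, which has none, from the first
    long-range matrix arriving at it) and applied consistently to all
    matrices, traces and bookkeeping states touching that population.
    Intended to be used on a freshly built network (dynamic states at
    rest).
    """
    perms: dict[str, np.ndarray] = {}
    for name in net.populations:
        ref = None
        for c in net.connections:
            if c.tgt == (name, "exc") and c.src[1] == "input":
                ref = c
                break
        if ref is None:
            for c in net.connections:
                if c.tgt == (name, "exc") and c.cm.plasticity == "P+S":
                    ref = c
                    break
        if ref is None:
            continue
        perms[name] = sort_columns_by_preference(ref.cm)
    for name, perm in perms.items():
        _apply_exc_permutation(net, name, perm)
    return perms


def _apply_exc_permutation(net: Network, pop: str, perm: np.ndarray) -> None:
    for c in net.connections:
        if c.tgt == (pop, "exc"):
            c.cm.w = np.ascontiguousarray(c.cm.w[:, perm])
            c.cm.mask = np.ascontiguousarray(c.cm.mask[:, perm])
            if c.trace is not None:
                c.trace.o = c.trace.o[perm]
            if c.bk is not None:
                c.bk.b = c.bk.b[:, perm]
                c.bk.c_float = c.bk.c_float[perm]
            if c.init_col_sums is not None:
                c.init_col_sums = c.init_col_sums[perm]
        if c.src == (pop, "exc"):
            c.cm.w = np.ascontiguousarray(c.cm.w[perm, :])
            c.cm.mask = np.ascontiguousarray(c.cm.mask[perm, :])
            if c.trace is not None:
                c.trace.r = c.trace.r[perm]
            if c.bk is not None:
                c.bk.b = c.bk.b[perm, :]
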