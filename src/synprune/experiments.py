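"""Training and evaluation harness.

Stimuli are presented for 250 ms each at a 0.5 ms step.  Structural
plasticity (and synaptic scaling) runs after every 50 examples on the
"P+S" matrices; metrics are evaluated every ``eval_interval`` examples
on held-out probe stimuli with all plasticity frozen.  Membrane,
conductance and trace states carry over between training examples but
are reset between the training and probe contexts (and restored
afterwards), so evaluation is side-effect-free.  A run is a pure
function of (configuration, seed).

The hot path is :class:`KernelNet`, which stacks the network state into
the layout of the numba kernel; :func:`simulate_example_reference` is a
slow pure-numpy path composed from the lif/stdp module operations,
kept as the behavioural reference (the two agree spike for spike;
weights agree to floating-point rounding, since different pow
implementations may differ in the last ulp).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba.typed import List as NumbaList

from . import _kernel
from .coding import (
    UndefinedCircularMeanError,
    circular_error,
    circular_mean,
    encode_stimulus,
)
from .lif import EXC_PARAMS, INH_PARAMS, inject_spikes, step_population
from .networks import Network, NetworkSpec, build_single_population, build_three_way, sort_network
from .noisefit import FitFailureError, fit_gaussian_offset, normalize_response
from .stdp import decay_traces, on_post_spike, on_pre_spike, scale_columns
from .structural import apply_structural_plasticity

__all__ = [
    "InstabilityError",
    "TrainingSchedule",
    "KernelNet",
    "simulate_example_reference",
    "run_single_population_training",
    "run_three_way_training",
    "run_inference_test",
    "CompareConfig",
    "compare_modes",
    "full_scale_spec",
    "full_scale_schedule",
]

SP_MODES = ("none", "basic", "bookkeeping", "bookkeeping_pruning", "spatial_pruning")


class InstabilityError(RuntimeError):
    """Mean population rate exceeded the configured ceiling (runaway excitation)."""


@dataclass(frozen=True)
class TrainingSchedule:
    """Stimulus schedule and plasticity cadence (times in ms)."""

    n_examples: int = 2000
    t_example: float = 250.0
    dt: float = 0.5
    sp_interval: int = 50
    sp_mode: str = "none"
    eval_interval: int = 250
    n_probes: int = 5
    probe_pairs: int = 5
    rate_ceiling: float = 200.0  # Hz, instability guard on mean exc rate
    ceiling_patience: int = 5  # consecutive over-ceiling examples = divergence

    def __post_init__(self) -> None:
        if self.sp_mode not in SP_MODES:
            raise ValueError(f"sp_mode must be one of {SP_MODES}")
        steps = self.t_example / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("t_example must be an integer number of steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_example / self.dt))


def full_scale_spec() -> NetworkSpec:
    """The published full-scale network (1600 input/exc, 400 inh per population)."""
    return NetworkSpec(scale=1.0)


def full_scale_schedule(sp_mode: str = "bookkeeping_pruning") -> TrainingSchedule:
    """The published full-scale training schedule (15,000 examples).

    Running it is a multi-hour job; the desk-scale defaults elsewhere in
    this package are the tested configuration.
    """
    return TrainingSchedule(n_examples=15_000, sp_mode=sp_mode)


_KIND = {"input": 0, "exc": 1, "inh": 2}


class KernelNet:
    """Network state re-packed for the fused numba kernel.

    Weights, masks and traces are shared by reference with the
    :class:`~synprune.networks.Network` (the kernel mutates them in
    place); membrane and conductance vectors are stacked copies, synced
    from the network at construction and written back by
    :meth:`sync_to_net`.  Build it *after* any column sorting.
    """

    def __init__(self, net: Network, dt: float = 0.5):
        self.net = net
        self.dt = dt
        self.pop_names = list(net.populations)
        self.input_names = list(net.inputs)
        self.pop_index = {n: i for i, n in enumerate(self.pop_names)}
        self.input_index = {n: i for i, n in enumerate(self.input_names)}
        n_pop = len(self.pop_names)
        self.n_exc = len(net.populations[self.pop_names[0]].exc)
        self.n_inh = len(net.populations[self.pop_names[0]].inh)
        self.n_in = net.inputs[self.input_names[0]] if self.input_names else 0

        self.v_e = np.empty((n_pop, self.n_exc))
        self.ge_e = np.empty((n_pop, self.n_exc))
        self.gi_e = np.empty((n_pop, self.n_exc))
        self.v_i = np.empty((n_pop, self.n_inh))
        self.ge_i = np.empty((n_pop, self.n_inh))
        self.gi_i = np.empty((n_pop, self.n_inh))
        self.sync_from_net()

        self.ws = NumbaList()
        self.masks = NumbaList()
        self.rs = NumbaList()
        self.os = NumbaList()
        n_conn = len(net.connections)
        self.src_kind = np.empty(n_conn, np.int32)
        self.src_pop = np.empty(n_conn, np.int32)
        self.tgt_kind = np.empty(n_conn, np.int32)
        self.tgt_pop = np.empty(n_conn, np.int32)
        self.is_plastic = np.zeros(n_conn, np.uint8)
        self.fr = np.ones(n_conn)
        self.fo = np.ones(n_conn)
        self.nu_pre = np.zeros(n_conn)
        self.nu_post = np.zeros(n_conn)
        self.eta_pre = np.ones(n_conn)
        self.eta_post = np.ones(n_conn)
        self.w_maxs = np.ones(n_conn)
        dummy = np.zeros(1)
        for i, c in enumerate(net.connections):
            self.ws.append(c.cm.w)
            self.masks.append(c.cm.mask)
            s_pop, s_kind = c.src
            t_pop, t_kind = c.tgt
            self.src_kind[i] = _KIND[s_kind]
            self.src_pop[i] = (self.input_index[s_pop] if s_kind == "input"
                               else self.pop_index[s_pop])
            self.tgt_kind[i] = _KIND[t_kind]
            self.tgt_pop[i] = self.pop_index[t_pop]
            if c.trace is not None:
                self.is_plastic[i] = 1
                self.rs.append(c.trace.r)
                self.os.append(c.trace.o)
                self.fr[i] = np.exp(-dt / c.stdp.tau_r)
                self.fo[i] = np.exp(-dt / c.stdp.tau_o)
                self.nu_pre[i] = c.stdp.nu_pre
                self.nu_post[i] = c.stdp.nu_post
                self.eta_pre[i] = c.stdp.eta_pre
                self.eta_post[i] = c.stdp.eta_post
                self.w_maxs[i] = c.stdp.w_max
            else:
                self.rs.append(dummy)
                self.os.append(dummy)
        self.counts_e = np.zeros((n_pop, self.n_exc), np.int64)

    def sync_from_net(self) -> None:
        for i, name in enumerate(self.pop_names):
            pop = self.net.populations[name]
            self.v_e[i] = pop.exc.v
            self.ge_e[i] = pop.exc.g_e
            self.gi_e[i] = pop.exc.g_i
            self.v_i[i] = pop.inh.v
            self.ge_i[i] = pop.inh.g_e
            self.gi_i[i] = pop.inh.g_i

    def sync_to_net(self) -> None:
        for i, name in enumerate(self.pop_names):
            pop = self.net.populations[name]
            pop.exc.v[:] = self.v_e[i]
            pop.exc.g_e[:] = self.ge_e[i]
            pop.exc.g_i[:] = self.gi_e[i]
            pop.inh.v[:] = self.v_i[i]
            pop.inh.g_e[:] = self.ge_i[i]
            pop.inh.g_i[:] = self.gi_i[i]

    def snapshot_dynamic(self):
        """Copies of membrane/conductance state (traces stay put when frozen)."""
        return tuple(a.copy() for a in
                     (self.v_e, self.ge_e, self.gi_e, self.v_i, self.ge_i, self.gi_i))

    def restore_dynamic(self, snap) -> None:
        for dst, src in zip((self.v_e, self.ge_e, self.gi_e,
                             self.v_i, self.ge_i, self.gi_i), snap):
            dst[:] = src

    def reset_dynamic(self) -> None:
        self.v_e[:] = EXC_PARAMS.v_rest
        self.v_i[:] = INH_PARAMS.v_rest
        for a in (self.ge_e, self.gi_e, self.ge_i, self.gi_i):
            a[:] = 0.0

    def sample_input_spikes(
        self, rates: dict[str, np.ndarray | None], n_steps: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Pre-sample Bernoulli input spike trains; ``None`` rates = silent."""
        inp = np.zeros((max(1, len(self.input_names)), n_steps, self.n_in), np.uint8)
        for name, r in rates.items():
            if r is None:
                continue
            p = np.asarray(r) * (self.dt * 1e-3)
            if np.any(p >= 1.0):
                raise ValueError("rate * dt must stay below 1")
            k = self.input_index[name]
            inp[k] = rng.random((n_steps, self.n_in)) < p
        return inp

    def run_example(
        self, inp: np.ndarray, plastic_on: bool = True
    ) -> tuple[np.ndarray, int, int]:
        """Advance by one presentation; returns (exc spike counts, total exc, total inh)."""
        self.counts_e[:] = 0
        total_e, total_i = _kernel.run_example(
            inp.shape[1], self.dt,
            self.v_e, self.ge_e, self.gi_e,
            EXC_PARAMS.v_rest, EXC_PARAMS.v_reset, EXC_PARAMS.v_thresh,
            EXC_PARAMS.tau_v,
            np.exp(-self.dt / EXC_PARAMS.tau_ge), np.exp(-self.dt / EXC_PARAMS.tau_gi),
            self.v_i, self.ge_i, self.gi_i,
            INH_PARAMS.v_rest, INH_PARAMS.v_reset, INH_PARAMS.v_thresh,
            INH_PARAMS.tau_v,
            inp,
            self.ws, self.masks,
            self.src_kind, self.src_pop, self.tgt_kind, self.tgt_pop,
            self.is_plastic, self.rs, self.os, self.fr, self.fo,
            self.nu_pre, self.nu_post, self.eta_pre, self.eta_post, self.w_maxs,
            plastic_on, self.counts_e,
        )
        return self.counts_e, int(total_e), int(total_i)


def simulate_example_reference(
    net: Network, inp: np.ndarray, dt: float = 0.5, plastic_on: bool = True
) -> np.ndarray:
    """Pure-numpy presentation, composed from the module-level operations.

    Follows the documented update order exactly (decay, integrate,
    detect, deliver) and agrees with the numba kernel spike for spike
    (state to floating-point rounding); the behavioural reference in
    tests.  Returns per-population exc
    spike counts, shape (n_populations, n_exc).
    """
    pop_names = list(net.populations)
    input_names = list(net.inputs)
    n_steps = inp.shape[1]
    n_exc = len(net.populations[pop_names[0]].exc)
    counts = np.zeros((len(pop_names), n_exc), np.int64)
    for t in range(n_steps):
        if plastic_on:
            for c in net.plastic_connections():
                decay_traces(c.trace, dt, c.stdp)
        spikes: dict[tuple[str, str], np.ndarray] = {}
        for p, name in enumerate(pop_names):
            pop = net.populations[name]
            _, spk_e = step_population(pop.exc, pop.exc_params, dt)
            _, spk_i = step_population(pop.inh, pop.inh_params, dt)
            spikes[(name, "exc")] = spk_e
            spikes[(name, "inh")] = spk_i
            counts[p, spk_e] += 1
        for k, name in enumerate(input_names):
            spikes[(name, "input")] = np.flatnonzero(inp[k, t])
        for c in net.connections:
            src_spk = spikes[c.src]
            tgt_pop = net.populations[c.tgt[0]]
            tgt_state = tgt_pop.exc if c.tgt[1] == "exc" else tgt_pop.inh
            polarity = "inhibitory" if c.src[1] == "inh" else "excitatory"
            plast = plastic_on and c.trace is not None
            for s in src_spk:
                inject_spikes(tgt_state, c.cm, [s], polarity)
                if plast:
                    row = c.cm.mask[s]
                    c.cm.w[s, row] = on_pre_spike(
                        c.cm.w[s, row], c.trace.o[row], c.stdp)
            if plast:
                for j in spikes[(c.tgt[0], "exc")]:
                    col = c.cm.mask[:, j]
                    c.cm.w[col, j] = on_post_spike(
                        c.cm.w[col, j], c.trace.r[col], c.trace.o[j], c.stdp)
        if plastic_on:
            for c in net.plastic_connections():
                c.trace.r[spikes[c.src]] = 1.0
                c.trace.o[spikes[(c.tgt[0], "exc")]] = 1.0
    return counts


def _structural_event(net: Network, sched: TrainingSchedule,
                      rng: np.random.Generator) -> None:
    """Synaptic scaling plus (unless sp_mode='none') structural plasticity."""
    for c in net.ps_connections():
        if net.spec.synaptic_scaling:
            scale_columns(c.cm, c.init_col_sums)
        if sched.sp_mode != "none":
            apply_structural_plasticity(c.cm, c.bk, sched.sp_mode, rng)


def _fit_probe(counts: np.ndarray, sigma_input: float):
    """(o_noise, decoded value) of one probe response, NaNs on failure."""
    if counts.sum() <= 0:
        return np.nan, np.nan
    try:
        decoded = circular_mean(counts)
    except UndefinedCircularMeanError:
        decoded = np.nan
    try:
        fit = fit_gaussian_offset(normalize_response(counts), sigma_input)
        return fit.o_noise, decoded
    except FitFailureError:
        return np.nan, decoded


def _as_trajectory(rows: list[dict], net: Network, metric_cols: list[str]) -> pd.DataFrame:
    """Rows to a DataFrame with stable columns even when no evaluation ran."""
    if rows:
        return pd.DataFrame(rows)
    cols = ["examples_seen", *metric_cols, *_count_columns(net)]
    return pd.DataFrame(columns=cols)


def _count_columns(net: Network) -> dict[str, int]:
    cols = {f"count[{c.name}]": int(c.cm.mask.sum()) for c in net.ps_connections()}
    cols["synapse_count_total"] = net.total_synapses()
    return cols


def run_single_population_training(
    net: Network, sched: TrainingSchedule, rng: np.random.Generator
) -> pd.DataFrame:
    """Train the single-population network on uniform random stimuli.

    Returns one row per evaluation with the seed-relevant metrics:
    examples_seen, mean probe o_noise, mean probe decoding error, fit
    failure count and synapse counts.
    """
    if net.kind != "single":
        raise ValueError("expected a single-population network")
    spec = net.spec
    kn = KernelNet(net, sched.dt)
    rows = []
    hot = 0
    for ex in range(sched.n_examples):
        x = rng.random()
        rates = {"X": encode_stimulus(x, spec.input_size, spec.sigma_input, spec.r_max)}
        inp = kn.sample_input_spikes(rates, sched.n_steps, rng)
        _, total_e, _ = kn.run_example(inp, plastic_on=True)
        hot = _check_rate(total_e, kn.n_exc, sched, hot)
        if (ex + 1) % sched.sp_interval == 0:
            _structural_event(net, sched, rng)
        if (ex + 1) % sched.eval_interval == 0:
            rows.append(_evaluate_single(kn, net, sched, rng, ex + 1))
    kn.sync_to_net()
    return _as_trajectory(rows, net, ["o_noise", "circular_error", "fit_failures"])


def _check_rate(total_e: int, n_exc: int, sched: TrainingSchedule, hot: int) -> int:
    """Sustained-runaway guard.

    Single over-ceiling examples occur transiently and are quenched by
    inhibitory plasticity; divergence (the saturated attractor) keeps the
    rate above the ceiling on every example.  Raises after
    ``ceiling_patience`` consecutive over-ceiling examples, returns the
    updated consecutive count otherwise.
    """
    mean_rate = total_e / (n_exc * sched.t_example * 1e-3)
    if mean_rate <= sched.rate_ceiling:
        return 0
    hot += 1
    if hot >= sched.ceiling_patience:
        raise InstabilityError(
            f"mean excitatory rate above the {sched.rate_ceiling:.0f} Hz "
            f"ceiling for {hot} consecutive examples (last: {mean_rate:.1f} Hz)")
    return hot


def _evaluate_single(kn, net, sched, rng, examples_seen) -> dict:
    spec = net.spec
    snap = kn.snapshot_dynamic()
    kn.reset_dynamic()
    noises, errors, failures = [], [], 0
    for i in range(sched.n_probes):
        x = i / sched.n_probes
        rates = {"X": encode_stimulus(x, spec.input_size, spec.sigma_input, spec.r_max)}
        inp = kn.sample_input_spikes(rates, sched.n_steps, rng)
        counts, _, _ = kn.run_example(inp, plastic_on=False)
        o_noise, decoded = _fit_probe(counts[kn.pop_index["P"]], spec.sigma_input)
        if np.isnan(o_noise):
            failures += 1
        else:
            noises.append(o_noise)
        if not np.isnan(decoded):
            errors.append(circular_error(decoded, x))
        kn.reset_dynamic()
    kn.restore_dynamic(snap)
    row = {
        "examples_seen": examples_seen,
        "o_noise": float(np.mean(noises)) if noises else np.nan,
        "circular_error": float(np.mean(errors)) if errors else np.nan,
        "fit_failures": failures,
    }
    row.update(_count_columns(net))
    return row


def run_three_way_training(
    net: Network, sched: TrainingSchedule, rng: np.random.Generator
) -> pd.DataFrame:
    """Train the three-way network on triples with A + B - C = 0 (mod 1).

    Evaluations run the inference test (X and Y driven, Z silent) on
    ``probe_pairs`` random pairs with plasticity frozen.
    """
    if net.kind != "threeway":
        raise ValueError("expected a three-way network")
    spec = net.spec
    kn = KernelNet(net, sched.dt)
    rows = []
    hot = 0
    for ex in range(sched.n_examples):
        a, b = rng.random(), rng.random()
        c = (a + b) % 1.0
        rates = {
            "X": encode_stimulus(a, spec.input_size, spec.sigma_input, spec.r_max),
            "Y": encode_stimulus(b, spec.input_size, spec.sigma_input, spec.r_max),
            "Z": encode_stimulus(c, spec.input_size, spec.sigma_input, spec.r_max),
        }
        inp = kn.sample_input_spikes(rates, sched.n_steps, rng)
        _, total_e, _ = kn.run_example(inp, plastic_on=True)
        hot = _check_rate(total_e, kn.n_exc * len(kn.pop_names), sched, hot)
        if (ex + 1) % sched.sp_interval == 0:
            _structural_event(net, sched, rng)
        if (ex + 1) % sched.eval_interval == 0:
            pairs = [(rng.random(), rng.random()) for _ in range(sched.probe_pairs)]
            err, noise = run_inference_test(net, pairs, rng, kn=kn, sched=sched)
            row = {"examples_seen": ex + 1, "circular_error": err, "o_noise": noise}
            row.update(_count_columns(net))
            rows.append(row)
    kn.sync_to_net()
    return _as_trajectory(rows, net, ["circular_error", "o_noise"])


def run_inference_test(
    net: Network,
    pairs,
    rng: np.random.Generator,
    kn: KernelNet | None = None,
    sched: TrainingSchedule | None = None,
    r_probe: float = 40.0,
) -> tuple[float, float]:
    """Infer C from A and B with plasticity frozen.

    Drives inputs X and Y with the pair values, leaves Z silent, decodes
    population C by the circular mean of its spike counts and compares
    against (A + B) mod 1.  Returns the mean circular error and the mean
    fitted o_noise of C's responses over the pairs (NaN-tolerant).

    ``r_probe`` is the peak drive of the test stimuli.  Unlike the noise
    probes of the single-population experiment (which measure the
    response to the code the network was trained on, hence use the
    training rate), inference requires activity to propagate through two
    synaptic stages (input to A/B, then via H to C); the default 40 Hz
    delivers enough spikes per 250 ms window for a stable readout of C
    at reduced scales.
    """
    if sched is None:
        sched = TrainingSchedule(n_examples=0)
    if kn is None:
        kn = KernelNet(net, sched.dt)
    spec = net.spec
    snap = kn.snapshot_dynamic()
    kn.reset_dynamic()
    errors, noises = [], []
    c_idx = kn.pop_index["C"]
    for a, b in pairs:
        rates = {
            "X": encode_stimulus(a, spec.input_size, spec.sigma_input, r_probe),
            "Y": encode_stimulus(b, spec.input_size, spec.sigma_input, r_probe),
            "Z": None,
        }
        inp = kn.sample_input_spikes(rates, sched.n_steps, rng)
        counts, _, _ = kn.run_example(inp, plastic_on=False)
        o_noise, decoded = _fit_probe(counts[c_idx], spec.sigma_input)
        if not np.isnan(decoded):
            errors.append(circular_error(decoded, (a + b) % 1.0))
        if not np.isnan(o_noise):
            noises.append(o_noise)
        kn.reset_dynamic()
    kn.restore_dynamic(snap)
    mean_err = float(np.mean(errors)) if errors else np.nan
    mean_noise = float(np.mean(noises)) if noises else np.nan
    return mean_err, mean_noise


@dataclass(frozen=True)
class CompareConfig:
    """Matched-seed comparison of structural-plasticity modes."""

    network: str = "single"  # "single" | "threeway"
    scale: float = 0.125
    n_examples: int = 2000
    modes: tuple[str, ...] = ("none", "bookkeeping", "bookkeeping_pruning", "spatial_pruning")
    seeds: tuple[int, ...] = (0, 1, 2)
    eval_interval: int = 250
    sort_before_training: bool = True
    lam: float | None = None  # None: floor reached after 2/3 of training


def _schedule_for(config: CompareConfig, mode: str) -> TrainingSchedule:
    return TrainingSchedule(n_examples=config.n_examples, sp_mode=mode,
                            eval_interval=config.eval_interval)


def _spec_for(config: CompareConfig) -> NetworkSpec:
    spec = NetworkSpec(scale=config.scale)
    lam = config.lam
    if lam is None:
        # Reach the 50% floor after two thirds of the training examples.
        n_events = max(1.0, (2.0 / 3.0) * config.n_examples
                       / TrainingSchedule().sp_interval)
        lam = 0.5 ** (1.0 / n_events)
    return replace(spec, structural=replace(spec.structural, lam=lam))


def compare_modes(config: CompareConfig) -> dict[str, pd.DataFrame]:
    """Run every (mode, seed) with matched initial matrices.

    For each seed the network is built once and deep-copied per mode, so
    initial matrices are bit-identical across modes; the training rng is
    re-seeded identically per mode as well.  Returns long-format
    per-run trajectories and seed-averaged curves.
    """
    spec = _spec_for(config)
    frames = []
    for seed in config.seeds:
        build_rng = np.random.default_rng([int(seed), 0])
        if config.network == "single":
            base = build_single_population(spec, build_rng)
        else:
            base = build_three_way(spec, build_rng)
        if config.sort_before_training:
            sort_network(base)
        for mode in config.modes:
            net = base.copy()
            sched = _schedule_for(config, mode)
            train_rng = np.random.default_rng([int(seed), 1])
            if config.network == "single":
                traj = run_single_population_training(net, sched, train_rng)
            else:
                traj = run_three_way_training(net, sched, train_rng)
            traj["mode"] = mode
            traj["seed"] = seed
            frames.append(traj)
    trajectories = pd.concat(frames, ignore_index=True)
    averages = (trajectories
                .groupby(["mode", "examples_seen"], as_index=False)
                [["o_noise", "circular_error", "synapse_count_total"]]
                .mean())
    return {"trajectories": trajectories, "averages": averages}
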