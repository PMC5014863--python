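"""Training harness: kernel/reference agreement, determinism, frozen probes."""

import numpy as np
import pandas as pd

from synprune.coding import encode_stimulus
from synprune.experiments import (
    CompareConfig,
    KernelNet,
    TrainingSchedule,
    compare_modes,
    full_scale_schedule,
    full_scale_spec,
    run_inference_test,
    run_single_population_training,
    run_three_way_training,
    simulate_example_reference,
)
from synprune.networks import (
    NetworkSpec,
    build_single_population,
    build_three_way,
    sort_network,
)
from synprune.snapshot import load_snapshot_arrays, save_snapshot

HOT = 60.0  # drive strong enough to recruit inhibitory spikes in a tiny net


def test_kernel_agrees_with_module_reference(tiny_spec):
    """The fused kernel and the numpy path composed from lif/stdp ops
    produce identical spike trains and state equal to floating-point
    rounding (the two use different libm pow implementations, which may
    differ in the last ulp)."""
    net_a = build_single_population(tiny_spec, np.random.default_rng(7))
    net_b = net_a.copy()
    kn = KernelNet(net_a)
    rates = {"X": encode_stimulus(0.3, tiny_spec.input_size,
                                  tiny_spec.sigma_input, HOT)}
    inp = kn.sample_input_spikes(rates, 300, np.random.default_rng(11))
    counts_k, total_e, total_i = kn.run_example(inp, plastic_on=True)
    kn.sync_to_net()
    assert total_e > 0 and total_i > 0  # both delivery paths exercised

    counts_r = simulate_example_reference(net_b, inp, 0.5, plastic_on=True)
    np.testing.assert_array_equal(counts_k, counts_r)
    tight = dict(rtol=1e-13, atol=1e-15)
    for ca, cb in zip(net_a.connections, net_b.connections):
        np.testing.assert_allclose(ca.cm.w, cb.cm.w, **tight)
        if ca.trace is not None:
            np.testing.assert_array_equal(ca.trace.r, cb.trace.r)
            np.testing.assert_array_equal(ca.trace.o, cb.trace.o)
    pa, pb = net_a.populations["P"], net_b.populations["P"]
    np.testing.assert_allclose(pa.exc.v, pb.exc.v, **tight)
    np.testing.assert_allclose(pa.exc.g_e, pb.exc.g_e, **tight)
    np.testing.assert_allclose(pa.inh.g_i, pb.inh.g_i, **tight)


def test_zero_examples_give_empty_trajectory(tiny_net):
    sched = TrainingSchedule(n_examples=0)
    traj = run_single_population_training(
        tiny_net, sched, np.random.default_rng(0))
    assert len(traj) == 0


def test_without_structural_plasticity_counts_stay_constant(tiny_spec):
    net = build_single_population(tiny_spec, np.random.default_rng(1))
    total0 = net.total_synapses()
    sched = TrainingSchedule(n_examples=100, sp_mode="none", eval_interval=50)
    traj = run_single_population_training(net, sched, np.random.default_rng(2))
    assert (traj["synapse_count_total"] == total0).all()
    assert list(traj["examples_seen"]) == [50, 100]


def test_training_is_deterministic_in_config_and_seed(tiny_spec):
    def run():
        net = build_single_population(tiny_spec, np.random.default_rng(5))
        sort_network(net)
        sched = TrainingSchedule(n_examples=60, sp_mode="bookkeeping",
                                 eval_interval=30)
        return run_single_population_training(
            net, sched, np.random.default_rng(6)), net

    t1, n1 = run()
    t2, n2 = run()
    pd.testing.assert_frame_equal(t1, t2)
    for c1, c2 in zip(n1.connections, n2.connections):
        np.testing.assert_array_equal(c1.cm.w, c2.cm.w)


def test_frozen_probe_leaves_training_state_untouched(tiny_spec):
    from synprune.experiments import _evaluate_single

    net = build_single_population(tiny_spec, np.random.default_rng(8))
    kn = KernelNet(net)
    rates = {"X": encode_stimulus(0.7, tiny_spec.input_size,
                                  tiny_spec.sigma_input, HOT)}
    inp = kn.sample_input_spikes(rates, 200, np.random.default_rng(9))
    kn.run_example(inp, plastic_on=True)

    weights = [c.cm.w.copy() for c in net.connections]
    traces = [(c.trace.r.copy(), c.trace.o.copy())
              for c in net.plastic_connections()]
    dyn = kn.snapshot_dynamic()
    sched = TrainingSchedule(n_examples=0, n_probes=3)
    _evaluate_single(kn, net, sched, np.random.default_rng(10), 0)
    for c, w in zip(net.connections, weights):
        np.testing.assert_array_equal(c.cm.w, w)
    for c, (r, o) in zip(net.plastic_connections(), traces):
        np.testing.assert_array_equal(c.trace.r, r)
        np.testing.assert_array_equal(c.trace.o, o)
    for a, b in zip(kn.snapshot_dynamic(), dyn):
        np.testing.assert_array_equal(a, b)


def test_three_way_training_smoke_and_schedule_bookkeeping():
    spec = NetworkSpec(scale=0.05)
    net = build_three_way(spec, np.random.default_rng(3))
    sort_network(net)
    sched = TrainingSchedule(n_examples=60, sp_mode="bookkeeping_pruning",
                             eval_interval=30, probe_pairs=2)
    traj = run_three_way_training(net, sched, np.random.default_rng(4))
    assert list(traj["examples_seen"]) == [30, 60]
    assert traj["examples_seen"].is_monotonic_increasing
    assert {"o_noise", "circular_error", "synapse_count_total"} <= set(traj.columns)
    # one pruning application happened after example 50
    assert traj["synapse_count_total"].iloc[-1] <= traj["synapse_count_total"].iloc[0]


def test_inference_error_is_bounded_and_deterministic():
    spec = NetworkSpec(scale=0.05)
    net = build_three_way(spec, np.random.default_rng(13))
    pairs = [(0.1, 0.2), (0.6, 0.7), (0.25, 0.5)]
    e1, n1 = run_inference_test(net, pairs, np.random.default_rng(14))
    e2, n2 = run_inference_test(net, pairs, np.random.default_rng(14))
    assert e1 == e2 and (n1 == n2 or (np.isnan(n1) and np.isnan(n2)))
    assert np.isnan(e1) or 0.0 <= e1 <= 0.5


def test_compare_modes_matched_seeds_and_count_columns():
    config = CompareConfig(network="single", scale=0.05, n_examples=100,
                           modes=("none", "bookkeeping_pruning"), seeds=(0,),
                           eval_interval=50)
    report = compare_modes(config)
    traj = report["trajectories"]
    assert set(traj["mode"]) == {"none", "bookkeeping_pruning"}
    none_counts = traj[traj["mode"] == "none"]["synapse_count_total"]
    prune_counts = traj[traj["mode"] == "bookkeeping_pruning"]["synapse_count_total"]
    assert none_counts.nunique() == 1
    assert prune_counts.is_monotonic_decreasing
    assert {"o_noise", "circular_error"} <= set(report["averages"].columns)


def test_matched_seed_builds_are_bit_identical():
    spec = NetworkSpec(scale=0.05)
    a = build_single_population(spec, np.random.default_rng([3, 0]))
    b = build_single_population(spec, np.random.default_rng([3, 0]))
    for ca, cb in zip(a.connections, b.connections):
        np.testing.assert_array_equal(ca.cm.w, cb.cm.w)


def test_full_scale_configuration_matches_published_setup():
    spec = full_scale_spec()
    assert (spec.input_size, spec.exc_size, spec.inh_size) == (1600, 1600, 400)
    assert spec.density == 0.1
    sched = full_scale_schedule()
    assert sched.n_examples == 15_000
    assert sched.t_example == 250.0 and sched.dt == 0.5
    assert sched.sp_interval == 50


def test_snapshot_round_trip(tmp_path, tiny_net):
    path = tmp_path / "snap.npz"
    save_snapshot(tiny_net, path)
    arrays = load_snapshot_arrays(path)
    cm = tiny_net.connection("X->P.exc").cm
    rows, cols, vals = cm.to_triplets()
    np.testing.assert_array_equal(arrays["conn/X->P.exc/rows"], rows)
    np.testing.assert_array_equal(arrays["conn/X->P.exc/weights"], vals)
    np.testing.assert_array_equal(arrays["pop/P/exc/v"],
                                  tiny_net.populations["P"].exc.v)
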