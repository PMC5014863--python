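"""Structural plasticity: deletion, bookkeeping, pruning schedule, placement."""

import numpy as np
import pytest

from synprune.fixtures import make_toy_matrix
from synprune.structural import (
    BookkeepingState,
    ColumnFullError,
    ConnectionMatrix,
    PlacementDistribution,
    StructuralParams,
    apply_structural_plasticity,
    bookkeeping_update,
    create_synapses,
    prune_basic,
    pruning_schedule_step,
    spatial_probability,
    wrapped_gaussian_profile,
)


def _toy(values, w_max=0.5):
    w = np.asarray(values, dtype=float)
    return ConnectionMatrix(w.copy(), w > 0, w_init_max=w_max, w_max=w_max)


class TestPruneBasic:
    def test_zero_threshold_deletes_nothing(self, rng):
        cm = make_toy_matrix("random", 16, 16, rng, k=3)
        before = cm.mask.sum()
        _, deleted = prune_basic(cm, 0.0, rng)
        assert deleted.sum() == 0 and cm.mask.sum() == before

    def test_threshold_above_max_deletes_all(self, rng):
        cm = make_toy_matrix("random", 16, 16, rng, k=3)
        _, deleted = prune_basic(cm, 1e9, rng)
        assert cm.mask.sum() == 0
        assert deleted.sum() == 48

    def test_exactly_weak_entries_removed(self):
        w = np.zeros((4, 4))
        w[0, 0], w[1, 0], w[2, 1], w[3, 2], w[0, 3] = 0.05, 0.2, 0.4, 0.05, 0.2
        cm = _toy(w)
        _, deleted = prune_basic(cm, 0.1)
        assert not cm.mask[0, 0] and not cm.mask[3, 2]
        assert cm.mask[1, 0] and cm.mask[2, 1] and cm.mask[0, 3]
        np.testing.assert_array_equal(deleted, [1, 0, 1, 0])


class TestBookkeeping:
    def _setup(self, w, **kw):
        cm = _toy(w)
        params = StructuralParams(theta_w=0.1, **kw)
        bk = BookkeepingState.for_matrix(cm, params)
        return cm, bk

    def test_healthy_synapse_never_counted_or_deleted(self):
        cm, bk = self._setup([[0.4]])
        for _ in range(50):
            _, deleted = bookkeeping_update(cm, bk)
            assert deleted.sum() == 0
            assert bk.b[0, 0] <= 0
        assert cm.mask[0, 0]

    def test_persistently_weak_synapse_deleted_after_theta_c_plus_one(self):
        cm, bk = self._setup([[0.01]], theta_c=3)
        for k in range(1, 4):  # evaluations 1..theta_c: counted, still present
            bookkeeping_update(cm, bk)
            assert cm.mask[0, 0] and bk.b[0, 0] == k
        _, deleted = bookkeeping_update(cm, bk)  # evaluation theta_c + 1
        assert deleted[0] == 1 and not cm.mask[0, 0]

    def test_grace_period_consumed_without_deletion(self):
        cm, bk = self._setup([[0.01]], theta_c=3, grace=2)
        bk.b[0, 0] = -2
        for _ in range(2):
            bookkeeping_update(cm, bk)
        assert bk.b[0, 0] == 0 and cm.mask[0, 0]

    def test_recovered_synapse_counter_walks_back_to_zero(self):
        cm, bk = self._setup([[0.01]], theta_c=5)
        bookkeeping_update(cm, bk)
        bookkeeping_update(cm, bk)
        assert bk.b[0, 0] == 2
        cm.w[0, 0] = 0.4  # recovery
        bookkeeping_update(cm, bk)
        bookkeeping_update(cm, bk)
        assert bk.b[0, 0] == 0 and cm.mask[0, 0]
        bookkeeping_update(cm, bk)
        assert bk.b[0, 0] == 0

    def test_counter_bounds_invariant(self, rng):
        cm = make_toy_matrix("random", 20, 8, rng, k=5)
        params = StructuralParams(theta_w=0.25, theta_c=3, grace=2)
        bk = BookkeepingState.for_matrix(cm, params)
        for _ in range(60):
            rows, cols = np.nonzero(cm.mask)
            cm.w[rows, cols] = rng.uniform(0, 0.5, rows.size)
            apply_structural_plasticity(cm, bk, "bookkeeping", rng)
            live = bk.b[cm.mask]
            assert live.max(initial=0) <= params.theta_c
            assert live.min(initial=0) >= -params.grace


class TestPruningSchedule:
    def _bk(self, c0, lam, floor_frac=0.5):
        w = np.full((c0, 4), 0.4)
        cm = ConnectionMatrix(w.copy(), w > 0, 0.5, 0.5)
        params = StructuralParams(theta_w=0.1, lam=lam, floor_frac=floor_frac)
        return BookkeepingState.for_matrix(cm, params)

    def test_lambda_one_leaves_target_unchanged(self):
        bk = self._bk(100, 1.0)
        pruning_schedule_step(bk)
        np.testing.assert_array_equal(bk.c_target, 100)

    def test_reaches_floor_after_69_steps_at_099(self):
        """round(160 * 0.99**k) first hits the 50% floor (80) at k = 69."""
        bk = self._bk(160, 0.99)
        for k in range(1, 70):
            pruning_schedule_step(bk)
            expected = max(round(160 * 0.99**k), 80)
            np.testing.assert_array_equal(bk.c_target, expected)
        assert bk.c_target[0] == 80

    def test_floor_is_absorbing(self):
        bk = self._bk(20, 0.5)
        for _ in range(30):
            pruning_schedule_step(bk)
        np.testing.assert_array_equal(bk.c_target, 10)


class TestSpatialProbability:
    def test_empty_matrix_gives_uniform_columns(self):
        w = np.zeros((12, 6))
        cm = ConnectionMatrix(w, w > 0, 0.5, 0.5)
        dist = spatial_probability(cm, 3.0, 2.0)
        np.testing.assert_allclose(dist.p, 1.0 / 12.0, rtol=1e-12)
        assert not dist.full_columns.any()

    def test_single_synapse_neighborhood_peak_and_symmetry(self):
        w = np.zeros((16, 16))
        w[8, 5] = 0.5
        cm = ConnectionMatrix(w, w > 0, 0.5, 0.5)
        dist = spatial_probability(cm, 3.0, 2.0)
        col = dist.p[:, 5]
        assert col[8] == 0.0  # occupied
        assert np.argmax(col) in (7, 9)
        np.testing.assert_allclose(col[9:], col[7::-1][: col[9:].size], rtol=1e-10)

    def test_nearby_synapses_interact_multiplicatively(self):
        """exp of summed contributions exceeds the sum of isolated effects."""
        sigma = (3.0, 2.0)
        w_pair = np.zeros((16, 16))
        w_pair[6, 4] = w_pair[10, 4] = 0.5
        pair = ConnectionMatrix(w_pair, w_pair > 0, 0.5, 0.5)
        a_only = np.zeros((16, 16))
        a_only[6, 4] = 0.5
        b_only = np.zeros((16, 16))
        b_only[10, 4] = 0.5
        conv = lambda m: _direct_wrapped_conv(m, *sigma)
        mid = 8
        joint = np.exp(conv(w_pair))[mid, 4]
        isolated = np.exp(conv(a_only))[mid, 4] + np.exp(conv(b_only))[mid, 4] - 1.0
        assert joint > isolated

    def test_matches_direct_convolution_oracle(self, rng):
        cm = make_toy_matrix("two-cluster", 16, 16, rng)
        dist = spatial_probability(cm, 3.0, 2.0)
        expected = np.exp(_direct_wrapped_conv(cm.w, 3.0, 2.0))
        expected[cm.mask] = 0.0
        expected /= expected.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(dist.p, expected, atol=1e-10)


def _direct_wrapped_conv(w, sigma_src, sigma_tgt):
    """O(n^4) torus convolution with a unit-peak Gaussian, for oracles."""
    n_src, n_tgt = w.shape
    g_src = wrapped_gaussian_profile(n_src, sigma_src)
    g_tgt = wrapped_gaussian_profile(n_tgt, sigma_tgt)
    out = np.zeros_like(w)
    for i in range(n_src):
        for j in range(n_tgt):
            acc = 0.0
            for u in range(n_src):
                for v in range(n_tgt):
                    acc += w[u, v] * g_src[(i - u) % n_src] * g_tgt[(j - v) % n_tgt]
            out[i, j] = acc
    return out


class TestCreateSynapses:
    def test_zero_count_is_identity(self, rng):
        cm = make_toy_matrix("random", 16, 8, rng, k=3)
        before = cm.mask.copy()
        create_synapses(cm, 2, 0, rng=rng)
        np.testing.assert_array_equal(cm.mask, before)

    def test_single_free_slot_is_chosen(self, rng):
        w = np.full((4, 2), 0.3)
        w[2, 0] = 0.0
        cm = ConnectionMatrix(w, w > 0, 0.5, 0.5)
        create_synapses(cm, 0, 1, w_new=0.05, rng=rng)
        assert cm.mask[2, 0] and cm.w[2, 0] == 0.05

    def test_full_column_raises(self, rng):
        w = np.full((4, 2), 0.3)
        cm = ConnectionMatrix(w, w > 0, 0.5, 0.5)
        with pytest.raises(ColumnFullError):
            create_synapses(cm, 0, 1, rng=rng)

    def test_spatial_sampling_follows_distribution(self, rng):
        """A 90%-weight slot is picked with empirical frequency 0.9 +- 0.01."""
        n = 10_000
        hits = 0
        p = np.zeros((11, 1))
        p[0, 0] = 0.9
        p[1:10, 0] = 0.1 / 9.0
        dist = PlacementDistribution(p=p, full_columns=np.array([False]))
        for _ in range(n):
            w = np.zeros((11, 1))
            w[10, 0] = 0.3  # occupied elsewhere
            cm = ConnectionMatrix(w, w > 0, 0.5, 0.5)
            create_synapses(cm, 0, 1, placement="spatial", dist=dist,
                            w_new=0.05, rng=rng)
            hits += bool(cm.mask[0, 0])
        assert hits / n == pytest.approx(0.9, abs=0.01)

    def test_counters_start_at_minus_grace(self, rng):
        cm = make_toy_matrix("random", 16, 8, rng, k=3)
        params = StructuralParams(theta_w=0.05, grace=2)
        bk = BookkeepingState.for_matrix(cm, params)
        col = 0
        free_before = ~cm.mask[:, col]
        create_synapses(cm, col, 2, w_new=0.05, rng=rng, bk=bk)
        new = cm.mask[:, col] & free_before
        assert new.sum() == 2
        assert (bk.b[new, col] == -2).all()


class TestApply:
    def test_basic_mode_identity_when_nothing_weak(self, rng):
        cm = make_toy_matrix("random", 20, 8, rng, k=5)
        cm.w[cm.mask] = 0.4
        bk = BookkeepingState.for_matrix(cm, StructuralParams(theta_w=0.1))
        w_before = cm.w.copy()
        apply_structural_plasticity(cm, bk, "basic", rng)
        np.testing.assert_array_equal(cm.w, w_before)

    def test_unknown_mode_rejected(self, rng):
        cm = make_toy_matrix("random", 8, 4, rng, k=2)
        bk = BookkeepingState.for_matrix(cm, StructuralParams())
        with pytest.raises(ValueError):
            apply_structural_plasticity(cm, bk, "annealing", rng)

    @pytest.mark.parametrize("mode", ["basic", "bookkeeping"])
    def test_counts_conserved_without_pruning(self, mode, rng):
        cm = make_toy_matrix("random", 30, 10, rng, k=8)
        bk = BookkeepingState.for_matrix(cm, StructuralParams(theta_w=0.25))
        counts0 = cm.col_counts().copy()
        for _ in range(30):
            rows, cols = np.nonzero(cm.mask)
            cm.w[rows, cols] = rng.uniform(0, 0.5, rows.size)
            apply_structural_plasticity(cm, bk, mode, rng)
            np.testing.assert_array_equal(cm.col_counts(), counts0)

    @pytest.mark.parametrize("mode", ["bookkeeping_pruning", "spatial_pruning"])
    def test_pruning_counts_non_increasing_to_floor(self, mode, rng):
        cm = make_toy_matrix("random", 30, 10, rng, k=8)
        params = StructuralParams(theta_w=0.05, lam=0.9)
        bk = BookkeepingState.for_matrix(cm, params)
        prev = cm.col_counts().copy()
        for _ in range(25):
            apply_structural_plasticity(cm, bk, mode, rng)
            counts = cm.col_counts()
            assert (counts <= prev).all()
            assert (counts >= bk.floor).all()
            assert (counts >= 1).all()  # no starved target neuron
            prev = counts.copy()
        np.testing.assert_array_equal(prev, bk.floor)

    def test_no_negative_weights_or_duplicates_after_rewiring(self, rng):
        cm = make_toy_matrix("random", 24, 12, rng, k=6)
        bk = BookkeepingState.for_matrix(cm, StructuralParams(theta_w=0.2, lam=0.95))
        for _ in range(20):
            rows, cols = np.nonzero(cm.mask)
            cm.w[rows, cols] = rng.uniform(0, 0.5, rows.size)
            apply_structural_plasticity(cm, bk, "spatial_pruning", rng)
            assert (cm.w[cm.mask] >= 0).all()
            assert (cm.w[~cm.mask] == 0).all()


def test_wrap_shift_equivariance_of_placement(rng):
    """Rolling sources and targets rolls the placement distribution."""
    cm = make_toy_matrix("two-cluster", 16, 16, rng)
    dr, dc = 5, 7
    rolled = ConnectionMatrix(
        np.roll(cm.w, (dr, dc), axis=(0, 1)).copy(),
        np.roll(cm.mask, (dr, dc), axis=(0, 1)).copy(),
        cm.w_init_max, cm.w_max,
    )
    p_ref = spatial_probability(cm, 3.0, 2.0).p
    p_rolled = spatial_probability(rolled, 3.0, 2.0).p
    np.testing.assert_allclose(p_rolled, np.roll(p_ref, (dr, dc), axis=(0, 1)),
                               atol=1e-12)


def test_connection_matrix_triplet_round_trip(rng):
    cm = make_toy_matrix("random", 12, 9, rng, k=4)
    rows, cols, vals = cm.to_triplets()
    back = ConnectionMatrix.from_triplets(
        (12, 9), rows, cols, vals, cm.w_init_max, cm.w_max)
    np.testing.assert_array_equal(back.w, cm.w)
    np.testing.assert_array_equal(back.mask, cm.mask)
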