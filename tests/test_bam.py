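"""Bidirectional associative memory: storage, retrieval, energy, classification."""

import numpy as np
import pytest

from spikebam import (
    AssociativeMemory,
    PatternPair,
    bam_energy,
    bam_iterate,
    classify,
    encode_bipolar_onehot,
    hebbian_store,
    recall_backward,
    recall_forward,
    spikes_to_bipolar,
)

from conftest import hebbian_double_loop_oracle

# the two-pair worked example used throughout
X1 = np.array([1, -1, 1, -1])
Y1 = np.array([1, -1])
X2 = np.array([1, 1, -1, -1])
Y2 = np.array([-1, 1])
W_EXPECTED = np.array([[0, -2, 2, 0], [0, 2, -2, 0]])


def _two_pair_memory() -> AssociativeMemory:
    return hebbian_store([PatternPair(X1, Y1), PatternPair(X2, Y2)])


class TestSpikesToBipolar:
    def test_flatten_and_map(self):
        assert list(spikes_to_bipolar(np.array([[0, 1], [1, 0]]))) == [-1, 1, 1, -1]

    def test_all_zero(self):
        assert np.all(spikes_to_bipolar(np.zeros((3, 4))) == -1)

    def test_length_is_neurons_times_bins(self):
        assert spikes_to_bipolar(np.zeros((200, 64))).size == 200 * 64

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            spikes_to_bipolar(np.array([[0.5]]))


class TestHebbianStore:
    def test_two_pair_worked_example(self):
        assert np.array_equal(_two_pair_memory().W, W_EXPECTED)

    def test_single_pair_outer_product(self):
        mem = hebbian_store([PatternPair([1, -1, 1], [1, -1])])
        assert np.array_equal(mem.W, [[1, -1, 1], [-1, 1, -1]])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        xs = [rng.choice([-1, 1], 7) for _ in range(5)]
        ys = [encode_bipolar_onehot(int(rng.integers(0, 3)), 3) for _ in range(5)]
        mem = hebbian_store([PatternPair(x, y) for x, y in zip(xs, ys)])
        assert np.array_equal(mem.W, hebbian_double_loop_oracle(xs, ys))

    def test_linearity_double_store(self):
        once = hebbian_store([PatternPair(X1, Y1)])
        twice = hebbian_store([PatternPair(X1, Y1), PatternPair(X1, Y1)])
        assert np.array_equal(twice.W, 2 * once.W)

    def test_order_independent(self):
        a = hebbian_store([PatternPair(X1, Y1), PatternPair(X2, Y2)])
        b = hebbian_store([PatternPair(X2, Y2), PatternPair(X1, Y1)])
        assert np.array_equal(a.W, b.W)

    def test_entry_bound_and_parity(self):
        """After K pairs every entry is an integer in [-K, K] with parity K mod 2."""
        rng = np.random.default_rng(1)
        k = 5
        pairs = [
            PatternPair(rng.choice([-1, 1], 6), encode_bipolar_onehot(int(rng.integers(0, 2)), 2))
            for _ in range(k)
        ]
        w = hebbian_store(pairs).W
        assert np.abs(w).max() <= k
        assert np.all(w % 2 == k % 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hebbian_store([])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hebbian_store([PatternPair(X1, Y1), PatternPair([1, -1], Y2)])

    def test_non_bipolar_rejected(self):
        with pytest.raises(ValueError):
            PatternPair([1, 0, 1, -1], Y1)


class TestRecall:
    def test_forward_recovers_stored_labels(self):
        mem = _two_pair_memory()
        assert np.array_equal(recall_forward(mem, X1), Y1)
        assert np.array_equal(recall_forward(mem, X2), Y2)

    def test_backward_sgn_zero_convention(self):
        """W^T y1 = [0,-4,4,0]: zeros map to -1 under sgn(z<=0) = -1."""
        mem = _two_pair_memory()
        assert np.array_equal(recall_backward(mem, Y1), [-1, -1, 1, -1])

    def test_single_pair_backward_is_exact(self):
        mem = hebbian_store([PatternPair(X1, Y1)])
        assert np.array_equal(recall_backward(mem, Y1), X1)

    def test_zero_matrix_gives_all_minus_one(self):
        mem = AssociativeMemory(W=np.zeros((2, 4), dtype=int))
        assert np.all(recall_forward(mem, X1) == -1)
        assert np.all(recall_backward(mem, Y1) == -1)

    def test_dimension_checks(self):
        mem = _two_pair_memory()
        with pytest.raises(ValueError):
            recall_forward(mem, np.array([1, -1]))
        with pytest.raises(ValueError):
            recall_backward(mem, np.array([1, -1, 1]))


class TestEnergy:
    def test_worked_example(self):
        assert bam_energy(_two_pair_memory(), X1, Y1) == -8.0

    def test_zero_matrix(self):
        mem = AssociativeMemory(W=np.zeros((2, 4), dtype=int))
        assert bam_energy(mem, X1, Y1) == 0.0

    def test_transpose_identity(self):
        mem = _two_pair_memory()
        assert bam_energy(mem, X1, Y1) == pytest.approx(-(X1 @ (mem.W.T @ Y1)))


class TestIterate:
    def test_stored_pair_fixpoint_in_one_iteration(self):
        mem = _two_pair_memory()
        x, y, trace, converged = bam_iterate(mem, X1)
        assert converged
        assert np.array_equal(y, Y1)
        assert len(trace) <= 5

    def test_energy_trace_non_increasing_random(self):
        """100 random (W, x0): every half-update descends the energy."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            m, n = int(rng.integers(2, 5)), int(rng.integers(3, 9))
            mem = AssociativeMemory(W=rng.integers(-3, 4, (m, n)))
            x0 = rng.choice([-1, 1], n)
            _, _, trace, converged = bam_iterate(mem, x0, max_iters=20)
            assert converged
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_one_hot_outputs_stabilize_after_single_iteration(self):
        """With bipolar one-hot labels the y-update settles immediately."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            xs = [rng.choice([-1, 1], 8) for _ in range(3)]
            ys = [encode_bipolar_onehot(c, 3) for c in range(3)]
            mem = hebbian_store([PatternPair(x, y) for x, y in zip(xs, ys)])
            x0 = rng.choice([-1, 1], 8)
            y1 = recall_forward(mem, x0)
            x1 = recall_backward(mem, y1)
            y2 = recall_forward(mem, x1)
            x2 = recall_backward(mem, y2)
            assert np.array_equal(recall_forward(mem, x2), y2)  # y settled
            _, _, _, converged = bam_iterate(mem, x0, max_iters=10)
            assert converged

    def test_max_iters_validation(self):
        with pytest.raises(ValueError):
            bam_iterate(_two_pair_memory(), X1, max_iters=0)


class TestClassify:
    def test_worked_example_scores(self):
        mem = _two_pair_memory()
        label1, scores1 = classify(mem, X1)
        label2, scores2 = classify(mem, X2)
        assert (label1, label2) == (0, 1)
        assert list(scores1) == [4, -4]
        assert list(scores2) == [-4, 4]

    def test_tie_breaks_to_lowest_index(self):
        mem = AssociativeMemory(W=np.array([[1, 1], [1, 1]]))
        label, scores = classify(mem, np.array([1, 1]))
        assert label == 0 and scores[0] == scores[1]

    def test_positive_rescaling_invariance(self):
        mem = _two_pair_memory()
        for k in (0.1, 3.0, 100.0):
            assert classify(mem, X1 * k)[0] == classify(mem, X1)[0]

    def test_literal_argmin_mode(self):
        mem = _two_pair_memory()
        assert classify(mem, X1, mode="literal-argmin")[0] == 1
        with pytest.raises(ValueError):
            classify(mem, X1, mode="mystery")

    def test_perfect_recall_orthogonal_patterns(self):
        """K <= m mutually orthogonal patterns are all classified exactly."""
        # rows of a 8x8 Hadamard matrix are mutually orthogonal bipolar vectors
        h = np.array([[1]])
        for _ in range(3):
            h = np.block([[h, h], [h, -h]])
        for k in (2, 3, 4):
            xs = [h[i] for i in range(k)]
            ys = [encode_bipolar_onehot(i, k) for i in range(k)]
            mem = hebbian_store([PatternPair(x, y) for x, y in zip(xs, ys)])
            for i in range(k):
                label, _ = classify(mem, xs[i])
                assert label == i
                assert np.array_equal(recall_forward(mem, xs[i]), ys[i])


class TestStage2:
    @pytest.fixture()
    def trained(self, small_trialset, tiny_spec):
        from spikebam import LIFConfig, TrainConfig, train_stage1

        cfg = TrainConfig(epochs=2, batch_size=8, seed=0)
        lif_cfg = LIFConfig(n_in=tiny_spec.latent_channels, n_neurons=tiny_spec.n_neurons)
        model, _ = train_stage1(small_trialset, tiny_spec, lif_cfg, cfg)
        return model

    def test_one_memory_per_subject_with_amm_shape(self, trained, small_trialset, tiny_spec):
        from spikebam import train_stage2

        memories = train_stage2(small_trialset, trained)
        assert sorted(memories) == [0, 1]
        n = tiny_spec.n_neurons * tiny_spec.T // 4
        for s, mem in memories.items():
            assert mem.W.shape == (small_trialset.n_classes, n)
            assert mem.n_stored == (small_trialset.subject_ids == s).sum()

    def test_storage_order_independent(self, trained, small_trialset):
        from spikebam import train_stage2

        memories = train_stage2(small_trialset, trained)
        perm = np.random.default_rng(5).permutation(small_trialset.n_trials)
        shuffled = small_trialset.select(perm)
        memories2 = train_stage2(shuffled, trained)
        for s in memories:
            assert np.array_equal(memories[s].W, memories2[s].W)

    def test_unseen_subject_error_lists_known(self, trained, small_trialset):
        from spikebam import predict, train_stage2

        memories = train_stage2(small_trialset, trained)
        alien = small_trialset.select(np.arange(4))
        alien.subject_ids[:] = 99
        with pytest.raises(KeyError, match=r"99.*\[0, 1\]"):
            predict(alien, trained, memories)

    def test_memory_round_trip(self, trained, small_trialset, tmp_path):
        from spikebam.bam import load_memories, save_memories, train_stage2

        memories = train_stage2(small_trialset, trained)
        p = tmp_path / "mem.npz"
        save_memories(memories, p)
        back = load_memories(p)
        assert sorted(back) == sorted(memories)
        for s in memories:
            assert np.array_equal(back[s].W, memories[s].W)
            assert back[s].n_stored == memories[s].n_stored

    def test_runtime_scales_linearly_in_trials(self):
        """Hebbian storage is one pass: 2x the pairs stays near 2x the time."""
        import time

        rng = np.random.default_rng(7)
        xs = rng.choice([-1, 1], size=(400, 2000))
        ys = [encode_bipolar_onehot(int(rng.integers(0, 4)), 4) for _ in range(400)]
        pairs = [PatternPair(x, y) for x, y in zip(xs, ys)]

        def best_time(p):
            times = []
            for _ in range(5):
                t0 = time.perf_counter()
                hebbian_store(p)
                times.append(time.perf_counter() - t0)
            return min(times)

        t_half, t_full = best_time(pairs[:200]), best_time(pairs)
        assert t_full <= 4.0 * t_half + 1e-3
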