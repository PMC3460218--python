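"""Core network: vocabulary, training, dynamics, energies, slot operations."""

import warnings

import numpy as np
import pytest

from dpaan import (
    BLANK,
    CalibrationError,
    DpaanError,
    GateMatrix,
    NetworkState,
    PartitionLayout,
    SymbolVocabulary,
    VocabularyError,
    active_pairs,
    blank_slot,
    build_vocabulary,
    calibrate_equality,
    decode_slot,
    energy_cross,
    energy_total,
    equality_readout,
    hopfield_train,
    partition_pairs,
    set_slot,
    settle,
    slot_overlap,
    transfer,
)
from conftest import random_tiny_network, small_network


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def test_layout_indexing_covers_all_neurons():
    layout = PartitionLayout((3, 5, 2))
    assert layout.n_partitions == 3
    assert layout.n_neurons == 10
    covered = []
    for k in range(3):
        sl = layout.slice_of(k)
        covered.extend(range(sl.start, sl.stop))
    assert covered == list(range(10))
    assert list(layout.partition_of()) == [0] * 3 + [1] * 5 + [2] * 2


@pytest.mark.parametrize("sizes", [(), (0,), (5, -1)])
def test_layout_rejects_bad_sizes(sizes):
    with pytest.raises(ValueError):
        PartitionLayout(sizes)


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

def test_vocabulary_shapes_and_pieces():
    layout = PartitionLayout((100,) * 5)
    vocab = build_vocabulary(layout, ["red", "blue", "square", "circle"], seed=1)
    assert vocab.patterns.shape == (4, 500)
    assert set(np.unique(vocab.patterns)) <= {-1.0, 1.0}
    for l, name in enumerate(vocab.symbols):
        reassembled = np.concatenate([vocab.piece(name, k) for k in range(5)])
        assert np.array_equal(reassembled, vocab.patterns[l])
        assert len(vocab.piece(name, 0)) == 100


def test_vocabulary_seed_reproducibility():
    layout = PartitionLayout((50, 50))
    a = build_vocabulary(layout, ["x", "y", "z"], seed=7)
    b = build_vocabulary(layout, ["x", "y", "z"], seed=7)
    c = build_vocabulary(layout, ["x", "y", "z"], seed=8)
    assert np.array_equal(a.patterns, b.patterns)
    assert not np.array_equal(a.patterns, c.patterns)


def test_vocabulary_empty_names_gives_zero_patterns():
    vocab = build_vocabulary(PartitionLayout((10,)), [], seed=0)
    assert vocab.n_symbols == 0
    assert vocab.patterns.shape == (0, 10)


def test_vocabulary_rejects_duplicates_and_bad_coding():
    layout = PartitionLayout((10,))
    with pytest.raises(VocabularyError):
        build_vocabulary(layout, ["a", "a"], seed=0)
    for bad in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(VocabularyError):
            build_vocabulary(layout, ["a"], coding_level=bad, seed=0)


def test_vocabulary_collision_on_too_small_partition():
    # a 1-neuron partition admits only two distinct pieces
    with pytest.raises(VocabularyError):
        build_vocabulary(PartitionLayout((1, 50)), ["a", "b", "c"], seed=0)


def test_vocabulary_pieces_distinct_on_every_partition():
    vocab = build_vocabulary(PartitionLayout((3, 3)), list("abcd"), seed=0)
    for k in range(2):
        pieces = {tuple(vocab.piece(s, k)) for s in vocab.symbols}
        assert len(pieces) == 4


def test_random_patterns_are_nearly_orthogonal():
    """Monte Carlo: dense random bipolar patterns have ~zero mean overlap."""
    overlaps = []
    for seed in range(50):
        vocab = build_vocabulary(PartitionLayout((1000,)), list("abcd"), 0.5, seed)
        P = vocab.patterns
        for a in range(4):
            for b in range(a + 1, 4):
                overlaps.append(P[a] @ P[b] / 1000)
    overlaps = np.array(overlaps)
    assert abs(overlaps.mean()) < 0.01
    assert np.max(np.abs(overlaps)) < 0.15


# ---------------------------------------------------------------------------
# Hopfield training
# ---------------------------------------------------------------------------

def hopfield_oracle(patterns: np.ndarray) -> np.ndarray:
    """Naive double-loop outer-product rule, for oracle comparisons."""
    L, N = patterns.shape
    W = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            for l in range(L):
                W[i, j] += patterns[l, i] * patterns[l, j] / N
    return W


def test_train_single_uniform_pattern():
    layout = PartitionLayout((4,))
    vocab = SymbolVocabulary(layout, ("all",), np.ones((1, 4)), 0.5, 0)
    W = hopfield_train(vocab).matrix
    off = W[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 0.25)
    assert np.all(np.diag(W) == 0)


def test_train_matches_double_loop_oracle():
    vocab = build_vocabulary(PartitionLayout((3, 3)), ["a"], seed=3)
    W = hopfield_train(vocab).matrix
    assert np.allclose(W, hopfield_oracle(vocab.patterns), atol=1e-12)

    vocab2 = build_vocabulary(PartitionLayout((7, 6, 7)), list("abc"), seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W2 = hopfield_train(vocab2).matrix
    assert np.allclose(W2, hopfield_oracle(vocab2.patterns), atol=1e-9)


def test_train_symmetry_and_zero_diagonal(net3x6):
    _, weights, _ = net3x6
    assert np.allclose(weights.matrix, weights.matrix.T, atol=1e-12)
    assert np.all(np.diag(weights.matrix) == 0)


def test_train_empty_vocab_raises():
    vocab = build_vocabulary(PartitionLayout((10,)), [], seed=0)
    with pytest.raises(VocabularyError):
        hopfield_train(vocab)


def test_train_warns_near_capacity():
    vocab = build_vocabulary(PartitionLayout((40, 40)), list("abcdefgh"), seed=0)
    with pytest.warns(UserWarning, match="capacity"):
        hopfield_train(vocab)


def test_stored_patterns_are_fixed_points(net3x6):
    vocab, weights, _ = net3x6
    gates = GateMatrix.all_on(3)
    for name in vocab.symbols:
        state = NetworkState(vocab.pattern(name).copy())
        res = settle(state, weights, gates, max_steps=5)
        assert res.converged
        assert len(res.states) == 1   # immediate fixed point
        assert np.array_equal(res.final.activations, vocab.pattern(name))


def test_isolated_pieces_are_fixed_points_at_low_load():
    """With cross-slot gates off, each slot alone retains every symbol piece
    (exact at the binding-demo load of 4 symbols on 100-unit slots)."""
    for seed in range(10):
        vocab, weights, _ = small_network(seed, n_slots=5, slot_size=100,
                                          symbols=("red", "blue", "square", "circle"))
        gates = GateMatrix.within_only(5)
        for name in vocab.symbols:
            for k in range(5):
                state = NetworkState.blank(vocab.layout)
                state.activations[vocab.layout.slice_of(k)] = vocab.piece(name, k)
                res = settle(state, weights, gates, max_steps=3)
                assert res.converged and len(res.states) == 1, (seed, name, k)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def test_settle_respects_clamps(net3x6):
    vocab, weights, _ = net3x6
    state = NetworkState(vocab.pattern("red").copy())
    state.activations[:10] *= -1      # recurrent drive would flip these back
    state.clamped[:10] = True
    frozen = state.activations[:10].copy()
    res = settle(state, weights, GateMatrix.all_on(3), max_steps=10)
    assert np.array_equal(res.final.activations[:10], frozen)


def test_settle_transfer_via_single_gated_block():
    """Clamped source + one open block pulls a blank slot onto the same
    global attractor within the step budget."""
    vocab, weights, _ = small_network(2, n_slots=5, slot_size=100,
                                      symbols=("red", "blue", "square", "circle"))
    layout = vocab.layout
    state = NetworkState.blank(layout)
    state.activations[layout.slice_of(0)] = vocab.piece("red", 0)
    state.clamped[layout.slice_of(0)] = True
    gates = GateMatrix.within_only(5)
    gates.set_gate(0, 4, True)
    res = settle(state, weights, gates, max_steps=40)
    assert np.array_equal(res.final.activations[layout.slice_of(4)],
                          vocab.piece("red", 4))


def test_settle_validates_arguments(net3x6):
    vocab, weights, _ = net3x6
    state = NetworkState(vocab.pattern(0).copy())
    with pytest.raises(ValueError):
        settle(state, weights, GateMatrix.all_on(3), max_steps=0)
    with pytest.raises(ValueError):
        settle(state, weights, GateMatrix.all_on(3), mode="simultaneous")


def test_asynchronous_energy_is_lyapunov(rng):
    """Under seeded asynchronous single-unit updates with a symmetric gate
    configuration, total energy never increases at any update."""
    for trial in range(20):
        layout, vocab, weights = random_tiny_network(rng, n_neurons=15, n_patterns=2)
        x = rng.choice([-1.0, 1.0], size=layout.n_neurons)
        state = NetworkState(x)
        res = settle(state, weights, GateMatrix.all_on(layout.n_partitions),
                     mode="asynchronous", max_steps=10,
                     seed=trial, record_updates=True)
        energies = [energy_total(s, weights) for s in res.states]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(energies, energies[1:]))


def test_blank_network_stays_blank():
    """Blank units exert no drive: with every unit blank there is no input
    anywhere, so the all-blank state is a fixed point."""
    vocab, weights, _ = small_network(3)
    empty = NetworkState.blank(vocab.layout)
    res = settle(empty, weights, GateMatrix.all_on(3), max_steps=3)
    assert np.all(res.final.activations == BLANK)
    assert res.converged


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------

def energy_total_oracle(x, W):
    E = 0.0
    for i in range(len(x)):
        for j in range(len(x)):
            if i != j:
                E -= 0.5 * W[i, j] * x[i] * x[j]
    return E


def energy_cross_oracle(x, W, layout, k, kp):
    sk, sp = layout.slice_of(k), layout.slice_of(kp)
    E = 0.0
    for i in range(sk.start, sk.stop):
        for j in range(sp.start, sp.stop):
            E -= W[i, j] * x[i] * x[j]
            E -= W[j, i] * x[j] * x[i]
    return E


def test_energy_blank_state_is_zero(net3x6):
    vocab, weights, _ = net3x6
    state = NetworkState.blank(vocab.layout)
    assert energy_total(state, weights) == 0.0
    assert energy_cross(state, weights, 0, 1) == 0.0


def test_energy_of_stored_pattern_closed_form():
    """One stored pattern, normalized outer-product weights: E = −(N−1)/2."""
    for N in (4, 10, 25):
        layout = PartitionLayout((N,))
        vocab = build_vocabulary(layout, ["a"], seed=1)
        weights = hopfield_train(vocab)
        state = NetworkState(vocab.pattern("a").copy())
        assert energy_total(state, weights) == pytest.approx(-(N - 1) / 2, abs=1e-9)


def test_energies_match_brute_force_oracles(rng):
    for _ in range(5):
        layout, vocab, weights = random_tiny_network(rng, n_neurons=12)
        x = rng.choice([-1.0, 0.0, 1.0], size=layout.n_neurons)
        state = NetworkState(x)
        assert energy_total(state, weights) == pytest.approx(
            energy_total_oracle(x, weights.matrix), abs=1e-9)
        for k, kp in partition_pairs(layout.n_partitions):
            expected = energy_cross_oracle(x, weights.matrix, layout, k, kp)
            assert energy_cross(state, weights, k, kp) == pytest.approx(expected, abs=1e-9)
            # symmetric in (k, k')
            assert energy_cross(state, weights, kp, k) == pytest.approx(expected, abs=1e-9)


def test_energy_cross_rejects_same_partition(net3x6):
    vocab, weights, _ = net3x6
    with pytest.raises(ValueError):
        energy_cross(NetworkState.blank(vocab.layout), weights, 1, 1)


# ---------------------------------------------------------------------------
# Equality calibration and readout
# ---------------------------------------------------------------------------

def test_calibration_separates_matched_from_mismatched(net3x6):
    vocab, weights, eqcfg = net3x6
    for pair in partition_pairs(3):
        assert eqcfg.margin(pair) > 0
        assert eqcfg.matched_means[pair] < eqcfg.thresholds[pair] \
            < eqcfg.mismatched_means[pair]


def test_calibration_two_symbol_two_slot():
    vocab, weights, eqcfg = small_network(0, n_slots=2, slot_size=200,
                                          symbols=("a", "b"))
    (pair,) = partition_pairs(2)
    state = NetworkState(vocab.pattern("a").copy())
    assert energy_cross(state, weights, *pair) < eqcfg.thresholds[pair]
    mixed = set_slot(state, 1, "b", vocab)
    assert energy_cross(mixed, weights, *pair) > eqcfg.thresholds[pair]


def test_calibration_requires_two_symbols():
    vocab = build_vocabulary(PartitionLayout((50, 50)), ["only"], seed=0)
    weights = hopfield_train(vocab)
    with pytest.raises(CalibrationError):
        calibrate_equality(vocab, weights)


def test_equality_truth_table_exhaustive(net3x6):
    """eq(k,k') fires iff the two slots hold pieces of the same symbol,
    over every (slot pair, symbol pair)."""
    vocab, weights, eqcfg = net3x6
    for k, kp in partition_pairs(3):
        for a in vocab.symbols:
            for b in vocab.symbols:
                state = NetworkState.blank(vocab.layout)
                state = set_slot(state, k, a, vocab)
                state = set_slot(state, kp, b, vocab)
                eq = equality_readout(state, weights, eqcfg)
                assert eq[(k, kp)] == int(a == b), (k, kp, a, b)


def test_equality_readout_binding_scenario():
    """Red/circle/red/square/blank: only the (1,3) neuron fires; setting
    every slot to the same symbol turns them all on."""
    vocab, weights, eqcfg = small_network(1, n_slots=5, slot_size=100,
                                          symbols=("red", "blue", "square", "circle"))
    state = NetworkState.blank(vocab.layout)
    for k, sym in enumerate(("red", "circle", "red", "square")):
        state = set_slot(state, k, sym, vocab)
    eq = equality_readout(state, weights, eqcfg)
    assert active_pairs(eq) == {(0, 2)}

    all_red = NetworkState(vocab.pattern("red").copy())
    eq_all = equality_readout(all_red, weights, eqcfg)
    assert active_pairs(eq_all) == set(partition_pairs(5))


def test_blank_partition_never_reads_equal(net3x6):
    vocab, weights, eqcfg = net3x6
    state = NetworkState.blank(vocab.layout)
    state = set_slot(state, 0, "red", vocab)
    eq = equality_readout(state, weights, eqcfg)
    assert active_pairs(eq) == set()


# ---------------------------------------------------------------------------
# Slot operations
# ---------------------------------------------------------------------------

def test_set_blank_decode_roundtrip(net3x6):
    vocab, weights, _ = net3x6
    state = NetworkState.blank(vocab.layout)
    state = set_slot(state, 1, "circle", vocab)
    assert decode_slot(state, 1, vocab) == "circle"
    assert decode_slot(state, 0, vocab) is None
    # idempotence
    again = set_slot(state, 1, "circle", vocab)
    assert np.array_equal(again.activations, state.activations)
    blanked = blank_slot(state, 1, vocab.layout)
    assert decode_slot(blanked, 1, vocab) is None
    assert np.array_equal(blank_slot(blanked, 1, vocab.layout).activations,
                          blanked.activations)
    assert energy_cross(blanked, weights, 0, 1) == 0.0


def test_decode_tolerates_flipped_units(net3x6):
    vocab, _, _ = net3x6
    state = NetworkState.blank(vocab.layout)
    state = set_slot(state, 0, "blue", vocab)
    sl = vocab.layout.slice_of(0)
    state.activations[sl.start:sl.start + 5] *= -1   # 5% of 100 units
    assert slot_overlap(state, 0, "blue", vocab) == pytest.approx(0.9)
    assert decode_slot(state, 0, vocab, min_overlap=0.8) == "blue"


def test_decode_validates_min_overlap(net3x6):
    vocab, _, _ = net3x6
    with pytest.raises(ValueError):
        decode_slot(NetworkState.blank(vocab.layout), 0, vocab, min_overlap=0.0)


def test_transfer_moves_symbol_and_restores_gates(net3x6):
    vocab, weights, _ = net3x6
    state = NetworkState.blank(vocab.layout)
    state = set_slot(state, 1, "circle", vocab)
    gates = GateMatrix.within_only(3)
    out = transfer(state, weights, gates, 1, 2, steps=40)
    assert decode_slot(out, 2, vocab) == "circle"
    assert decode_slot(out, 1, vocab) == "circle"   # source kept
    assert not gates.is_on(1, 2)                    # cross block closed again
    assert gates.is_on(2, 2)                        # target holds its content
    assert not out.clamped.any()


def test_transfer_onto_same_symbol_is_stable(net3x6):
    vocab, weights, _ = net3x6
    state = NetworkState.blank(vocab.layout)
    state = set_slot(state, 0, "green", vocab)
    state = set_slot(state, 2, "green", vocab)
    out = transfer(state, weights, GateMatrix.within_only(3), 0, 2)
    assert decode_slot(out, 2, vocab) == "green"


def test_transfer_from_blank_slot_raises(net3x6):
    vocab, weights, _ = net3x6
    state = NetworkState.blank(vocab.layout)
    with pytest.raises(DpaanError):
        transfer(state, weights, GateMatrix.within_only(3), 0, 1)
    with pytest.raises(ValueError):
        transfer(state, weights, GateMatrix.within_only(3), 1, 1)
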