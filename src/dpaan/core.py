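"""Partitioned autoassociative (Hopfield) networks with gateable synapse blocks.

A dynamically partitionable autoassociative network (DPAAN) is a single
fully connected Hopfield network whose N neurons are split into K contiguous
partitions ("slots").  The network is trained once, as a whole, on L random
global patterns — the symbol vocabulary.  At run time, blocks of synapses
between partitions can be switched off (isolating each slot as an independent
buffer that holds its piece of some global attractor) or on (forcing joint
attractor completion, which implements slot-to-slot symbol transfer).
Because every slot's piece belongs to the same global attractor, a symbol
keeps its identity — and every association learned for it — no matter which
slot currently holds it (role–filler independence).

Activations are bipolar: +1 (active), −1 (inactive), with 0 as a distinct
*blank* value.  A blank unit contributes no drive to any other unit, so a
fully blanked partition is genuinely empty rather than "all inactive".

Partitions and vocabulary symbols are indexed 0-based throughout.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

logger = logging.getLogger("dpaan")

#: default number of synchronous settle steps given to a slot-to-slot transfer
DEFAULT_TRANSFER_STEPS = 40
#: default minimum normalized overlap for decoding a slot to a symbol
DEFAULT_DECODE_OVERLAP = 0.8
#: retries allowed when regenerating colliding vocabulary patterns
MAX_PATTERN_RETRIES = 100

ACTIVE = 1.0
INACTIVE = -1.0
BLANK = 0.0


class DpaanError(Exception):
    """Base class for errors raised by this package."""


class VocabularyError(DpaanError):
    """Vocabulary construction failed (duplicate names, collisions, ...)."""


class CalibrationError(DpaanError):
    """Equality-threshold calibration failed or does not separate."""


# ---------------------------------------------------------------------------
# Layout and vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionLayout:
    """Division of the N network neurons into K contiguous partitions.

    Parameters
    ----------
    partition_sizes
        Neuron count of each partition, ``(N_1, ..., N_K)``; all positive.
    """

    partition_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.partition_sizes)
        if len(sizes) < 1:
            raise ValueError("layout needs at least one partition")
        if any(s < 1 for s in sizes):
            raise ValueError("every partition must have at least one neuron")
        object.__setattr__(self, "partition_sizes", sizes)

    @property
    def n_partitions(self) -> int:
        return len(self.partition_sizes)

    @property
    def n_neurons(self) -> int:
        return sum(self.partition_sizes)

    @property
    def offsets(self) -> tuple[int, ...]:
        out, acc = [], 0
        for s in self.partition_sizes:
            out.append(acc)
            acc += s
        return tuple(out)

    def slice_of(self, k: int) -> slice:
        """Index range of partition ``k`` in the concatenated vector."""
        if not 0 <= k < self.n_partitions:
            raise IndexError(f"partition {k} not in 0..{self.n_partitions - 1}")
        off = self.offsets[k]
        return slice(off, off + self.partition_sizes[k])

    def partition_of(self) -> NDArray[np.intp]:
        """Length-N vector mapping neuron index to its partition index."""
        return np.repeat(np.arange(self.n_partitions), self.partition_sizes)


@dataclass(frozen=True)
class SymbolVocabulary:
    """L global attractor patterns, one per symbol name.

    ``patterns`` is an (L, N) bipolar array; pattern ``l`` restricted to
    partition ``k`` is the *piece* of symbol ``l`` on slot ``k``.
    """

    layout: PartitionLayout
    symbols: tuple[str, ...]
    patterns: NDArray[np.float64]
    coding_level: float
    seed: int

    @property
    def n_symbols(self) -> int:
        return len(self.symbols)

    def index_of(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"unknown symbol {symbol!r}") from None

    def pattern(self, symbol: int | str) -> NDArray[np.float64]:
        l = symbol if isinstance(symbol, int) else self.index_of(symbol)
        return self.patterns[l]

    def piece(self, symbol: int | str, k: int) -> NDArray[np.float64]:
        """Piece of symbol's global pattern on partition ``k``."""
        return self.pattern(symbol)[self.layout.slice_of(k)]

    def pieces(self, k: int) -> NDArray[np.float64]:
        """(L, N_k) array of every symbol's piece on partition ``k``."""
        return self.patterns[:, self.layout.slice_of(k)]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.patterns).tobytes())
        h.update("|".join(self.symbols).encode())
        return h.hexdigest()[:16]


def build_vocabulary(
    layout: PartitionLayout,
    symbol_names: list[str] | tuple[str, ...],
    coding_level: float = 0.5,
    seed: int = 0,
) -> SymbolVocabulary:
    """Create L seeded random bipolar patterns, one global attractor per name.

    Each unit of each pattern is +1 with probability ``coding_level`` and −1
    otherwise.  Patterns must be pairwise distinct on *every* partition so
    that any slot can distinguish any two symbols; colliding patterns are
    resampled a bounded number of times.
    """
    names = tuple(symbol_names)
    if len(set(names)) != len(names):
        raise VocabularyError("symbol names must be unique")
    if not 0.0 < coding_level < 1.0:
        raise VocabularyError(f"coding_level must be in (0, 1), got {coding_level}")

    rng = np.random.default_rng(seed)
    L, N = len(names), layout.n_neurons

    def draw(n_rows: int) -> NDArray[np.float64]:
        return np.where(rng.random((n_rows, N)) < coding_level, ACTIVE, INACTIVE)

    patterns = draw(L)
    for _ in range(MAX_PATTERN_RETRIES):
        clash = _colliding_rows(patterns, layout)
        if not clash:
            break
        patterns[list(clash)] = draw(len(clash))
    else:
        raise VocabularyError(
            "could not generate pairwise-distinct pieces on every partition; "
            "some partition is too small for this many symbols"
        )
    return SymbolVocabulary(layout, names, patterns, float(coding_level), int(seed))


def _colliding_rows(patterns: NDArray, layout: PartitionLayout) -> set[int]:
    """Rows whose piece equals another row's piece on some partition."""
    clash: set[int] = set()
    for k in range(layout.n_partitions):
        pieces = patterns[:, layout.slice_of(k)]
        for a in range(len(pieces)):
            for b in range(a + 1, len(pieces)):
                if np.array_equal(pieces[a], pieces[b]):
                    clash.add(b)
    return clash


# ---------------------------------------------------------------------------
# State, weights, gates
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Concatenated activation vector plus clamp flags.

    Entries of ``activations`` are +1, −1 or 0 (blank).  Clamped units are
    never updated by the dynamics.
    """

    activations: NDArray[np.float64]
    clamped: NDArray[np.bool_] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=np.float64)
        if self.clamped is None:
            self.clamped = np.zeros(self.activations.shape, dtype=bool)
        else:
            self.clamped = np.asarray(self.clamped, dtype=bool)
        if self.clamped.shape != self.activations.shape:
            raise ValueError("clamp mask must match activation vector shape")

    def copy(self) -> "NetworkState":
        return NetworkState(self.activations.copy(), self.clamped.copy())

    @classmethod
    def blank(cls, layout: PartitionLayout) -> "NetworkState":
        return cls(np.zeros(layout.n_neurons))


@dataclass(frozen=True)
class Weights:
    """Trained N×N synaptic matrix; ``matrix[i, j]`` is the weight onto
    postsynaptic unit ``i`` from presynaptic unit ``j``.

    Always symmetric with zero diagonal for the Hopfield rule used here.
    """

    matrix: NDArray[np.float64]
    layout: PartitionLayout
    rule: str = "hopfield"
    vocab_hash: str = ""

    def block(self, post: int, pre: int) -> NDArray[np.float64]:
        """Synapse block onto partition ``post`` from partition ``pre``."""
        return self.matrix[self.layout.slice_of(post), self.layout.slice_of(pre)]


@dataclass
class GateMatrix:
    """K×K directed block gates; ``blocks[k, kp]`` is the state of the
    transfer-control signal gating synapses from partition ``k`` (presynaptic)
    onto partition ``kp`` (postsynaptic).  Diagonal entries gate the
    within-partition synapses.  Gating zeroes a block's *effect*, never the
    stored weights.
    """

    blocks: NDArray[np.bool_]

    def __post_init__(self) -> None:
        self.blocks = np.asarray(self.blocks, dtype=bool)
        if self.blocks.ndim != 2 or self.blocks.shape[0] != self.blocks.shape[1]:
            raise ValueError("gate matrix must be square")

    @classmethod
    def all_on(cls, n_partitions: int) -> "GateMatrix":
        return cls(np.ones((n_partitions, n_partitions), dtype=bool))

    @classmethod
    def within_only(cls, n_partitions: int) -> "GateMatrix":
        """Cross-partition blocks off; each slot an independent buffer."""
        return cls(np.eye(n_partitions, dtype=bool))

    def copy(self) -> "GateMatrix":
        return GateMatrix(self.blocks.copy())

    def set_gate(self, pre: int, post: int, on: bool) -> None:
        self.blocks[pre, post] = on

    def is_on(self, pre: int, post: int) -> bool:
        return bool(self.blocks[pre, post])

    def mask(self, layout: PartitionLayout) -> NDArray[np.float64]:
        """N×N multiplicative mask: entry (i, j) is 1 iff the block from
        partition-of(j) onto partition-of(i) is gated on."""
        part = layout.partition_of()
        return self.blocks.T[np.ix_(part, part)].astype(np.float64)


def hopfield_train(vocab: SymbolVocabulary) -> Weights:
    """Hebbian outer-product (Hopfield) learning over the whole network.

    ``w_ij = (1/N) * sum_l xi_i^l xi_j^l`` with a zeroed diagonal, creating a
    stable global attractor per vocabulary symbol (for loads well below
    capacity).  Warns when L exceeds a tenth of the smallest partition, the
    point beyond which isolated slots start losing exact piece stability.
    """
    if vocab.n_symbols < 1:
        raise VocabularyError("cannot train on an empty vocabulary")
    min_nk = min(vocab.layout.partition_sizes)
    if vocab.n_symbols > 0.1 * min_nk:
        warnings.warn(
            f"{vocab.n_symbols} patterns on partitions of {min_nk} units is near "
            "the isolated-slot Hopfield capacity; pieces may not be exact fixed "
            "points of their subnetworks",
            stacklevel=2,
        )
    P = vocab.patterns
    W = (P.T @ P) / vocab.layout.n_neurons
    np.fill_diagonal(W, 0.0)
    return Weights(W, vocab.layout, rule="hopfield", vocab_hash=vocab.content_hash())


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

@dataclass
class SettleResult:
    """Trajectory of visited states; ``states[0]`` is the initial state."""

    states: list[NetworkState]
    converged: bool

    @property
    def final(self) -> NetworkState:
        return self.states[-1]

    def __len__(self) -> int:
        return len(self.states)


def _threshold(h: NDArray, prev: NDArray) -> NDArray:
    # sign of net input; exactly-zero drive keeps the previous value,
    # so an undriven blank unit stays blank
    return np.where(h > 0, ACTIVE, np.where(h < 0, INACTIVE, prev))


def settle(
    state: NetworkState,
    weights: Weights,
    gates: GateMatrix,
    mode: str = "synchronous",
    max_steps: int = 100,
    seed: int | None = None,
    record_updates: bool = False,
) -> SettleResult:
    """Run gated attractor dynamics from ``state`` until a fixed point or
    ``max_steps``.

    Synchronous mode updates all unclamped units at once per step.
    Asynchronous mode visits units one at a time in a seeded random order
    (one step = one full sweep); with a symmetric effective weight matrix this
    makes the Hopfield energy non-increasing at every single-unit update.
    ``record_updates`` additionally records the state after each single-unit
    update in asynchronous mode.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if mode not in ("synchronous", "asynchronous"):
        raise ValueError(f"unknown mode {mode!r}")

    Wm = weights.matrix * gates.mask(weights.layout)
    x = state.activations.copy()
    clamped = state.clamped
    free = np.flatnonzero(~clamped)
    traj = [NetworkState(x.copy(), clamped.copy())]
    rng = np.random.default_rng(seed)

    converged = False
    prev: NDArray | None = None
    for _ in range(max_steps):
        if mode == "synchronous":
            new = _threshold(Wm @ x, x)
            new[clamped] = x[clamped]
            if prev is not None and np.array_equal(new, prev):
                # period-2 limit cycle (a synchronous-update artifact):
                # stop on the lower-energy state of the pair
                e_new = -0.5 * new @ Wm @ new
                e_x = -0.5 * x @ Wm @ x
                if e_new < e_x:
                    x = new
                    traj.append(NetworkState(x.copy(), clamped.copy()))
                break
            prev = x
            changed = not np.array_equal(new, x)
            x = new
        else:
            changed = False
            for i in rng.permutation(free):
                hi = Wm[i] @ x
                xi = _threshold(np.array(hi), np.array(x[i])).item()
                if xi != x[i]:
                    x[i] = xi
                    changed = True
                if record_updates:
                    traj.append(NetworkState(x.copy(), clamped.copy()))
        if not changed:
            # already at a fixed point: no new state to record
            converged = True
            break
        if mode == "synchronous" or not record_updates:
            traj.append(NetworkState(x.copy(), clamped.copy()))
    if not converged:
        logger.debug("settle: no fixed point within %d %s steps", max_steps, mode)
    return SettleResult(traj, converged)


# ---------------------------------------------------------------------------
# Energy functions and equality detection
# ---------------------------------------------------------------------------

def energy_total(state: NetworkState, weights: Weights) -> float:
    """Hopfield energy of the whole network, E = −½ Σ_i Σ_{j≠i} w_ij x_i x_j.

    Blank units (activation 0) contribute nothing.  The trained diagonal is
    zero, so the quadratic form needs no diagonal correction.
    """
    x = state.activations
    return float(-0.5 * x @ weights.matrix @ x)


def energy_cross(state: NetworkState, weights: Weights, k: int, kp: int) -> float:
    """Hopfield energy restricted to the synapses between partitions ``k``
    and ``kp`` (both directed blocks; no ½ factor).

    Low (strongly negative) precisely when the two slots hold pieces of the
    same stored global pattern.  Computed on the stored weights, independent
    of the current gate configuration.
    """
    if k == kp:
        raise ValueError("energy_cross requires two distinct partitions")
    sk = weights.layout.slice_of(k)
    sp = weights.layout.slice_of(kp)
    xk, xp = state.activations[sk], state.activations[sp]
    W_pk = weights.matrix[sp, sk]   # onto kp from k
    W_kp = weights.matrix[sk, sp]   # onto k from kp
    return float(-(xp @ W_pk @ xk) - (xk @ W_kp @ xp))


def partition_pairs(n_partitions: int) -> list[tuple[int, int]]:
    """Canonical ordering of the K(K−1)/2 unordered partition pairs."""
    return [(k, kp) for k in range(n_partitions) for kp in range(k + 1, n_partitions)]


@dataclass(frozen=True)
class EqualityConfig:
    """Calibrated per-pair thresholds for the equality-detection neurons.

    ``eq_kk' = 1 iff E_kk' < thresholds[(k, k')]``.  The calibration record
    keeps, per pair, the mean matched-pair and mean mismatched-pair cross
    energies over the calibration vocabulary and the separation margin.
    """

    layout: PartitionLayout
    thresholds: dict[tuple[int, int], float]
    matched_means: dict[tuple[int, int], float]
    mismatched_means: dict[tuple[int, int], float]

    def margin(self, pair: tuple[int, int]) -> float:
        return self.mismatched_means[pair] - self.matched_means[pair]


def calibrate_equality(vocab: SymbolVocabulary, weights: Weights) -> EqualityConfig:
    """Set each pair's equality threshold at the midpoint between the mean
    matched-symbol and mean mismatched-symbol cross energies.

    The cross energy between slots holding pieces of the *same* global
    attractor sits far below the near-zero energies of mismatched pieces, so
    the midpoint separates the two populations with a wide margin whenever
    the load is reasonable.
    """
    if vocab.n_symbols < 2:
        raise CalibrationError("equality calibration needs at least 2 symbols")
    layout = vocab.layout
    thresholds: dict[tuple[int, int], float] = {}
    matched: dict[tuple[int, int], float] = {}
    mismatched: dict[tuple[int, int], float] = {}
    for k, kp in partition_pairs(layout.n_partitions):
        Pk = vocab.pieces(k)          # (L, N_k)
        Pp = vocab.pieces(kp)         # (L, N_kp)
        W_pk = weights.block(kp, k)
        # E[l, lp] = cross energy with slot k holding l and slot kp holding lp
        E = -2.0 * (Pk @ W_pk.T @ Pp.T)
        m = float(np.mean(np.diag(E)))
        off = E[~np.eye(len(E), dtype=bool)]
        mm = float(np.mean(off))
        if mm - m <= 0:
            raise CalibrationError(
                f"matched and mismatched cross energies do not separate on pair "
                f"({k}, {kp}); use larger partitions or fewer symbols"
            )
        thresholds[(k, kp)] = 0.5 * (m + mm)
        matched[(k, kp)] = m
        mismatched[(k, kp)] = mm
    return EqualityConfig(layout, thresholds, matched, mismatched)


def equality_readout(
    state: NetworkState, weights: Weights, eqcfg: EqualityConfig
) -> dict[tuple[int, int], int]:
    """State of every equality-detection neuron: for each unordered pair,
    1 iff the pair's cross energy is below its calibrated threshold.

    A blank partition has zero cross energy against every partner, which lies
    above the (negative) thresholds, so blanks never read as equal.
    """
    if eqcfg.layout != weights.layout:
        raise ValueError("equality config was calibrated for a different layout")
    return {
        pair: int(energy_cross(state, weights, *pair) < eqcfg.thresholds[pair])
        for pair in partition_pairs(weights.layout.n_partitions)
    }


def active_pairs(eq: dict[tuple[int, int], int]) -> set[tuple[int, int]]:
    """Unordered pairs whose equality neuron is firing."""
    return {pair for pair, bit in eq.items() if bit}


# ---------------------------------------------------------------------------
# Slot operations
# ---------------------------------------------------------------------------

def set_slot(
    state: NetworkState, k: int, symbol: str, vocab: SymbolVocabulary
) -> NetworkState:
    """Overwrite partition ``k`` with the symbol's piece; other slots untouched."""
    new = state.copy()
    new.activations[vocab.layout.slice_of(k)] = vocab.piece(symbol, k)
    return new


def blank_slot(state: NetworkState, k: int, layout: PartitionLayout) -> NetworkState:
    """Blank partition ``k`` (all activations 0: no drive onto any unit)."""
    new = state.copy()
    new.activations[layout.slice_of(k)] = BLANK
    return new


def decode_slot(
    state: NetworkState,
    k: int,
    vocab: SymbolVocabulary,
    min_overlap: float = DEFAULT_DECODE_OVERLAP,
) -> str | None:
    """Symbolic interpretation of a slot's activation, or ``None``.

    Returns the symbol whose piece has the highest normalized overlap
    ``(x_k · P_k^l) / N_k`` with the slot, provided it reaches
    ``min_overlap``; ties break toward the earlier vocabulary entry.  This is
    a readout/logging device — the network dynamics never consult it.
    """
    if not 0.0 < min_overlap <= 1.0:
        raise ValueError("min_overlap must be in (0, 1]")
    if vocab.n_symbols == 0:
        return None
    xk = state.activations[vocab.layout.slice_of(k)]
    overlaps = vocab.pieces(k) @ xk / vocab.layout.partition_sizes[k]
    best = int(np.argmax(overlaps))
    return vocab.symbols[best] if overlaps[best] >= min_overlap else None


def slot_overlap(
    state: NetworkState, k: int, symbol: str, vocab: SymbolVocabulary
) -> float:
    """Normalized overlap of slot ``k`` with one symbol's piece."""
    xk = state.activations[vocab.layout.slice_of(k)]
    return float(vocab.piece(symbol, k) @ xk / vocab.layout.partition_sizes[k])


def transfer(
    state: NetworkState,
    weights: Weights,
    gates: GateMatrix,
    k: int,
    kp: int,
    steps: int = DEFAULT_TRANSFER_STEPS,
    record: list[NetworkState] | None = None,
) -> NetworkState:
    """Transfer the symbol held in slot ``k`` into slot ``kp``.

    Blanks the target, clamps the source, momentarily opens the directed
    synapse block k→kp (with the target's within-slot synapses on), and lets
    the target evolve toward the joint attractor — pattern completion pulls
    the target onto the *same global attractor* piece, whatever symbol the
    source holds.  Afterwards the cross-block is gated off again; the
    target's within-slot gate stays on, holding the result.

    ``gates`` is updated in place to reflect the post-transfer configuration.
    ``record``, if given, receives a copy of the state after each settle step.
    """
    if k == kp:
        raise ValueError("transfer requires distinct source and target slots")
    sk = weights.layout.slice_of(k)
    if not np.any(state.activations[sk]):
        raise DpaanError(f"transfer from blank slot {k}: nothing to transfer")

    work = blank_slot(state, kp, weights.layout)
    work.clamped = state.clamped.copy()
    work.clamped[sk] = True

    gates.set_gate(k, kp, True)
    gates.set_gate(kp, kp, True)
    result = settle(work, weights, gates, mode="synchronous", max_steps=steps)
    gates.set_gate(k, kp, False)
    if not result.converged:
        logger.warning("transfer %d->%d did not converge within %d steps", k, kp, steps)
    if record is not None:
        record.extend(s.copy() for s in result.states[1:])

    out = result.final.copy()
    out.clamped = state.clamped.copy()
    return out
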