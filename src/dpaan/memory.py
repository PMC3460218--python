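"""Declarative memory: chunk storage and cue-based slot completion.

A declarative chunk is a mapping from DM slot names to symbols — e.g. the
count-order fact {IsA: count-order, first: three, second: four}.  Chunks are
stored as concatenated pattern pieces over the designated DM partitions.
Retrieval completes the blanked DM slots from the non-blank ones by nearest
match: the stored vector with the highest mean per-slot normalized overlap
against the cue wins (earliest stored on ties), and its pieces overwrite the
blank slots only.  The default backend is an explicit lookup table; the same
chunks could equally live in a second set of attractor weights over the DM
partitions, which the store can also build for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DpaanError,
    NetworkState,
    PartitionLayout,
    SymbolVocabulary,
)


class RetrievalError(DpaanError):
    """Declarative retrieval attempted with no usable cue or empty store."""


@dataclass(frozen=True)
class DMChunk:
    """One declarative fact: DM slot name → symbol name."""

    slots: dict[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "slots", dict(self.slots))


@dataclass
class DMStore:
    """Stored chunk vectors over the DM partitions.

    ``slot_map`` maps DM slot names to partition indices (ordered); each row
    of ``vectors`` is one chunk's pieces concatenated in slot_map order.
    """

    slot_map: dict[str, int]
    chunks: list[DMChunk]
    vectors: np.ndarray
    backend: str = "lookup"
    weights: np.ndarray | None = None   # attractor backend only

    @property
    def dm_partitions(self) -> list[int]:
        return list(self.slot_map.values())

    def __len__(self) -> int:
        return len(self.chunks)


def dm_store(
    chunks: list[DMChunk],
    vocab: SymbolVocabulary,
    dm_slots: dict[str, int],
    backend: str = "lookup",
) -> DMStore:
    """Encode each chunk as its concatenated DM-partition pieces.

    Every chunk must cover exactly the declared DM slots with symbols from
    the vocabulary.  Duplicate chunks are all stored; retrieval ties break
    toward the earlier stored vector.
    """
    if not chunks:
        raise RetrievalError("cannot build a DM store from an empty chunk list")
    if backend not in ("lookup", "attractor"):
        raise ValueError(f"unknown DM backend {backend!r}")
    slot_names = list(dm_slots)
    rows = []
    for chunk in chunks:
        if set(chunk.slots) != set(slot_names):
            raise ValueError(
                f"chunk {chunk.name or chunk.slots!r} must cover exactly the DM "
                f"slots {slot_names}"
            )
        rows.append(
            np.concatenate([
                vocab.piece(chunk.slots[name], dm_slots[name]) for name in slot_names
            ])
        )
    vectors = np.array(rows)
    weights = None
    if backend == "attractor":
        # second synaptic matrix over the DM partitions, outer-product rule
        n_dm = vectors.shape[1]
        weights = (vectors.T @ vectors) / n_dm
        np.fill_diagonal(weights, 0.0)
    return DMStore(dict(dm_slots), list(chunks), vectors, backend, weights)


def _dm_slices(store: DMStore, layout: PartitionLayout) -> dict[str, tuple[slice, slice]]:
    """Per DM slot: (slice into the global vector, slice into a store row)."""
    out: dict[str, tuple[slice, slice]] = {}
    off = 0
    for name, k in store.slot_map.items():
        size = layout.partition_sizes[k]
        out[name] = (layout.slice_of(k), slice(off, off + size))
        off += size
    return out


def dm_retrieve(
    state: NetworkState,
    store: DMStore,
    vocab: SymbolVocabulary,
) -> NetworkState:
    """Fill the blank DM slots from the closest stored chunk.

    Similarity is the mean per-slot normalized overlap between the cue (the
    non-blank DM slots) and the stored vector; blank slots carry no vote.
    The winner's pieces overwrite blank DM slots only; non-blank DM slots and
    all non-DM partitions are left untouched.
    """
    if len(store) == 0:
        raise RetrievalError("DM store is empty")
    layout = vocab.layout
    slices = _dm_slices(store, layout)

    cue_slots = [
        name for name, (gsl, _) in slices.items() if np.any(state.activations[gsl])
    ]
    if not cue_slots:
        raise RetrievalError("all DM slots are blank: no retrieval cue")

    if store.backend == "attractor":
        return _retrieve_attractor(state, store, slices, cue_slots)

    sims = np.zeros(len(store))
    for name in cue_slots:
        gsl, rsl = slices[name]
        xk = state.activations[gsl]
        size = layout.partition_sizes[store.slot_map[name]]
        sims += store.vectors[:, rsl] @ xk / size
    sims /= len(cue_slots)
    winner = int(np.argmax(sims))   # argmax takes the earliest on exact ties

    new = state.copy()
    for name, (gsl, rsl) in slices.items():
        if name not in cue_slots:
            new.activations[gsl] = store.vectors[winner, rsl]
    return new


def _retrieve_attractor(state, store, slices, cue_slots, max_steps: int = 50):
    """Experimental completion via the store's own attractor weights:
    synchronous sign dynamics on the concatenated DM vector with the cue
    slots clamped."""
    x = np.concatenate([state.activations[gsl] for gsl, _ in slices.values()])
    clamped = np.zeros(len(x), dtype=bool)
    for name, (_, rsl) in slices.items():
        if name in cue_slots:
            clamped[rsl] = True
    for _ in range(max_steps):
        h = store.weights @ x
        new = np.where(h > 0, 1.0, np.where(h < 0, -1.0, x))
        new[clamped] = x[clamped]
        if np.array_equal(new, x):
            break
        x = new
    out = state.copy()
    for name, (gsl, rsl) in slices.items():
        if name not in cue_slots:
            out.activations[gsl] = x[rsl]
    return out
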