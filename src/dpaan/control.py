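"""Symbol detectors, production-rule neurons and action execution.

The control layer reads two binary populations off the network — equality
detection neurons (one per unordered slot pair) and symbol detection neurons
(perceptrons matching a specific symbol in a specific slot) — and implements
each production rule as a single linear thresholded neuron over them.
Synapse weights are +1 (required condition) or −1 (veto); a rule fires when
its signed sum reaches its integer threshold.  A fired rule's actions
overwrite slots, trigger slot-to-slot transfers, or request a
declarative-memory retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_TRANSFER_STEPS,
    GateMatrix,
    NetworkState,
    SymbolVocabulary,
    Weights,
    set_slot,
    slot_overlap,
    transfer,
)

DEFAULT_SD_THRESHOLD = 0.9


@dataclass(frozen=True)
class SymbolDetector:
    """Perceptron firing when slot ``partition`` holds ``symbol``'s piece
    with normalized overlap at least ``threshold``."""

    partition: int
    symbol: str
    threshold: float = DEFAULT_SD_THRESHOLD


def symbol_detection(
    state: NetworkState,
    vocab: SymbolVocabulary,
    detectors: list[SymbolDetector] | tuple[SymbolDetector, ...],
) -> np.ndarray:
    """One bit per detector.  A blank slot has zero overlap with every piece
    and can never trigger a detector."""
    bits = np.zeros(len(detectors), dtype=int)
    for i, det in enumerate(detectors):
        if not 0 <= det.partition < vocab.layout.n_partitions:
            raise IndexError(f"detector references partition {det.partition}")
        ov = slot_overlap(state, det.partition, det.symbol, vocab)
        bits[i] = int(ov >= det.threshold)
    return bits


# ---------------------------------------------------------------------------
# Actions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetSlot:
    """Overwrite a slot with a named symbol's piece."""

    slot: int
    symbol: str


@dataclass(frozen=True)
class Transfer:
    """Slot-to-slot semantic transfer (source → target)."""

    source: int
    target: int


@dataclass(frozen=True)
class DMTrigger:
    """Request a declarative-memory retrieval.

    ``blank_slots`` names the DM partitions the retrieval request asks to be
    filled in: they are blanked before the retrieval so the store completes
    them from the remaining (cue) slots.  When ``None``, only DM slots that
    currently decode to no symbol are blanked.
    """

    blank_slots: tuple[int, ...] | None = None


Action = SetSlot | Transfer | DMTrigger


# ---------------------------------------------------------------------------
# Production rules
# ---------------------------------------------------------------------------

#: rule input referencing an equality neuron: ("eq", k, k') with k < k'
#: rule input referencing a symbol detector: ("sd", k, symbol)
RuleInput = tuple


@dataclass(frozen=True)
class RuleSpec:
    """A production: a thresholded neuron over Eq/SD inputs plus actions.

    ``inputs`` is a list of ``(ref, weight)`` where ``ref`` is
    ``("eq", k, k')`` or ``("sd", k, symbol)`` and weight is +1 or −1.
    Negative weights are vetoes only: the positive weights alone must be able
    to reach ``threshold``.  ``halt`` marks the rule whose firing stops a
    run loop (its neuron output is otherwise unwired).
    """

    name: str
    inputs: tuple[tuple[RuleInput, int], ...]
    threshold: int
    actions: tuple[Action, ...] = ()
    halt: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple((tuple(r), int(w)) for r, w in self.inputs))
        object.__setattr__(self, "actions", tuple(self.actions))
        if self.threshold < 1:
            raise ValueError(f"rule {self.name!r}: threshold must be >= 1")
        if not self.inputs:
            raise ValueError(f"rule {self.name!r}: needs at least one input")
        for ref, w in self.inputs:
            if w not in (1, -1):
                raise ValueError(f"rule {self.name!r}: weights must be +1 or -1")
            if ref[0] not in ("eq", "sd"):
                raise ValueError(f"rule {self.name!r}: unknown input kind {ref[0]!r}")
        pos = sum(w for _, w in self.inputs if w > 0)
        if pos < self.threshold:
            raise ValueError(
                f"rule {self.name!r}: positive inputs sum to {pos} < threshold "
                f"{self.threshold}; negative weights may only act as vetoes"
            )

    def net_input(
        self, eq: dict[tuple[int, int], int], sd: dict[tuple[int, str], int]
    ) -> int:
        total = 0
        for ref, w in self.inputs:
            if ref[0] == "eq":
                k, kp = int(ref[1]), int(ref[2])
                pair = (k, kp) if k < kp else (kp, k)
                total += w * eq[pair]
            else:
                total += w * sd[(int(ref[1]), str(ref[2]))]
        return total


def rule_detectors(
    rules: list[RuleSpec] | tuple[RuleSpec, ...],
    threshold: float = DEFAULT_SD_THRESHOLD,
) -> list[SymbolDetector]:
    """The symbol detectors a rule set needs, in first-reference order."""
    seen: dict[tuple[int, str], SymbolDetector] = {}
    for rule in rules:
        for ref, _ in rule.inputs:
            if ref[0] == "sd":
                key = (int(ref[1]), str(ref[2]))
                seen.setdefault(key, SymbolDetector(key[0], key[1], threshold))
    return list(seen.values())


def sd_states(
    state: NetworkState,
    vocab: SymbolVocabulary,
    detectors: list[SymbolDetector],
) -> dict[tuple[int, str], int]:
    """Detector states keyed by (partition, symbol)."""
    bits = symbol_detection(state, vocab, detectors)
    return {(d.partition, d.symbol): int(b) for d, b in zip(detectors, bits)}


def evaluate_productions(
    rules: list[RuleSpec] | tuple[RuleSpec, ...],
    eq: dict[tuple[int, int], int],
    sd: dict[tuple[int, str], int],
) -> str | None:
    """Conflict-resolved match: name of the winning fired rule, or ``None``.

    A rule fires when its signed net input reaches its threshold.  Among
    fired rules the highest net input wins; ties break by definition order.
    Pure function of its arguments.
    """
    best: tuple[int, int] | None = None   # (net, -index), max wins
    best_name = None
    for idx, rule in enumerate(rules):
        net = rule.net_input(eq, sd)
        if net >= rule.threshold:
            key = (net, -idx)
            if best is None or key > best:
                best, best_name = key, rule.name
    return best_name


def production_nets(
    rules: list[RuleSpec] | tuple[RuleSpec, ...],
    eq: dict[tuple[int, int], int],
    sd: dict[tuple[int, str], int],
) -> dict[str, int]:
    """Net input of every production neuron (for traces/reports)."""
    return {rule.name: rule.net_input(eq, sd) for rule in rules}


def execute_actions(
    state: NetworkState,
    weights: Weights,
    gates: GateMatrix,
    vocab: SymbolVocabulary,
    actions: tuple[Action, ...] | list[Action],
    transfer_steps: int = DEFAULT_TRANSFER_STEPS,
    record: list[NetworkState] | None = None,
) -> tuple[NetworkState, DMTrigger | None]:
    """Apply a fired rule's actions.

    Slot sets are applied first (a set must not be disturbed by a concurrent
    transfer's settling), then transfers in their listed order, each a full
    blank–gate–settle transfer.  A DM trigger is not executed here; it is
    returned for the runtime to schedule the retrieval phase.
    """
    dm_request: DMTrigger | None = None
    for action in actions:
        if isinstance(action, SetSlot):
            state = set_slot(state, action.slot, action.symbol, vocab)
    for action in actions:
        if isinstance(action, Transfer):
            state = transfer(
                state, weights, gates, action.source, action.target,
                steps=transfer_steps, record=record,
            )
        elif isinstance(action, DMTrigger):
            dm_request = action
    return state, dm_request
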