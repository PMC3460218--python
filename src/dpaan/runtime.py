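"""Match–execute production-cycle runtime and the built-in Count Model.

Each cycle mirrors the four phases of an ACT-R-style production system run
on the partitioned attractor network:

1. *matching*: the network settles under within-slot gates only, then the
   equality and symbol-detection neurons are read and the production neurons
   evaluated;
2. *execution*: the winning production's slot sets and transfers run (each
   transfer gets a fixed settle budget);
3. *retrieval* (if requested): the retrieval-request DM slots are blanked
   and held for a few steps, the declarative store completes them from the
   remaining cue slots;
4. *post-retrieval*: a short settle before the next match.

The built-in Count Model counts from a start number to an end number using
three productions (start / increment / stop) over a 7-slot network — four
goal slots (IsA, start, end, count) and three declarative-memory slots
(IsA, first, second) — and seven count-order facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .control import (
    DMTrigger,
    RuleSpec,
    SetSlot,
    Transfer,
    evaluate_productions,
    execute_actions,
    production_nets,
    rule_detectors,
    sd_states,
)
from .core import (
    EqualityConfig,
    GateMatrix,
    NetworkState,
    PartitionLayout,
    SymbolVocabulary,
    Weights,
    active_pairs,
    blank_slot,
    build_vocabulary,
    calibrate_equality,
    decode_slot,
    equality_readout,
    hopfield_train,
    settle,
)
from .memory import DMChunk, DMStore, dm_retrieve, dm_store

NUMBER_ORDER = ("one", "two", "three", "four", "five", "six", "seven", "eight")
COUNT_MODEL_SYMBOLS = NUMBER_ORDER + ("count-from", "count-order", "nil")


@dataclass(frozen=True)
class CycleSchedule:
    """Step budgets of one match–execute cycle (simulated time steps)."""

    pre_match_steps: int = 10
    transfer_steps: int = 40
    blank_steps: int = 5
    post_retrieval_steps: int = 5
    max_cycles: int = 30

    def __post_init__(self) -> None:
        for name in ("pre_match_steps", "transfer_steps", "blank_steps",
                     "post_retrieval_steps", "max_cycles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ModelDefinition:
    """A complete runnable model: network geometry, vocabulary, declarative
    chunks, initial slot contents and production rules.

    ``slot_names`` maps human slot names bijectively onto partition indices;
    ``dm_slots`` is the subset serving the declarative-memory module.
    ``initial`` assigns a starting symbol to (some) slots by name.
    """

    name: str
    layout: PartitionLayout
    slot_names: dict[str, int]
    symbols: tuple[str, ...]
    chunks: tuple[DMChunk, ...]
    dm_slots: dict[str, int]
    initial: dict[str, str]
    rules: tuple[RuleSpec, ...]
    schedule: CycleSchedule = CycleSchedule()
    coding_level: float = 0.5

    def __post_init__(self) -> None:
        K = self.layout.n_partitions
        vals = list(self.slot_names.values())
        if sorted(vals) != list(range(K)):
            raise ValueError("slot names must map bijectively onto partitions 0..K-1")
        for slot, sym in self.initial.items():
            if slot not in self.slot_names:
                raise ValueError(f"initial assignment references unknown slot {slot!r}")
            if sym not in self.symbols:
                raise ValueError(f"initial symbol {sym!r} not in vocabulary")

    def partition(self, slot: str) -> int:
        return self.slot_names[slot]


@dataclass
class NetworkBundle:
    """Everything derived from a model + seed: vocabulary, trained weights,
    calibrated equality thresholds, DM store, gates and initial state."""

    vocab: SymbolVocabulary
    weights: Weights
    eqcfg: EqualityConfig
    store: DMStore | None
    gates: GateMatrix
    state: NetworkState


@dataclass
class RunTrace:
    """Full record of a run: activity raster plus structured events.

    ``raster`` holds one length-N activation vector per simulated time step;
    ``events`` are ordered records (cycle summaries, gate changes, fired
    rules, decoded slots, equality states) each stamped with the raster row
    index ``t`` it refers to.
    """

    raster: list[np.ndarray] = field(default_factory=list)
    events: list[dict[str, Any]] = field(default_factory=list)
    config: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def raster_array(self) -> np.ndarray:
        return np.array(self.raster) if self.raster else np.zeros((0, 0))

    def fired_rules(self) -> list[str | None]:
        return [e["fired"] for e in self.events if e.get("kind") == "cycle"]

    def count_fired(self, name: str) -> int:
        return sum(1 for r in self.fired_rules() if r == name)


# ---------------------------------------------------------------------------
# Count Model definition
# ---------------------------------------------------------------------------

def count_order_chunks() -> tuple[DMChunk, ...]:
    """The seven successor facts one→two … seven→eight."""
    return tuple(
        DMChunk(
            {"IsA": "count-order", "first": NUMBER_ORDER[i], "second": NUMBER_ORDER[i + 1]},
            name=f"{NUMBER_ORDER[i]}-{NUMBER_ORDER[i + 1]}",
        )
        for i in range(len(NUMBER_ORDER) - 1)
    )


def build_count_model(
    start: str = "two",
    end: str = "seven",
    slot_size: int = 100,
    schedule: CycleSchedule | None = None,
) -> ModelDefinition:
    """The Count Model: count aloud from ``start`` to ``end``.

    Seven slots: goal IsA/start/end/count on partitions 0–3 and DM
    IsA/first/second on partitions 4–6.  Three productions:

    * **start** — goal IsA holds "count-from" and count holds "nil"
      (threshold 2): set DM IsA to "count-order", transfer start→count and
      start→DM-first, request a retrieval of DM-second.
    * **increment** — goal IsA "count-from", DM IsA "count-order", count
      equals DM-first, *and* count differs from end (a −1 veto from the
      end/count equality neuron; threshold 3): transfer DM-second→count and
      DM-second→DM-first, request a retrieval of DM-second.
    * **stop** — goal IsA "count-from" and count equals end (threshold 2):
      halts the run.
    """
    if start not in NUMBER_ORDER or end not in NUMBER_ORDER:
        raise ValueError(f"start and end must be among {NUMBER_ORDER}")
    if NUMBER_ORDER.index(start) >= NUMBER_ORDER.index(end):
        raise ValueError(f"start {start!r} must come before end {end!r}")

    slot_names = {
        "goal-IsA": 0, "start": 1, "end": 2, "count": 3,
        "dm-IsA": 4, "first": 5, "second": 6,
    }
    dm_slots = {"IsA": 4, "first": 5, "second": 6}

    rules = (
        RuleSpec(
            name="start",
            inputs=((("sd", 0, "count-from"), 1), (("sd", 3, "nil"), 1)),
            threshold=2,
            actions=(
                SetSlot(4, "count-order"),
                Transfer(1, 3),
                Transfer(1, 5),
                DMTrigger(blank_slots=(6,)),
            ),
        ),
        RuleSpec(
            name="increment",
            inputs=(
                (("sd", 0, "count-from"), 1),
                (("sd", 4, "count-order"), 1),
                (("eq", 2, 3), -1),
                (("eq", 3, 5), 1),
            ),
            threshold=3,
            actions=(
                Transfer(6, 3),
                Transfer(6, 5),
                DMTrigger(blank_slots=(6,)),
            ),
        ),
        RuleSpec(
            name="stop",
            inputs=((("sd", 0, "count-from"), 1), (("eq", 2, 3), 1)),
            threshold=2,
            halt=True,
        ),
    )
    return ModelDefinition(
        name="count",
        layout=PartitionLayout((slot_size,) * 7),
        slot_names=slot_names,
        symbols=COUNT_MODEL_SYMBOLS,
        chunks=count_order_chunks(),
        dm_slots=dm_slots,
        initial={
            "goal-IsA": "count-from", "start": start, "end": end, "count": "nil",
            "dm-IsA": "nil", "first": "nil", "second": "nil",
        },
        rules=rules,
        schedule=schedule or CycleSchedule(),
    )


# ---------------------------------------------------------------------------
# Network assembly and the cycle
# ---------------------------------------------------------------------------

def build_network(model: ModelDefinition, seed: int) -> NetworkBundle:
    """Instantiate a model: seeded vocabulary, Hopfield training, equality
    calibration, DM store and the initial slot contents."""
    vocab = build_vocabulary(model.layout, list(model.symbols), model.coding_level, seed)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")   # near-capacity load is the model's choice
        weights = hopfield_train(vocab)
    eqcfg = calibrate_equality(vocab, weights)
    store = dm_store(list(model.chunks), vocab, model.dm_slots) if model.chunks else None
    gates = GateMatrix.within_only(model.layout.n_partitions)
    state = NetworkState.blank(model.layout)
    for slot, sym in model.initial.items():
        state.activations[model.layout.slice_of(model.partition(slot))] = vocab.piece(
            sym, model.partition(slot)
        )
    return NetworkBundle(vocab, weights, eqcfg, store, gates, state)


#: confidence floor for the *trace* readout.  Event logs report the nearest
#: symbol whenever it is clearly above chance overlap (distinct random pieces
#: overlap near 0): at loads near the isolated-slot capacity a held piece can
#: transiently drift below the stricter default decode confidence while the
#: energy-based equality neurons and transfers still treat it as its symbol.
TRACE_DECODE_OVERLAP = 0.5


def _decode_all(model: ModelDefinition, state: NetworkState, vocab: SymbolVocabulary):
    return {
        slot: decode_slot(state, k, vocab, min_overlap=TRACE_DECODE_OVERLAP)
        for slot, k in model.slot_names.items()
    }


def run_cycle(
    model: ModelDefinition,
    state: NetworkState,
    weights: Weights,
    gates: GateMatrix,
    eqcfg: EqualityConfig,
    store: DMStore | None,
    schedule: CycleSchedule | None = None,
    vocab: SymbolVocabulary | None = None,
    record: list[np.ndarray] | None = None,
) -> tuple[NetworkState, dict[str, Any]]:
    """One match–execute cycle; returns the new state and an event record."""
    sched = schedule or model.schedule
    if vocab is None:
        raise ValueError("run_cycle needs the vocabulary for detectors/decoding")

    def rec(states) -> None:
        if record is not None:
            record.extend(s.activations.copy() for s in states)

    # matching phase: settle under the current (within-slot) gating
    res = settle(state, weights, gates, max_steps=sched.pre_match_steps)
    # hold for the full budget so the raster timing matches the schedule
    pad = sched.pre_match_steps - (len(res.states) - 1)
    rec(res.states[1:])
    rec([res.final] * pad)
    state = res.final

    eq = equality_readout(state, weights, eqcfg)
    detectors = rule_detectors(model.rules)
    sd = sd_states(state, vocab, detectors)
    nets = production_nets(model.rules, eq, sd)
    fired = evaluate_productions(model.rules, eq, sd)
    event: dict[str, Any] = {
        "kind": "cycle",
        "fired": fired,
        "nets": nets,
        "eq_active": [[k, kp] for k, kp in sorted(active_pairs(eq))],
        "slots": _decode_all(model, state, vocab),
        "halted": False,
    }

    if fired is None:
        return state, event
    rule = next(r for r in model.rules if r.name == fired)
    if rule.halt:
        event["halted"] = True
        return state, event

    # execution phase
    xfer_record: list[NetworkState] = [] if record is not None else None  # type: ignore
    state, dm_request = execute_actions(
        state, weights, gates, vocab, rule.actions,
        transfer_steps=sched.transfer_steps, record=xfer_record,
    )
    if record is not None:
        rec(xfer_record)

    # retrieval phase
    if dm_request is not None and store is not None:
        if dm_request.blank_slots is not None:
            to_blank = dm_request.blank_slots
        else:
            to_blank = tuple(
                k for k in store.dm_partitions
                if decode_slot(state, k, vocab) is None
            )
        for k in to_blank:
            state = blank_slot(state, k, weights.layout)
        res = settle(state, weights, gates, max_steps=sched.blank_steps)
        pad = sched.blank_steps - (len(res.states) - 1)
        rec(res.states[1:])
        rec([res.final] * pad)
        state = dm_retrieve(res.final, store, vocab)
        retrieved = {
            name: decode_slot(state, k, vocab) for name, k in store.slot_map.items()
        }
        event["dm_retrieved"] = retrieved
        res = settle(state, weights, gates, max_steps=sched.post_retrieval_steps)
        pad = sched.post_retrieval_steps - (len(res.states) - 1)
        rec(res.states[1:])
        rec([res.final] * pad)
        state = res.final

    event["slots_after"] = _decode_all(model, state, vocab)
    return state, event


def run_model(
    model: ModelDefinition,
    seed: int = 0,
    schedule: CycleSchedule | None = None,
    network: NetworkBundle | None = None,
) -> RunTrace:
    """Run match–execute cycles until a halting production fires or the
    cycle budget runs out; returns the full activity raster and event log.

    ``network`` lets callers reuse an already-built network (the vocabulary
    depends only on the model layout/symbols and the seed).
    """
    sched = schedule or model.schedule
    net = network or build_network(model, seed)
    state = net.state.copy()
    trace = RunTrace(seed=seed, config={
        "model": model.name,
        "layout": list(model.layout.partition_sizes),
        "symbols": list(model.symbols),
        "initial": dict(model.initial),
        "schedule": {
            "pre_match_steps": sched.pre_match_steps,
            "transfer_steps": sched.transfer_steps,
            "blank_steps": sched.blank_steps,
            "post_retrieval_steps": sched.post_retrieval_steps,
            "max_cycles": sched.max_cycles,
        },
    })
    trace.raster.append(state.activations.copy())

    halted = False
    for cycle in range(sched.max_cycles):
        state, event = run_cycle(
            model, state, net.weights, net.gates, net.eqcfg, net.store,
            schedule=sched, vocab=net.vocab, record=trace.raster,
        )
        event["cycle"] = cycle
        event["t"] = len(trace.raster) - 1
        trace.events.append(event)
        if event["halted"]:
            halted = True
            break
        if event["fired"] is None:
            break
    if not halted:
        trace.events.append({
            "kind": "end", "t": len(trace.raster) - 1,
            "reason": "no-rule-fired" if trace.events and trace.events[-1]["fired"] is None
            else "max-cycles-exhausted",
        })
    return trace
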