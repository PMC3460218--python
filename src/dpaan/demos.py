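"""The three reference simulations, plus trace export.

* **binding demo** — a five-slot network (color #1, shape #1, color #2,
  shape #2, vocalization) showing that opening a single synapse block
  transfers a symbol between slots while the equality neurons track semantic
  identity across slots: the classic two-object binding scenario (a red
  circle and a red square) without superposition ambiguity.
* **jealousy demo** — a six-slot network and one production implementing the
  syntax-sensitive rule "if A loves B, B loves C, and A is not C, then A is
  jealous of C", including the mutual-love veto.
* **count demo** — the full production-system Count Model run.

Traces export as plain text: a raster (one row per time step, one column per
neuron, 1 = active, 0 = inactive, ``-`` = blank) plus JSON-lines events and
a JSON config snapshot; the round trip reloads to an equal trace.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .control import RuleSpec, SymbolDetector, Transfer, evaluate_productions, \
    rule_detectors, sd_states
from .core import (
    ACTIVE,
    BLANK,
    GateMatrix,
    INACTIVE,
    NetworkState,
    PartitionLayout,
    active_pairs,
    build_vocabulary,
    calibrate_equality,
    decode_slot,
    equality_readout,
    hopfield_train,
    settle,
    transfer,
)
from .runtime import RunTrace, build_count_model, build_network, run_model

BLANK_MARKER = "-"

BINDING_SYMBOLS = ("red", "blue", "square", "circle")
JEALOUSY_SYMBOLS = ("John", "Mary", "Sam", "Leela", "Fry", "Zap", "Kif", "Amy", "who")
#: slot contents (A, B, B, C, A, "who") instantiate the rule "if A loves B,
#: B loves C, and A is not C, then A is jealous of C"
JEALOUSY_TRIANGLE_SCENARIO = ("John", "Mary", "Mary", "Sam", "John", "who")
JEALOUSY_MUTUAL_SCENARIO = ("John", "Mary", "Mary", "John", "John", "who")


def _pairs_1based(pairs) -> list[list[int]]:
    return sorted([k + 1, kp + 1] for k, kp in pairs)


# ---------------------------------------------------------------------------
# Demo 1: perceptual binding / slot-to-slot transfer
# ---------------------------------------------------------------------------

def run_binding_demo(
    seed: int = 0, slot_size: int = 100, steps: int = 40
) -> tuple[RunTrace, dict[str, Any]]:
    """Transfer "red" from the color-1 slot into the vocalization slot.

    Five slots of ``slot_size`` neurons; symbols red/blue/square/circle;
    initial contents X1=red, X2=circle, X3=red, X4=square, X5 blank.  All
    cross-slot synapse blocks are masked off except X1→X5, so the network
    holds slots 1–4 on their attractors while attractor completion fills X5
    with the piece of "red".  The report gives the equality-neuron sets
    before and after (1-based slot labels, as in the figure conventions).
    """
    layout = PartitionLayout((slot_size,) * 5)
    vocab = build_vocabulary(layout, list(BINDING_SYMBOLS), seed=seed)
    weights = hopfield_train(vocab)
    eqcfg = calibrate_equality(vocab, weights)

    state = NetworkState.blank(layout)
    for k, sym in enumerate(("red", "circle", "red", "square")):
        state.activations[layout.slice_of(k)] = vocab.piece(sym, k)

    gates = GateMatrix.within_only(5)
    gates.set_gate(0, 4, True)

    eq0 = equality_readout(state, weights, eqcfg)
    decoded0 = {k + 1: decode_slot(state, k, vocab) for k in range(5)}

    trace = RunTrace(seed=seed, config={
        "demo": "binding", "layout": list(layout.partition_sizes),
        "symbols": list(BINDING_SYMBOLS), "steps": steps,
    })
    trace.raster.append(state.activations.copy())
    res = settle(state, weights, gates, max_steps=steps)
    trace.raster.extend(s.activations.copy() for s in res.states[1:])
    final = res.final

    eq1 = equality_readout(final, weights, eqcfg)
    decoded1 = {k + 1: decode_slot(final, k, vocab) for k in range(5)}
    report = {
        "initial_eq_active": _pairs_1based(active_pairs(eq0)),
        "final_eq_active": _pairs_1based(active_pairs(eq1)),
        "initial_slots": decoded0,
        "final_slots": decoded1,
        "converged": res.converged,
    }
    trace.events.append({"kind": "report", "t": len(trace.raster) - 1, **{
        k: v for k, v in report.items() if k != "initial_slots" and k != "final_slots"
    }})
    return trace, report


# ---------------------------------------------------------------------------
# Demo 2: the Jealousy rule
# ---------------------------------------------------------------------------

def jealousy_rule() -> RuleSpec:
    """+1(Eq_1,5) +1(Eq_2,3) −1(Eq_1,4) +1(SD_6,"who"), threshold 3; on
    firing, transfer slot 4 → slot 6 (0-based: 3 → 5)."""
    return RuleSpec(
        name="jealousy",
        inputs=(
            (("eq", 0, 4), 1),
            (("eq", 1, 2), 1),
            (("eq", 0, 3), -1),
            (("sd", 5, "who"), 1),
        ),
        threshold=3,
        actions=(Transfer(3, 5),),
    )


def run_jealousy_demo(
    scenario: str | tuple[str, ...] | list[str] = "triangle",
    seed: int = 0,
    slot_size: int = 100,
    steps: int = 40,
) -> dict[str, Any]:
    """Evaluate the Jealousy rule on a six-slot network.

    ``scenario`` is "triangle" (John loves Mary, Mary loves Sam → jealous
    of Sam), "mutual" (Mary loves John back → vetoed), or a custom assignment
    of six names to the slots.  Reports whether the rule fired and the final
    decode of slot 6.
    """
    if scenario == "triangle":
        assignment = JEALOUSY_TRIANGLE_SCENARIO
    elif scenario == "mutual":
        assignment = JEALOUSY_MUTUAL_SCENARIO
    else:
        assignment = tuple(scenario)
        if len(assignment) != 6:
            raise ValueError("a custom scenario must assign all six slots")
        unknown = set(assignment) - set(JEALOUSY_SYMBOLS)
        if unknown:
            raise ValueError(f"unknown names in scenario: {sorted(unknown)}")

    layout = PartitionLayout((slot_size,) * 6)
    vocab = build_vocabulary(layout, list(JEALOUSY_SYMBOLS), seed=seed)
    weights = hopfield_train(vocab)
    eqcfg = calibrate_equality(vocab, weights)

    state = NetworkState.blank(layout)
    for k, sym in enumerate(assignment):
        state.activations[layout.slice_of(k)] = vocab.piece(sym, k)
    gates = GateMatrix.within_only(6)

    rule = jealousy_rule()
    eq = equality_readout(state, weights, eqcfg)
    sd = sd_states(state, vocab, rule_detectors([rule]))
    fired = evaluate_productions([rule], eq, sd)
    if fired == "jealousy":
        state = transfer(state, weights, gates, 3, 5, steps=steps)
    return {
        "scenario": list(assignment),
        "fired": fired == "jealousy",
        "net_input": rule.net_input(eq, sd),
        "eq_active": _pairs_1based(active_pairs(eq)),
        "slot6": decode_slot(state, 5, vocab),
        "slots": {k + 1: decode_slot(state, k, vocab) for k in range(6)},
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# Demo 3: the Count Model
# ---------------------------------------------------------------------------

def run_count_demo(
    start: str = "two",
    end: str = "seven",
    seed: int = 0,
    slot_size: int = 100,
    schedule=None,
) -> tuple[RunTrace, dict[str, Any]]:
    """Run the Count Model and summarize the symbolic behavior per cycle."""
    model = build_count_model(start, end, slot_size=slot_size, schedule=schedule)
    trace = run_model(model, seed=seed)
    cycles = [e for e in trace.events if e.get("kind") == "cycle"]
    count_sequence = []
    for e in cycles:
        slots = e.get("slots_after", e["slots"])
        if slots.get("count") is not None:
            if not count_sequence or count_sequence[-1] != slots["count"]:
                count_sequence.append(slots["count"])
    report = {
        "start": start, "end": end, "seed": seed,
        "cycles": len(cycles),
        "fired": [e["fired"] for e in cycles],
        "increment_fired": trace.count_fired("increment"),
        "count_sequence": count_sequence,
        "final_count": cycles[-1]["slots"].get("count") if cycles else None,
        "halted": bool(cycles) and cycles[-1]["halted"],
    }
    return trace, report


# ---------------------------------------------------------------------------
# Trace export / reload
# ---------------------------------------------------------------------------

def _encode_row(row: np.ndarray) -> list[str]:
    return ["1" if v > 0 else "0" if v < 0 else BLANK_MARKER for v in row]


def _decode_cell(c: str) -> float:
    return ACTIVE if c == "1" else INACTIVE if c == "0" else BLANK


def export_trace(trace: RunTrace, outdir: str | Path) -> dict[str, Path]:
    """Write ``raster.tsv`` (0/1/`-` cells), ``events.jsonl`` and
    ``config.json`` under ``outdir``; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "raster": out / "raster.tsv",
        "events": out / "events.jsonl",
        "config": out / "config.json",
    }
    with open(paths["raster"], "w") as fh:
        for row in trace.raster:
            fh.write("\t".join(_encode_row(row)) + "\n")
    with open(paths["events"], "w") as fh:
        for event in trace.events:
            fh.write(json.dumps(event, default=_jsonable) + "\n")
    with open(paths["config"], "w") as fh:
        json.dump({"seed": trace.seed, "config": trace.config}, fh,
                  indent=2, default=_jsonable)
        fh.write("\n")
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_trace(outdir: str | Path) -> RunTrace:
    """Reload an exported trace; inverse of :func:`export_trace`."""
    out = Path(outdir)
    raster = []
    with open(out / "raster.tsv") as fh:
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            raster.append(np.array([_decode_cell(c) for c in cells]))
    events = []
    with open(out / "events.jsonl") as fh:
        for line in fh:
            if line.strip():
                events.append(json.loads(line))
    with open(out / "config.json") as fh:
        snap = json.load(fh)
    return RunTrace(raster=raster, events=events,
                    config=snap["config"], seed=snap["seed"])


def plot_raster(trace: RunTrace, path: str | Path | None = None):
    """Optional white-active/black-inactive raster figure (blank = gray)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = trace.raster_array()
    img = np.where(arr > 0, 1.0, np.where(arr < 0, 0.0, 0.5))
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(img.T, aspect="auto", cmap="gray", interpolation="nearest")
    ax.set_xlabel("time step")
    ax.set_ylabel("neuron")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
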