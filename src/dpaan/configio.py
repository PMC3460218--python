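"""YAML config schema: network setup, production rules and declarative chunks.

The schema is deliberately small and round-trips bit-exactly
(parse → serialize → parse is the identity on the parsed objects):

.. code-block:: yaml

    layout: [100, 100, 100]
    symbols: [red, blue, circle]
    coding_level: 0.5
    seed: 1
    settle: {mode: synchronous, max_steps: 100}
    rules:
      - name: jealousy
        threshold: 3
        conditions:
          - {eq: [0, 4], required: true}
          - {eq: [1, 2], required: true}
          - {eq: [0, 3], required: false}   # a veto
          - {slot: 5, symbol: who}
        actions:
          - {transfer: {source: 3, target: 5}}
        halt: false
    chunks:
      - name: c
        slots: {IsA: count-order, first: three, second: four}

Conditions: ``{eq: [k, k'], required: bool}`` wires the equality neuron of
the slot pair with weight +1 (required) or −1 (forbidden / veto);
``{slot: k, symbol: s, required: bool}`` wires a symbol-detection neuron the
same way.  Actions: ``set``, ``transfer`` and ``dm_trigger`` (optionally
``{dm_trigger: {blank: [k, ...]}}`` naming the retrieval-request slots).
"""

from __future__ import annotations

from typing import Any

import yaml

from .control import DMTrigger, RuleSpec, SetSlot, Transfer
from .core import PartitionLayout
from .memory import DMChunk


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

def rule_to_dict(rule: RuleSpec) -> dict[str, Any]:
    conditions: list[dict[str, Any]] = []
    for ref, w in rule.inputs:
        if ref[0] == "eq":
            conditions.append({"eq": [int(ref[1]), int(ref[2])], "required": w > 0})
        else:
            conditions.append({"slot": int(ref[1]), "symbol": str(ref[2]),
                               "required": w > 0})
    actions: list[dict[str, Any]] = []
    for a in rule.actions:
        if isinstance(a, SetSlot):
            actions.append({"set": {"slot": a.slot, "symbol": a.symbol}})
        elif isinstance(a, Transfer):
            actions.append({"transfer": {"source": a.source, "target": a.target}})
        elif isinstance(a, DMTrigger):
            body = {} if a.blank_slots is None else {"blank": list(a.blank_slots)}
            actions.append({"dm_trigger": body})
    return {
        "name": rule.name,
        "threshold": rule.threshold,
        "conditions": conditions,
        "actions": actions,
        "halt": rule.halt,
    }


def rule_from_dict(d: dict[str, Any]) -> RuleSpec:
    inputs: list[tuple[tuple, int]] = []
    for cond in d.get("conditions", []):
        w = 1 if cond.get("required", True) else -1
        if "eq" in cond:
            k, kp = cond["eq"]
            inputs.append((("eq", int(k), int(kp)), w))
        elif "slot" in cond:
            inputs.append((("sd", int(cond["slot"]), str(cond["symbol"])), w))
        else:
            raise ValueError(f"unrecognized condition {cond!r}")
    actions: list = []
    for act in d.get("actions", []):
        if "set" in act:
            actions.append(SetSlot(int(act["set"]["slot"]), str(act["set"]["symbol"])))
        elif "transfer" in act:
            actions.append(Transfer(int(act["transfer"]["source"]),
                                    int(act["transfer"]["target"])))
        elif "dm_trigger" in act:
            body = act["dm_trigger"] or {}
            blank = body.get("blank")
            actions.append(DMTrigger(tuple(blank) if blank is not None else None))
        else:
            raise ValueError(f"unrecognized action {act!r}")
    return RuleSpec(
        name=str(d["name"]),
        inputs=tuple(inputs),
        threshold=int(d["threshold"]),
        actions=tuple(actions),
        halt=bool(d.get("halt", False)),
    )


# ---------------------------------------------------------------------------
# Chunks and whole configs
# ---------------------------------------------------------------------------

def chunk_to_dict(chunk: DMChunk) -> dict[str, Any]:
    d: dict[str, Any] = {"slots": dict(chunk.slots)}
    if chunk.name:
        d["name"] = chunk.name
    return d


def chunk_from_dict(d: dict[str, Any]) -> DMChunk:
    return DMChunk(dict(d["slots"]), name=str(d.get("name", "")))


def config_to_dict(
    layout: PartitionLayout,
    symbols: list[str] | tuple[str, ...],
    coding_level: float = 0.5,
    seed: int = 0,
    settle: dict[str, Any] | None = None,
    rules: list[RuleSpec] | tuple[RuleSpec, ...] = (),
    chunks: list[DMChunk] | tuple[DMChunk, ...] = (),
) -> dict[str, Any]:
    d: dict[str, Any] = {
        "layout": list(layout.partition_sizes),
        "symbols": list(symbols),
        "coding_level": float(coding_level),
        "seed": int(seed),
    }
    if settle:
        d["settle"] = dict(settle)
    if rules:
        d["rules"] = [rule_to_dict(r) for r in rules]
    if chunks:
        d["chunks"] = [chunk_to_dict(c) for c in chunks]
    return d


def parse_config(d: dict[str, Any]) -> dict[str, Any]:
    """Parse a config mapping into constructed objects."""
    out: dict[str, Any] = {
        "layout": PartitionLayout(tuple(d["layout"])),
        "symbols": tuple(d["symbols"]),
        "coding_level": float(d.get("coding_level", 0.5)),
        "seed": int(d.get("seed", 0)),
        "settle": dict(d.get("settle", {})),
        "rules": tuple(rule_from_dict(r) for r in d.get("rules", [])),
        "chunks": tuple(chunk_from_dict(c) for c in d.get("chunks", [])),
    }
    return out


def save_config(path, **kwargs) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(**kwargs), fh, sort_keys=False)


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh))
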