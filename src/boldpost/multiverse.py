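"""Multiverse pipeline planning with hash-based step deduplication.

A multiverse analysis runs many pipelines that differ only in a few
settings; most steps are shared.  Each step is identified by a short
letter code derived from a cryptographic digest of its canonicalized
specification (operation name, parameters, and upstream step hashes), so
identical steps across pipelines collapse onto a single graph node and
are computed once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Callable

__all__ = [
    "StepSpec",
    "PipelinePlan",
    "step_digest",
    "step_hash",
    "build_plan",
    "reuse_report",
    "execute_plan",
]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
CODE_LENGTH = 4


def _canonical(value: Any) -> Any:
    """Type-tagged canonical form, independent of dict insertion order.

    Floats are serialized via Python's shortest round-trip repr so the
    digest is stable across platforms.
    """
    if isinstance(value, dict):
        return {"t": "map", "v": sorted((str(k), _canonical(v)) for k, v in value.items())}
    if isinstance(value, (list, tuple)):
        return {"t": "seq", "v": [_canonical(v) for v in value]}
    if isinstance(value, bool):
        return {"t": "bool", "v": value}
    if isinstance(value, int):
        return {"t": "int", "v": value}
    if isinstance(value, float):
        return {"t": "float", "v": repr(value)}
    if value is None:
        return {"t": "null"}
    return {"t": "str", "v": str(value)}


@dataclass(frozen=True)
class StepSpec:
    """One processing step: operation name, parameters, upstream hashes.

    The upstream list is ordered (inputs are positional); the parameter
    mapping is canonicalized, so insertion order never matters.
    """

    operation: str
    params: tuple = ()
    upstream: tuple[str, ...] = ()

    @classmethod
    def make(cls, operation: str, params: dict | None = None,
             upstream: tuple[str, ...] = ()) -> "StepSpec":
        items = tuple(sorted((params or {}).items()))
        return cls(operation=operation, params=items, upstream=tuple(upstream))

    def canonical_serialization(self) -> str:
        payload = {
            "operation": self.operation,
            "params": _canonical(dict(self.params)),
            "upstream": list(self.upstream),
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def step_digest(step: StepSpec) -> str:
    """Full SHA-256 digest of the step's canonical serialization."""
    return hashlib.sha256(step.canonical_serialization().encode()).hexdigest()


def _digest_to_letters(digest: str, length: int) -> str:
    number = int(digest, 16)
    letters = []
    for _ in range(length):
        number, rem = divmod(number, 26)
        letters.append(_ALPHABET[rem])
    return "".join(letters)


def step_hash(step: StepSpec, registry: dict[str, str] | None = None) -> str:
    """Short letter code for a step (default four letters, base-26).

    If a ``registry`` (code -> full digest) is supplied, a truncated-code
    collision between *different* steps is resolved by extending the code
    one letter at a time; two steps never silently share a code.
    """
    digest = step_digest(step)
    length = CODE_LENGTH
    code = _digest_to_letters(digest, length)
    if registry is None:
        return code
    while code in registry and registry[code] != digest:
        length += 1
        code = _digest_to_letters(digest, length)
    registry[code] = digest
    return code


@dataclass
class PipelinePlan:
    """Deduplicated DAG of steps; node identity is the step hash."""

    nodes: dict[str, StepSpec] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)  # code -> full digest
    sinks: dict[str, str] = field(default_factory=dict)  # feature name -> code

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(code: str) -> None:
            mark = state.get(code, 0)
            if mark == 1:
                raise ValueError(f"cycle detected at step {code}")
            if mark == 2:
                return
            state[code] = 1
            for up in self.nodes[code].upstream:
                if up in self.nodes:
                    visit(up)
            state[code] = 2
            order.append(code)

        for code in self.nodes:
            visit(code)
        return order


def build_plan(pipelines: list[list[StepSpec]], names: list[str] | None = None) -> PipelinePlan:
    """Merge pipelines into one plan, re-using steps with equal hashes.

    Each pipeline is an ordered chain; step i's upstream is step i-1's
    hash (the chains' own upstream fields are filled in here).  Before a
    step is added, its hash is looked up: if present, the existing node is
    re-used.  Shared prefixes therefore appear once.
    """
    plan = PipelinePlan()
    names = names or [f"pipeline{i}" for i in range(len(pipelines))]
    for name, chain in zip(names, pipelines):
        prev: str | None = None
        for raw in chain:
            upstream = (prev,) if prev is not None else ()
            step = StepSpec(operation=raw.operation, params=raw.params, upstream=upstream)
            code = step_hash(step, plan.digests)
            if code not in plan.nodes:
                plan.nodes[code] = step
            prev = code
        if prev is not None:
            plan.sinks[name] = prev
    plan.topological_order()  # raises on cycles
    return plan


def reuse_report(plan: PipelinePlan, pipelines: list[list[StepSpec]]) -> dict:
    """Node-count accounting for the deduplication.

    ``naive_node_count`` is what running every pipeline separately would
    compute; ``saved_fraction = 1 - deduped / naive``.
    """
    naive = sum(len(chain) for chain in pipelines)
    deduped = len(plan.nodes)
    return {
        "naive_node_count": naive,
        "deduped_node_count": deduped,
        "saved_fraction": 1.0 - deduped / naive if naive else 0.0,
    }


def execute_plan(
    plan: PipelinePlan,
    operations: dict[str, Callable],
    sources: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Run the plan topologically; each node body runs exactly once.

    ``operations`` maps operation names to callables of signature
    ``op(*upstream_outputs, **params)``.  Source nodes (no upstream) may
    instead pull a value from ``sources`` keyed by operation name.
    Returns the output of every node keyed by its hash code.
    """
    sources = sources or {}
    outputs: dict[str, Any] = {}
    for code in plan.topological_order():
        step = plan.nodes[code]
        inputs = [outputs[up] for up in step.upstream if up in outputs]
        if not step.upstream and step.operation in sources:
            outputs[code] = sources[step.operation]
            continue
        fn = operations.get(step.operation)
        if fn is None:
            raise KeyError(f"no executor registered for operation {step.operation!r}")
        outputs[code] = fn(*inputs, **dict(step.params))
    return outputs


def prune_missing_inputs(
    pipelines: list[list[StepSpec]],
    available: set[str],
    requires: dict[str, set[str]],
    log: list[str] | None = None,
) -> list[list[StepSpec]]:
    """Drop steps whose required inputs are absent instead of failing.

    ``requires`` maps operation names to the set of input roles they
    need; a step needing an unavailable role is pruned with a logged
    reason, and the chain simply continues without it (the best-possible-
    pipeline rule for, e.g., a missing field map).
    """
    pruned: list[list[StepSpec]] = []
    for chain in pipelines:
        kept: list[StepSpec] = []
        for step in chain:
            needed = requires.get(step.operation, set())
            missing = needed - available
            if missing:
                if log is not None:
                    log.append(
                        f"pruned step {step.operation!r}: missing inputs {sorted(missing)}"
                    )
                continue
            kept.append(step)
        pruned.append(kept)
    return pruned
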