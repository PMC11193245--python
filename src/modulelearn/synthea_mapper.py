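"""Map learned rule graphs into Synthea generic-module documents.

A Synthea disease module is a directed state graph: exactly one Initial
state, at least one Terminal state, and here one Encounter state per
medical concept.  Edges are "distributed transitions" — each non-Terminal
state carries a probability distribution over successor states that must
sum to exactly 1 for the sampler.  Sampling walks Initial -> ... ->
Terminal and emits one synthetic patient history per walk, which closes
the loop back to a :class:`~modulelearn.datatypes.SequenceDataset`.

Codes are recorded with system "SNOMED-CT" carrying the OMOP concept_id as
the code value; this is a documented placeholder, not a terminology
translation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .datatypes import (
    Concept,
    EventSequence,
    RuleGraph,
    SequenceDataset,
    START_ID,
    STOP_ID,
    sentinel_concepts,
)

logger = logging.getLogger(__name__)

INITIAL_STATE = "Initial"
TERMINAL_STATE = "Terminal"
DIST_SUM_TOL = 1e-9


class ModuleFormatError(ValueError):
    """Raised when a module document cannot be interpreted."""


@dataclass
class SyntheaModule:
    """An in-memory Synthea generic module (Initial/Terminal/Encounter only).

    ``states`` maps state name to its record dict in the module-builder
    JSON dialect; insertion order is preserved on write.
    """

    name: str
    states: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "states": self.states}

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheaModule":
        if not isinstance(doc, dict) or "states" not in doc:
            raise ModuleFormatError("document has no 'states' mapping")
        return cls(name=doc.get("name", ""), states=dict(doc["states"]))

    def write(self, path: str | Path) -> None:
        violations = validate_module(self.to_dict())
        if violations:
            raise ValueError("refusing to write invalid module: " + "; ".join(violations))
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, ensure_ascii=False)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "SyntheaModule":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def concept_of_state(self, state_name: str) -> Optional[int]:
        state = self.states[state_name]
        if state.get("type") == "Initial":
            return START_ID
        if state.get("type") == "Terminal":
            return STOP_ID
        codes = state.get("codes") or []
        return int(codes[0]["code"]) if codes else None


def _round_distribution(weights: list[float]) -> list[float]:
    """Round shares to 6 decimals; the largest absorbs the residue so the
    rounded values still sum to exactly 1."""
    probs = [round(w, 6) for w in weights]
    residue = round(1.0 - sum(probs), 6)
    imax = max(range(len(probs)), key=lambda i: weights[i])
    probs[imax] = round(probs[imax] + residue, 6)
    return probs


def rules_to_module(
    graph: RuleGraph,
    module_name: str,
    labels: Optional[dict[int, str]] = None,
    drop_self_loops: bool = True,
) -> SyntheaModule:
    """Convert a rule graph into a valid, sampleable Synthea module.

    Per-state outgoing rule weights are normalized proportionally into a
    distributed transition; dead-end states route to Terminal with
    probability 1; states unreachable from Initial are pruned with a
    warning.  A concept can appear only once in a module, so state names
    are deduplicated labels.
    """
    if not graph.edges:
        raise ValueError("cannot map an empty rule graph")
    labels = labels or {}

    rules = [r for r in graph.rules() if not (drop_self_loops and r.is_self_loop)]
    for r in rules:
        if r.weight < 0:
            raise ValueError(f"negative rule weight on {r.antecedent}->{r.consequent}")
    if not any(r.antecedent == START_ID for r in rules):
        raise ValueError("no entry distribution: rule graph has no START-anchored edges")

    # Reachability from START over the rule edges
    succ: dict[int, list] = {}
    for r in rules:
        succ.setdefault(r.antecedent, []).append(r)
    reachable = {START_ID}
    frontier = [START_ID]
    while frontier:
        node = frontier.pop()
        for r in succ.get(node, ()):
            if r.consequent not in reachable:
                reachable.add(r.consequent)
                frontier.append(r.consequent)
    pruned = graph.nodes - reachable
    if pruned:
        logger.warning("pruned %d states unreachable from Initial", len(pruned))
    reachable.add(STOP_ID)  # Terminal always exists

    # State names: deduplicated labels, deterministic order
    concept_order = [START_ID] + sorted(c for c in reachable if c not in (START_ID, STOP_ID)) + [STOP_ID]
    state_name: dict[int, str] = {START_ID: INITIAL_STATE, STOP_ID: TERMINAL_STATE}
    used = {INITIAL_STATE, TERMINAL_STATE}
    for cid in concept_order:
        if cid in state_name:
            continue
        base = labels.get(cid, f"concept_{cid}") or f"concept_{cid}"
        name = base
        k = 2
        while name in used:
            name = f"{base} ({k})"
            k += 1
        used.add(name)
        state_name[cid] = name

    module = SyntheaModule(name=module_name)
    for cid in concept_order:
        name = state_name[cid]
        if cid == START_ID:
            state: dict = {"type": "Initial"}
        elif cid == STOP_ID:
            module.states[name] = {"type": "Terminal"}
            continue
        else:
            state = {
                "type": "Encounter",
                "encounter_class": "ambulatory",
                "codes": [
                    {
                        "system": "SNOMED-CT",
                        "code": str(cid),
                        "display": labels.get(cid, f"concept_{cid}"),
                    }
                ],
            }
        out = [r for r in succ.get(cid, ()) if r.consequent in reachable]
        total = sum(r.weight for r in out)
        if not out or total <= 0:
            state["distributed_transition"] = [
                {"distribution": 1.0, "transition": TERMINAL_STATE}
            ]
        else:
            shares = [r.weight / total for r in out]
            probs = _round_distribution(shares)
            state["distributed_transition"] = [
                {"distribution": p, "transition": state_name[r.consequent]}
                for r, p in zip(out, probs)
            ]
        module.states[name] = state
    return module


def validate_module(doc: dict | SyntheaModule) -> list[str]:
    """Check the invariants the Synthea engine enforces; return violations.

    An empty list means the module is valid: exactly one Initial, at least
    one Terminal, every distribution sums to 1 within tolerance, every
    transition target exists, and every non-Terminal state has a transition.
    """
    if isinstance(doc, SyntheaModule):
        doc = doc.to_dict()
    if not isinstance(doc, dict) or not isinstance(doc.get("states"), dict):
        raise ModuleFormatError("document has no 'states' mapping")
    states = doc["states"]
    violations: list[str] = []
    initials = [n for n, s in states.items() if s.get("type") == "Initial"]
    terminals = [n for n, s in states.items() if s.get("type") == "Terminal"]
    if len(initials) != 1:
        violations.append(f"expected exactly one Initial state, found {len(initials)}")
    if not terminals:
        violations.append("no Terminal state")
    for name, state in states.items():
        stype = state.get("type")
        if stype not in ("Initial", "Terminal", "Encounter"):
            violations.append(f"state {name!r}: unsupported type {stype!r}")
            continue
        if stype == "Terminal":
            continue
        dist = state.get("distributed_transition")
        if not dist:
            violations.append(f"state {name!r}: non-Terminal state has no transition")
            continue
        total = 0.0
        for entry in dist:
            p = entry.get("distribution")
            target = entry.get("transition")
            if p is None or p < 0:
                violations.append(f"state {name!r}: bad probability {p!r}")
                continue
            total += p
            if target not in states:
                violations.append(f"state {name!r}: transition to nonexistent state {target!r}")
        if abs(total - 1.0) > DIST_SUM_TOL:
            violations.append(f"state {name!r}: distribution sums to {total!r}, not 1")
    return violations


def sample_module(
    module: SyntheaModule,
    n: int,
    seed: int,
    max_steps: int = 1000,
) -> SequenceDataset:
    """Generate n patient sequences by random walks Initial -> Terminal.

    Successors are drawn per distributed-transition probabilities; walks
    are truncated at ``max_steps`` states with a warning.  Deterministic
    for a fixed seed.
    """
    violations = validate_module(module)
    if violations:
        raise ValueError("refusing to sample invalid module: " + "; ".join(violations))
    rng = np.random.default_rng(seed)
    states = module.states
    initial = next(n_ for n_, s in states.items() if s.get("type") == "Initial")

    # Pre-extract transition tables
    table: dict[str, tuple[list[str], np.ndarray]] = {}
    for name, state in states.items():
        if state.get("type") == "Terminal":
            continue
        dist = state["distributed_transition"]
        targets = [e["transition"] for e in dist]
        probs = np.array([e["distribution"] for e in dist], dtype=float)
        table[name] = (targets, probs / probs.sum())

    vocab: dict[int, Concept] = {c.concept_id: c for c in sentinel_concepts()}
    for name, state in states.items():
        if state.get("type") == "Encounter":
            cid = module.concept_of_state(name)
            if cid is not None and cid not in vocab:
                display = (state.get("codes") or [{}])[0].get("display", f"concept_{cid}")
                vocab[cid] = Concept(cid, display)

    sequences = []
    n_truncated = 0
    for i in range(n):
        current = initial
        ids = [START_ID]
        steps = 0
        while states[current].get("type") != "Terminal":
            targets, probs = table[current]
            current = targets[rng.choice(len(targets), p=probs)]
            steps += 1
            if states[current].get("type") == "Encounter":
                ids.append(module.concept_of_state(current))
            if steps >= max_steps and states[current].get("type") != "Terminal":
                n_truncated += 1
                break
        ids.append(STOP_ID)
        sequences.append(
            EventSequence(person_id=f"synth{i:06d}", events=[(c, None) for c in ids])
        )
    if n_truncated:
        logger.warning("truncated %d walks at max_steps=%d", n_truncated, max_steps)
    ds = SequenceDataset(
        sequences=sequences, vocabulary=vocab, provenance=f"sample_module({module.name},seed={seed})"
    )
    ds.validate()
    return ds
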