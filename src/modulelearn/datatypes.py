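"""Core containers shared across the learning pipeline.

The central object is the :class:`SequenceDataset`: a collection of
per-patient, time-ordered discrete event series over a vocabulary of
medical concepts, wrapped in START/STOP sentinels so that learners can
model where a patient history begins and ends.  Learned pairwise temporal
rules are collected in a :class:`RuleGraph`, the exchange object between
the learners and the Synthea module mapper.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

#: Reserved concept id for the START sentinel prepended to every sequence.
START_ID: int = -1
#: Reserved concept id for the STOP sentinel appended to every sequence.
STOP_ID: int = -2

SENTINEL_LABELS = {START_ID: "START", STOP_ID: "STOP"}


@dataclass(frozen=True)
class Concept:
    """A vocabulary entry: an OMOP concept id with a display label."""

    concept_id: int
    label: str
    domain: str = "condition"  # condition | procedure | sentinel

    def __post_init__(self) -> None:
        if self.concept_id in SENTINEL_LABELS and self.domain != "sentinel":
            object.__setattr__(self, "domain", "sentinel")


def sentinel_concepts() -> list[Concept]:
    return [Concept(cid, lbl, "sentinel") for cid, lbl in SENTINEL_LABELS.items()]


@dataclass
class EventSequence:
    """One patient's ordered event history, including sentinels.

    ``events`` is a list of ``(concept_id, event_date)`` pairs; sentinel
    events carry ``None`` dates.  The first event must be START, the last
    STOP, and dates of the non-sentinel events must be non-decreasing.
    """

    person_id: str
    events: list[tuple[int, Optional[_dt.date]]]

    def __len__(self) -> int:
        return len(self.events)

    @property
    def concept_ids(self) -> list[int]:
        return [cid for cid, _ in self.events]

    def validate(self) -> None:
        if len(self.events) < 2:
            raise ValueError(f"sequence for {self.person_id!r} has fewer than 2 events")
        if self.events[0][0] != START_ID:
            raise ValueError(f"sequence for {self.person_id!r} does not begin with START")
        if self.events[-1][0] != STOP_ID:
            raise ValueError(f"sequence for {self.person_id!r} does not end with STOP")
        dates = [d for cid, d in self.events if d is not None and cid not in SENTINEL_LABELS]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"sequence for {self.person_id!r} has decreasing dates")


@dataclass
class SequenceDataset:
    """A set of patient event sequences plus their concept vocabulary."""

    sequences: list[EventSequence]
    vocabulary: dict[int, Concept]
    provenance: str = ""

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def dimensionality(self) -> int:
        """Number of distinct non-sentinel concepts."""
        return sum(1 for c in self.vocabulary.values() if c.domain != "sentinel")

    def mean_length(self) -> float:
        """Arithmetic mean sequence length, sentinels included."""
        if not self.sequences:
            return 0.0
        return sum(len(s) for s in self.sequences) / len(self.sequences)

    def concept_ids(self) -> list[int]:
        """Vocabulary ids in a deterministic order: sentinels first, then ascending."""
        ids = sorted(cid for cid in self.vocabulary if cid not in SENTINEL_LABELS)
        return [START_ID, STOP_ID] + ids

    def label(self, concept_id: int) -> str:
        c = self.vocabulary.get(concept_id)
        return c.label if c is not None else f"concept_{concept_id}"

    def validate(self) -> None:
        if not self.sequences:
            raise ValueError("dataset has no sequences")
        for seq in self.sequences:
            seq.validate()
            missing = [cid for cid in seq.concept_ids if cid not in self.vocabulary]
            if missing:
                raise ValueError(f"concept ids {missing} missing from vocabulary")

    def __iter__(self) -> Iterator[EventSequence]:
        return iter(self.sequences)


@dataclass(frozen=True)
class TemporalRule:
    """A weighted directed edge antecedent -> consequent with provenance.

    ``weight`` is the learner's native score: a transition probability for
    the Markov chain, sequential confidence for rule mining, and an absolute
    SVAR coefficient for the causal learner.
    """

    antecedent: int
    consequent: int
    weight: float
    provenance: str  # markov | tarm | dynotears-intra | dynotears-inter
    seq_sup: Optional[float] = None
    seq_conf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.antecedent == STOP_ID:
            raise ValueError("STOP cannot be a rule antecedent")
        if self.consequent == START_ID:
            raise ValueError("START cannot be a rule consequent")

    @property
    def is_self_loop(self) -> bool:
        return self.antecedent == self.consequent


@dataclass
class RuleGraph:
    """The learned directed graph: one edge per (antecedent, consequent)."""

    algorithm: str = ""
    dataset_tag: str = ""
    nodes: set[int] = field(default_factory=set)
    edges: dict[tuple[int, int], TemporalRule] = field(default_factory=dict)

    def add_rule(self, rule: TemporalRule) -> None:
        key = (rule.antecedent, rule.consequent)
        if key in self.edges:
            raise ValueError(f"duplicate rule {key}")
        self.edges[key] = rule
        self.nodes.add(rule.antecedent)
        self.nodes.add(rule.consequent)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges)

    def rules(self) -> list[TemporalRule]:
        return [self.edges[k] for k in sorted(self.edges)]

    def out_rules(self, antecedent: int) -> list[TemporalRule]:
        return [r for r in self.rules() if r.antecedent == antecedent]

    def in_degree(self, concept_id: int) -> int:
        return sum(1 for (_, c) in self.edges if c == concept_id)


def dataset_from_id_lists(
    id_lists: Iterable[list[int]],
    labels: Optional[dict[int, str]] = None,
    provenance: str = "",
) -> SequenceDataset:
    """Build a dataset from bare concept-id lists (sentinels included).

    Convenience constructor used by tests and by module sampling, where no
    calendar dates exist.
    """
    labels = labels or {}
    sequences = []
    vocab: dict[int, Concept] = {c.concept_id: c for c in sentinel_concepts()}
    for i, ids in enumerate(id_lists):
        sequences.append(EventSequence(person_id=f"p{i}", events=[(cid, None) for cid in ids]))
        for cid in ids:
            if cid not in vocab:
                vocab[cid] = Concept(cid, labels.get(cid, f"concept_{cid}"))
    ds = SequenceDataset(sequences=sequences, vocabulary=vocab, provenance=provenance)
    ds.validate()
    return ds


__all__ = [
    "START_ID",
    "STOP_ID",
    "SENTINEL_LABELS",
    "Concept",
    "EventSequence",
    "SequenceDataset",
    "TemporalRule",
    "RuleGraph",
    "sentinel_concepts",
    "dataset_from_id_lists",
    "replace",
]
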