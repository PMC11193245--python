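"""Shared fixtures: tiny hand-checkable datasets and random-graph helpers."""

from __future__ import annotations

import numpy as np
import pytest

from modulelearn.datatypes import (
    RuleGraph,
    SequenceDataset,
    START_ID,
    STOP_ID,
    TemporalRule,
    dataset_from_id_lists,
)

A, B, C, D = 11, 12, 13, 14


@pytest.fixture
def three_seq_dataset() -> SequenceDataset:
    """[START,A,B,STOP], [START,A,C,STOP], [START,A,B,STOP] — the canonical
    worked example: P(B|A)=2/3, P(C|A)=1/3."""
    return dataset_from_id_lists(
        [
            [START_ID, A, B, STOP_ID],
            [START_ID, A, C, STOP_ID],
            [START_ID, A, B, STOP_ID],
        ]
    )


def random_dataset(rng: np.random.Generator, n_concepts=5, n_seqs=10, max_events=6) -> SequenceDataset:
    """Random small dataset over concepts 1..n_concepts, sentinels attached."""
    concepts = list(range(1, n_concepts + 1))
    seqs = []
    for _ in range(n_seqs):
        k = int(rng.integers(1, max_events + 1))
        body = [int(rng.choice(concepts)) for _ in range(k)]
        seqs.append([START_ID] + body + [STOP_ID])
    return dataset_from_id_lists(seqs)


def random_rule_graph(rng: np.random.Generator, n_concepts=6, edge_prob=0.35) -> RuleGraph:
    """Random weighted rule graph guaranteed to have a START-anchored edge."""
    concepts = list(range(101, 101 + n_concepts))
    graph = RuleGraph(algorithm="random")
    entry = [c for c in concepts if rng.random() < 0.5] or [concepts[0]]
    for c in entry:
        graph.add_rule(TemporalRule(START_ID, c, float(rng.uniform(0.1, 1.0)), "markov"))
    for a in concepts:
        for c in concepts + [STOP_ID]:
            if rng.random() < edge_prob:
                graph.add_rule(TemporalRule(a, c, float(rng.uniform(0.05, 1.0)), "markov"))
    return graph
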