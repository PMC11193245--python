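"""First-order Markov chain over medical observations.

Every concept (including the START/STOP sentinels) is a state; the model
estimates P(consequent | antecedent) from consecutive event pairs pooled
over the whole patient population — the maximum-likelihood estimate of the
transition matrix.  No smoothing is applied: probabilities are exact
integer-count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import RuleGraph, SequenceDataset, TemporalRule, START_ID, STOP_ID


@dataclass
class TransitionModel:
    """Fitted transition counts and row-normalized probabilities.

    ``states`` orders the concept ids; ``counts[a, c]`` is the number of
    adjacent pairs (state a at t, state c at t+1) over all patients, and
    ``probs`` is ``counts`` normalized per row (all-zero rows stay zero).
    """

    states: list[int]
    counts: np.ndarray
    probs: np.ndarray
    labels: dict[int, str]

    @property
    def index(self) -> dict[int, int]:
        return {cid: i for i, cid in enumerate(self.states)}

    def prob(self, antecedent: int, consequent: int) -> float:
        ix = self.index
        return float(self.probs[ix[antecedent], ix[consequent]])


def fit_markov(dataset: SequenceDataset) -> TransitionModel:
    """Estimate the transition matrix by pooled adjacent-pair counts."""
    if dataset.n == 0:
        raise ValueError("cannot fit on an empty dataset")
    states = dataset.concept_ids()
    ix = {cid: i for i, cid in enumerate(states)}
    d = len(states)
    counts = np.zeros((d, d), dtype=np.int64)
    for seq in dataset:
        ids = seq.concept_ids
        for a, c in zip(ids, ids[1:]):
            counts[ix[a], ix[c]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    labels = {cid: dataset.label(cid) for cid in states}
    return TransitionModel(states=states, counts=counts, probs=probs, labels=labels)


def markov_to_rules(
    model: TransitionModel,
    min_prob: float = 0.0,
    dataset_tag: str = "",
) -> RuleGraph:
    """One rule per transition with probability strictly above ``min_prob``.

    Self-loops are retained (flagged via :attr:`TemporalRule.is_self_loop`);
    transitions out of STOP or into START cannot occur by construction.
    """
    graph = RuleGraph(algorithm="markov", dataset_tag=dataset_tag)
    for i, a in enumerate(model.states):
        if a == STOP_ID:
            continue
        for j, c in enumerate(model.states):
            if c == START_ID:
                continue
            p = float(model.probs[i, j])
            if p > min_prob:
                graph.add_rule(TemporalRule(antecedent=a, consequent=c, weight=p, provenance="markov"))
    return graph


def write_transition_tsv(model: TransitionModel, path: str | Path) -> None:
    """Dump nonzero transitions: antecedent, consequent, count, probability."""
    with open(path, "w") as fh:
        fh.write("antecedent_label\tconsequent_label\tcount\tprobability\n")
        for i, a in enumerate(model.states):
            for j, c in enumerate(model.states):
                if model.counts[i, j] > 0:
                    fh.write(
                        f"{model.labels[a]}\t{model.labels[c]}\t"
                        f"{int(model.counts[i, j])}\t{model.probs[i, j]:.10g}\n"
                    )
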