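"""Pairwise temporal association rule mining over the sequence database.

Mines rules X -> Y between single medical observations using the two
sequential-rule statistics:

* ``seqSup(X->Y) = sup(X Y) / |S|`` — the fraction of sequences in which
  some occurrence of X strictly precedes some occurrence of Y;
* ``seqConf(X->Y) = sup(X Y) / sup(X)`` — the same count relative to the
  number of sequences containing X at all.

Antecedents and consequents are restricted to singletons because the
downstream Synthea edge is pairwise; the mining itself is an exhaustive
scan over concept pairs, O(N * T^2) via per-sequence first/last occurrence
indices — ample at the scale of per-patient encounter histories.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

from .datatypes import RuleGraph, SequenceDataset, TemporalRule, START_ID, STOP_ID


def _first_last(ids: list[int]) -> tuple[dict[int, int], dict[int, int]]:
    first: dict[int, int] = {}
    last: dict[int, int] = {}
    for i, cid in enumerate(ids):
        first.setdefault(cid, i)
        last[cid] = i
    return first, last


def sequence_support(dataset: SequenceDataset, x: int, y: int) -> int:
    """Number of sequences where some occurrence of x precedes one of y.

    Each sequence contributes at most 1; for x == y a sequence counts only
    if x occurs at least twice.
    """
    for cid in (x, y):
        if cid not in dataset.vocabulary:
            raise ValueError(f"concept {cid} not in vocabulary")
    count = 0
    for seq in dataset:
        first, last = _first_last(seq.concept_ids)
        if x in first and y in last and first[x] < last[y]:
            count += 1
    return count


def mine_rules(
    dataset: SequenceDataset,
    min_seq_sup: float = 0.1,
    min_seq_conf: float = 0.5,
    dataset_tag: str = "",
) -> RuleGraph:
    """Emit every pair rule meeting both threshold statistics.

    START-anchored rules are exempted from the confidence threshold so the
    mined graph always carries an entry distribution for module sampling
    (START occurs in every sequence, so its confidence equals its support
    anyway).  Pairs whose antecedent never occurs are skipped, as their
    confidence is undefined.
    """
    for thr in (min_seq_sup, min_seq_conf):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    n_seq = dataset.n
    pair_sup: Counter[tuple[int, int]] = Counter()
    item_sup: Counter[int] = Counter()
    for seq in dataset:
        first, last = _first_last(seq.concept_ids)
        for cid in first:
            item_sup[cid] += 1
        for x, fx in first.items():
            if x == STOP_ID:
                continue
            for y, ly in last.items():
                if y == START_ID:
                    continue
                if fx < ly:
                    pair_sup[(x, y)] += 1

    graph = RuleGraph(algorithm="tarm", dataset_tag=dataset_tag)
    for (x, y), sup_xy in sorted(pair_sup.items()):
        seq_sup = sup_xy / n_seq
        seq_conf = sup_xy / item_sup[x]
        if seq_sup < min_seq_sup:
            continue
        if seq_conf < min_seq_conf and x != START_ID:
            continue
        graph.add_rule(
            TemporalRule(
                antecedent=x,
                consequent=y,
                weight=seq_conf,
                provenance="tarm",
                seq_sup=seq_sup,
                seq_conf=seq_conf,
            )
        )
    return graph


def write_rules_tsv(graph: RuleGraph, dataset: SequenceDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("antecedent_label\tconsequent_label\tseq_sup\tseq_conf\n")
        for rule in graph.rules():
            fh.write(
                f"{dataset.label(rule.antecedent)}\t{dataset.label(rule.consequent)}\t"
                f"{rule.seq_sup:.10g}\t{rule.seq_conf:.10g}\n"
            )
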