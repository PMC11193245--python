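"""End-to-end experiment orchestration.

Runs the full study design on one dataset: ETL (or synthetic cohort
generation), a descending subsampling ladder, each selected learner on
each dataset size with wall-clock timing, mapping of every rule graph to
a Synthea module, and finally the complexity report and pairwise
edge-overlap matrix over all learner x size graphs.  Every artifact lands
under the output directory together with a manifest, and the whole run is
reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import graph_eval, markov, omop_etl, synthetic_data, tarm
from . import dynotears as dyn
from .datatypes import RuleGraph, SequenceDataset, TemporalRule
from .synthea_mapper import rules_to_module

logger = logging.getLogger(__name__)

LEARNERS = ("markov", "tarm", "dynotears")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    # input: either OMOP CSV paths or a synthetic cohort
    condition_csv: Optional[str] = None
    procedure_csv: Optional[str] = None
    vocabulary_csv: Optional[str] = None
    synthetic: bool = True
    n_patients: int = 1000
    vocab_size: int = 30
    mean_length: float = 5.5
    confounder_rate: float = 0.0

    subsample_sizes: list[int] = field(default_factory=list)  # descending; [] = full only
    nested_subsampling: bool = True
    learners: list[str] = field(default_factory=lambda: list(LEARNERS))
    dedupe: bool = False

    markov_min_prob: float = 0.0
    tarm_min_seq_sup: float = 0.1
    tarm_min_seq_conf: float = 0.5
    dynotears_lambda_w: float = 0.1
    dynotears_lambda_a: float = 0.1
    dynotears_threshold: float = 0.3
    dynotears_top_k: int = 100
    dynotears_lag: int = 1

    out_dir: str = "experiment_out"
    seed: int = 0

    def validate(self) -> None:
        if not self.learners:
            raise ValueError("learner set must be non-empty")
        unknown = set(self.learners) - set(LEARNERS)
        if unknown:
            raise ValueError(f"unknown learners: {sorted(unknown)}")
        if any(n < 1 for n in self.subsample_sizes):
            raise ValueError("subsample sizes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Rule-graph TSV exchange format

def write_rule_graph(graph: RuleGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# algorithm=%s\tdataset_tag=%s\n" % (graph.algorithm, graph.dataset_tag))
        fh.write("antecedent\tconsequent\tweight\tprovenance\tseq_sup\tseq_conf\n")
        for rule in graph.rules():
            sup = "" if rule.seq_sup is None else f"{rule.seq_sup:.10g}"
            conf = "" if rule.seq_conf is None else f"{rule.seq_conf:.10g}"
            fh.write(
                f"{rule.antecedent}\t{rule.consequent}\t{rule.weight:.10g}\t"
                f"{rule.provenance}\t{sup}\t{conf}\n"
            )


def read_rule_graph(path: str | Path) -> RuleGraph:
    graph = RuleGraph()
    with open(path) as fh:
        header = fh.readline().strip()
        if header.startswith("#"):
            parts = dict(
                kv.split("=", 1) for kv in header.lstrip("# ").split("\t") if "=" in kv
            )
            graph.algorithm = parts.get("algorithm", "")
            graph.dataset_tag = parts.get("dataset_tag", "")
            fh.readline()  # column header
        for line in fh:
            a, c, w, prov, sup, conf = line.rstrip("\n").split("\t")
            graph.add_rule(
                TemporalRule(
                    antecedent=int(a),
                    consequent=int(c),
                    weight=float(w),
                    provenance=prov,
                    seq_sup=float(sup) if sup else None,
                    seq_conf=float(conf) if conf else None,
                )
            )
    return graph


# ---------------------------------------------------------------------------

def load_dataset(config: ExperimentConfig) -> SequenceDataset:
    """Either read the OMOP CSVs named in the config or generate the
    synthetic cohort with the configured shape."""
    if config.synthetic:
        gen = synthetic_data.GeneratorConfig(
            n_patients=config.n_patients,
            vocab_size=config.vocab_size,
            mean_length=config.mean_length,
            seed=config.seed,
            confounder_rate=config.confounder_rate,
        )
        dataset, _ = synthetic_data.generate_cohort(gen)
        return dataset
    records = []
    if config.condition_csv:
        records += omop_etl.read_occurrence_table(config.condition_csv, "condition")
    if config.procedure_csv:
        records += omop_etl.read_occurrence_table(config.procedure_csv, "procedure")
    if not records:
        raise ValueError("no input: set synthetic=true or provide occurrence CSVs")
    dataset = omop_etl.build_sequences(records, dedupe=config.dedupe)
    if config.vocabulary_csv:
        dataset = omop_etl.map_labels(dataset, config.vocabulary_csv)
    return dataset


def fit_learner(learner: str, dataset: SequenceDataset, config: ExperimentConfig, tag: str) -> RuleGraph:
    if learner == "markov":
        model = markov.fit_markov(dataset)
        return markov.markov_to_rules(model, min_prob=config.markov_min_prob, dataset_tag=tag)
    if learner == "tarm":
        return tarm.mine_rules(
            dataset,
            min_seq_sup=config.tarm_min_seq_sup,
            min_seq_conf=config.tarm_min_seq_conf,
            dataset_tag=tag,
        )
    if learner == "dynotears":
        dm = dyn.encode_binary_panel(dataset, top_k=config.dynotears_top_k, p=config.dynotears_lag)
        model = dyn.fit_dynotears(
            dm,
            lambda_w=config.dynotears_lambda_w,
            lambda_a=config.dynotears_lambda_a,
            threshold=config.dynotears_threshold,
        )
        graph = dyn.svar_to_rules(
            model, dm.concepts, threshold=config.dynotears_threshold, dataset_tag=tag
        )
        return graph
    raise ValueError(f"unknown learner {learner!r}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run every (learner, dataset size) cell and write all artifacts.

    A failing cell is recorded in the manifest and does not stop the
    remaining cells.  Returns the manifest dict.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    full = load_dataset(config)
    omop_etl.write_sequences(full, out_dir / "sequences_full.tsv")

    sizes = sorted(set(config.subsample_sizes or []), reverse=True)
    if any(n > full.n for n in sizes):
        raise ValueError(f"subsample sizes {sizes} exceed dataset size {full.n}")
    ladder: list[tuple[int, SequenceDataset]] = [(full.n, full)]
    current = full
    for i, n in enumerate(sizes):
        if n == full.n:
            continue
        source = current if config.nested_subsampling else full
        sub = omop_etl.subsample(source, n, seed=config.seed + 1000 + i)
        ladder.append((n, sub))
        current = sub

    manifest: dict = {"config": dataclasses.asdict(config), "cells": []}
    report_rows = []
    graphs: list[tuple[str, RuleGraph]] = []
    for learner in config.learners:
        for n, dataset in ladder:
            tag = f"{learner}-{n}"
            cell: dict = {"learner": learner, "size": n, "tag": tag}
            try:
                t0 = time.perf_counter()
                graph = fit_learner(learner, dataset, config, tag)
                fit_seconds = time.perf_counter() - t0
                rules_path = out_dir / f"rules_{tag}.tsv"
                write_rule_graph(graph, rules_path)
                labels = {cid: dataset.label(cid) for cid in graph.nodes}
                module_path = None
                try:
                    module = rules_to_module(graph, module_name=tag, labels=labels)
                    module_path = out_dir / f"module_{tag}.json"
                    module.write(module_path)
                except ValueError as exc:
                    cell["module_error"] = str(exc)
                report = graph_eval.complexity(graph)
                report_rows.append((tag, report, fit_seconds))
                graphs.append((tag, graph))
                cell.update(
                    status="ok",
                    fit_seconds=round(fit_seconds, 4),
                    n_nodes=report.n_nodes,
                    n_edges=report.n_edges,
                    artifacts={
                        "rules": str(rules_path),
                        **({"module": str(module_path)} if module_path else {}),
                    },
                )
            except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
                logger.exception("cell %s failed", tag)
                cell.update(status="failed", error=f"{type(exc).__name__}: {exc}")
            manifest["cells"].append(cell)

    graph_eval.write_report_tsv(report_rows, out_dir / "complexity_report.tsv")
    if graphs:
        graph_eval.overlap_matrix(graphs).write_tsv(out_dir / "overlap_matrix.tsv")
    manifest["success"] = all(c["status"] == "ok" for c in manifest["cells"])
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
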