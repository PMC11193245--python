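"""Quantitative comparison of learned graphs.

Six complexity measures per graph — node count, edge count, density,
average clustering, number of strongly connected components, and flow
hierarchy — plus the pairwise identical-edge overlap matrix and per-cell
runtime bookkeeping for the experiment report.

Conventions: self-loops count as edges and as cyclic edges but the density
denominator stays n(n-1); directed clustering follows the all-directed-
triangle (Fagiolo) generalization, with the undirected-projection variant
available behind a flag; flow hierarchy is the fraction of edges not lying
inside any strongly connected component, i.e. not on any directed cycle
(Luo-Magee), so a DAG scores 1 and a single big cycle scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .datatypes import RuleGraph


@dataclass
class ComplexityReport:
    n_nodes: int
    n_edges: int
    density: float
    avg_clustering: float
    n_scc: int
    flow_hierarchy: float

    def as_row(self) -> list:
        return [
            self.n_nodes,
            self.n_edges,
            round(self.density, 6),
            round(self.avg_clustering, 6),
            self.n_scc,
            round(self.flow_hierarchy, 6),
        ]

    FIELDS = ["n_nodes", "n_edges", "density", "avg_clustering", "n_scc", "flow_hierarchy"]


@dataclass
class OverlapMatrix:
    labels: list[str]
    values: list[list[float]]  # percentages, row = subject graph

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("graph\t" + "\t".join(self.labels) + "\n")
            for lbl, row in zip(self.labels, self.values):
                fh.write(lbl + "\t" + "\t".join(f"{v:.2f}" for v in row) + "\n")


def to_networkx(graph: RuleGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(sorted(graph.nodes))
    for (a, c), rule in sorted(graph.edges.items()):
        g.add_edge(a, c, weight=rule.weight, provenance=rule.provenance)
    return g


def complexity(graph: RuleGraph, undirected_clustering: bool = False) -> ComplexityReport:
    """Compute the six structural measures of a rule graph."""
    g = to_networkx(graph)
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return ComplexityReport(0, 0, 0.0, 0.0, 0, 0.0)
    n_scc = nx.number_strongly_connected_components(g)
    if n <= 1:
        return ComplexityReport(n, m, 0.0, 0.0, n_scc, 0.0)
    density = m / (n * (n - 1))
    g_noself = g.copy()
    g_noself.remove_edges_from(nx.selfloop_edges(g_noself))
    if undirected_clustering:
        avg_clustering = nx.average_clustering(g_noself.to_undirected())
    else:
        avg_clustering = nx.average_clustering(g_noself)
    # fraction of edges not inside any single SCC (self-loops are cyclic)
    scc_of = {}
    for i, comp in enumerate(nx.strongly_connected_components(g)):
        for node in comp:
            scc_of[node] = i
    if m == 0:
        flow_hierarchy = 0.0
    else:
        cyclic = sum(1 for a, c in g.edges if scc_of[a] == scc_of[c])
        flow_hierarchy = (m - cyclic) / m
    return ComplexityReport(n, m, density, float(avg_clustering), n_scc, flow_hierarchy)


def edge_overlap(g1: RuleGraph, g2: RuleGraph) -> float:
    """Percentage of g1's directed edges also present in g2 (weights ignored)."""
    e1, e2 = g1.edge_set(), g2.edge_set()
    if not e1:
        return 0.0
    return 100.0 * len(e1 & e2) / len(e1)


def overlap_matrix(graphs: Sequence[tuple[str, RuleGraph]]) -> OverlapMatrix:
    """All pairwise overlaps; values[r][c] = how much graph r overlaps graph c."""
    if not graphs:
        raise ValueError("need at least one graph")
    labels = [lbl for lbl, _ in graphs]
    values = [[edge_overlap(gr, gc) for _, gc in graphs] for _, gr in graphs]
    return OverlapMatrix(labels=labels, values=values)


def write_report_tsv(
    rows: Sequence[tuple[str, ComplexityReport, float]], path: str | Path
) -> None:
    """One row per (graph tag, complexity, fit seconds)."""
    with open(path, "w") as fh:
        fh.write("graph\t" + "\t".join(ComplexityReport.FIELDS) + "\tfit_seconds\n")
        for tag, report, seconds in rows:
            fh.write(tag + "\t" + "\t".join(str(v) for v in report.as_row()) + f"\t{seconds:.3f}\n")
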