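# modulelearn

Learn Synthea disease-module graphs from OMOP-formatted patient event
histories.

Synthea generates lifelong synthetic electronic health records by sampling
from hand-built "disease modules" — directed state graphs describing how a
disease and its treatment progress over time. Building those modules by
hand is slow and subjective. `modulelearn` derives them from real
observational data instead: it extracts per-patient event sequences from
OMOP CDM occurrence tables, learns weighted temporal rules between medical
observations with statistical and causal algorithms, and maps the learned
rule graphs into valid, sampleable Synthea module documents. It is aimed
at registry informaticians and medical-informatics researchers who want a
data-driven starting point for interpretable synthetic-data generators.

## Methods at the core

Patient histories are treated as N independent discrete time series
x_{n,t} ∈ C^D — per-patient event sequences over a vocabulary of D
concepts, ordered by encounter date and wrapped in START/STOP sentinels.
Three learners turn them into a directed rule graph:

* **Markov chain** — every observation is a state; transition
  probabilities are pooled adjacent-pair counts,
  P(consequent | antecedent) = P(antecedent ∩ consequent) / P(antecedent).
* **Temporal association rule mining** — pairwise sequential rules X→Y
  scored by seqSup(X→Y) = sup(X Y)/|S| and seqConf(X→Y) = sup(X Y)/sup(X),
  where sup(X Y) counts sequences in which some occurrence of X strictly
  precedes some occurrence of Y.
* **Acyclicity-constrained SVAR (DYNOTEARS)** — a structural vector
  autoregressive model x_t = Wᵀx_t + Aᵀ[x_{t−1..t−p}] + ε, estimated by
  minimizing ½M⁻¹‖X − XW − YA‖²_F + λ_w‖W‖₁ + λ_a‖A‖₁ subject to the
  smooth acyclicity constraint h(W) = tr(exp(W∘W)) − d = 0, solved with an
  augmented Lagrangian. Inter-slice (A) coefficients above a magnitude
  threshold become temporal rules; this learner is designed to debias the
  graph from ubiquitous confounder events (e.g. blood sampling) that
  purely statistical learners turn into bottleneck nodes.

Rule graphs become Synthea modules (one `Encounter` state per concept,
`distributed_transition` edges normalized per state, `Initial`/`Terminal`
anchors), and graphs are compared by six complexity measures (nodes,
edges, density, average clustering, strongly connected components, flow
hierarchy) plus the pairwise percentage of identical directed edges.

A synthetic-cohort generator with a known ground-truth module (and a known
SVAR simulator) makes the whole pipeline testable end to end without
access to registry data.

## Worked example

Generate a confounded synthetic cohort, learn all three graphs, map one to
a Synthea module and compare them:

```bash
modulelearn synth --n 500 --vocab-size 20 --mean-length 5.5 \
    --confounder-rate 0.5 --seed 42 --out-dir data
modulelearn fit --sequences data/sequences.tsv --learner markov --out rules_markov.tsv
modulelearn fit --sequences data/sequences.tsv --learner tarm   --out rules_tarm.tsv
modulelearn fit --sequences data/sequences.tsv --learner dynotears --out rules_dyn.tsv
modulelearn map --rules rules_tarm.tsv --name demo-module --out module.json
modulelearn eval rules_markov.tsv rules_tarm.tsv rules_dyn.tsv --out-dir eval
```

which prints

```
wrote cohort N=500, D=21, mean length 7.17 to data
markov: 23 nodes, 141 edges -> rules_markov.tsv
tarm: 18 nodes, 46 edges -> rules_tarm.tsv
dynotears: 5 nodes, 5 edges -> rules_dyn.tsv
wrote module with 18 states to module.json
markov: n_nodes=23 n_edges=141 density=0.278656 avg_clustering=0.432162 n_scc=5 flow_hierarchy=0.269504
tarm: n_nodes=18 n_edges=46 density=0.150327 avg_clustering=0.435736 n_scc=18 flow_hierarchy=0.978261
dynotears: n_nodes=5 n_edges=5 density=0.25 avg_clustering=0.166667 n_scc=5 flow_hierarchy=1.0
```

The pattern is the method's main qualitative point: the Markov chain
*extracts* every observed transition (141 edges, low flow hierarchy — the
ubiquitous confounder makes it cyclic), rule mining compresses the data to
the frequent precedences, and the causal SVAR learner yields the most
compact, fully hierarchical graph. The overlap matrix
(`eval/overlap_matrix.tsv`) shows how much each graph's edges reappear in
the others, e.g. 76% of the mined rules are also Markov transitions while
the causal graph shares far fewer edges with either. A full multi-size,
multi-learner run with a manifest is available through
`modulelearn experiment --config config.yaml`.

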