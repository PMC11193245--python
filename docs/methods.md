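# Methods

This note documents the models, conventions, numerical choices and known
limitations of `modulelearn` — what each component assumes, which knobs
matter, and what the synthetic fixtures do and do not establish about real
registry data.

## Event-sequence model

A patient history is an ordered list of discrete medical observations
(OMOP concept ids) from the `condition_occurrence` and
`procedure_occurrence` tables, grouped by `person_id` and ordered by
encounter date. START (`-1`) and STOP (`-2`) sentinels wrap every
sequence so learners can model where histories begin and end, and so the
mapped module has an entry and exit point for sampling.

Time is the **event index**, not calendar time: the learners' t is the
position within the ordered sequence. Dates only determine the order;
same-day ties are broken by ascending concept id so the whole pipeline is
deterministic and permutation-invariant in its inputs. Rows with
`concept_id = 0` (OMOP's "no matching concept") and unparseable dates are
dropped and counted. Repeated same-day records of the same concept are
real observations and kept by default (`dedupe` removes them). The
intermediate exchange format is one line per patient:
`person_id TAB comma-separated concept ids`.

## Learners

### Markov chain

First order, over all concepts including sentinels. "Averaged across the
patient population" is implemented as pooled adjacent-pair counts — the
maximum-likelihood transition matrix — rather than an average of
per-patient conditional probabilities; the two agree when patients
contribute equal evidence and the pooled estimate is the standard one. No
smoothing is applied: probabilities are exact integer-count ratios, and
all-zero rows stay zero. `markov_to_rules` keeps every transition above
`min_prob` (default 0, i.e. everything observed), so the Markov graph
grows with the data — it *extracts* rather than learns, which is exactly
the behavior the comparison is designed to expose.

### Sequential rule mining

Rules are restricted to singleton antecedent/consequent because the
downstream Synthea edge is pairwise. For each ordered pair (x, y):
seqSup = sup(x y)/|S| with sup(x y) the number of sequences where some x
strictly precedes some y (each sequence counts once; x = y needs two
occurrences), and seqConf = sup(x y)/sup(x). A rule is emitted iff both
thresholds hold; the weight is seqConf. Defaults are min_seq_sup = 0.1
and min_seq_conf = 0.5, both configurable. START-anchored rules are
exempted from the confidence threshold so the mined graph always carries
an entry distribution — inconsequential in practice since START occurs in
every sequence, making its confidence equal its support. The scan is an
exhaustive O(N·T²) pass over per-sequence first/last occurrence indices
(equivalently O(N·T·D²) bounded by the vocabulary), ample at
encounter-history scale; no candidate-generation optimization is needed.

### Acyclicity-constrained SVAR

The causal learner estimates x_t = Wᵀx_t + Aᵀ[x_{t−1..t−p}] + ε by
minimizing

    ½M⁻¹‖X − XW − YA‖²_F + λ_w‖W‖₁ + λ_a‖A‖₁   s.t.  h(W) = 0,

with h(W) = tr(exp(W∘W)) − d, which is zero exactly when the intra-slice
graph is acyclic. The augmented-Lagrangian schedule is ρ₀ = 1, ρ ← 10ρ
whenever h fails to shrink by factor 4, α ← α + ρh, h_tol = 1e-8, up to
100 outer iterations; the inner problem is solved by L-BFGS-B over the
non-negative split W = W⁺ − W⁻, A = A⁺ − A⁻ (which makes the L1 terms
smooth), initialized at zero, with tight tolerances (ftol 1e-14,
gtol 1e-10) so the fit is deterministic and permutation-equivariant to
numerical precision. Gram matrices XᵀX, XᵀY, YᵀY are precomputed so each
gradient costs O(d³) regardless of sample count. The diagonal of W is
pinned to zero by box constraints.

Discrete sequences enter as **one-hot binary panels** over the event
index (the minimal encoding consistent with a discrete-state series):
each modelled concept is one 0/1 coordinate, each (t, t−1..t−p) window is
one row, and windows never cross patients. Lag order defaults to p = 1,
matching the reading of inter-slice edges as links from t to t+1. A
`top_k` frequency filter (default 100) caps the dimension, since the fit
is quadratic in d.

**Scaling and penalty defaults.** λ_w = λ_a = 0.1 with column
standardization is the default: on standardized columns the L1 weights
are scale-free, which is the sensible regime for binary panels whose
column variances span orders of magnitude. Coefficients are mapped back
to the original scale (W = D⁻¹W̃D for D = diag of column sds — a
similarity transform, so acyclicity is preserved) before the magnitude
threshold (default 0.3) selects edges. For *continuous* low-noise SVAR
panels, such as the recovery benchmark's (σ = 0.1, coefficients up to 1),
the appropriate setting is near-zero penalty on the raw scale
(λ = 0.001, `standardize=False`): a stable draw may be nearly unit-root,
which creates highly collinear current/lagged predictor pairs with
near-cancelling true coefficients, and any substantive L1 penalty drops
both members of such a pair. In that regime the estimator is effectively
penalized least squares plus thresholding, which recovers the support
essentially perfectly (mean SHD ≈ 0 over repeated 20-replicate blocks).
The lesson carries to practice: λ must be chosen relative to the data
scale, and the threshold, not the penalty, does the structure selection.

Inter-slice coefficients above the threshold become temporal rules
(provenance `dynotears-inter`; lags beyond 1 collapse onto one edge
keeping the largest magnitude); intra-slice coefficients are emitted too,
tagged `dynotears-intra`, so either subset can be selected downstream.
Edges out of STOP or into START are structurally impossible and skipped.

## Synthea mapping

One `Encounter` state per non-sentinel concept — a concept can occur only
once in a module, so state names are deduplicated labels; START becomes
`Initial`, STOP becomes `Terminal`. Outgoing rule weights are normalized
proportionally into a `distributed_transition` (the source material gives
weights but no recipe for turning them into probabilities; proportional
shares are the least-informative choice). Dead-end states route to
Terminal with probability 1, since every Synthea path must terminate.
States unreachable from Initial are pruned with a warning rather than an
error — real learners produce disconnected fragments. Distributions are
rounded to 6 decimals with the largest share absorbing the residue so
sums are exactly 1; the validator enforces 1e-9. Codes are recorded as
system "SNOMED-CT" with the OMOP concept id as code value — a documented
placeholder, not a terminology translation. Learned cycles are emitted
as-is (the module format tolerates them; the sampler truncates runaway
walks at `max_steps`), and their extent is reported via the flow-hierarchy
metric rather than silenced.

## Graph evaluation

Six measures per graph: node count, edge count, density m/(n(n−1)),
average clustering, number of strongly connected components (Tarjan via
networkx), and flow hierarchy = fraction of edges not inside any single
SCC, i.e. not on a directed cycle (Luo–Magee), so a DAG scores 1.
Directed clustering uses the all-directed-triangle (Fagiolo)
generalization; the undirected-projection variant is available behind a
flag because the two conventions differ and published values rarely say
which was used. Self-loops count as edges and as cyclic edges; the
density denominator stays n(n−1); clustering is computed with self-loops
removed. Edge overlap is 100·|E_r ∩ E_c|/|E_r| on unweighted directed
pairs — deliberately asymmetric (rows are the subject graph).

## Synthetic data

The cohort generator emulates the *shape* of a registry cohort — sample
size, vocabulary size, mean sequence length targeting ≈ 5.5 events
including sentinels — not clinical semantics. Ground truth is a random
layered DAG of Encounter states: each state continues to the next layer
with probability c (random Dirichlet shares) or terminates, with c solved
by bisection so the expected walk length matches the target. Synthetic
dates advance one day per step with 10% same-day ties by design, and
sequences are stored in canonical (date, concept id) order so the OMOP
CSV → ETL round trip is byte-identical. A ubiquitous
"blood-sampling-like" confounder is inserted after each event with
probability `confounder_rate`, reproducing the bottleneck bias that
motivates the causal learner. The SVAR simulator draws W acyclic by
construction along a random topological order, rejects draws until the
reduced-form companion matrix has spectral radius < 1, and generates one
burn-in-discarded trajectory.

What passing tests show — and do not. The generators establish that each
learner recovers the structure it is designed to recover under its own
model assumptions, and that every pipeline stage composes correctly. They
do not establish clinical validity on registry data: real histories have
heavy-tailed lengths, hierarchical vocabularies of hundreds of concepts,
informative calendar gaps, and confounding far messier than a single
inserted event.

## Experiment sizes and reproducibility

The default experiment and the acceptance script use a cohort of N = 1000
patients over D = 30 concepts with confounder rate 0.5, a 20-replicate
recovery benchmark at d = 5, M = 2000, and a 10,000-walk round trip —
sizes at which sampling error is well inside the tolerances asserted
(±0.02 on probabilities is ≈ 2–4 binomial standard errors at the
relevant counts). Markov and rule-mining cells are byte-identical across
reruns; the SVAR fit is deterministic given its zero initialization.
Subsampling ladders are nested by default (smaller samples drawn from the
larger) so graph-growth comparisons are not confounded by resampling
noise; independent subsamples are available via a flag. Runtime is
reported per cell but never asserted — it is hardware.

## Known limitations

* Only `Initial`/`Terminal`/`Encounter` states and distributed
  transitions are emitted; Synthea's conditional, loop, delay and guard
  constructs are out of scope.
* Rules are pairwise; multi-item antecedents/consequents are not mined.
* The SVAR learner models linear-Gaussian structure on one-hot
  indicators — a working approximation, not a generative model of
  categorical sequences.
* Concept codes are passed through, not translated to SNOMED-CT.
* The command-line interface reads CSV exports; live OMOP database access
  is not included.
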