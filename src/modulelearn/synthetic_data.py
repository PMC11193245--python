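"""Synthetic fixtures with known ground truth.

Two generators make every learner testable without access to real
registry data:

* a cohort generator that samples patient event sequences from a known,
  randomly constructed Synthea module (a layered DAG of Encounter states),
  optionally laced with a ubiquitous "blood-sampling-like" confounder
  event, and can write the cohort back out as OMOP-style occurrence CSVs
  so the full ETL path is exercised;
* an SVAR simulator producing continuous lagged panels from a known
  (W, A) pair, the oracle for structure-recovery tests.

The cohort generator emulates the *shape* of a registry cohort — sample
size, mean sequence length around 5.5 events, vocabulary size — not any
clinical semantics; concept ids are synthetic integers with fake labels.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .datatypes import (
    Concept,
    EventSequence,
    SequenceDataset,
    START_ID,
    STOP_ID,
    sentinel_concepts,
)
from .dynotears import DesignMatrices, SVARModel, h_acyclicity
from .synthea_mapper import (
    SyntheaModule,
    TERMINAL_STATE,
    _round_distribution,
    sample_module,
    validate_module,
)

#: Synthetic concept id reserved for the ubiquitous confounder event.
CONFOUNDER_ID = 9000
CONFOUNDER_LABEL = "blood sampling (synthetic)"

_BASE_CONCEPT_ID = 1000


@dataclass
class GeneratorConfig:
    """Shape parameters of the synthetic cohort.

    ``mean_length`` targets the mean total sequence length including the
    START/STOP sentinels; ``confounder_rate`` is the probability of
    inserting the confounder event after each sampled event.
    """

    n_patients: int = 1000
    vocab_size: int = 30
    mean_length: float = 5.5
    seed: int = 0
    confounder_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_length < 2:
            raise ValueError("mean_length must be >= 2 (sentinels alone)")
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if not 0.0 <= self.confounder_rate <= 1.0:
            raise ValueError("confounder_rate must lie in [0, 1]")


def _concept_label(i: int) -> str:
    return f"synthetic observation {i:03d}"


def random_ground_truth(config: GeneratorConfig) -> SyntheaModule:
    """A random layered-DAG module whose expected walk length matches
    ``mean_length``.

    States are arranged in layers; every state transitions to the next
    layer with continuation probability c (split by random Dirichlet
    weights) or to Terminal with 1-c, and the last layer is absorbing, so
    the expected number of Encounter visits is (1-c^L)/(1-c).  c is solved
    by bisection against the target mean_length - 2.
    """
    target = max(1.0, config.mean_length - 2.0)
    if target > config.vocab_size:
        raise ValueError(
            f"mean_length {config.mean_length} infeasible for vocab_size {config.vocab_size}"
        )
    n_layers = min(config.vocab_size, int(np.ceil(target)) + 2)

    def expected_visits(c: float) -> float:
        return float(sum(c**k for k in range(n_layers)))

    lo, hi = 0.0, 1.0 - 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_visits(mid) < target:
            lo = mid
        else:
            hi = mid
    cont = 0.5 * (lo + hi)

    rng = np.random.default_rng(config.seed)
    concept_ids = [_BASE_CONCEPT_ID + i for i in range(config.vocab_size)]
    # spread concepts over layers as evenly as possible, each layer non-empty
    layers: list[list[int]] = [[] for _ in range(n_layers)]
    for i, cid in enumerate(concept_ids):
        layers[i % n_layers].append(cid)

    labels = {cid: _concept_label(i) for i, cid in enumerate(concept_ids)}
    name_of = {cid: labels[cid] for cid in concept_ids}

    module = SyntheaModule(name=f"synthetic-ground-truth-seed{config.seed}")

    def distribute(targets: list[str], weights: np.ndarray) -> list[dict]:
        probs = _round_distribution(list(weights))
        return [
            {"distribution": p, "transition": t} for t, p in zip(targets, probs) if p > 0
        ] or [{"distribution": 1.0, "transition": TERMINAL_STATE}]

    entry_w = rng.dirichlet(np.ones(len(layers[0])))
    module.states["Initial"] = {
        "type": "Initial",
        "distributed_transition": distribute([name_of[c] for c in layers[0]], entry_w),
    }
    for li, layer in enumerate(layers):
        last = li == n_layers - 1
        for cid in layer:
            state = {
                "type": "Encounter",
                "encounter_class": "ambulatory",
                "codes": [{"system": "SNOMED-CT", "code": str(cid), "display": labels[cid]}],
            }
            if last:
                state["distributed_transition"] = [
                    {"distribution": 1.0, "transition": TERMINAL_STATE}
                ]
            else:
                nxt = layers[li + 1]
                w = rng.dirichlet(np.ones(len(nxt))) * cont
                targets = [name_of[c] for c in nxt] + [TERMINAL_STATE]
                weights = np.append(w, 1.0 - cont)
                state["distributed_transition"] = distribute(targets, weights)
            module.states[labels[cid]] = state
    module.states[TERMINAL_STATE] = {"type": "Terminal"}
    assert not validate_module(module)
    return module


def generate_cohort(
    config: GeneratorConfig,
    out_dir: Optional[str | Path] = None,
) -> tuple[SequenceDataset, SyntheaModule]:
    """Sample a cohort from a random ground-truth module.

    After each sampled event the confounder concept is inserted with
    probability ``confounder_rate``.  Synthetic calendar dates are attached
    (non-decreasing, with ~10% same-day ties so the ETL tie-break is
    exercised) and each sequence is put into the canonical
    (date, concept_id) order, so a round trip through the OMOP CSVs and
    the ETL reproduces the in-memory dataset exactly.  When ``out_dir`` is
    given, OMOP-style occurrence CSVs, a vocabulary CSV and the
    ground-truth module are written there.
    """
    module = random_ground_truth(config)
    rng = np.random.default_rng(config.seed + 1)
    base = sample_module(module, config.n_patients, seed=int(rng.integers(2**31)))

    vocab: dict[int, Concept] = {c.concept_id: c for c in sentinel_concepts()}
    for i in range(config.vocab_size):
        cid = _BASE_CONCEPT_ID + i
        domain = "condition" if i % 2 == 0 else "procedure"
        vocab[cid] = Concept(cid, _concept_label(i), domain)
    if config.confounder_rate > 0:
        vocab[CONFOUNDER_ID] = Concept(CONFOUNDER_ID, CONFOUNDER_LABEL, "procedure")

    sequences: list[EventSequence] = []
    for seq in base:
        ids: list[int] = []
        for cid in seq.concept_ids:
            if cid in (START_ID, STOP_ID):
                continue
            ids.append(cid)
            if config.confounder_rate > 0 and rng.random() < config.confounder_rate:
                ids.append(CONFOUNDER_ID)
        start = _dt.date(2016, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 5 * 365)))
        dates: list[_dt.date] = []
        day = start
        for k in range(len(ids)):
            if k > 0 and rng.random() >= 0.10:  # 10% of steps share a date
                day = day + _dt.timedelta(days=1)
            dates.append(day)
        dated = sorted(zip(ids, dates), key=lambda e: (e[1], e[0]))
        events = [(START_ID, None)] + [(c, d) for c, d in dated] + [(STOP_ID, None)]
        sequences.append(EventSequence(person_id=seq.person_id, events=events))

    dataset = SequenceDataset(
        sequences=sequences,
        vocabulary=vocab,
        provenance=f"synthetic cohort (seed={config.seed})",
    )
    dataset.validate()
    if out_dir is not None:
        write_omop_csvs(dataset, out_dir)
        module.write(Path(out_dir) / "ground_truth_module.json")
    return dataset, module


def write_omop_csvs(dataset: SequenceDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as OMOP-style condition/procedure occurrence CSVs
    plus a concept vocabulary CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "condition": out_dir / "condition_occurrence.csv",
        "procedure": out_dir / "procedure_occurrence.csv",
        "vocabulary": out_dir / "concept.csv",
    }
    with open(paths["condition"], "w", newline="") as fc, open(
        paths["procedure"], "w", newline=""
    ) as fp:
        wc = csv.writer(fc)
        wp = csv.writer(fp)
        wc.writerow(["person_id", "condition_concept_id", "condition_start_date"])
        wp.writerow(["person_id", "procedure_concept_id", "procedure_date"])
        for seq in dataset:
            for cid, date in seq.events:
                if cid in (START_ID, STOP_ID):
                    continue
                concept = dataset.vocabulary[cid]
                row = [seq.person_id, cid, date.isoformat()]
                (wc if concept.domain == "condition" else wp).writerow(row)
    with open(paths["vocabulary"], "w", newline="") as fv:
        wv = csv.writer(fv)
        wv.writerow(["concept_id", "concept_name"])
        for cid in dataset.concept_ids():
            if cid in (START_ID, STOP_ID):
                continue
            wv.writerow([cid, dataset.label(cid)])
    return paths


def simulate_svar(
    d: int,
    p: int = 1,
    edge_prob: float = 0.3,
    coef_range: tuple[float, float] = (0.5, 1.0),
    noise_sd: float = 0.1,
    M: int = 2000,
    seed: int = 0,
    max_rejections: int = 1000,
) -> tuple[DesignMatrices, SVARModel]:
    """Simulate a stable SVAR panel with known (W, A).

    W is drawn acyclic by construction (edges follow a random topological
    order; h(W) is asserted < 1e-10), coefficients have magnitude
    U(coef_range) and random sign.  Draws are rejected until the companion
    matrix of the reduced-form VAR has spectral radius < 1.  Data follow
    x_t = (I - W^T)^{-1} (A^T [lags] + eps), eps ~ N(0, noise_sd^2), as one
    long burn-in-discarded trajectory of M usable rows.
    """
    rng = np.random.default_rng(seed)
    low, high = coef_range

    def draw_coef(shape):
        mag = rng.uniform(low, high, size=shape)
        sign = rng.choice([-1.0, 1.0], size=shape)
        return mag * sign

    for _ in range(max_rejections):
        order = rng.permutation(d)
        W = np.zeros((d, d))
        for a in range(d):
            for b in range(a + 1, d):
                if rng.random() < edge_prob:
                    W[order[a], order[b]] = draw_coef(())
        A = np.where(rng.random((d * p, d)) < edge_prob, draw_coef((d * p, d)), 0.0)
        if h_acyclicity(W) >= 1e-10:
            continue
        # reduced form: x_t = sum_l B_l x_{t-l} + noise, B_l = inv(I-W^T) A_l^T
        inv = np.linalg.inv(np.eye(d) - W.T)
        blocks = [inv @ A[l * d : (l + 1) * d, :].T for l in range(p)]
        companion = np.zeros((d * p, d * p))
        for l, B in enumerate(blocks):
            companion[:d, l * d : (l + 1) * d] = B
        if p > 1:
            companion[d:, : d * (p - 1)] = np.eye(d * (p - 1))
        if np.max(np.abs(np.linalg.eigvals(companion))) < 1.0:
            break
    else:
        raise RuntimeError(f"no stable SVAR draw after {max_rejections} rejections")

    burn_in = 100
    T = M + p + burn_in
    x = np.zeros((T, d))
    for t in range(p, T):
        lags = np.concatenate([x[t - l] for l in range(1, p + 1)])
        eps = rng.normal(0.0, noise_sd, size=d)
        x[t] = inv @ (A.T @ lags + eps)
    rows = range(p + burn_in, T)
    X = x[list(rows)]
    Y = np.stack(
        [np.concatenate([x[t - l] for l in range(1, p + 1)]) for t in rows]
    )
    dm = DesignMatrices(X=X, Y=Y, p=p, concepts=list(range(d)))
    truth = SVARModel(W=W, A=A, p=p)
    return dm, truth
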