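"""ETL from OMOP CDM occurrence tables to per-patient event sequences.

Reads ``condition_occurrence`` and ``procedure_occurrence`` CSV exports,
merges them into one discrete time series per patient ordered by encounter
date, attaches START/STOP sentinels, and optionally maps concept ids to
human-readable labels from an Athena-style vocabulary export.

The time axis downstream is the event *index* within the ordered sequence,
not calendar time; dates only determine the ordering.  Same-day ties are
broken by ascending concept id so the pipeline is deterministic.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    SENTINEL_LABELS,
    START_ID,
    STOP_ID,
    Concept,
    EventSequence,
    SequenceDataset,
    sentinel_concepts,
)

logger = logging.getLogger(__name__)

#: (person, concept, date) column names per OMOP CDM v5 table.
DEFAULT_COLUMNS = {
    "condition": ("person_id", "condition_concept_id", "condition_start_date"),
    "procedure": ("person_id", "procedure_concept_id", "procedure_date"),
}

Record = tuple[str, int, _dt.date]


class ConfigurationError(ValueError):
    """A required column is missing or an input file is malformed."""


def read_occurrence_table(
    path: str | Path,
    table_kind: str,
    column_map: Optional[dict[str, str]] = None,
) -> list[Record]:
    """Read one OMOP occurrence table into (person_id, concept_id, date) records.

    Rows with ``concept_id == 0`` (OMOP's "no matching concept") or with
    unparseable dates are dropped and counted in the log.

    Parameters
    ----------
    path:
        CSV file with a header row.
    table_kind:
        ``"condition"`` or ``"procedure"``; selects the default CDM v5
        column names.
    column_map:
        Optional mapping with keys ``person_id``, ``concept_id``,
        ``event_date`` overriding the defaults.
    """
    if table_kind not in DEFAULT_COLUMNS:
        raise ValueError(f"unknown table_kind {table_kind!r}")
    person_col, concept_col, date_col = DEFAULT_COLUMNS[table_kind]
    if column_map:
        person_col = column_map.get("person_id", person_col)
        concept_col = column_map.get("concept_id", concept_col)
        date_col = column_map.get("event_date", date_col)

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty file", path)
        return []
    if df.empty and df.columns.size == 0:
        logger.warning("%s: empty file", path)
        return []
    for col in (person_col, concept_col, date_col):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: required column {col!r} not found")

    concept = pd.to_numeric(df[concept_col], errors="coerce")
    dates = pd.to_datetime(df[date_col], errors="coerce", format="ISO8601")
    bad_date = dates.isna()
    unmapped = concept.isna() | (concept == 0)
    keep = ~(bad_date | unmapped)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d of %d rows (%d unmapped concept, %d bad date)",
            path, n_dropped, len(df), int(unmapped.sum()), int(bad_date.sum()),
        )
    records = [
        (str(p), int(c), d.date())
        for p, c, d in zip(df[person_col][keep], concept[keep], dates[keep])
    ]
    return records


def build_sequences(records: Sequence[Record], dedupe: bool = False) -> SequenceDataset:
    """Group records by patient, order by (date, concept_id), attach sentinels.

    ``dedupe`` drops repeated same-day records of the same concept within a
    patient (kept by default; duplicate encounters are real observations).
    """
    if not records:
        raise ValueError("no records to build sequences from")
    by_person: dict[str, list[tuple[int, _dt.date]]] = {}
    for person_id, concept_id, date in records:
        by_person.setdefault(person_id, []).append((concept_id, date))

    vocab: dict[int, Concept] = {c.concept_id: c for c in sentinel_concepts()}
    sequences = []
    for person_id in sorted(by_person):
        events = sorted(by_person[person_id], key=lambda e: (e[1], e[0]))
        if dedupe:
            deduped: list[tuple[int, _dt.date]] = []
            for ev in events:
                if not deduped or deduped[-1] != ev:
                    deduped.append(ev)
            events = deduped
        for cid, _ in events:
            if cid not in vocab:
                vocab[cid] = Concept(cid, f"concept_{cid}")
        seq_events: list[tuple[int, Optional[_dt.date]]] = [(START_ID, None)]
        seq_events.extend((cid, d) for cid, d in events)
        seq_events.append((STOP_ID, None))
        sequences.append(EventSequence(person_id=person_id, events=seq_events))
    ds = SequenceDataset(sequences=sequences, vocabulary=vocab, provenance="omop_etl")
    ds.validate()
    return ds


def subsample(dataset: SequenceDataset, n: int, seed: int) -> SequenceDataset:
    """Uniform sample of ``n`` sequences without replacement; vocabulary recomputed."""
    if n > dataset.n:
        raise ValueError(f"cannot subsample {n} from {dataset.n} sequences")
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    if n == dataset.n:
        return dataset
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(dataset.n, size=n, replace=False))
    sequences = [dataset.sequences[i] for i in idx]
    vocab = {c.concept_id: c for c in sentinel_concepts()}
    for seq in sequences:
        for cid in seq.concept_ids:
            if cid not in vocab:
                vocab[cid] = dataset.vocabulary.get(cid, Concept(cid, f"concept_{cid}"))
    return SequenceDataset(
        sequences=sequences,
        vocabulary=vocab,
        provenance=f"{dataset.provenance}|subsample(n={n},seed={seed})",
    )


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def map_labels(dataset: SequenceDataset, vocabulary_path: str | Path) -> SequenceDataset:
    """Attach concept_name labels from an Athena-style vocabulary CSV/TSV.

    Unknown ids keep the ``concept_<id>`` fallback with a warning; sentinels
    always keep their START/STOP labels.
    """
    vocabulary_path = Path(vocabulary_path)
    sep = _sniff_delimiter(vocabulary_path)
    df = pd.read_csv(vocabulary_path, sep=sep, dtype=str)
    for col in ("concept_id", "concept_name"):
        if col not in df.columns:
            raise ConfigurationError(f"{vocabulary_path}: required column {col!r} not found")
    name_by_id = {
        int(cid): name
        for cid, name in zip(pd.to_numeric(df["concept_id"], errors="coerce"), df["concept_name"])
        if not pd.isna(cid)
    }
    vocab: dict[int, Concept] = {}
    for cid, concept in dataset.vocabulary.items():
        if cid in SENTINEL_LABELS:
            vocab[cid] = Concept(cid, SENTINEL_LABELS[cid], "sentinel")
        elif cid in name_by_id:
            vocab[cid] = Concept(cid, name_by_id[cid], concept.domain)
        else:
            logger.warning("concept id %d not in vocabulary file; using fallback label", cid)
            vocab[cid] = Concept(cid, f"concept_{cid}", concept.domain)
    return SequenceDataset(
        sequences=dataset.sequences, vocabulary=vocab, provenance=dataset.provenance
    )


# ---------------------------------------------------------------------------
# Intermediate sequence file: the canonical exchange format between the ETL
# and the learners.  One line per patient: person_id TAB comma-separated
# concept ids, sentinels included.

def write_sequences(dataset: SequenceDataset, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for seq in dataset.sequences:
            fh.write(f"{seq.person_id}\t{','.join(str(c) for c in seq.concept_ids)}\n")


def read_sequences(path: str | Path, labels: Optional[dict[int, str]] = None) -> SequenceDataset:
    labels = labels or {}
    sequences = []
    vocab: dict[int, Concept] = {c.concept_id: c for c in sentinel_concepts()}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            person_id, ids_str = line.split("\t")
            ids = [int(tok) for tok in ids_str.split(",")]
            sequences.append(EventSequence(person_id=person_id, events=[(c, None) for c in ids]))
            for cid in ids:
                if cid not in vocab:
                    vocab[cid] = Concept(cid, labels.get(cid, f"concept_{cid}"))
    ds = SequenceDataset(sequences=sequences, vocabulary=vocab, provenance=str(path))
    ds.validate()
    return ds


def write_vocabulary(dataset: SequenceDataset, path: str | Path) -> None:
    """Write the dataset vocabulary as a concept_id,concept_name CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concept_id", "concept_name"])
        for cid in dataset.concept_ids():
            if cid in SENTINEL_LABELS:
                continue
            writer.writerow([cid, dataset.label(cid)])
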