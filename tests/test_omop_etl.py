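"""ETL: occurrence-table reading, sequence building, subsampling, labels."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modulelearn import omop_etl
from modulelearn.datatypes import START_ID, STOP_ID


def write_csv(path, header, rows):
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")
    return path


class TestReadOccurrenceTable:
    def test_concept_zero_and_bad_dates_dropped(self, tmp_path):
        path = write_csv(
            tmp_path / "cond.csv",
            ["person_id", "condition_concept_id", "condition_start_date"],
            [("p1", 4115276, "2016-03-01"), ("p1", 0, "2016-03-02"), ("p2", 5, "not-a-date")],
        )
        records = omop_etl.read_occurrence_table(path, "condition")
        assert records == [("p1", 4115276, dt.date(2016, 3, 1))]

    def test_table_kind_selects_cdm_default_columns(self, tmp_path):
        cond = write_csv(
            tmp_path / "cond.csv",
            ["person_id", "condition_concept_id", "condition_start_date"],
            [("p1", 1, "2016-01-01"), ("p1", 2, "2016-01-02"), ("p2", 3, "2016-01-03")],
        )
        proc = write_csv(
            tmp_path / "proc.csv",
            ["person_id", "procedure_concept_id", "procedure_date"],
            [("p1", 9, "2016-02-01")],
        )
        assert len(omop_etl.read_occurrence_table(cond, "condition")) == 3
        assert len(omop_etl.read_occurrence_table(proc, "procedure")) == 1

    def test_column_map_override(self, tmp_path):
        path = write_csv(
            tmp_path / "odd.csv",
            ["pid", "code", "when"],
            [("p1", 7, "2020-05-05")],
        )
        records = omop_etl.read_occurrence_table(
            path, "condition",
            column_map={"person_id": "pid", "concept_id": "code", "event_date": "when"},
        )
        assert records == [("p1", 7, dt.date(2020, 5, 5))]

    def test_missing_column_names_the_column(self, tmp_path):
        path = write_csv(tmp_path / "bad.csv", ["person_id", "x"], [("p1", 1)])
        with pytest.raises(omop_etl.ConfigurationError, match="condition_concept_id"):
            omop_etl.read_occurrence_table(path, "condition")

    def test_empty_file_returns_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert omop_etl.read_occurrence_table(path, "condition") == []


class TestBuildSequences:
    def test_orders_by_date_and_attaches_sentinels(self):
        d1, d2 = dt.date(2016, 1, 1), dt.date(2016, 1, 2)
        ds = omop_etl.build_sequences([("p1", 5, d2), ("p1", 4, d1)])
        assert ds.sequences[0].concept_ids == [START_ID, 4, 5, STOP_ID]

    def test_same_day_tie_broken_by_concept_id(self):
        d = dt.date(2016, 1, 1)
        ds = omop_etl.build_sequences([("p1", 8, d), ("p1", 3, d)])
        assert ds.sequences[0].concept_ids == [START_ID, 3, 8, STOP_ID]

    def test_mean_length_includes_sentinels(self):
        d = dt.date(2016, 1, 1)
        records = [("p1", c, d) for c in (1, 2, 3)] + [("p2", c, d) for c in (4, 5)]
        ds = omop_etl.build_sequences(records)
        assert ds.n == 2
        assert ds.mean_length() == pytest.approx(4.5)

    def test_total_length_is_records_plus_two_per_patient(self):
        rng = np.random.default_rng(0)
        records = [
            (f"p{rng.integers(4)}", int(rng.integers(1, 6)),
             dt.date(2016, 1, 1) + dt.timedelta(days=int(rng.integers(30))))
            for _ in range(40)
        ]
        ds = omop_etl.build_sequences(records)
        assert sum(len(s) for s in ds) == len(records) + 2 * ds.n

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.permutations(list(range(12))))
    def test_permutation_invariant(self, order):
        base = [
            (f"p{i % 3}", 1 + i % 4, dt.date(2016, 1, 1) + dt.timedelta(days=i % 5))
            for i in range(12)
        ]
        ds_a = omop_etl.build_sequences(base)
        ds_b = omop_etl.build_sequences([base[i] for i in order])
        assert [s.events for s in ds_a] == [s.events for s in ds_b]
        assert [s.person_id for s in ds_a] == [s.person_id for s in ds_b]

    def test_dedupe_drops_repeated_same_day_concept(self):
        d = dt.date(2016, 1, 1)
        records = [("p1", 5, d), ("p1", 5, d), ("p1", 5, d + dt.timedelta(days=1))]
        assert omop_etl.build_sequences(records).sequences[0].concept_ids == [
            START_ID, 5, 5, 5, STOP_ID
        ]
        assert omop_etl.build_sequences(records, dedupe=True).sequences[0].concept_ids == [
            START_ID, 5, 5, STOP_ID
        ]


class TestSubsample:
    @pytest.fixture
    def dataset(self):
        d = dt.date(2016, 1, 1)
        return omop_etl.build_sequences([(f"p{i}", 1 + i % 5, d) for i in range(20)])

    def test_identity_when_n_equals_dataset_size(self, dataset):
        assert omop_etl.subsample(dataset, dataset.n, seed=3) is dataset

    def test_single_sequence(self, dataset):
        sub = omop_etl.subsample(dataset, 1, seed=5)
        assert sub.n == 1
        assert sub.sequences[0] in dataset.sequences

    def test_deterministic_for_fixed_seed(self, dataset):
        ids = lambda ds: [s.person_id for s in ds]
        assert ids(omop_etl.subsample(dataset, 7, seed=11)) == ids(
            omop_etl.subsample(dataset, 7, seed=11)
        )

    def test_vocabulary_recomputed(self, dataset):
        sub = omop_etl.subsample(dataset, 3, seed=1)
        used = {cid for s in sub for cid in s.concept_ids}
        assert set(sub.vocabulary) == used | {START_ID, STOP_ID}

    def test_oversample_rejected(self, dataset):
        with pytest.raises(ValueError):
            omop_etl.subsample(dataset, dataset.n + 1, seed=0)


class TestMapLabels:
    def test_known_unknown_and_sentinel_labels(self, tmp_path):
        d = dt.date(2016, 1, 1)
        ds = omop_etl.build_sequences([("p1", 4115276, d), ("p1", 999, d)])
        vocab = tmp_path / "concept.csv"
        vocab.write_text("concept_id,concept_name\n4115276,Lobectomy\n")
        mapped = omop_etl.map_labels(ds, vocab)
        assert mapped.label(4115276) == "Lobectomy"
        assert mapped.label(999) == "concept_999"
        assert mapped.label(START_ID) == "START"
        assert mapped.label(STOP_ID) == "STOP"

    def test_tab_separated_vocabulary_autodetected(self, tmp_path):
        d = dt.date(2016, 1, 1)
        ds = omop_etl.build_sequences([("p1", 42, d)])
        vocab = tmp_path / "concept.tsv"
        vocab.write_text("concept_id\tconcept_name\n42\tBiopsy\n")
        assert omop_etl.map_labels(ds, vocab).label(42) == "Biopsy"

    def test_missing_columns_rejected(self, tmp_path):
        d = dt.date(2016, 1, 1)
        ds = omop_etl.build_sequences([("p1", 42, d)])
        vocab = tmp_path / "bad.csv"
        vocab.write_text("id,name\n42,Biopsy\n")
        with pytest.raises(omop_etl.ConfigurationError):
            omop_etl.map_labels(ds, vocab)


def test_sequence_file_round_trip(tmp_path):
    d = dt.date(2016, 1, 1)
    ds = omop_etl.build_sequences(
        [("p1", 5, d), ("p1", 3, d), ("p2", 7, d + dt.timedelta(days=2))]
    )
    path = tmp_path / "sequences.tsv"
    omop_etl.write_sequences(ds, path)
    back = omop_etl.read_sequences(path)
    assert [s.person_id for s in back] == [s.person_id for s in ds]
    assert [s.concept_ids for s in back] == [s.concept_ids for s in ds]
    # writing again is byte-identical
    path2 = tmp_path / "again.tsv"
    omop_etl.write_sequences(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_every_sequence_wrapped_in_sentinels():
    rng = np.random.default_rng(1)
    records = [
        (f"p{rng.integers(6)}", int(rng.integers(1, 9)),
         dt.date(2017, 1, 1) + dt.timedelta(days=int(rng.integers(100))))
        for _ in range(60)
    ]
    for seq in omop_etl.build_sequences(records):
        assert seq.concept_ids[0] == START_ID
        assert seq.concept_ids[-1] == STOP_ID
        assert all(c not in (START_ID, STOP_ID) for c in seq.concept_ids[1:-1])
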