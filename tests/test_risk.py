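"""Equivalence classes, prosecutor risk, categories, gate, recommendations."""

import json
from collections import Counter

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wisedeid as w
from wisedeid.deid import ActionKind, SharingContext
from wisedeid.detection import QuasiKind
from wisedeid.errors import OutOfRange
from wisedeid.risk import (GateDecision, RiskCategory, Thresholds, categorize,
                           equivalence_classes, gate, prosecutor_risk, recommend,
                           single_record_category)

from conftest import random_quasi_table

TRUSTED = SharingContext.TRUSTED_PARTY
PUBLIC = SharingContext.GENERAL_AUDIENCE


def pandas_oracle(table):
    """Independent group-and-count of quasi tuples."""
    df = pd.DataFrame(table)
    return df.groupby(list(df.columns)).size().sort_index()


class TestEquivalenceClasses:
    def test_identical_tuples_form_one_class(self):
        classes = equivalence_classes([("1984", "101", "f")] * 10)
        assert len(classes) == 1 and classes[0].size == 10

    def test_all_distinct_tuples(self):
        classes = equivalence_classes([(str(i),) for i in range(5)])
        assert sorted(c.size for c in classes) == [1] * 5

    @pytest.mark.parametrize("seed", range(10))
    def test_class_sizes_match_pandas_groupby_oracle(self, seed):
        table = random_quasi_table(seed, n_max=400)
        sizes = sorted(c.size for c in equivalence_classes(table))
        oracle = sorted(pandas_oracle(table).tolist())
        assert sizes == oracle

    def test_partition_covers_all_records(self):
        table = random_quasi_table(42)
        classes = equivalence_classes(table)
        assert sum(c.size for c in classes) == len(table)
        indices = sorted(i for c in classes for i in c.record_indices)
        assert indices == list(range(len(table)))

    def test_missing_values_are_their_own_equivalence_value(self):
        records = [{"a": "x"}, {}]
        classes = equivalence_classes(records, ["a"])
        assert len(classes) == 2

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("xy")),
                    min_size=1, max_size=50))
    def test_partition_invariants_hold_for_any_table(self, table):
        classes = equivalence_classes(table)
        assert all(c.size >= 1 for c in classes)
        assert sum(c.size for c in classes) == len(table)
        stats = prosecutor_risk(classes)
        assert all(0.0 < r <= 1.0 for r in stats["per_record_risk"])
        assert stats["avg_risk"] <= stats["max_risk"]


class TestProsecutorRisk:
    def test_uniform_class_of_10(self):
        stats = prosecutor_risk(equivalence_classes([("x",)] * 10))
        assert stats["per_record_risk"] == [0.1] * 10
        assert stats["max_risk"] == 0.1

    def test_singleton_class_dominates(self):
        stats = prosecutor_risk(equivalence_classes([("a",), ("a",), ("b",)]))
        assert stats["max_risk"] == 1.0
        assert stats["unique_fraction"] == pytest.approx(1 / 3)

    def test_min_class_size_4_gives_quarter_risk(self):
        table = [("a",)] * 4 + [("b",)] * 6
        stats = prosecutor_risk(equivalence_classes(table))
        # oracle: smallest group has 4 members
        assert min(pandas_oracle(table)) == 4
        assert stats["max_risk"] == 0.25

    @pytest.mark.parametrize("seed", range(5))
    def test_risks_match_oracle_counts(self, seed):
        table = random_quasi_table(seed + 100, n_max=300)
        stats = prosecutor_risk(equivalence_classes(table))
        counts = Counter(table)
        expected = [1.0 / counts[row] for row in table]
        assert stats["per_record_risk"] == expected
        assert stats["avg_risk"] == pytest.approx(sum(expected) / len(expected))


class TestCategoriesAndGate:
    @pytest.mark.parametrize("risk,category", [
        (0.05, RiskCategory.LOW),
        (0.10, RiskCategory.LOW),          # boundary pinned
        (0.10 + 1e-9, RiskCategory.MEDIUM),
        (0.25, RiskCategory.MEDIUM),
        (0.34, RiskCategory.MEDIUM),
        (0.35, RiskCategory.HIGH),
        (1.0, RiskCategory.HIGH),
    ])
    def test_categorize(self, risk, category):
        assert categorize(risk) is category

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range(self, bad):
        with pytest.raises(OutOfRange):
            categorize(bad)

    def test_thresholds_configurable(self):
        assert categorize(0.4, Thresholds(low=0.5, medium=0.9)) is RiskCategory.LOW

    def test_gate_truth_table_exhaustive(self):
        expected = {
            (RiskCategory.LOW, TRUSTED): GateDecision.ACCEPT,
            (RiskCategory.LOW, PUBLIC): GateDecision.ACCEPT,
            (RiskCategory.MEDIUM, TRUSTED): GateDecision.ACCEPT,
            (RiskCategory.MEDIUM, PUBLIC): GateDecision.REJECT,
            (RiskCategory.HIGH, TRUSTED): GateDecision.REJECT,
            (RiskCategory.HIGH, PUBLIC): GateDecision.REJECT,
        }
        for (category, context), decision in expected.items():
            assert gate(category, context) is decision

    def test_sweep_yields_exactly_three_categories(self):
        labels = {categorize(i / 1000).value for i in range(1, 1001)}
        assert labels == {"LOW", "MEDIUM", "HIGH"}


def _scan_record(resource: dict):
    flat = w.flatten(w.parse(json.dumps(resource)))
    return w.scan(flat, w.default_registry())


class TestSingleRecordMode:
    def test_full_birth_date_is_high(self):
        annotated = _scan_record({"resourceType": "Patient",
                                  "birthDate": "1984-07-21"})
        assert single_record_category(annotated) is RiskCategory.HIGH

    def test_year_and_gender_is_low(self):
        annotated = _scan_record({"resourceType": "Patient",
                                  "birthDate": "1984", "gender": "female"})
        assert single_record_category(annotated) is RiskCategory.LOW

    def test_three_generalized_quasi_is_medium(self):
        annotated = _scan_record({"resourceType": "Patient",
                                  "birthDate": "1984", "gender": "female",
                                  "address": [{"postalCode": "101"}]})
        assert single_record_category(annotated) is RiskCategory.MEDIUM

    def test_remaining_direct_identifier_is_high(self):
        annotated = _scan_record({"resourceType": "Patient",
                                  "name": [{"family": "Doe"}]})
        assert single_record_category(annotated) is RiskCategory.HIGH


def _records_from_columns(**columns):
    """Build FlatRecords holding the given quasi columns."""
    from wisedeid.formats import FlatEntry, FlatRecord, FormatKind, ValueKind
    n = len(next(iter(columns.values())))
    records = []
    for i in range(n):
        entries = [FlatEntry(path, str(vals[i]), ValueKind.TEXT)
                   for path, vals in columns.items()]
        records.append(FlatRecord(entries=entries,
                                  format=FormatKind.FHIR_JSON_RESOURCE))
    return records


class TestRecommend:
    def test_full_dates_trigger_year_generalization_first(self):
        records = _records_from_columns(**{
            "Patient.birthDate": [f"19{60 + i}-01-0{1 + i % 5}" for i in range(12)],
            "Patient.gender": ["female"] * 12,
        })
        amendments = recommend(records, ["Patient.birthDate", "Patient.gender"],
                               {"Patient.birthDate": QuasiKind.DATE,
                                "Patient.gender": QuasiKind.GENDER},
                               TRUSTED)
        assert amendments, "gate fails, so amendments must be proposed"
        first = amendments[0]
        assert first.path == "Patient.birthDate"
        assert first.action.kind is ActionKind.GENERALIZE and first.action.level == 1

    def test_accepting_dataset_needs_no_amendments(self):
        records = _records_from_columns(**{"Patient.gender": ["f"] * 20})
        report = w.assess(records, ["Patient.gender"], PUBLIC)
        assert report.gate is GateDecision.ACCEPT
        assert recommend(records, ["Patient.gender"],
                         {"Patient.gender": QuasiKind.GENDER}, PUBLIC) == []

    def test_loop_terminates_in_accept_or_exhaustion(self):
        records = _records_from_columns(**{
            "Patient.birthDate": [f"19{50 + i}-03-15" for i in range(15)],
            "Patient.address.postalCode": [f"{10100 + 7 * i}" for i in range(15)],
        })
        kinds = {"Patient.birthDate": QuasiKind.DATE,
                 "Patient.address.postalCode": QuasiKind.POSTAL}
        amendments = recommend(records, list(kinds), kinds, PUBLIC)
        # replay the amendments and verify the gate now accepts
        columns = {p: [r.value_at(p) for r in records] for p in kinds}
        for a in amendments:
            if a.action is None:
                continue
            if a.action.kind is ActionKind.SUPPRESS:
                columns[a.path] = ["*"] * 15
            else:
                columns[a.path] = [w.generalize(v, kinds[a.path], a.action.level)
                                   for v in columns[a.path]]
        rows = list(zip(*columns.values()))
        stats = prosecutor_risk(equivalence_classes(rows))
        assert gate(categorize(stats["max_risk"]), PUBLIC) is GateDecision.ACCEPT


class TestGeneralizationMonotonicity:
    @pytest.mark.parametrize("seed", range(20))
    def test_coarsening_never_increases_max_risk(self, seed):
        import random
        rng = random.Random(seed)
        n = rng.randint(10, 200)
        dates = [f"{rng.randint(1950, 2005)}-{rng.randint(1, 12):02d}-15"
                 for _ in range(n)]
        genders = [rng.choice(["f", "m"]) for _ in range(n)]
        base = list(zip(dates, genders))
        risk0 = prosecutor_risk(equivalence_classes(base))["max_risk"]
        for level in (1, 2):
            coarse = list(zip([w.generalize(d, QuasiKind.DATE, level)
                               for d in dates], genders))
            risk1 = prosecutor_risk(equivalence_classes(coarse))["max_risk"]
            assert risk1 <= risk0
            risk0 = risk1
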