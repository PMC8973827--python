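"""Exclusion cascade, covariate coding, and outcome aggregation."""

import pandas as pd
import pytest

from notelex.classify import NEGATIVE, OUT_OF_CONTEXT, POSITIVE
from notelex.cohort import (
    EncounterRecord,
    PatientRecord,
    aggregate_note_outcomes,
    apply_exclusion_cascade,
    apply_sensitivity_exclusion,
    build_model_rows,
    code_covariates,
    patient_negative_note_counts,
    patient_prevalence_percent,
    patients_from_frame,
    patients_to_frame,
)


def _patient(pid="p1", **kw):
    base = dict(
        patient_id=pid,
        race_ethnicity="white",
        age_band="65+",
        sex="male",
        insurance="private",
        married=True,
        english_primary=True,
        covid_positive=False,
    )
    base.update(kw)
    return PatientRecord(**base)


def _encounter(eid="e1", pid="p1", **kw):
    base = dict(
        encounter_id=eid, patient_id=pid, location="inpatient",
        length_days=3.0, cci=1.0, after_cutoff=False,
    )
    base.update(kw)
    return EncounterRecord(**base)


def build_registry(n_dementia=647, n_missing_race=1564, n_missing_cov=978, n_complete=18459):
    """A synthetic registry with the target exclusion structure."""
    registry = []
    i = 0
    for _ in range(n_dementia):
        registry.append(_patient(f"p{i}", icd10_codes=("F03.90",))); i += 1
    for _ in range(n_missing_race):
        registry.append(_patient(f"p{i}", race_ethnicity=None)); i += 1
    for _ in range(n_missing_cov):
        registry.append(_patient(f"p{i}", insurance=None)); i += 1
    for _ in range(n_complete):
        registry.append(_patient(f"p{i}")); i += 1
    return registry


def test_cascade_reproduces_stage_counts():
    registry = build_registry()
    cohort, report = apply_exclusion_cascade(registry)
    stages = {name: (n_in, n_ex, n_ret) for name, n_in, n_ex, n_ret in report.stages}
    assert stages["dementia_diagnosis"] == (21648, 647, 21001)
    assert stages["missing_race_ethnicity"] == (21001, 1564, 19437)
    assert stages["missing_covariates"] == (19437, 978, 18459)
    assert len(cohort) == 18459


def test_cascade_conservation_and_chaining():
    _, report = apply_exclusion_cascade(build_registry(10, 20, 30, 40))
    prev_ret = None
    for _, n_in, n_ex, n_ret in report.stages:
        assert n_in == n_ex + n_ret
        if prev_ret is not None:
            assert n_in == prev_ret
        prev_ret = n_ret


def test_cascade_edge_cases():
    cohort, report = apply_exclusion_cascade([])
    assert cohort == [] and report.final_n == 0
    clean = [_patient(f"p{i}") for i in range(5)]
    cohort, _ = apply_exclusion_cascade(clean)
    assert len(cohort) == 5
    all_missing = [_patient(f"p{i}", race_ethnicity=None) for i in range(5)]
    cohort, _ = apply_exclusion_cascade(all_missing)
    assert cohort == []


def test_sensitivity_exclusion_is_a_pure_filter():
    cohort = [_patient(f"p{i}", icd10_codes=("F10.1",) if i % 10 == 0 else ()) for i in range(100)]
    assert apply_sensitivity_exclusion(cohort, []) == cohort
    assert apply_sensitivity_exclusion(cohort, ["F"]) == [p for p in cohort if not p.icd10_codes]
    assert len(apply_sensitivity_exclusion(cohort, ["F10"])) == 90


def test_code_covariates_reference_row_is_all_zero():
    row = code_covariates(_patient(), _encounter())
    indicators = {k: v for k, v in row.items() if k not in ("cci", "length_days")}
    assert all(v == 0.0 for v in indicators.values())
    assert row["cci"] == 1.0 and row["length_days"] == 3.0


def test_code_covariates_sets_expected_indicators():
    row = code_covariates(
        _patient(race_ethnicity="black", insurance="medicaid"),
        _encounter(location="outpatient", after_cutoff=True),
    )
    assert row["race_black"] == 1.0 and row["ins_medicaid"] == 1.0
    assert row["race_hispanic_latino"] == 0.0 and row["ins_medicare"] == 0.0
    assert row["loc_outpatient"] == 1.0 and row["loc_ed"] == 0.0
    assert row["after_cutoff"] == 1.0


def test_closed_category_sets_are_enforced():
    with pytest.raises(ValueError, match="insurance"):
        _patient(insurance="tricare")
    with pytest.raises(ValueError, match="location"):
        _encounter(location="telehealth")
    with pytest.raises(ValueError, match="missing insurance"):
        code_covariates(_patient(insurance=None), _encounter())


def test_aggregate_note_outcomes_at_least_one_rule():
    labels = [
        ("n1", POSITIVE), ("n1", OUT_OF_CONTEXT),
        ("n2", POSITIVE), ("n2", NEGATIVE),
    ]
    notes = [("n1", "e1", "p1"), ("n2", "e1", "p1"), ("n3", "e2", "p2")]
    outcomes = {o.note_id: o for o in aggregate_note_outcomes(labels, notes)}
    assert outcomes["n1"].any_negative == 0
    assert outcomes["n2"].any_negative == 1
    assert outcomes["n3"].any_negative == 0 and outcomes["n3"].n_positive_sentences == 0
    for o in outcomes.values():
        assert o.any_negative == (1 if o.n_negative_sentences >= 1 else 0)


def test_aggregation_is_monotone_in_negative_sentences():
    labels = [("n1", POSITIVE)]
    notes = [("n1", "e1", "p1")]
    before = aggregate_note_outcomes(labels, notes)[0].any_negative
    after = aggregate_note_outcomes(labels + [("n1", NEGATIVE)], notes)[0].any_negative
    assert before == 0 and after == 1


def test_patient_counts_zero_fill_and_conservation():
    notes = [("n1", "e1", "p1"), ("n2", "e1", "p1"), ("n3", "e2", "p1"), ("n4", "e3", "p2")]
    labels = [("n1", NEGATIVE), ("n3", NEGATIVE), ("n4", POSITIVE)]
    outcomes = aggregate_note_outcomes(labels, notes)
    counts = patient_negative_note_counts(outcomes, patient_ids=["p1", "p2", "p3"])
    assert counts["p1"] == 2 and counts["p2"] == 0 and counts["p3"] == 0
    assert counts.sum() == sum(o.any_negative for o in outcomes)


def test_prevalence_computed_two_ways_agrees():
    notes = [(f"n{i}", f"e{i}", f"p{i % 5}") for i in range(10)]
    labels = [("n0", NEGATIVE), ("n5", NEGATIVE), ("n7", NEGATIVE)]
    outcomes = aggregate_note_outcomes(labels, notes)
    counts = patient_negative_note_counts(outcomes, patient_ids=[f"p{i}" for i in range(5)])
    via_counts = patient_prevalence_percent(counts)
    flagged = {o.patient_id for o in outcomes if o.any_negative}
    via_notes = 100.0 * len(flagged) / 5
    assert via_counts == pytest.approx(via_notes)


def test_patient_table_round_trip_preserves_missingness(tmp_path):
    patients = [
        _patient("a"),
        _patient("b", race_ethnicity=None, icd10_codes=("F03", "I10")),
        _patient("c", married=None, covid_positive=True),
    ]
    frame = patients_to_frame(patients)
    path = tmp_path / "patients.tsv"
    frame.to_csv(path, sep="\t", index=False)
    back = patients_from_frame(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))
    assert back == patients


def test_build_model_rows_joins_hierarchy():
    patients = [_patient("p1", race_ethnicity="black"), _patient("p2")]
    encounters = [_encounter("e1", "p1"), _encounter("e2", "p2", location="ed")]
    outcomes = aggregate_note_outcomes(
        [("n1", NEGATIVE)], [("n1", "e1", "p1"), ("n2", "e2", "p2")]
    )
    rows = build_model_rows(patients, encounters, outcomes)
    assert len(rows) == 2
    assert rows.set_index("note_id").loc["n1", "outcome"] == 1
    assert rows.set_index("note_id").loc["n1", "race_black"] == 1.0
    assert rows.set_index("note_id").loc["n2", "loc_ed"] == 1.0
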