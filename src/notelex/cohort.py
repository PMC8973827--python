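"""Analytic cohort construction, covariate coding and outcome aggregation.

The analysis cohort is built by an ordered exclusion cascade
(diagnosis-based exclusion, then missing race/ethnicity, then missing
covariates) with per-stage accounting, mirroring standard EHR cohort
reporting.  Sentence-level context labels are aggregated to the
note-level binary outcome — at least one negatively-used descriptor in
the note — and to per-patient counts of negative notes.

Missing values are explicit (``None`` in memory, the sentinel ``NA`` in
delimited files); nothing is ever imputed silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import NEGATIVE, OUT_OF_CONTEXT, POSITIVE

__all__ = [
    "RACE_LEVELS",
    "AGE_BANDS",
    "SEX_LEVELS",
    "INSURANCE_LEVELS",
    "LOCATION_LEVELS",
    "ADJUSTED_TERMS",
    "PatientRecord",
    "EncounterRecord",
    "NoteOutcome",
    "CascadeReport",
    "apply_exclusion_cascade",
    "apply_sensitivity_exclusion",
    "code_covariates",
    "aggregate_note_outcomes",
    "patient_negative_note_counts",
    "patient_prevalence_percent",
    "build_model_rows",
    "patients_to_frame",
    "patients_from_frame",
    "encounters_to_frame",
    "encounters_from_frame",
]

#: Sentinel for missing values in delimited files.
NA = "NA"

RACE_LEVELS = ("white", "black", "hispanic_latino", "other")
AGE_BANDS = ("0-17", "18-29", "30-44", "45-64", "65+")
SEX_LEVELS = ("male", "female")
INSURANCE_LEVELS = ("medicaid", "medicare", "private")
LOCATION_LEVELS = ("inpatient", "outpatient", "ed")

#: Design columns of the fully adjusted model, in reporting order.
#: Reference levels (indicator = 0 everywhere): race=white, age=65+,
#: sex=male, married, English-speaking, private insurance, inpatient,
#: encounter before the 2020-03-01 cutoff.
ADJUSTED_TERMS = (
    "race_black",
    "race_hispanic_latino",
    "race_other",
    "age_0_17",
    "age_18_29",
    "age_30_44",
    "age_45_64",
    "sex_female",
    "not_married",
    "not_english",
    "ins_medicaid",
    "ins_medicare",
    "loc_outpatient",
    "loc_ed",
    "cci",
    "length_days",
    "covid_positive",
    "after_cutoff",
)

UNADJUSTED_TERMS = ("race_black", "race_hispanic_latino", "race_other")


@dataclass
class PatientRecord:
    patient_id: str
    race_ethnicity: str | None
    age_band: str | None
    sex: str | None
    insurance: str | None
    married: bool | None
    english_primary: bool | None
    covid_positive: bool = False
    icd10_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.race_ethnicity is not None and self.race_ethnicity not in RACE_LEVELS:
            raise ValueError(f"race_ethnicity: unknown value {self.race_ethnicity!r}")
        if self.age_band is not None and self.age_band not in AGE_BANDS:
            raise ValueError(f"age_band: unknown value {self.age_band!r}")
        if self.sex is not None and self.sex not in SEX_LEVELS:
            raise ValueError(f"sex: unknown value {self.sex!r}")
        if self.insurance is not None and self.insurance not in INSURANCE_LEVELS:
            raise ValueError(f"insurance: unknown value {self.insurance!r}")

    def has_missing_race(self) -> bool:
        return self.race_ethnicity is None

    def has_missing_covariate(self) -> bool:
        return any(
            v is None
            for v in (self.age_band, self.sex, self.insurance, self.married, self.english_primary)
        )


@dataclass
class EncounterRecord:
    encounter_id: str
    patient_id: str
    location: str
    length_days: float
    cci: float
    after_cutoff: bool

    def __post_init__(self) -> None:
        if self.location not in LOCATION_LEVELS:
            raise ValueError(f"location: unknown value {self.location!r}")
        if self.length_days < 0:
            raise ValueError("length_days must be non-negative")
        if self.cci < 0:
            raise ValueError("cci must be non-negative")


@dataclass(frozen=True)
class NoteOutcome:
    note_id: str
    encounter_id: str
    patient_id: str
    any_negative: int
    n_negative_sentences: int
    n_positive_sentences: int
    n_out_of_context: int


@dataclass
class CascadeReport:
    """Per-stage accounting of the exclusion cascade.

    Each stage is (name, n_input, n_excluded, n_retained); stage k+1's
    input equals stage k's retained count.
    """

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_input: int, n_excluded: int) -> None:
        self.stages.append((name, n_input, n_excluded, n_input - n_excluded))

    @property
    def final_n(self) -> int:
        return self.stages[-1][3] if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_input", "n_excluded", "n_retained"]
        )


def _has_code_prefix(patient: PatientRecord, prefixes: Sequence[str]) -> bool:
    return any(code.startswith(p) for code in patient.icd10_codes for p in prefixes)


def apply_exclusion_cascade(
    registry: Sequence[PatientRecord],
    dementia_code_prefixes: Sequence[str] = ("F00", "F01", "F02", "F03", "G30"),
) -> tuple[list[PatientRecord], CascadeReport]:
    """Build the analytic cohort.

    Stages, in order: (1) drop patients carrying any dementia-prefix
    ICD-10 code; (2) drop patients missing race/ethnicity; (3) drop
    patients missing any model covariate.  An empty registry yields an
    empty cohort and a zero-count report.
    """
    report = CascadeReport()

    stage1 = [p for p in registry if not _has_code_prefix(p, dementia_code_prefixes)]
    report.add("dementia_diagnosis", len(registry), len(registry) - len(stage1))

    stage2 = [p for p in stage1 if not p.has_missing_race()]
    report.add("missing_race_ethnicity", len(stage1), len(stage1) - len(stage2))

    stage3 = [p for p in stage2 if not p.has_missing_covariate()]
    report.add("missing_covariates", len(stage2), len(stage2) - len(stage3))

    return stage3, report


def apply_sensitivity_exclusion(
    cohort: Sequence[PatientRecord], behavioral_code_prefixes: Sequence[str]
) -> list[PatientRecord]:
    """Drop patients with delirium / substance-use / behavioural codes
    (pure filter; empty prefix list is a no-op)."""
    return [p for p in cohort if not _has_code_prefix(p, behavioral_code_prefixes)]


def code_covariates(patient: PatientRecord, encounter: EncounterRecord) -> dict[str, float]:
    """Produce a design-ready row of indicator and numeric covariates.

    Raises on any missing field (the cascade must already have been
    applied) and on values outside the closed category sets.
    """
    for name in ("race_ethnicity", "age_band", "sex", "insurance", "married", "english_primary"):
        if getattr(patient, name) is None:
            raise ValueError(f"missing {name} for patient {patient.patient_id}; run the cascade first")
    row = {term: 0.0 for term in ADJUSTED_TERMS}
    if patient.race_ethnicity != "white":
        row[f"race_{patient.race_ethnicity}"] = 1.0
    if patient.age_band != "65+":
        row["age_" + patient.age_band.replace("-", "_")] = 1.0
    if patient.sex == "female":
        row["sex_female"] = 1.0
    if not patient.married:
        row["not_married"] = 1.0
    if not patient.english_primary:
        row["not_english"] = 1.0
    if patient.insurance != "private":
        row[f"ins_{patient.insurance}"] = 1.0
    if encounter.location != "inpatient":
        row[f"loc_{encounter.location}"] = 1.0
    row["cci"] = float(encounter.cci)
    row["length_days"] = float(encounter.length_days)
    row["covid_positive"] = 1.0 if patient.covid_positive else 0.0
    row["after_cutoff"] = 1.0 if encounter.after_cutoff else 0.0
    return row


def aggregate_note_outcomes(
    sentence_labels: Iterable[tuple[str, str]],
    notes: Iterable[tuple[str, str, str]],
) -> list[NoteOutcome]:
    """Reduce per-sentence context labels to per-note outcomes.

    Parameters
    ----------
    sentence_labels : iterable of (note_id, label)
        One entry per descriptor-containing sentence.
    notes : iterable of (note_id, encounter_id, patient_id)
        Every note in scope; notes with no labeled sentences get
        ``any_negative = 0``.
    """
    counts: dict[str, dict[str, int]] = {}
    for note_id, label in sentence_labels:
        c = counts.setdefault(note_id, {NEGATIVE: 0, POSITIVE: 0, OUT_OF_CONTEXT: 0})
        c[label] += 1
    outcomes = []
    for note_id, encounter_id, patient_id in notes:
        c = counts.get(note_id, {NEGATIVE: 0, POSITIVE: 0, OUT_OF_CONTEXT: 0})
        outcomes.append(
            NoteOutcome(
                note_id=note_id,
                encounter_id=encounter_id,
                patient_id=patient_id,
                any_negative=1 if c[NEGATIVE] >= 1 else 0,
                n_negative_sentences=c[NEGATIVE],
                n_positive_sentences=c[POSITIVE],
                n_out_of_context=c[OUT_OF_CONTEXT],
            )
        )
    return outcomes


def patient_negative_note_counts(
    outcomes: Iterable[NoteOutcome], patient_ids: Iterable[str] | None = None
) -> pd.Series:
    """Number of negative notes per patient, zero-filled over
    ``patient_ids`` (defaults to the patients present in ``outcomes``)."""
    outcomes = list(outcomes)
    counts: dict[str, int] = {}
    for o in outcomes:
        counts[o.patient_id] = counts.get(o.patient_id, 0) + o.any_negative
    if patient_ids is not None:
        counts = {pid: counts.get(pid, 0) for pid in patient_ids}
    return pd.Series(counts, dtype=int, name="n_negative_notes").sort_index()


def patient_prevalence_percent(counts: pd.Series) -> float:
    """Percentage of patients with at least one negative note."""
    if len(counts) == 0:
        raise ValueError("no patients")
    return 100.0 * float((counts >= 1).sum()) / len(counts)


def build_model_rows(
    patients: Mapping[str, PatientRecord] | Sequence[PatientRecord],
    encounters: Mapping[str, EncounterRecord] | Sequence[EncounterRecord],
    outcomes: Sequence[NoteOutcome],
) -> pd.DataFrame:
    """Join note outcomes with coded covariates into one model-ready
    row per note (columns: ids, ``outcome``, then ADJUSTED_TERMS)."""
    if not isinstance(patients, Mapping):
        patients = {p.patient_id: p for p in patients}
    if not isinstance(encounters, Mapping):
        encounters = {e.encounter_id: e for e in encounters}
    rows = []
    for o in outcomes:
        row = {
            "note_id": o.note_id,
            "encounter_id": o.encounter_id,
            "patient_id": o.patient_id,
            "outcome": o.any_negative,
        }
        row.update(code_covariates(patients[o.patient_id], encounters[o.encounter_id]))
        rows.append(row)
    return pd.DataFrame(rows)


def _enc(value) -> str:
    if value is None:
        return NA
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


def _dec_str(value: str) -> str | None:
    return None if value == NA else value


def _dec_bool(value: str) -> bool | None:
    return None if value == NA else value == "1"


def patients_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Serialize patients to a delimited-file-ready table (``NA`` marks
    missing; booleans as 0/1; ICD-10 codes semicolon-joined)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "race_ethnicity": [_enc(p.race_ethnicity) for p in patients],
            "age_band": [_enc(p.age_band) for p in patients],
            "sex": [_enc(p.sex) for p in patients],
            "insurance": [_enc(p.insurance) for p in patients],
            "married": [_enc(p.married) for p in patients],
            "english_primary": [_enc(p.english_primary) for p in patients],
            "covid_positive": [_enc(p.covid_positive) for p in patients],
            "icd10_codes": [";".join(p.icd10_codes) for p in patients],
        }
    )


def patients_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for row in frame.astype(str).itertuples(index=False):
        out.append(
            PatientRecord(
                patient_id=row.patient_id,
                race_ethnicity=_dec_str(row.race_ethnicity),
                age_band=_dec_str(row.age_band),
                sex=_dec_str(row.sex),
                insurance=_dec_str(row.insurance),
                married=_dec_bool(row.married),
                english_primary=_dec_bool(row.english_primary),
                covid_positive=row.covid_positive == "1",
                icd10_codes=tuple(c for c in row.icd10_codes.split(";") if c and c != "nan"),
            )
        )
    return out


def encounters_to_frame(encounters: Sequence[EncounterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "encounter_id": [e.encounter_id for e in encounters],
            "patient_id": [e.patient_id for e in encounters],
            "location": [e.location for e in encounters],
            "length_days": [e.length_days for e in encounters],
            "cci": [e.cci for e in encounters],
            "after_cutoff": [_enc(e.after_cutoff) for e in encounters],
        }
    )


def encounters_from_frame(frame: pd.DataFrame) -> list[EncounterRecord]:
    return [
        EncounterRecord(
            encounter_id=str(row.encounter_id),
            patient_id=str(row.patient_id),
            location=str(row.location),
            length_days=float(row.length_days),
            cci=float(row.cci),
            after_cutoff=str(row.after_cutoff) == "1",
        )
        for row in frame.itertuples(index=False)
    ]
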