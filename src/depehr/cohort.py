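"""Cohort data model: patients, visits, notes, and their on-disk layout.

A patient record combines cancer-registry attributes (type, stage,
chemotherapy, diagnosis date) with a dated visit timeline; each visit
carries ICD-9-CM codes and one or more free-text notes in Spanish or
Catalan. On disk a cohort is ``patients.csv`` + ``visits.csv`` +
``notes.jsonl`` (and, for synthetic cohorts, ``truth.json``).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CANCER_TYPES = ("breast", "colorectal")
STAGES = ("in_situ", "I", "II", "III", "IV")


class CohortError(ValueError):
    pass


@dataclass
class Note:
    language: str  # es | ca
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise CohortError("note text must be non-empty")
        if self.language not in ("es", "ca"):
            raise CohortError(f"bad note language {self.language!r}")


@dataclass
class Visit:
    visit_id: str
    date: dt.date
    icd_codes: list[str] = field(default_factory=list)
    notes: list[Note] = field(default_factory=list)


@dataclass
class PatientRecord:
    patient_id: str
    sex: str  # F | M
    age_at_diagnosis: float
    cancer_type: str  # breast | colorectal
    stage: str  # in_situ | I | II | III | IV
    chemotherapy: bool | None  # None encodes missing treatment information
    diagnosis_date: dt.date | None
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cancer_type not in CANCER_TYPES:
            raise CohortError(f"bad cancer type {self.cancer_type!r}")
        if self.stage not in STAGES:
            raise CohortError(f"bad stage {self.stage!r}")
        self.visits.sort(key=lambda v: (v.date, v.visit_id))

    def visits_before(self) -> list[Visit]:
        self._require_index()
        return [v for v in self.visits if v.date < self.diagnosis_date]

    def visits_on_or_after(self) -> list[Visit]:
        self._require_index()
        return [v for v in self.visits if v.date >= self.diagnosis_date]

    def _require_index(self) -> None:
        if self.diagnosis_date is None:
            raise CohortError(
                f"patient {self.patient_id} has no diagnosis date"
            )


# ---------------------------------------------------------------------------
# Serialization


def write_cohort(patients: list[PatientRecord], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prows, vrows, nrows = [], [], []
    for p in patients:
        prows.append(
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "age_at_diagnosis": p.age_at_diagnosis,
                "cancer_type": p.cancer_type,
                "stage": p.stage,
                "chemotherapy": "" if p.chemotherapy is None else int(p.chemotherapy),
                "diagnosis_date": p.diagnosis_date.isoformat()
                if p.diagnosis_date
                else "",
            }
        )
        for v in p.visits:
            vrows.append(
                {
                    "patient_id": p.patient_id,
                    "visit_id": v.visit_id,
                    "date": v.date.isoformat(),
                    "icd_codes": ";".join(v.icd_codes),
                }
            )
            for i, note in enumerate(v.notes):
                nrows.append(
                    {
                        "patient_id": p.patient_id,
                        "visit_id": v.visit_id,
                        "note_index": i,
                        "date": v.date.isoformat(),
                        "language": note.language,
                        "text": note.text,
                    }
                )
    pd.DataFrame(prows).to_csv(outdir / "patients.csv", index=False)
    pd.DataFrame(vrows).to_csv(outdir / "visits.csv", index=False)
    with open(outdir / "notes.jsonl", "w", encoding="utf-8") as fh:
        for row in nrows:
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_cohort(indir: str | Path) -> list[PatientRecord]:
    indir = Path(indir)
    pdf = pd.read_csv(indir / "patients.csv", dtype={"patient_id": str})
    vdf = pd.read_csv(
        indir / "visits.csv", dtype={"patient_id": str, "visit_id": str}
    )
    notes: dict[tuple[str, str], list[Note]] = {}
    with open(indir / "notes.jsonl", encoding="utf-8") as fh:
        for line in fh:
            row = json.loads(line)
            key = (str(row["patient_id"]), str(row["visit_id"]))
            notes.setdefault(key, []).append(
                Note(language=row["language"], text=row["text"])
            )
    visits: dict[str, list[Visit]] = {}
    for row in vdf.itertuples(index=False):
        codes = [] if pd.isna(row.icd_codes) or not row.icd_codes else str(
            row.icd_codes
        ).split(";")
        visits.setdefault(row.patient_id, []).append(
            Visit(
                visit_id=row.visit_id,
                date=dt.date.fromisoformat(row.date),
                icd_codes=codes,
                notes=notes.get((row.patient_id, row.visit_id), []),
            )
        )
    patients = []
    for row in pdf.itertuples(index=False):
        chemo = row.chemotherapy
        chemo_val: bool | None
        if pd.isna(chemo) or chemo == "":
            chemo_val = None
        else:
            chemo_val = bool(int(chemo))
        diag = (
            None
            if pd.isna(row.diagnosis_date) or not row.diagnosis_date
            else dt.date.fromisoformat(row.diagnosis_date)
        )
        patients.append(
            PatientRecord(
                patient_id=row.patient_id,
                sex=row.sex,
                age_at_diagnosis=float(row.age_at_diagnosis),
                cancer_type=row.cancer_type,
                stage=row.stage,
                chemotherapy=chemo_val,
                diagnosis_date=diag,
                visits=visits.get(row.patient_id, []),
            )
        )
    return patients
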