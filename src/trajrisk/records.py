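"""Patient records and the delimited-text interchange format.

A cohort is exchanged as two delimited text files (TSV by default):

* an **event file** with columns ``patient_id, date, code, system`` — one row
  per diagnosis event, ISO-8601 dates;
* a **patient file** with columns ``patient_id, birth_date, sex, end_of_data,
  cancer_date`` — one row per patient, ``cancer_date`` empty for controls.

Reading validates dates and ordering and reports malformed rows with their
line numbers; writing round-trips field-for-field.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd

from .codes import truncate_code

__all__ = [
    "DiseaseEvent",
    "PatientRecord",
    "read_event_file",
    "read_patient_file",
    "write_event_file",
    "write_patient_file",
    "load_cohort",
    "write_cohort",
]

EVENT_COLUMNS = ["patient_id", "date", "code", "system"]
PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "end_of_data", "cancer_date"]


@dataclass(frozen=True)
class DiseaseEvent:
    """One coded diagnosis: level-3 code, calendar date, code-system tag."""

    code: str
    date: dt.date
    system: str = "icd10"

    @property
    def token(self) -> tuple[str, str]:
        return (self.system, self.code)


@dataclass
class PatientRecord:
    """A patient's ordered diagnosis history plus the dates that frame it."""

    patient_id: str
    birth_date: dt.date
    end_of_data: dt.date
    events: list[DiseaseEvent] = field(default_factory=list)
    sex: str | None = None
    cancer_date: dt.date | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        dates = [e.date for e in self.events]
        if any(b > a for b, a in zip(dates, dates[1:])):
            # stable sort: same-day events keep their input order
            self.events = sorted(self.events, key=lambda e: e.date)
        for e in self.events:
            if not (self.birth_date <= e.date <= self.end_of_data):
                raise ValueError(
                    f"patient {self.patient_id}: event on {e.date} outside "
                    f"[{self.birth_date}, {self.end_of_data}]"
                )
        if self.cancer_date is not None and self.cancer_date > self.end_of_data:
            raise ValueError(
                f"patient {self.patient_id}: cancer date {self.cancer_date} "
                f"after end of data {self.end_of_data}"
            )

    @property
    def is_case(self) -> bool:
        return self.cancer_date is not None

    def copy_with_events(self, events: list[DiseaseEvent]) -> "PatientRecord":
        return replace(self, events=list(events))


def _parse_date(value: str, *, line: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        raise ValueError(f"line {line}: malformed {column} {value!r}") from None


def read_event_file(path, sep: str = "\t", truncate: bool = True) -> pd.DataFrame:
    """Read an event file into a DataFrame of validated, parsed rows."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file missing columns: {missing}")
    dates, codes = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        dates.append(_parse_date(row.date, line=line, column="date"))
        codes.append(truncate_code(row.code, row.system) if truncate else row.code)
    out = df[EVENT_COLUMNS].copy()
    out["date"] = dates
    out["code"] = codes
    return out


def read_patient_file(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient file missing columns: {missing}")
    for col in ("birth_date", "end_of_data"):
        df[col] = [
            _parse_date(v, line=i + 2, column=col) for i, v in enumerate(df[col])
        ]
    df["cancer_date"] = [
        _parse_date(v, line=i + 2, column="cancer_date") if v else None
        for i, v in enumerate(df["cancer_date"])
    ]
    return df


def load_cohort(event_path, patient_path, sep: str = "\t") -> list[PatientRecord]:
    """Assemble PatientRecords from an event file and a patient file."""
    events = read_event_file(event_path, sep=sep)
    patients = read_patient_file(patient_path, sep=sep)
    by_patient: dict[str, list[DiseaseEvent]] = {}
    for row in events.itertuples(index=False):
        by_patient.setdefault(row.patient_id, []).append(
            DiseaseEvent(code=row.code, date=row.date, system=row.system)
        )
    records = []
    for row in patients.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                birth_date=row.birth_date,
                end_of_data=row.end_of_data,
                sex=row.sex or None,
                cancer_date=row.cancer_date,
                events=by_patient.get(row.patient_id, []),
            )
        )
    return records


def write_event_file(records: list[PatientRecord], path, sep: str = "\t") -> None:
    rows = [
        (p.patient_id, e.date.isoformat(), e.code, e.system)
        for p in records
        for e in p.events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep=sep, index=False)


def write_patient_file(records: list[PatientRecord], path, sep: str = "\t") -> None:
    rows = [
        (
            p.patient_id,
            p.birth_date.isoformat(),
            p.sex or "",
            p.end_of_data.isoformat(),
            p.cancer_date.isoformat() if p.cancer_date else "",
        )
        for p in records
    ]
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, sep=sep, index=False)


def write_cohort(records: list[PatientRecord], event_path, patient_path,
                 sep: str = "\t") -> None:
    write_event_file(records, event_path, sep=sep)
    write_patient_file(records, patient_path, sep=sep)
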