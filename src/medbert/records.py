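"""Domain model for structured EHR diagnosis records.

A patient's structured EHR is modeled as a time-ordered sequence of visits,
each visit carrying an ordered list of diagnosis codes (ICD-9/ICD-10-style
strings treated as opaque vocabulary tokens).  Each code carries the three
attributes used to order codes within a visit: a present-on-admission flag,
a captured-during-visit flag (versus billing-phase only), and an integer
billing priority (1 = principal diagnosis).

Records are serialized as line-delimited JSON, one patient per line, with
ISO-8601 dates.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, replace
from enum import Enum
from typing import IO, Iterable, Iterator


class CodeSystem(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"
    OTHER = "O"


class DegenerateVisitError(ValueError):
    """Raised for operations on visits with no diagnosis codes."""


@dataclass(frozen=True)
class DiagnosisCode:
    """One coded diagnosis attached to a visit.

    Attributes
    ----------
    system : CodeSystem
        Coding standard the token comes from (ICD-9 or ICD-10).
    code : str
        The code string, e.g. ``"E11.9"``.  Non-empty.
    poa : bool
        Present on admission.  First-ranked within-visit ordering key.
    captured_during_visit : bool
        True when the diagnosis was captured during the encounter itself
        rather than only at the billing phase.  Second ordering key.
    priority : int
        Billing priority, 1 = principal diagnosis.  Third ordering key.
    """

    system: CodeSystem
    code: str
    poa: bool = False
    captured_during_visit: bool = True
    priority: int = 1

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("diagnosis code string must be non-empty")
        if self.priority < 1:
            raise ValueError(f"priority must be >= 1, got {self.priority}")


@dataclass(frozen=True)
class VisitRecord:
    """One dated encounter carrying an ordered list of diagnosis codes."""

    admit_date: _dt.date
    codes: tuple[DiagnosisCode, ...]
    discharge_date: _dt.date | None = None
    encounter_type: str = "outpatient"

    def __post_init__(self) -> None:
        if not isinstance(self.codes, tuple):
            object.__setattr__(self, "codes", tuple(self.codes))

    @property
    def has_valid_dates(self) -> bool:
        """False only when a discharge date precedes the admission date."""
        if self.discharge_date is None:
            return True
        return self.discharge_date >= self.admit_date


@dataclass(frozen=True)
class PatientRecord:
    """Demographics plus visits sorted ascending by admission date."""

    patient_id: str
    birth_year: int
    sex: Sex
    visits: tuple[VisitRecord, ...]
    deceased: bool = False  # death recorded anywhere in the record

    def __post_init__(self) -> None:
        if not isinstance(self.visits, tuple):
            object.__setattr__(self, "visits", tuple(self.visits))

    @property
    def total_code_count(self) -> int:
        return sum(len(v.codes) for v in self.visits)

    def sorted_by_time(self) -> "PatientRecord":
        """Return a copy with visits sorted ascending by admission date (stable)."""
        return replace(self, visits=tuple(sorted(self.visits, key=lambda v: v.admit_date)))

    def age_at(self, date: _dt.date) -> int:
        """Age in whole years as event-year minus birth-year."""
        return date.year - self.birth_year


class PhenotypeStatus(str, Enum):
    CASE = "case"
    CONTROL = "control"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class PhenotypeDecision:
    """Outcome of a rule-based case/control assignment for one patient."""

    status: PhenotypeStatus
    reasons: tuple[str, ...] = ()
    index_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.reasons, tuple):
            object.__setattr__(self, "reasons", tuple(self.reasons))
        if self.status is PhenotypeStatus.EXCLUDED and not self.reasons:
            raise ValueError("excluded decisions must carry at least one rule id")
        if self.status is PhenotypeStatus.CASE and self.index_date is None:
            raise ValueError("case decisions must carry an index date")


# ---------------------------------------------------------------------------
# JSONL serialization
# ---------------------------------------------------------------------------

def _code_to_json(c: DiagnosisCode) -> dict:
    return {
        "system": c.system.value,
        "code": c.code,
        "poa": c.poa,
        "captured": c.captured_during_visit,
        "priority": c.priority,
    }


def _code_from_json(d: dict) -> DiagnosisCode:
    return DiagnosisCode(
        system=CodeSystem(d.get("system", "ICD10")),
        code=d["code"],
        poa=bool(d.get("poa", False)),
        captured_during_visit=bool(d.get("captured", True)),
        priority=int(d.get("priority", 1)),
    )


def patient_to_json(p: PatientRecord) -> dict:
    return {
        "patient_id": p.patient_id,
        "birth_year": p.birth_year,
        "sex": p.sex.value,
        "deceased": p.deceased,
        "visits": [
            {
                "admit_date": v.admit_date.isoformat(),
                "discharge_date": v.discharge_date.isoformat() if v.discharge_date else None,
                "encounter_type": v.encounter_type,
                "codes": [_code_to_json(c) for c in v.codes],
            }
            for v in p.visits
        ],
    }


def patient_from_json(d: dict) -> PatientRecord:
    visits = tuple(
        VisitRecord(
            admit_date=_dt.date.fromisoformat(v["admit_date"]),
            discharge_date=(
                _dt.date.fromisoformat(v["discharge_date"]) if v.get("discharge_date") else None
            ),
            encounter_type=v.get("encounter_type", "outpatient"),
            codes=tuple(_code_from_json(c) for c in v["codes"]),
        )
        for v in d["visits"]
    )
    return PatientRecord(
        patient_id=str(d["patient_id"]),
        birth_year=int(d["birth_year"]),
        sex=Sex(d.get("sex", "O")),
        visits=visits,
        deceased=bool(d.get("deceased", False)),
    )


def write_jsonl(patients: Iterable[PatientRecord], fh: IO[str]) -> int:
    """Write patients one-per-line; returns the number written."""
    n = 0
    for p in patients:
        fh.write(json.dumps(patient_to_json(p)) + "\n")
        n += 1
    return n


def read_jsonl(fh: IO[str]) -> Iterator[PatientRecord]:
    for line in fh:
        line = line.strip()
        if line:
            yield patient_from_json(json.loads(line))


__all__ = [
    "CodeSystem",
    "Sex",
    "DiagnosisCode",
    "VisitRecord",
    "PatientRecord",
    "PhenotypeStatus",
    "PhenotypeDecision",
    "DegenerateVisitError",
    "patient_to_json",
    "patient_from_json",
    "write_jsonl",
    "read_jsonl",
]
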