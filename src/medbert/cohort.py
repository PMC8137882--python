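"""Cohort preparation rules: within-visit code ordering, pretraining-cohort
attrition filters, length-of-stay extraction and the prolonged-LOS label.

Within each visit, diagnosis codes are ranked by three criteria applied in
sequence: (1) flagged as present on admission; (2) captured during the visit
rather than only at the billing phase; (3) the integer billing priority
(1 = principal).  Full ties keep input order (stable sort) — billing priority
fields are known to be imperfect rankings, so no further tie-break is imposed.

The pretraining attrition filter removes patients with fewer than three
diagnosis codes in their whole record and patients with inconsistent time
information (a discharge date before the admission date on any visit).

Prolonged length of stay is a *patient-level* binary label: 1 iff any visit
in the record has a length of stay strictly greater than 7 days.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

from .records import DegenerateVisitError, PatientRecord, VisitRecord

PROLONGED_LOS_THRESHOLD_DAYS = 7
MIN_TOTAL_CODES = 3

RULE_MIN_CODES = "min_codes"
RULE_BAD_DATES = "bad_dates"


def order_codes_within_visit(visit: VisitRecord) -> VisitRecord:
    """Sort a visit's codes by (POA desc, captured desc, priority asc), stably.

    Raises :class:`DegenerateVisitError` for a visit with no codes.
    """
    if not visit.codes:
        raise DegenerateVisitError("cannot order codes of a visit with no codes")
    ordered = sorted(
        visit.codes,
        key=lambda c: (not c.poa, not c.captured_during_visit, c.priority),
    )
    return replace(visit, codes=tuple(ordered))


def order_patient_codes(
    patient: PatientRecord,
    mode: str = "sort",
    rng=None,
) -> PatientRecord:
    """Apply within-visit ordering to every non-empty visit of a patient.

    ``mode`` is ``"sort"`` (the three-key ranking, the default), ``"keep"``
    (leave input order), or ``"shuffle"`` (randomly scatter codes within each
    visit using ``rng``).  Within-visit order contributes little predictive
    signal, so scattering is offered for ablations; the canonical
    serialization stays the sort.
    """
    if mode == "keep":
        return patient
    if mode == "shuffle":
        if rng is None:
            raise ValueError("mode='shuffle' requires an rng")
        return replace(
            patient,
            visits=tuple(
                replace(v, codes=tuple(v.codes[i] for i in rng.permutation(len(v.codes))))
                if v.codes
                else v
                for v in patient.visits
            ),
        )
    if mode != "sort":
        raise ValueError(f"unknown ordering mode {mode!r}")
    return replace(
        patient,
        visits=tuple(order_codes_within_visit(v) if v.codes else v for v in patient.visits),
    )


def filter_pretraining_cohort(
    patients: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Apply the pretraining attrition rules, preserving input order.

    Returns ``(kept, report)`` where ``report`` maps each rule id to the
    number of patients it removed.  A patient failing several rules is counted
    once, under the first failing rule (minimum-code-count first).
    """
    kept: list[PatientRecord] = []
    report = {RULE_MIN_CODES: 0, RULE_BAD_DATES: 0}
    for p in patients:
        if p.total_code_count < MIN_TOTAL_CODES:
            report[RULE_MIN_CODES] += 1
        elif any(not v.has_valid_dates for v in p.visits):
            report[RULE_BAD_DATES] += 1
        else:
            kept.append(p)
    return kept, report


def length_of_stay_days(visit: VisitRecord) -> int | None:
    """Discharge minus admission in whole days; None when discharge is absent.

    A negative span signals bad time information that the attrition filter
    should have removed, and raises ``ValueError``.
    """
    if visit.discharge_date is None:
        return None
    span = (visit.discharge_date - visit.admit_date).days
    if span < 0:
        raise ValueError(
            f"discharge {visit.discharge_date} precedes admission {visit.admit_date}"
        )
    return span


def prolonged_los_label(patient: PatientRecord) -> int:
    """1 iff any visit has a length of stay strictly greater than 7 days.

    Visits without a discharge date carry no length of stay and are skipped.
    The label is patient-level: one stay longer than a week anywhere in the
    record makes the patient a positive.
    """
    for v in patient.visits:
        los = length_of_stay_days(v)
        if los is not None and los > PROLONGED_LOS_THRESHOLD_DAYS:
            return 1
    return 0


def select_pretraining_task_labels(patients: Sequence[PatientRecord]) -> list[int]:
    """Prolonged-LOS labels for a filtered cohort, one per patient in order.

    Prolonged LOS is the sequence-level pretraining objective of choice:
    mortality and early readmission converge to near-perfect accuracy too
    quickly to provide useful pretraining signal, so they are deliberately
    not implemented.
    """
    return [prolonged_los_label(p) for p in patients]


__all__ = [
    "PROLONGED_LOS_THRESHOLD_DAYS",
    "MIN_TOTAL_CODES",
    "RULE_MIN_CODES",
    "RULE_BAD_DATES",
    "order_codes_within_visit",
    "order_patient_codes",
    "filter_pretraining_cohort",
    "length_of_stay_days",
    "prolonged_los_label",
    "select_pretraining_task_labels",
]
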