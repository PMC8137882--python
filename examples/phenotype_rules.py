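"""Cohort rules on hand-built patients: within-visit code ordering, the
pretraining attrition filter, and the two disease phenotypes.

Each printed decision names the rule that fired, showing how the rule
engines adjudicate inclusion windows, encounter counts and age limits.
"""

import datetime as dt

from medbert import (
    DiagnosisCode,
    PatientRecord,
    VisitRecord,
    filter_pretraining_cohort,
    order_codes_within_visit,
    phenotype_dhf,
    phenotype_paca,
)
from medbert.records import CodeSystem, Sex

D = dt.date

# --- within-visit ordering: POA first, then captured-during-visit, then priority
visit = VisitRecord(
    admit_date=D(2015, 1, 1),
    codes=(
        DiagnosisCode(CodeSystem.ICD10, "J18.9", poa=False, priority=1),
        DiagnosisCode(CodeSystem.ICD10, "E11.9", poa=True, priority=5),
        DiagnosisCode(CodeSystem.ICD10, "I10", poa=True, priority=2),
    ),
)
print("ordered codes:", [c.code for c in order_codes_within_visit(visit).codes])
# E11.9 and I10 are present on admission so they outrank the principal
# pneumonia code; between them the billing priority decides.


def patient(visit_specs, birth=1950, pid="p"):
    visits = tuple(
        VisitRecord(day, tuple(DiagnosisCode(CodeSystem.ICD10, c) for c in codes))
        for day, codes in visit_specs
    )
    return PatientRecord(pid, birth, Sex.FEMALE, visits)


# --- attrition: a 2-code record is below the pretraining floor
thin = patient([(D(2015, 1, 1), ["E11.9", "I10"])], pid="thin")
ok = patient([(D(2015, 1, 1), ["E11.9", "I10", "J18.9"])], pid="ok")
kept, report = filter_pretraining_cohort([thin, ok])
print("attrition:", [p.patient_id for p in kept], report)

# --- DHF: two diabetes encounters + A1C >= 6.5, first HF 32 days later
dhf_case = patient([
    (D(2015, 1, 1), ["E11.9"]),
    (D(2015, 2, 1), ["E11.9"]),
    (D(2015, 2, 2), ["I50.9"]),
    (D(2015, 3, 10), ["I50.9"]),
])
d = phenotype_dhf(dhf_case, a1c_readings=[6.7])
print("DHF decision:", d.status.value, d.reasons, "index", d.index_date)

# the same history with heart failure at day 29 misses the 30-day window
dhf_early = patient([
    (D(2015, 1, 1), ["E11.9"]),
    (D(2015, 1, 20), ["E11.9"]),
    (D(2015, 1, 30), ["I50.9"]),
    (D(2015, 3, 10), ["I50.9"]),
])
print("DHF 29-day window:", phenotype_dhf(dhf_early, a1c_readings=[6.7]).reasons)

# --- PaCa: age >= 45 at first pancreatic-cancer code, no prior other cancer
paca = patient([(D(2015, 6, 1), ["C25.0"])], birth=1940)
print("PaCa decision:", phenotype_paca(paca).status.value)
too_young = patient([(D(2015, 6, 1), ["C25.0"])], birth=1975)
print("PaCa at age 40:", phenotype_paca(too_young).reasons)
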