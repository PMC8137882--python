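"""Rule-based disease phenotyping on coded patient records.

Two phenotypes are implemented as deterministic rule engines over diagnosis
codes, simple medication-name lists and numeric A1C values:

* **DHF** — incident heart failure among type-II diabetes patients.  A
  patient enters the denominator with at least two encounters carrying a
  diabetes code and laboratory/medication confirmation (A1C >= 6.5, the
  inclusive diagnostic threshold, or any antidiabetic agent on the
  medication list).  Histories of type-I, gestational, secondary or neonatal
  diabetes, or diabetes insipidus, are excluded as probable miscodings.
  Cases need at least two heart-failure encounters, with the first one at
  least 30 days after the first type-II diabetes code; a single HF encounter
  excludes the patient rather than making them a control.  Patients younger
  than 18 at first diabetes diagnosis, and patients recorded as deceased
  before their event, are excluded.

* **PaCa** — first primary pancreatic cancer (ICD-9 ``157*`` / ICD-10
  ``C25*`` by default): cases are at least 45 at the first qualifying code
  and carry no other cancer code strictly before it.

Code lists are configuration data (YAML shipped with the package, editable),
not hard-coded; matching is by code-string prefix with dots ignored.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources
from typing import Sequence

import yaml

from .records import PatientRecord, PhenotypeDecision, PhenotypeStatus

A1C_THRESHOLD = 6.5  # inclusive
HF_MIN_DAYS_AFTER_DM = 30
DHF_MIN_AGE = 18
PACA_MIN_AGE = 45


class ConfigurationError(ValueError):
    """Raised when a required phenotype code list is missing."""


def load_phenotype_config(path: str | None = None) -> dict:
    """Load phenotype code lists from YAML (packaged defaults when path is None)."""
    if path is None:
        text = resources.files("medbert.data").joinpath("phenotype_codes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError("phenotype configuration must be a mapping")
    return cfg


def _norm(code: str) -> str:
    return code.replace(".", "").upper()


def _matches(code: str, prefixes: Sequence[str]) -> bool:
    c = _norm(code)
    return any(c.startswith(_norm(p)) for p in prefixes)


def _encounters_matching(
    patient: PatientRecord, prefixes: Sequence[str]
) -> list[_dt.date]:
    """Admission dates of visits carrying at least one matching code, in order."""
    out = []
    for v in patient.visits:
        if any(_matches(c.code, prefixes) for c in v.codes):
            out.append(v.admit_date)
    return out


def _require(cfg: dict, section: str, key: str) -> list[str]:
    try:
        val = cfg[section][key]
    except (KeyError, TypeError) as e:
        raise ConfigurationError(f"missing phenotype code list {section}.{key}") from e
    if not val:
        raise ConfigurationError(f"empty phenotype code list {section}.{key}")
    return list(val)


def phenotype_dhf(
    patient: PatientRecord,
    a1c_readings: Sequence[float] = (),
    medications: Sequence[str] = (),
    config: dict | None = None,
) -> PhenotypeDecision:
    """Classify one patient for the diabetes→heart-failure phenotype.

    ``a1c_readings`` is the patient's numeric A1C history and ``medications``
    their drug-name strings (case-insensitive substring match against the
    configured antidiabetic agents).
    """
    cfg = config if config is not None else load_phenotype_config()
    dm_any = _require(cfg, "dhf", "diabetes_any")
    hf = _require(cfg, "dhf", "heart_failure")
    agents = [a.lower() for a in _require(cfg, "dhf", "antidiabetic_agents")]
    exclusion_lists = {
        "type1_dm": _require(cfg, "dhf", "type1_dm"),
        "gestational_dm": _require(cfg, "dhf", "gestational_dm"),
        "secondary_dm": _require(cfg, "dhf", "secondary_dm"),
        "neonatal_dm": _require(cfg, "dhf", "neonatal_dm"),
        "diabetes_insipidus": _require(cfg, "dhf", "diabetes_insipidus"),
    }

    p = patient.sorted_by_time()
    dm_dates = _encounters_matching(p, dm_any)
    if len(dm_dates) < 2:
        return PhenotypeDecision(PhenotypeStatus.EXCLUDED, ("lt_two_dm_encounters",))

    confirmed = any(r >= A1C_THRESHOLD for r in a1c_readings) or any(
        agent in m.lower() for m in medications for agent in agents
    )
    if not confirmed:
        return PhenotypeDecision(PhenotypeStatus.EXCLUDED, ("no_type2_confirmation",))

    fired = tuple(
        name for name, prefixes in exclusion_lists.items() if _encounters_matching(p, prefixes)
    )
    if fired:
        return PhenotypeDecision(PhenotypeStatus.EXCLUDED, fired)

    first_dm = dm_dates[0]
    if p.age_at(first_dm) < DHF_MIN_AGE:
        return PhenotypeDecision(PhenotypeStatus.EXCLUDED, ("under_18_at_first_dm",))

    hf_dates = _encounters_matching(p, hf)
    if len(hf_dates) == 1:
        return PhenotypeDecision(PhenotypeStatus.EXCLUDED, ("single_hf_encounter",))
    if len(hf_dates) >= 2:
        first_hf = hf_dates[0]
        if (first_hf - first_dm).days < HF_MIN_DAYS_AFTER_DM:
            return PhenotypeDecision(PhenotypeStatus.EXCLUDED, ("hf_within_30_days_of_dm",))
        if p.deceased:
            # death status is a record-level flag; a recorded death before the
            # qualifying event cannot be dated, so it excludes conservatively
            return PhenotypeDecision(PhenotypeStatus.EXCLUDED, ("death_before_event",))
        return PhenotypeDecision(PhenotypeStatus.CASE, ("dhf_case",), index_date=first_hf)

    if p.deceased:
        return PhenotypeDecision(PhenotypeStatus.EXCLUDED, ("death_before_event",))
    last = p.visits[-1].admit_date if p.visits else None
    return PhenotypeDecision(PhenotypeStatus.CONTROL, ("dhf_control",), index_date=last)


def phenotype_paca(
    patient: PatientRecord,
    config: dict | None = None,
) -> PhenotypeDecision:
    """Classify one patient for the first-primary pancreatic cancer phenotype."""
    cfg = config if config is not None else load_phenotype_config()
    paca = _require(cfg, "paca", "pancreatic_cancer")
    other = _require(cfg, "paca", "other_cancer")

    p = patient.sorted_by_time()
    paca_dates = _encounters_matching(p, paca)
    if not paca_dates:
        last = p.visits[-1].admit_date if p.visits else None
        return PhenotypeDecision(PhenotypeStatus.CONTROL, ("no_paca_code",), index_date=last)

    first_paca = paca_dates[0]
    if p.age_at(first_paca) < PACA_MIN_AGE:
        return PhenotypeDecision(PhenotypeStatus.EXCLUDED, ("under_45_at_first_paca",))

    # other-cancer means: matches an other-cancer prefix but is NOT itself a
    # pancreatic-cancer code (the broad C*/14x-20x prefixes cover C25/157 too)
    for v in p.visits:
        if v.admit_date >= first_paca:
            break
        for c in v.codes:
            if _matches(c.code, other) and not _matches(c.code, paca):
                return PhenotypeDecision(
                    PhenotypeStatus.EXCLUDED, ("other_cancer_before_paca",)
                )
    return PhenotypeDecision(PhenotypeStatus.CASE, ("paca_case",), index_date=first_paca)


__all__ = [
    "A1C_THRESHOLD",
    "HF_MIN_DAYS_AFTER_DM",
    "DHF_MIN_AGE",
    "PACA_MIN_AGE",
    "ConfigurationError",
    "load_phenotype_config",
    "phenotype_dhf",
    "phenotype_paca",
]
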