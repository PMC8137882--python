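"""Synthetic longitudinal diagnosis-record generator.

The generator plants the statistical structure that contextual pretraining
is supposed to exploit, while emulating the shape of real structured EHR:
variable visit counts (negative-binomial, mean ≈ 8 visits/patient), variable
codes per visit (1 + Poisson, ≈ 2 codes/visit so ≈ 15–16 codes/patient),
irregular gaps between visits, mixed encounter types with occasionally
missing discharge dates, and within-visit priority order.

Mechanism: each patient carries a small set of latent chronic conditions;
each condition owns a disjoint block of the code vocabulary and progresses
through severity stages by a Markov chain, one step per visit.  A visit
emits codes drawn near a stage-specific anchor inside each active
condition's block, so codes from one condition co-occur within visits and
drift with severity.  Prolonged hospital stays (> 7 days) become more likely
at higher severity — giving the sequence-level pretraining task cross-visit
signal — and the disease outcome label is a logistic function of the
final severity of a designated subset of "risk" conditions.

The intercepts of both links are calibrated numerically (bisection on the
sampled latent trajectories) so that the expected prevalence of the
prolonged-stay event and of the outcome match the configured targets
(both default to 15%, the prevalence regime of large general-EHR pretraining
corpora).  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .records import CodeSystem, DiagnosisCode, PatientRecord, Sex, VisitRecord

_EPOCH = _dt.date(2008, 1, 6)


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 20_000
    n_conditions: int = 10
    codes_per_condition: int = 50
    n_stages: int = 3
    # row-stochastic severity-stage transition matrix, shared by conditions
    stage_transition: tuple[tuple[float, ...], ...] = (
        (0.70, 0.25, 0.05),
        (0.00, 0.70, 0.30),
        (0.00, 0.05, 0.95),
    )
    visits_nb_r: float = 4.0          # negative-binomial dispersion
    visits_mean: float = 8.0          # mean visits per patient
    codes_per_visit_rate: float = 1.0  # codes per visit = 1 + Poisson(rate)
    conditions_per_patient_rate: float = 0.8  # active = 1 + Poisson(rate), capped
    inpatient_fraction: float = 0.4
    los_prevalence: float = 0.15      # patient-level prolonged-stay target
    los_slope: float = 1.6            # severity → prolonged-stay log-odds slope
    outcome_prevalence: float = 0.15
    outcome_slope: float = 1.8        # risk-condition severity → outcome log-odds
    n_risk_conditions: int = 3        # conditions 0..n-1 drive the outcome
    inject_errors: int = 0            # extra deliberately invalid patients
    seed: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.stage_transition)
        if tm.shape != (self.n_stages, self.n_stages):
            raise ValueError("stage_transition must be n_stages x n_stages")
        if (tm < 0).any() or not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("stage_transition rows must be probabilities summing to 1")
        if not (0 < self.los_prevalence < 1 and 0 < self.outcome_prevalence < 1):
            raise ValueError("prevalence targets must be in (0, 1)")
        if self.n_risk_conditions > self.n_conditions:
            raise ValueError("n_risk_conditions cannot exceed n_conditions")

    @property
    def vocab_size(self) -> int:
        return self.n_conditions * self.codes_per_condition


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    outcome_labels: np.ndarray             # (n,) int — disease label per patient
    latent_truth: dict = field(repr=False)  # diagnostics only; never fed to models

    def __len__(self) -> int:
        return len(self.patients)


def code_token(condition: int, offset: int) -> str:
    """Deterministic ICD-10-shaped token for condition block + offset."""
    return f"D{condition:02d}.{offset:03d}"


def condition_of_token(token: str) -> int:
    return int(token[1:3])


def _sample_visit_counts(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    r = cfg.visits_nb_r
    p = r / (r + (cfg.visits_mean - 1.0))
    return 1 + rng.negative_binomial(r, p, size=n)


def _stage_paths(
    cfg: SyntheticConfig, rng: np.random.Generator, n_visits: int, n_active: int
) -> np.ndarray:
    """(n_active, n_visits) severity stages, each condition an independent chain."""
    tm = np.asarray(cfg.stage_transition)
    cum = tm.cumsum(axis=1)
    out = np.zeros((n_active, n_visits), dtype=np.int64)
    u = rng.random((n_active, n_visits))
    state = np.zeros(n_active, dtype=np.int64)
    for t in range(n_visits):
        out[:, t] = state
        state = (u[:, t, None] > cum[state]).sum(axis=1)
    return out


def _emit_offsets(
    cfg: SyntheticConfig, rng: np.random.Generator, stages: np.ndarray
) -> np.ndarray:
    """Code offsets within a condition block, clustered near a stage anchor."""
    K = cfg.codes_per_condition
    anchors = (stages * K) // cfg.n_stages
    jumps = rng.geometric(0.3, size=stages.shape) - 1
    return (anchors + jumps) % K


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Sample a full cohort; byte-identical across calls with the same config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    visit_counts = _sample_visit_counts(config, rng, n)

    # pass 1: latent structure and visit skeletons
    all_active: list[np.ndarray] = []
    all_stages: list[np.ndarray] = []
    all_inpatient: list[np.ndarray] = []
    for i in range(n):
        nv = int(visit_counts[i])
        n_active = min(1 + rng.poisson(config.conditions_per_patient_rate), config.n_conditions)
        active = rng.choice(config.n_conditions, size=n_active, replace=False)
        stages = _stage_paths(config, rng, nv, n_active)
        inpatient = rng.random(nv) < config.inpatient_fraction
        all_active.append(active)
        all_stages.append(stages)
        all_inpatient.append(inpatient)

    # calibrate the two logistic intercepts on the sampled trajectories
    mean_sev = [s.mean(axis=0) for s in all_stages]  # per-visit mean stage
    los_intercept = _solve_los_intercept(config, mean_sev, all_inpatient)
    risk = [
        float(
            stages[np.isin(active, np.arange(config.n_risk_conditions)), -1].sum()
        )
        for active, stages in zip(all_active, all_stages)
    ]
    out_intercept = _solve_outcome_intercept(config, np.asarray(risk))

    # pass 2: materialize records, stays and labels
    patients: list[PatientRecord] = []
    labels = np.zeros(n, dtype=np.int64)
    for i in range(n):
        nv = int(visit_counts[i])
        active, stages, inpatient = all_active[i], all_stages[i], all_inpatient[i]
        n_codes = 1 + rng.poisson(config.codes_per_visit_rate, size=nv)
        while n_codes.sum() < 3:  # records below the attrition floor are topped up
            n_codes[rng.integers(nv)] += 1
        gaps = rng.integers(7, 180, size=nv)
        admit = _EPOCH + _dt.timedelta(days=int(rng.integers(0, 3650)))
        visits: list[VisitRecord] = []
        for t in range(nv):
            admit = admit + _dt.timedelta(days=int(gaps[t]))
            which = rng.integers(0, len(active), size=int(n_codes[t]))
            offsets = _emit_offsets(config, rng, stages[which, t])
            codes = []
            for rank, (c_idx, off) in enumerate(zip(which, offsets), start=1):
                codes.append(
                    DiagnosisCode(
                        system=CodeSystem.ICD10,
                        code=code_token(int(active[c_idx]), int(off)),
                        poa=bool(rng.random() < 0.5),
                        captured_during_visit=bool(rng.random() < 0.8),
                        priority=rank,
                    )
                )
            discharge = None
            enc_type = "outpatient"
            if inpatient[t]:
                enc_type = "inpatient"
                p_long = _sigmoid(los_intercept + config.los_slope * (stages[:, t].mean() - 1.0))
                if rng.random() < p_long:
                    los = 8 + int(rng.poisson(4.0))
                else:
                    los = int(rng.integers(0, 8))
                discharge = admit + _dt.timedelta(days=los)
            visits.append(
                VisitRecord(
                    admit_date=admit,
                    discharge_date=discharge,
                    encounter_type=enc_type,
                    codes=tuple(codes),
                )
            )
        p_out = _sigmoid(out_intercept + config.outcome_slope * risk[i])
        labels[i] = int(rng.random() < p_out)
        patients.append(
            PatientRecord(
                patient_id=f"S{config.seed}-{i:06d}",
                birth_year=int(rng.integers(1930, 2001)),
                sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                visits=tuple(visits),
            )
        )

    if config.inject_errors:
        patients.extend(_invalid_patients(config, rng))

    truth = {
        "active_conditions": all_active,
        "stage_paths": all_stages,
        "token_condition": {
            code_token(c, j): c
            for c in range(config.n_conditions)
            for j in range(config.codes_per_condition)
        },
        "los_intercept": los_intercept,
        "outcome_intercept": out_intercept,
    }
    return SyntheticCohort(patients=patients, outcome_labels=labels, latent_truth=truth)


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _solve_los_intercept(cfg, mean_sev, all_inpatient) -> float:
    """Bisection: expected share of patients with >=1 prolonged stay hits target."""

    def prevalence(b0: float) -> float:
        ps = []
        for sev, inp in zip(mean_sev, all_inpatient):
            pv = 1.0 / (1.0 + np.exp(-(b0 + cfg.los_slope * (sev[inp] - 1.0))))
            ps.append(1.0 - np.prod(1.0 - pv) if pv.size else 0.0)
        return float(np.mean(ps))

    return _bisect(prevalence, cfg.los_prevalence)


def _solve_outcome_intercept(cfg, risk: np.ndarray) -> float:
    def prevalence(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + cfg.outcome_slope * risk)))))

    return _bisect(prevalence, cfg.outcome_prevalence)


def _bisect(fn, target: float, lo: float = -30.0, hi: float = 10.0, iters: int = 80) -> float:
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _invalid_patients(cfg: SyntheticConfig, rng: np.random.Generator) -> list[PatientRecord]:
    """Deliberately broken records for exercising the attrition filter."""
    out = []
    for j in range(cfg.inject_errors):
        day = _EPOCH + _dt.timedelta(days=int(rng.integers(0, 3650)))
        code = DiagnosisCode(CodeSystem.ICD10, code_token(0, 0))
        if j % 2 == 0:  # too few codes
            visits = (VisitRecord(admit_date=day, codes=(code,)),)
        else:  # discharge precedes admission
            visits = (
                VisitRecord(
                    admit_date=day,
                    discharge_date=day - _dt.timedelta(days=3),
                    encounter_type="inpatient",
                    codes=(code, code, code),
                ),
            )
        out.append(
            PatientRecord(
                patient_id=f"X{cfg.seed}-{j:06d}", birth_year=1970, sex=Sex.OTHER, visits=visits
            )
        )
    return out


def generate_worked_example() -> PatientRecord:
    """A fixed four-visit record of a hypothetical patient, mixing encounter
    types and leaving some fields unrecorded, as a typical EHR system would.
    Used across the test suite as a stable fixture."""
    d = _dt.date
    return PatientRecord(
        patient_id="EXAMPLE-0001",
        birth_year=1952,
        sex=Sex.FEMALE,
        visits=(
            VisitRecord(
                admit_date=d(2015, 3, 2),
                encounter_type="outpatient",
                codes=(
                    DiagnosisCode(CodeSystem.ICD9, "250.00", poa=True, priority=1),
                    DiagnosisCode(CodeSystem.ICD9, "401.9", poa=True, priority=2),
                ),
            ),
            VisitRecord(
                admit_date=d(2015, 9, 14),
                discharge_date=d(2015, 9, 18),
                encounter_type="inpatient",
                codes=(
                    DiagnosisCode(CodeSystem.ICD9, "428.0", poa=False, priority=1),
                    DiagnosisCode(
                        CodeSystem.ICD9, "250.00", poa=True, priority=2,
                        captured_during_visit=False,
                    ),
                    DiagnosisCode(CodeSystem.ICD9, "585.9", poa=True, priority=3),
                ),
            ),
            VisitRecord(
                admit_date=d(2016, 2, 1),
                encounter_type="emergency",
                codes=(DiagnosisCode(CodeSystem.ICD10, "I50.9", poa=True, priority=1),),
            ),
            VisitRecord(
                admit_date=d(2016, 11, 23),
                discharge_date=d(2016, 12, 4),
                encounter_type="inpatient",
                codes=(
                    DiagnosisCode(CodeSystem.ICD10, "I50.9", poa=True, priority=1),
                    DiagnosisCode(CodeSystem.ICD10, "N18.3", poa=True, priority=2),
                    DiagnosisCode(CodeSystem.ICD10, "E11.9", poa=False, priority=3),
                ),
            ),
        ),
    )


__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_worked_example",
    "code_token",
    "condition_of_token",
]
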