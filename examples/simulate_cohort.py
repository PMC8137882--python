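"""Generate a synthetic EHR cohort and inspect its shape.

Builds 2,000 synthetic patients from the latent-condition generator and
prints the modality statistics a real structured-EHR corpus would show:
visit-count dispersion, codes per patient, prolonged-stay and outcome
prevalences (both calibrated to 15%).
"""

import numpy as np

from medbert import SyntheticConfig, generate_cohort, prolonged_los_label

cohort = generate_cohort(SyntheticConfig(n_patients=2000, seed=1))
visits = np.array([len(p.visits) for p in cohort.patients])
codes = np.array([p.total_code_count for p in cohort.patients])
los = np.array([prolonged_los_label(p) for p in cohort.patients])

print(f"patients:                {len(cohort.patients)}")
print(f"visits/patient:          mean {visits.mean():.2f}, range {visits.min()}-{visits.max()}")
print(f"codes/patient:           mean {codes.mean():.1f}")
print(f"prolonged-LOS prevalence {los.mean():.3f}   (calibrated target 0.15)")
print(f"outcome prevalence       {cohort.outcome_labels.mean():.3f}   (calibrated target 0.15)")

p = cohort.patients[0]
print(f"\nfirst patient {p.patient_id}: {len(p.visits)} visits")
for v in p.visits[:3]:
    print(f"  {v.admit_date} [{v.encounter_type:>10}] "
          + ", ".join(c.code for c in v.codes))
# Each code token D<condition>.<offset> is emitted by one latent chronic
# condition; same-condition codes co-occur within visits — the structure
# masked-code pretraining learns to exploit.
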