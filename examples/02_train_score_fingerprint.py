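"""Train a model on synthetic reference data and fingerprint one patient.

Training subjects are drawn from the stable-like (control) and AD-like
(case) variable distributions; the fitted model is then applied to a
patient with a partly missing work-up, showing how missing branches drop
out and the remaining weights renormalise.
"""

from dsindex import (
    compute_dsi,
    default_design,
    default_tree,
    default_variables,
    fingerprint,
    generate_training,
    train,
)
from dsindex.cohort import PatientRecord

_, distributions = default_design()
training = generate_training(400, 400, distributions, seed=7)
model = train(training, default_tree(), default_variables())

print("variable relevances (weight of each test in the composite):")
for name, info in sorted(model.training_summary.items(), key=lambda kv: -kv[1]["relevance"]):
    print(f"  {name:16s} {info['relevance']:.3f}  ({info['direction']})")

# an MCI patient with an AD-like profile but no lumbar puncture
patient = PatientRecord(
    patient_id="EX01",
    baseline_dx="MCI",
    values={
        "age": 74, "sex_female": 0, "mmse": 25, "memory_learning": 28,
        "memory_recall": 3, "tmt_a": 66, "tmt_b": 180, "fluency_animal": 15,
        "fluency_letter": 11, "clock_drawing": 2,
        "abeta42": None, "ptau": None, "ttau": None,  # no CSF available
        "gca": 1, "mta_left": 2, "mta_right": 2, "fazekas": 1,
    },
)
dsi = compute_dsi(patient, model)
print(f"\nDSI = {dsi:.3f}  (>= 0.5 classifies as likely to progress)")
print("\nfingerprint (value = fitness, weight = share of the composite):")
print(fingerprint(patient, model).to_text())
print(
    "\nThe csf branch is marked missing and contributes nothing; the other\n"
    "branches' weights sum to 1 after renormalisation."
)
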