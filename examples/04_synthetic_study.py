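"""End-to-end synthetic validation study.

Generates the default 429-patient memory-clinic cohort (230 SCD at 9%
progression, 199 MCI at 32%), trains the index on synthetic reference data,
simulates a clinician with sensitivity 0.67 / specificity 0.79 who partly
adopts the tool's advice, and runs the full paired evaluation.
"""

from dsindex import evaluate_study, render_impact_table, render_performance_table, simulate_study

cohort, model, training = simulate_study(seed=0)
report = evaluate_study(cohort, model)

print(render_impact_table(report))
print()
print(render_performance_table(report))
print(
    "\nEvery quantity above is computed from the generated cohort; because\n"
    "the generative clinician operates at SN 0.67 / SP 0.79 and the VAS\n"
    "shift is +4, the recovered values should sit near those parameters\n"
    "(within sampling noise at n = 429)."
)
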