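"""Paired clinician-without vs clinician-with-tool comparison from counts.

The discordant-pair bookkeeping of a paired prognostic study: 301 patients
predicted correctly both times, 72 incorrectly both times, 29 changed to a
correct and 27 to an incorrect prediction after seeing the tool. McNemar's
test and a Wald interval quantify whether the accuracy moved.
"""

from dsindex import paired_compare

both, neither, b, c = 301, 72, 29, 27
correct_without = [True] * both + [False] * neither + [False] * b + [True] * c
correct_with = [True] * both + [False] * neither + [True] * b + [False] * c

res = paired_compare(correct_without, correct_with)
print(f"n = {res.n}")
print(f"accuracy without tool: {100 * res.acc_without:.1f}%")
print(f"accuracy with tool:    {100 * res.acc_with:.1f}%")
print(f"difference:            {100 * res.diff:+.2f}%")
print(f"95% CI:                ({100 * res.ci_low:+.1f}%, {100 * res.ci_high:+.1f}%)")
print(f"McNemar chi2 = {res.statistic:.3f}, p = {res.p:.3f}")
print(
    "\nThe interval straddles zero and p is large: with 29 vs 27 discordant\n"
    "pairs the tool neither helped nor harmed overall accuracy."
)
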