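# Methods

## The index

The Disease State Index compares one patient's measurements with reference
samples from two training classes — controls and patients with established
Alzheimer's disease — and returns a scalar in [0, 1] read here as the
likelihood of clinical progression.

**Fitness.** Fix the convention "case iff value ≥ x" after mirroring
low-abnormal variables (CSF amyloid-β42, memory scores, verbal fluency,
MMSE, clock drawing) by sign negation. At a query value x, FN(x) is the
number of training cases strictly below x and FP(x) the number of training
controls at or above x; the fitness is the smoothed error ratio

    f(x) = (FN(x) + 0.5) / (FN(x) + FP(x) + 1).

The add-half smoothing resolves the 0/0 gap in perfectly separated regions
while keeping the bare ratio FN/(FN+FP) as the training set grows, and it
preserves monotonicity: writing u = FN + 0.5 (non-decreasing in x) and
v = FP + 0.5 (non-increasing), f = u/(u+v) is non-decreasing. The curve is
stored as a right-continuous step function over the sorted distinct
training values; queries outside the training range clamp to the end
values, so fitness is always in (0, 1).

**Relevance.** A variable's weight is its Youden index on the training
data: the maximum of sensitivity + specificity − 1 over candidate cutoffs
(midpoints of adjacent distinct pooled values plus one sentinel beyond
each extreme). Ties prefer higher specificity, then the lower cutoff —
a fixed, documented tie-break so training is deterministic. Negative J
clamps to 0 and the variable is excluded from the weighted sum rather than
having its direction flipped after the fact; the abnormal direction is
fixed before fitness estimation (declared per variable, or inferred from
the class medians with means as tie-break).

**Composite and tree.** Over a grouping tree (leaves = variables, internal
nodes = modality groups), each node's value is the relevance-weighted mean
of its contributing children; a child contributes when its relevance is
positive and its value is defined. Missing children drop out and the
remaining weights renormalise; a single contributor passes its value
through unchanged (exact, no floating-point round trip). A node with no
contributing descendant is *undefined* — signalled as `None`, never a
silent 0.5 — and propagates upward; a patient with no usable variable has
an undefined index and is excluded (and counted) in index-alone analyses.

**Internal-node relevance.** The hierarchical weighting of groups is
under-determined by the flat definition, so it is a configurable policy.
Default `composite_youden`: score every training subject with the group's
own composite and take the Youden index of those composite samples — a
group of individually weak but complementary tests can earn more weight
than any member, and a redundant group earns less than the sum of its
parts. Alternative `sum_children`: the sum of child relevances, capped at
1. Both policies leave leaf scoring untouched.

**Ordinal variables** (MTA 0–4, GCA 0–3, Fazekas 0–3, clock drawing,
MMSE) use the same empirical machinery with no continuity correction;
integer-valuedness is enforced at I/O time, not in the estimator.

## The evaluation

Progression is defined as SCD → MCI or dementia, and MCI → dementia, as
diagnosed at follow-up; clinical improvement (MCI → SCD) counts as stable.
The clinician's predicted follow-up diagnosis, passed through the same
rule, gives the binary prediction; the index predicts progression at
DSI ≥ 0.5 (boundary inclusive, as are the 0.2/0.8 subgroup bounds).

With binary predictions, a changed prediction flips correctness, so the
paired bookkeeping reduces to the discordant counts b (wrong without,
right with) and c (right without, wrong with). The accuracy difference is
exactly (b − c)/n in integer arithmetic; McNemar's statistic is
(b − c)²/(b + c) referred to χ²(1) *without* continuity correction (an
exact binomial variant is available behind a flag for small b + c); the
95% CI on the difference is Wald: diff ± 1.959964·√(b + c − (b−c)²/n)/n.
With counts 301/72/29/27 this machinery yields accuracies 76%/77%, CI
(−3.0%, +3.9%) and p = 0.789, matching the printed values of the
validation study the package emulates — the continuity-corrected p (≈0.89)
does not, which is why the uncorrected form is the default. Confidence
change is the paired t-test on with-minus-without VAS; zero-variance
differences flag the statistic as undefined instead of fabricating one.
Reported percentages round half away from zero at the printed precision.
Performance proportions with a zero denominator are `None`, never a
stand-in number.

Strata: all patients, baseline SCD, baseline MCI, Alzheimer-type outcomes
only (progressors to non-AD dementia excluded), and the confident
subgroup DSI ≤ 0.2 or ≥ 0.8. A cutoff sweep of index-alone metrics over a
configurable grid (default 0.10–0.90 step 0.05) is emitted as CSV.

## The synthetic cohort

The generator emulates the printed group-level statistics of a prospective
four-centre SCD/MCI cohort; its defaults are the study conditions, not
tuning knobs:

* 230 SCD and 199 MCI patients; progression probabilities 0.09 and 0.32;
  progressed SCD split MCI/AD/non-AD at 16:3:2 and progressed MCI split
  AD/non-AD at 41:22; follow-up times 1.9 ± 0.3 (SCD) and 1.6 ± 0.5 (MCI)
  years, truncated positive.
* Outcome-conditional variable distributions with the published
  stable/progressed means and SDs for age, sex, MMSE, word-list learning
  and recall, Trail Making A/B, animal and letter fluency, clock drawing,
  CSF amyloid-β42 / P-tau / total tau, GCA, left/right MTA and Fazekas.
  Continuous scores are truncated to instrument ranges and ordinal scales
  rounded to integers.
* Bounded instruments bias naive truncated sampling, so the truncated
  normal is re-parameterised to *carry* the published moments: both
  moments are matched where the family allows it, and where the published
  SD exceeds what any truncated normal on the interval can reach at that
  mean (scales piled against a bound — MMSE 28 ± 2 under a ceiling of 30
  sits exactly at the family's exponential limit), the mean is matched
  exactly with the scale held at the published SD. The same philosophy
  applies to the VAS confidence shift: the pre-clipping shift mean is
  solved so the realised mean shift on the clipped 0–100 scale equals the
  profile's stated +4.
* Missingness: one lumbar-puncture indicator per patient (p = 145/429)
  gates all three CSF variables jointly; other variables drop out
  independently at the published available-n rates (e.g. TMT-B 402/429).
  Dropout before follow-up is not modelled; the generator emits analysable
  patients only.
* Clinician: without-tool prediction drawn Bernoulli at sensitivity 0.67 /
  specificity 0.79 against the latent outcome; with-tool prediction adopts
  the index classification with probability 0.4 when the two disagree
  (chosen a priori to put the changed-prediction share in the low teens of
  percent, the magnitude such validation studies report; undefined index
  means no change). VAS baseline 65 ± 15 on [0, 100]; categorical
  confidence from fixed thresholds low < 50 ≤ moderate < 75 ≤ high. The
  VAS shift is drawn independently of correctness — the real study saw
  larger gains for correct predictions, which this simple behavioural
  model does not reproduce.

Variables are drawn independently given the outcome group: the published
tables state no correlation structure, and inventing one silently would
misrepresent what is known. An optional single-factor latent severity
(`severity_weight`) induces positive inter-test correlation for
sensitivity analyses; it is off by default. A consequence worth knowing:
with 17 conditionally independent informative variables the composite
separates the groups more cleanly than the real tool separated real
patients (synthetic index-alone accuracy ≈ 0.9 vs the study's 0.79, and a
smaller share of patients in the 0.2–0.8 middle band). Passing tests on
synthetic data therefore demonstrate correctness of the machinery and
recoverability of the generative parameters, not the clinical performance
level of the tool. For the same reason the training reference here is
drawn from the stable/progressed distributions, while the deployed tool
was trained on a proprietary AD-vs-controls database; absolute index
values are not comparable between the two.

All randomness flows from one integer seed: `numpy.random.default_rng`
throughout, with stage sub-seeds spawned via `SeedSequence` (kept below
2³¹), so every artefact is byte-reproducible given the seed.

## Problem sizes and numerical choices

Training defaults to 400 subjects per class; the evaluation cohort is the
study-sized n = 429. The brute-force oracle suite enumerates training sets
of up to 8 points per class on an integer grid against independent
error-count enumeration; parameter-recovery assertions use correctly
computed binomial 95% half-widths at the realised stratum sizes
(±1.96·√(p(1−p)/n), ≈ ±0.10 for sensitivity at n ≈ 84). Model files are
versioned JSON with `repr`-exact floats, so a save/load round trip leaves
every score bit-identical; cohort CSV uses empty cells (or `NA`) for
missing values, which parse back as missing, never zero.

## Known limitations

* The behavioural clinician model (Bernoulli operating point + fixed
  adoption probability) is deliberately minimal; it ignores case
  difficulty, centre effects and the dependence of confidence change on
  correctness and on the index value.
* Right-skewed quantities (TMT, tau) are generated as truncated normals
  with the published moments, not as log-normals; only first and second
  moments are faithful.
* The default tree groups variables by modality; the deployed tool's exact
  tree is known only by example, and a different grouping changes internal
  weights (though not leaf machinery).
* Multi-visit trajectories, site effects and drop-out are out of scope.
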