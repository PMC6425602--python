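"""Synthetic memory-clinic cohorts and training references.

The generator emulates the group-level statistics of a prospective
multicenter SCD/MCI cohort: 230 SCD and 199 MCI patients, of whom 9% and
32% respectively progress over roughly 1.7 years of follow-up; variable
distributions conditional on the stable/progressed outcome (e.g. MMSE
28 +/- 2 vs 26 +/- 3, CSF amyloid-beta 42 933 +/- 285 vs 748 +/- 338
pg/ml); lumbar puncture performed on clinical indication in about a third
of patients (CSF present for ~145/429); and a clinician who predicts
progression with sensitivity 0.67 and specificity 0.79 before seeing the
tool, then adopts the tool's classification with a fixed probability when
the two disagree.

Variables are drawn independently given the outcome group, as truncated
normals with the published moments (ordinal scales rounded to integers in
range); the published tables give no correlation structure, so an optional
single latent "severity" factor can induce positive inter-test correlation
but is off by default. All randomness flows from one integer seed through
``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.stats import truncnorm

from .cohort import Cohort, PatientRecord, TrainingReference, TreeConfig, TreeGroup, VariableSpec
from .dsi import DsiModel, compute_dsi
from .evaluate import PROGRESSED, STABLE, classify_dsi, define_outcome

__all__ = [
    "VariableDistribution",
    "ClinicianProfile",
    "CohortDesign",
    "default_variables",
    "default_tree",
    "default_design",
    "default_profile",
    "generate_training",
    "generate_cohort",
    "simulate_clinician",
    "simulate_study",
    "vas_to_category",
]

#: VAS thresholds for the low/moderate/high confidence categories
VAS_CATEGORY_BOUNDS = (50.0, 75.0)


@lru_cache(maxsize=None)
def _match_truncnorm(mean: float, sd: float, lower: float, upper: float) -> tuple[float, float]:
    """Underlying (loc, scale) so the [lower, upper]-truncated normal carries the
    published moments.

    Published cohort moments come from bounded instruments, so naively
    truncating N(mean, sd) would bias them. Both moments are matched when
    the family allows it; when the published SD exceeds what any truncated
    normal on the interval can reach at that mean (ordinal scales piled
    against a bound, e.g. MMSE 28 +/- 2 under a ceiling of 30), the mean is
    matched exactly with the scale held at the published SD.
    """
    if not (math.isfinite(lower) or math.isfinite(upper)):
        return mean, sd

    def residual(params):
        loc, log_scale = params
        scale = math.exp(log_scale)
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, math.sqrt(max(float(v), 1e-12)) - sd]

    sol = root(residual, x0=[mean, math.log(sd)], tol=1e-12)
    if sol.success and max(abs(r) for r in residual(sol.x)) < 1e-6 * max(1.0, sd):
        return float(sol.x[0]), float(math.exp(sol.x[1]))

    # fallback: truncated mean is strictly increasing in loc -> bisect
    def mean_residual(loc):
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd)) - mean

    lo, hi = mean - 8.0 * sd, mean + 8.0 * sd
    flo, fhi = mean_residual(lo), mean_residual(hi)
    if flo > 0 or fhi < 0:  # pragma: no cover - target mean outside bounds
        return mean, sd
    loc = brentq(mean_residual, lo, hi, xtol=1e-10)
    return float(loc), sd


def vas_to_category(vas: float, bounds: tuple[float, float] = VAS_CATEGORY_BOUNDS) -> str:
    lo, hi = bounds
    if vas < lo:
        return "low"
    if vas < hi:
        return "moderate"
    return "high"


def _clipped_mean(m: float, s: float, lo: float, hi: float) -> float:
    """E[clip(X, lo, hi)] for X ~ N(m, s)."""
    from scipy.stats import norm

    a, b = (lo - m) / s, (hi - m) / s
    return (
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + m * (norm.cdf(b) - norm.cdf(a))
        - s * (norm.pdf(b) - norm.pdf(a))
    )


@lru_cache(maxsize=None)
def _match_vas_shift(
    base_mean: float, base_sd: float, shift_mean: float, shift_sd: float
) -> float:
    """Pre-clipping shift mean whose *realized* mean shift on the clipped
    0-100 scale equals the profile's stated value.

    Clipping the with-tool VAS at the scale ends would otherwise shrink the
    generative truth (a +4 mean shift loses about a point against the
    ceiling when the baseline sits near 65), breaking parameter recovery.
    """
    loc, scale = _match_truncnorm(base_mean, base_sd, 0.0, 100.0)
    a, b = (0.0 - loc) / scale, (100.0 - loc) / scale
    qs = np.linspace(0.0005, 0.9995, 401)
    base = truncnorm.ppf(qs, a, b, loc=loc, scale=scale)

    def realized(mu: float) -> float:
        vals = [_clipped_mean(bb + mu, shift_sd, 0.0, 100.0) - bb for bb in base]
        return float(np.mean(vals)) - shift_mean

    return brentq(realized, shift_mean - 25.0, shift_mean + 25.0, xtol=1e-8)


@dataclass(frozen=True)
class VariableDistribution:
    """Group-conditional sampling model for one variable.

    ``kind='normal'``: truncated normal with the given mean/SD per outcome
    group, optionally rounded to integers (instrument scales).
    ``kind='categorical'``: explicit category values with per-group
    probabilities (used for sex).
    """

    name: str
    kind: str = "normal"
    stable_mean: float = 0.0
    stable_sd: float = 1.0
    progressed_mean: float = 0.0
    progressed_sd: float = 1.0
    lower: float = -math.inf
    upper: float = math.inf
    integer: bool = False
    categories: tuple[float, ...] = ()
    stable_probs: tuple[float, ...] = ()
    progressed_probs: tuple[float, ...] = ()
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "categorical"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "normal" and (self.stable_sd <= 0 or self.progressed_sd <= 0):
            raise ValueError(f"variable {self.name!r}: standard deviations must be positive")
        if self.kind == "categorical":
            for probs in (self.stable_probs, self.progressed_probs):
                if len(probs) != len(self.categories) or abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(
                        f"variable {self.name!r}: category probabilities must sum to 1"
                    )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"variable {self.name!r}: missing_rate outside [0, 1]")

    def sample(self, group: str, size: int, rng: np.random.Generator) -> np.ndarray:
        if group == STABLE:
            mean, sd, probs = self.stable_mean, self.stable_sd, self.stable_probs
        elif group == PROGRESSED:
            mean, sd, probs = self.progressed_mean, self.progressed_sd, self.progressed_probs
        else:
            raise ValueError(f"unknown group {group!r}")
        if self.kind == "categorical":
            return rng.choice(np.asarray(self.categories, dtype=float), size=size, p=probs)
        loc, scale = _match_truncnorm(mean, sd, self.lower, self.upper)
        a = (self.lower - loc) / scale
        b = (self.upper - loc) / scale
        x = truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)
        if self.integer:
            x = np.clip(np.rint(x), self.lower, self.upper)
        return x


@dataclass(frozen=True)
class ClinicianProfile:
    """Behavioral model of the predicting clinician.

    ``sensitivity``/``specificity`` are the without-tool operating point
    against the true outcome. When the tool's classification disagrees with
    the without-tool call, the clinician adopts it with probability
    ``adoption_prob``. Confidence is a truncated-normal VAS baseline plus a
    normal with-tool shift, both on the 0-100% scale.
    """

    sensitivity: float = 0.67
    specificity: float = 0.79
    adoption_prob: float = 0.4
    vas_base_mean: float = 65.0
    vas_base_sd: float = 15.0
    vas_shift_mean: float = 4.0
    vas_shift_sd: float = 13.0

    def __post_init__(self) -> None:
        for fld in ("sensitivity", "specificity", "adoption_prob"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fld} = {v} outside [0, 1]")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort sizes, progression rates, outcome subtype mixes, follow-up times."""

    n_scd: int = 230
    n_mci: int = 199
    progression_rate_scd: float = 0.09
    progression_rate_mci: float = 0.32
    # outcome subtype mix among progressors (observed counts 16/3/2 and 41/22)
    scd_subtypes: tuple[str, ...] = ("MCI", "AD", "NONAD")
    scd_subtype_probs: tuple[float, ...] = (16 / 21, 3 / 21, 2 / 21)
    mci_subtypes: tuple[str, ...] = ("AD", "NONAD")
    mci_subtype_probs: tuple[float, ...] = (41 / 63, 22 / 63)
    followup_scd: tuple[float, float] = (1.9, 0.3)  # mean, sd (years)
    followup_mci: tuple[float, float] = (1.6, 0.5)
    #: fraction of patients with a lumbar puncture (CSF variables present jointly)
    csf_availability: float = 145 / 429
    #: optional latent severity factor inducing inter-test correlation
    severity_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.n_scd < 0 or self.n_mci < 0:
            raise ValueError("cohort sizes must be non-negative")
        for r in (self.progression_rate_scd, self.progression_rate_mci, self.csf_availability):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")


_CSF_VARIABLES = ("abeta42", "ptau", "ttau")


def default_variables() -> list[VariableSpec]:
    """Default variable set: demographics, cognitive battery, CSF, visual MRI ratings."""
    d = VariableSpec
    return [
        d("age", "demographic", "continuous", "higher_abnormal"),
        d("sex_female", "demographic", "ordinal"),
        d("mmse", "cognitive", "ordinal", "lower_abnormal"),
        d("memory_learning", "cognitive", "continuous", "lower_abnormal"),
        d("memory_recall", "cognitive", "continuous", "lower_abnormal"),
        d("tmt_a", "cognitive", "continuous", "higher_abnormal"),
        d("tmt_b", "cognitive", "continuous", "higher_abnormal"),
        d("fluency_animal", "cognitive", "continuous", "lower_abnormal"),
        d("fluency_letter", "cognitive", "continuous", "lower_abnormal"),
        d("clock_drawing", "cognitive", "ordinal", "lower_abnormal"),
        d("abeta42", "csf", "continuous", "lower_abnormal"),
        d("ptau", "csf", "continuous", "higher_abnormal"),
        d("ttau", "csf", "continuous", "higher_abnormal"),
        d("gca", "mri_visual", "ordinal", "higher_abnormal"),
        d("mta_left", "mri_visual", "ordinal", "higher_abnormal"),
        d("mta_right", "mri_visual", "ordinal", "higher_abnormal"),
        d("fazekas", "mri_visual", "ordinal", "higher_abnormal"),
    ]


def default_tree() -> TreeConfig:
    """Fingerprint tree grouping the default variables by modality."""
    return TreeConfig(
        root=TreeGroup(
            "progression",
            [
                TreeGroup("demographics", ["age", "sex_female"]),
                TreeGroup(
                    "cognitive",
                    [
                        "mmse", "memory_learning", "memory_recall", "tmt_a", "tmt_b",
                        "fluency_animal", "fluency_letter", "clock_drawing",
                    ],
                ),
                TreeGroup("csf", ["abeta42", "ptau", "ttau"]),
                TreeGroup("mri_visual", ["gca", "mta_left", "mta_right", "fazekas"]),
            ],
        )
    )


def default_design() -> tuple[CohortDesign, list[VariableDistribution]]:
    """The emulated study conditions: cohort design plus variable distributions.

    Means/SDs are the published stable-vs-progressed moments; per-variable
    missing rates reproduce the published available-n out of 429 (CSF is
    handled jointly through ``csf_availability``).
    """
    n_total = 429

    def miss(n_avail: int) -> float:
        return 1.0 - n_avail / n_total

    v = VariableDistribution
    dists = [
        v("age", stable_mean=65, stable_sd=9, progressed_mean=72, progressed_sd=8,
          lower=40, upper=100),
        v("sex_female", kind="categorical", categories=(0.0, 1.0),
          stable_probs=(1 - 191 / 345, 191 / 345), progressed_probs=(1 - 39 / 84, 39 / 84)),
        v("mmse", stable_mean=28, stable_sd=2, progressed_mean=26, progressed_sd=3,
          lower=0, upper=30, integer=True, missing_rate=miss(427)),
        v("memory_learning", stable_mean=42, stable_sd=11, progressed_mean=31, progressed_sd=10,
          lower=0, upper=75, missing_rate=miss(420)),
        v("memory_recall", stable_mean=9, stable_sd=4, progressed_mean=4, progressed_sd=3,
          lower=0, upper=15, missing_rate=miss(420)),
        v("tmt_a", stable_mean=42, stable_sd=19, progressed_mean=58, progressed_sd=30,
          lower=10, upper=400, missing_rate=miss(422)),
        v("tmt_b", stable_mean=102, stable_sd=60, progressed_mean=164, progressed_sd=82,
          lower=20, upper=900, missing_rate=miss(402)),
        v("fluency_animal", stable_mean=23, stable_sd=7, progressed_mean=18, progressed_sd=6,
          lower=0, upper=60, missing_rate=miss(407)),
        v("fluency_letter", stable_mean=14, stable_sd=5, progressed_mean=12, progressed_sd=5,
          lower=0, upper=60, missing_rate=miss(377)),
        v("clock_drawing", stable_mean=3, stable_sd=1, progressed_mean=2, progressed_sd=1,
          lower=0, upper=5, integer=True, missing_rate=miss(394)),
        v("abeta42", stable_mean=933, stable_sd=285, progressed_mean=748, progressed_sd=338,
          lower=100, upper=2500),
        v("ptau", stable_mean=53, stable_sd=24, progressed_mean=63, progressed_sd=33,
          lower=5, upper=300),
        v("ttau", stable_mean=348, stable_sd=197, progressed_mean=445, progressed_sd=318,
          lower=50, upper=2500),
        v("gca", stable_mean=0.7, stable_sd=0.7, progressed_mean=1.2, progressed_sd=0.8,
          lower=0, upper=3, integer=True, missing_rate=miss(418)),
        v("mta_left", stable_mean=0.6, stable_sd=0.8, progressed_mean=1.6, progressed_sd=1.0,
          lower=0, upper=4, integer=True, missing_rate=miss(398)),
        v("mta_right", stable_mean=0.6, stable_sd=0.8, progressed_mean=1.4, progressed_sd=1.0,
          lower=0, upper=4, integer=True, missing_rate=miss(398)),
        v("fazekas", stable_mean=0.8, stable_sd=0.8, progressed_mean=1.1, progressed_sd=0.8,
          lower=0, upper=3, integer=True, missing_rate=miss(420)),
    ]
    return CohortDesign(), dists


def default_profile() -> ClinicianProfile:
    return ClinicianProfile()


def generate_training(
    n_controls: int,
    n_cases: int,
    distributions: Sequence[VariableDistribution],
    seed: int,
) -> TrainingReference:
    """Draw a training reference: controls from the stable-group distributions,
    cases from the progressed-group (AD-like) distributions. No missingness —
    a curated training database is assumed complete."""
    if n_controls < 2 or n_cases < 2:
        raise ValueError("need at least 2 subjects per class")
    rng = np.random.default_rng(seed)
    controls = {d.name: d.sample(STABLE, n_controls, rng) for d in distributions}
    cases = {d.name: d.sample(PROGRESSED, n_cases, rng) for d in distributions}
    return TrainingReference(controls=pd.DataFrame(controls), cases=pd.DataFrame(cases))


def generate_cohort(
    design: CohortDesign,
    distributions: Sequence[VariableDistribution],
    seed: int,
) -> Cohort:
    """Generate a cohort (no clinician fields yet) from the design.

    Per patient: a latent progression outcome drawn at the baseline-specific
    rate; variables drawn conditional on the outcome group; a follow-up
    diagnosis drawn from the subtype mix; modality-level missingness (one
    lumbar-puncture indicator gates all CSF variables; other variables drop
    out independently); follow-up time truncated positive. Sampling is
    vectorised per baseline block and variable.
    """
    rng = np.random.default_rng(seed)
    patients: list[PatientRecord] = []
    idx = 0
    for baseline, n, rate, subtypes, probs, fu in (
        ("SCD", design.n_scd, design.progression_rate_scd,
         design.scd_subtypes, design.scd_subtype_probs, design.followup_scd),
        ("MCI", design.n_mci, design.progression_rate_mci,
         design.mci_subtypes, design.mci_subtype_probs, design.followup_mci),
    ):
        if n == 0:
            continue
        progressed = rng.random(n) < rate
        z = rng.standard_normal(n) if design.severity_weight > 0.0 else None
        columns: dict[str, np.ndarray] = {}
        masks: dict[str, np.ndarray] = {}
        has_csf = rng.random(n) < design.csf_availability
        for d in distributions:
            x = np.empty(n, dtype=float)
            for group, sel in ((STABLE, ~progressed), (PROGRESSED, progressed)):
                k = int(np.sum(sel))
                if k:
                    x[sel] = d.sample(group, k, rng)
            if z is not None and d.kind == "normal":
                # shared latent severity: shift along the abnormal displacement
                sd = np.where(progressed, d.progressed_sd, d.stable_sd)
                sign = math.copysign(1.0, d.progressed_mean - d.stable_mean) or 1.0
                x = np.clip(x + design.severity_weight * sd * sign * z, d.lower, d.upper)
                if d.integer:
                    x = np.clip(np.rint(x), d.lower, d.upper)
            columns[d.name] = x
            if d.name in _CSF_VARIABLES:
                masks[d.name] = ~has_csf
            elif d.missing_rate > 0.0:
                masks[d.name] = rng.random(n) < d.missing_rate
            else:
                masks[d.name] = np.zeros(n, dtype=bool)
        followups = np.where(progressed, rng.choice(subtypes, size=n, p=probs), baseline)
        mean, sd = fu
        t = rng.normal(mean, sd, size=n)
        while np.any(t <= 0.05):  # truncate follow-up time positive
            bad = t <= 0.05
            t[bad] = rng.normal(mean, sd, size=int(np.sum(bad)))
        for i in range(n):
            idx += 1
            values = {
                name: (None if masks[name][i] else float(columns[name][i]))
                for name in columns
            }
            patients.append(
                PatientRecord(
                    patient_id=f"P{idx:04d}",
                    baseline_dx=baseline,
                    values=values,
                    followup_dx=str(followups[i]),
                    followup_years=round(float(t[i]), 3),
                )
            )
    cohort = Cohort(
        patients=patients,
        provenance={
            "generator": "dsindex.simulate.generate_cohort",
            "seed": int(seed),
            "n_scd": design.n_scd,
            "n_mci": design.n_mci,
            "progression_rate_scd": design.progression_rate_scd,
            "progression_rate_mci": design.progression_rate_mci,
            "csf_availability": design.csf_availability,
            "severity_weight": design.severity_weight,
        },
    )
    cohort.validate()
    return cohort


def _binary_to_prediction(baseline_dx: str, binary: str) -> str:
    """Predicted follow-up diagnosis token consistent with the baseline.

    A predicted progression from SCD is encoded as MCI (the dominant
    observed conversion), from MCI as dementia.
    """
    if binary == STABLE:
        return baseline_dx
    return "MCI" if baseline_dx == "SCD" else "DEM"


def simulate_clinician(
    cohort: Cohort,
    model: DsiModel,
    profile: ClinicianProfile,
    seed: int,
    cutoff: float = 0.5,
) -> Cohort:
    """Add paired predictions, VAS confidences and categories to a cohort.

    Returns a new cohort; the input is not modified. The without-tool call
    is Bernoulli at the profile operating point against the true outcome;
    the with-tool call adopts the index classification with probability
    ``adoption_prob`` when they disagree (undefined index: no change).
    """
    rng = np.random.default_rng(seed)
    base_loc, base_scale = _match_truncnorm(profile.vas_base_mean, profile.vas_base_sd, 0.0, 100.0)
    base_a, base_b = (0.0 - base_loc) / base_scale, (100.0 - base_loc) / base_scale
    shift_mu = _match_vas_shift(
        profile.vas_base_mean, profile.vas_base_sd, profile.vas_shift_mean, profile.vas_shift_sd
    )
    out: list[PatientRecord] = []
    for p in cohort.patients:
        truth = define_outcome(p.baseline_dx, p.followup_dx).label
        if truth == PROGRESSED:
            wo = PROGRESSED if rng.random() < profile.sensitivity else STABLE
        else:
            wo = STABLE if rng.random() < profile.specificity else PROGRESSED
        dsi_call = classify_dsi(compute_dsi(p, model), cutoff)
        wt = wo
        if dsi_call is not None and dsi_call != wo and rng.random() < profile.adoption_prob:
            wt = dsi_call
        vas_wo = float(
            truncnorm.rvs(base_a, base_b, loc=base_loc, scale=base_scale, random_state=rng)
        )
        vas_wt = float(np.clip(vas_wo + rng.normal(shift_mu, profile.vas_shift_sd), 0, 100))
        vas_wo, vas_wt = round(vas_wo, 1), round(vas_wt, 1)
        out.append(
            replace(
                p,
                values=dict(p.values),
                pred_without_tool=_binary_to_prediction(p.baseline_dx, wo),
                pred_with_tool=_binary_to_prediction(p.baseline_dx, wt),
                vas_without_tool=vas_wo,
                vas_with_tool=vas_wt,
                conf_without_tool=vas_to_category(vas_wo),
                conf_with_tool=vas_to_category(vas_wt),
            )
        )
    provenance = dict(cohort.provenance)
    provenance.update(
        {
            "clinician_seed": int(seed),
            "clinician_sensitivity": profile.sensitivity,
            "clinician_specificity": profile.specificity,
            "adoption_prob": profile.adoption_prob,
            "vas_shift_mean": profile.vas_shift_mean,
            "vas_shift_sd": profile.vas_shift_sd,
        }
    )
    result = Cohort(patients=out, provenance=provenance)
    result.validate()
    return result


def simulate_study(
    seed: int,
    design: CohortDesign | None = None,
    distributions: Sequence[VariableDistribution] | None = None,
    profile: ClinicianProfile | None = None,
    n_training: int = 400,
):
    """End-to-end convenience: training -> model -> cohort -> clinician.

    Returns ``(cohort, model, training)``. Sub-seeds for the three stages
    are drawn from one ``SeedSequence`` spawned from ``seed``.
    """
    from .dsi import train  # local import to keep module load cheap

    if design is None or distributions is None:
        d0, x0 = default_design()
        design = design or d0
        distributions = distributions or x0
    profile = profile or default_profile()
    s_train, s_cohort, s_clin = np.random.SeedSequence(seed).spawn(3)

    def sub(ss: np.random.SeedSequence) -> int:
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))

    training = generate_training(n_training, n_training, distributions, sub(s_train))
    model = train(training, default_tree(), default_variables())
    cohort = generate_cohort(design, distributions, sub(s_cohort))
    cohort = simulate_clinician(cohort, model, profile, sub(s_clin))
    cohort.provenance["cohort_seed"] = cohort.provenance.pop("seed")
    cohort.provenance["seed"] = int(seed)
    return cohort, model, training
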