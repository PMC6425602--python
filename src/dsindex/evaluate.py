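"""Prognostic evaluation: outcomes, accuracy metrics, paired comparisons.

Progression is the study outcome: a patient with subjective cognitive
decline (SCD) at baseline progresses by converting to mild cognitive
impairment (MCI) or any dementia at follow-up; an MCI patient progresses by
converting to dementia. Clinical improvement (MCI back to SCD) counts as
stable. The clinician's predicted follow-up diagnosis, mapped through the
same rule, yields a binary prediction of progression; the index classifier
predicts progression when DSI >= 0.5.

The without-tool and with-tool predictions of the same clinician on the
same patient are paired, so their accuracies are compared on the discordant
pairs: McNemar's chi-square (b - c)^2 / (b + c) without continuity
correction on 1 df, and a Wald normal-approximation 95% CI on the accuracy
difference (b - c)/n. Confidence change is the paired difference in the
0-100% visual-analogue confidence, tested with a paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, PatientRecord
from .dsi import DsiModel, compute_dsi

__all__ = [
    "STABLE",
    "PROGRESSED",
    "ProgressionOutcome",
    "PerformanceMetrics",
    "PairedEvalResult",
    "ConfidenceResult",
    "StudyReport",
    "define_outcome",
    "prediction_to_binary",
    "classify_dsi",
    "subgroup_extreme",
    "confusion_metrics",
    "paired_compare",
    "confidence_analysis",
    "evaluate_study",
    "round_half_away",
]

STABLE = "stable"
PROGRESSED = "progressed"

_DEMENTIA_TOKENS = frozenset({"AD", "NONAD", "DEM"})
_Z_95 = 1.959964
_CONF_ORDER = {"low": 0, "moderate": 1, "high": 2}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProgressionOutcome:
    label: str  # STABLE | PROGRESSED
    subtype: str | None = None  # to_MCI | to_AD | to_nonAD, iff progressed

    def __post_init__(self) -> None:
        if self.label not in (STABLE, PROGRESSED):
            raise ValueError(f"bad outcome label {self.label!r}")
        if (self.subtype is not None) != (self.label == PROGRESSED):
            raise ValueError("subtype present iff progressed")


def define_outcome(baseline_dx: str, followup_dx: str) -> ProgressionOutcome:
    """Map baseline and follow-up diagnoses to the progression outcome."""
    if baseline_dx not in ("SCD", "MCI"):
        raise ValueError(f"baseline diagnosis {baseline_dx!r} outside the cohort definition")
    if followup_dx == "AD":
        return ProgressionOutcome(PROGRESSED, "to_AD")
    if followup_dx == "NONAD":
        return ProgressionOutcome(PROGRESSED, "to_nonAD")
    if followup_dx == "MCI":
        if baseline_dx == "SCD":
            return ProgressionOutcome(PROGRESSED, "to_MCI")
        return ProgressionOutcome(STABLE)
    if followup_dx == "SCD":
        return ProgressionOutcome(STABLE)  # improvement handled as stable
    raise ValueError(f"unknown follow-up diagnosis {followup_dx!r}")


def prediction_to_binary(baseline_dx: str, predicted_followup_dx: str) -> str:
    """Map a predicted follow-up diagnosis to a binary prediction of progression."""
    if baseline_dx not in ("SCD", "MCI"):
        raise ValueError(f"baseline diagnosis {baseline_dx!r} outside the cohort definition")
    pred = predicted_followup_dx
    if pred in _DEMENTIA_TOKENS:
        return PROGRESSED
    if pred == "MCI":
        return PROGRESSED if baseline_dx == "SCD" else STABLE
    if pred == "SCD":
        return STABLE
    raise ValueError(f"unknown predicted diagnosis {pred!r}")


def classify_dsi(dsi: float | None, cutoff: float = 0.5) -> str | None:
    """Progression call of the index alone: progressed iff DSI >= cutoff.

    An undefined score (None/NaN) propagates as ``None`` (unclassifiable).
    """
    if dsi is None or (isinstance(dsi, float) and math.isnan(dsi)):
        return None
    return PROGRESSED if dsi >= cutoff else STABLE


def subgroup_extreme(
    dsi_values: Sequence[float | None], low: float = 0.2, high: float = 0.8
) -> list[int]:
    """Indices of patients with a confident classification: DSI <= low or >= high.

    Both boundaries inclusive; undefined scores are never selected.
    """
    if not (0.0 <= low < high <= 1.0):
        raise ValueError("need 0 <= low < high <= 1")
    out = []
    for i, v in enumerate(dsi_values):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if v <= low or v >= high:
            out.append(i)
    return out


@dataclass
class PerformanceMetrics:
    """Confusion counts and the derived proportions for one binary predictor.

    Progressed is the positive class. A proportion whose denominator is zero
    is ``None`` (undefined), never an arbitrary number.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.n if self.n else None

    @property
    def balanced_accuracy(self) -> float | None:
        sn, sp = self.sensitivity, self.specificity
        if sn is None or sp is None:
            return None
        return (sn + sp) / 2.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn, "n": self.n,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "accuracy": self.accuracy, "balanced_accuracy": self.balanced_accuracy,
        }


def confusion_metrics(predictions: Sequence[str], outcomes: Sequence[str]) -> PerformanceMetrics:
    """Confusion counts of binary progression predictions against outcomes."""
    if len(predictions) != len(outcomes):
        raise ValueError("predictions and outcomes differ in length")
    tp = fp = tn = fn = 0
    for pred, truth in zip(predictions, outcomes):
        if pred not in (STABLE, PROGRESSED) or truth not in (STABLE, PROGRESSED):
            raise ValueError(f"labels must be {STABLE!r}/{PROGRESSED!r}")
        if truth == PROGRESSED:
            if pred == PROGRESSED:
                tp += 1
            else:
                fn += 1
        else:
            if pred == PROGRESSED:
                fp += 1
            else:
                tn += 1
    return PerformanceMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class PairedEvalResult:
    """Concordant/discordant bookkeeping of two paired binary predictors.

    With binary calls, a changed prediction flips correctness, so
    ``changed_correct`` is the discordant count b (wrong without, right
    with) and ``changed_incorrect`` is c. The accuracy difference is exactly
    (b - c)/n; the CI is Wald; the p-value is McNemar's test.
    """

    n: int
    unchanged_correct: int
    unchanged_incorrect: int
    changed_correct: int
    changed_incorrect: int
    acc_without: float
    acc_with: float
    diff: float
    ci_low: float
    ci_high: float
    p: float
    statistic: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "unchanged_correct", "unchanged_incorrect", "changed_correct",
            "changed_incorrect", "acc_without", "acc_with", "diff",
            "ci_low", "ci_high", "p", "statistic",
        )}


def paired_compare(
    correct_without: Sequence[bool],
    correct_with: Sequence[bool],
    exact: bool = False,
) -> PairedEvalResult:
    """Compare paired correctness vectors with McNemar's test and a Wald CI.

    ``exact=True`` replaces the chi-square p-value with the exact two-sided
    binomial test on the discordant pairs (useful when b + c is small).
    """
    w = np.asarray(correct_without, dtype=bool)
    t = np.asarray(correct_with, dtype=bool)
    if w.shape != t.shape or w.ndim != 1:
        raise ValueError("correctness vectors must be 1-d and equal length")
    n = int(w.size)
    if n < 1:
        raise ValueError("need at least one pair")
    both = int(np.sum(w & t))
    neither = int(np.sum(~w & ~t))
    b = int(np.sum(~w & t))  # changed to correct
    c = int(np.sum(w & ~t))  # changed to incorrect
    diff = (b - c) / n
    if b + c == 0:
        statistic: float | None = None
        p = 1.0
    elif exact:
        statistic = None
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
    else:
        statistic = (b - c) ** 2 / (b + c)
        p = float(stats.chi2.sf(statistic, df=1))
    half = _Z_95 * math.sqrt(max(0.0, b + c - (b - c) ** 2 / n)) / n
    return PairedEvalResult(
        n=n,
        unchanged_correct=both,
        unchanged_incorrect=neither,
        changed_correct=b,
        changed_incorrect=c,
        acc_without=(both + c) / n,
        acc_with=(both + b) / n,
        diff=diff,
        ci_low=diff - half,
        ci_high=diff + half,
        p=p,
        statistic=statistic,
    )


@dataclass
class ConfidenceResult:
    """Change in prediction confidence after adding the tool.

    ``mean_delta_vas`` is on the 0-100% scale. The t-test is the paired
    two-sided test on with-minus-without VAS; it is ``None``-flagged when
    the differences have zero variance or fewer than two pairs exist.
    Categorical shifts partition the cohort into increase/decrease/stable
    and are further split by with-tool correctness.
    """

    n: int
    mean_delta_vas: float
    sd_delta_vas: float | None
    t_statistic: float | None
    p: float | None
    mean_delta_correct: float | None
    mean_delta_incorrect: float | None
    increase_correct: int = 0
    increase_incorrect: int = 0
    decrease_correct: int = 0
    decrease_incorrect: int = 0
    stable_correct: int = 0
    stable_incorrect: int = 0

    @property
    def n_increase(self) -> int:
        return self.increase_correct + self.increase_incorrect

    @property
    def share_increase_correct(self) -> float | None:
        """Share of confidence-increase cases that supported a correct prediction."""
        return self.increase_correct / self.n_increase if self.n_increase else None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_delta_vas": self.mean_delta_vas,
            "sd_delta_vas": self.sd_delta_vas,
            "t_statistic": self.t_statistic,
            "p": self.p,
            "mean_delta_correct": self.mean_delta_correct,
            "mean_delta_incorrect": self.mean_delta_incorrect,
            "increase_correct": self.increase_correct,
            "increase_incorrect": self.increase_incorrect,
            "decrease_correct": self.decrease_correct,
            "decrease_incorrect": self.decrease_incorrect,
            "stable_correct": self.stable_correct,
            "stable_incorrect": self.stable_incorrect,
            "share_increase_correct": self.share_increase_correct,
        }


def confidence_analysis(
    vas_without: Sequence[float],
    vas_with: Sequence[float],
    correctness: Sequence[bool],
    categories_without: Sequence[str] | None = None,
    categories_with: Sequence[str] | None = None,
) -> ConfidenceResult:
    """Paired analysis of prediction confidence without vs. with the tool."""
    vw = np.asarray(vas_without, dtype=float)
    vt = np.asarray(vas_with, dtype=float)
    ok = np.asarray(correctness, dtype=bool)
    if not (vw.shape == vt.shape == ok.shape) or vw.ndim != 1:
        raise ValueError("inputs must be 1-d and equal length")
    if np.any((vw < 0) | (vw > 100) | (vt < 0) | (vt > 100)):
        raise ValueError("VAS values must lie in [0, 100]")
    n = int(vw.size)
    delta = vt - vw
    mean_delta = float(np.mean(delta)) if n else 0.0
    sd = float(np.std(delta, ddof=1)) if n >= 2 else None
    if n >= 2 and sd is not None and sd > 0.0:
        tt = stats.ttest_rel(vt, vw)
        t_stat, p = float(tt.statistic), float(tt.pvalue)
    else:
        t_stat = p = None  # zero variance or too few pairs: flagged, not faked
    res = ConfidenceResult(
        n=n,
        mean_delta_vas=mean_delta,
        sd_delta_vas=sd,
        t_statistic=t_stat,
        p=p,
        mean_delta_correct=float(np.mean(delta[ok])) if np.any(ok) else None,
        mean_delta_incorrect=float(np.mean(delta[~ok])) if np.any(~ok) else None,
    )
    if categories_without is not None and categories_with is not None:
        if len(categories_without) != n or len(categories_with) != n:
            raise ValueError("category vectors must match VAS length")
        for cw, ct, good in zip(categories_without, categories_with, ok):
            a, z = _CONF_ORDER[cw], _CONF_ORDER[ct]
            key = "increase" if z > a else ("decrease" if z < a else "stable")
            attr = f"{key}_{'correct' if good else 'incorrect'}"
            setattr(res, attr, getattr(res, attr) + 1)
    return res


# ---------------------------------------------------------------------------
# full study evaluation


@dataclass
class StratumResult:
    name: str
    n: int
    n_unclassifiable_dsi: int
    metrics_without: PerformanceMetrics | None
    metrics_with: PerformanceMetrics | None
    metrics_dsi: PerformanceMetrics | None
    paired_without_with: PairedEvalResult | None
    paired_without_dsi: PairedEvalResult | None
    confidence: ConfidenceResult | None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n": self.n,
            "n_unclassifiable_dsi": self.n_unclassifiable_dsi,
            "metrics_without": self.metrics_without.to_dict() if self.metrics_without else None,
            "metrics_with": self.metrics_with.to_dict() if self.metrics_with else None,
            "metrics_dsi": self.metrics_dsi.to_dict() if self.metrics_dsi else None,
            "paired_without_with": (
                self.paired_without_with.to_dict() if self.paired_without_with else None
            ),
            "paired_without_dsi": (
                self.paired_without_dsi.to_dict() if self.paired_without_dsi else None
            ),
            "confidence": self.confidence.to_dict() if self.confidence else None,
        }


@dataclass
class StudyReport:
    """Per-stratum results plus the cutoff-sweep table of the index alone."""

    strata: dict[str, StratumResult]
    cutoff: float
    subgroup_bounds: tuple[float, float]
    sweep: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        sweep = None
        if self.sweep is not None:
            sweep = [
                {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in row.items()}
                for row in self.sweep.to_dict(orient="records")
            ]
        return {
            "cutoff": self.cutoff,
            "subgroup_bounds": list(self.subgroup_bounds),
            "strata": {k: v.to_dict() for k, v in self.strata.items()},
            "cutoff_sweep": sweep,
        }


def _stratum_result(
    name: str,
    patients: list[PatientRecord],
    scores: list[float | None],
    cutoff: float,
) -> StratumResult:
    n = len(patients)
    if n == 0:
        return StratumResult(name, 0, 0, None, None, None, None, None, None)
    outcomes = [define_outcome(p.baseline_dx, p.followup_dx).label for p in patients]
    pred_wo = [prediction_to_binary(p.baseline_dx, p.pred_without_tool) for p in patients]
    pred_wt = [prediction_to_binary(p.baseline_dx, p.pred_with_tool) for p in patients]
    pred_dsi = [classify_dsi(s, cutoff) for s in scores]
    clf = [i for i, d in enumerate(pred_dsi) if d is not None]

    correct_wo = [pw == o for pw, o in zip(pred_wo, outcomes)]
    correct_wt = [pw == o for pw, o in zip(pred_wt, outcomes)]

    metrics_dsi = (
        confusion_metrics([pred_dsi[i] for i in clf], [outcomes[i] for i in clf]) if clf else None
    )
    paired_dsi = (
        paired_compare(
            [correct_wo[i] for i in clf],
            [pred_dsi[i] == outcomes[i] for i in clf],
        )
        if clf
        else None
    )
    conf = None
    if all(p.vas_without_tool is not None and p.vas_with_tool is not None for p in patients):
        cats = all(
            p.conf_without_tool is not None and p.conf_with_tool is not None for p in patients
        )
        conf = confidence_analysis(
            [p.vas_without_tool for p in patients],
            [p.vas_with_tool for p in patients],
            correct_wt,
            [p.conf_without_tool for p in patients] if cats else None,
            [p.conf_with_tool for p in patients] if cats else None,
        )
    return StratumResult(
        name=name,
        n=n,
        n_unclassifiable_dsi=n - len(clf),
        metrics_without=confusion_metrics(pred_wo, outcomes),
        metrics_with=confusion_metrics(pred_wt, outcomes),
        metrics_dsi=metrics_dsi,
        paired_without_with=paired_compare(correct_wo, correct_wt),
        paired_without_dsi=paired_dsi,
        confidence=conf,
    )


def evaluate_study(
    cohort: Cohort,
    model: DsiModel | None = None,
    cutoff: float = 0.5,
    subgroup_bounds: tuple[float, float] = (0.2, 0.8),
    sweep_grid: Sequence[float] | None = None,
) -> StudyReport:
    """Run the full paired evaluation on a cohort with follow-up data.

    Index scores come from ``model`` when given, else from a pre-scored
    ``dsi`` column. Strata: all patients; baseline SCD; baseline MCI;
    Alzheimer-type outcomes only (patients who progressed to non-AD
    dementia excluded); and the confident-classification subgroup
    (DSI <= low or >= high). Patients with an undefined index are excluded
    from index-alone and subgroup analyses and counted in the report.
    """
    patients = [p for p in cohort.patients]
    missing_fu = [p.patient_id for p in patients if p.followup_dx is None]
    if missing_fu:
        raise ValueError(f"patients without follow-up diagnosis: {missing_fu[:5]}")
    missing_pred = [
        p.patient_id
        for p in patients
        if p.pred_without_tool is None or p.pred_with_tool is None
    ]
    if missing_pred:
        raise ValueError(f"patients without paired predictions: {missing_pred[:5]}")
    if model is not None:
        scores: list[float | None] = [compute_dsi(p, model) for p in patients]
    else:
        scores = [p.dsi for p in patients]

    low, high = subgroup_bounds
    extreme = set(subgroup_extreme(scores, low, high))
    subsets = {
        "all": list(range(len(patients))),
        "scd": [i for i, p in enumerate(patients) if p.baseline_dx == "SCD"],
        "mci": [i for i, p in enumerate(patients) if p.baseline_dx == "MCI"],
        "excl_nonad": [i for i, p in enumerate(patients) if p.followup_dx != "NONAD"],
        "extreme_dsi": sorted(extreme),
    }
    strata = {
        name: _stratum_result(
            name, [patients[i] for i in idx], [scores[i] for i in idx], cutoff
        )
        for name, idx in subsets.items()
    }

    if sweep_grid is None:
        sweep_grid = np.round(np.arange(0.1, 0.91, 0.05), 2)
    outcomes = [define_outcome(p.baseline_dx, p.followup_dx).label for p in patients]
    clf = [i for i, s in enumerate(scores) if classify_dsi(s) is not None]
    rows = []
    for c in sweep_grid:
        m = confusion_metrics(
            [classify_dsi(scores[i], float(c)) for i in clf], [outcomes[i] for i in clf]
        )
        rows.append({"cutoff": float(c), **m.to_dict()})
    sweep = pd.DataFrame(rows)
    return StudyReport(
        strata=strata, cutoff=cutoff, subgroup_bounds=(low, high), sweep=sweep
    )
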