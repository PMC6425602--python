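"""Human-readable rendering of study reports.

Two text tables mirror the layout a paired validation study prints: an
impact table (prediction changes and confidence) and a performance table
(SN/SP/PPV/NPV/accuracy/balanced accuracy per predictor and stratum).
Percentages round half away from zero to the printed precision.
"""

from __future__ import annotations

import json

from .evaluate import PerformanceMetrics, StratumResult, StudyReport, round_half_away

__all__ = ["render_impact_table", "render_performance_table", "report_to_json"]

_STRATUM_TITLES = {
    "all": "All",
    "scd": "SCD",
    "mci": "MCI",
    "excl_nonad": "Excl. non-AD dementia",
    "extreme_dsi": "Confident DSI subgroup",
}


def _pct(x: float | None, ndigits: int = 0) -> str:
    if x is None:
        return "--"
    v = round_half_away(100.0 * x, ndigits)
    return f"{v:.{ndigits}f}"


def _num(x: float | None, ndigits: int = 2) -> str:
    return "--" if x is None else f"{round_half_away(x, ndigits):.{ndigits}f}"


def render_impact_table(report: StudyReport) -> str:
    """Prediction-change and confidence bookkeeping per stratum."""
    lines = ["Impact of the tool on the baseline prediction of progression", ""]
    header = f"{'':38s}" + "".join(f"{_STRATUM_TITLES.get(k, k):>24s}" for k in ("all", "scd", "mci"))
    lines.append(header)
    strata = [report.strata[k] for k in ("all", "scd", "mci")]

    def row(label: str, cells: list[str]) -> None:
        lines.append(f"{label:38s}" + "".join(f"{c:>24s}" for c in cells))

    row("n", [str(s.n) for s in strata])
    for label, attr in (
        ("Unchanged correct, n (%)", "unchanged_correct"),
        ("Unchanged incorrect, n (%)", "unchanged_incorrect"),
        ("Changed correct, n (%)", "changed_correct"),
        ("Changed incorrect, n (%)", "changed_incorrect"),
    ):
        cells = []
        for s in strata:
            pr = s.paired_without_with
            cells.append("--" if pr is None else f"{getattr(pr, attr)} ({_pct(getattr(pr, attr) / pr.n)})")
        row(label, cells)
    for label, fn in (
        ("Accuracy without tool (%)", lambda pr: _pct(pr.acc_without)),
        ("Accuracy with tool (%)", lambda pr: _pct(pr.acc_with)),
        ("Difference (%)", lambda pr: _pct(pr.diff, 1)),
        ("95% CI (%)", lambda pr: f"{_pct(pr.ci_low, 1)}; {_pct(pr.ci_high, 1)}"),
        ("McNemar p", lambda pr: _num(pr.p)),
    ):
        row(label, ["--" if s.paired_without_with is None else fn(s.paired_without_with) for s in strata])
    lines.append("")
    lines.append("Confidence (VAS 0-100%)")
    for label, fn in (
        ("Mean change", lambda c: _num(c.mean_delta_vas, 1)),
        ("Mean change, correct", lambda c: _num(c.mean_delta_correct, 1)),
        ("Mean change, incorrect", lambda c: _num(c.mean_delta_incorrect, 1)),
        ("Paired t p", lambda c: _num(c.p, 4)),
        ("Increase correct/incorrect, n", lambda c: f"{c.increase_correct}/{c.increase_incorrect}"),
        ("Decrease correct/incorrect, n", lambda c: f"{c.decrease_correct}/{c.decrease_incorrect}"),
        ("Stable correct/incorrect, n", lambda c: f"{c.stable_correct}/{c.stable_incorrect}"),
    ):
        row(label, ["--" if s.confidence is None else fn(s.confidence) for s in strata])
    return "\n".join(lines)


def _metric_row(m: PerformanceMetrics | None) -> str:
    if m is None:
        return f"{'--':>8s}" * 6
    cells = (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy, m.balanced_accuracy)
    return "".join(f"{_num(c):>8s}" for c in cells)


def render_performance_table(report: StudyReport) -> str:
    """SN/SP/PPV/NPV/accuracy/balanced accuracy per predictor and stratum."""
    lines = [
        "Performance to predict progression (clinician without/with tool, index alone)",
        "",
        f"{'Cohort / predictor':34s}" + "".join(
            f"{h:>8s}" for h in ("SN", "SP", "PPV", "NPV", "Acc", "BalAcc")
        ),
    ]
    for key, s in report.strata.items():
        title = _STRATUM_TITLES.get(key, key)
        lines.append(f"{title} (n = {s.n})")
        for label, m in (
            ("Without tool", s.metrics_without),
            ("With tool", s.metrics_with),
            ("DSI alone", s.metrics_dsi),
        ):
            lines.append(f"  {label:32s}" + _metric_row(m))
        if s.n_unclassifiable_dsi:
            lines.append(f"  (index undefined for {s.n_unclassifiable_dsi} patients)")
    return "\n".join(lines)


def report_to_json(report: StudyReport, **kwargs) -> str:
    kwargs.setdefault("indent", 1)
    return json.dumps(report.to_dict(), **kwargs)
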