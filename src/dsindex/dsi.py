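"""The Disease State Index: empirical fitness, Youden relevance, weighted composite.

The index compares one patient's measurements with reference samples from
two training classes (controls vs. established Alzheimer's disease) and
returns a scalar in [0, 1]:

1. Each variable value ``x`` is scored by an empirical *fitness* function
   built from the training error counts when ``x`` is used as a
   classification cutoff: ``f(x) = FN(x) / (FN(x) + FP(x))``, where under
   the fixed convention "case iff value >= x" (abnormal direction high)
   ``FN(x)`` is the number of training cases strictly below ``x`` and
   ``FP(x)`` the number of training controls at or above ``x``. A fitness
   near 0 means the value looks control-like, near 1 case-like.
2. Each variable's *relevance* is its Youden index ``J = max over cutoffs
   (sensitivity + specificity - 1)`` on the training data — how well the
   variable alone separates the classes. Negative J clamps to 0.
3. The composite index is the relevance-weighted mean of fitness values,
   ``DSI = sum(relevance * fitness) / sum(relevance)``, applied recursively
   over a grouping tree (the disease-state fingerprint). Missing variables
   simply drop out and the remaining weights renormalise; if nothing
   contributes the index is *undefined* and signalled as ``None``, never a
   silent number.

Numerical conventions (pinned by the oracle tests): fitness uses add-half
smoothing ``(FN + 0.5) / (FN + FP + 1)`` so perfectly separated regions do
not hit 0/0, and the bare error ratio is recovered as the training set
grows; queries outside the training range clamp to the end values; the
Youden search runs over midpoints of adjacent distinct pooled values plus a
sentinel beyond each extreme, with ties broken toward higher specificity and
then the lower cutoff. Variables whose abnormal direction is low (e.g. CSF
amyloid-beta 42, memory scores) are handled by sign-mirroring onto the
high-abnormal convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import (
    PatientRecord,
    TrainingReference,
    TreeConfig,
    TreeGroup,
    VariableSpec,
)

__all__ = [
    "FitnessCurve",
    "DsiNode",
    "DsiModel",
    "Fingerprint",
    "FingerprintNode",
    "ModelFormatError",
    "infer_direction",
    "fit_fitness",
    "compute_relevance",
    "train",
    "compute_dsi",
    "fingerprint",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "dsi-model"
MODEL_VERSION = 1

#: internal-node relevance policies (see ``train``)
NODE_RELEVANCE_POLICIES = ("composite_youden", "sum_children")


class ModelFormatError(ValueError):
    """Raised for unreadable, wrong-version or inconsistent model files."""


def _mirror_sign(direction: str) -> float:
    if direction == "higher_abnormal":
        return 1.0
    if direction == "lower_abnormal":
        return -1.0
    raise ValueError(f"unknown direction {direction!r}")


def infer_direction(
    control_values: Sequence[float],
    case_values: Sequence[float],
    declared: str | None = None,
) -> str:
    """Decide which end of a variable's scale is abnormal.

    A declared direction (anything but ``auto``) wins. Otherwise the case
    class's median above the control median means high values are abnormal;
    median ties fall back to means; a full tie defaults to higher_abnormal
    (such a variable earns relevance 0 downstream anyway).
    """
    if declared is not None and declared != "auto":
        return declared
    ctl = np.asarray(control_values, dtype=float)
    cas = np.asarray(case_values, dtype=float)
    if ctl.size == 0 or cas.size == 0:
        raise ValueError("both classes must be non-empty to infer a direction")
    d = float(np.median(cas) - np.median(ctl))
    if d == 0.0:
        d = float(np.mean(cas) - np.mean(ctl))
    return "lower_abnormal" if d < 0 else "higher_abnormal"


@dataclass
class FitnessCurve:
    """Piecewise-constant fitness of a single variable.

    Stored in the mirrored space ``z = x`` (high abnormal) or ``z = -x``
    (low abnormal): ``breakpoints`` are the sorted distinct training values
    and ``values[i]`` is the fitness on the interval
    ``(breakpoints[i-1], breakpoints[i]]`` (with the two outer intervals
    open-ended), so ``len(values) == len(breakpoints) + 1``.
    """

    variable: str
    direction: str
    breakpoints: np.ndarray
    values: np.ndarray
    n_controls: int
    n_cases: int

    def __call__(self, x):
        z = _mirror_sign(self.direction) * np.asarray(x, dtype=float)
        idx = np.searchsorted(self.breakpoints, z, side="left")
        out = self.values[idx]
        return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def fit_fitness(
    control_values: Sequence[float],
    case_values: Sequence[float],
    direction: str = "higher_abnormal",
    variable: str = "",
) -> FitnessCurve:
    """Estimate the empirical fitness curve of one variable.

    For any query ``x`` (after mirroring onto the high-abnormal convention)
    the returned curve evaluates to ``(FN(x)+0.5) / (FN(x)+FP(x)+1)`` with
    ``FN(x)`` = cases strictly below ``x`` and ``FP(x)`` = controls at or
    above ``x`` — exactly the counts a brute-force enumeration produces.
    """
    s = _mirror_sign(direction)
    ctl = np.sort(s * np.asarray(control_values, dtype=float))
    cas = np.sort(s * np.asarray(case_values, dtype=float))
    if ctl.size == 0 or cas.size == 0:
        raise ValueError(f"variable {variable!r}: a training class is empty")
    if not (np.all(np.isfinite(ctl)) and np.all(np.isfinite(cas))):
        raise ValueError(f"variable {variable!r}: non-finite training values")
    bps = np.unique(np.concatenate([ctl, cas]))
    # representative query for interval (bps[i-1], bps[i]] is bps[i] itself;
    # the last interval (bps[-1], inf) has FN = all cases, FP = 0
    probes = np.append(bps, bps[-1] + 1.0)
    fn = np.searchsorted(cas, probes, side="left").astype(float)
    fp = ctl.size - np.searchsorted(ctl, probes, side="left").astype(float)
    values = (fn + 0.5) / (fn + fp + 1.0)
    return FitnessCurve(
        variable=variable,
        direction=direction,
        breakpoints=bps,
        values=values,
        n_controls=int(ctl.size),
        n_cases=int(cas.size),
    )


def compute_relevance(
    control_values: Sequence[float],
    case_values: Sequence[float],
    direction: str = "higher_abnormal",
    return_cutoff: bool = False,
):
    """Youden index of one variable on the training data, clamped to [0, 1].

    Candidate cutoffs are the midpoints of adjacent distinct pooled values
    plus one sentinel beyond each extreme, classified as "case iff value >=
    cutoff" in the mirrored space. Ties in J prefer higher specificity, then
    the lower cutoff.
    """
    s = _mirror_sign(direction)
    ctl = np.sort(s * np.asarray(control_values, dtype=float))
    cas = np.sort(s * np.asarray(case_values, dtype=float))
    if ctl.size == 0 or cas.size == 0:
        raise ValueError("a training class is empty")
    pooled = np.unique(np.concatenate([ctl, cas]))
    cutoffs = np.concatenate(
        [[pooled[0] - 1.0], (pooled[:-1] + pooled[1:]) / 2.0, [pooled[-1] + 1.0]]
    )
    sn = 1.0 - np.searchsorted(cas, cutoffs, side="left") / cas.size
    sp = np.searchsorted(ctl, cutoffs, side="left") / ctl.size
    j = sn + sp - 1.0
    # lexicographic argmax: J, then SP, then lower cutoff (stable argmax
    # over ascending cutoffs handles the last key)
    order = np.lexsort((cutoffs, -sp, -j))
    best = order[0]
    relevance = float(min(1.0, max(0.0, j[best])))
    if return_cutoff:
        return relevance, float(s * cutoffs[best])
    return relevance


@dataclass
class DsiNode:
    """One node of the trained fingerprint tree."""

    name: str
    relevance: float
    children: list["DsiNode"] = field(default_factory=list)
    curve: FitnessCurve | None = None

    @property
    def is_leaf(self) -> bool:
        return self.curve is not None

    def value(self, values: Mapping[str, float | None]) -> float | None:
        """Fitness (leaf) or composite index (group) for one patient; None if undefined."""
        if self.is_leaf:
            x = values.get(self.curve.variable)
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return None
            return float(self.curve(x))
        contributions: list[tuple[float, float]] = []
        for child in self.children:
            if child.relevance <= 0.0:
                continue
            v = child.value(values)
            if v is not None:
                contributions.append((child.relevance, v))
        if not contributions:
            return None
        if len(contributions) == 1:  # exact: a lone contributor passes through
            return contributions[0][1]
        num = sum(r * v for r, v in contributions)
        den = sum(r for r, _ in contributions)
        return num / den


@dataclass
class DsiModel:
    """A trained Disease State Index model.

    ``training_summary`` records, per variable, the class sizes after
    missing-value removal plus the inferred direction and relevance.
    """

    root: DsiNode
    training_summary: dict = field(default_factory=dict)
    node_relevance_policy: str = "composite_youden"

    def leaf_variables(self) -> list[str]:
        out: list[str] = []

        def walk(node: DsiNode) -> None:
            if node.is_leaf:
                out.append(node.curve.variable)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out


def _patient_values(patient) -> Mapping[str, float | None]:
    if isinstance(patient, PatientRecord):
        return patient.values
    return patient


def compute_dsi(patient, model: DsiModel) -> float | None:
    """Composite index for one patient, or ``None`` when no variable contributes.

    ``patient`` is a :class:`~dsindex.cohort.PatientRecord` or a plain
    mapping of variable name to value (``None``/NaN = missing).
    """
    return model.root.value(_patient_values(patient))


def train(
    training: TrainingReference,
    tree: TreeConfig,
    specs: Sequence[VariableSpec] | None = None,
    node_relevance_policy: str = "composite_youden",
) -> DsiModel:
    """Fit fitness curves and relevances over the fingerprint tree.

    Leaves get their curve and Youden relevance from the per-variable
    training samples. A group node's relevance is, under the default
    ``composite_youden`` policy, the Youden index of the group's own
    composite score evaluated on every training subject (undefined
    composites dropped) — so a group of individually weak but jointly
    informative tests can still carry weight; the ``sum_children`` policy
    instead uses the capped sum of child relevances.

    A variable with identical constant samples in both classes is retained
    with relevance 0 (it never influences a score).
    """
    if node_relevance_policy not in NODE_RELEVANCE_POLICIES:
        raise ValueError(f"unknown node relevance policy {node_relevance_policy!r}")
    declared = {s.name: s.declared_direction for s in specs} if specs else {}
    missing = [v for v in tree.leaf_names() if v not in training.variables]
    if missing:
        raise ValueError(f"training reference lacks tree variables: {missing}")

    summary: dict[str, dict] = {}

    def build(node: TreeGroup | str) -> DsiNode:
        if isinstance(node, str):
            ctl, cas = training.variable_samples(node)
            if ctl.size == 0 or cas.size == 0:
                raise ValueError(f"variable {node!r}: empty class after missing-value removal")
            direction = infer_direction(ctl, cas, declared.get(node))
            curve = fit_fitness(ctl, cas, direction, variable=node)
            relevance = compute_relevance(ctl, cas, direction)
            summary[node] = {
                "n_controls": int(ctl.size),
                "n_cases": int(cas.size),
                "direction": direction,
                "relevance": relevance,
            }
            return DsiNode(name=node, relevance=relevance, curve=curve)
        dsi_node = DsiNode(name=node.name, relevance=0.0, children=[build(c) for c in node.children])
        if node_relevance_policy == "sum_children":
            dsi_node.relevance = min(1.0, sum(c.relevance for c in dsi_node.children))
        else:
            ctl_scores = [
                v
                for row in training.controls.to_dict(orient="records")
                if (v := dsi_node.value(_nan_to_none(row))) is not None
            ]
            cas_scores = [
                v
                for row in training.cases.to_dict(orient="records")
                if (v := dsi_node.value(_nan_to_none(row))) is not None
            ]
            if ctl_scores and cas_scores:
                dsi_node.relevance = compute_relevance(ctl_scores, cas_scores, "higher_abnormal")
        return dsi_node

    root = build(tree.root)
    return DsiModel(root=root, training_summary=summary, node_relevance_policy=node_relevance_policy)


def _nan_to_none(row: Mapping[str, float]) -> dict[str, float | None]:
    return {k: (None if (isinstance(v, float) and math.isnan(v)) else v) for k, v in row.items()}


# ---------------------------------------------------------------------------
# fingerprints


@dataclass
class FingerprintNode:
    """Per-node entry of a patient's fingerprint.

    ``value`` is the leaf fitness or group composite (None when every
    descendant is missing); ``weight`` is the node's share of its parent's
    weighted sum (contributing siblings sum to 1; None for non-contributing
    nodes); ``missing`` flags nodes with no contributing descendant.
    """

    name: str
    kind: str  # "leaf" | "group"
    relevance: float
    value: float | None
    weight: float | None
    missing: bool
    children: list["FingerprintNode"] = field(default_factory=list)


@dataclass
class Fingerprint:
    """The disease-state fingerprint of one patient under one model.

    The tree view of how each test and biomarker contributes to the
    composite index: per node a fitness value in [0, 1] (rendered on a
    two-pole colour scale, pole 0 control-like/blue, pole 1 case-like/red)
    and the normalised weight of its contribution (rendered as box size).
    """

    patient_id: str
    dsi: float | None
    root: FingerprintNode

    def to_dict(self) -> dict:
        def conv(n: FingerprintNode) -> dict:
            return {
                "name": n.name,
                "kind": n.kind,
                "relevance": n.relevance,
                "value": n.value,
                "weight": n.weight,
                "missing": n.missing,
                "children": [conv(c) for c in n.children],
            }

        return {"patient_id": self.patient_id, "dsi": self.dsi, "root": conv(self.root)}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(n: FingerprintNode, depth: int) -> None:
            pad = "  " * depth
            if n.missing:
                body = "missing"
            else:
                body = f"value={n.value:.3f} weight={n.weight:.3f}"
            lines.append(f"{pad}{n.name} [{n.kind}] relevance={n.relevance:.3f} {body}")
            for c in n.children:
                walk(c, depth + 1)

        head = "undefined" if self.dsi is None else f"{self.dsi:.3f}"
        lines.append(f"patient {self.patient_id}: DSI = {head}")
        walk(self.root, 1)
        return "\n".join(lines)

    def to_svg(self, width: float = 640.0, row_height: float = 26.0) -> str:
        """Render the fingerprint as a standalone SVG document.

        One row per tree level; box widths are proportional to the product
        of normalised weights down the path (a node's absolute share of the
        composite), colours run blue (control-like, 0) through white to red
        (case-like, 1), grey for missing.
        """

        def color(v: float | None) -> str:
            if v is None:
                return "#c8c8c8"
            lo, hi = (59, 76, 192), (180, 4, 38)
            if v < 0.5:
                t = v / 0.5
                rgb = tuple(round(a + t * (255 - a)) for a in lo)
            else:
                t = (v - 0.5) / 0.5
                rgb = tuple(round(255 + t * (a - 255)) for a in hi)
            return "#%02x%02x%02x" % rgb

        boxes: list[tuple[int, float, float, FingerprintNode]] = []

        def walk(n: FingerprintNode, depth: int, x0: float, w: float) -> int:
            boxes.append((depth, x0, w, n))
            deepest = depth
            x = x0
            total = sum(c.weight for c in n.children if c.weight) or 1.0
            for c in n.children:
                cw = w * ((c.weight or 0.0) / total) if n.children else 0.0
                if c.weight is None:  # non-contributing: thin fixed-share slot
                    cw = 0.0
                deepest = max(deepest, walk(c, depth + 1, x, cw if cw > 0 else w * 0.02))
                x += cw if cw > 0 else w * 0.02
            return deepest

        depth = walk(self.root, 0, 0.0, width)
        height = (depth + 1) * row_height + 24
        head = "undefined" if self.dsi is None else f"{self.dsi:.3f}"
        parts = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" height="{height:.0f}">',
            f'<text x="4" y="14" font-family="sans-serif" font-size="12">'
            f"patient {self.patient_id} &#8212; DSI {head}</text>",
        ]
        for d, x0, w, n in boxes:
            y = 20 + d * row_height
            label = n.name if n.missing or n.value is None else f"{n.name} {n.value:.2f}"
            parts.append(
                f'<rect x="{x0:.1f}" y="{y:.1f}" width="{max(w, 1.0):.1f}" '
                f'height="{row_height - 3:.1f}" fill="{color(None if n.missing else n.value)}" '
                f'stroke="#333" stroke-width="0.8"/>'
            )
            if w > 40:
                parts.append(
                    f'<text x="{x0 + 3:.1f}" y="{y + row_height - 10:.1f}" '
                    f'font-family="sans-serif" font-size="10">{label}</text>'
                )
        parts.append("</svg>")
        return "\n".join(parts)


def fingerprint(patient, model: DsiModel) -> Fingerprint:
    """Build the fingerprint of one patient: per-node value, relevance, weight."""
    values = _patient_values(patient)
    pid = patient.patient_id if isinstance(patient, PatientRecord) else ""

    def build(node: DsiNode, weight: float | None) -> FingerprintNode:
        v = node.value(values)
        fp = FingerprintNode(
            name=node.name,
            kind="leaf" if node.is_leaf else "group",
            relevance=node.relevance,
            value=v,
            weight=weight,
            missing=v is None,
        )
        if not node.is_leaf:
            contributing = [
                (c, c.value(values)) for c in node.children if c.relevance > 0.0
            ]
            den = sum(c.relevance for c, cv in contributing if cv is not None)
            for child in node.children:
                cv = child.value(values)
                w = (
                    child.relevance / den
                    if (cv is not None and child.relevance > 0.0 and den > 0.0)
                    else None
                )
                fp.children.append(build(child, w))
        return fp

    root_value = model.root.value(values)
    root = build(model.root, 1.0 if root_value is not None else None)
    return Fingerprint(patient_id=pid, dsi=root_value, root=root)


# ---------------------------------------------------------------------------
# model serialization (structured text, versioned)


def _curve_to_dict(curve: FitnessCurve) -> dict:
    return {
        "variable": curve.variable,
        "direction": curve.direction,
        "breakpoints": [float(b) for b in curve.breakpoints],
        "values": [float(v) for v in curve.values],
        "n_controls": curve.n_controls,
        "n_cases": curve.n_cases,
    }


def _curve_from_dict(d: dict) -> FitnessCurve:
    return FitnessCurve(
        variable=d["variable"],
        direction=d["direction"],
        breakpoints=np.asarray(d["breakpoints"], dtype=float),
        values=np.asarray(d["values"], dtype=float),
        n_controls=int(d["n_controls"]),
        n_cases=int(d["n_cases"]),
    )


def _node_to_dict(node: DsiNode) -> dict:
    d: dict = {"name": node.name, "relevance": float(node.relevance)}
    if node.is_leaf:
        d["curve"] = _curve_to_dict(node.curve)
    else:
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> DsiNode:
    if "curve" in d:
        return DsiNode(name=d["name"], relevance=float(d["relevance"]), curve=_curve_from_dict(d["curve"]))
    return DsiNode(
        name=d["name"],
        relevance=float(d["relevance"]),
        children=[_node_from_dict(c) for c in d.get("children", [])],
    )


def save_model(model: DsiModel, path) -> None:
    """Serialize a trained model as versioned JSON; floats round-trip exactly."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "node_relevance_policy": model.node_relevance_policy,
        "training_summary": model.training_summary,
        "root": _node_to_dict(model.root),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path, known_variables: Sequence[str] | None = None) -> DsiModel:
    """Load a model file, checking format, version and leaf references."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"not a valid model document: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError("missing or wrong format tag")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"unsupported model version {doc.get('version')!r} (expected {MODEL_VERSION})"
        )
    model = DsiModel(
        root=_node_from_dict(doc["root"]),
        training_summary=doc.get("training_summary", {}),
        node_relevance_policy=doc.get("node_relevance_policy", "composite_youden"),
    )
    if known_variables is not None:
        unknown = sorted(set(model.leaf_variables()) - set(known_variables))
        if unknown:
            raise ModelFormatError(f"model references unknown variables: {unknown}")
    return model
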