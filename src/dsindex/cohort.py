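"""Domain types and file I/O for memory-clinic cohorts.

A cohort is one row per patient: a baseline working diagnosis (SCD or MCI),
per-variable measurements with missingness, the clinician's paired
predictions of the follow-up diagnosis made without and then with decision
support, the clinician's confidence in each prediction (visual analogue
scale 0-100% plus a low/moderate/high category), and the reference diagnosis
actually made at follow-up.

File dialect: comma-separated UTF-8, "." decimal separator, an empty cell or
the token ``NA`` means missing. Diagnoses are fixed uppercase tokens
(``SCD``, ``MCI``, ``AD``, ``NONAD``; predictions may also use ``DEM`` for
"dementia, type unspecified").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "TreeGroup",
    "TreeConfig",
    "TrainingReference",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "ConfigError",
    "read_cohort",
    "write_cohort",
    "read_training",
    "write_training",
    "load_config",
    "save_config",
]

MISSING_TOKENS = frozenset({"", "NA"})
BASELINE_DIAGNOSES = ("SCD", "MCI")
FOLLOWUP_DIAGNOSES = ("SCD", "MCI", "AD", "NONAD")
#: tokens accepted for a *predicted* follow-up diagnosis; AD/NONAD/DEM all
#: denote a prediction of dementia.
PREDICTED_DIAGNOSES = ("SCD", "MCI", "DEM", "AD", "NONAD")
CONFIDENCE_CATEGORIES = ("low", "moderate", "high")
MODALITIES = ("demographic", "cognitive", "csf", "mri_visual", "mri_computed")
SCALES = ("continuous", "ordinal")
DIRECTIONS = ("higher_abnormal", "lower_abnormal", "auto")

#: fixed clinical columns, in file order, preceding the variable columns
CLINICAL_COLUMNS = (
    "patient_id",
    "baseline_dx",
    "pred_without_tool",
    "pred_with_tool",
    "vas_without_tool",
    "vas_with_tool",
    "conf_without_tool",
    "conf_with_tool",
    "followup_dx",
    "followup_years",
)
#: reserved optional column carrying a previously computed index score
DSI_COLUMN = "dsi"


class CohortValidationError(ValueError):
    """Raised when a cohort file or object violates the schema.

    ``errors`` holds one human-readable message per violation, each naming
    the offending row (file line number) and field.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class ConfigError(ValueError):
    """Raised for malformed variable/tree configuration documents."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one input variable.

    ``declared_direction`` pins which end of the scale is abnormal
    (e.g. CSF amyloid-beta 42 is *lower* in Alzheimer's disease); ``auto``
    (or None) lets training infer it from the class medians.
    """

    name: str
    modality: str = "cognitive"
    scale: str = "continuous"
    declared_direction: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ConfigError(f"variable {self.name!r}: unknown modality {self.modality!r}")
        if self.scale not in SCALES:
            raise ConfigError(f"variable {self.name!r}: unknown scale {self.scale!r}")
        if self.declared_direction is not None and self.declared_direction not in DIRECTIONS:
            raise ConfigError(
                f"variable {self.name!r}: unknown direction {self.declared_direction!r}"
            )


@dataclass
class TreeGroup:
    """Internal node of the fingerprint tree; children are groups or leaf variable names."""

    name: str
    children: list["TreeGroup | str"] = field(default_factory=list)


@dataclass
class TreeConfig:
    """Rooted tree whose leaves name variables and whose internal nodes are groups."""

    root: TreeGroup

    def leaf_names(self) -> list[str]:
        leaves: list[str] = []

        def walk(node: TreeGroup | str) -> None:
            if isinstance(node, str):
                leaves.append(node)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return leaves

    def validate(self, specs: Sequence[VariableSpec]) -> None:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"tree references variables more than once: {dupes}")
        known = {s.name for s in specs}
        unknown = sorted(set(names) - known)
        if unknown:
            raise ConfigError(f"tree references unknown variables: {unknown}")

        group_names: list[str] = []

        def walk(node: TreeGroup) -> None:
            group_names.append(node.name)
            if not node.children:
                raise ConfigError(f"group {node.name!r} has no children")
            for child in node.children:
                if isinstance(child, TreeGroup):
                    walk(child)

        walk(self.root)
        if len(group_names) != len(set(group_names)):
            raise ConfigError("group names are not unique")


@dataclass
class TrainingReference:
    """Per-variable reference samples for the two training classes.

    ``controls`` and ``cases`` are DataFrames with one row per training
    subject and one column per variable; NaN marks a missing measurement.
    The control class stands for cognitively healthy reference subjects and
    the case class for patients with established Alzheimer's disease.
    """

    controls: pd.DataFrame
    cases: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.controls.columns) != list(self.cases.columns):
            raise CohortValidationError(
                ["training reference: control and case tables have different columns"]
            )

    @property
    def variables(self) -> list[str]:
        return list(self.controls.columns)

    def variable_samples(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (control_values, case_values) for one variable, missing removed."""
        if name not in self.controls.columns:
            raise KeyError(f"training reference has no variable {name!r}")
        ctl = self.controls[name].to_numpy(dtype=float)
        cas = self.cases[name].to_numpy(dtype=float)
        return ctl[~np.isnan(ctl)], cas[~np.isnan(cas)]


@dataclass
class PatientRecord:
    """One patient: measurements, paired predictions, confidence, outcome.

    ``values`` maps variable name to a float, with ``None`` for missing.
    Prediction/confidence/follow-up fields are ``None`` until the
    corresponding study stage has happened (a freshly simulated cohort has
    no clinician fields yet).
    """

    patient_id: str
    baseline_dx: str
    values: dict[str, float | None] = field(default_factory=dict)
    pred_without_tool: str | None = None
    pred_with_tool: str | None = None
    vas_without_tool: float | None = None
    vas_with_tool: float | None = None
    conf_without_tool: str | None = None
    conf_with_tool: str | None = None
    followup_dx: str | None = None
    followup_years: float | None = None
    dsi: float | None = None

    def validation_errors(self, context: str = "") -> list[str]:
        where = f"{context}: " if context else ""
        errs: list[str] = []
        if self.baseline_dx not in BASELINE_DIAGNOSES:
            errs.append(f"{where}baseline_dx {self.baseline_dx!r} not in {BASELINE_DIAGNOSES}")
        for fld in ("pred_without_tool", "pred_with_tool"):
            v = getattr(self, fld)
            if v is not None and v not in PREDICTED_DIAGNOSES:
                errs.append(f"{where}{fld} {v!r} not in {PREDICTED_DIAGNOSES}")
        for fld in ("vas_without_tool", "vas_with_tool"):
            v = getattr(self, fld)
            if v is not None and not (0.0 <= v <= 100.0):
                errs.append(f"{where}{fld} = {v} outside [0, 100]")
        for fld in ("conf_without_tool", "conf_with_tool"):
            v = getattr(self, fld)
            if v is not None and v not in CONFIDENCE_CATEGORIES:
                errs.append(f"{where}{fld} {v!r} not in {CONFIDENCE_CATEGORIES}")
        if self.followup_dx is not None and self.followup_dx not in FOLLOWUP_DIAGNOSES:
            errs.append(f"{where}followup_dx {self.followup_dx!r} not in {FOLLOWUP_DIAGNOSES}")
        if self.followup_years is not None and not self.followup_years > 0:
            errs.append(f"{where}followup_years = {self.followup_years} not positive")
        for name, v in self.values.items():
            if v is not None and not math.isfinite(v):
                errs.append(f"{where}variable {name!r} non-finite value {v}")
        return errs


@dataclass
class Cohort:
    """A list of patients plus free-form provenance metadata."""

    patients: list[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def validate(self) -> None:
        errs: list[str] = []
        seen: set[str] = set()
        for i, p in enumerate(self.patients):
            if p.patient_id in seen:
                errs.append(f"patient {i}: duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)
            errs.extend(p.validation_errors(context=f"patient {p.patient_id}"))
        if errs:
            raise CohortValidationError(errs)

    def variable_names(self) -> list[str]:
        names: list[str] = []
        for p in self.patients:
            for k in p.values:
                if k not in names:
                    names.append(k)
        return names


# ---------------------------------------------------------------------------
# number formatting / parsing — lossless float round-trip


def _format_number(x: float | None) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and math.isnan(x):
        return ""
    f = float(x)
    if f.is_integer() and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def _parse_number(token: str, *, row: int, column: str, errors: list[str]) -> float | None:
    tok = token.strip()
    if tok in MISSING_TOKENS:
        return None
    try:
        return float(tok)
    except ValueError:
        errors.append(f"row {row}: non-numeric value {token!r} in column {column!r}")
        return None


def _parse_category(
    token: str, allowed: Iterable[str], *, row: int, column: str, errors: list[str]
) -> str | None:
    tok = token.strip()
    if tok in MISSING_TOKENS:
        return None
    if tok not in tuple(allowed):
        errors.append(f"row {row}: value {token!r} in column {column!r} not in {tuple(allowed)}")
        return None
    return tok


# ---------------------------------------------------------------------------
# cohort CSV


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV; repeated writes of the same cohort are byte-identical.

    Missing values are empty cells. A ``dsi`` column is emitted only when at
    least one patient carries a score.
    """
    cohort.validate()
    var_names = cohort.variable_names()
    with_dsi = any(p.dsi is not None for p in cohort.patients)
    header = list(CLINICAL_COLUMNS) + ([DSI_COLUMN] if with_dsi else []) + var_names
    lines = [",".join(header)]
    for p in cohort.patients:
        row = [
            p.patient_id,
            p.baseline_dx,
            p.pred_without_tool or "",
            p.pred_with_tool or "",
            _format_number(p.vas_without_tool),
            _format_number(p.vas_with_tool),
            p.conf_without_tool or "",
            p.conf_with_tool or "",
            p.followup_dx or "",
            _format_number(p.followup_years),
        ]
        if with_dsi:
            row.append(_format_number(p.dsi))
        row.extend(_format_number(p.values.get(name)) for name in var_names)
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cohort(path, spec: Sequence[VariableSpec] | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    With ``spec`` given, every non-clinical column must match a declared
    variable (unknown columns are an error) and ordinal variables must hold
    integer values. With ``spec=None`` all non-clinical columns are accepted
    as continuous variables. Empty cells and ``NA`` parse as missing, never
    as zero. All violations are collected and raised together, each naming
    its file row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    errors: list[str] = []
    columns = list(df.columns)
    missing_clinical = [c for c in CLINICAL_COLUMNS if c not in columns]
    if missing_clinical:
        raise CohortValidationError([f"missing clinical columns: {missing_clinical}"])
    var_columns = [c for c in columns if c not in CLINICAL_COLUMNS and c != DSI_COLUMN]
    ordinal: set[str] = set()
    if spec is not None:
        known = {s.name: s for s in spec}
        unknown = [c for c in var_columns if c not in known]
        if unknown:
            raise CohortValidationError([f"unknown columns: {unknown}"])
        ordinal = {s.name for s in spec if s.scale == "ordinal"}

    patients: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for i, rec in enumerate(df.to_dict(orient="records")):
        row = i + 2  # header is file line 1
        pid = str(rec["patient_id"]).strip()
        if not pid:
            errors.append(f"row {row}: empty patient_id")
        if pid in seen_ids:
            errors.append(f"row {row}: duplicate patient_id {pid!r}")
        seen_ids.add(pid)
        baseline = _parse_category(
            rec["baseline_dx"], BASELINE_DIAGNOSES, row=row, column="baseline_dx", errors=errors
        )
        p = PatientRecord(patient_id=pid, baseline_dx=baseline or "SCD")
        p.pred_without_tool = _parse_category(
            rec["pred_without_tool"], PREDICTED_DIAGNOSES,
            row=row, column="pred_without_tool", errors=errors,
        )
        p.pred_with_tool = _parse_category(
            rec["pred_with_tool"], PREDICTED_DIAGNOSES,
            row=row, column="pred_with_tool", errors=errors,
        )
        for fld in ("vas_without_tool", "vas_with_tool"):
            v = _parse_number(rec[fld], row=row, column=fld, errors=errors)
            if v is not None and not (0.0 <= v <= 100.0):
                errors.append(f"row {row}: {fld} = {_format_number(v)} outside [0, 100]")
            setattr(p, fld, v)
        p.conf_without_tool = _parse_category(
            rec["conf_without_tool"], CONFIDENCE_CATEGORIES,
            row=row, column="conf_without_tool", errors=errors,
        )
        p.conf_with_tool = _parse_category(
            rec["conf_with_tool"], CONFIDENCE_CATEGORIES,
            row=row, column="conf_with_tool", errors=errors,
        )
        p.followup_dx = _parse_category(
            rec["followup_dx"], FOLLOWUP_DIAGNOSES, row=row, column="followup_dx", errors=errors
        )
        fy = _parse_number(rec["followup_years"], row=row, column="followup_years", errors=errors)
        if fy is not None and not fy > 0:
            errors.append(f"row {row}: followup_years = {_format_number(fy)} not positive")
        p.followup_years = fy
        if DSI_COLUMN in columns:
            p.dsi = _parse_number(rec[DSI_COLUMN], row=row, column=DSI_COLUMN, errors=errors)
        for name in var_columns:
            v = _parse_number(rec[name], row=row, column=name, errors=errors)
            if v is not None and name in ordinal and not float(v).is_integer():
                errors.append(f"row {row}: ordinal variable {name!r} has non-integer value {v}")
            p.values[name] = v
        patients.append(p)
    if errors:
        raise CohortValidationError(errors)
    return Cohort(patients=patients, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# training reference CSV

TRAINING_GROUP_COLUMN = "group"
TRAINING_GROUPS = ("CONTROL", "CASE")


def write_training(training: TrainingReference, path) -> None:
    """Write a training reference as CSV with a leading CONTROL/CASE group column."""
    var_names = training.variables
    lines = [",".join([TRAINING_GROUP_COLUMN] + var_names)]
    for group, table in ((TRAINING_GROUPS[0], training.controls), (TRAINING_GROUPS[1], training.cases)):
        for rec in table.itertuples(index=False):
            cells = [group] + [
                _format_number(None if (isinstance(v, float) and math.isnan(v)) else float(v))
                for v in rec
            ]
            lines.append(",".join(cells))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_training(path) -> TrainingReference:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if TRAINING_GROUP_COLUMN not in df.columns:
        raise CohortValidationError([f"training file lacks a {TRAINING_GROUP_COLUMN!r} column"])
    errors: list[str] = []
    var_names = [c for c in df.columns if c != TRAINING_GROUP_COLUMN]
    rows = {g: [] for g in TRAINING_GROUPS}
    for i, rec in enumerate(df.to_dict(orient="records")):
        row = i + 2
        group = rec[TRAINING_GROUP_COLUMN].strip()
        if group not in TRAINING_GROUPS:
            errors.append(f"row {row}: group {group!r} not in {TRAINING_GROUPS}")
            continue
        parsed = {
            name: _parse_number(rec[name], row=row, column=name, errors=errors)
            for name in var_names
        }
        rows[group].append({k: (math.nan if v is None else v) for k, v in parsed.items()})
    if errors:
        raise CohortValidationError(errors)
    controls = pd.DataFrame(rows["CONTROL"], columns=var_names, dtype=float)
    cases = pd.DataFrame(rows["CASE"], columns=var_names, dtype=float)
    return TrainingReference(controls=controls, cases=cases)


# ---------------------------------------------------------------------------
# variable / tree configuration (YAML)


def _tree_from_obj(obj, default_name: str = "root") -> TreeGroup:
    if isinstance(obj, dict):
        if "name" in obj:
            name = obj["name"]
            raw_children = obj.get("children", [])
        elif len(obj) == 1:
            name, raw_children = next(iter(obj.items()))
        else:
            raise ConfigError(f"ambiguous tree node: {obj!r}")
    elif isinstance(obj, list):
        name, raw_children = default_name, obj
    else:
        raise ConfigError(f"tree node must be mapping or list, got {type(obj).__name__}")
    if isinstance(raw_children, dict):
        raw_children = [{k: v} for k, v in raw_children.items()]
    children: list[TreeGroup | str] = []
    for child in raw_children:
        if isinstance(child, str):
            children.append(child)
        else:
            children.append(_tree_from_obj(child))
    return TreeGroup(name=str(name), children=children)


def _tree_to_obj(node: TreeGroup | str):
    if isinstance(node, str):
        return node
    return {"name": node.name, "children": [_tree_to_obj(c) for c in node.children]}


def load_config(path) -> tuple[list[VariableSpec], TreeConfig]:
    """Load the variable declarations and fingerprint tree from one YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variables" not in doc or "tree" not in doc:
        raise ConfigError("configuration must contain 'variables' and 'tree' sections")
    specs = []
    for entry in doc["variables"]:
        if isinstance(entry, str):
            entry = {"name": entry}
        specs.append(
            VariableSpec(
                name=str(entry["name"]),
                modality=entry.get("modality", "cognitive"),
                scale=entry.get("scale", "continuous"),
                declared_direction=entry.get("direction"),
            )
        )
    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        raise ConfigError("variable names are not unique")
    tree = TreeConfig(root=_tree_from_obj(doc["tree"]))
    tree.validate(specs)
    return specs, tree


def save_config(specs: Sequence[VariableSpec], tree: TreeConfig, path) -> None:
    doc = {
        "variables": [
            {
                "name": s.name,
                "modality": s.modality,
                "scale": s.scale,
                **({"direction": s.declared_direction} if s.declared_direction else {}),
            }
            for s in specs
        ],
        "tree": _tree_to_obj(tree.root),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
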