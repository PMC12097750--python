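"""Variable schema for the screening-consequences survey.

A schema is a list of :class:`VariableSpec` describing every column the
analysis may touch: the four PCQ outcome scales (total plus emotional,
physical and social dysfunction subscales) and the candidate predictors
(health literacy, communication competence, comorbidity burden, treatment
evaluation, social support and sociodemographics). The default schema
bundled with the package has 4 outcomes and 24 predictors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "SchemaError",
    "load_schema",
    "default_schema",
    "outcome_names",
    "predictor_names",
    "validate_dataset",
    "ValidationReport",
]

_VTYPES = ("continuous", "ordinal", "binary")
_ROLES = ("outcome", "predictor")


class SchemaError(ValueError):
    """Raised when a schema definition is internally inconsistent."""


@dataclass(frozen=True)
class VariableSpec:
    """One survey variable: its type, admissible range and analysis role."""

    name: str
    vtype: str
    lo: float
    hi: float
    role: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.vtype not in _VTYPES:
            raise SchemaError(
                f"variable {self.name!r}: unknown vtype {self.vtype!r} "
                f"(expected one of {_VTYPES})"
            )
        if self.role not in _ROLES:
            raise SchemaError(
                f"variable {self.name!r}: unknown role {self.role!r} "
                f"(expected one of {_ROLES})"
            )
        if not self.lo < self.hi:
            raise SchemaError(
                f"variable {self.name!r}: lower bound {self.lo} must be "
                f"strictly below upper bound {self.hi}"
            )
        if self.vtype == "binary" and (self.lo, self.hi) != (0, 1):
            raise SchemaError(
                f"variable {self.name!r}: binary variables must have range "
                f"[0, 1], got [{self.lo}, {self.hi}]"
            )


def _specs_from_mapping(doc: Mapping) -> list[VariableSpec]:
    try:
        rows = doc["variables"]
    except (KeyError, TypeError):
        raise SchemaError("schema config must contain a 'variables' list")
    specs: list[VariableSpec] = []
    seen: set[str] = set()
    for row in rows:
        try:
            spec = VariableSpec(
                name=str(row["name"]),
                vtype=str(row["vtype"]),
                lo=float(row["lo"]),
                hi=float(row["hi"]),
                role=str(row["role"]),
                source=str(row.get("source", "")),
            )
        except KeyError as exc:
            raise SchemaError(f"schema row {row!r}: missing field {exc}")
        if spec.name in seen:
            raise SchemaError(f"duplicate variable name {spec.name!r}")
        seen.add(spec.name)
        specs.append(spec)
    return specs


def load_schema(source: str | Path | Mapping) -> list[VariableSpec]:
    """Load and validate a variable schema.

    Parameters
    ----------
    source
        A mapping with a ``variables`` list, a YAML string, or a path to a
        YAML file. Each variable block needs ``name``, ``vtype``
        (continuous/ordinal/binary), ``lo``, ``hi`` and ``role``
        (outcome/predictor); ``source`` is an optional instrument label.
    """
    if isinstance(source, Mapping):
        return _specs_from_mapping(source)
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml"))
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    return _specs_from_mapping(yaml.safe_load(text))


def default_schema() -> list[VariableSpec]:
    """The bundled default schema: 4 PCQ outcomes + 24 candidate predictors."""
    ref = importlib.resources.files("screenlasso") / "data" / "default_schema.yaml"
    return _specs_from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


def outcome_names(schema: Iterable[VariableSpec]) -> list[str]:
    return [s.name for s in schema if s.role == "outcome"]


def predictor_names(schema: Iterable[VariableSpec]) -> list[str]:
    return [s.name for s in schema if s.role == "predictor"]


@dataclass
class ValidationReport:
    """Per-variable data-quality counts for a dataset against a schema."""

    n_rows: int
    out_of_range: dict[str, int]
    missing: dict[str, int]
    non_integer: dict[str, int]
    zero_variance: list[str]

    @property
    def n_violations(self) -> int:
        return sum(self.out_of_range.values()) + sum(self.non_integer.values())

    @property
    def ok(self) -> bool:
        return self.n_violations == 0 and not self.zero_variance

    def to_frame(self) -> pd.DataFrame:
        names = sorted(set(self.out_of_range) | set(self.missing))
        return pd.DataFrame(
            {
                "variable": names,
                "out_of_range": [self.out_of_range.get(n, 0) for n in names],
                "missing": [self.missing.get(n, 0) for n in names],
                "non_integer": [self.non_integer.get(n, 0) for n in names],
                "zero_variance": [n in self.zero_variance for n in names],
            }
        )


def validate_dataset(
    data: pd.DataFrame, schema: Iterable[VariableSpec]
) -> ValidationReport:
    """Check a survey table against a schema.

    Counts, per schema variable present in ``data``, values outside the
    admissible range, missing cells and (for ordinal/binary variables)
    non-integer entries, and flags constant columns — a zero-variance
    predictor carries no information and cannot be selected.

    Raises
    ------
    SchemaError
        If an outcome column declared by the schema is absent.
    """
    schema = list(schema)
    missing_outcomes = [
        s.name for s in schema if s.role == "outcome" and s.name not in data.columns
    ]
    if missing_outcomes:
        raise SchemaError(f"required outcome column(s) missing: {missing_outcomes}")

    out_of_range: dict[str, int] = {}
    missing: dict[str, int] = {}
    non_integer: dict[str, int] = {}
    zero_variance: list[str] = []
    for spec in schema:
        if spec.name not in data.columns:
            continue
        col = pd.to_numeric(data[spec.name], errors="coerce")
        isna = col.isna()
        missing[spec.name] = int(isna.sum())
        vals = col[~isna]
        out_of_range[spec.name] = int(((vals < spec.lo) | (vals > spec.hi)).sum())
        if spec.vtype in ("ordinal", "binary"):
            non_integer[spec.name] = int((vals != np.round(vals)).sum())
        else:
            non_integer[spec.name] = 0
        if len(vals) > 0 and float(vals.max() - vals.min()) == 0.0:
            zero_variance.append(spec.name)
    return ValidationReport(
        n_rows=len(data),
        out_of_range=out_of_range,
        missing=missing,
        non_integer=non_integer,
        zero_variance=zero_variance,
    )
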