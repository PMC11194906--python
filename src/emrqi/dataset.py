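"""In-memory containers for EMR-style tabular data and its declared standard.

An :class:`EMRDataset` holds one wide table of admission records (one row per
patient/admission, columns = data elements, plus bookkeeping columns for
admission/discharge anchors, record-creation timestamp and record state) and
an optional long table of repeated measurements (vitals, labs) carrying
per-value timestamps, units and measurement-method tags.

A :class:`ReferenceSchema` is the data dictionary every quality indicator is
measured against: required elements with synonyms, declared types, formats,
plausibility ranges, units and conversions, terminology bindings, derived
value definitions, required recording intervals and the timeliness window.

A :class:`ModelingPlan` states what a particular ML risk-prediction task
needs from the data: predictor and outcome elements, the minimum sample
size, and required measurement methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ElementSpec",
    "DerivedDefinition",
    "ReferenceSchema",
    "ModelingPlan",
    "EMRDataset",
    "missing_mask",
    "parse_timestamps",
]

DEFAULT_MISSING_CODES = ("", "-1", "9999", "NA", "N/A")

#: Long-measurements table column names.
MEAS_COLS = ("admission_id", "element", "value", "measured_at", "recorded_at",
             "unit", "method")


@dataclass
class ElementSpec:
    """Declared requirements for one data element."""

    name: str
    synonyms: list[str] = field(default_factory=list)
    dtype: str = "float"  # float | int | str | category | datetime
    unit: str | None = None
    format_pattern: str | None = None  # full-match regex on the string form
    decimals: int | None = None  # minimum decimal places required
    plausible_range: tuple[float, float] | None = None
    code_set: list[str] | None = None
    required_method: str | None = None
    required_interval_hours: float | None = None

    def all_names(self) -> list[str]:
        return [self.name, *self.synonyms]


@dataclass
class DerivedDefinition:
    """A stored element that must equal a formula of other elements."""

    target: str
    components: list[str]
    expr: str  # pandas.DataFrame.eval expression over component columns
    tolerance: float = 1e-6


@dataclass
class ReferenceSchema:
    elements: dict[str, ElementSpec]
    key_fields: list[str] = field(default_factory=lambda: ["patient_id", "admission_id"])
    unit_conversions: dict[str, dict[str, float]] = field(default_factory=dict)
    derived: list[DerivedDefinition] = field(default_factory=list)
    timeliness_window_hours: float = 24.0
    timestamp_format: str | None = None  # None => ISO 8601
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES

    def __post_init__(self):
        declared = set(self.elements)
        for d in self.derived:
            unknown = [c for c in [d.target, *d.components] if c not in declared]
            if unknown:
                raise ValueError(
                    f"derived definition {d.target!r} references undeclared "
                    f"elements {unknown}"
                )

    # resolution of dataset column names to canonical elements ---------

    def resolve(self, column: str) -> list[str]:
        """Canonical element names a dataset column name could refer to."""
        low = column.strip().lower()
        return [
            name for name, spec in self.elements.items()
            if low in {s.strip().lower() for s in spec.all_names()}
        ]

    def unit_convertible(self, element: str, observed_unit: str) -> bool:
        spec = self.elements[element]
        if spec.unit is None:
            return True
        if observed_unit == spec.unit:
            return True
        return observed_unit in self.unit_conversions.get(spec.unit, {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceSchema":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls.from_config(cfg)

    @classmethod
    def from_config(cls, cfg: dict) -> "ReferenceSchema":
        elements = {}
        for name, e in (cfg.get("elements") or {}).items():
            e = dict(e or {})
            rng = e.pop("plausible_range", None)
            elements[name] = ElementSpec(
                name=name,
                synonyms=list(e.pop("synonyms", [])),
                dtype=e.pop("dtype", "float"),
                unit=e.pop("unit", None),
                format_pattern=e.pop("format_pattern", None),
                decimals=e.pop("decimals", None),
                plausible_range=tuple(rng) if rng else None,
                code_set=e.pop("code_set", None),
                required_method=e.pop("required_method", None),
                required_interval_hours=e.pop("required_interval_hours", None),
            )
        derived = [
            DerivedDefinition(
                target=d["target"], components=list(d["components"]),
                expr=d["expr"], tolerance=float(d.get("tolerance", 1e-6)),
            )
            for d in cfg.get("derived", [])
        ]
        return cls(
            elements=elements,
            key_fields=list(cfg.get("key_fields", ["patient_id", "admission_id"])),
            unit_conversions={k: dict(v) for k, v in
                              (cfg.get("unit_conversions") or {}).items()},
            derived=derived,
            timeliness_window_hours=float(cfg.get("timeliness_window_hours", 24.0)),
            timestamp_format=cfg.get("timestamp_format"),
            missing_codes=tuple(cfg.get("missing_codes", DEFAULT_MISSING_CODES)),
        )

    def to_config(self) -> dict:
        out = {"key_fields": list(self.key_fields),
               "timeliness_window_hours": self.timeliness_window_hours,
               "missing_codes": list(self.missing_codes),
               "unit_conversions": {k: dict(v) for k, v in self.unit_conversions.items()},
               "elements": {}, "derived": []}
        if self.timestamp_format:
            out["timestamp_format"] = self.timestamp_format
        for name, s in self.elements.items():
            e = {"dtype": s.dtype}
            if s.synonyms:
                e["synonyms"] = list(s.synonyms)
            for k in ("unit", "format_pattern", "decimals", "required_method",
                      "required_interval_hours"):
                v = getattr(s, k)
                if v is not None:
                    e[k] = v
            if s.plausible_range:
                e["plausible_range"] = list(s.plausible_range)
            if s.code_set:
                e["code_set"] = list(s.code_set)
            out["elements"][name] = e
        for d in self.derived:
            out["derived"].append({"target": d.target, "components": d.components,
                                   "expr": d.expr, "tolerance": d.tolerance})
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=False))


@dataclass
class ModelingPlan:
    inputs: list[str]
    outputs: list[str]
    required_n: int = 1
    required_methods: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.inputs or not self.outputs:
            raise ValueError("modeling plan needs non-empty input and output sets")
        overlap = set(self.inputs) & set(self.outputs)
        if overlap:
            raise ValueError(f"plan inputs and outputs overlap: {sorted(overlap)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelingPlan":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(inputs=list(cfg["inputs"]), outputs=list(cfg["outputs"]),
                   required_n=int(cfg.get("required_n", 1)),
                   required_methods=dict(cfg.get("required_methods", {})))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"inputs": self.inputs, "outputs": self.outputs,
             "required_n": self.required_n,
             "required_methods": self.required_methods}, sort_keys=False))


def missing_mask(values: pd.Series,
                 missing_codes: Iterable[str] = DEFAULT_MISSING_CODES) -> pd.Series:
    """True where a cell counts as missing: NaN/None, empty string, or a
    configured sentinel code (string-compared after stripping)."""
    mask = values.isna()
    codes = {str(c) for c in missing_codes}
    as_str = values.astype("string").str.strip()
    return mask | as_str.isna() | as_str.isin(codes)


def parse_timestamps(values: pd.Series, fmt: str | None = None) -> pd.Series:
    """Parse to datetimes; unparseable entries become NaT, never an error."""
    fmt = fmt or "ISO8601"
    return pd.to_datetime(values, format=fmt, errors="coerce")


@dataclass
class EMRDataset:
    """One admission-level table plus an optional long measurements table."""

    records: pd.DataFrame
    measurements: pd.DataFrame | None = None
    key_fields: tuple[str, ...] = ("patient_id", "admission_id")
    admit_col: str = "admit_time"
    discharge_col: str = "discharge_time"
    created_col: str = "created_at"
    state_col: str = "state"
    extraction_date: pd.Timestamp | None = None
    source_manifest: dict | None = None  # {"n_records": int, "non_missing": {col: int}}
    label: str = "dataset"

    def __post_init__(self):
        if self.records.columns.duplicated().any():
            dupes = self.records.columns[self.records.columns.duplicated()].tolist()
            raise ValueError(f"duplicate record columns: {dupes}")
        if self.measurements is not None:
            missing = [c for c in ("admission_id", "element", "value")
                       if c not in self.measurements.columns]
            if missing:
                raise ValueError(f"measurements table lacks columns {missing}")

    # -- accessors -----------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def element_columns(self) -> list[str]:
        """Record columns that are data elements (not keys/bookkeeping)."""
        reserved = set(self.key_fields) | {
            self.admit_col, self.discharge_col, self.created_col, self.state_col
        }
        return [c for c in self.records.columns if c not in reserved]

    def observed_elements(self) -> list[str]:
        """All element names present: wide columns plus long-table elements."""
        names = list(self.element_columns)
        if self.measurements is not None and len(self.measurements):
            for e in pd.unique(self.measurements["element"]):
                if e not in names:
                    names.append(str(e))
        return names

    def has_element(self, name: str) -> bool:
        return name in self.observed_elements()

    def measurements_for(self, element: str) -> pd.DataFrame:
        if self.measurements is None:
            return pd.DataFrame(columns=list(MEAS_COLS))
        return self.measurements[self.measurements["element"] == element]

    def manifest(self) -> dict:
        """Record count + per-column non-missing counts (for migration checks)."""
        return {
            "n_records": int(self.n_records),
            "non_missing": {
                c: int((~missing_mask(self.records[c])).sum())
                for c in self.records.columns
            },
        }

    # -- I/O -----------------------------------------------------------

    @classmethod
    def from_csv(cls, records_path: str | Path,
                 measurements_path: str | Path | None = None,
                 **kwargs) -> "EMRDataset":
        records = pd.read_csv(records_path)
        measurements = None
        if measurements_path is not None:
            measurements = pd.read_csv(measurements_path)
        return cls(records=records, measurements=measurements, **kwargs)

    def to_csv(self, records_path: str | Path,
               measurements_path: str | Path | None = None) -> None:
        self.records.to_csv(records_path, index=False)
        if self.measurements is not None and measurements_path is not None:
            self.measurements.to_csv(measurements_path, index=False)
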