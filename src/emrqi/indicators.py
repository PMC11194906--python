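"""Raw-score calculators for the 33 leaf quality indicators.

Every calculator maps ``(EMRDataset, ReferenceSchema, ModelingPlan)`` to a
score in [0, 1] — a ratio of conforming units over measured units, or a
binary/bounded quantity. The exact formulas are this package's definitions
(registry-pluggable so alternative formulations can be dropped in without
touching the engine); each is documented on its function.

An indicator that cannot be measured on a given dataset (the schema lacks
the needed section, or the dataset has no applicable values) is *not
evaluable*. The default policy scores it 1.0 with a prominent warning
("benefit of the doubt" — appropriate when datasets from one source are
compared, where such indicators are constant); alternatives are 0.0 or
exclusion with weight renormalization at scoring time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .dataset import (
    EMRDataset,
    ModelingPlan,
    ReferenceSchema,
    missing_mask,
    parse_timestamps,
)

__all__ = [
    "IndicatorScore",
    "CALCULATORS",
    "compute_indicator",
    "compute_all_indicators",
    "value_completeness_ratio",
    "normalized_entropy_balance",
    "range_conformance_ratio",
    "temporal_order_compliance",
    "recording_timeliness",
    "recording_frequency_ratio",
    "derived_value_consistency",
    "mapping_ratio",
]

_DIAG_LIMIT = 20  # diagnostics lists are truncated to this many entries

NOT_EVALUABLE_POLICIES = ("one", "zero", "exclude")


@dataclass
class IndicatorScore:
    indicator_id: str
    raw: float
    numerator: float | None = None
    denominator: float | None = None
    evaluable: bool = True
    reason: str = ""
    diagnostics: list[str] = field(default_factory=list)


def _ratio(indicator_id: str, num: float, den: float,
           diagnostics: Iterable[str] = ()) -> IndicatorScore:
    if den <= 0:
        return _not_evaluable(indicator_id, "zero denominator (nothing to measure)")
    raw = float(num) / float(den)
    raw = min(max(raw, 0.0), 1.0)
    return IndicatorScore(indicator_id, raw, float(num), float(den),
                          diagnostics=list(diagnostics)[:_DIAG_LIMIT])


def _not_evaluable(indicator_id: str, reason: str) -> IndicatorScore:
    return IndicatorScore(indicator_id, raw=float("nan"), evaluable=False,
                          reason=reason)


# ---------------------------------------------------------------------------
# shared element-resolution helpers
# ---------------------------------------------------------------------------

def _wide_column_for(ds: EMRDataset, schema: ReferenceSchema,
                     element: str) -> str | None:
    """Dataset record column holding canonical ``element``, if any."""
    if element in ds.records.columns:
        return element
    for col in ds.element_columns:
        if element in schema.resolve(col):
            return col
    return None


def _element_available(ds: EMRDataset, schema: ReferenceSchema,
                       element: str) -> bool:
    if _wide_column_for(ds, schema, element) is not None:
        return True
    for obs in ds.observed_elements():
        if obs == element or element in schema.resolve(obs):
            return True
    return False


def _observed_units(ds: EMRDataset, element: str) -> list[str]:
    meas = ds.measurements_for(element)
    if "unit" not in meas.columns or meas.empty:
        return []
    units = meas["unit"].dropna().astype(str)
    return sorted(units.unique())


def _observed_methods(ds: EMRDataset, element: str) -> list[str]:
    meas = ds.measurements_for(element)
    if "method" not in meas.columns or meas.empty:
        return []
    tags = meas["method"].dropna().astype(str)
    return sorted(tags.unique())


# ---------------------------------------------------------------------------
# reusable scoring primitives (public operations)
# ---------------------------------------------------------------------------

def value_completeness_ratio(ds: EMRDataset, columns: list[str],
                             schema: ReferenceSchema | None = None) -> float:
    """(non-missing cells) / (total cells) over ``columns``.

    A column absent from the records table contributes all-missing cells, so
    dropping a required element is penalized, not ignored.
    """
    if not columns:
        raise ValueError("empty column set")
    codes = schema.missing_codes if schema is not None else None
    total = len(ds.records) * len(columns)
    if total == 0:
        return 0.0
    present = 0
    for col in columns:
        if col in ds.records.columns:
            mask = (missing_mask(ds.records[col], codes) if codes is not None
                    else missing_mask(ds.records[col]))
            present += int((~mask).sum())
    return present / total


def normalized_entropy_balance(values: pd.Series) -> float | None:
    """Shannon entropy of the observed category distribution over log k.

    k is the number of *observed* categories; a single observed category
    yields 0 by convention. Returns None on an all-missing series.
    """
    x = values[~missing_mask(values)]
    if x.empty:
        return None
    counts = x.astype(str).value_counts().to_numpy(dtype=float)
    k = counts.size
    if k == 1:
        return 0.0
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(min(max(h / math.log(k), 0.0), 1.0))


def _numeric(values: pd.Series) -> pd.Series:
    return pd.to_numeric(values, errors="coerce")


def range_conformance_ratio(ds: EMRDataset, schema: ReferenceSchema) -> float | None:
    """Fraction of non-missing values inside their element's plausible range.

    Unparseable numerics count as non-conforming. None when no element with a
    declared range is present in the dataset.
    """
    num = den = 0
    for name, spec in schema.elements.items():
        if spec.plausible_range is None:
            continue
        col = _wide_column_for(ds, schema, name)
        lo, hi = spec.plausible_range
        if col is not None:
            vals = ds.records[col][~missing_mask(ds.records[col], schema.missing_codes)]
            x = _numeric(vals)
            den += len(vals)
            num += int(((x >= lo) & (x <= hi)).sum())
        meas = ds.measurements_for(name)
        if not meas.empty:
            vals = meas["value"][~missing_mask(meas["value"], schema.missing_codes)]
            x = _numeric(vals)
            den += len(vals)
            num += int(((x >= lo) & (x <= hi)).sum())
    if den == 0:
        return None
    return num / den


def temporal_order_compliance(ds: EMRDataset,
                              schema: ReferenceSchema | None = None) -> float:
    """Fraction of records whose event times are internally ordered.

    A record complies when admission and discharge anchors parse, admission
    <= discharge, every measurement timestamp of the record lies within the
    stay, and no timestamp postdates the dataset's extraction date. Records
    lacking anchors are non-compliant.
    """
    fmt = schema.timestamp_format if schema is not None else None
    n = ds.n_records
    if n == 0:
        return 0.0
    rec = ds.records
    if ds.admit_col not in rec.columns or ds.discharge_col not in rec.columns:
        return 0.0
    admit = parse_timestamps(rec[ds.admit_col], fmt)
    disch = parse_timestamps(rec[ds.discharge_col], fmt)
    ok = admit.notna() & disch.notna() & (admit <= disch)
    if ds.extraction_date is not None:
        cutoff = pd.Timestamp(ds.extraction_date)
        ok &= (disch <= cutoff) & (admit <= cutoff)
    key = ds.key_fields[-1] if ds.key_fields else "admission_id"
    if ds.measurements is not None and len(ds.measurements) and key in rec.columns:
        meas = ds.measurements.copy()
        mt = parse_timestamps(meas["measured_at"], fmt) if "measured_at" in meas else None
        if mt is not None:
            meas["_t"] = mt
            meas["_rid"] = meas["admission_id"].astype(str)
            bounds = pd.DataFrame({"_admit": admit.values, "_disch": disch.values,
                                   key: rec[key].astype(str).values})
            merged = meas.merge(bounds, left_on="_rid", right_on=key,
                                how="left")
            # NaT measurement times are a completeness defect, not an
            # ordering violation; they are scored by timestamp integrity.
            bad_time = ((merged["_t"] < merged["_admit"])
                        | (merged["_t"] > merged["_disch"]))
            if ds.extraction_date is not None:
                bad_time |= merged["_t"] > pd.Timestamp(ds.extraction_date)
            bad_ids = set(merged.loc[bad_time, "_rid"])
            ok &= ~rec[key].astype(str).isin(bad_ids)
    return float(ok.sum()) / n


def recording_timeliness(ds: EMRDataset, schema: ReferenceSchema) -> float | None:
    """Fraction of measurement values logged within the timeliness window.

    delay = recorded_at - measured_at must lie in [0, tau] where tau is the
    schema's ``timeliness_window_hours``. Values lacking either timestamp are
    excluded from the denominator; None if nothing is measurable.
    """
    if ds.measurements is None or not len(ds.measurements):
        return None
    meas = ds.measurements
    if "measured_at" not in meas.columns or "recorded_at" not in meas.columns:
        return None
    t0 = parse_timestamps(meas["measured_at"], schema.timestamp_format)
    t1 = parse_timestamps(meas["recorded_at"], schema.timestamp_format)
    both = t0.notna() & t1.notna()
    if not both.any():
        return None
    delay_h = (t1[both] - t0[both]).dt.total_seconds() / 3600.0
    tau = schema.timeliness_window_hours
    return float(((delay_h >= 0) & (delay_h <= tau)).mean())


def recording_frequency_ratio(ds: EMRDataset, schema: ReferenceSchema) -> float | None:
    """Observed vs required recording cadence for monitored elements.

    Per monitored element (one with a declared required recording interval)
    and record: min(1, observed count / expected count) with expected =
    ceil(stay_hours / interval), at least 1 (zero-length or unparseable stays
    expect one measurement). Scores average over elements within a record,
    then over records. None when no element is monitored.
    """
    monitored = [name for name, spec in schema.elements.items()
                 if spec.required_interval_hours]
    if not monitored or ds.n_records == 0:
        return None
    rec = ds.records
    key = ds.key_fields[-1] if ds.key_fields else "admission_id"
    if key not in rec.columns:
        return None
    fmt = schema.timestamp_format
    stay_h = pd.Series(np.nan, index=rec.index)
    if ds.admit_col in rec.columns and ds.discharge_col in rec.columns:
        admit = parse_timestamps(rec[ds.admit_col], fmt)
        disch = parse_timestamps(rec[ds.discharge_col], fmt)
        stay_h = (disch - admit).dt.total_seconds() / 3600.0
    counts = {}
    if ds.measurements is not None and len(ds.measurements):
        grouped = ds.measurements.assign(
            _rid=ds.measurements["admission_id"].astype(str)
        ).groupby(["element", "_rid"]).size()
        counts = grouped.to_dict()
    per_record = []
    for idx, rid in zip(rec.index, rec[key].astype(str)):
        dur = stay_h.loc[idx]
        per_element = []
        for name in monitored:
            interval = schema.elements[name].required_interval_hours
            if pd.isna(dur) or dur <= 0:
                expected = 1
            else:
                expected = max(1, math.ceil(dur / interval))
            observed = counts.get((name, rid), 0)
            per_element.append(min(1.0, observed / expected))
        per_record.append(float(np.mean(per_element)))
    return float(np.mean(per_record))


def derived_value_consistency(ds: EMRDataset, schema: ReferenceSchema) -> float | None:
    """Fraction of rows where a stored derived value matches its recomputation.

    Only rows with the target and every component non-missing enter the
    denominator; agreement is |stored - recomputed| <= tolerance.
    None when the schema defines no derived elements or nothing is checkable.
    """
    if not schema.derived:
        return None
    num = den = 0
    for d in schema.derived:
        cols = {}
        missing_col = False
        for name in [d.target, *d.components]:
            col = _wide_column_for(ds, schema, name)
            if col is None:
                missing_col = True
                break
            cols[name] = col
        if missing_col:
            continue
        frame = pd.DataFrame({name: _numeric(ds.records[col])
                              for name, col in cols.items()})
        complete = frame.dropna()
        if complete.empty:
            continue
        try:
            recomputed = complete.eval(d.expr)
        except Exception:
            continue
        den += len(complete)
        num += int((np.abs(complete[d.target] - recomputed) <= d.tolerance).sum())
    if den == 0:
        return None
    return num / den


def mapping_ratio(ds: EMRDataset, schema: ReferenceSchema,
                  aspect: str) -> tuple[float, float] | None:
    """(numerator, denominator) for one mapping aspect, or None if unsupported.

    * ``primary-key``: required key fields present in the records table.
    * ``element``: required schema elements resolvable from observed dataset
      element names (directly or via synonyms).
    * ``convertibility``: among mapped elements with a canonical unit and an
      observed unit annotation, those whose observed units all convert.
    * ``terminology``: coded values lying inside their element's bound code
      set, over all non-missing values of bound elements.
    """
    if aspect == "primary-key":
        required = schema.key_fields
        if not required:
            return None
        matched = sum(1 for k in required if k in ds.records.columns)
        return float(matched), float(len(required))
    if aspect == "element":
        required = list(schema.elements)
        if not required:
            return None
        matched = sum(1 for name in required if _element_available(ds, schema, name))
        return float(matched), float(len(required))
    if aspect == "convertibility":
        num = den = 0
        for name, spec in schema.elements.items():
            if spec.unit is None or not _element_available(ds, schema, name):
                continue
            units = _observed_units(ds, name)
            if not units:
                continue
            den += 1
            if all(schema.unit_convertible(name, u) for u in units):
                num += 1
        if den == 0:
            return None
        return float(num), float(den)
    if aspect == "terminology":
        num = den = 0
        for name, spec in schema.elements.items():
            if not spec.code_set:
                continue
            col = _wide_column_for(ds, schema, name)
            if col is None:
                continue
            vals = ds.records[col][~missing_mask(ds.records[col], schema.missing_codes)]
            den += len(vals)
            num += int(vals.astype(str).isin([str(c) for c in spec.code_set]).sum())
        if den == 0:
            return None
        return float(num), float(den)
    raise ValueError(f"unknown mapping aspect {aspect!r}")


# ---------------------------------------------------------------------------
# the 33 registered calculators
# ---------------------------------------------------------------------------

Calculator = Callable[[EMRDataset, ReferenceSchema, ModelingPlan], IndicatorScore]
CALCULATORS: dict[str, Calculator] = {}


def _register(name: str):
    def deco(fn: Calculator) -> Calculator:
        CALCULATORS[name] = fn
        return fn
    return deco


def _mapping_calc(indicator_id: str, ds, schema, aspect: str) -> IndicatorScore:
    pair = mapping_ratio(ds, schema, aspect)
    if pair is None:
        return _not_evaluable(indicator_id, f"no schema support for {aspect} mapping")
    return _ratio(indicator_id, *pair)


@_register("primary_key_mapping")
def _primary_key_mapping(ds, schema, plan):
    """Required primary-key fields found in the records table."""
    return _mapping_calc("primary_key_mapping", ds, schema, "primary-key")


@_register("element_mapping")
def _element_mapping(ds, schema, plan):
    """Required schema elements resolvable from the dataset's element names."""
    return _mapping_calc("element_mapping", ds, schema, "element")


@_register("unit_convertibility")
def _unit_convertibility(ds, schema, plan):
    """Mapped elements whose observed units convert to the canonical unit."""
    return _mapping_calc("unit_convertibility", ds, schema, "convertibility")


@_register("reliable_migration")
def _reliable_migration(ds, schema, plan):
    """Binary: working copy matches the source-extract manifest exactly
    (record count and per-column non-missing counts)."""
    if ds.source_manifest is None:
        return _not_evaluable("reliable_migration", "no source manifest recorded")
    current = ds.manifest()
    src = ds.source_manifest
    ok = current["n_records"] == src.get("n_records")
    diffs = []
    for col, n in (src.get("non_missing") or {}).items():
        if current["non_missing"].get(col) != n:
            ok = False
            diffs.append(col)
    return IndicatorScore("reliable_migration", 1.0 if ok else 0.0,
                          diagnostics=diffs[:_DIAG_LIMIT])


def _sufficiency(indicator_id: str, ds, schema, elements: list[str]) -> IndicatorScore:
    if not elements:
        return _not_evaluable(indicator_id, "plan declares no elements")
    available = [e for e in elements if _element_available(ds, schema, e)]
    missing = sorted(set(elements) - set(available))
    return _ratio(indicator_id, len(available), len(elements), missing)


@_register("input_sufficiency")
def _input_sufficiency(ds, schema, plan):
    """Available plan predictor elements over required predictor elements."""
    return _sufficiency("input_sufficiency", ds, schema, plan.inputs)


@_register("output_sufficiency")
def _output_sufficiency(ds, schema, plan):
    """Available plan outcome elements over required outcome elements."""
    return _sufficiency("output_sufficiency", ds, schema, plan.outputs)


def _method_selectivity(indicator_id: str, ds, plan, elements) -> IndicatorScore:
    required = {e: plan.required_methods[e] for e in elements
                if e in plan.required_methods}
    if not required:
        return _not_evaluable(indicator_id, "plan requires no measurement methods")
    good, bad = 0, []
    for element, method in required.items():
        observed = _observed_methods(ds, element)
        if observed and all(tag == method for tag in observed):
            good += 1
        else:
            bad.append(element)
    return _ratio(indicator_id, good, len(required), bad)


@_register("input_method_selectivity")
def _input_method_selectivity(ds, schema, plan):
    """Predictor elements recorded with the plan's required measurement method."""
    return _method_selectivity("input_method_selectivity", ds, plan, plan.inputs)


@_register("output_method_selectivity")
def _output_method_selectivity(ds, schema, plan):
    """Outcome elements recorded with the plan's required measurement method."""
    return _method_selectivity("output_method_selectivity", ds, plan, plan.outputs)


@_register("input_element_integrity")
def _input_element_integrity(ds, schema, plan):
    """Plan predictor columns present in the dataset over those required."""
    return _sufficiency("input_element_integrity", ds, schema, plan.inputs)


@_register("output_element_integrity")
def _output_element_integrity(ds, schema, plan):
    """Plan outcome columns present in the dataset over those required."""
    return _sufficiency("output_element_integrity", ds, schema, plan.outputs)


def _value_integrity(indicator_id, ds, schema, elements) -> IndicatorScore:
    if not elements:
        return _not_evaluable(indicator_id, "plan declares no elements")
    columns = [(_wide_column_for(ds, schema, e) or e) for e in elements]
    raw = value_completeness_ratio(ds, columns, schema)
    total = len(ds.records) * len(columns)
    return IndicatorScore(indicator_id, raw, raw * total, total)


@_register("input_value_integrity")
def _input_value_integrity(ds, schema, plan):
    """Non-missing predictor cells over all predictor cells."""
    return _value_integrity("input_value_integrity", ds, schema, plan.inputs)


@_register("output_value_integrity")
def _output_value_integrity(ds, schema, plan):
    """Non-missing outcome cells over all outcome cells."""
    return _value_integrity("output_value_integrity", ds, schema, plan.outputs)


@_register("record_timestamp_integrity")
def _record_timestamp_integrity(ds, schema, plan):
    """Records carrying a valid (parseable) creation timestamp."""
    if ds.n_records == 0:
        return _not_evaluable("record_timestamp_integrity", "empty dataset")
    if ds.created_col not in ds.records.columns:
        return IndicatorScore("record_timestamp_integrity", 0.0, 0, ds.n_records,
                              diagnostics=[f"column {ds.created_col} absent"])
    parsed = parse_timestamps(ds.records[ds.created_col], schema.timestamp_format)
    return _ratio("record_timestamp_integrity", int(parsed.notna().sum()),
                  ds.n_records)


@_register("value_timestamp_integrity")
def _value_timestamp_integrity(ds, schema, plan):
    """Measurement values carrying a valid measurement timestamp."""
    if ds.measurements is None or not len(ds.measurements):
        return _not_evaluable("value_timestamp_integrity", "no measurements table")
    meas = ds.measurements
    if "measured_at" not in meas.columns:
        return IndicatorScore("value_timestamp_integrity", 0.0, 0, len(meas))
    parsed = parse_timestamps(meas["measured_at"], schema.timestamp_format)
    return _ratio("value_timestamp_integrity", int(parsed.notna().sum()), len(meas))


@_register("state_availability")
def _state_availability(ds, schema, plan):
    """Records whose state flag is 'available' (voided/error records are not
    usable). An absent state column treats all records as available, with a
    warning in the diagnostics."""
    if ds.n_records == 0:
        return _not_evaluable("state_availability", "empty dataset")
    if ds.state_col not in ds.records.columns:
        return IndicatorScore(
            "state_availability", 1.0, ds.n_records, ds.n_records,
            diagnostics=[f"no {ds.state_col} column; all records assumed available"])
    state = ds.records[ds.state_col].astype(str).str.lower()
    return _ratio("state_availability", int((state == "available").sum()),
                  ds.n_records)


@_register("sample_adequacy")
def _sample_adequacy(ds, schema, plan):
    """min(1, n / required n): is the cohort large enough for the plan?"""
    need = max(1, plan.required_n)
    return IndicatorScore("sample_adequacy", min(1.0, ds.n_records / need),
                          ds.n_records, need)


@_register("input_balance")
def _input_balance(ds, schema, plan):
    """Mean normalized entropy over categorical predictor distributions
    (numeric predictors are excluded)."""
    scores = []
    for name in plan.inputs:
        spec = schema.elements.get(name)
        if spec is None or spec.dtype != "category":
            continue
        col = _wide_column_for(ds, schema, name)
        if col is None:
            continue
        h = normalized_entropy_balance(ds.records[col])
        if h is not None:
            scores.append(h)
    if not scores:
        return _not_evaluable("input_balance", "no categorical predictors observed")
    return IndicatorScore("input_balance", float(np.mean(scores)))


@_register("output_balance")
def _output_balance(ds, schema, plan):
    """Normalized entropy of the outcome distribution (1.0 at 50/50)."""
    col = _wide_column_for(ds, schema, plan.outputs[0])
    if col is None:
        return _not_evaluable("output_balance", "outcome column absent")
    h = normalized_entropy_balance(ds.records[col])
    if h is None:
        return _not_evaluable("output_balance", "outcome entirely missing")
    return IndicatorScore("output_balance", h)


@_register("format_accuracy")
def _format_accuracy(ds, schema, plan):
    """Non-missing values matching their element's declared format pattern."""
    num = den = 0
    offenders = []
    for name, spec in schema.elements.items():
        if spec.format_pattern is None:
            continue
        col = _wide_column_for(ds, schema, name)
        if col is None:
            continue
        vals = ds.records[col][~missing_mask(ds.records[col], schema.missing_codes)]
        if vals.empty:
            continue
        try:
            pattern = re.compile(spec.format_pattern)
        except re.error:
            continue
        ok = vals.astype(str).str.fullmatch(pattern).fillna(False)
        den += len(vals)
        num += int(ok.sum())
        if not ok.all():
            offenders.append(name)
    if den == 0:
        return _not_evaluable("format_accuracy", "no format patterns applicable")
    return _ratio("format_accuracy", num, den, offenders)


def _parseable_as(values: pd.Series, dtype: str) -> pd.Series:
    s = values.astype(str)
    if dtype in ("float", "int"):
        x = pd.to_numeric(s, errors="coerce")
        ok = x.notna()
        if dtype == "int":
            ok &= (x % 1 == 0).fillna(False)
        return ok
    if dtype == "datetime":
        return pd.to_datetime(s, format="ISO8601", errors="coerce").notna()
    return pd.Series(True, index=values.index)  # str / category: any text is valid


@_register("type_accuracy")
def _type_accuracy(ds, schema, plan):
    """Non-missing values parseable as their element's declared type."""
    num = den = 0
    offenders = []
    for name, spec in schema.elements.items():
        col = _wide_column_for(ds, schema, name)
        if col is None:
            continue
        vals = ds.records[col][~missing_mask(ds.records[col], schema.missing_codes)]
        if vals.empty:
            continue
        ok = _parseable_as(vals, spec.dtype)
        den += len(vals)
        num += int(ok.sum())
        if not ok.all():
            offenders.append(name)
    if den == 0:
        return _not_evaluable("type_accuracy", "no typed elements observed")
    return _ratio("type_accuracy", num, den, offenders)


def _decimal_places(values: pd.Series) -> pd.Series:
    """Significant decimals in the string form (trailing zeros ignored)."""
    s = values.astype(str).str.strip()
    frac = s.str.extract(r"^-?\d+\.(\d*?)0*$", expand=False)
    out = frac.str.len().astype(float)
    out[s.str.fullmatch(r"-?\d+").fillna(False)] = 0.0
    return out


@_register("granularity")
def _granularity(ds, schema, plan):
    """Columns recorded at at least the declared numeric precision.

    A column meets its requirement when the median observed count of
    significant decimals reaches the declared minimum; the score is the
    fraction of requirement-bearing columns that meet it.
    """
    num = den = 0
    offenders = []
    for name, spec in schema.elements.items():
        if spec.decimals is None:
            continue
        col = _wide_column_for(ds, schema, name)
        if col is None:
            continue
        vals = ds.records[col][~missing_mask(ds.records[col], schema.missing_codes)]
        places = _decimal_places(vals).dropna()
        if places.empty:
            continue
        den += 1
        if places.median() >= spec.decimals:
            num += 1
        else:
            offenders.append(name)
    if den == 0:
        return _not_evaluable("granularity", "no precision requirements applicable")
    return _ratio("granularity", num, den, offenders)


@_register("range_conformance")
def _range_conformance(ds, schema, plan):
    """Non-missing numeric values inside their declared plausibility range."""
    r = range_conformance_ratio(ds, schema)
    if r is None:
        return _not_evaluable("range_conformance", "no plausibility ranges applicable")
    return IndicatorScore("range_conformance", r)


@_register("element_unambiguity")
def _element_unambiguity(ds, schema, plan):
    """Observed elements resolving to exactly one canonical concept, over
    observed elements resolving to at least one (unmapped elements are a
    mapping problem, not an ambiguity problem)."""
    num = den = 0
    ambiguous = []
    for obs in ds.observed_elements():
        concepts = schema.resolve(obs)
        if not concepts:
            continue
        den += 1
        if len(concepts) == 1:
            num += 1
        else:
            ambiguous.append(obs)
    if den == 0:
        return _not_evaluable("element_unambiguity", "no resolvable elements")
    return _ratio("element_unambiguity", num, den, ambiguous)


def _single_method_ratio(indicator_id: str, ds) -> IndicatorScore:
    tagged = []
    for element in ds.observed_elements():
        methods = _observed_methods(ds, element)
        if methods:
            tagged.append((element, methods))
    if not tagged:
        return _not_evaluable(indicator_id, "no measurement-method tags recorded")
    num = sum(1 for _, m in tagged if len(m) == 1)
    offenders = [e for e, m in tagged if len(m) > 1]
    return _ratio(indicator_id, num, len(tagged), offenders)


@_register("method_unambiguity")
def _method_unambiguity(ds, schema, plan):
    """Tagged elements measured under a single, unambiguous method tag."""
    return _single_method_ratio("method_unambiguity", ds)


@_register("method_consistency")
def _method_consistency(ds, schema, plan):
    """Tagged elements whose method tag is constant across all records."""
    return _single_method_ratio("method_consistency", ds)


@_register("derived_value_consistency")
def _derived_value_consistency(ds, schema, plan):
    """Stored derived values matching their recomputed formula."""
    r = derived_value_consistency(ds, schema)
    if r is None:
        return _not_evaluable("derived_value_consistency",
                              "no derived definitions applicable")
    return IndicatorScore("derived_value_consistency", r)


@_register("unit_consistency")
def _unit_consistency(ds, schema, plan):
    """Unit-annotated measurement values expressed in the canonical unit."""
    if ds.measurements is None or "unit" not in (ds.measurements.columns
                                                 if ds.measurements is not None else []):
        return _not_evaluable("unit_consistency", "no unit annotations")
    num = den = 0
    for name, spec in schema.elements.items():
        if spec.unit is None:
            continue
        meas = ds.measurements_for(name)
        units = meas["unit"].dropna().astype(str) if not meas.empty else pd.Series(dtype=str)
        den += len(units)
        num += int((units == spec.unit).sum())
    if den == 0:
        return _not_evaluable("unit_consistency", "no annotated values for declared units")
    return _ratio("unit_consistency", num, den)


@_register("element_terminology_compliance")
def _element_terminology_compliance(ds, schema, plan):
    """Bindable elements whose every coded value lies in the bound code set."""
    num = den = 0
    offenders = []
    for name, spec in schema.elements.items():
        if not spec.code_set:
            continue
        col = _wide_column_for(ds, schema, name)
        if col is None:
            continue
        vals = ds.records[col][~missing_mask(ds.records[col], schema.missing_codes)]
        if vals.empty:
            continue
        den += 1
        if vals.astype(str).isin([str(c) for c in spec.code_set]).all():
            num += 1
        else:
            offenders.append(name)
    if den == 0:
        return _not_evaluable("element_terminology_compliance",
                              "no terminology bindings applicable")
    return _ratio("element_terminology_compliance", num, den, offenders)


@_register("value_terminology_compliance")
def _value_terminology_compliance(ds, schema, plan):
    """Coded values inside their bound code set, value by value."""
    return _mapping_calc("value_terminology_compliance", ds, schema, "terminology")


@_register("timestamp_standard_compliance")
def _timestamp_standard_compliance(ds, schema, plan):
    """All timestamp-bearing cells parsing under the declared standard format."""
    num = den = 0
    fmt = schema.timestamp_format
    for col in (ds.admit_col, ds.discharge_col, ds.created_col):
        if col in ds.records.columns:
            vals = ds.records[col][~missing_mask(ds.records[col], schema.missing_codes)]
            if len(vals):
                den += len(vals)
                num += int(parse_timestamps(vals, fmt).notna().sum())
    if ds.measurements is not None:
        for col in ("measured_at", "recorded_at"):
            if col in ds.measurements.columns:
                vals = ds.measurements[col][~missing_mask(ds.measurements[col],
                                                          schema.missing_codes)]
                if len(vals):
                    den += len(vals)
                    num += int(parse_timestamps(vals, fmt).notna().sum())
    if den == 0:
        return _not_evaluable("timestamp_standard_compliance", "no timestamps present")
    return _ratio("timestamp_standard_compliance", num, den)


@_register("temporal_order_compliance")
def _temporal_order_compliance(ds, schema, plan):
    """Records whose admission/measurement/discharge times are in order."""
    if ds.n_records == 0:
        return _not_evaluable("temporal_order_compliance", "empty dataset")
    return IndicatorScore("temporal_order_compliance",
                          temporal_order_compliance(ds, schema))


@_register("recording_timeliness")
def _recording_timeliness(ds, schema, plan):
    """Measurement values logged within tau hours of being measured."""
    r = recording_timeliness(ds, schema)
    if r is None:
        return _not_evaluable("recording_timeliness",
                              "no measured/recorded timestamp pairs")
    return IndicatorScore("recording_timeliness", r)


@_register("recording_frequency")
def _recording_frequency(ds, schema, plan):
    """Observed recording cadence against the required interval."""
    r = recording_frequency_ratio(ds, schema)
    if r is None:
        return _not_evaluable("recording_frequency",
                              "no required recording intervals declared")
    return IndicatorScore("recording_frequency", r)


# ---------------------------------------------------------------------------
# engine entry points
# ---------------------------------------------------------------------------

def compute_indicator(ds: EMRDataset, schema: ReferenceSchema, plan: ModelingPlan,
                      calculator_id: str, policy: str = "one") -> IndicatorScore:
    """Compute one leaf indicator; deterministic for a fixed dataset.

    ``policy`` resolves not-evaluable results: ``"one"`` scores 1.0 (benefit
    of the doubt, the default), ``"zero"`` scores 0.0, ``"exclude"`` leaves
    raw as NaN for weight renormalization downstream.
    """
    if calculator_id not in CALCULATORS:
        raise KeyError(f"unknown indicator calculator {calculator_id!r} "
                       f"(known: {sorted(CALCULATORS)})")
    if policy not in NOT_EVALUABLE_POLICIES:
        raise ValueError(f"unknown not-evaluable policy {policy!r}")
    score = CALCULATORS[calculator_id](ds, schema, plan)
    if not score.evaluable and policy != "exclude":
        score.raw = 1.0 if policy == "one" else 0.0
    return score


def compute_all_indicators(ds: EMRDataset, schema: ReferenceSchema,
                           plan: ModelingPlan,
                           policy: str = "one") -> dict[str, IndicatorScore]:
    return {cid: compute_indicator(ds, schema, plan, cid, policy)
            for cid in CALCULATORS}
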