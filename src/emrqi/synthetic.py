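"""Seeded synthetic ICU-style cohorts with plantable quality defects.

The generator emulates the shape of an ICU sepsis-risk cohort: demographics,
admission/discharge anchors, baseline labs (white-cell count, lactate,
creatinine, bilirubin), a derived BMI element, a long table of vital-sign
measurements on a fixed cadence with units and method tags, and a binary
sepsis-like outcome drawn from a logistic model on five standardized
predictors. Quality defects (element dropout, cadence thinning, cell
missingness, delayed or missing timestamps, range violations, format errors,
unit inconsistencies, corrupted derived values, voided records, label noise)
are injected afterwards in a fixed, documented order, each governed by a
per-opportunity probability; realized counts are reported in the ground
truth rather than forced exact.

Everything is reproducible from the integer seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset import EMRDataset, ModelingPlan, ReferenceSchema
from .delphi import ExpertProfile, RatingsMatrix

__all__ = [
    "DefectProfile",
    "GroundTruth",
    "default_schema",
    "default_plan",
    "generate_cohort",
    "defect_sweep",
    "generate_expert_panel",
]

PREDICTORS = ("age", "wbc", "lactate", "creatinine", "heart_rate_baseline")
PLAN_INPUTS = PREDICTORS + ("sex",)  # sex is categorical: balance-scored, not modeled
OUTCOME = "sepsis"
VITALS = ("heart_rate", "resp_rate", "sbp")

#: Outcome-model log-odds coefficients on the five standardized predictors;
#: sized so a clean cohort yields held-out AUC around 0.80-0.85, leaving
#: headroom for defect-driven degradation.
DEFAULT_COEFFICIENTS = (0.8, 0.9, 1.1, 0.7, 0.6)

_VITAL_PARAMS = {  # mean, sd, canonical unit, plausible range
    "heart_rate": (85.0, 12.0, "bpm", (20.0, 300.0)),
    "resp_rate": (18.0, 4.0, "breaths/min", (4.0, 60.0)),
    "sbp": (120.0, 15.0, "mmHg", (40.0, 300.0)),
}
_LAB_PARAMS = {  # log-mean, log-sd, unit, plausible range
    "wbc": (math.log(9.0), 0.4, "10^9/L", (0.5, 100.0)),
    "lactate": (math.log(1.8), 0.5, "mmol/L", (0.1, 30.0)),
    "creatinine": (math.log(1.0), 0.5, "mg/dL", (0.1, 30.0)),
    "bilirubin": (math.log(0.8), 0.7, "mg/dL", (0.05, 80.0)),
}

VITAL_INTERVAL_HOURS = 4.0  # required (and clean) recording cadence

#: Plausibility ranges for the non-lab record columns; single source for the
#: schema declarations and the range-violation injector.
_DEMO_RANGES = {
    "age": (18.0, 110.0),
    "height_cm": (120.0, 230.0),
    "weight_kg": (25.0, 350.0),
    "bmi": (10.0, 80.0),
    "heart_rate_baseline": (20.0, 300.0),
}


@dataclass
class DefectProfile:
    """Specification of the planted quality problems for one cohort."""

    n_records: int = 2500
    cell_missingness: dict[str, float] = field(default_factory=dict)  # "inputs"/"outputs"
    timestamp_missing_rate: float = 0.0
    creation_delay: tuple[str, float] = ("fixed", 1.0)  # (kind, mean hours)
    frequency_thinning: dict[str, float] = field(default_factory=dict)  # element -> keep
    range_violation_rate: float = 0.0
    format_error_rate: float = 0.0
    unit_inconsistency_rate: float = 0.0
    derived_corruption_rate: float = 0.0
    state_unavailable_rate: float = 0.0
    outcome_prevalence: float = 0.25
    label_noise_rate: float = 0.0
    element_dropout: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if not (0.0 < self.outcome_prevalence < 1.0):
            raise ValueError("outcome_prevalence must lie in (0, 1)")
        rates = {
            "timestamp_missing_rate": self.timestamp_missing_rate,
            "range_violation_rate": self.range_violation_rate,
            "format_error_rate": self.format_error_rate,
            "unit_inconsistency_rate": self.unit_inconsistency_rate,
            "derived_corruption_rate": self.derived_corruption_rate,
            "state_unavailable_rate": self.state_unavailable_rate,
            "label_noise_rate": self.label_noise_rate,
            **{f"cell_missingness[{k}]": v for k, v in self.cell_missingness.items()},
            **{f"frequency_thinning[{k}]": v for k, v in self.frequency_thinning.items()},
        }
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} = {r} outside [0, 1]")
        if self.creation_delay[0] not in ("fixed", "exponential"):
            raise ValueError(f"unknown delay kind {self.creation_delay[0]!r}")
        if set(self.element_dropout) >= set(PREDICTORS):
            raise ValueError("element_dropout removes every predictor")


@dataclass
class GroundTruth:
    """What was actually planted, recountable against the emitted tables."""

    profile: DefectProfile
    coefficients: tuple[float, ...]
    intercept: float
    realized: dict[str, int] = field(default_factory=dict)
    opportunities: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        prof = {f.name: getattr(self.profile, f.name) for f in fields(DefectProfile)}
        prof["creation_delay"] = list(self.profile.creation_delay)
        return {"profile": prof, "coefficients": list(self.coefficients),
                "intercept": self.intercept, "realized": self.realized,
                "opportunities": self.opportunities}


def default_schema() -> ReferenceSchema:
    """The reference data dictionary the synthetic cohorts are scored against."""
    cfg = {
        "key_fields": ["patient_id", "admission_id"],
        "timeliness_window_hours": 24.0,
        "unit_conversions": {"mg/dL": {"umol/L": 0.0113}},
        "elements": {
            "age": {"dtype": "float", "unit": "years",
                    "plausible_range": list(_DEMO_RANGES["age"]),
                    "synonyms": ["age_years"]},
            "sex": {"dtype": "category", "code_set": ["M", "F"]},
            "height_cm": {"dtype": "float", "unit": "cm",
                          "plausible_range": list(_DEMO_RANGES["height_cm"])},
            "weight_kg": {"dtype": "float", "unit": "kg", "decimals": 1,
                          "plausible_range": list(_DEMO_RANGES["weight_kg"])},
            "bmi": {"dtype": "float", "unit": "kg/m^2",
                    "plausible_range": list(_DEMO_RANGES["bmi"])},
            "icd_code": {"dtype": "str",
                         "format_pattern": r"[A-Z]\d{2}\.\d"},
            "sepsis": {"dtype": "int", "code_set": ["0", "1"],
                       "synonyms": ["sepsis_flag"]},
            "heart_rate_baseline": {
                "dtype": "float", "unit": "bpm",
                "plausible_range": list(_DEMO_RANGES["heart_rate_baseline"])},
            **{
                name: {"dtype": "float", "unit": unit,
                       "plausible_range": list(rng),
                       "required_interval_hours": VITAL_INTERVAL_HOURS}
                for name, (_, _, unit, rng) in _VITAL_PARAMS.items()
            },
            **{
                name: {"dtype": "float", "unit": unit,
                       "plausible_range": list(rng)}
                for name, (_, _, unit, rng) in _LAB_PARAMS.items()
            },
        },
        "derived": [{"target": "bmi", "components": ["weight_kg", "height_cm"],
                     "expr": "weight_kg / (height_cm / 100) ** 2",
                     "tolerance": 0.05}],
    }
    return ReferenceSchema.from_config(cfg)


def default_plan() -> ModelingPlan:
    return ModelingPlan(inputs=list(PLAN_INPUTS), outputs=[OUTCOME],
                        required_n=1000)


def _solve_intercept(linear: np.ndarray, prevalence: float) -> float:
    def gap(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + linear))))) - prevalence

    return float(optimize.brentq(gap, -30.0, 30.0))


def _iso(ts: pd.Series) -> pd.Series:
    return ts.dt.strftime("%Y-%m-%dT%H:%M:%S")


def generate_cohort(
    profile: DefectProfile,
    coefficients: Sequence[float] = DEFAULT_COEFFICIENTS,
) -> tuple[EMRDataset, GroundTruth]:
    """Draw a clean cohort, attach the outcome, then inject defects.

    Injection order is fixed so rates compose predictably: element dropout,
    cadence thinning, cell missingness, missing timestamps, recording delays,
    range violations, format errors, unit inconsistencies, derived-value
    corruption, record-state flags, label noise.
    """
    rng = np.random.default_rng(profile.seed)
    n = profile.n_records
    realized: dict[str, int] = {}
    opportunities: dict[str, int] = {}

    # ---- clean cohort -------------------------------------------------
    rec = pd.DataFrame({
        "patient_id": [f"P{100000 + i}" for i in range(n)],
        "admission_id": [f"A{200000 + i}" for i in range(n)],
    })
    rec["age"] = np.round(rng.uniform(18, 95, n), 0)
    rec["sex"] = rng.choice(["M", "F"], size=n)
    rec["height_cm"] = np.round(rng.normal(170, 10, n).clip(130, 215), 1)
    rec["weight_kg"] = np.round(rng.normal(78, 15, n).clip(35, 250), 1)
    rec["bmi"] = np.round(rec["weight_kg"] / (rec["height_cm"] / 100) ** 2, 2)
    letters = rng.choice(list("AIJKN"), size=n)
    rec["icd_code"] = [f"{c}{rng.integers(10, 99)}.{rng.integers(0, 9)}"
                       for c in letters]
    for name, (mu, sd, _, _) in _LAB_PARAMS.items():
        rec[name] = np.round(np.exp(rng.normal(mu, sd, n)), 2)
    rec["heart_rate_baseline"] = np.round(
        rng.normal(*_VITAL_PARAMS["heart_rate"][:2], size=n).clip(30, 180), 0)

    admit = (pd.Timestamp("2019-01-01")
             + pd.to_timedelta(rng.uniform(0, 365 * 24, n), unit="h")).floor("min")
    stay_draw = np.exp(rng.normal(math.log(60.0), 0.5, n)).clip(12, 500)
    discharge = (admit + pd.to_timedelta(stay_draw, unit="h")).floor("min")
    # the effective stay is taken from the stored (minute-floored) anchors so
    # the clean cadence and the frequency indicator agree exactly
    stay_h = (discharge - admit).total_seconds() / 3600.0
    created = admit + pd.to_timedelta(rng.uniform(0.1, 2.0, n), unit="h")
    rec["admit_time"] = _iso(pd.Series(admit))
    rec["discharge_time"] = _iso(pd.Series(discharge))
    rec["created_at"] = _iso(pd.Series(created.floor("min")))
    rec["state"] = "available"

    # outcome from a logistic model on standardized predictors
    Z = np.column_stack([
        (rec[p] - rec[p].mean()) / rec[p].std(ddof=0) for p in PREDICTORS
    ])
    beta = np.asarray(coefficients, dtype=float)
    linear = Z @ beta
    alpha = _solve_intercept(linear, profile.outcome_prevalence)
    p_event = 1.0 / (1.0 + np.exp(-(alpha + linear)))
    rec[OUTCOME] = (rng.uniform(size=n) < p_event).astype(int)

    # long vitals table on the required cadence
    counts = np.maximum(1, np.ceil(stay_h / VITAL_INTERVAL_HOURS).astype(int))
    adm_rep = np.repeat(rec["admission_id"].to_numpy(), counts)
    offsets = np.concatenate([np.arange(c) for c in counts]) * VITAL_INTERVAL_HOURS
    base_time = np.repeat(admit.values, counts)
    measured = pd.Series(pd.DatetimeIndex(base_time)
                         + pd.to_timedelta(offsets, unit="h"))
    frames = []
    hr_base = np.repeat(rec["heart_rate_baseline"].to_numpy(), counts)
    for name in VITALS:
        mean, sd, unit, rngt = _VITAL_PARAMS[name]
        center = hr_base if name == "heart_rate" else mean
        values = np.round(rng.normal(0, sd * 0.5, adm_rep.size) + center, 0)
        values = values.clip(rngt[0] + 1, rngt[1] - 1)
        frames.append(pd.DataFrame({
            "admission_id": adm_rep, "element": name, "value": values,
            "measured_at": _iso(measured), "unit": unit, "method": "monitor",
        }))
    meas = pd.concat(frames, ignore_index=True)

    # ---- defect injection (fixed order) --------------------------------
    # 1. element dropout
    for element in profile.element_dropout:
        if element in rec.columns:
            rec = rec.drop(columns=[element])
        meas = meas[meas["element"] != element]
    realized["element_dropout"] = len(profile.element_dropout)

    # 2. cadence thinning
    kept_masks = np.ones(len(meas), dtype=bool)
    thinned = 0
    for element, keep in profile.frequency_thinning.items():
        sel = (meas["element"] == element).to_numpy()
        drop = sel & (rng.uniform(size=len(meas)) > keep)
        kept_masks &= ~drop
        thinned += int(drop.sum())
    meas = meas[kept_masks].reset_index(drop=True)
    realized["frequency_thinning"] = thinned

    # 3. cell missingness per column group
    groups = {"inputs": [p for p in PLAN_INPUTS if p in rec.columns],
              "outputs": [OUTCOME] if OUTCOME in rec.columns else []}
    for group, rate in profile.cell_missingness.items():
        cols = groups.get(group, [c for c in [group] if c in rec.columns])
        hit = 0
        for col in cols:
            mask = rng.uniform(size=n) < rate
            rec.loc[mask, col] = np.nan
            hit += int(mask.sum())
        realized[f"cell_missingness.{group}"] = hit
        opportunities[f"cell_missingness.{group}"] = n * len(cols)

    # 4. missing timestamps (value-level and record-creation)
    ts_mask = rng.uniform(size=len(meas)) < profile.timestamp_missing_rate
    meas.loc[ts_mask, "measured_at"] = np.nan
    rc_mask = rng.uniform(size=n) < profile.timestamp_missing_rate
    rec.loc[rc_mask, "created_at"] = np.nan
    realized["timestamp_missing"] = int(ts_mask.sum()) + int(rc_mask.sum())
    opportunities["timestamp_missing"] = len(meas) + n

    # 5. recording delays
    kind, mean_h = profile.creation_delay
    if kind == "fixed":
        delay_h = np.full(len(meas), mean_h)
    else:
        delay_h = rng.exponential(mean_h, size=len(meas))
    measured_dt = pd.to_datetime(meas["measured_at"], errors="coerce")
    recorded = measured_dt + pd.to_timedelta(delay_h, unit="h")
    meas["recorded_at"] = recorded.dt.strftime("%Y-%m-%dT%H:%M:%S")
    realized["delays_beyond_24h"] = int((delay_h > 24.0).sum())
    opportunities["delays_beyond_24h"] = len(meas)

    # 6. range violations (every ranged record column, vitals in the long table)
    violated = 0
    wide_cells = 0
    ranged_wide = {**{k: v[3] for k, v in _LAB_PARAMS.items()}, **_DEMO_RANGES}
    for name, (lo, hi) in ranged_wide.items():
        if name not in rec.columns:
            continue
        present = rec[name].notna().to_numpy()
        mask = (rng.uniform(size=n) < profile.range_violation_rate) & present
        rec.loc[mask, name] = hi + rng.uniform(0.1 * (hi - lo), 0.5 * (hi - lo),
                                               int(mask.sum()))
        violated += int(mask.sum())
        wide_cells += int(present.sum())
    vmask = rng.uniform(size=len(meas)) < profile.range_violation_rate
    for name, (_, _, _, (lo, hi)) in _VITAL_PARAMS.items():
        sel = vmask & (meas["element"] == name).to_numpy()
        meas.loc[sel, "value"] = hi + rng.uniform(0.1 * (hi - lo), 0.5 * (hi - lo),
                                                  int(sel.sum()))
        violated += int(sel.sum())
    realized["range_violations"] = violated
    opportunities["range_violations"] = wide_cells + len(meas)

    # 7. format errors on the coded diagnosis string
    if "icd_code" in rec.columns:
        mask = rng.uniform(size=n) < profile.format_error_rate
        rec.loc[mask, "icd_code"] = "code?" + pd.Series(
            np.arange(n), index=rec.index).astype(str)[mask]
        realized["format_errors"] = int(mask.sum())
        opportunities["format_errors"] = n

    # 8. unit inconsistencies on vital annotations
    umask = rng.uniform(size=len(meas)) < profile.unit_inconsistency_rate
    meas.loc[umask, "unit"] = "nonstandard-unit"
    realized["unit_inconsistencies"] = int(umask.sum())
    opportunities["unit_inconsistencies"] = len(meas)

    # 9. derived-value corruption
    if "bmi" in rec.columns:
        present = rec["bmi"].notna().to_numpy()
        mask = (rng.uniform(size=n) < profile.derived_corruption_rate) & present
        rec.loc[mask, "bmi"] = rec.loc[mask, "bmi"] + rng.uniform(
            2.0, 10.0, int(mask.sum()))
        realized["derived_corruption"] = int(mask.sum())
        opportunities["derived_corruption"] = int(present.sum())

    # 10. record state flags
    smask = rng.uniform(size=n) < profile.state_unavailable_rate
    rec.loc[smask, "state"] = "voided"
    realized["state_unavailable"] = int(smask.sum())
    opportunities["state_unavailable"] = n

    # 11. label noise
    if OUTCOME in rec.columns:
        present = rec[OUTCOME].notna().to_numpy()
        mask = (rng.uniform(size=n) < profile.label_noise_rate) & present
        rec.loc[mask, OUTCOME] = 1 - rec.loc[mask, OUTCOME]
        realized["label_noise"] = int(mask.sum())
        opportunities["label_noise"] = int(present.sum())

    dataset = EMRDataset(
        records=rec, measurements=meas.reset_index(drop=True),
        extraction_date=pd.Timestamp("2020-12-31"),
        label=f"synthetic-seed{profile.seed}",
    )
    dataset.source_manifest = dataset.manifest()
    truth = GroundTruth(profile=profile, coefficients=tuple(beta),
                        intercept=alpha, realized=realized,
                        opportunities=opportunities)
    return dataset, truth


def defect_sweep(
    base_profile: DefectProfile,
    axis: str,
    levels: Sequence[float],
    seeds: Sequence[int],
) -> tuple[list[tuple[str, EMRDataset, GroundTruth]], pd.DataFrame]:
    """One cohort per (level, seed) varying a single defect axis.

    ``axis`` names a scalar rate field of :class:`DefectProfile`, or the
    forms ``cell_missingness.inputs`` / ``cell_missingness.outputs``.
    Returns the cohorts plus a manifest linking labels to settings.
    """
    scalar_axes = {f.name for f in fields(DefectProfile)} - {
        "cell_missingness", "frequency_thinning", "element_dropout",
        "creation_delay", "seed", "n_records"}
    group = None
    if axis.startswith("cell_missingness."):
        group = axis.split(".", 1)[1]
        if group not in ("inputs", "outputs"):
            raise ValueError(f"unknown missingness group {group!r}")
    elif axis not in scalar_axes:
        raise ValueError(f"unknown sweep axis {axis!r} "
                         f"(scalar axes: {sorted(scalar_axes)})")
    cohorts = []
    manifest_rows = []
    for level in levels:
        for seed in seeds:
            if group is not None:
                miss = dict(base_profile.cell_missingness)
                miss[group] = float(level)
                prof = replace(base_profile, cell_missingness=miss, seed=int(seed))
            else:
                prof = replace(base_profile, **{axis: float(level)}, seed=int(seed))
            ds, truth = generate_cohort(prof)
            label = f"{axis}={level}@seed{seed}"
            ds.label = label
            cohorts.append((label, ds, truth))
            manifest_rows.append({"label": label, "axis": axis,
                                  "level": float(level), "seed": int(seed)})
    return cohorts, pd.DataFrame(manifest_rows)


DEFAULT_FAMILIARITY_FREQS = {
    "very_familiar": 0.4, "familiar": 0.4, "somewhat_familiar": 0.15,
    "unfamiliar": 0.05,
}
DEFAULT_INFLUENCE_FREQS = {"high": 0.6, "medium": 0.3, "low": 0.1}
_JUDGMENT_BASES = ("practical_experience", "theoretical_analysis",
                   "peer_knowledge", "intuition")


def generate_expert_panel(
    n_experts: int,
    n_items: int,
    consensus: float,
    seed: int = 0,
    latent_importances: Sequence[float] | None = None,
) -> tuple[RatingsMatrix, list[ExpertProfile]]:
    """Likert ratings drawn around per-item latent importances.

    ``consensus`` is a precision: rating = clip(round(latent + eps), 1, 5)
    with eps ~ Normal(0, 1/consensus). ``consensus <= 0`` degenerates to
    uniform random ratings (no agreement); ``consensus = inf`` gives every
    expert the rounded latent exactly. Higher consensus lowers per-item CV
    and raises Kendall's W.
    """
    if n_experts < 2 or n_items < 2:
        raise ValueError("need n_experts >= 2 and n_items >= 2")
    rng = np.random.default_rng(seed)
    if latent_importances is None:
        latent = rng.uniform(2.0, 5.0, n_items)
    else:
        latent = np.asarray(latent_importances, dtype=float)
        if latent.size != n_items:
            raise ValueError("latent_importances length must equal n_items")
    if consensus <= 0:
        ratings = rng.integers(1, 6, size=(n_experts, n_items))
    elif math.isinf(consensus):
        ratings = np.tile(np.round(latent), (n_experts, 1))
    else:
        noise = rng.normal(0.0, 1.0 / consensus, size=(n_experts, n_items))
        ratings = np.clip(np.round(latent[None, :] + noise), 1, 5)
    matrix = RatingsMatrix(values=pd.DataFrame(
        ratings.astype(float),
        index=[f"E{i + 1:02d}" for i in range(n_experts)],
        columns=[f"I{j + 1:02d}" for j in range(n_items)],
    ))
    fam_cats = list(DEFAULT_FAMILIARITY_FREQS)
    fam_p = np.array(list(DEFAULT_FAMILIARITY_FREQS.values()))
    inf_cats = list(DEFAULT_INFLUENCE_FREQS)
    inf_p = np.array(list(DEFAULT_INFLUENCE_FREQS.values()))
    profiles = [
        ExpertProfile(
            expert_id=f"E{i + 1:02d}",
            familiarity=str(rng.choice(fam_cats, p=fam_p / fam_p.sum())),
            judgment_basis={b: str(rng.choice(inf_cats, p=inf_p / inf_p.sum()))
                            for b in _JUDGMENT_BASES},
        )
        for i in range(n_experts)
    ]
    return matrix, profiles
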