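import numpy as np
import pandas as pd
import pytest

from emrqi import (
    DefectProfile,
    EMRDataset,
    ModelingPlan,
    ReferenceSchema,
    default_index_system,
    default_plan,
    default_schema,
    generate_cohort,
)


@pytest.fixture(scope="session")
def system():
    return default_index_system()


@pytest.fixture(scope="session")
def synth_schema():
    return default_schema()


@pytest.fixture(scope="session")
def synth_plan():
    return default_plan()


@pytest.fixture(scope="session")
def clean_cohort(synth_schema, synth_plan):
    """Balanced, defect-free cohort large enough to satisfy the plan."""
    ds, truth = generate_cohort(
        DefectProfile(n_records=1200, outcome_prevalence=0.5, seed=11))
    return ds, truth


# ---- a small hand-built world for indicator unit tests -------------------

def make_mini_schema():
    return ReferenceSchema.from_config({
        "key_fields": ["patient_id", "admission_id"],
        "timeliness_window_hours": 24.0,
        "unit_conversions": {"C": {"F": 0.5556}},
        "elements": {
            "hr": {"dtype": "float", "unit": "bpm", "plausible_range": [20, 300],
                   "required_interval_hours": 4.0, "synonyms": ["heart_rate"]},
            "temp": {"dtype": "float", "unit": "C", "decimals": 1,
                     "plausible_range": [30, 45]},
            "sex": {"dtype": "category", "code_set": ["M", "F"]},
            "icd": {"dtype": "str", "format_pattern": r"[A-Z]\d{2}"},
            "wt": {"dtype": "float", "unit": "kg"},
            "ht": {"dtype": "float", "unit": "cm"},
            "bmi": {"dtype": "float"},
            "outcome": {"dtype": "int", "code_set": ["0", "1"]},
        },
        "derived": [{"target": "bmi", "components": ["wt", "ht"],
                     "expr": "wt / (ht / 100) ** 2", "tolerance": 0.01}],
    })


def make_mini_plan():
    return ModelingPlan(inputs=["hr", "temp", "sex"], outputs=["outcome"],
                        required_n=10)


@pytest.fixture(scope="session")
def mini_schema():
    return make_mini_schema()


@pytest.fixture(scope="session")
def mini_plan():
    return make_mini_plan()


def make_mini_dataset(n=20, seed=0, measurements=None, **column_overrides):
    """A compliant record table; override or drop columns to plant defects."""
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "admission_id": [f"A{i}" for i in range(n)],
        "hr": np.round(rng.uniform(60, 110, n), 0),
        "temp": np.round(rng.uniform(36.1, 38.4, n), 1),
        "sex": rng.choice(["M", "F"], n),
        "icd": ["A41"] * n,
        "wt": np.round(rng.uniform(50, 110, n), 1),
        "ht": np.round(rng.uniform(150, 195, n), 1),
        "outcome": rng.integers(0, 2, n),
        "admit_time": "2019-03-01T08:00:00",
        "discharge_time": "2019-03-04T08:00:00",
        "created_at": "2019-03-01T09:00:00",
        "state": "available",
    })
    rec["bmi"] = np.round(rec["wt"] / (rec["ht"] / 100) ** 2, 4)
    for col, value in column_overrides.items():
        if value is None:
            rec = rec.drop(columns=[col])
        else:
            rec[col] = value
    return EMRDataset(records=rec, measurements=measurements,
                      extraction_date=pd.Timestamp("2020-01-01"))


@pytest.fixture
def mini_dataset():
    return make_mini_dataset()
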