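"""Shared fixtures: one session-scoped synthetic study at the default
conditions (n = 5,000 patients, three planted blocks per domain,
multiplier 6) plus small hand-built event fixtures."""

from __future__ import annotations

import pandas as pd
import pytest

from patientprofiler import (FeatureMatrix, assign_cohorts,
                             build_feature_matrix, generate_cohort_events)
from patientprofiler.config import SimulationConfig


@pytest.fixture(scope="session")
def study():
    """Full synthetic study: events, truth, assignments, pooled matrices."""
    cfg = SimulationConfig(n_patients=5000, seed=1)
    patients, events, truth = generate_cohort_events(cfg)
    assignments = assign_cohorts(events, patients)
    pooled = {}
    for domain in ("diagnosis", "procedure"):
        mats = build_feature_matrix(events, assignments, domain)
        X = pd.concat([m.data for m in mats.values()]).fillna(0).astype("int8")
        X = X[[c for c in X.columns if X[c].mean() >= 0.01]]
        pooled[domain] = FeatureMatrix(X, domain)
    return {"config": cfg, "patients": patients, "events": events,
            "truth": truth, "assignments": assignments, "pooled": pooled}


def make_events(rows: list[tuple[str, str, str, str]]) -> pd.DataFrame:
    """rows of (patient_id, kind, code, iso-date) -> events frame."""
    df = pd.DataFrame(rows, columns=["patient_id", "kind", "code", "date"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def make_patients(rows: list[tuple[str, str]], sex: str = "Female"
                  ) -> pd.DataFrame:
    """rows of (patient_id, birth_date)."""
    df = pd.DataFrame(rows, columns=["patient_id", "birth_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["sex"] = sex
    df["race"] = "White"
    df["ethnicity"] = "Not Hispanic or Latino"
    return df
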