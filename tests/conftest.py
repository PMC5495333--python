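"""Shared fixtures: synthetic cohorts and small fitted pipeline pieces."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from adgfs import (
    SimulationDesign,
    calibrate_hazards,
    fit_kml,
    generate_cohort,
)
from adgfs.trajectory_clustering import trajectory_matrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

BASELINE_FACTORS = ["donor_age", "scr_m12", "prot_m12", "ndsa_pre", "scr_cluster"]


@pytest.fixture(scope="session")
def default_design() -> SimulationDesign:
    return SimulationDesign(n=600, seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_design):
    """A 600-patient cohort under the default study design."""
    hazards = calibrate_hazards(default_design)
    return generate_cohort(default_design, hazards)


@pytest.fixture(scope="session")
def clustered_cohort(default_cohort):
    """Default cohort with fitted k=3 creatinine clusters assigned."""
    tm = trajectory_matrix(default_cohort)
    model = fit_kml(tm, 3, restarts=10, seed=1)
    return default_cohort.with_clusters(model.label_map()), model


def toy_patients_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p2"],
            "donor_age": [44.0, 61.5],
            "ndsa_pre": [0, 1],
            "scr_m12": [120.0, 190.0],
            "prot_m12": [0.1, 0.8],
            "dndsa_time": [np.nan, 3.0],
            "rejection_time": [np.nan, 0.4],
            "followup_time": [10.0, 6.5],
            "graft_failure": [0, 1],
        }
    )


def toy_series_frame() -> pd.DataFrame:
    rows = []
    for pid, base in (("p1", 120.0), ("p2", 180.0)):
        for m in range(13):
            rows.append((pid, m, base + m))
    return pd.DataFrame(rows, columns=["patient_id", "month", "scr"])
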