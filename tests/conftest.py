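import warnings

import numpy as np
import pandas as pd
import pytest

import ehrtrial as et

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_sim():
    """A small default (null-effect, confounded) simulation shared by unit tests."""
    tables, gt = et.simulate(et.SimConfig(n_patients=4000, seed=7))
    return tables, gt


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    tables, gt = small_sim
    cohort, flow = et.build_cohort(tables, et.CohortSpec())
    return cohort, flow


@pytest.fixture(scope="session")
def small_features(small_sim, small_cohort):
    tables, _ = small_sim
    cohort, _ = small_cohort
    return et.build_features(cohort, tables, strategy="first_and_last")


def toy_tables():
    """Six hand-written patients for cohort-selection arithmetic.

    Patients 0,1: under-age.  Patient 2: no crystalloid (anchor) event.
    Patients 3,4,5: eligible; patient 3 receives albumin at t0+2h
    (treated), 4 and 5 are controls.  Patient 5 dies at hour 100.
    """
    static = pd.DataFrame(
        {
            "patient_id": [0, 1, 2, 3, 4, 5],
            "age": [16.0, 17.5, 70.0, 55.0, 80.0, 66.0],
            "sex": ["F", "M", "F", "M", "F", "M"],
            "race": ["white", "black", "white", "other", "white", "hispanic"],
            "emergency_admission": [1, 0, 1, 1, 0, 1],
            "septic_shock": [0, 0, 1, 1, 0, 1],
            "admission_time_h": 0.0,
        }
    )
    interventions = pd.DataFrame(
        {
            "patient_id": [0, 1, 3, 4, 5, 3],
            "time_h": [1.0, 2.0, 1.0, 2.0, 1.5, 3.0],
            "intervention": ["crystalloid"] * 5 + ["albumin"],
        }
    )
    measurements = pd.DataFrame(
        {
            "patient_id": [3, 3, 4],
            "time_h": [0.0, 0.5, 0.0],
            "variable": ["sofa", "sofa", "sofa"],
            "value": [5.0, 9.0, 7.0],
        }
    )
    outcomes = pd.DataFrame(
        {
            "patient_id": [0, 1, 2, 3, 4, 5],
            "death_time_h": [np.nan, np.nan, np.nan, np.nan, np.nan, 100.0],
            "last_seen_h": [700.0, 700.0, 700.0, 700.0, 700.0, 100.0],
        }
    )
    return et.EventTables(static, measurements, interventions, outcomes)


@pytest.fixture()
def toy():
    return toy_tables()
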