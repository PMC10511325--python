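import numpy as np
import pandas as pd
import pytest

import growthfalter as gf


@pytest.fixture(scope="session")
def lms_ref():
    return gf.load_synthetic_reference()


@pytest.fixture(scope="session")
def tiny_lms():
    """Hand-built LMS table with simple parameters for exact z-score checks."""
    rows = []
    for sex in ("male", "female"):
        for age, L, M, S in [(0, 1.0, 50.0, 0.04), (365, 1.0, 70.0, 0.04),
                             (730, 1.0, 85.0, 0.04)]:
            rows.append((sex, age, L, M + (2.0 if sex == "male" else 0.0), S))
    return gf.LMSReference(pd.DataFrame(rows, columns=["sex", "age_days", "L", "M", "S"]))


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration study at seed 1, shared across tests."""
    return gf.simulate(gf.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def monthly_grid(default_sim):
    """Monthly-grid frame restricted to the monthly-measured cohorts."""
    measurements, truth = default_sim
    monthly = truth.cohorts.loc[truth.cohorts["schedule"] == "monthly", "cohort_id"]
    return gf.month_grid(measurements[measurements["cohort_id"].isin(monthly)])


def make_child(laz_by_age, cohort="C", child="c1", sex="male"):
    """Measurement frame for one child from {age_days: laz} (lengths dummy)."""
    ages = sorted(laz_by_age)
    return pd.DataFrame({
        "cohort_id": cohort, "child_id": child, "sex": sex,
        "age_days": ages, "length_cm": 50.0,
        "laz": [laz_by_age[a] for a in ages],
    })


def make_grid(laz_by_month, cohort="C", child="c1", sex="male", month_days=gf.MONTH_DAYS):
    """Monthly-grid frame for one child from {month: laz}, nominal ages."""
    months = sorted(laz_by_month)
    return pd.DataFrame({
        "cohort_id": cohort, "child_id": child, "sex": sex,
        "month": months,
        "age_days": [int(np.ceil(m * month_days)) for m in months],
        "length_cm": 50.0,
        "laz": [laz_by_month[m] for m in months],
    })
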