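import numpy as np
import pandas as pd
import pytest

from adipometry.synthetic import CohortConfig, generate_cohort

# stratum layout of the study's BMI prevalence table, age-band columns:
# (sex, band, n, n_overweight, n_obese)
TABLE3_STRATA = [
    ("male", "15-19", 170, 20, 3),
    ("male", "20-25", 284, 36, 8),
    ("female", "15-19", 266, 54, 16),
    ("female", "20-25", 307, 77, 29),
]

# the table's separately printed Total column (the female obese total, 46,
# exceeds the sum of its band counts by one in the source table)
TABLE3_TOTALS = [
    ("male", 454, 56, 11),
    ("female", 573, 131, 46),
]


def _record(i, sex, band, bmi_target):
    """One participant row with weight chosen to hit a BMI value exactly."""
    height = 170.0
    return {
        "id": i,
        "sex": sex,
        "age_years": 18 if band == "15-19" else 22,
        "year_of_study": 1,
        "college": "college_0",
        "height_cm": height,
        "weight_kg": bmi_target * (height / 100.0) ** 2,
        "wc_cm": 75.0,
        "tpbf_pct": 25.0,
        "alcohol": False,
        "smoking": False,
        "exercise": "never",
        "fh_hypertension": False,
        "fh_diabetes": False,
        "fh_obesity": False,
    }


@pytest.fixture(scope="session")
def table3_records() -> pd.DataFrame:
    """A cohort whose BMI classes reproduce the published stratum counts."""
    rows = []
    i = 0
    for sex, band, n, n_ow, n_ob in TABLE3_STRATA:
        for _ in range(n_ob):
            rows.append(_record(i := i + 1, sex, band, 32.0))
        for _ in range(n_ow):
            rows.append(_record(i := i + 1, sex, band, 27.0))
        for _ in range(n - n_ow - n_ob):
            rows.append(_record(i := i + 1, sex, band, 21.0))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def table3_totals_records() -> pd.DataFrame:
    """A cohort reproducing the table's Total-column counts per sex."""
    rows = []
    i = 0
    for sex, n, n_ow, n_ob in TABLE3_TOTALS:
        for _ in range(n_ob):
            rows.append(_record(i := i + 1, sex, "15-19", 32.0))
        for _ in range(n_ow):
            rows.append(_record(i := i + 1, sex, "15-19", 27.0))
        for _ in range(n - n_ow - n_ob):
            rows.append(_record(i := i + 1, sex, "15-19", 21.0))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def dummy_cutoffs():
    """Cutoffs no subject can reach, for BMI-only classification paths."""
    return {
        (sex, band, ep): 1e6
        for sex in ("female", "male")
        for band in ("15-19", "20-25")
        for ep in ("overweight", "obese")
    }


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """A mid-sized synthetic cohort under the default study conditions."""
    return generate_cohort(CohortConfig(n_subjects=4000, seed=20240321))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
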