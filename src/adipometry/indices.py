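"""Adiposity indices, threshold classification and survey design quantities.

BMI is weight (kg) over squared height (m²); RFM (relative fat mass) is the
height/waist anthropometric surrogate for whole-body fat percentage,

    RFM = 64 − 20·(height / waist circumference) + 12·[sex == female],

unit-free in the ratio, so height and waist must share units.  Subjects are
classified against the WHO BMI thresholds (overweight ≥ 25 kg/m², obesity
≥ 30 kg/m²) and, for TPBF and RFM, against externally supplied sex- and
age-band-specific cutoffs (typically ROC-derived; see
:mod:`adipometry.roc`).  Cluster-survey sample-size arithmetic
(design effect 1 + (m−1)·ICC) lives here too.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from adipometry.errors import ConfigurationError, DomainError

# BMI class labels, ordered.  "normal" pools normal and underweight: the
# analysis only ever contrasts overweight/obese against the rest.
BMI_CLASSES = ("normal", "overweight", "obese")

#: Age bands used throughout the stratified analyses.
AGE_BANDS = ("15-19", "20-25")

WHO_OVERWEIGHT = 25.0
WHO_OBESE = 30.0

ENDPOINTS = ("overweight", "obese")

#: Columns a cohort CSV must carry.  Units are declared in the column names
#: (cm, kg, %) to guard against metre/centimetre mix-ups.
COHORT_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "year_of_study",
    "college",
    "height_cm",
    "weight_kg",
    "wc_cm",
    "tpbf_pct",
    "alcohol",
    "smoking",
    "exercise",
    "fh_hypertension",
    "fh_diabetes",
    "fh_obesity",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the study's tables)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def age_band(age_years) -> str | pd.Series:
    """Map age in years to the '15-19' / '20-25' analysis bands."""
    if np.isscalar(age_years):
        return AGE_BANDS[0] if age_years < 20 else AGE_BANDS[1]
    arr = np.asarray(age_years)
    return pd.Series(np.where(arr < 20, AGE_BANDS[0], AGE_BANDS[1]), name="age_band")


def compute_bmi(weight_kg, height_cm):
    """Body mass index, kg/m².  Height is taken in centimetres."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise DomainError("weight_kg and height_cm must be strictly positive")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def compute_rfm(height_cm, wc_cm, sex):
    """Relative fat mass: 64 − 20·(height/WC) + 12·[female].

    ``sex`` is 'female'/'male' (scalar or array).  Height and waist
    circumference must be in the same unit; centimetres by convention.
    """
    height_cm = np.asarray(height_cm, dtype=float)
    wc_cm = np.asarray(wc_cm, dtype=float)
    if np.any(height_cm <= 0) or np.any(wc_cm <= 0):
        raise DomainError("height_cm and wc_cm must be strictly positive")
    female = np.char.lower(np.asarray(sex, dtype=str)) == "female"
    out = 64.0 - 20.0 * (height_cm / wc_cm) + 12.0 * female
    return float(out) if out.ndim == 0 else out


def classify_bmi(bmi, overweight: float = WHO_OVERWEIGHT, obese: float = WHO_OBESE):
    """WHO BMI class: obese iff BMI ≥ 30, overweight iff 25 ≤ BMI < 30.

    Thresholds are inclusive on the left, as defined.  Scalar in → scalar
    label; array in → ordered pandas Categorical.
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise DomainError("BMI must be finite")
    labels = np.where(arr >= obese, "obese", np.where(arr >= overweight, "overweight", "normal"))
    if arr.ndim == 0:
        return str(labels)
    return pd.Categorical(labels, categories=list(BMI_CLASSES), ordered=True)


def index_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject BMI/RFM values, WHO BMI class and age band.

    The cutoff-free part of cohort classification; input for ROC cutoff
    derivation and the prevalence summaries.
    """
    bmi = compute_bmi(records["weight_kg"].to_numpy(), records["height_cm"].to_numpy())
    rfm = compute_rfm(
        records["height_cm"].to_numpy(), records["wc_cm"].to_numpy(), records["sex"].to_numpy()
    )
    return pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "sex": records["sex"].to_numpy(),
            "age_band": np.asarray(age_band(records["age_years"].to_numpy())),
            "bmi_kg_m2": bmi,
            "rfm": rfm,
            "bmi_class": np.asarray(classify_bmi(bmi)),
        }
    )


CutoffMapping = Mapping[tuple[str, str, str], float]
"""Cutoffs keyed by (sex, age_band, endpoint) with endpoint in ENDPOINTS."""


def _check_cutoff_coverage(records: pd.DataFrame, cutoffs: CutoffMapping, index_name: str) -> None:
    present = set(zip(records["sex"], age_band(records["age_years"].to_numpy())))
    missing = [
        (sex, band, ep)
        for sex, band in sorted(present)
        for ep in ENDPOINTS
        if (sex, band, ep) not in cutoffs
    ]
    if missing:
        raise ConfigurationError(
            f"missing {index_name} cutoffs for strata: " + ", ".join(map(str, missing))
        )


def classify_cohort(
    records: pd.DataFrame,
    tpbf_cutoffs: CutoffMapping,
    rfm_cutoffs: CutoffMapping,
    *,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Classify every subject under the BMI, TPBF and RFM criteria.

    Parameters
    ----------
    records
        Cohort table with at least sex, age_years, height_cm, weight_kg,
        wc_cm and tpbf_pct columns.
    tpbf_cutoffs, rfm_cutoffs
        Mappings (sex, age_band, endpoint) → cutoff, with endpoint in
        ``("overweight", "obese")``.  Every stratum present in ``records``
        must be covered, else :class:`ConfigurationError`.
    inclusive
        If True (default) a value equal to the cutoff counts positive
        (value ≥ cutoff).  ROC cutoffs are reported with a strict ">"
        convention; boundary mass on a continuous index is negligible, but
        one convention has to be fixed, and it is configurable here.

    Returns
    -------
    DataFrame with id, sex, age_band, bmi_kg_m2, rfm, bmi_class and the four
    TPBF/RFM positivity flags.
    """
    _check_cutoff_coverage(records, tpbf_cutoffs, "TPBF")
    _check_cutoff_coverage(records, rfm_cutoffs, "RFM")
    bmi = compute_bmi(records["weight_kg"].to_numpy(), records["height_cm"].to_numpy())
    rfm = compute_rfm(
        records["height_cm"].to_numpy(), records["wc_cm"].to_numpy(), records["sex"].to_numpy()
    )
    bands = age_band(records["age_years"].to_numpy())
    out = pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "sex": records["sex"].to_numpy(),
            "age_band": np.asarray(bands),
            "bmi_kg_m2": bmi,
            "rfm": rfm,
            "bmi_class": classify_bmi(bmi),
        }
    )
    tpbf = records["tpbf_pct"].to_numpy(dtype=float)
    compare = np.greater_equal if inclusive else np.greater

    for index_name, values, cutoffs in (
        ("tpbf", tpbf, tpbf_cutoffs),
        ("rfm", rfm, rfm_cutoffs),
    ):
        for endpoint in ENDPOINTS:
            cuts = np.array(
                [cutoffs[(s, b, endpoint)] for s, b in zip(out["sex"], out["age_band"])]
            )
            out[f"{index_name}_positive_{endpoint}"] = compare(values, cuts)
    return out


def summarize_bmi_prevalence(classified: pd.DataFrame) -> pd.DataFrame:
    """Sex- and age-band-stratified prevalence under the BMI criterion.

    Returns a long table with one row per (sex, age_band-or-'total',
    category) where category is '25.0-29.9', '>=30.0' or
    'overweight_or_obese'; counts, stratum size, and percentage rounded
    half-up to one decimal, matching the study's presentation.
    """
    rows = []
    for sex, sex_df in classified.groupby("sex", observed=True):
        groups = [(band, df) for band, df in sex_df.groupby("age_band", observed=True)]
        groups.append(("total", sex_df))
        for band, df in groups:
            n = len(df)
            n_ow = int((df["bmi_class"] == "overweight").sum())
            n_ob = int((df["bmi_class"] == "obese").sum())
            for cat, count in (
                ("25.0-29.9", n_ow),
                (">=30.0", n_ob),
                ("overweight_or_obese", n_ow + n_ob),
            ):
                rows.append(
                    {
                        "sex": sex,
                        "age_band": band,
                        "category": cat,
                        "count": count,
                        "n": n,
                        "pct": round_half_up(100.0 * count / n, 1) if n else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def design_effect(m: float, icc: float) -> float:
    """Design effect of a cluster sample: DEFF = 1 + (m − 1)·ICC."""
    if m < 1:
        raise DomainError("cluster size m must be >= 1")
    if not 0 <= icc < 1:
        raise DomainError("icc must lie in [0, 1)")
    return 1.0 + (m - 1.0) * icc


def compute_sample_size(
    p: float,
    d: float,
    z: float = 1.96,
    deff: float = 1.0,
    j: float = 1.0,
    k: float = 1.0,
    l: float = 1.0,
) -> dict:
    """Two-stage cluster-survey sample size.

    n = z²·p(1−p)·DEFF / (j·k·l·d²), where j is the expected response
    proportion, k the average cluster (department) size and l the fraction
    of the population in the target group.  Returns the unadjusted
    individual requirement ceil(z²·p(1−p)·DEFF / d²) and the department
    count from the full formula, rounded half-down (28.375 → 28, matching
    the convention of the source survey's published numbers).
    """
    if not 0 < p < 1:
        raise DomainError("p must lie strictly in (0, 1)")
    if d <= 0 or z <= 0:
        raise DomainError("d and z must be positive")
    if not (0 < j <= 1 and 0 < l <= 1):
        raise DomainError("j and l must lie in (0, 1]")
    if k < 1:
        raise DomainError("k must be >= 1")
    if deff < 1:
        raise DomainError("deff must be >= 1")
    individuals_raw = z**2 * p * (1 - p) * deff / d**2
    departments_raw = individuals_raw / (j * k * l)
    return {
        "individuals": math.ceil(individuals_raw),
        # round half-down: ceil(x - 0.5)
        "departments": math.ceil(departments_raw - 0.5),
    }


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, checking the unit-bearing header columns."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort CSV missing columns: {missing}")
    return df


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
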