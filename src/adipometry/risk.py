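"""Logistic risk-factor models for overweight/obesity under each index.

One multiple logistic regression per outcome definition (BMI-, TPBF- and
RFM-based overweight/obesity), with the covariate set of the study's
risk-factor table: sex, age band, year of study, exercise frequency,
alcohol, smoking, and the three family-history flags.  Categorical factors
are dummy-coded against the stated reference levels (male; < 20 years;
1st year; never exercises; no family history) and odds ratios carry 95%
Wald intervals.  The fit itself is maximum likelihood by iteratively
reweighted least squares (statsmodels GLM binomial backend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from adipometry.errors import ConfigurationError, DomainError
from adipometry.indices import age_band

EXERCISE_ORDER = ("never", "rarely", "sometimes", "almost_everyday")

#: Table-4 covariate set as (column, kind) — kind 'binary' enters as 0/1,
#: 'dummy' is expanded against its first listed level.
RISK_COVARIATES = (
    ("female", "binary"),
    ("age_20_plus", "binary"),
    ("year_2", "binary"),
    ("year_3", "binary"),
    ("year_4", "binary"),
    ("exercise_rarely", "binary"),
    ("exercise_sometimes", "binary"),
    ("exercise_almost_everyday", "binary"),
    ("alcohol", "binary"),
    ("smoking", "binary"),
    ("fh_hypertension", "binary"),
    ("fh_diabetes", "binary"),
    ("fh_obesity", "binary"),
)


@dataclass
class OddsRatio2x2:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool


def odds_ratio_2x2(a, b, c, d) -> OddsRatio2x2:
    """OR = ad/(bc) with the Woolf log-scale 95% interval.

    ``a``..``d`` are the exposed-case, exposed-control, unexposed-case and
    unexposed-control counts.  Any zero cell triggers the Haldane–Anscombe
    +0.5 continuity correction, flagged on the result.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise DomainError("counts must be non-negative")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(0.975)
    return OddsRatio2x2(
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - z * se)),
        ci_high=float(np.exp(np.log(or_) + z * se)),
        corrected=corrected,
    )


@dataclass
class LogisticFit:
    """Per-covariate log-odds estimates, ORs, Wald 95% CIs and p-values."""

    table: pd.DataFrame
    n: int
    outcome: str
    deviance: float
    converged: bool
    warnings: list = field(default_factory=list)

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "odds_ratio"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def fit_logistic(
    outcome,
    covariates: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-8,
    outcome_name: str = "outcome",
) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald 95% intervals.

    ``covariates`` is the already-coded numeric design (no intercept
    column; one is added).  Raises on a constant covariate, a degenerate
    outcome, or n ≤ number of parameters; attaches a warning (never
    silent) if quasi-separation inflates a standard error.
    """
    y = np.asarray(outcome, dtype=float)
    X = covariates.astype(float)
    if len(y) != len(X):
        raise DomainError("outcome and covariates must align")
    if y.min() == y.max():
        raise DomainError("degenerate outcome: all responses identical")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ConfigurationError(f"constant covariates cannot be fit: {constant}")
    if len(y) <= X.shape[1] + 1:
        raise DomainError("need more observations than parameters")

    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(maxiter=max_iter, tol=tol)
    notes = [str(w.message) for w in caught]
    if not res.converged:
        raise DomainError(
            f"IRLS failed to converge in {max_iter} iterations (deviance {res.deviance:.3f})"
        )
    se = res.bse
    sep = [c for c in design.columns if se[c] > 10]
    if sep:
        notes.append(f"possible quasi-separation; unstable terms: {sep}")

    z = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "odds_ratio": np.exp(res.params),
            "ci_low": np.exp(res.params - z * se),
            "ci_high": np.exp(res.params + z * se),
            "se": se,
            "p_value": res.pvalues,
        }
    )
    return LogisticFit(
        table=table,
        n=len(y),
        outcome=outcome_name,
        deviance=float(res.deviance),
        converged=bool(res.converged),
        warnings=notes,
    )


def build_risk_design(records: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded covariate design against the reference levels.

    References: male, < 20 years, 1st year, never exercises, no family
    history / flag absent.
    """
    required = [
        "sex",
        "age_years",
        "year_of_study",
        "exercise",
        "alcohol",
        "smoking",
        "fh_hypertension",
        "fh_diabetes",
        "fh_obesity",
    ]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ConfigurationError(f"missing covariates: {missing}")
    bands = np.asarray(age_band(records["age_years"].to_numpy()))
    X = pd.DataFrame(index=records.index)
    X["female"] = (records["sex"] == "female").astype(int)
    X["age_20_plus"] = (bands == "20-25").astype(int)
    for yr in (2, 3, 4):
        X[f"year_{yr}"] = (records["year_of_study"] == yr).astype(int)
    for level in EXERCISE_ORDER[1:]:
        X[f"exercise_{level}"] = (records["exercise"] == level).astype(int)
    for flag in ("alcohol", "smoking", "fh_hypertension", "fh_diabetes", "fh_obesity"):
        X[flag] = records[flag].astype(int)
    return X


def run_risk_table(
    classifications: pd.DataFrame,
    records: pd.DataFrame,
    outcome: str = "overweight_or_obese",
) -> dict[str, LogisticFit]:
    """Fit the three outcome definitions (BMI, TPBF, RFM) on one covariate set.

    ``outcome`` selects the combined overweight-or-obese endpoint (the
    default, matching the risk table's caption) or "obese" for the
    obesity-only endpoint.
    """
    if outcome not in ("overweight_or_obese", "obese"):
        raise ConfigurationError("outcome must be 'overweight_or_obese' or 'obese'")
    if len(classifications) == 0 or len(records) == 0:
        raise DomainError("empty input table")
    merged = records.merge(classifications, on="id", suffixes=("", "_cls"))
    if len(merged) != len(records):
        raise ConfigurationError("classification and covariate tables do not align on id")
    X = build_risk_design(merged)
    endpoint = "obese" if outcome == "obese" else "overweight"
    outcomes = {
        "bmi": (
            (merged["bmi_class"] == "obese")
            if outcome == "obese"
            else (merged["bmi_class"] != "normal")
        ).astype(int),
        "tpbf": merged[f"tpbf_positive_{endpoint}"].astype(int),
        "rfm": merged[f"rfm_positive_{endpoint}"].astype(int),
    }
    return {
        name: fit_logistic(y, X, outcome_name=f"{name}:{outcome}")
        for name, y in outcomes.items()
    }


def risk_table_frame(fits: dict[str, LogisticFit]) -> pd.DataFrame:
    """Long-form OR table across the three outcome definitions."""
    frames = []
    for name, fit in fits.items():
        t = fit.table.drop(index="const").reset_index(names="factor")
        t.insert(0, "outcome_index", name)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
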