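"""Synthetic cohorts and cross-classified two-test count data.

The real study surveyed 1027 undergraduates (573 female, 454 male) across
six college clusters; the generator here emulates that cohort so the whole
pipeline is exercisable without the deposited data.  Body composition is
driven by a single latent adiposity factor z with a cluster-shared random
intercept (intra-cluster correlation ICC): weight, waist circumference and
TPBF are sex-specific affine functions of z plus independent Gaussian
noise, which induces the BMI–TPBF–RFM correlation the downstream ROC and
method-comparison stages rely on.  Family history of obesity and year of
study shift z (latent-scale units), producing odds ratios of the order
reported for those factors; lifestyle flags are generated independent of z
by default, mirroring the null findings for them.

A second generator draws cross-classified counts for two imperfect binary
tests over one population with known prevalence, sensitivities and
specificities, optionally with within-stratum error dependence
(Dendukuri–Joseph covariance form) — the simulation twin of the
latent-class prevalence model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from adipometry.errors import ConfigurationError
from adipometry.latent_class import TwoTestCounts

EXERCISE_LEVELS = ("never", "rarely", "sometimes", "almost_everyday")


@dataclass
class SexAnthro:
    """Per-sex anthropometry targets: base means and noise SDs.

    ``weight_per_z``, ``wc_per_z`` and ``tpbf_per_z`` size the loading of
    each measurement on the latent adiposity factor; marginal SDs are
    sqrt(loading² + noise²) for unit latent SD.
    """

    height_mean: float
    height_sd: float
    weight_base: float
    weight_noise_sd: float
    wc_base: float
    wc_noise_sd: float
    tpbf_base: float
    tpbf_noise_sd: float
    weight_per_z: float = 8.5
    wc_per_z: float = 6.5
    tpbf_per_z: float = 8.5
    # allometry: taller subjects are heavier at equal adiposity, which keeps
    # height variation from acting as pure noise on BMI
    weight_per_height: float = 0.55


# Defaults calibrated to the surveyed cohort's magnitudes: pooled height
# ~166 ± 9 cm, weight ~64 ± 10 kg, WC ~73 ± 7 cm, BMI ~23, TPBF ~25 ± 11
# with the familiar female excess in TPBF and obesity prevalence.
FEMALE_DEFAULT = SexAnthro(
    height_mean=162.0,
    height_sd=6.0,
    weight_base=61.5,
    weight_noise_sd=3.5,
    wc_base=71.5,
    wc_noise_sd=2.5,
    tpbf_base=31.0,
    tpbf_noise_sd=2.0,
)
MALE_DEFAULT = SexAnthro(
    height_mean=172.0,
    height_sd=7.0,
    weight_base=66.0,
    weight_noise_sd=3.5,
    wc_base=74.0,
    wc_noise_sd=2.5,
    tpbf_base=17.5,
    tpbf_noise_sd=2.0,
)


@dataclass
class CohortConfig:
    """Configuration of the synthetic student cohort.

    Defaults reproduce the study conditions: n = 1027 with 573 female,
    six college clusters, ICC 0.1 on the latent adiposity factor.
    """

    n_subjects: int = 1027
    sex_ratio_female: float = 573 / 1027
    female: SexAnthro = field(default_factory=lambda: FEMALE_DEFAULT)
    male: SexAnthro = field(default_factory=lambda: MALE_DEFAULT)
    latent_adiposity_sd: float = 1.0
    fh_obesity_shift: float = 0.75
    per_year_of_study_shift: float = 0.10
    cluster_count: int = 6
    icc: float = 0.1
    # covariate frequencies, matched to the surveyed cohort's margins
    p_fh_obesity: float = 0.11
    p_fh_hypertension: float = 0.18
    p_fh_diabetes: float = 0.20
    p_alcohol: float = 0.07
    p_smoking: float = 0.02
    exercise_probs: tuple = (0.20, 0.31, 0.37, 0.12)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if not 0 <= self.sex_ratio_female <= 1:
            raise ConfigurationError("sex_ratio_female must lie in [0, 1]")
        if self.latent_adiposity_sd <= 0:
            raise ConfigurationError("latent_adiposity_sd must be positive")
        for sex in (self.female, self.male):
            for name in ("height_sd", "weight_noise_sd", "wc_noise_sd", "tpbf_noise_sd"):
                if getattr(sex, name) <= 0:
                    raise ConfigurationError(f"{name} must be strictly positive")
        if self.cluster_count <= 0:
            raise ConfigurationError("cluster_count must be positive")
        if not 0 <= self.icc < 1:
            raise ConfigurationError("icc must lie in [0, 1)")
        for name in ("p_fh_obesity", "p_fh_hypertension", "p_fh_diabetes", "p_alcohol", "p_smoking"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if len(self.exercise_probs) != len(EXERCISE_LEVELS) or not np.isclose(
            sum(self.exercise_probs), 1.0
        ):
            raise ConfigurationError("exercise_probs must be 4 probabilities summing to 1")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic participant table under ``config``.

    Identical config and seed give bitwise-identical tables.  The returned
    frame includes the ground-truth ``latent_adiposity`` column (handy for
    checking the realized ICC); downstream stages ignore it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    n_female = int(round(n * config.sex_ratio_female))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)
    female = sex == "female"

    college = rng.integers(0, config.cluster_count, size=n)
    year = rng.integers(1, 5, size=n)
    age = np.clip(np.rint(16.5 + year + rng.normal(0, 1.2, size=n)), 16, 25).astype(int)

    fh_obesity = rng.random(n) < config.p_fh_obesity
    fh_htn = rng.random(n) < config.p_fh_hypertension
    fh_dm = rng.random(n) < config.p_fh_diabetes
    alcohol = rng.random(n) < config.p_alcohol
    smoking = rng.random(n) < config.p_smoking
    exercise = rng.choice(EXERCISE_LEVELS, size=n, p=config.exercise_probs)

    # latent adiposity: cluster random intercept + individual deviation,
    # partitioned so Var(z) = latent_adiposity_sd² and Corr within cluster = icc
    sd = config.latent_adiposity_sd
    u = rng.normal(0.0, np.sqrt(config.icc) * sd, size=config.cluster_count)
    e = rng.normal(0.0, np.sqrt(1.0 - config.icc) * sd, size=n)
    shift = config.fh_obesity_shift * fh_obesity + config.per_year_of_study_shift * (year - 1)
    z = u[college] + e + shift

    height = np.empty(n)
    weight = np.empty(n)
    wc = np.empty(n)
    tpbf = np.empty(n)
    for is_f, anthro in ((True, config.female), (False, config.male)):
        m = female == is_f
        k = int(m.sum())
        height[m] = rng.normal(anthro.height_mean, anthro.height_sd, size=k)
        weight[m] = (
            anthro.weight_base
            + anthro.weight_per_z * z[m]
            + anthro.weight_per_height * (height[m] - anthro.height_mean)
            + rng.normal(0, anthro.weight_noise_sd, size=k)
        )
        wc[m] = anthro.wc_base + anthro.wc_per_z * z[m] + rng.normal(0, anthro.wc_noise_sd, size=k)
        tpbf[m] = (
            anthro.tpbf_base
            + anthro.tpbf_per_z * z[m]
            + rng.normal(0, anthro.tpbf_noise_sd, size=k)
        )

    # keep measurements physically plausible
    height = np.clip(height, 120.0, 220.0)
    weight = np.clip(weight, 30.0, 180.0)
    wc = np.clip(wc, 45.0, 160.0)
    tpbf = np.clip(tpbf, 3.0, 60.0)

    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": sex,
            "age_years": age,
            "year_of_study": year,
            "college": np.char.add("college_", college.astype(str)),
            "height_cm": np.round(height, 1),
            "weight_kg": np.round(weight, 1),
            "wc_cm": np.round(wc, 1),
            "tpbf_pct": np.round(tpbf, 1),
            "alcohol": alcohol,
            "smoking": smoking,
            "exercise": exercise,
            "fh_hypertension": fh_htn,
            "fh_diabetes": fh_dm,
            "fh_obesity": fh_obesity,
            "latent_adiposity": z,
        }
    )


@dataclass
class TwoTestSimConfig:
    """Ground truth for the two-test count generator.

    ``dependence_pos``/``dependence_neg`` are the within-stratum error
    covariances added to the product of conditionals (zero = conditional
    independence, the assumption of the fitted model).
    """

    n: int
    prevalence: float
    sens1: float
    spec1: float
    sens2: float
    spec2: float
    dependence_pos: float = 0.0
    dependence_neg: float = 0.0
    seed: int = 0

    def stratum_cell_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """Joint (p11, p10, p01, p00) within the diseased / healthy strata."""
        d1, d2 = self.sens1, self.sens2
        g1, g2 = self.spec1, self.spec2
        cp, cn = self.dependence_pos, self.dependence_neg
        pos = np.array(
            [
                d1 * d2 + cp,
                d1 * (1 - d2) - cp,
                (1 - d1) * d2 - cp,
                (1 - d1) * (1 - d2) + cp,
            ]
        )
        neg = np.array(
            [
                (1 - g1) * (1 - g2) + cn,
                (1 - g1) * g2 - cn,
                g1 * (1 - g2) - cn,
                g1 * g2 + cn,
            ]
        )
        return pos, neg

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        for name in ("prevalence", "sens1", "spec1", "sens2", "spec2"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        pos, neg = self.stratum_cell_probs()
        if np.any(pos < -1e-12) or np.any(neg < -1e-12) or np.any(pos > 1 + 1e-12) or np.any(neg > 1 + 1e-12):
            raise ConfigurationError(
                "dependence terms produce conditional cell probabilities outside [0, 1]"
            )


def generate_two_test_counts(config: TwoTestSimConfig) -> TwoTestCounts:
    """Draw cross-classified counts (n11, n10, n01, n00) with known truth.

    True status is Bernoulli(prevalence) per subject; test outcomes follow
    the stratum-conditional joint distribution (independent errors when
    both dependence terms are zero).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pos = rng.binomial(config.n, config.prevalence)
    pos_p, neg_p = config.stratum_cell_probs()
    pos_p = np.clip(pos_p, 0.0, 1.0)
    neg_p = np.clip(neg_p, 0.0, 1.0)
    cells = rng.multinomial(n_pos, pos_p / pos_p.sum()) + rng.multinomial(
        config.n - n_pos, neg_p / neg_p.sum()
    )
    return TwoTestCounts(*(int(c) for c in cells))


def simulate_logistic_outcome(
    design: pd.DataFrame | np.ndarray,
    intercept: float,
    coefs,
    seed: int = 0,
) -> np.ndarray:
    """Bernoulli outcomes from a logistic model on ``design``.

    ``coefs`` is a mapping column → log-odds coefficient (DataFrame input)
    or a vector (array input).  Used to build cohorts whose covariates
    multiply the odds by known factors, e.g. exp(coef) = 3.5 for family
    history of obesity.
    """
    rng = np.random.default_rng(seed)
    if isinstance(design, pd.DataFrame):
        eta = np.full(len(design), float(intercept))
        for col, beta in dict(coefs).items():
            eta += beta * design[col].to_numpy(dtype=float)
    else:
        eta = intercept + np.asarray(design, dtype=float) @ np.asarray(coefs, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(p)) < p).astype(int)


def cohort_config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    for sex in ("female", "male"):
        if sex in d and isinstance(d[sex], dict):
            d[sex] = SexAnthro(**d[sex])
    if "exercise_probs" in d:
        d["exercise_probs"] = tuple(d["exercise_probs"])
    return CohortConfig(**d)
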