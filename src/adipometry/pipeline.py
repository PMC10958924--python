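"""End-to-end orchestration: simulate → indices → compare → thresholds →
prevalence → risks.

Each stage reads its inputs from the output directory and writes plain
CSV/JSON/YAML intermediates, so any stage can be re-run from the on-disk
artifacts of its predecessors; a manifest records the package version,
seed, and a hash of the configuration.  The stage order mirrors the
analysis sequence of the study: anthropometric indices and WHO BMI classes
first, Passing–Bablok agreement of TPBF and RFM with BMI, ROC-derived
sex/age-band cutoffs, the Bayesian latent-class combination of the TPBF
and RFM calls into one posterior prevalence per sex and endpoint, and
finally the logistic risk-factor table.  Thresholds are derived on the
same cohort they are applied to, as in the source analysis (in-sample).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import adipometry
from adipometry.errors import ConfigurationError
from adipometry.indices import (
    ENDPOINTS,
    classify_cohort,
    index_table,
    read_cohort_csv,
    round_half_up,
    summarize_bmi_prevalence,
    write_cohort_csv,
)
from adipometry.latent_class import (
    PriorSpec,
    TwoTestCounts,
    posterior_predictive_check,
    sample_posterior,
)
from adipometry.passing_bablok import concordance_three_way, fit_passing_bablok
from adipometry.risk import risk_table_frame, run_risk_table
from adipometry.roc import CutoffTable, derive_cutoff_table
from adipometry.synthetic import (
    CohortConfig,
    cohort_config_from_dict,
    cohort_config_to_dict,
    generate_cohort,
)

STAGES = ("simulate", "indices", "compare", "thresholds", "prevalence", "risks")

#: Sampler presets: "desk" for routine runs, "paper" mirroring the source
#: analysis's 20 chains × 25k warmup / 25k kept draws.
SAMPLER_PRESETS = {
    "desk": {"chains": 4, "warmup": 2000, "iters": 2000},
    "paper": {"chains": 20, "warmup": 25000, "iters": 25000},
}


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; exactly one input source."""

    cohort_csv: str | None = None
    cohort: CohortConfig | None = None
    prior_ess: float = 50.0
    pi_prior: tuple[float, float] = (1.0, 1.0)
    sampler_preset: str = "desk"
    chains: int | None = None
    warmup: int | None = None
    iters: int | None = None
    seed: int = 0
    risk_outcome: str = "overweight_or_obese"

    def __post_init__(self):
        if (self.cohort_csv is None) == (self.cohort is None):
            raise ConfigurationError("specify exactly one of cohort_csv or cohort")
        if self.sampler_preset not in SAMPLER_PRESETS:
            raise ConfigurationError(f"unknown sampler preset {self.sampler_preset!r}")
        if self.prior_ess <= 0:
            raise ConfigurationError("prior_ess must be positive")
        if self.risk_outcome not in ("overweight_or_obese", "obese"):
            raise ConfigurationError("risk_outcome must be 'overweight_or_obese' or 'obese'")

    def sampler_settings(self) -> dict:
        out = dict(SAMPLER_PRESETS[self.sampler_preset])
        for key in ("chains", "warmup", "iters"):
            if getattr(self, key) is not None:
                out[key] = getattr(self, key)
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = cohort_config_to_dict(self.cohort)
        d["pi_prior"] = list(self.pi_prior)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = cohort_config_from_dict(d["cohort"])
        if "pi_prior" in d:
            d["pi_prior"] = tuple(d["pi_prior"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def _path(outdir, name: str) -> Path:
    return Path(outdir) / name


def stage_simulate(config: PipelineConfig, outdir) -> Path:
    """Materialize the cohort CSV (synthetic or copied from the input)."""
    out = _path(outdir, "cohort.csv")
    if config.cohort is not None:
        write_cohort_csv(generate_cohort(config.cohort), out)
    else:
        write_cohort_csv(read_cohort_csv(config.cohort_csv), out)
    return out


def stage_indices(config: PipelineConfig, outdir) -> Path:
    """BMI/RFM values and WHO BMI classes per subject (pre-cutoff)."""
    records = read_cohort_csv(_path(outdir, "cohort.csv"))
    base = index_table(records)
    out = _path(outdir, "indices_base.csv")
    base.to_csv(out, index=False)
    summarize_bmi_prevalence(base).to_csv(_path(outdir, "bmi_prevalence.csv"), index=False)
    return out


def stage_compare(config: PipelineConfig, outdir) -> Path:
    """Passing–Bablok fits of TPBF and RFM against BMI, per sex."""
    records = read_cohort_csv(_path(outdir, "cohort.csv"))
    base = pd.read_csv(_path(outdir, "indices_base.csv"))
    merged = base.merge(records[["id", "tpbf_pct"]], on="id")
    report = {}
    for sex, df in merged.groupby("sex"):
        bmi = df["bmi_kg_m2"].to_numpy()
        for name, y in (("tpbf", df["tpbf_pct"].to_numpy()), ("rfm", df["rfm"].to_numpy())):
            report[f"{sex}_{name}_vs_bmi"] = fit_passing_bablok(bmi, y).as_dict()
    out = _path(outdir, "passing_bablok.json")
    out.write_text(json.dumps(report, indent=2, sort_keys=True))
    return out


def stage_thresholds(config: PipelineConfig, outdir) -> Path:
    """ROC-derived TPBF/RFM cutoff table per sex × age band × endpoint."""
    records = read_cohort_csv(_path(outdir, "cohort.csv"))
    base = pd.read_csv(_path(outdir, "indices_base.csv"))
    table = derive_cutoff_table(records, base)
    out = _path(outdir, "cutoffs.yaml")
    table.to_yaml(out)
    return out


def _classified(config: PipelineConfig, outdir) -> pd.DataFrame:
    records = read_cohort_csv(_path(outdir, "cohort.csv"))
    cutoff_path = _path(outdir, "cutoffs.yaml")
    if not cutoff_path.exists():
        raise ConfigurationError(
            "prevalence/risks requested but cutoffs.yaml is missing; run the thresholds stage"
        )
    cutoffs = CutoffTable.from_yaml(cutoff_path)
    classified = classify_cohort(records, cutoffs.tpbf, cutoffs.rfm)
    classified.to_csv(_path(outdir, "indices.csv"), index=False)
    return classified


def stage_prevalence(config: PipelineConfig, outdir) -> Path:
    """Latent-class posterior prevalence per sex × endpoint.

    The TPBF and RFM binary calls are cross-classified per sex, and the
    test-accuracy priors are centered at the ROC-stage sensitivities and
    specificities (averaged over the sex's age bands) with prior effective
    sample size ``prior_ess``.
    """
    classified = _classified(config, outdir)
    cutoffs = CutoffTable.from_yaml(_path(outdir, "cutoffs.yaml"))
    settings = config.sampler_settings()
    report = {}
    concordance = {}
    for sex, df in classified.groupby("sex"):
        obese_bmi = (df["bmi_class"] == "obese").to_numpy()
        ow_bmi = (df["bmi_class"] != "normal").to_numpy()
        for endpoint in ENDPOINTS:
            t1 = df[f"tpbf_positive_{endpoint}"].to_numpy()
            t2 = df[f"rfm_positive_{endpoint}"].to_numpy()
            counts = TwoTestCounts.from_labels(t1, t2)

            # prior centers: mean ROC sens/spec across the sex's age bands
            def _center(idx, key):
                vals = [
                    cutoffs.entries[(idx, sex, band, endpoint)][key] / 100.0
                    for band in ("15-19", "20-25")
                    if (idx, sex, band, endpoint) in cutoffs.entries
                ]
                return float(np.clip(np.mean(vals), 0.02, 0.98))

            priors = PriorSpec.from_accuracy(
                sens1=_center("tpbf", "sensitivity_pct"),
                spec1=_center("tpbf", "specificity_pct"),
                sens2=_center("rfm", "sensitivity_pct"),
                spec2=_center("rfm", "specificity_pct"),
                ess=config.prior_ess,
                pi=config.pi_prior,
            )
            stratum_tag = int(
                hashlib.sha256(f"{sex}_{endpoint}".encode()).hexdigest()[:4], 16
            )
            post = sample_posterior(
                counts, priors, seed=config.seed + stratum_tag, **settings
            )
            summ = post.summary()
            ppc = posterior_predictive_check(
                post, counts, n_rep=min(1000, post.chains * post.iterations), seed=config.seed
            )
            report[f"{sex}_{endpoint}"] = {
                "counts": {k: int(v) for k, v in zip(("n11", "n10", "n01", "n00"), counts.as_array())},
                "priors": {k: list(v) for k, v in priors.as_dict().items()},
                "posterior": {
                    p: {
                        "mean": summ.loc[p, "mean"],
                        "ci_low": summ.loc[p, "ci_low"],
                        "ci_high": summ.loc[p, "ci_high"],
                        "rhat": summ.loc[p, "rhat"],
                    }
                    for p in summ.index
                },
                "warnings": post.warnings,
                "ppc": ppc.to_dict(orient="records"),
            }
            ref = obese_bmi if endpoint == "obese" else ow_bmi
            prop, lower = concordance_three_way(ref, t1, t2)
            concordance[f"{sex}_{endpoint}"] = {
                "proportion": prop,
                "lower_95": lower,
            }
    out = _path(outdir, "prevalence.json")
    out.write_text(json.dumps(report, indent=2, sort_keys=True))
    _path(outdir, "concordance.json").write_text(
        json.dumps(concordance, indent=2, sort_keys=True)
    )
    summarize_prevalence_files(outdir).to_csv(
        _path(outdir, "prevalence_summary.csv"), index=False
    )
    return out


def stage_risks(config: PipelineConfig, outdir) -> Path:
    """Logistic risk-factor table across the three outcome definitions."""
    records = read_cohort_csv(_path(outdir, "cohort.csv"))
    indices_path = _path(outdir, "indices.csv")
    if not indices_path.exists():
        _classified(config, outdir)
    classified = pd.read_csv(indices_path)
    fits = run_risk_table(classified, records, outcome=config.risk_outcome)
    out = _path(outdir, "risk_table.csv")
    risk_table_frame(fits).to_csv(out, index=False)
    return out


def summarize_prevalence(posteriors: dict, bmi_prevalences: dict) -> pd.DataFrame:
    """Side-by-side crude BMI prevalence vs combined posterior per stratum.

    ``posteriors`` maps stratum → {"mean": ..., "ci_low": ..., "ci_high": ...}
    (proportions); ``bmi_prevalences`` maps the same strata → crude
    proportion under the BMI criterion.  Percentages are reported
    half-up to one decimal.
    """
    if not posteriors:
        raise ConfigurationError("no posterior summaries supplied")
    missing = set(posteriors) ^ set(bmi_prevalences)
    if missing:
        raise ConfigurationError(f"stratum mismatch between inputs: {sorted(missing)}")
    rows = []
    for stratum in sorted(posteriors):
        p = posteriors[stratum]
        rows.append(
            {
                "stratum": stratum,
                "crude_bmi_pct": round_half_up(100 * bmi_prevalences[stratum], 1),
                "combined_posterior_mean_pct": round_half_up(100 * p["mean"], 1),
                "ci_low_pct": round_half_up(100 * p["ci_low"], 1),
                "ci_high_pct": round_half_up(100 * p["ci_high"], 1),
            }
        )
    return pd.DataFrame(rows)


def summarize_prevalence_files(outdir) -> pd.DataFrame:
    """Build the comparison table from the on-disk stage outputs."""
    report = json.loads(_path(outdir, "prevalence.json").read_text())
    base = pd.read_csv(_path(outdir, "bmi_prevalence.csv"))
    posteriors = {
        stratum: entry["posterior"]["pi"] for stratum, entry in report.items()
    }
    crude = {}
    for stratum in posteriors:
        sex, endpoint = stratum.rsplit("_", 1)
        cat = ">=30.0" if endpoint == "obese" else "overweight_or_obese"
        row = base[(base["sex"] == sex) & (base["age_band"] == "total") & (base["category"] == cat)]
        crude[stratum] = float(row["count"].iloc[0] / row["n"].iloc[0])
    return summarize_prevalence(posteriors, crude)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages in order; returns the manifest.

    Stage failures halt the run with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "adipometry",
        "version": adipometry.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": [],
    }
    stage_fns = {
        "simulate": stage_simulate,
        "indices": stage_indices,
        "compare": stage_compare,
        "thresholds": stage_thresholds,
        "prevalence": stage_prevalence,
        "risks": stage_risks,
    }
    for name in STAGES:
        try:
            path = stage_fns[name](config, outdir)
        except Exception as err:
            manifest["failed_stage"] = name
            _path(outdir, "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True)
            )
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        manifest["stages"].append({"stage": name, "output": Path(path).name})
    _path(outdir, "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
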