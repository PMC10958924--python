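"""ROC analysis and Youden-optimal cutoffs for TPBF and RFM against BMI.

TPBF and RFM thresholds are anchored to the WHO BMI definitions by
treating the BMI class as the reference label and sweeping every cutoff of
the index: the "optimal" cutoff maximizes Youden's J = sensitivity +
specificity − 1, reported with the strict "> c" convention (c is the
highest value still classified negative at the optimum).  The AUC is
computed both as the trapezoidal area of the empirical curve and as the
tie-corrected Mann–Whitney concordance probability; the two are identical
by construction and the identity is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from adipometry.errors import ConfigurationError, DomainError
from adipometry.indices import AGE_BANDS, ENDPOINTS


@dataclass
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    curve_points: np.ndarray  # (k, 2) of (fpr, tpr), (0,0) → (1,1)
    thresholds: np.ndarray  # "> t" cutoffs aligned with sens/spec below
    sensitivity: np.ndarray  # per threshold, proportions
    specificity: np.ndarray
    cutoff: float = float("nan")
    sensitivity_pct: float = float("nan")
    specificity_pct: float = float("nan")


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = labels.astype(bool)
    if not pos.any():
        raise DomainError("no positive labels: ROC undefined")
    if pos.all():
        raise DomainError("no negative labels: ROC undefined")
    return pos, ~pos


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC curve sweeping every distinct score threshold.

    For each distinct score value t the rule "positive iff score > t" is
    evaluated; ties are grouped.  The returned curve runs from (0, 0)
    (cutoff above the maximum) to (1, 1) (everything positive), and the
    AUC is its trapezoidal area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise DomainError("scores and labels must have equal length")
    pos, neg = _check_labels(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())

    thresholds = np.unique(scores)  # ascending; rule is score > t
    sorted_pos = np.sort(scores[pos])
    sorted_neg = np.sort(scores[neg])
    sens = 1.0 - np.searchsorted(sorted_pos, thresholds, side="right") / n_pos
    spec = np.searchsorted(sorted_neg, thresholds, side="right") / n_neg

    fpr = 1.0 - spec
    tpr = sens
    # descending threshold order gives ascending fpr; prepend all-positive point
    order = np.argsort(-thresholds, kind="stable")
    curve = np.vstack(
        [
            np.column_stack([fpr[order], tpr[order]]),
            [1.0, 1.0],
        ]
    )
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return ROCResult(
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        curve_points=curve,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
    )


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann–Whitney concordance (#concordant + ½·#tied)/(n⁺·n⁻).

    Equals the trapezoidal area of :func:`roc_curve` exactly, ties and all.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _check_labels(labels)
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_optimal_cutoff(curve: ROCResult) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J, tie-broken toward higher specificity.

    Returns (cutoff, sensitivity %, specificity %) with the "> cutoff"
    positivity convention; the curve object is updated in place as well.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    # higher threshold → higher specificity; take the largest tied cutoff
    i = best[np.argmax(curve.specificity[best])]
    curve.cutoff = float(curve.thresholds[i])
    curve.sensitivity_pct = float(100.0 * curve.sensitivity[i])
    curve.specificity_pct = float(100.0 * curve.specificity[i])
    return curve.cutoff, curve.sensitivity_pct, curve.specificity_pct


@dataclass
class CutoffTable:
    """ROC-derived cutoffs per (index, sex, age band, endpoint).

    ``entries[(index, sex, band, endpoint)]`` holds cutoff/AUC/sens/spec;
    ``tpbf`` / ``rfm`` expose the plain (sex, band, endpoint) → cutoff
    mappings consumed by :func:`adipometry.indices.classify_cohort`.
    """

    entries: dict = field(default_factory=dict)

    def _mapping(self, index_name: str) -> dict:
        return {
            (sex, band, ep): e["cutoff"]
            for (idx, sex, band, ep), e in self.entries.items()
            if idx == index_name
        }

    @property
    def tpbf(self) -> dict:
        return self._mapping("tpbf")

    @property
    def rfm(self) -> dict:
        return self._mapping("rfm")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"index": idx, "sex": sex, "age_band": band, "endpoint": ep, **e}
            for (idx, sex, band, ep), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def to_yaml(self, path) -> None:
        payload = [
            {"index": idx, "sex": sex, "age_band": band, "endpoint": ep, **e}
            for (idx, sex, band, ep), e in sorted(self.entries.items())
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CutoffTable":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        entries = {}
        for row in payload:
            key = (row.pop("index"), row.pop("sex"), row.pop("age_band"), row.pop("endpoint"))
            entries[key] = row
        return cls(entries=entries)


def derive_cutoff_table(records: pd.DataFrame, classified: pd.DataFrame) -> CutoffTable:
    """Derive the 16 stratified cutoffs (2 indices × 2 sexes × 2 bands × 2 endpoints).

    ``records`` supplies the TPBF scores; ``classified`` (from
    :func:`adipometry.indices.classify_cohort` or any table with id, sex,
    age_band, bmi_kg_m2, rfm, bmi_class) supplies RFM and the BMI-anchored
    labels: endpoint "overweight" labels BMI ≥ 25, "obese" labels BMI ≥ 30.
    Strata with an empty class are collected and reported by name.
    """
    merged = classified.merge(records[["id", "tpbf_pct"]], on="id")
    table = CutoffTable()
    problems = []
    for sex in sorted(merged["sex"].unique()):
        for band in AGE_BANDS:
            stratum = merged[(merged["sex"] == sex) & (merged["age_band"] == band)]
            if stratum.empty:
                problems.append(f"{sex}/{band}: empty stratum")
                continue
            for endpoint in ENDPOINTS:
                if endpoint == "obese":
                    labels = (stratum["bmi_class"] == "obese").to_numpy()
                else:
                    labels = (stratum["bmi_class"] != "normal").to_numpy()
                for index_name, scores in (
                    ("tpbf", stratum["tpbf_pct"].to_numpy(dtype=float)),
                    ("rfm", stratum["rfm"].to_numpy(dtype=float)),
                ):
                    try:
                        curve = roc_curve(scores, labels)
                    except DomainError as err:
                        problems.append(f"{index_name}/{sex}/{band}/{endpoint}: {err}")
                        continue
                    cutoff, sens, spec = youden_optimal_cutoff(curve)
                    table.entries[(index_name, sex, band, endpoint)] = {
                        "cutoff": cutoff,
                        "auc": curve.auc,
                        "sensitivity_pct": sens,
                        "specificity_pct": spec,
                        "n_pos": curve.n_pos,
                        "n_neg": curve.n_neg,
                    }
    if problems:
        raise ConfigurationError("cutoff derivation failed for: " + "; ".join(problems))
    return table
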