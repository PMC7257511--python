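"""Diagnostic-test metric suite, ROC/AUC and Ki-67 index agreement.

The suite mirrors the twelve standard indicators of a binary diagnostic
test (positive class = invasive ductal carcinoma throughout): sensitivity,
specificity, balance accuracy, accuracy, positive/negative likelihood
ratios, predictive values, diagnostic index, Youden index, and the false
positive/negative rates. Internal values are never rounded; the report
layer rounds to 4 decimals (2 for likelihood ratios).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricSuite",
    "metric_suite",
    "metric_suite_from_rates",
    "roc_auc",
    "index_agreement",
    "write_metric_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fn < 1 or self.tn + self.fp < 1:
            raise ValueError("need at least one actual positive and one actual negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSuite:
    sensitivity: float
    specificity: float
    balance_accuracy: float
    accuracy: float  # nan when prevalence unknown
    plr: float  # positive likelihood ratio; inf when specificity = 1
    nlr: float
    ppv: float  # nan when undefined / prevalence unknown
    npv: float
    diagnostic_index: float
    youden_index: float
    fpr: float
    fnr: float

    def as_dict(self, ndigits: int | None = None) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if ndigits is not None:
            d = {k: (round(v, ndigits) if math.isfinite(v) else v) for k, v in d.items()}
        return d


def _derived(sensitivity: float, specificity: float, accuracy: float = math.nan,
             ppv: float = math.nan, npv: float = math.nan) -> MetricSuite:
    if specificity == 1.0:
        warnings.warn("specificity = 1: positive likelihood ratio is infinite",
                      stacklevel=3)
        plr = math.inf
    else:
        plr = sensitivity / (1.0 - specificity)
    nlr = (1.0 - sensitivity) / specificity if specificity > 0 else math.inf
    return MetricSuite(
        sensitivity=sensitivity,
        specificity=specificity,
        balance_accuracy=(sensitivity + specificity) / 2.0,
        accuracy=accuracy,
        plr=plr,
        nlr=nlr,
        ppv=ppv,
        npv=npv,
        diagnostic_index=sensitivity + specificity,
        youden_index=sensitivity + specificity - 1.0,
        fpr=1.0 - specificity,
        fnr=1.0 - sensitivity,
    )


def metric_suite(counts: ConfusionCounts) -> MetricSuite:
    """All twelve indicators from a confusion matrix."""
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        warnings.warn("no predicted positives: PPV undefined", stacklevel=2)
        ppv = math.nan
    else:
        ppv = counts.tp / (counts.tp + counts.fp)
    if counts.tn + counts.fn == 0:
        warnings.warn("no predicted negatives: NPV undefined", stacklevel=2)
        npv = math.nan
    else:
        npv = counts.tn / (counts.tn + counts.fn)
    return _derived(sens, spec, accuracy=accuracy, ppv=ppv, npv=npv)


def metric_suite_from_rates(sensitivity: float, specificity: float) -> MetricSuite:
    """The indicators derivable from (sensitivity, specificity) alone;
    prevalence-dependent fields (accuracy, PPV, NPV) are NaN."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return _derived(float(sensitivity), float(specificity))


def roc_auc(scores, truth) -> float:
    """AUC as the Mann-Whitney rank statistic: the probability that a random
    positive outranks a random negative, ties counted half. Equals the
    trapezoidal area under the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D arrays")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def index_agreement(predicted: float, reference: float,
                    tolerance: float = 1.0) -> tuple[bool, float]:
    """Agreement of two Ki-67 indices (%) at the given tolerance in
    percentage points (competition rule: accurate to 1%). Returns
    (agree, absolute error)."""
    for name, v in (("predicted", predicted), ("reference", reference)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} index must lie in [0, 100]")
    error = abs(predicted - reference)
    return error <= tolerance, error


def write_metric_report(path: str | Path, suite: MetricSuite) -> None:
    """Write the suite as JSON and as a two-column indicator/result CSV."""
    path = Path(path)
    rounded = suite.as_dict(ndigits=4)
    rounded["plr"] = round(suite.plr, 2) if math.isfinite(suite.plr) else suite.plr
    rounded["nlr"] = round(suite.nlr, 2) if math.isfinite(suite.nlr) else suite.nlr
    path.with_suffix(".json").write_text(
        json.dumps({k: (None if isinstance(v, float) and math.isnan(v) else v)
                    for k, v in rounded.items()}, indent=2) + "\n")
    pd.DataFrame({"Test Indicators": list(rounded), "Test Results": list(rounded.values())}
                 ).to_csv(path.with_suffix(".csv"), index=False)
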