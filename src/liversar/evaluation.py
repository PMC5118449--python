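"""Classification-performance statistics for the hepatotoxicity model.

Unpredicted ("unknown") compounds are excluded from all four headline
metrics and reported separately as coverage, so accuracy, sensitivity,
specificity and MCC are computed over predicted compounds only.  Percent
values are reported with round-half-up to the integer, the convention the
printed performance tables follow most closely.

Also provides the likelihood ratio LR = (TP/FP) * (negatives/positives)
used to score mined fragments, and per-alert occurrence statistics (for a
non-hepatotoxic alert the "TP" column plays the TN role).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .chem_io import (
    Activity,
    ConsistencyError,
    LabeledDataset,
    ParameterError,
)
from .alert_engine import AlertStats, RuleSet, StructuralAlert, match
from .classifier import Prediction, VERDICT_UNKNOWN, predict_dataset


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN over predicted compounds plus the unpredicted count."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_unknown: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.n_unknown) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_total(self) -> int:
        return self.n_predicted + self.n_unknown


def confusion(
    predictions: list[Prediction], labels: LabeledDataset
) -> ConfusionCounts:
    """Tally predictions against experimental labels.

    Positive = hepatotoxic.  Unknown verdicts are counted only in
    ``n_unknown``.
    """
    tp = fp = tn = fn = unk = 0
    for p in predictions:
        if p.record_id not in labels:
            raise ConsistencyError(
                f"prediction for unknown record {p.record_id!r}"
            )
        truth = labels[p.record_id].activity_label
        if truth is Activity.UNLABELED:
            raise ConsistencyError(f"record {p.record_id!r} is unlabeled")
        if p.verdict == VERDICT_UNKNOWN:
            unk += 1
        elif p.verdict is Activity.HEPATOTOXIC:
            if truth is Activity.HEPATOTOXIC:
                tp += 1
            else:
                fp += 1
        else:
            if truth is Activity.NON_HEPATOTOXIC:
                tn += 1
            else:
                fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_unknown=unk)


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN) / predicted compounds."""
    if c.n_predicted == 0:
        raise ParameterError("accuracy undefined: no compound was predicted")
    return (c.tp + c.tn) / c.n_predicted


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP+FN)."""
    if c.tp + c.fn == 0:
        raise ParameterError("sensitivity undefined: no predicted positives")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN+FP)."""
    if c.tn + c.fp == 0:
        raise ParameterError("specificity undefined: no predicted negatives")
    return c.tn / (c.tn + c.fp)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    ((TP*TN) - (FP*FN)) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); returns 0
    when any denominator factor is zero (standard convention).
    """
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return ((c.tp * c.tn) - (c.fp * c.fn)) / math.sqrt(denom)


def coverage(c: ConfusionCounts) -> float:
    """Fraction of compounds receiving a verdict other than unknown."""
    if c.n_total == 0:
        raise ParameterError("coverage undefined: empty evaluation")
    return c.n_predicted / c.n_total


def percent(x: float) -> int:
    """Report a proportion as an integer percentage, rounding half up."""
    return int(math.floor(100.0 * x + 0.5))


@dataclass
class MetricsReport:
    """The four headline metrics plus coverage, on the [0, 1] scale."""

    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    coverage: float

    def as_printed(self) -> dict:
        """Percent-scale integers and two-decimal MCC, as reported."""
        return {
            "accuracy_pct": percent(self.accuracy),
            "sensitivity_pct": percent(self.sensitivity),
            "specificity_pct": percent(self.specificity),
            "mcc": round(self.mcc, 2),
            "coverage_pct": percent(self.coverage),
        }


def metrics_report(c: ConfusionCounts) -> MetricsReport:
    return MetricsReport(
        accuracy=accuracy(c),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        mcc=mcc(c),
        coverage=coverage(c),
    )


def evaluate(
    ds: LabeledDataset, rules: RuleSet
) -> tuple[ConfusionCounts, MetricsReport]:
    """Screen, classify and score a labeled dataset in one step."""
    counts = confusion(predict_dataset(ds, rules), ds)
    return counts, metrics_report(counts)


def likelihood_ratio(
    tp: int, fp: int, positives: int, negatives: int
) -> float:
    """LR = (TP/FP) * (negatives/positives).

    The rule-precision statistic used to rank mined fragments: how much a
    fragment is enriched in one class after correcting for class balance.
    ``fp == 0`` returns positive infinity (a fragment never seen in the
    wrong class).
    """
    if positives <= 0 or negatives <= 0:
        raise ParameterError(
            "likelihood_ratio needs positives > 0 and negatives > 0"
        )
    if tp < 0 or fp < 0:
        raise ParameterError("tp and fp must be non-negative")
    if fp == 0:
        return math.inf
    return (tp / fp) * (negatives / positives)


@dataclass
class AlertPerformance:
    """Occurrence statistics of one alert on one labeled dataset."""

    alert_id: str
    occurrences: int
    tp: int
    fp: int

    @property
    def tp_pct(self) -> Optional[float]:
        if self.occurrences == 0:
            return None
        return 100.0 * self.tp / self.occurrences


def alert_performance(
    alert: StructuralAlert, ds: LabeledDataset
) -> AlertPerformance:
    """Count matched compounds and how many carry the alert's own label.

    ``occurrences`` counts compounds (not embeddings); ``tp`` counts
    matched compounds whose experimental label equals the alert's
    predicted activity, so for non-hepatotoxic alerts it is the TN count.
    """
    occ = tp = 0
    for r in ds:
        if match(r.smiles_canonical, alert):
            occ += 1
            if r.activity_label is alert.predicted_activity:
                tp += 1
    return AlertPerformance(
        alert_id=alert.alert_id, occurrences=occ, tp=tp, fp=occ - tp
    )
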