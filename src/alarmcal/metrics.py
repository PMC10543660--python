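"""Clinically tailored alarm metrics.

Seizure-prediction systems are judged event-wise, not sample-wise: one
alarm anywhere inside a seizure's preictal window warns the patient (a
true positive), while an uninterrupted run of alarm samples outside any
preictal window is a single false alarm.  Accordingly:

* sensitivity = 100 * TP / (TP + FN), pooled over records, where TP counts
  seizures with at least one preictal alarm;
* false alarm rate = false-positive alarm events per non-preictal hour —
  a conservative definition under which alarms during ictal or "nearly
  preictal" time still count as false.

The aggregator reproduces per-record and summary arithmetic for report
tables: pooled sensitivity, duration-weighted total false alarm rates, and
unweighted or duration-weighted mean false-alarm-rate reduction.  Reported
percentages are rounded to the nearest integer; raw values are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedMetricError
from .series import BinarySeries

__all__ = [
    "RecordEvaluation",
    "RecordComparison",
    "AggregateReport",
    "detect_alarm_events",
    "evaluate_record",
    "sensitivity",
    "false_alarm_rate",
    "reduction_percent",
    "pointwise_accuracy",
    "aggregate",
    "parse_hms",
    "write_report_csv",
    "read_comparison_table",
]


def parse_hms(text: str) -> float:
    """Parse a ``H:MM:SS`` duration into hours."""
    h, m, s = (int(part) for part in text.split(":"))
    return h + m / 60.0 + s / 3600.0


def detect_alarm_events(series: BinarySeries) -> list[tuple[int, int]]:
    """Maximal runs of consecutive ones as half-open ``(start, end)``
    sample intervals, 0-based."""
    v = series.values
    edges = np.flatnonzero(np.diff(np.concatenate(([0], v, [0]))))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


@dataclass(frozen=True)
class RecordEvaluation:
    """Event counts and exposure for one record under one set of alarms."""

    n_seizures: int
    n_predicted: int
    false_positive_events: int
    non_preictal_hours: float
    record_duration_hours: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_predicted <= self.n_seizures):
            raise InvalidInputError("need 0 <= n_predicted <= n_seizures")
        if self.false_positive_events < 0:
            raise InvalidInputError("false_positive_events must be >= 0")
        if self.non_preictal_hours < 0 or self.record_duration_hours < 0:
            raise InvalidInputError("durations must be >= 0")
        if self.non_preictal_hours > self.record_duration_hours + 1e-9:
            raise InvalidInputError("non-preictal time cannot exceed the record duration")

    @property
    def far(self) -> float:
        return false_alarm_rate(self.false_positive_events, self.non_preictal_hours)


def evaluate_record(prediction: BinarySeries, label: BinarySeries) -> RecordEvaluation:
    """Score one record's alarms against its preictal labels.

    Each maximal run of label ones is one seizure's preictal window; it is
    predicted when at least one alarm sample falls inside it.  An alarm
    event containing any non-preictal sample is a false positive.  Sample
    periods are in seconds.
    """
    if len(prediction) != len(label) or prediction.sample_period != label.sample_period:
        raise InvalidInputError("prediction and label must share length and sample period")
    seizures = detect_alarm_events(label)
    pred = prediction.values
    neg = label.values == 0
    n_predicted = sum(1 for a, b in seizures if pred[a:b].any())
    fp = sum(1 for a, b in detect_alarm_events(prediction) if neg[a:b].any())
    hours_per_sample = label.sample_period / 3600.0
    return RecordEvaluation(
        n_seizures=len(seizures),
        n_predicted=n_predicted,
        false_positive_events=fp,
        non_preictal_hours=float(neg.sum()) * hours_per_sample,
        record_duration_hours=len(label) * hours_per_sample,
    )


def sensitivity(evaluations: Sequence[RecordEvaluation]) -> float:
    """Pooled event-based sensitivity in percent: 100 * TP / (TP + FN)."""
    total = sum(e.n_seizures for e in evaluations)
    if total == 0:
        raise UndefinedMetricError("sensitivity undefined with zero seizures")
    predicted = sum(e.n_predicted for e in evaluations)
    return 100.0 * predicted / total


def false_alarm_rate(false_positive_events: int, non_preictal_hours: float) -> float:
    """False positives per non-preictal hour."""
    if non_preictal_hours <= 0:
        raise UndefinedMetricError("false alarm rate undefined with zero exposure")
    return false_positive_events / non_preictal_hours


def reduction_percent(raw_rate: float, calibrated_rate: float) -> float:
    """Relative false-alarm-rate reduction, 100 * (raw - cal) / raw.

    Defined only for raw_rate > 0 (it is 100 when calibration removes all
    alarms).  Returned unrounded; reports round to the nearest integer.
    """
    if raw_rate <= 0:
        raise UndefinedMetricError("reduction undefined when the raw rate is zero")
    return 100.0 * (raw_rate - calibrated_rate) / raw_rate


def pointwise_accuracy(prediction: BinarySeries, label: BinarySeries) -> float:
    """Fraction of matching samples; both series must be at the same
    temporal resolution (pool labels identically when pooling is on)."""
    if len(prediction) != len(label):
        raise InvalidInputError("prediction and label lengths differ")
    return float((prediction.values == label.values).mean())


# ---------------------------------------------------------------------------
# raw-vs-calibrated comparison rows and their aggregation


@dataclass(frozen=True)
class RecordComparison:
    """One report row: a record's raw vs calibrated alarm performance.

    ``reduction_pct`` may carry an externally reported (already rounded)
    value; when ``None`` it is computed from the two rates and rounded.
    Rows can come from :func:`evaluate_record` pairs or from a published
    table's printed columns.
    """

    label: str
    duration_hours: float
    n_seizures: int
    raw_sensitivity_pct: float
    calibrated_sensitivity_pct: float
    raw_far: float
    calibrated_far: float
    reduction_pct: float | None = None
    n_items: int | None = None

    @property
    def reduction(self) -> float:
        """Per-record reduction percent, rounded to the nearest integer."""
        if self.reduction_pct is not None:
            return float(self.reduction_pct)
        return float(round(reduction_percent(self.raw_far, self.calibrated_far)))

    @staticmethod
    def from_evaluations(
        label: str, raw: RecordEvaluation, calibrated: RecordEvaluation
    ) -> "RecordComparison":
        if raw.n_seizures != calibrated.n_seizures:
            raise InvalidInputError("raw and calibrated rows describe different records")
        sens = lambda e: sensitivity([e]) if e.n_seizures else float("nan")
        return RecordComparison(
            label=label,
            duration_hours=raw.record_duration_hours,
            n_seizures=raw.n_seizures,
            raw_sensitivity_pct=sens(raw),
            calibrated_sensitivity_pct=sens(calibrated),
            raw_far=raw.far,
            calibrated_far=calibrated.far,
        )


@dataclass(frozen=True)
class AggregateReport:
    """Summary-row arithmetic over per-record comparisons."""

    records: tuple[RecordComparison, ...]
    weighting: str
    total_duration_hours: float
    total_items: int | None
    total_seizures: int
    raw_sensitivity_pct: float
    calibrated_sensitivity_pct: float
    raw_far: float
    calibrated_far: float
    mean_reduction_pct: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "record": r.label,
                "n_items": r.n_items,
                "duration_hours": r.duration_hours,
                "n_seizures": r.n_seizures,
                "raw_sensitivity_pct": r.raw_sensitivity_pct,
                "calibrated_sensitivity_pct": r.calibrated_sensitivity_pct,
                "raw_far": r.raw_far,
                "calibrated_far": r.calibrated_far,
                "reduction_pct": r.reduction,
            }
            for r in self.records
        ]
        rows.append(
            {
                "record": "total",
                "n_items": self.total_items,
                "duration_hours": self.total_duration_hours,
                "n_seizures": self.total_seizures,
                "raw_sensitivity_pct": self.raw_sensitivity_pct,
                "calibrated_sensitivity_pct": self.calibrated_sensitivity_pct,
                "raw_far": self.raw_far,
                "calibrated_far": self.calibrated_far,
                "reduction_pct": self.mean_reduction_pct,
            }
        )
        return pd.DataFrame(rows)


def aggregate(
    comparisons: Sequence[RecordComparison], weighting: str = "duration"
) -> AggregateReport:
    """Summarise per-record comparisons.

    Pooled sensitivity weights each record by its seizure count.  Total
    false alarm rates are duration-weighted means of the per-record rates
    (equivalent to summed counts over summed exposure when per-record
    exposures equal durations).  The mean reduction averages the rounded
    per-record reduction percentages, unweighted or duration-weighted.
    """
    if len(comparisons) == 0:
        raise InvalidInputError("aggregate needs at least one record")
    if weighting not in ("unweighted", "duration"):
        raise InvalidInputError("weighting must be 'unweighted' or 'duration'")
    durations = np.array([r.duration_hours for r in comparisons], dtype=float)
    total_hours = float(durations.sum())
    seiz = np.array([r.n_seizures for r in comparisons], dtype=float)
    total_seiz = int(seiz.sum())
    if total_seiz == 0:
        raise UndefinedMetricError("sensitivity undefined with zero seizures")

    def pooled_sens(values: np.ndarray) -> float:
        tp = np.round(values / 100.0 * seiz)
        return float(100.0 * tp.sum() / seiz.sum())

    raw_sens = pooled_sens(np.array([r.raw_sensitivity_pct for r in comparisons]))
    cal_sens = pooled_sens(np.array([r.calibrated_sensitivity_pct for r in comparisons]))
    raw_far = float(np.average([r.raw_far for r in comparisons], weights=durations))
    cal_far = float(np.average([r.calibrated_far for r in comparisons], weights=durations))
    reductions = np.array([r.reduction for r in comparisons], dtype=float)
    weights = durations if weighting == "duration" else np.ones_like(durations)
    mean_red = float(np.average(reductions, weights=weights))
    items = [r.n_items for r in comparisons]
    total_items = int(sum(items)) if all(i is not None for i in items) else None
    return AggregateReport(
        records=tuple(comparisons),
        weighting=weighting,
        total_duration_hours=total_hours,
        total_items=total_items,
        total_seizures=total_seiz,
        raw_sensitivity_pct=raw_sens,
        calibrated_sensitivity_pct=cal_sens,
        raw_far=raw_far,
        calibrated_far=cal_far,
        mean_reduction_pct=mean_red,
    )


def write_report_csv(report: AggregateReport, path: str | Path) -> None:
    """Write the per-record table plus summary row as CSV."""
    report.to_dataframe().to_csv(path, index=False)


def read_comparison_table(path: str | Path) -> list[RecordComparison]:
    """Read per-record comparison rows from a CSV with the columns of
    :meth:`AggregateReport.to_dataframe` (summary rows labelled 'total'
    are skipped).  Lets published per-record columns be re-aggregated."""
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        if str(r["record"]) == "total":
            continue
        rows.append(
            RecordComparison(
                label=str(r["record"]),
                duration_hours=float(r["duration_hours"]),
                n_seizures=int(r["n_seizures"]),
                raw_sensitivity_pct=float(r["raw_sensitivity_pct"]),
                calibrated_sensitivity_pct=float(r["calibrated_sensitivity_pct"]),
                raw_far=float(r["raw_far"]),
                calibrated_far=float(r["calibrated_far"]),
                reduction_pct=float(r["reduction_pct"]) if "reduction_pct" in df else None,
                n_items=int(r["n_items"]) if "n_items" in df and pd.notna(r["n_items"]) else None,
            )
        )
    return rows
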