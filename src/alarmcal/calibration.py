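"""Learn-Then-Test calibration of the alarm threshold lambda.

For every lambda on a grid, the post-processed alarms are scored on a
calibration set of independent units (series or records), yielding per-unit
false-alarm risks.  A one-sided CLT p-value tests the null "the true mean
risk at this lambda exceeds alpha"; a familywise-error-rate controlling
multiple-testing procedure (Bonferroni, or fixed-sequence testing walking
the grid from the strictest lambda down) converts the p-values into a
validated set of thresholds.  Any threshold in that set controls the risk
at level alpha with probability at least 1 - delta over the draw of the
calibration set — an (alpha, delta) risk-controlling prediction.

An empty validated set is a legitimate outcome, reported explicitly: it
means the base model cannot be calibrated to the requested risk level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import InvalidInputError, InvalidParameterError, UndefinedMetricError
from .metrics import detect_alarm_events
from .postprocess import (
    PostprocessParams,
    _block_max,
    _causal_counts,
    apply_g_lambda,
    vote_cutoff,
)
from .series import BinarySeries

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "CalibrationConfig",
    "RiskSample",
    "CalibrationResult",
    "empirical_unit_risk",
    "event_unit_risk",
    "clt_pvalue",
    "bonferroni_select",
    "fst_select",
    "unit_risk_matrix",
    "unit_accuracy_matrix",
    "calibrate",
]

#: Default threshold grid 0.51 .. 0.99 in steps of 0.01.  Sub-majority
#: thresholds are degenerate for a majority vote, so the grid starts just
#: above one half.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    float(x) for x in np.round(np.arange(0.51, 0.995, 0.01), 2)
)


@dataclass(frozen=True)
class CalibrationConfig:
    """Risk level, FWER budget, threshold grid and the fixed aggregation.

    Attributes
    ----------
    alpha
        Risk bound, in the units of the risk estimator (per-sample
        false-alarm fraction for ``risk="sample_fraction"``, false alarm
        events per non-preictal hour for ``risk="event_rate"``).
    delta
        Familywise error rate of the calibration, in (0, 1).
    lambda_grid
        Strictly increasing candidate thresholds in [0, 1].
    mhc_method
        ``"bonferroni"`` or ``"fixed_sequence"``.
    postprocess
        Vote window / pooling configuration held fixed while lambda is
        calibrated (its ``vote_threshold`` field is ignored).
    risk
        Which per-unit risk estimator to use.
    """

    alpha: float
    delta: float = 0.1
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    mhc_method: str = "fixed_sequence"
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    risk: str = "sample_fraction"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InvalidParameterError("alpha must be >= 0")
        if not (0.0 < self.delta < 1.0):
            raise InvalidParameterError("delta must lie in (0, 1)")
        grid = tuple(float(x) for x in self.lambda_grid)
        if len(grid) == 0:
            raise InvalidParameterError("lambda_grid must be non-empty")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise InvalidParameterError("lambda_grid must be strictly increasing")
        if any(not (0.0 <= x <= 1.0) for x in grid):
            raise InvalidParameterError("lambda_grid values must lie in [0, 1]")
        if self.mhc_method not in ("bonferroni", "fixed_sequence"):
            raise InvalidParameterError("mhc_method must be 'bonferroni' or 'fixed_sequence'")
        if self.risk not in ("sample_fraction", "event_rate"):
            raise InvalidParameterError("risk must be 'sample_fraction' or 'event_rate'")
        object.__setattr__(self, "lambda_grid", grid)


@dataclass(frozen=True)
class RiskSample:
    """Per-unit empirical risks over the calibration set."""

    per_unit_risks: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.per_unit_risks, dtype=float)
        if r.ndim != 1 or r.size < 2:
            raise InvalidInputError("need at least 2 calibration units for a CLT p-value")
        if not np.isfinite(r).all() or (r < 0).any():
            raise InvalidInputError("per-unit risks must be finite and non-negative")
        object.__setattr__(self, "per_unit_risks", r)

    @property
    def n(self) -> int:
        return int(self.per_unit_risks.size)


@dataclass(frozen=True)
class CalibrationResult:
    """Per-lambda p-values, the validated set and the chosen threshold.

    ``chosen_lambda`` is ``None`` when the validated set is empty — the
    explicit "risk not controllable at this alpha" outcome.
    """

    p_values: dict[float, float]
    valid_set: tuple[float, ...]
    chosen_lambda: float | None
    mean_risks: dict[float, float]
    config: CalibrationConfig

    def to_dict(self) -> dict:
        return {
            "alpha": self.config.alpha,
            "delta": self.config.delta,
            "mhc_method": self.config.mhc_method,
            "risk": self.config.risk,
            "postprocess": {
                "vote_window_len": self.config.postprocess.vote_window_len,
                "pool_size": self.config.postprocess.pool_size,
                "pooling_enabled": self.config.postprocess.pooling_enabled,
            },
            "p_values": {str(k): v for k, v in self.p_values.items()},
            "mean_risks": {str(k): v for k, v in self.mean_risks.items()},
            "valid_set": list(self.valid_set),
            "chosen_lambda": self.chosen_lambda,
        }


# ---------------------------------------------------------------------------
# per-unit risk estimators


def empirical_unit_risk(prediction: BinarySeries, label: BinarySeries) -> float:
    """Pointwise false-alarm fraction for one unit: predicted-positive
    samples outside the label's positive state, divided by the number of
    non-positive (non-preictal) samples."""
    if len(prediction) != len(label) or prediction.sample_period != label.sample_period:
        raise InvalidInputError("prediction and label must share length and sample period")
    neg = label.values == 0
    exposure = int(neg.sum())
    if exposure == 0:
        raise UndefinedMetricError("no non-preictal samples: risk undefined")
    fp = int(np.logical_and(prediction.values == 1, neg).sum())
    return fp / exposure


def event_unit_risk(prediction: BinarySeries, label: BinarySeries) -> float:
    """False-alarm events per non-preictal hour for one clocked record.

    Alarm events are maximal runs of ones; an event counts as false if it
    contains any non-preictal sample.  Sample periods are in seconds.
    """
    if len(prediction) != len(label) or prediction.sample_period != label.sample_period:
        raise InvalidInputError("prediction and label must share length and sample period")
    neg = label.values == 0
    hours = float(neg.sum()) * prediction.sample_period / 3600.0
    if hours <= 0:
        raise UndefinedMetricError("no non-preictal exposure: risk undefined")
    fp = sum(1 for a, b in detect_alarm_events(prediction) if neg[a:b].any())
    return fp / hours


# ---------------------------------------------------------------------------
# p-values and multiple-testing selection


def clt_pvalue(risks: RiskSample, alpha: float) -> float:
    """One-sided CLT p-value for the null "true mean risk > alpha".

    p = Phi((mean - alpha) * sqrt(n) / s) with the sample standard
    deviation s (n - 1 divisor).  The degenerate s = 0 case is the limit
    of the z statistic: 0 when the mean is <= alpha, 1 otherwise.
    """
    r = risks.per_unit_risks
    mean = float(r.mean())
    s = float(r.std(ddof=1))
    if s == 0.0:
        return 0.0 if mean <= alpha else 1.0
    z = (mean - alpha) * np.sqrt(risks.n) / s
    return float(np.clip(norm.cdf(z), 0.0, 1.0))


def bonferroni_select(p_values: Mapping[float, float], delta: float) -> set[float]:
    """Reject (validate) every lambda with p <= delta / |grid|.  Valid
    under arbitrary dependence between the hypotheses."""
    if len(p_values) == 0:
        raise InvalidInputError("p_values must be non-empty")
    thresh = delta / len(p_values)
    return {lam for lam, p in p_values.items() if p <= thresh}


def fst_select(p_values: Mapping[float, float], delta: float) -> set[float]:
    """Fixed-sequence testing: walk the mapping in its given (pre-declared)
    order, rejecting at full level delta while p <= delta; stop at the
    first p > delta and return the rejected prefix.

    Valid when p-values are monotone along the order — here, descending
    lambda, since higher thresholds control the risk more strictly.
    """
    if len(p_values) == 0:
        raise InvalidInputError("p_values must be non-empty")
    selected: set[float] = set()
    for lam, p in p_values.items():
        if p <= delta:
            selected.add(lam)
        else:
            break
    return selected


# ---------------------------------------------------------------------------
# vectorised per-lambda risk evaluation


def _stack(series: Sequence[BinarySeries] | np.ndarray) -> np.ndarray | None:
    """Stack equal-length series into an (n_units, T) array, or return
    None when lengths differ (the generic loop path is used instead)."""
    if isinstance(series, np.ndarray):
        return series if series.ndim == 2 else None
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        return None
    return np.stack([s.values for s in series])


def _as_series_list(series: Sequence[BinarySeries] | np.ndarray) -> list[BinarySeries]:
    if isinstance(series, np.ndarray):
        return [BinarySeries(row) for row in series]
    return list(series)


def unit_risk_matrix(
    labels: Sequence[BinarySeries] | np.ndarray,
    predictions: Sequence[BinarySeries] | np.ndarray,
    postprocess: PostprocessParams,
    lambda_grid: Sequence[float],
    risk: str = "sample_fraction",
) -> np.ndarray:
    """Per-unit risks for every lambda: shape (len(grid), n_units).

    When pooling is enabled the labels are max-pooled with the same rate,
    so risk is measured at the output resolution.  Equal-length
    sample-fraction inputs take a vectorised path that evaluates each
    distinct integer vote cutoff once.
    """
    lab2d = _stack(labels)
    pred2d = _stack(predictions)
    if risk == "sample_fraction" and lab2d is not None and pred2d is not None:
        if lab2d.shape != pred2d.shape:
            raise InvalidInputError("labels and predictions must have matching shapes")
        w, k = postprocess.vote_window_len, postprocess.pool_size
        if w > lab2d.shape[1]:
            raise InvalidParameterError("vote_window_len longer than the series")
        counts = _causal_counts(pred2d, w)
        lab_eval = _block_max(lab2d, k) if postprocess.pooling_enabled else lab2d
        neg = lab_eval == 0
        exposure = neg.sum(axis=1)
        if (exposure == 0).any():
            raise UndefinedMetricError("a unit has no non-preictal samples")
        by_cutoff: dict[int, np.ndarray] = {}
        rows = []
        for lam in lambda_grid:
            c = vote_cutoff(lam, w)
            if c not in by_cutoff:
                voted = counts >= c
                out = _block_max(voted, k) if postprocess.pooling_enabled else voted
                fp = np.logical_and(out, neg).sum(axis=1)
                by_cutoff[c] = fp / exposure
            rows.append(by_cutoff[c])
        return np.vstack(rows)

    # generic path: unequal lengths or the event-rate estimator
    lab_list = _as_series_list(labels)
    pred_list = _as_series_list(predictions)
    if len(lab_list) != len(pred_list):
        raise InvalidInputError("labels and predictions must pair up one-to-one")
    estimator = empirical_unit_risk if risk == "sample_fraction" else event_unit_risk
    rows = []
    for lam in lambda_grid:
        pp = postprocess.with_threshold(lam)
        row = []
        for lab, pred in zip(lab_list, pred_list):
            out = apply_g_lambda(pred, pp)
            lab_eval = (
                max_pool_label(lab, postprocess.pool_size)
                if postprocess.pooling_enabled
                else lab
            )
            row.append(estimator(out, lab_eval))
        rows.append(row)
    return np.asarray(rows, dtype=float)


def max_pool_label(label: BinarySeries, pool_size: int) -> BinarySeries:
    """Labels pooled to the alarm resolution: a block is preictal when any
    of its samples is."""
    from .postprocess import max_pool

    return max_pool(label, pool_size)


def unit_accuracy_matrix(
    labels: Sequence[BinarySeries] | np.ndarray,
    predictions: Sequence[BinarySeries] | np.ndarray,
    postprocess: PostprocessParams,
    lambda_grid: Sequence[float],
) -> np.ndarray:
    """Per-unit pointwise accuracy at the output resolution for every
    lambda: shape (len(grid), n_units)."""
    lab2d = _stack(labels)
    pred2d = _stack(predictions)
    if lab2d is None or pred2d is None or lab2d.shape != pred2d.shape:
        raise InvalidInputError("accuracy matrix needs equal-length, paired units")
    w, k = postprocess.vote_window_len, postprocess.pool_size
    counts = _causal_counts(pred2d, w)
    lab_eval = _block_max(lab2d, k) if postprocess.pooling_enabled else lab2d
    by_cutoff: dict[int, np.ndarray] = {}
    rows = []
    for lam in lambda_grid:
        c = vote_cutoff(lam, w)
        if c not in by_cutoff:
            voted = counts >= c
            out = _block_max(voted, k) if postprocess.pooling_enabled else voted
            by_cutoff[c] = (out == lab_eval).mean(axis=1)
        rows.append(by_cutoff[c])
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# the calibrator


def calibrate(
    cal_labels: Sequence[BinarySeries] | np.ndarray,
    cal_predictions: Sequence[BinarySeries] | np.ndarray,
    config: CalibrationConfig,
    select_fn: Callable[[tuple[float, ...]], float] | None = None,
) -> CalibrationResult:
    """Run Learn-Then-Test calibration of lambda on paired units.

    For every lambda on the grid the per-unit risks are computed, turned
    into a CLT p-value against ``config.alpha``, and the configured
    multiple-testing procedure (at FWER ``config.delta``) selects the
    validated set.  The chosen lambda is the minimum of the validated set
    (the least restrictive threshold, hence the best sensitivity), unless
    ``select_fn`` supplies a different secondary-metric maximiser.

    Deterministic: no randomness inside the calibrator.
    """
    n_units = len(cal_labels)
    if n_units == 0 or n_units != len(cal_predictions):
        raise InvalidInputError("calibration needs non-empty, paired units")
    grid = config.lambda_grid
    risk_matrix = unit_risk_matrix(
        cal_labels, cal_predictions, config.postprocess, grid, risk=config.risk
    )
    p_values = {
        lam: clt_pvalue(RiskSample(risk_matrix[i]), config.alpha)
        for i, lam in enumerate(grid)
    }
    if config.mhc_method == "bonferroni":
        valid = bonferroni_select(p_values, config.delta)
    else:
        descending = {lam: p_values[lam] for lam in sorted(grid, reverse=True)}
        valid = fst_select(descending, config.delta)
    valid_sorted = tuple(sorted(valid))
    if not valid_sorted:
        chosen = None
    elif select_fn is not None:
        chosen = float(select_fn(valid_sorted))
        if chosen not in valid:
            raise InvalidParameterError("select_fn must return a member of the validated set")
    else:
        chosen = valid_sorted[0]
    mean_risks = {lam: float(risk_matrix[i].mean()) for i, lam in enumerate(grid)}
    return CalibrationResult(
        p_values=p_values,
        valid_set=valid_sorted,
        chosen_lambda=chosen,
        mean_risks=mean_risks,
        config=config,
    )
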