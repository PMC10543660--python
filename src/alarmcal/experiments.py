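"""The synthetic validation study and end-to-end record evaluation.

``run_synthetic_study`` measures, by Monte Carlo, whether the calibrated
threshold actually controls the false alarm rate: each experiment draws a
fresh synthetic dataset, splits it into calibration and test halves,
calibrates lambda at each requested risk level alpha with each
multiple-testing method and pooling variant, then scores the chosen
threshold on the held-out half.  All variants of one experiment share the
same data, so pooling and multiple-testing comparisons are paired.

Reported per cell (alpha, pooling, method): mean and standard deviation of
the test false alarm rate and accuracy, the modal chosen lambda, and the
count of experiments whose validated set was empty (these are excluded
from the means, never silently dropped).

Two false-alarm summaries are kept: ``far`` is the controlled risk — the
per-sample false-alarm fraction at the alarm output's own resolution — and
``time_far`` re-expresses it per input time step (dividing by the pooling
rate), which puts pooled and non-pooled variants on a common time axis.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_LAMBDA_GRID,
    CalibrationConfig,
    CalibrationResult,
    RiskSample,
    bonferroni_select,
    clt_pvalue,
    fst_select,
    unit_accuracy_matrix,
    unit_risk_matrix,
)
from .errors import InvalidParameterError, NoValidLambdaError
from .metrics import AggregateReport, RecordComparison, aggregate, evaluate_record
from .postprocess import PostprocessParams, apply_g_lambda, max_pool
from .series import BinarySeries
from .synthetic import SyntheticParams, generate_arrays

__all__ = [
    "StudyConfig",
    "StudyCell",
    "StudyResult",
    "run_synthetic_study",
    "scaled_config",
    "run_record_evaluation",
]

PAPER_ALPHAS: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1, 1.0)


@dataclass(frozen=True)
class StudyConfig:
    """Protocol of the synthetic validation study.

    Defaults reproduce the full-scale protocol: 200 experiments per risk
    level, each with 10,000 sequences of length 1,000, label windows of 8
    samples, vote window 10 and pooling rate 10.  ``scaled_config`` derives
    desk-scale variants.
    """

    alphas: tuple[float, ...] = PAPER_ALPHAS
    n_experiments: int = 200
    synthetic: SyntheticParams = field(
        default_factory=lambda: SyntheticParams(n_series=10_000, series_len=1000)
    )
    vote_window_len: int = 10
    pool_size: int = 10
    pooling_variants: tuple[bool, ...] = (False, True)
    mhc_methods: tuple[str, ...] = ("bonferroni", "fixed_sequence")
    delta: float = 0.1
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise InvalidParameterError("split_fraction must lie in (0, 1)")
        if self.n_experiments < 1:
            raise InvalidParameterError("n_experiments must be >= 1")
        n_cal = int(round(self.synthetic.n_series * self.split_fraction))
        if n_cal < 2 or self.synthetic.n_series - n_cal < 1:
            raise InvalidParameterError(
                "split must leave >= 2 calibration units and >= 1 test unit"
            )


def scaled_config(config: StudyConfig, scale: float) -> StudyConfig:
    """Shrink experiment count and series count by ``scale`` (0 < s <= 1),
    keeping everything else fixed."""
    if not (0.0 < scale <= 1.0):
        raise InvalidParameterError("scale must lie in (0, 1]")
    return replace(
        config,
        n_experiments=max(1, int(round(config.n_experiments * scale))),
        synthetic=replace(
            config.synthetic, n_series=max(4, int(round(config.synthetic.n_series * scale)))
        ),
    )


@dataclass(frozen=True)
class StudyCell:
    """Aggregate over experiments for one (alpha, pooling, method) cell.

    Per-experiment vectors are index-aligned across cells (entry i always
    refers to experiment i); ``None``/NaN marks an empty validated set.
    """

    alpha: float
    pooling: bool
    mhc_method: str
    n_experiments: int
    n_empty: int
    mean_far: float
    std_far: float
    mean_accuracy: float
    std_accuracy: float
    modal_lambda: float | None
    lambdas: tuple[float | None, ...]
    fars: tuple[float, ...]
    time_fars: tuple[float, ...]
    accuracies: tuple[float, ...]


@dataclass(frozen=True)
class StudyResult:
    """All study cells plus the generating configuration."""

    config: StudyConfig
    cells: dict[tuple[float, bool, str], StudyCell]

    def cell(self, alpha: float, pooling: bool, method: str) -> StudyCell:
        return self.cells[(alpha, pooling, method)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (alpha, pooling, method), c in sorted(self.cells.items()):
            rows.append(
                {
                    "alpha": alpha,
                    "pooling": pooling,
                    "mhc_method": method,
                    "n_experiments": c.n_experiments,
                    "n_empty": c.n_empty,
                    "mean_far": c.mean_far,
                    "std_far": c.std_far,
                    "mean_accuracy": c.mean_accuracy,
                    "std_accuracy": c.std_accuracy,
                    "modal_lambda": c.modal_lambda,
                }
            )
        return pd.DataFrame(rows)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "study_cells.csv", index=False)
        summary = {
            "config": {
                **asdict(self.config),
                "synthetic": asdict(self.config.synthetic),
            },
            "cells": {
                f"alpha={a}|pooling={p}|method={m}": {
                    "mean_far": c.mean_far,
                    "std_far": c.std_far,
                    "mean_accuracy": c.mean_accuracy,
                    "std_accuracy": c.std_accuracy,
                    "modal_lambda": c.modal_lambda,
                    "n_empty": c.n_empty,
                    "lambdas": list(c.lambdas),
                }
                for (a, p, m), c in sorted(self.cells.items())
            },
        }
        (outdir / "study_summary.json").write_text(json.dumps(summary, indent=2))


def _nan_stats(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def run_synthetic_study(config: StudyConfig) -> StudyResult:
    """Run the Monte Carlo risk-control study.  Fully reproducible from
    ``config.seed``; every experiment uses an independent substream."""
    grid = config.lambda_grid
    root = np.random.SeedSequence(config.seed)
    exp_seeds = root.spawn(config.n_experiments)
    n_cal = int(round(config.synthetic.n_series * config.split_fraction))

    acc: dict[tuple[float, bool, str], dict[str, list]] = {
        (a, p, m): {"lam": [], "far": [], "tfar": [], "acc": []}
        for a in config.alphas
        for p in config.pooling_variants
        for m in config.mhc_methods
    }

    for ss in exp_seeds:
        labels, preds = generate_arrays(config.synthetic, seed_seq=ss)
        cal_l, cal_p = labels[:n_cal], preds[:n_cal]
        test_l, test_p = labels[n_cal:], preds[n_cal:]
        for pooling in config.pooling_variants:
            pp = PostprocessParams(
                vote_window_len=config.vote_window_len,
                pool_size=config.pool_size,
                pooling_enabled=pooling,
            )
            k_eff = config.pool_size if pooling else 1
            r_cal = unit_risk_matrix(cal_l, cal_p, pp, grid)
            r_test = unit_risk_matrix(test_l, test_p, pp, grid)
            a_test = unit_accuracy_matrix(test_l, test_p, pp, grid)
            samples = [RiskSample(r_cal[i]) for i in range(len(grid))]
            for alpha in config.alphas:
                p_values = {lam: clt_pvalue(samples[i], alpha) for i, lam in enumerate(grid)}
                for method in config.mhc_methods:
                    if method == "bonferroni":
                        valid = bonferroni_select(p_values, config.delta)
                    else:
                        ordered = {lam: p_values[lam] for lam in sorted(grid, reverse=True)}
                        valid = fst_select(ordered, config.delta)
                    slot = acc[(alpha, pooling, method)]
                    if not valid:
                        slot["lam"].append(None)
                        slot["far"].append(float("nan"))
                        slot["tfar"].append(float("nan"))
                        slot["acc"].append(float("nan"))
                        continue
                    lam_hat = min(valid)
                    idx = grid.index(lam_hat)
                    slot["lam"].append(lam_hat)
                    slot["far"].append(float(r_test[idx].mean()))
                    slot["tfar"].append(float(r_test[idx].mean()) / k_eff)
                    slot["acc"].append(float(a_test[idx].mean()))

    cells: dict[tuple[float, bool, str], StudyCell] = {}
    for key, slot in acc.items():
        alpha, pooling, method = key
        lams = [l for l in slot["lam"] if l is not None]
        fars = [f for f in slot["far"] if np.isfinite(f)]
        accs = [a for a in slot["acc"] if np.isfinite(a)]
        mean_far, std_far = _nan_stats(fars)
        mean_acc, std_acc = _nan_stats(accs)
        modal = Counter(lams).most_common(1)[0][0] if lams else None
        cells[key] = StudyCell(
            alpha=alpha,
            pooling=pooling,
            mhc_method=method,
            n_experiments=config.n_experiments,
            n_empty=config.n_experiments - len(lams),
            mean_far=mean_far,
            std_far=std_far,
            mean_accuracy=mean_acc,
            std_accuracy=std_acc,
            modal_lambda=modal,
            lambdas=tuple(slot["lam"]),
            fars=tuple(slot["far"]),
            time_fars=tuple(slot["tfar"]),
            accuracies=tuple(slot["acc"]),
        )
    return StudyResult(config=config, cells=cells)


def run_record_evaluation(
    labels: list[BinarySeries],
    raw_predictions: list[BinarySeries],
    result: CalibrationResult,
    record_names: list[str] | None = None,
    weighting: str = "duration",
) -> AggregateReport:
    """Score records with and without the calibrated post-processing.

    Raw predictions are evaluated at their native resolution; calibrated
    alarms (g at the chosen lambda) against identically pooled labels.
    Requires a non-empty validated set.
    """
    if result.chosen_lambda is None:
        raise NoValidLambdaError(
            f"no lambda controls the risk at alpha={result.config.alpha}"
        )
    if len(labels) != len(raw_predictions) or len(labels) == 0:
        raise InvalidParameterError("labels and predictions must pair up, non-empty")
    pp = result.config.postprocess.with_threshold(result.chosen_lambda)
    names = record_names or [f"record_{i}" for i in range(len(labels))]
    comparisons: list[RecordComparison] = []
    for name, lab, pred in zip(names, labels, raw_predictions):
        raw_eval = evaluate_record(pred, lab)
        calibrated = apply_g_lambda(pred, pp)
        lab_eval = max_pool(lab, pp.pool_size) if pp.pooling_enabled else lab
        cal_eval = evaluate_record(calibrated, lab_eval)
        comparisons.append(RecordComparison.from_evaluations(name, raw_eval, cal_eval))
    return aggregate(comparisons, weighting=weighting)
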