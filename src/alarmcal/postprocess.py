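"""The lambda-parameterised alarm transform g_lambda.

Two temporal aggregations turn raw binary model outputs into alarms:

1. a *causal majority vote*: sample t becomes 1 iff the fraction of ones in
   the window of ``vote_window_len`` samples ending at t strictly exceeds
   the threshold lambda (the left edge is zero-padded, i.e. pre-record time
   is treated as alarm-free);
2. optional *max-pooling*: the voted series is decimated into disjoint
   blocks of ``pool_size`` samples, each output sample being the block
   maximum; the trailing partial block is pooled as-is.

The vote adds robustness against pointwise prediction noise; pooling
mitigates isolated mistakes and coarsens the decision rate.  Raising lambda
can only switch alarms off, never on — every positive-count metric is
non-increasing in lambda, which is what makes the calibration's
fixed-sequence testing order valid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .series import BinarySeries

__all__ = [
    "PostprocessParams",
    "binarize",
    "majority_vote",
    "max_pool",
    "apply_g_lambda",
    "vote_cutoff",
]


@dataclass(frozen=True)
class PostprocessParams:
    """Knobs of g_lambda: vote threshold, vote window, pooling rate."""

    vote_threshold: float = 0.51
    vote_window_len: int = 10
    pool_size: int = 10
    pooling_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.vote_threshold <= 1.0):
            raise InvalidParameterError("vote_threshold must lie in [0, 1]")
        if int(self.vote_window_len) < 1 or int(self.pool_size) < 1:
            raise InvalidParameterError("window and pool sizes must be >= 1")

    def with_threshold(self, lam: float) -> "PostprocessParams":
        return replace(self, vote_threshold=float(lam))


def binarize(prob_series: np.ndarray, threshold: float, sample_period: float = 1.0) -> BinarySeries:
    """Threshold probabilistic model outputs: output 1 iff p > threshold.

    Adapter from real-valued model outputs to the binary alphabet the
    aggregations operate on.  Strict inequality, matching the vote.
    """
    p = np.asarray(prob_series, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise InvalidInputError("prob_series must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InvalidInputError("probabilities must lie in [0, 1]")
    if not (0.0 <= threshold <= 1.0):
        raise InvalidParameterError("threshold must lie in [0, 1]")
    return BinarySeries((p > threshold).astype(np.uint8), sample_period)


def vote_cutoff(lam: float, vote_window_len: int) -> int:
    """Smallest integer count s with s / w > lam, or w + 1 if none.

    Thresholding the integer window count against this cutoff is exactly
    the strict fractional comparison, with no float round-off on the grid
    of attainable fractions.
    """
    w = int(vote_window_len)
    for s in range(w + 1):
        if s / w > lam:
            return s
    return w + 1


def _causal_counts(values: np.ndarray, w: int) -> np.ndarray:
    """Sliding sum of the w samples ending at each t (left edge padded
    with zeros), for a 1-D or 2-D (series-per-row) array."""
    x = values.astype(np.int64)
    c = np.cumsum(x, axis=-1)
    out = c.copy()
    if w < x.shape[-1]:
        out[..., w:] = c[..., w:] - c[..., :-w]
    return out


def majority_vote(series: BinarySeries, lam: float, vote_window_len: int) -> BinarySeries:
    """Causal window majority vote: 1 iff the fraction of ones in the
    trailing window strictly exceeds lam."""
    w = int(vote_window_len)
    if w < 1:
        raise InvalidParameterError("vote_window_len must be >= 1")
    if w > len(series):
        raise InvalidParameterError("vote_window_len longer than the series")
    if not (0.0 <= lam <= 1.0):
        raise InvalidParameterError("lambda must lie in [0, 1]")
    counts = _causal_counts(series.values, w)
    out = (counts >= vote_cutoff(lam, w)).astype(np.uint8)
    return BinarySeries(out, series.sample_period)


def _block_max(values: np.ndarray, k: int) -> np.ndarray:
    """Disjoint block maxima along the last axis; trailing partial block
    pooled over the samples that exist."""
    if k == 1:
        return values
    t = values.shape[-1]
    idx = np.arange(0, t, k)
    return np.maximum.reduceat(values, idx, axis=-1)


def max_pool(series: BinarySeries, pool_size: int) -> BinarySeries:
    """Decimate to one sample per disjoint block of ``pool_size`` inputs,
    taking the block maximum.  The output sample period grows by the
    pooling rate."""
    k = int(pool_size)
    if k < 1:
        raise InvalidParameterError("pool_size must be >= 1")
    out = _block_max(series.values, k)
    return BinarySeries(out, series.sample_period * k)


def apply_g_lambda(series: BinarySeries, params: PostprocessParams) -> BinarySeries:
    """Majority vote, then (if enabled) max-pooling."""
    voted = majority_vote(series, params.vote_threshold, params.vote_window_len)
    if params.pooling_enabled:
        return max_pool(voted, params.pool_size)
    return voted
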