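"""Synthetic binary label/prediction generator.

Emulates the structure of seizure-prediction data: rare event points drawn
Bernoulli(p) per sample are widened into fixed-length windows of ones (the
"preictal" label), and a noisy oracle produces model predictions by flipping
the ground truth pointwise with probability ``p_flip``.  For ``p * w << 1``
the label series is mostly zero with sparse windows of ones.

The generator is the data source for the simulation study and for test
fixtures.  Randomness is organised as one master seed spawning an
independent substream per series, so changing ``n_series`` never reshuffles
earlier series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .series import BinarySeries

__all__ = [
    "SyntheticParams",
    "gen_point_series",
    "widen_to_windows",
    "noisy_oracle",
    "generate_arrays",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic label/prediction generator.

    Attributes
    ----------
    event_rate
        Per-sample probability p of an event point, in (0, 1) for the
        generic case; 0 and 1 are accepted as degenerate settings.
    label_window_len
        Width w (samples) of the window of ones each event point becomes.
    flip_prob
        Pointwise label-flip probability of the noisy oracle, in [0, 1).
    series_len
        Number of samples T per series.
    n_series
        Number of independent series pairs.
    seed
        Master seed of the pseudorandom stream.
    """

    event_rate: float = 0.005
    label_window_len: int = 8
    flip_prob: float = 0.05
    series_len: int = 1000
    n_series: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.event_rate <= 1.0):
            raise InvalidParameterError("event_rate must be a probability in [0, 1]")
        if not (0.0 <= self.flip_prob < 1.0):
            raise InvalidParameterError("flip_prob must be in [0, 1)")
        for name in ("label_window_len", "series_len", "n_series"):
            if int(getattr(self, name)) < 1:
                raise InvalidParameterError(f"{name} must be a positive integer")
        if self.event_rate * self.label_window_len >= 1.0:
            warnings.warn(
                "event_rate * label_window_len >= 1: the sparse-window regime "
                "(p*w << 1) is violated and labels will be mostly ones",
                stacklevel=2,
            )


def gen_point_series(params: SyntheticParams, stream: np.random.Generator) -> BinarySeries:
    """Draw the sparse event-point series: each sample is independently 1
    with probability ``params.event_rate``."""
    pts = stream.random(params.series_len) < params.event_rate
    return BinarySeries(pts.astype(np.uint8))


def widen_to_windows(points: BinarySeries, label_window_len: int) -> BinarySeries:
    """Spread every event point forward over ``label_window_len`` samples.

    A point at index t produces ones at t .. t+w-1; the full convolution is
    truncated to the original length, so windows at the tail are clipped.
    """
    w = int(label_window_len)
    if w < 1:
        raise InvalidParameterError("label_window_len must be >= 1")
    if w > len(points):
        raise InvalidParameterError("label_window_len longer than the series")
    out = _widen(points.values, w)
    return BinarySeries(out, points.sample_period)


def _widen(points: np.ndarray, w: int) -> np.ndarray:
    if w == 1:
        return points.astype(np.uint8)
    conv = np.convolve(points.astype(np.int64), np.ones(w, dtype=np.int64))
    return (conv[: points.size] > 0).astype(np.uint8)


def noisy_oracle(
    truth: BinarySeries, flip_prob: float, stream: np.random.Generator
) -> BinarySeries:
    """Return the truth with each sample independently flipped with
    probability ``flip_prob`` (a mostly-good surrogate for a black-box
    model's predictions)."""
    if not (0.0 <= flip_prob < 1.0):
        raise InvalidParameterError("flip_prob must be in [0, 1)")
    flips = stream.random(len(truth)) < flip_prob
    out = truth.values ^ flips.astype(np.uint8)
    return BinarySeries(out, truth.sample_period)


def generate_arrays(
    params: SyntheticParams, seed_seq: np.random.SeedSequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate the dataset as two (n_series, series_len) uint8 arrays
    (labels, predictions).  This is the vectorised core behind
    :func:`generate_dataset`."""
    ss = seed_seq if seed_seq is not None else np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_series)
    n, t, w = params.n_series, params.series_len, params.label_window_len
    if w > t:
        raise InvalidParameterError("label_window_len longer than the series")
    labels = np.empty((n, t), dtype=np.uint8)
    preds = np.empty((n, t), dtype=np.uint8)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pts = (rng.random(t) < params.event_rate).astype(np.uint8)
        lab = _widen(pts, w)
        flips = (rng.random(t) < params.flip_prob).astype(np.uint8)
        labels[i] = lab
        preds[i] = lab ^ flips
    return labels, preds


def generate_dataset(
    params: SyntheticParams,
) -> tuple[list[BinarySeries], list[BinarySeries]]:
    """Generate ``n_series`` i.i.d. (label, prediction) pairs.

    Reproducible: the same ``params`` (including seed) always yield
    bit-identical data.
    """
    labels, preds = generate_arrays(params)
    return (
        [BinarySeries(row) for row in labels],
        [BinarySeries(row) for row in preds],
    )


# ---------------------------------------------------------------------------
# dataset I/O: one series per row in delimited text, params in a JSON sidecar


def save_dataset(
    prefix: str | Path,
    labels: list[BinarySeries] | np.ndarray,
    predictions: list[BinarySeries] | np.ndarray,
    params: SyntheticParams | None = None,
) -> None:
    """Write ``<prefix>_labels.csv``, ``<prefix>_predictions.csv`` and, when
    params are given, ``<prefix>_params.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, data in (("labels", labels), ("predictions", predictions)):
        arr = np.asarray([s.values if isinstance(s, BinarySeries) else s for s in data])
        np.savetxt(f"{prefix}_{name}.csv", arr, fmt="%d", delimiter=",")
    if params is not None:
        Path(f"{prefix}_params.json").write_text(json.dumps(asdict(params), indent=2))


def load_dataset(
    prefix: str | Path,
) -> tuple[list[BinarySeries], list[BinarySeries], SyntheticParams | None]:
    """Inverse of :func:`save_dataset`."""
    prefix = Path(prefix)
    out = []
    for name in ("labels", "predictions"):
        arr = np.loadtxt(f"{prefix}_{name}.csv", delimiter=",", dtype=np.int64, ndmin=2)
        out.append([BinarySeries(row) for row in arr])
    params = None
    params_path = Path(f"{prefix}_params.json")
    if params_path.exists():
        params = SyntheticParams(**json.loads(params_path.read_text()))
    return out[0], out[1], params
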