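"""Binary time-series container used for labels, raw predictions and alarms.

A :class:`BinarySeries` is an ordered sequence over {0, 1} with a known
sample period.  The sample period is dimensionless by default ("steps");
when working with clocked recordings it is interpreted in seconds.
Max-pooling multiplies the sample period by the pooling rate, so a series
always knows how much wall time one of its samples represents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["BinarySeries"]


@dataclass(eq=False)
class BinarySeries:
    """A finite {0,1}-valued series with a per-sample duration.

    Parameters
    ----------
    values
        One-dimensional array-like over {0, 1}; length >= 1.
    sample_period
        Duration represented by one sample (arbitrary units, > 0).
    """

    values: np.ndarray
    sample_period: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 1 or v.size < 1:
            raise InvalidInputError("values must be a non-empty 1-D sequence")
        if not np.isin(v, (0, 1)).all():
            raise InvalidInputError("values must contain only 0 and 1")
        if not (float(self.sample_period) > 0):
            raise InvalidInputError("sample_period must be positive")
        self.values = v.astype(np.uint8)
        self.sample_period = float(self.sample_period)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinarySeries):
            return NotImplemented
        return (
            self.sample_period == other.sample_period
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )

    @property
    def duration(self) -> float:
        """Total duration covered by the series (len * sample_period)."""
        return len(self) * self.sample_period

    def mean(self) -> float:
        """Fraction of ones."""
        return float(self.values.mean())
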