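"""Prediction-interval figures of merit and regression scores.

* PINC — prediction interval nominal coverage, 100 (1 - alpha) %.
* PICP — empirical fraction of targets falling inside their (closed)
  intervals.
* ACE — average coverage error, PICP - PINC (both as fractions); values
  near zero mean the intervals are well calibrated, positive means
  conservative, negative means too narrow.
* PINAW — mean interval width normalised by the range R of the actual
  test-set values; smaller is sharper.

An :class:`IntervalReport` collects these together with MSE, R^2 and the
min/mean/max lower- and upper-interval sizes for one model — the row
schema of the study's model-comparison table.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .conformal import PredictionInterval, interval_sizes
from .exceptions import InvalidInputError


def pinc(alpha: float) -> float:
    """Prediction interval nominal coverage as a percentage: 100 (1 - alpha)."""
    if not (0.0 <= alpha <= 1.0) or not np.isfinite(alpha):
        raise InvalidInputError(f"alpha must be in [0, 1], got {alpha}")
    return 100.0 * (1.0 - alpha)


def picp(y_true: Sequence[float], intervals: Sequence[PredictionInterval]) -> float:
    """Empirical coverage: fraction of targets inside their closed intervals."""
    y = np.asarray(y_true, dtype=float)
    if y.size == 0:
        raise InvalidInputError("picp needs at least one observation")
    if y.size != len(intervals):
        raise InvalidInputError("y_true and intervals must have equal length")
    lower = np.asarray([iv.lower for iv in intervals])
    upper = np.asarray([iv.upper for iv in intervals])
    covered = (y >= lower) & (y <= upper)
    return float(covered.mean())


def ace(picp_value: float, pinc_fraction: float) -> float:
    """Average coverage error: PICP - PINC, both as fractions in [0, 1]."""
    for name, value in (("picp_value", picp_value), ("pinc_fraction", pinc_fraction)):
        if not (0.0 <= value <= 1.0):
            raise InvalidInputError(f"{name} must be in [0, 1], got {value}")
    return float(picp_value) - float(pinc_fraction)


def pinaw(intervals: Sequence[PredictionInterval], norm_range: float) -> float:
    """Mean interval width divided by the range of the actual values."""
    if len(intervals) == 0:
        raise InvalidInputError("pinaw needs at least one interval")
    if not (norm_range > 0) or not np.isfinite(norm_range):
        raise InvalidInputError(f"normalisation range must be > 0, got {norm_range}")
    widths = np.asarray([iv.upper - iv.lower for iv in intervals])
    return float(widths.mean() / norm_range)


def regression_scores(y_true, y_pred) -> tuple[float, float]:
    """(MSE, R^2) of point predictions."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.size != p.size:
        raise InvalidInputError("y_true and y_pred must have equal length")
    if y.size < 2:
        raise InvalidInputError("need at least two observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise InvalidInputError("R^2 undefined: zero variance in y_true")
    sse = float(np.sum((y - p) ** 2))
    return sse / y.size, 1.0 - sse / sst


@dataclass
class IntervalReport:
    """One model's accuracy and interval figures of merit (one table column)."""

    mse: float
    r2: float
    picp: float
    ace: float
    pinaw: float
    lower_min: float
    lower_mean: float
    lower_max: float
    upper_min: float
    upper_mean: float
    upper_max: float
    n_test: int
    norm_range: float

    #: canonical presentation order of the table rows
    FIELD_ORDER = (
        "lower_min", "lower_mean", "lower_max",
        "upper_min", "upper_mean", "upper_max",
        "mse", "picp", "ace", "pinaw",
    )

    def to_dict(self) -> dict:
        return asdict(self)


def build_interval_report(
    y_true,
    y_pred,
    intervals: Sequence[PredictionInterval],
    alpha: float = 0.05,
    norm_range: float | None = None,
) -> IntervalReport:
    """Assemble an :class:`IntervalReport` from test-set outputs.

    ``norm_range`` defaults to max - min of the actual test-set values, the
    normalisation the PINAW definition calls for.
    """
    y = np.asarray(y_true, dtype=float)
    if y.size != len(intervals):
        raise InvalidInputError("y_true and intervals must have equal length")
    if norm_range is None:
        norm_range = float(y.max() - y.min())
    mse, r2 = regression_scores(y, y_pred)
    lower_sizes, upper_sizes = interval_sizes(intervals, np.asarray(y_pred, float))
    coverage = picp(y, intervals)
    return IntervalReport(
        mse=mse,
        r2=r2,
        picp=coverage,
        ace=ace(coverage, 1.0 - alpha),
        pinaw=pinaw(intervals, norm_range),
        lower_min=float(lower_sizes.min()),
        lower_mean=float(lower_sizes.mean()),
        lower_max=float(lower_sizes.max()),
        upper_min=float(upper_sizes.min()),
        upper_mean=float(upper_sizes.mean()),
        upper_max=float(upper_sizes.max()),
        n_test=int(y.size),
        norm_range=float(norm_range),
    )
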