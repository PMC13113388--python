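"""Jackknife+-after-bootstrap (JAB) prediction intervals.

A model-agnostic, distribution-free way to attach finite-sample prediction
intervals to any point-regression learner.  B models are trained on
with-replacement bootstrap resamples of the training set; each training
point i then has an out-of-bag (OOB) ensemble — the models whose resample
missed i — giving a leave-one-out-style residual R_i without extra fits.
For a test point x the interval is

    [ q-_alpha { mu_-i(x) - R_i } ,  q+_alpha { mu_-i(x) + R_i } ]

over the n training points, where mu_-i is the OOB ensemble prediction and
the quantiles use the conservative ceil((1-alpha)(n+1)) order-statistic
convention.  The construction guarantees coverage >= 1 - 2*alpha and is
empirically close to 1 - alpha for well-specified learners.

The learner protocol is functional: ``learner_factory(X, y)`` must return a
callable mapping new X to predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidInputError,
    ResampleDegeneracyError,
)

LearnerFactory = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


@dataclass
class ConformalConfig:
    """Settings for the JAB construction.

    alpha is the nominal miscoverage (0.05 -> 95% intervals); z is the
    normal quantile used only to convert interval widths to the sigma
    uncertainty proxy.  ``point`` selects the reported point prediction:
    "refit" (a model retrained on the full training set — the default) or
    "ensemble" (mean over all B bootstrap models).
    """

    alpha: float = 0.05
    n_bootstrap: int = 100
    seed: object = None
    z: float = 1.96
    point: str = "refit"
    max_retries: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InvalidInputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_bootstrap < 20:
            raise InvalidInputError("n_bootstrap must be >= 20")
        if self.point not in ("refit", "ensemble"):
            raise InvalidInputError("point must be 'refit' or 'ensemble'")
        if self.z <= 0:
            raise InvalidInputError("z must be positive")


@dataclass(frozen=True)
class PredictionInterval:
    """Point prediction with lower/upper bounds and a sigma proxy.

    sigma = (upper - lower) / (2 z): the half-width of the interval
    expressed as a standard-deviation-like uncertainty.  The point does not
    have to lie inside [lower, upper] (refit point vs ensemble interval),
    but lower <= upper always holds.
    """

    point: float
    lower: float
    upper: float
    sigma: float

    def __post_init__(self) -> None:
        if self.upper < self.lower:
            raise InvalidInputError(
                f"upper bound {self.upper} below lower bound {self.lower}"
            )
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")

    @classmethod
    def from_bounds(
        cls, point: float, lower: float, upper: float, z: float = 1.96
    ) -> "PredictionInterval":
        return cls(
            point=float(point),
            lower=float(lower),
            upper=float(upper),
            sigma=(float(upper) - float(lower)) / (2.0 * z),
        )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _upper_rank(n: int, alpha: float) -> int:
    """0-based index of the ceil((1-alpha)(n+1))-th smallest of n values."""
    k = int(np.ceil((1.0 - alpha) * (n + 1)))
    return min(max(k, 1), n) - 1


def _lower_rank(n: int, alpha: float) -> int:
    """0-based index of the floor(alpha(n+1))-th smallest of n values."""
    k = int(np.floor(alpha * (n + 1)))
    return min(max(k, 1), n) - 1


def jab_intervals(
    X_train,
    y_train,
    X_test,
    learner_factory: LearnerFactory,
    config: ConformalConfig | None = None,
) -> list[PredictionInterval]:
    """Jackknife+-after-bootstrap intervals for every row of ``X_test``.

    Seeded and fully reproducible: fixed (data, seed, B) give identical
    intervals.  If some training point ends up in every bootstrap resample
    (no OOB model), the resample matrix is redrawn up to
    ``config.max_retries`` times before failing.
    """
    config = config or ConformalConfig()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    n = y_train.size
    if X_train.shape[0] != n:
        raise InvalidInputError("X_train and y_train disagree on sample count")
    if n < 10:
        raise InvalidInputError(f"need >= 10 training samples, got {n}")

    rng = np.random.default_rng(config.seed)
    B = config.n_bootstrap
    for attempt in range(config.max_retries):
        boot = rng.integers(0, n, size=(B, n))
        in_bag = np.zeros((B, n), dtype=bool)
        rows = np.repeat(np.arange(B), n)
        in_bag[rows, boot.ravel()] = True
        oob = ~in_bag
        oob_counts = oob.sum(axis=0)
        if np.all(oob_counts > 0):
            break
    else:
        raise ResampleDegeneracyError(
            f"some training point appeared in all {B} bootstrap resamples "
            f"after {config.max_retries} redraws"
        )

    preds_train = np.empty((B, n))
    preds_test = np.empty((B, X_test.shape[0]))
    for b in range(B):
        predictor = learner_factory(X_train[boot[b]], y_train[boot[b]])
        preds_train[b] = np.asarray(predictor(X_train), dtype=float).ravel()
        preds_test[b] = np.asarray(predictor(X_test), dtype=float).ravel()

    oob_f = oob.astype(float)
    # OOB ensemble prediction for each training point at its own x ...
    mu_self = np.einsum("bi,bi->i", oob_f, preds_train) / oob_counts
    residuals = np.abs(y_train - mu_self)                     # R_i
    # ... and at every test point: mu[i, j] = mean over models OOB for i.
    mu_test = (oob_f.T @ preds_test) / oob_counts[:, None]    # (n, n_test)

    lo_vals = np.sort(mu_test - residuals[:, None], axis=0)
    hi_vals = np.sort(mu_test + residuals[:, None], axis=0)
    lower = lo_vals[_lower_rank(n, config.alpha)]
    upper = hi_vals[_upper_rank(n, config.alpha)]

    if config.point == "refit":
        predictor = learner_factory(X_train, y_train)
        points = np.asarray(predictor(X_test), dtype=float).ravel()
    else:
        points = preds_test.mean(axis=0)

    return [
        PredictionInterval.from_bounds(p, lo, hi, z=config.z)
        for p, lo, hi in zip(points, lower, upper)
    ]


class JackknifeAfterBootstrap:
    """Object-style wrapper: ``fit(X, y)`` then ``predict_interval(X_new)``."""

    def __init__(self, learner_factory: LearnerFactory, config: ConformalConfig | None = None):
        self.learner_factory = learner_factory
        self.config = config or ConformalConfig()
        self._X = None
        self._y = None

    def fit(self, X, y) -> "JackknifeAfterBootstrap":
        self._X = np.atleast_2d(np.asarray(X, dtype=float))
        self._y = np.asarray(y, dtype=float).ravel()
        return self

    def predict_interval(self, X_test) -> list[PredictionInterval]:
        if self._X is None:
            raise InvalidInputError("call fit() before predict_interval()")
        return jab_intervals(self._X, self._y, X_test, self.learner_factory, self.config)


def interval_sizes(
    intervals: Sequence[PredictionInterval],
    points: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval (lower size, upper size) = (point - lower, upper - point)."""
    if points is None:
        points = [iv.point for iv in intervals]
    points = np.asarray(points, dtype=float)
    if points.size != len(intervals):
        raise InvalidInputError("points and intervals must have equal length")
    lower = points - np.asarray([iv.lower for iv in intervals])
    upper = np.asarray([iv.upper for iv in intervals]) - points
    return lower, upper


def size_summary(sizes: np.ndarray) -> dict[str, float]:
    """min/mean/max of one side's interval sizes (the Table-style summary)."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise InvalidInputError("no interval sizes to summarise")
    return {
        "min": float(sizes.min()),
        "mean": float(sizes.mean()),
        "max": float(sizes.max()),
    }


def intervals_to_frame(
    intervals: Sequence[PredictionInterval],
    sample_ids: Sequence[str] | None = None,
    y_true: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Tabulate intervals as (sample_id, y_true, point, lower, upper, sigma)."""
    n = len(intervals)
    frame = pd.DataFrame(
        {
            "sample_id": list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)],
            "y_true": list(y_true) if y_true is not None else [np.nan] * n,
            "point": [iv.point for iv in intervals],
            "lower": [iv.lower for iv in intervals],
            "upper": [iv.upper for iv in intervals],
            "sigma": [iv.sigma for iv in intervals],
        }
    )
    return frame
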