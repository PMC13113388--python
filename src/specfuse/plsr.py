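"""Partial least squares regression (PLS1) with cross-validated model selection.

The model class follows the statsmodels convention: ``PLSR(endog, exog)``
holds the data, ``fit(n_components)`` returns a :class:`PLSRResults` object
carrying the regression state, fitted values and diagnostics.

The core is the single-response NIPALS algorithm with X (and y) deflation.
One deflation pass at the maximum component count yields the regression
coefficients of *every* nested model 1..A, which is what makes the
repeated cross-validation (50 random 80/20 splits, components 1..30) and
the bootstrap interval construction affordable.

Model complexity is chosen by an F-ratio parsimony rule: among all
component counts k not larger than the cross-validation MSE minimiser k*,
the smallest k whose CV-test MSE ratio ``MSE_k / MSE_k*`` stays below the
one-sided critical F at level alpha is selected.  This typically returns
fewer components than the raw MSE minimum, trading a statistically
insignificant loss of fit for better generalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidComplexityError, InvalidDesignError, InvalidInputError

_EPS = np.finfo(float).eps


def _nipals_coef_path(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Coefficient paths of nested PLS1 models on *centered* data.

    Returns B of shape (n_channels, n_components); column a-1 holds the
    regression vector of the a-component model, so predictions are
    ``Xc @ B + y_mean``.  If the residual covariance collapses before
    n_components components are extracted, the remaining columns repeat the
    last valid one (the fit cannot improve further).
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    x_scale = max(np.abs(X).max(), 1.0)
    y_scale = max(np.abs(y).max(), 1.0)
    tol = 1e-12 * x_scale * y_scale
    extracted = 0
    for a in range(n_components):
        w = Xd.T @ yd
        norm_w = np.linalg.norm(w)
        if norm_w <= tol:
            break
        w /= norm_w
        t = Xd @ w
        tt = t @ t
        if tt <= tol**2:
            break
        P[:, a] = Xd.T @ t / tt
        Q[a] = yd @ t / tt
        W[:, a] = w
        Xd -= np.outer(t, P[:, a])
        yd = yd - Q[a] * t
        extracted += 1

    B = np.zeros((p, n_components))
    prev = np.zeros(p)
    for a in range(n_components):
        k = min(a + 1, extracted)
        if k == 0:
            B[:, a] = 0.0
            continue
        if a + 1 <= extracted:
            Wk, Pk, Qk = W[:, :k], P[:, :k], Q[:k]
            # R = W (P'W)^-1 maps X to scores; B = R q
            PtW = Pk.T @ Wk
            coef = Wk @ np.linalg.solve(PtW, Qk)
            prev = coef
        B[:, a] = prev
    return B


class PLSR:
    """PLS1 regression model of a response on spectra.

    Parameters
    ----------
    endog : array-like, shape (n_samples,)
        Response (the L/S ratio in this package's application).
    exog : array-like, shape (n_samples, n_channels)
        Predictor matrix (one preprocessed spectrum per row).
    n_components : int
        Number of latent variables of the model to be fitted.

    X is mean-centered per channel and y is mean-centered; no variance
    scaling is applied (SNV preprocessing already sets the spectral scale).
    """

    def __init__(self, endog, exog, n_components: int = 2):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise InvalidInputError(
                f"endog has {self.endog.shape[0]} samples but exog has "
                f"{self.exog.shape[0]} rows"
            )
        if not (np.all(np.isfinite(self.endog)) and np.all(np.isfinite(self.exog))):
            raise InvalidInputError("endog and exog must be finite")
        n, p = self.exog.shape
        max_lv = max_components(n, p)
        if not (1 <= n_components <= max_lv):
            raise InvalidComplexityError(
                f"n_components={n_components} outside the feasible range "
                f"[1, {max_lv}] for an {n}x{p} problem"
            )
        self.n_components = int(n_components)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, target: str, n_components: int = 2):
        """Build a model from a DataFrame; all non-target columns are channels."""
        y = frame[target]
        X = frame.drop(columns=[target])
        return cls(y.to_numpy(), X.to_numpy(), n_components)

    def fit(self) -> "PLSRResults":
        x_mean = self.exog.mean(axis=0)
        y_mean = self.endog.mean()
        B = _nipals_coef_path(
            self.exog - x_mean, self.endog - y_mean, self.n_components
        )
        return PLSRResults(
            model=self,
            coef=B[:, -1],
            coef_path=B,
            x_mean=x_mean,
            y_mean=y_mean,
            n_components=self.n_components,
        )


@dataclass
class PLSRResults:
    """Fitted PLS1 state: centering vectors, coefficients and diagnostics."""

    model: PLSR
    coef: np.ndarray
    coef_path: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    n_components: int

    def predict(self, exog, n_components: int | None = None) -> np.ndarray:
        """Predict the response for new spectra (affine map).

        ``n_components`` lets callers evaluate any nested sub-model without
        refitting (used heavily by cross-validation).
        """
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise InvalidInputError(
                f"expected {self.x_mean.size} channels, got {X.shape[1]}"
            )
        if n_components is None:
            beta = self.coef
        else:
            if not (1 <= n_components <= self.n_components):
                raise InvalidComplexityError(
                    f"n_components={n_components} not in [1, {self.n_components}]"
                )
            beta = self.coef_path[:, n_components - 1]
        return (X - self.x_mean) @ beta + self.y_mean

    def predict_path(self, exog) -> np.ndarray:
        """Predictions of every nested model, shape (n_samples, n_components)."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        return (X - self.x_mean) @ self.coef_path + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def mse(self) -> float:
        return float(np.mean(self.resid**2))

    @property
    def rsquared(self) -> float:
        y = self.model.endog
        sst = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(self.resid**2)) / sst if sst > 0 else np.nan

    def summary(self) -> str:
        lines = [
            "PLS1 Regression Results",
            "=" * 40,
            f"{'n samples':<22}{self.model.endog.size:>18}",
            f"{'n channels':<22}{self.x_mean.size:>18}",
            f"{'latent variables':<22}{self.n_components:>18}",
            f"{'training MSE':<22}{self.mse:>18.6g}",
            f"{'training R^2':<22}{self.rsquared:>18.6g}",
            f"{'y mean':<22}{self.y_mean:>18.6g}",
            "=" * 40,
        ]
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Serialise the fitted state to a single JSON archive."""
        import json

        path = Path(path)
        payload = {
            "coef_path": self.coef_path.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "n_components": int(self.n_components),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PLSRResults":
        import json

        payload = json.loads(Path(path).read_text())
        coef_path = np.asarray(payload["coef_path"], dtype=float)
        results = cls.__new__(cls)
        results.model = None
        results.coef_path = coef_path
        results.coef = coef_path[:, -1]
        results.x_mean = np.asarray(payload["x_mean"], dtype=float)
        results.y_mean = float(payload["y_mean"])
        results.n_components = int(payload["n_components"])
        return results


def max_components(n_samples: int, n_channels: int) -> int:
    """Rank bound on the latent-variable count."""
    return max(1, min(n_samples - 1, n_channels))


def fit_plsr(X, y, n_components: int) -> PLSRResults:
    """Functional shorthand for ``PLSR(y, X, n_components).fit()``."""
    return PLSR(y, X, n_components).fit()


@dataclass
class CVResult:
    """Per-component cross-validation curves averaged over random splits."""

    components: np.ndarray        # 1..lv_max_effective
    train_mse: np.ndarray
    test_mse: np.ndarray
    train_r2: np.ndarray
    test_r2: np.ndarray
    n_splits: int
    splits: list[tuple[np.ndarray, np.ndarray]]
    n_test_total: int             # CV-test predictions per component (all splits)
    seed: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lv": self.components,
                "train_mse": self.train_mse,
                "test_mse": self.test_mse,
                "train_r2": self.train_r2,
                "test_r2": self.test_r2,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def plot(self, ax=None):
        """Plot the CV train/test MSE curves against component count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.components, self.train_mse, "o-", label="CV train MSE")
        ax.plot(self.components, self.test_mse, "s-", label="CV test MSE")
        ax.set_xlabel("latent variables")
        ax.set_ylabel("mean squared error")
        ax.legend()
        return ax


def cross_validate(
    X,
    y,
    lv_max: int = 30,
    n_splits: int = 50,
    test_frac: float = 0.2,
    seed=None,
) -> CVResult:
    """Repeated random-split cross-validation of nested PLS1 models.

    The same ``n_splits`` random 80/20 partitions of the rows are reused for
    every component count, so the per-component curves are directly
    comparable.  Rows are paired samples; callers pass one modality's (or
    the fused) matrix, so pairing across modalities is preserved by
    construction (splits are defined on row indices).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 5:
        raise InvalidDesignError(f"need >= 5 samples for cross-validation, got {n}")
    if not (0 < test_frac < 1):
        raise InvalidInputError(f"test_frac must be in (0, 1), got {test_frac}")
    n_test = max(1, int(round(test_frac * n)))
    n_train = n - n_test
    if n_train < 2:
        raise InvalidDesignError("cross-validation training sets would be too small")
    lv_eff = min(int(lv_max), max_components(n_train, X.shape[1]))

    rng = np.random.default_rng(seed)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))

    train_mse = np.zeros((n_splits, lv_eff))
    test_mse = np.zeros((n_splits, lv_eff))
    train_r2 = np.full((n_splits, lv_eff), np.nan)
    test_r2 = np.full((n_splits, lv_eff), np.nan)
    for s, (tr, te) in enumerate(splits):
        res = PLSR(y[tr], X[tr], lv_eff).fit()
        pred_tr = res.predict_path(X[tr])            # (n_train, lv_eff)
        pred_te = res.predict_path(X[te])
        err_tr = pred_tr - y[tr][:, None]
        err_te = pred_te - y[te][:, None]
        train_mse[s] = np.mean(err_tr**2, axis=0)
        test_mse[s] = np.mean(err_te**2, axis=0)
        sst_tr = np.sum((y[tr] - y[tr].mean()) ** 2)
        sst_te = np.sum((y[te] - y[te].mean()) ** 2)
        if sst_tr > 0:
            train_r2[s] = 1.0 - np.sum(err_tr**2, axis=0) / sst_tr
        if sst_te > 0:
            test_r2[s] = 1.0 - np.sum(err_te**2, axis=0) / sst_te

    return CVResult(
        components=np.arange(1, lv_eff + 1),
        train_mse=train_mse.mean(axis=0),
        test_mse=test_mse.mean(axis=0),
        train_r2=np.nanmean(train_r2, axis=0),
        test_r2=np.nanmean(test_r2, axis=0),
        n_splits=n_splits,
        splits=splits,
        n_test_total=n_test * n_splits,
        seed=seed,
    )


def select_n_components(cv: CVResult, alpha: float = 0.05) -> int:
    """Parsimonious component count via a one-sided F-ratio rule.

    Let k* minimise the CV-test MSE.  Return the smallest k <= k* whose
    MSE ratio ``MSE_k / MSE_k*`` falls below the critical
    ``F(1 - alpha; df, df)`` with df = total number of CV-test predictions.
    Always <= k*; equal CV MSEs (ratio 1) select the simpler model.
    """
    if not (0 < alpha < 1):
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    mse = np.asarray(cv.test_mse, dtype=float)
    if mse.size == 0 or not np.all(np.isfinite(mse)):
        raise InvalidInputError("cross-validation MSE curve must be finite")
    k_star_idx = int(np.argmin(mse))
    df = max(int(cv.n_test_total), 1)
    f_crit = stats.f.ppf(1.0 - alpha, df, df)
    floor = max(mse[k_star_idx], _EPS)
    for idx in range(k_star_idx + 1):
        if mse[idx] / floor < f_crit:
            return int(cv.components[idx])
    return int(cv.components[k_star_idx])
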