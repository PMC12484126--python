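"""Proportional and power-law scaling fits on log-transformed data.

Two model families cover the scaling analysis:

- the proportional (Montgomery-type) model ``y = k * x``, fitted on the log
  scale with the slope fixed at one, so ``log k`` is the mean log ratio and
  ``k`` the geometric mean of ``y / x``;
- the power law ``y = beta * x ** alpha``, fitted on the log scale either by
  ordinary least squares (when the two variables share physical dimensions)
  or by reduced major axis (RMA, when they do not), following standard
  allometric practice.

Logs are natural internally; ``k``, ``alpha`` and ``beta`` do not depend on
the base, while the reported log-scale RMSE and intercept ``gamma`` are
converted to the configured base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DataValidationError, NonIdentifiableError

__all__ = [
    "ProportionalFit",
    "PowerLawFit",
    "ProportionalRegression",
    "PowerLawRegression",
    "fit_proportional",
    "fit_ols_loglog",
    "fit_rma_loglog",
    "fit_metrics",
    "select_method",
]


def _ln_base(log_base) -> float:
    if log_base in ("e", None):
        return 1.0
    base = float(log_base)
    if base <= 0 or base == 1:
        raise ValueError(f"invalid log base {log_base!r}")
    return np.log(base)


def _check_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise DataValidationError(f"x and y lengths differ ({len(x)} vs {len(y)})")
    if len(x) < min_n:
        raise DataValidationError(f"need at least {min_n} observations, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataValidationError("non-finite values in input")
    if not ((x > 0).all() and (y > 0).all()):
        raise DataValidationError("scaling fits require strictly positive data")
    return x, y


@dataclass(frozen=True)
class ProportionalFit:
    """Result of a slope-one (proportional) log-scale fit."""

    k_hat: float
    log_k: float
    n: int
    rmse: float
    r2: float
    mape: float
    log_base: str | float = "e"
    ci_k: tuple[float, float] | None = None


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log power-law fit (OLS or RMA)."""

    alpha: float
    gamma: float
    beta: float
    method: Literal["OLS", "RMA"]
    n: int
    rmse: float
    r2: float
    log_base: str | float = "e"
    ci_alpha: tuple[float, float] | None = None
    ci_gamma: tuple[float, float] | None = None


class ProportionalRegression(RegressorMixin, BaseEstimator):
    """Proportional model y = k x, fitted as a fixed-slope log-log regression.

    ``log k`` is the mean of ``log y - log x`` (so ``k_`` is the geometric
    mean ratio), which is the least-squares intercept when the log-log slope
    is constrained to one.

    Fitted attributes: ``k_``, ``log_k_`` (configured base), ``rmse_`` (log
    scale, n - 1 denominator), ``r2_`` (1 - SSE/SST on the log scale, not
    clamped), ``mape_`` (percent, original scale), ``n_``.
    """

    def __init__(self, log_base: str | float = "e"):
        self.log_base = log_base

    def fit(self, X, y):
        x, y = _check_xy(X, y, min_n=2)
        lx, ly = np.log(x), np.log(y)
        log_k = float(np.mean(ly - lx))
        resid = ly - lx - log_k
        sse = float(resid @ resid)
        sst = float(np.sum((ly - ly.mean()) ** 2))
        scale = _ln_base(self.log_base)
        self.k_ = float(np.exp(log_k))
        self.log_k_ = log_k / scale
        self.n_ = len(x)
        self.rmse_ = np.sqrt(sse / (len(x) - 1)) / scale
        self.r2_ = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
        self.mape_ = float(100.0 * np.mean(np.abs(y - self.k_ * x) / y))
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        return self.k_ * x

    def fit_many(self, x_rows: np.ndarray, y_rows: np.ndarray) -> dict[str, np.ndarray]:
        """Vectorised refit over resampled rows; used by the bootstrap."""
        log_k = np.mean(np.log(y_rows) - np.log(x_rows), axis=1)
        return {"log_k_": log_k / _ln_base(self.log_base), "k_": np.exp(log_k)}

    def result(self) -> ProportionalFit:
        return ProportionalFit(
            k_hat=self.k_,
            log_k=self.log_k_,
            n=self.n_,
            rmse=float(self.rmse_),
            r2=float(self.r2_),
            mape=self.mape_,
            log_base=self.log_base,
        )


class PowerLawRegression(RegressorMixin, BaseEstimator):
    """Power law y = beta x**alpha on the log-log scale, by OLS or RMA.

    OLS minimises squared log-scale residuals of y on x. RMA takes
    ``alpha = sign(r) * sd(log y) / sd(log x)`` and passes the line through
    the log-scale centroid; it treats the axes symmetrically, as appropriate
    when the variables carry different physical dimensions and neither is an
    error-free predictor.

    Fitted attributes: ``alpha_``, ``gamma_`` (intercept in the configured
    base), ``beta_``, ``rmse_`` (log scale, n - 2 denominator), ``r2_``
    (squared correlation of the logs), ``n_``.
    """

    def __init__(self, method: Literal["OLS", "RMA"] = "OLS", log_base: str | float = "e"):
        self.method = method
        self.log_base = log_base

    def fit(self, X, y):
        x, y = _check_xy(X, y, min_n=3)
        lx, ly = np.log(x), np.log(y)
        if np.ptp(lx) == 0:
            raise NonIdentifiableError("zero variance in log x")
        method = self.method.upper()
        if method == "OLS":
            res = stats.linregress(lx, ly)
            alpha, gamma_nat = float(res.slope), float(res.intercept)
            r = float(res.rvalue)
        elif method == "RMA":
            if np.ptp(ly) == 0:
                raise NonIdentifiableError("zero variance in log y")
            r = float(np.corrcoef(lx, ly)[0, 1])
            if r == 0:
                raise NonIdentifiableError(
                    "zero log-scale correlation: RMA slope sign is ambiguous"
                )
            alpha = float(np.sign(r) * np.std(ly, ddof=1) / np.std(lx, ddof=1))
            gamma_nat = float(ly.mean() - alpha * lx.mean())
        else:
            raise ValueError(f"unknown method {self.method!r}; use 'OLS' or 'RMA'")
        resid = ly - gamma_nat - alpha * lx
        scale = _ln_base(self.log_base)
        self.alpha_ = alpha
        self.beta_ = float(np.exp(gamma_nat))
        self.gamma_ = gamma_nat / scale
        self.r_ = r
        self.r2_ = r * r
        self.rmse_ = float(np.sqrt(resid @ resid / (len(x) - 2))) / scale
        self.n_ = len(x)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        return self.beta_ * x**self.alpha_

    def fit_many(self, x_rows: np.ndarray, y_rows: np.ndarray) -> dict[str, np.ndarray]:
        """Vectorised refit over resampled rows; used by the bootstrap.

        Non-identifiable rows (zero variance or, for RMA, zero correlation)
        yield NaN and are dropped and counted by the caller.
        """
        lx, ly = np.log(x_rows), np.log(y_rows)
        mx = lx.mean(axis=1, keepdims=True)
        my = ly.mean(axis=1, keepdims=True)
        dx, dy = lx - mx, ly - my
        sxx = np.sum(dx * dx, axis=1)
        syy = np.sum(dy * dy, axis=1)
        sxy = np.sum(dx * dy, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.method.upper() == "OLS":
                alpha = np.where(sxx > 0, sxy / sxx, np.nan)
            else:
                alpha = np.where(
                    (sxx > 0) & (syy > 0) & (sxy != 0),
                    np.sign(sxy) * np.sqrt(syy / sxx),
                    np.nan,
                )
        gamma_nat = my.ravel() - alpha * mx.ravel()
        return {
            "alpha_": alpha,
            "gamma_": gamma_nat / _ln_base(self.log_base),
            "beta_": np.exp(gamma_nat),
        }

    def result(self) -> PowerLawFit:
        return PowerLawFit(
            alpha=self.alpha_,
            gamma=self.gamma_,
            beta=self.beta_,
            method=self.method.upper(),
            n=self.n_,
            rmse=self.rmse_,
            r2=float(self.r2_),
            log_base=self.log_base,
        )


def fit_proportional(x, y, log_base: str | float = "e") -> ProportionalFit:
    """Fit y = k x with the log-log slope fixed at one."""
    return ProportionalRegression(log_base=log_base).fit(x, y).result()


def fit_ols_loglog(x, y, log_base: str | float = "e") -> PowerLawFit:
    """Ordinary least-squares power-law fit on the log-log scale."""
    return PowerLawRegression(method="OLS", log_base=log_base).fit(x, y).result()


def fit_rma_loglog(x, y, log_base: str | float = "e") -> PowerLawFit:
    """Reduced-major-axis power-law fit on the log-log scale."""
    return PowerLawRegression(method="RMA", log_base=log_base).fit(x, y).result()


def fit_metrics(
    obs_log, pred_log, obs_raw, pred_raw, dof: int = 2
) -> tuple[float, float, float]:
    """(RMSE, r^2) on the log scale and MAPE (%) on the original scale.

    ``dof`` is the number of fitted parameters absorbed by the residual
    degrees of freedom (1 for the fixed-slope proportional model, 2 for the
    two-parameter power law).
    """
    obs_log = np.asarray(obs_log, dtype=float)
    pred_log = np.asarray(pred_log, dtype=float)
    obs_raw = np.asarray(obs_raw, dtype=float)
    pred_raw = np.asarray(pred_raw, dtype=float)
    if not (len(obs_log) == len(pred_log) == len(obs_raw) == len(pred_raw)):
        raise DataValidationError("metric inputs must have equal lengths")
    resid = obs_log - pred_log
    sse = float(resid @ resid)
    sst = float(np.sum((obs_log - obs_log.mean()) ** 2))
    rmse = float(np.sqrt(sse / max(len(resid) - dof, 1)))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    mape = float(100.0 * np.mean(np.abs(obs_raw - pred_raw) / obs_raw))
    return rmse, r2, mape


_DIMENSIONS = {"area", "mass", "count", "length", "dimensionless"}


def select_method(dim_x: str, dim_y: str) -> Literal["OLS", "RMA"]:
    """Regression-method choice by dimensional homogeneity.

    Variables sharing a physical dimension (area vs area) are fitted by OLS;
    dimensionally heterogeneous pairs (area vs count, area vs mass) by RMA.
    """
    for tag in (dim_x, dim_y):
        if tag not in _DIMENSIONS:
            raise ValueError(f"unknown physical-dimension tag {tag!r}; known: {_DIMENSIONS}")
    return "OLS" if dim_x == dim_y else "RMA"
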