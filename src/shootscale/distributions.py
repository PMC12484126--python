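"""Distribution models for per-shoot trait frequency distributions.

Normal, log-normal and two-parameter Weibull densities are fitted by maximum
likelihood to shoot traits (leaf count, total area, total dry mass), goodness
of fit is assessed with a one-sample Kolmogorov-Smirnov test against the
fitted CDF, and Weibull shapes are classified as right-skewed, symmetric or
left-skewed around the delta = 3.6 landmark (the shape at which the Weibull
density's third central moment changes sign).

The Weibull MLE is solved by profiling the scale analytically given the
shape, which reduces the problem to a bracketed one-dimensional root find on
the shape score and removes any initialisation sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .exceptions import (
    ConvergenceError,
    DataValidationError,
    NonIdentifiableError,
)

__all__ = [
    "DistFit",
    "WeibullDistribution",
    "NormalDistribution",
    "LogNormalDistribution",
    "fit_weibull_mle",
    "fit_normal",
    "fit_lognormal",
    "ks_gof",
    "classify_skew",
    "SYMMETRIC_WEIBULL_SHAPE",
]

#: Weibull shape at which the density is approximately symmetric; smaller
#: shapes are right-skewed, larger left-skewed.
SYMMETRIC_WEIBULL_SHAPE = 3.6


@dataclass(frozen=True)
class DistFit:
    """A fitted trait distribution with its goodness-of-fit summary."""

    family: Literal["normal", "lognormal", "weibull"]
    params: dict = field(default_factory=dict)
    loglik: float = np.nan
    ks_D: float = np.nan
    ks_p: float = np.nan
    skew_class: Literal["right", "symmetric", "left", "n/a"] = "n/a"
    n: int = 0


def _check_sample(sample, positive: bool, min_n: int = 3) -> np.ndarray:
    x = np.asarray(sample, dtype=float).ravel()
    if len(x) < min_n:
        raise DataValidationError(f"need at least {min_n} observations, got {len(x)}")
    if not np.isfinite(x).all():
        raise DataValidationError("sample contains non-finite values")
    if positive and not (x > 0).all():
        raise DataValidationError("sample must be strictly positive for this family")
    if np.ptp(x) == 0:
        raise NonIdentifiableError("constant sample: scale parameter is not identifiable")
    return x


class _FittedDistribution(BaseEstimator):
    """Shared scaffolding: fit stores parameters; frozen scipy dist serves pdf/cdf."""

    family: str

    def _frozen(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def pdf(self, x):
        return self._frozen().pdf(x)

    def cdf(self, x):
        return self._frozen().cdf(x)

    def logpdf(self, x):
        return self._frozen().logpdf(x)

    def ks_test(
        self,
        sample,
        method: Literal["asymptotic", "bootstrap"] = "asymptotic",
        n_boot: int = 999,
        seed: int | None = None,
    ) -> tuple[float, float]:
        """One-sample KS statistic of ``sample`` against the fitted CDF.

        The default p-value comes from the asymptotic KS distribution and
        ignores that the parameters were estimated from the same sample
        (anti-conservative). ``method='bootstrap'`` instead refits the family
        to parametric resamples and returns the Monte Carlo p-value.
        """
        x = np.asarray(sample, dtype=float).ravel()
        if len(x) == 0:
            raise DataValidationError("empty sample")
        res = stats.kstest(x, self._frozen().cdf, mode="asymp")
        if method == "asymptotic":
            return float(res.statistic), float(res.pvalue)
        rng = np.random.default_rng(seed)
        d_obs = res.statistic
        exceed = 0
        for _ in range(n_boot):
            sim = self._frozen().rvs(size=len(x), random_state=rng)
            refit = type(self)().fit(sim)
            d_sim = stats.kstest(sim, refit._frozen().cdf, mode="asymp").statistic
            exceed += d_sim >= d_obs
        return float(d_obs), (exceed + 1) / (n_boot + 1)

    def summary(self, sample=None) -> DistFit:
        """Bundle parameters, log-likelihood and (optionally) KS results."""
        ks_D = ks_p = np.nan
        if sample is not None:
            ks_D, ks_p = self.ks_test(sample)
        return DistFit(
            family=self.family,
            params=self._params(),
            loglik=float(self.loglik_),
            ks_D=ks_D,
            ks_p=ks_p,
            skew_class=self._skew_class(),
            n=int(self.n_),
        )

    def _skew_class(self) -> str:
        return "n/a"

    def _params(self) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError


def _weibull_moment_shape(x: np.ndarray) -> float:
    """Method-of-moments Weibull shape from the sample coefficient of variation."""
    cv = np.std(x, ddof=0) / np.mean(x)

    def cv_gap(delta):
        g1 = special.gamma(1 + 1 / delta)
        g2 = special.gamma(1 + 2 / delta)
        return np.sqrt(g2 / g1**2 - 1) - cv

    try:
        return float(optimize.brentq(cv_gap, 0.02, 200.0, xtol=1e-10))
    except ValueError:
        return 1.0


class WeibullDistribution(_FittedDistribution):
    """Two-parameter Weibull MLE, f(x) = (d/l)(x/l)^(d-1) exp(-(x/l)^d).

    Fitted attributes: ``shape_`` (delta), ``scale_`` (lambda), ``loglik_``,
    ``n_``. The scale is profiled analytically, lambda(delta) =
    (mean(x^delta))^(1/delta), so the optimisation is a bracketed root find
    on the one-dimensional shape score starting from the method-of-moments
    shape.
    """

    family = "weibull"

    def fit(self, X, y=None):
        x = _check_sample(X, positive=True)
        logx = np.log(x)
        mean_logx = logx.mean()

        def score(delta):
            xd = x**delta
            return (xd * logx).sum() / xd.sum() - 1.0 / delta - mean_logx

        d0 = max(_weibull_moment_shape(x), 1e-3)
        lo, hi = d0 / 4, d0 * 4
        for _ in range(80):
            if score(lo) < 0 < score(hi):
                break
            lo /= 2
            hi *= 2
        else:
            raise ConvergenceError(
                f"could not bracket the Weibull shape score (start {d0:.4g}, "
                f"last bracket [{lo:.3g}, {hi:.3g}])"
            )
        delta = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=8.9e-16)
        lam = (np.mean(x**delta)) ** (1.0 / delta)
        self.shape_ = float(delta)
        self.scale_ = float(lam)
        self.n_ = len(x)
        self.loglik_ = float(self.logpdf(x).sum())
        return self

    def _frozen(self):
        return stats.weibull_min(self.shape_, scale=self.scale_)

    def _params(self) -> dict:
        return {"shape": self.shape_, "scale": self.scale_}

    def _skew_class(self) -> str:
        return classify_skew(self.shape_)


class NormalDistribution(_FittedDistribution):
    """Gaussian MLE: ``mean_`` and maximum-likelihood ``sd_`` (ddof = 0)."""

    family = "normal"

    def fit(self, X, y=None):
        x = _check_sample(X, positive=False)
        self.mean_ = float(x.mean())
        self.sd_ = float(x.std(ddof=0))
        self.n_ = len(x)
        self.loglik_ = float(self.logpdf(x).sum())
        return self

    def _frozen(self):
        return stats.norm(self.mean_, self.sd_)

    def _params(self) -> dict:
        return {"mean": self.mean_, "sd": self.sd_}


class LogNormalDistribution(_FittedDistribution):
    """Log-normal MLE: ``log_mean_`` and maximum-likelihood ``log_sd_``."""

    family = "lognormal"

    def fit(self, X, y=None):
        x = _check_sample(X, positive=True)
        logx = np.log(x)
        self.log_mean_ = float(logx.mean())
        self.log_sd_ = float(logx.std(ddof=0))
        if self.log_sd_ == 0:
            raise NonIdentifiableError("constant sample on the log scale")
        self.n_ = len(x)
        self.loglik_ = float(self.logpdf(x).sum())
        return self

    def _frozen(self):
        return stats.lognorm(self.log_sd_, scale=np.exp(self.log_mean_))

    def _params(self) -> dict:
        return {"log_mean": self.log_mean_, "log_sd": self.log_sd_}


_FAMILIES = {
    "weibull": WeibullDistribution,
    "normal": NormalDistribution,
    "lognormal": LogNormalDistribution,
}


def fit_weibull_mle(sample) -> DistFit:
    """Weibull MLE with KS goodness of fit and skewness class."""
    return WeibullDistribution().fit(sample).summary(sample)


def fit_normal(sample) -> DistFit:
    return NormalDistribution().fit(sample).summary(sample)


def fit_lognormal(sample) -> DistFit:
    return LogNormalDistribution().fit(sample).summary(sample)


def ks_gof(sample, fit: _FittedDistribution) -> tuple[float, float]:
    """Plain one-sample KS test of ``sample`` against a fitted distribution."""
    return fit.ks_test(sample)


def classify_skew(delta: float) -> str:
    """Skewness class of a Weibull shape around the 3.6 landmark."""
    if not delta > 0:
        raise DataValidationError(f"Weibull shape must be positive, got {delta}")
    if delta < SYMMETRIC_WEIBULL_SHAPE:
        return "right"
    if delta > SYMMETRIC_WEIBULL_SHAPE:
        return "left"
    return "symmetric"
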