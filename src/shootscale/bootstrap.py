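"""Percentile-bootstrap confidence intervals and two-group parameter tests.

Cases (leaf rows for per-leaf fits, shoot rows for shoot-level fits) are
resampled with replacement, the estimator is refitted on every resample, and
confidence intervals are read off as order statistics of the replicate
parameter values. Two parameters are compared through the percentile CI of
index-matched replicate differences: a CI excluding zero is declared a
significant difference. Order-statistic endpoints make the intervals exactly
equivariant under monotone transforms (the CI of ``k`` is the antilog of the
CI of ``log k``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.base import clone

from .exceptions import DataValidationError, InferenceError, ShootScaleError

__all__ = [
    "BootstrapResult",
    "bootstrap_param",
    "percentile_ci",
    "compare_two",
    "test_against_value",
    "DEFAULT_REPLICATES",
]

#: Default replicate count for parameter CIs and two-group tests.
DEFAULT_REPLICATES = 3000


@dataclass(frozen=True)
class BootstrapResult:
    """Replicates and percentile CI for one bootstrapped parameter."""

    replicates: np.ndarray = field(repr=False)
    ci_lo: float
    ci_hi: float
    B: int
    seed: int | None
    coverage_level: float = 0.95
    n_failed: int = 0
    param: str = ""


def percentile_ci(replicates: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Percentile CI as order statistics of the replicates."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise DataValidationError("empty replicate vector")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [tail, 1.0 - tail], method="closest_observation")
    return float(lo), float(hi)


def bootstrap_param(
    x,
    y,
    estimator,
    param: str = "alpha_",
    B: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    level: float = 0.95,
    max_failure_rate: float = 0.01,
) -> BootstrapResult:
    """Case-resampling bootstrap of one fitted parameter.

    Pairs ``(x_i, y_i)`` are resampled with replacement ``B`` times and the
    estimator refitted on each resample; ``param`` names the fitted attribute
    to collect (e.g. ``"alpha_"``, ``"k_"``). Estimators exposing a
    vectorised ``fit_many`` are refitted in bulk; others are cloned and
    refitted per replicate. Replicates on which the fit is non-identifiable
    are dropped and counted; more than ``max_failure_rate * B`` failures
    aborts with an :class:`InferenceError`.

    Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise DataValidationError("x and y lengths differ")
    n = len(x)
    if n < 3:
        raise DataValidationError(f"need at least 3 cases to bootstrap, got {n}")
    if B < 1:
        raise DataValidationError("B must be >= 1")

    estimator.fit(x, y)  # the full-data fit must succeed before resampling

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    if hasattr(estimator, "fit_many"):
        reps = np.asarray(estimator.fit_many(x[idx], y[idx])[param], dtype=float)
    else:
        reps = np.full(B, np.nan)
        for b in range(B):
            try:
                reps[b] = getattr(clone(estimator).fit(x[idx[b]], y[idx[b]]), param)
            except ShootScaleError:
                pass
    ok = np.isfinite(reps)
    n_failed = int(B - ok.sum())
    if n_failed > max_failure_rate * B:
        raise InferenceError(
            f"estimator failed on {n_failed}/{B} bootstrap replicates "
            f"(> {max_failure_rate:.0%} allowed)"
        )
    reps = reps[ok]
    lo, hi = percentile_ci(reps, level)
    return BootstrapResult(
        replicates=reps,
        ci_lo=lo,
        ci_hi=hi,
        B=B,
        seed=seed,
        coverage_level=level,
        n_failed=n_failed,
        param=param,
    )


def compare_two(
    reps_a,
    reps_b,
    level: float = 0.95,
    mode: Literal["indexed", "all_pairs"] = "indexed",
) -> tuple[float, float, bool]:
    """Percentile CI of replicate differences a - b; significant if it excludes 0.

    ``indexed`` pairs replicates by index (the standard two-sample bootstrap
    for independently resampled groups; requires equal replicate counts).
    ``all_pairs`` differences every a-replicate against every b-replicate.
    """
    a = np.asarray(reps_a, dtype=float).ravel()
    b = np.asarray(reps_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise DataValidationError("empty replicate vector")
    if mode == "indexed":
        if len(a) != len(b):
            raise DataValidationError(
                f"indexed differencing needs equal replicate counts ({len(a)} vs "
                f"{len(b)}); use mode='all_pairs' for unequal groups"
            )
        diffs = a - b
    elif mode == "all_pairs":
        diffs = (a[:, None] - b[None, :]).ravel()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = percentile_ci(diffs, level)
    significant = (lo > 0) or (hi < 0)
    return lo, hi, significant


def test_against_value(reps, value: float, level: float = 0.95) -> tuple[tuple[float, float], bool]:
    """Percentile CI of the replicates and whether it contains ``value``.

    With ``value = 1`` on a scaling exponent this is the isometry test: a CI
    excluding one indicates allometric scaling.
    """
    reps = np.asarray(reps, dtype=float).ravel()
    if reps.size == 0:
        raise DataValidationError("empty replicate vector")
    lo, hi = percentile_ci(reps, level)
    return (lo, hi), bool(lo <= value <= hi)
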