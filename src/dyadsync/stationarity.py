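"""Augmented Dickey-Fuller stationarity screening of per-second RSA series.

Lag-1 dynamic models assume mean-reverting series, so each participant's RSA
is screened with the ADF unit-root test before modelling, in two deterministic
specifications (single mean and linear trend) at lag 1.  The screen is
advisory: a dyad that fails is flagged but retained for analysis.  Because the
regression requires contiguous observations, the test runs on the longest
contiguous valid run of the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .errors import DegenerateInputError
from .spectral import RSASeries

__all__ = ["ADFResult", "DyadScreen", "adf_test", "screen_dyad", "longest_valid_run"]

_REGRESSION = {"single-mean": "c", "trend": "ct"}
MIN_RUN_LENGTH = 20


@dataclass(frozen=True)
class ADFResult:
    statistic: float
    p_value: float
    model: str
    lags: int
    n_obs: int
    reject_unit_root: bool
    alpha: float


@dataclass(frozen=True)
class DyadScreen:
    parent_results: tuple[ADFResult, ADFResult]
    child_results: tuple[ADFResult, ADFResult]
    parent_meets_stationarity: bool
    child_meets_stationarity: bool
    dyad_meets_stationarity: bool


def longest_valid_run(values: np.ndarray, valid_mask: np.ndarray) -> np.ndarray:
    """Longest stretch of consecutively valid observations."""
    best_start, best_len, start = 0, 0, None
    mask = np.asarray(valid_mask, dtype=bool)
    for i, ok in enumerate(mask):
        if ok and start is None:
            start = i
        if (not ok or i == mask.size - 1) and start is not None:
            end = i + 1 if ok else i
            if end - start > best_len:
                best_start, best_len = start, end - start
            start = None
    return np.asarray(values, dtype=float)[best_start : best_start + best_len]


def adf_test(
    values: np.ndarray,
    valid_mask: np.ndarray | None = None,
    model: str = "single-mean",
    lags: int = 1,
    alpha: float = 0.05,
) -> ADFResult:
    """ADF unit-root test at a fixed lag order on the longest valid run."""
    if model not in _REGRESSION:
        raise ValueError(f"model must be one of {sorted(_REGRESSION)}, got {model!r}")
    values = np.asarray(values, dtype=float)
    if valid_mask is None:
        valid_mask = np.isfinite(values)
    run = longest_valid_run(values, valid_mask)
    if run.size < MIN_RUN_LENGTH:
        raise DegenerateInputError(
            f"need at least {MIN_RUN_LENGTH} contiguous valid observations, got {run.size}"
        )
    if np.ptp(run) == 0:
        raise DegenerateInputError("constant series has no unit-root test")
    stat, p_value, usedlag, nobs, *_ = adfuller(
        run, maxlag=lags, regression=_REGRESSION[model], autolag=None
    )
    return ADFResult(
        statistic=float(stat),
        p_value=float(p_value),
        model=model,
        lags=int(usedlag),
        n_obs=int(nobs),
        reject_unit_root=bool(p_value < alpha),
        alpha=alpha,
    )


def _series_meets(series: RSASeries, alpha: float) -> tuple[tuple[ADFResult, ADFResult], bool]:
    if series.n_valid == 0:
        raise DegenerateInputError("series has no valid observations")
    results = tuple(
        adf_test(series.values, series.valid_mask, model=m, alpha=alpha)
        for m in ("single-mean", "trend")
    )
    # lenient disjunction: stationary if either specification rejects the unit root
    return results, any(r.reject_unit_root for r in results)


def screen_dyad(parent_rsa: RSASeries, child_rsa: RSASeries, alpha: float = 0.05) -> DyadScreen:
    """Advisory stationarity screen for one dyad-task; dyads are retained either way."""
    parent_results, parent_ok = _series_meets(parent_rsa, alpha)
    child_results, child_ok = _series_meets(child_rsa, alpha)
    return DyadScreen(
        parent_results=parent_results,
        child_results=child_results,
        parent_meets_stationarity=parent_ok,
        child_meets_stationarity=child_ok,
        dyad_meets_stationarity=parent_ok and child_ok,
    )
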