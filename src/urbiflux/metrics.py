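"""Validation statistics and delta regressions.

Paired-series skill scores for simulated-vs-observed comparison:

    RMSE = sqrt(sum((X_sim - X_obs)^2) / n)
    MB   = sum(X_sim - X_obs) / n
    MAB  = sum(|X_sim - X_obs|) / n

plus an ordinary-least-squares utility for regressing flux deltas on
temperature/moisture deltas (slope, intercept, R^2, classical two-sided
t-test p-value of the slope).  Outlier handling is explicit: the fit takes
an exclusion mask; nothing is rejected automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import InvalidArgumentError

__all__ = ["RegressionFit", "rmse", "mean_bias", "mean_abs_bias", "ols_fit"]


def _paired(sim, obs) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(sim, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if s.shape != o.shape:
        raise InvalidArgumentError(
            f"length mismatch: sim has {s.size}, obs has {o.size}"
        )
    if s.size < 1:
        raise InvalidArgumentError("need at least one pair")
    return s, o


def rmse(sim, obs) -> float:
    """Root mean square error; zero iff the series are identical."""
    s, o = _paired(sim, obs)
    return float(np.sqrt(np.mean((s - o) ** 2)))


def mean_bias(sim, obs) -> float:
    """Mean bias MB (signed); |MB| <= MAB always."""
    s, o = _paired(sim, obs)
    return float(np.mean(s - o))


def mean_abs_bias(sim, obs) -> float:
    """Mean absolute bias MAB."""
    s, o = _paired(sim, obs)
    return float(np.mean(np.abs(s - o)))


@dataclass(frozen=True)
class RegressionFit:
    """Simple-linear-regression summary (y = slope * x + intercept)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __str__(self) -> str:
        return (
            f"y = {self.slope:.3g} x + {self.intercept:+.3g}  "
            f"(R^2 = {self.r_squared:.2f}, p = {self.p_value:.2g}, "
            f"n = {self.n})"
        )


def ols_fit(x, y, exclude=None) -> RegressionFit:
    """Least-squares line of y on x with an optional exclusion mask.

    ``exclude`` is a boolean mask of points to drop before fitting (e.g. a
    known outlier); it must leave at least 3 points and a non-constant x.
    The p-value is the classical two-sided t-test on the slope.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape != yv.shape:
        raise InvalidArgumentError(
            f"length mismatch: x has {xv.size}, y has {yv.size}"
        )
    if exclude is not None:
        mask = np.asarray(exclude, dtype=bool).ravel()
        if mask.shape != xv.shape:
            raise InvalidArgumentError("exclusion mask length mismatch")
        xv, yv = xv[~mask], yv[~mask]
    if xv.size < 3:
        raise InvalidArgumentError("need n >= 3 for a slope p-value")
    if np.ptp(xv) == 0.0:
        raise InvalidArgumentError("x is constant: degenerate design")

    model = sm.OLS(yv, sm.add_constant(xv)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(xv.size),
    )
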