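"""Log10-log10 ordinary-least-squares scaling fits and slope comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "loglog_ols", "slope_difference_test", "regression_report"]


class ScalingError(ValueError):
    """Invalid regression input."""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    x_name: str = "x"
    y_name: str = "y"
    group: str = ""

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ScalingError(f"need n >= 3, got {self.n}")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ScalingError(f"r_squared {self.r_squared} outside [0, 1]")

    def predict(self, x) -> np.ndarray:
        """Back-transformed prediction ``10**intercept * x**slope``."""
        return 10.0**self.intercept * np.asarray(x, dtype=float) ** self.slope


def _check_positive(name: str, values: np.ndarray) -> None:
    bad = np.flatnonzero(~(values > 0))
    if bad.size:
        raise ScalingError(
            f"{name} must be strictly positive for a log-log fit; "
            f"offending rows: {bad.tolist()[:20]}"
        )


def loglog_ols(
    x, y, x_name: str = "x", y_name: str = "y", group: str = ""
) -> RegressionResult:
    """OLS of log10(y) on log10(x) with slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ScalingError("x and y must have the same length")
    if x.size < 3:
        raise ScalingError(f"need n >= 3, got {x.size}")
    _check_positive(x_name, x)
    _check_positive(y_name, y)
    X = sm.add_constant(np.log10(x))
    fit = sm.OLS(np.log10(y), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(np.clip(fit.rsquared, 0.0, 1.0)),
        p_value=float(fit.pvalues[1]),
        n=int(x.size),
        x_name=x_name,
        y_name=y_name,
        group=group,
    )


def slope_difference_test(
    x1, y1, x2, y2, shared_x: bool = False
) -> float:
    """Two-sided p-value for slope equality of two log-log OLS fits.

    Pools both datasets and tests the group-by-log10(x) interaction term.
    ``shared_x=True`` asserts that the two datasets share the same x values
    (paired responses); a mismatch is an error.
    """
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if x1.shape != y1.shape or x2.shape != y2.shape:
        raise ScalingError("mismatched x/y lengths")
    if shared_x and (x1.shape != x2.shape or not np.allclose(x1, x2)):
        raise ScalingError("shared_x=True but the x vectors differ")
    for name, v in (("x1", x1), ("y1", y1), ("x2", x2), ("y2", y2)):
        _check_positive(name, v)
    lx = np.concatenate([np.log10(x1), np.log10(x2)])
    ly = np.concatenate([np.log10(y1), np.log10(y2)])
    g = np.concatenate([np.zeros(x1.size), np.ones(x2.size)])
    X = sm.add_constant(np.column_stack([lx, g, lx * g]))
    fit = sm.OLS(ly, X).fit()
    return float(fit.pvalues[3])


def regression_report(rows: list[RegressionResult]) -> pd.DataFrame:
    """One row per fitted relationship, mirroring a regression table."""
    return pd.DataFrame(
        [
            {
                "response": r.y_name,
                "predictor": r.x_name,
                "group": r.group,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "n": r.n,
            }
            for r in rows
        ]
    )
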