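"""Knotted linear-spline trend of FTSWc across decades of cultivar release.

Breeding-era analyses of this germplasm split at the mid-1960s, so the
decade trend of the critical soil-water threshold is modelled as a linear
spline with a single knot at 1965:

    mean FTSWc = a + b * Time + c * max(0, Time - knot)

with Time in decade units, Time = (decade - 1915)/10, so the knot sits at
index (1965 - 1915)/10 = 5.  The pre-knot slope is b (change per decade up
to the 1960s); the post-knot slope is b + c, with its standard error
propagated through the coefficient covariance.  A rise-then-fall trend
shows as b > 0 and b + c < 0, and the p-value on c tests whether the slope
change at the knot is real.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["DecadeSeries", "SplineTrendFit", "decade_means", "fit_spline_trend", "slope_after_knot"]

ORIGIN_YEAR = 1915
DEFAULT_KNOT_YEAR = 1965


@dataclass(frozen=True)
class DecadeSeries:
    """Mean threshold per release decade with the cultivar counts behind it."""

    decades: np.ndarray
    values: np.ndarray
    n_per_decade: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.decades) > 0):
            raise ValueError("decades must be strictly increasing")
        if len(self.decades) != len(self.values) or len(self.values) != len(self.n_per_decade):
            raise ValueError("decades, values and counts must align")


@dataclass(frozen=True)
class SplineTrendFit:
    """OLS estimates of the single-knot linear spline on decade means."""

    a: float
    b: float
    c: float
    knot_year: int
    se_b: float
    se_c: float
    se_b_plus_c: float
    p_b: float
    p_c: float
    p_b_plus_c: float
    r2: float
    n_decades: int


def decade_means(table: pd.DataFrame, value_col: str = "ftswc") -> DecadeSeries:
    """Arithmetic mean of the threshold per release decade.

    ``table`` needs a ``decade`` column and a value column (default
    ``ftswc``); rows with missing values are excluded, and a decade whose
    values are all missing is dropped with a warning.
    """
    for col in ("decade", value_col):
        if col not in table.columns:
            raise ValueError(f"table missing column {col!r}")
    present = table.dropna(subset=[value_col])
    empty = sorted(set(table["decade"].unique()) - set(present["decade"].unique()))
    if empty:
        warnings.warn(
            f"decades with no defined {value_col} excluded: {empty}",
            UserWarning,
            stacklevel=2,
        )
    if present.empty:
        raise ValueError(f"no defined {value_col} values in any decade")
    grp = present.groupby("decade")[value_col].agg(["mean", "count"]).sort_index()
    return DecadeSeries(
        decades=grp.index.to_numpy(dtype=int),
        values=grp["mean"].to_numpy(dtype=float),
        n_per_decade=grp["count"].to_numpy(dtype=int),
    )


def fit_spline_trend(
    series: DecadeSeries,
    knot_year: int = DEFAULT_KNOT_YEAR,
    origin_year: int = ORIGIN_YEAR,
    weighted: bool = False,
) -> SplineTrendFit:
    """Fit the single-knot linear spline to decade means by (W)OLS.

    Time is coded in decade units from ``origin_year`` so that b and b + c
    are slopes per decade.  ``weighted=True`` weights each decade by its
    cultivar count; the default is unweighted, treating each decade mean as
    one observation of the trend.  Inference is by two-sided t-tests with
    n - 3 residual degrees of freedom; the standard error of b + c uses the
    full coefficient covariance.
    """
    if len(series.decades) < 4:
        raise ValueError("need at least 4 decades to fit the spline")
    t = (series.decades - origin_year) / 10.0
    knot = (knot_year - origin_year) / 10.0
    if np.sum(t <= knot) < 2 or np.sum(t > knot) < 2:
        raise ValueError("need at least 2 decades on each side of the knot")

    hinge = np.maximum(0.0, t - knot)
    X = sm.add_constant(np.column_stack([t, hinge]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: decades do not identify both slopes")
    y = series.values
    if weighted:
        model = sm.WLS(y, X, weights=series.n_per_decade)
    else:
        model = sm.OLS(y, X)
    res = model.fit()

    bc = res.t_test(np.array([0.0, 1.0, 1.0]))
    # an (all-but-)constant series has no variance to explain: r2 is 0, not
    # the 0/0 ratio the float residue of the mean would otherwise produce
    tss = float(np.sum((y - y.mean()) ** 2))
    degenerate = tss <= 1e-12 * max(1.0, float(np.sum(y**2)))
    r2 = 0.0 if degenerate else float(res.rsquared)
    return SplineTrendFit(
        a=float(res.params[0]),
        b=float(res.params[1]),
        c=float(res.params[2]),
        knot_year=knot_year,
        se_b=float(res.bse[1]),
        se_c=float(res.bse[2]),
        se_b_plus_c=float(np.squeeze(bc.sd)),
        p_b=float(res.pvalues[1]),
        p_c=float(res.pvalues[2]),
        p_b_plus_c=float(np.squeeze(bc.pvalue)),
        r2=r2,
        n_decades=len(series.decades),
    )


def slope_after_knot(fit: SplineTrendFit) -> tuple[float, float, float]:
    """The post-knot slope b + c with its standard error and p-value."""
    return fit.b + fit.c, fit.se_b_plus_c, fit.p_b_plus_c
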