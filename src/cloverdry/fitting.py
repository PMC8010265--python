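"""Estimate the critical soil-water threshold from (FTSW, NTR) points.

Two complementary descriptions of the dry-down response are fitted per
cultivar:

* a logistic curve NTR = 1 / (1 + A*exp(B*FTSW)), whose coefficients A and
  B (with 95% confidence intervals) summarize the whole response and allow
  pairwise curve comparison by interval overlap;
* a plateau (breakpoint) regression — NTR constant at a plateau above the
  breakpoint c and declining linearly below it — whose breakpoint is the
  critical fraction of transpirable soil water, FTSWc, read as the onset of
  stomatal closure.

By default the declining segment passes through the origin (transpiration
reaches zero in fully dry soil), so the model is ntr = plateau * min(1,
ftsw/c); ``free_slope=True`` relaxes the constraint to an unrestricted
continuous two-segment line.  The breakpoint is located by a profile-SSE
grid search (step 0.005) with local refinement, and its confidence interval
comes from a seeded percentile bootstrap over response points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LogisticFit",
    "PlateauFit",
    "NoBreakpointError",
    "fit_logistic",
    "fit_plateau",
    "grid_breakpoint_oracle",
    "compare_cultivar_curves",
    "CurveComparison",
]

GRID_LO, GRID_HI, GRID_STEP = 0.02, 0.95, 0.005


class NoBreakpointError(ValueError):
    """The data show no decline, so no breakpoint is identifiable."""


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares coefficients of NTR = 1/(1 + A*exp(B*FTSW))."""

    A: float
    B: float
    ci95_A: tuple[float, float]
    ci95_B: tuple[float, float]
    sse: float
    n_points: int
    converged: bool
    message: str = ""

    @property
    def half_max_ftsw(self) -> float:
        """FTSW at which the fitted curve crosses half its zero-FTSW limit...

        Solves 1/(1+A*exp(B*f)) = 1/2, i.e. f = ln(1/A)/B = -ln(A)/B."""
        return float(-np.log(self.A) / self.B)


@dataclass(frozen=True)
class PlateauFit:
    """Plateau-regression estimate of the critical threshold FTSWc.

    ``slope`` is the decline rate per unit FTSW below the breakpoint
    (equal to plateau/ftswc in the through-origin parameterization).
    """

    ftswc: float
    plateau: float
    slope: float
    sse: float
    ci95_ftswc: tuple[float, float]
    n_points: int
    free_slope: bool = False
    n_boot: int = 0


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    """Accept a ResponsePoints-like frame or (ftsw, ntr) arrays."""
    if isinstance(points, pd.DataFrame):
        df = points.dropna(subset=["ftsw", "ntr"])
        return df["ftsw"].to_numpy(dtype=float), df["ntr"].to_numpy(dtype=float)
    f, y = points
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(f) & np.isfinite(y)
    return f[keep], y[keep]


# ---------------------------------------------------------------------------
# logistic fit
# ---------------------------------------------------------------------------

def _logistic(f, A, B):
    return 1.0 / (1.0 + A * np.exp(B * f))


def _logistic_starts(f: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    starts: list[tuple[float, float]] = []
    # ln-linearization: ln(1/y - 1) = ln A + B f, usable where 0 < y < 1
    inside = (y > 1e-6) & (y < 1 - 1e-6)
    if inside.sum() >= 3:
        z = np.log(1.0 / y[inside] - 1.0)
        B0, lnA0 = np.polyfit(f[inside], z, 1)
        if np.isfinite(B0) and np.isfinite(lnA0):
            starts.append((float(np.exp(np.clip(lnA0, -20, 20))), float(B0)))
    starts.extend((A0, B0) for A0 in (10.0, 50.0, 200.0) for B0 in (-5.0, -15.0, -30.0))
    return starts


def fit_logistic(points, conf: float = 0.95) -> LogisticFit:
    """Fit NTR = 1/(1 + A*exp(B*FTSW)) by multi-start nonlinear least squares.

    Requires at least 5 points spanning an FTSW range of at least 0.3.
    Confidence intervals are asymptotic (t with n-2 degrees of freedom from
    the Jacobian-based covariance).  If no start converges the fit is
    returned flagged (``converged=False``) with NaN coefficients — never a
    silent fallback.
    """
    f, y = _as_arrays(points)
    if len(f) < 5:
        raise ValueError(f"need at least 5 points, got {len(f)}")
    if np.ptp(f) < 0.3:
        raise ValueError(f"FTSW span {np.ptp(f):.3f} too narrow (need >= 0.3)")

    best = None
    for A0, B0 in _logistic_starts(f, y):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                popt, pcov = optimize.curve_fit(
                    _logistic, f, y, p0=(A0, B0), maxfev=20000
                )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        if not np.all(np.isfinite(popt)) or not np.all(np.isfinite(pcov)):
            continue
        sse = float(np.sum((y - _logistic(f, *popt)) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)

    if best is None:
        return LogisticFit(
            A=np.nan, B=np.nan, ci95_A=(np.nan, np.nan), ci95_B=(np.nan, np.nan),
            sse=np.nan, n_points=len(f), converged=False,
            message="no start converged",
        )
    popt, pcov, sse = best
    dof = max(len(f) - 2, 1)
    tcrit = stats.t.ppf(0.5 + conf / 2.0, dof)
    se = np.sqrt(np.diag(pcov))
    ci_A = (float(popt[0] - tcrit * se[0]), float(popt[0] + tcrit * se[0]))
    ci_B = (float(popt[1] - tcrit * se[1]), float(popt[1] + tcrit * se[1]))
    return LogisticFit(
        A=float(popt[0]), B=float(popt[1]), ci95_A=ci_A, ci95_B=ci_B,
        sse=sse, n_points=len(f), converged=True,
    )


# ---------------------------------------------------------------------------
# plateau (breakpoint) regression
# ---------------------------------------------------------------------------

def _segment_sse(
    f: np.ndarray,
    y: np.ndarray,
    c: float,
    free_slope: bool,
    fix_plateau: float | None,
) -> tuple[float, float, float]:
    """Profile SSE at breakpoint ``c``; returns (sse, plateau, slope)."""
    if free_slope:
        hinge = np.minimum(0.0, f - c)
        if fix_plateau is None:
            X = np.column_stack([np.ones_like(f), hinge])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            plateau, slope = float(beta[0]), float(beta[1])
        else:
            plateau = fix_plateau
            denom = float(hinge @ hinge)
            slope = float(hinge @ (y - plateau)) / denom if denom > 0 else 0.0
        resid = y - (plateau + slope * hinge)
    else:
        g = np.minimum(1.0, f / c)
        if fix_plateau is None:
            denom = float(g @ g)
            plateau = float(g @ y) / denom if denom > 0 else 0.0
        else:
            plateau = fix_plateau
        slope = plateau / c
        resid = y - plateau * g
    return float(resid @ resid), plateau, slope


def _fit_plateau_core(
    f: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    free_slope: bool,
    fix_plateau: float | None,
) -> tuple[float, float, float, float]:
    sses = np.array(
        [_segment_sse(f, y, c, free_slope, fix_plateau)[0] for c in grid]
    )
    i = int(np.argmin(sses))  # first occurrence -> ties go to the smaller c
    c_best, sse_best = float(grid[i]), float(sses[i])

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda c: _segment_sse(f, y, c, free_slope, fix_plateau)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if np.isfinite(res.fun) and res.fun < sse_best:
            c_best, sse_best = float(res.x), float(res.fun)
    sse_best, plateau, slope = _segment_sse(f, y, c_best, free_slope, fix_plateau)
    return c_best, sse_best, plateau, slope


def fit_plateau(
    points,
    free_slope: bool = False,
    fix_plateau: float | None = None,
    n_boot: int = 500,
    seed: int | None = 0,
    grid: np.ndarray | None = None,
) -> PlateauFit:
    """Plateau regression: locate the breakpoint FTSWc minimizing the SSE.

    The breakpoint is profiled over a grid (default 0.02..0.95, step 0.005)
    and refined locally between the neighbouring grid values; refinement is
    only accepted when it strictly improves the SSE, so the result never
    does worse than the grid optimum.  Ties on the grid resolve to the
    smaller breakpoint.  ``n_boot`` percentile-bootstrap draws (resampling
    points with replacement, seeded) give the 95% interval; the interval is
    widened, if necessary, to contain the point estimate.  ``n_boot=0``
    skips the bootstrap.

    Raises
    ------
    ValueError
        On fewer than 6 points.
    NoBreakpointError
        When no point lies below the SSE-minimizing breakpoint — the data
        show only plateau, the decline segment is unobserved.

    A warning (not an error) is emitted when fewer than 2 points sit at or
    above the breakpoint: the data are all declining and the breakpoint is
    effectively reported at the upper end the data support.
    """
    f, y = _as_arrays(points)
    if len(f) < 6:
        raise ValueError(f"need at least 6 points, got {len(f)}")
    if grid is None:
        grid = np.arange(GRID_LO, GRID_HI + GRID_STEP / 2, GRID_STEP)

    c, sse, plateau, slope = _fit_plateau_core(f, y, np.sort(grid), free_slope, fix_plateau)
    if np.sum(f < c) == 0:
        raise NoBreakpointError(
            "no decline detected: no points below the best-fit breakpoint"
        )
    if np.sum(f >= c) < 2:
        warnings.warn(
            "all points appear to be declining; the breakpoint sits at the "
            "upper edge of the data support",
            UserWarning,
            stacklevel=2,
        )

    ci = (c, c)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = np.arange(len(f))
        draws = np.empty(n_boot)
        sorted_grid = np.sort(grid)
        for b in range(n_boot):
            take = rng.choice(idx, size=len(idx), replace=True)
            fb, yb = f[take], y[take]
            sses = np.array(
                [_segment_sse(fb, yb, cb, free_slope, fix_plateau)[0] for cb in sorted_grid]
            )
            draws[b] = sorted_grid[int(np.argmin(sses))]
        draws = draws[np.isfinite(draws)]
        if len(draws):
            lo, hi = np.percentile(draws, [2.5, 97.5])
            ci = (min(float(lo), c), max(float(hi), c))

    return PlateauFit(
        ftswc=c, plateau=plateau, slope=slope, sse=sse, ci95_ftswc=ci,
        n_points=len(f), free_slope=free_slope, n_boot=n_boot,
    )


def grid_breakpoint_oracle(
    points,
    c_grid,
    free_slope: bool = False,
    fix_plateau: float | None = None,
) -> tuple[float, float]:
    """Brute-force breakpoint search: exhaustive SSE over ``c_grid``.

    An independent check on :func:`fit_plateau` — same segment model,
    no candidate filtering, no refinement.  Ties break toward smaller c.
    """
    f, y = _as_arrays(points)
    best_c, best_sse = None, np.inf
    for c in np.sort(np.unique(np.asarray(c_grid, dtype=float))):
        sse, _, _ = _segment_sse(f, y, float(c), free_slope, fix_plateau)
        if sse < best_sse:
            best_c, best_sse = float(c), sse
    return best_c, best_sse


FIT_COLUMNS = [
    "cultivar", "n_points", "A", "A_lo", "A_hi", "B", "B_lo", "B_hi",
    "ftswc", "ftswc_lo", "ftswc_hi", "plateau", "slope", "sse", "converged",
]


def fit_cultivars(
    points: pd.DataFrame,
    free_slope: bool = False,
    fix_plateau: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit logistic and plateau models per cultivar over pooled replicates.

    Returns one row per cultivar (``FIT_COLUMNS``); cultivars whose plateau
    fit raises (too few points, no decline) appear with NaN estimates and
    ``converged=False`` so failures are visible, never dropped silently.
    """
    rows = []
    for i, (cultivar, grp) in enumerate(points.groupby("cultivar", sort=True)):
        row = dict.fromkeys(FIT_COLUMNS, np.nan)
        row.update(cultivar=cultivar, n_points=len(grp), converged=False)
        try:
            lf = fit_logistic(grp)
            if lf.converged:
                row.update(
                    A=lf.A, A_lo=lf.ci95_A[0], A_hi=lf.ci95_A[1],
                    B=lf.B, B_lo=lf.ci95_B[0], B_hi=lf.ci95_B[1],
                )
            pf = fit_plateau(
                grp, free_slope=free_slope, fix_plateau=fix_plateau,
                n_boot=n_boot, seed=seed + i,
            )
            row.update(
                ftswc=pf.ftswc, ftswc_lo=pf.ci95_ftswc[0], ftswc_hi=pf.ci95_ftswc[1],
                plateau=pf.plateau, slope=pf.slope, sse=pf.sse,
                converged=bool(lf.converged),
            )
        except (ValueError, NoBreakpointError):
            pass
        rows.append(row)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


# ---------------------------------------------------------------------------
# curve comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveComparison:
    """Overlap verdict between two logistic fits.

    ``verdict`` is "distinct" when either coefficient's 95% intervals are
    disjoint, "not distinct" when both overlap, "undetermined" when either
    fit failed to converge.
    """

    overlap_A: bool | None
    overlap_B: bool | None
    verdict: str


def _intervals_overlap(ci1: tuple[float, float], ci2: tuple[float, float]) -> bool:
    return ci1[0] <= ci2[1] and ci2[0] <= ci1[1]


def compare_cultivar_curves(fit1: LogisticFit, fit2: LogisticFit) -> CurveComparison:
    """Compare two cultivars' logistic curves by 95% CI overlap of A and B."""
    if not (fit1.converged and fit2.converged):
        return CurveComparison(overlap_A=None, overlap_B=None, verdict="undetermined")
    oa = _intervals_overlap(fit1.ci95_A, fit2.ci95_A)
    ob = _intervals_overlap(fit1.ci95_B, fit2.ci95_B)
    return CurveComparison(
        overlap_A=oa,
        overlap_B=ob,
        verdict="not distinct" if (oa and ob) else "distinct",
    )
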