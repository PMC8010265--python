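"""Logistic and plateau (breakpoint) regression on response points."""

import numpy as np
import pytest

from cloverdry.fitting import (
    NoBreakpointError,
    compare_cultivar_curves,
    fit_logistic,
    fit_plateau,
    grid_breakpoint_oracle,
    LogisticFit,
)


def logistic(f, A, B):
    return 1.0 / (1.0 + A * np.exp(B * f))


class TestLogistic:
    def test_exact_recovery(self):
        f = np.arange(0.02, 1.0001, 0.02)
        fit = fit_logistic((f, logistic(f, 50.0, -15.0)))
        assert fit.converged
        assert fit.A == pytest.approx(50.0, rel=1e-4)
        assert fit.B == pytest.approx(-15.0, rel=1e-4)
        assert fit.sse < 1e-12

    def test_ci_coverage_under_noise(self):
        """True coefficients inside the 95% CIs in at least 90 of 100 fits."""
        f = np.arange(0.02, 1.0001, 0.02)
        y0 = logistic(f, 50.0, -15.0)
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            fit = fit_logistic((f, y0 + rng.normal(0, 0.05, f.size)))
            if (
                fit.converged
                and fit.ci95_A[0] <= 50.0 <= fit.ci95_A[1]
                and fit.ci95_B[0] <= -15.0 <= fit.ci95_B[1]
            ):
                hits += 1
        assert hits >= 90

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            fit_logistic(([0.1, 0.5, 0.9], [0.2, 1.0, 1.0]))

    def test_narrow_span_rejected(self):
        f = np.linspace(0.4, 0.6, 8)
        with pytest.raises(ValueError, match="span"):
            fit_logistic((f, logistic(f, 50, -15)))

    def test_half_max_lies_below_matching_breakpoint(self):
        # on exact two-segment data with c = 0.3 the logistic midpoint
        # must fall inside the declining branch
        f = np.arange(0.0, 1.0001, 0.02)
        y = np.minimum(1.0, f / 0.3)
        fit = fit_logistic((f, y))
        assert fit.converged
        assert 0.0 < fit.half_max_ftsw < 0.3


class TestPlateau:
    def test_exact_recovery_unit_plateau(self):
        f = np.arange(0.0, 1.0001, 0.05)
        fit = fit_plateau((f, np.minimum(1.0, f / 0.30)), n_boot=0)
        assert fit.ftswc == pytest.approx(0.30, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.plateau == pytest.approx(1.0, abs=1e-9)

    def test_exact_recovery_non_unit_plateau(self):
        f = np.arange(0.0, 1.0001, 0.05)
        fit = fit_plateau((f, np.minimum(0.9, 0.9 * f / 0.45)), n_boot=0)
        assert fit.ftswc == pytest.approx(0.45, abs=1e-6)
        assert fit.plateau == pytest.approx(0.9, abs=1e-9)
        assert fit.slope == pytest.approx(2.0, abs=1e-6)

    def test_noisy_recovery_and_bootstrap_coverage(self):
        rng = np.random.default_rng(3)
        f = np.tile(np.arange(0.0, 1.0001, 0.04), 2)
        y = np.minimum(1.0, f / 0.35) + rng.normal(0, 0.05, f.size)
        fit = fit_plateau((f, y), n_boot=500, seed=3)
        assert abs(fit.ftswc - 0.35) <= 0.05
        assert fit.ci95_ftswc[0] <= 0.35 <= fit.ci95_ftswc[1]
        assert fit.ci95_ftswc[0] <= fit.ftswc <= fit.ci95_ftswc[1]

    def test_flat_data_reports_no_breakpoint(self):
        f = np.linspace(0.4, 1.0, 12)
        with pytest.raises(NoBreakpointError):
            fit_plateau((f, np.ones_like(f)), n_boot=0)

    def test_all_declining_warns(self):
        f = np.linspace(0.0, 0.5, 12)
        with pytest.warns(UserWarning, match="declining"):
            fit_plateau((f, f / 0.9), n_boot=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6 points"):
            fit_plateau(([0.1, 0.5, 0.9, 1.0, 0.2], [0.3, 1, 1, 1, 0.6]), n_boot=0)

    def test_scaling_ntr_scales_plateau_not_breakpoint(self):
        rng = np.random.default_rng(5)
        f = np.arange(0.0, 1.0001, 0.05)
        y = np.minimum(1.0, f / 0.3) + rng.normal(0, 0.03, f.size)
        a = fit_plateau((f, y), free_slope=True, n_boot=0)
        b = fit_plateau((f, 3.0 * y), free_slope=True, n_boot=0)
        assert b.ftswc == pytest.approx(a.ftswc, abs=1e-6)
        assert b.plateau == pytest.approx(3.0 * a.plateau, rel=1e-6)
        assert b.slope == pytest.approx(3.0 * a.slope, rel=1e-6)

    def test_pinned_plateau(self):
        f = np.arange(0.0, 1.0001, 0.05)
        y = np.minimum(1.0, f / 0.3)
        fit = fit_plateau((f, y), fix_plateau=1.0, n_boot=0)
        assert fit.plateau == 1.0
        assert fit.ftswc == pytest.approx(0.3, abs=1e-6)


class TestGridOracle:
    def test_oracle_finds_true_breakpoint_on_exact_data(self):
        f = np.arange(0.0, 1.0001, 0.05)
        c, sse = grid_breakpoint_oracle((f, np.minimum(1.0, f / 0.30)), [0.2, 0.3, 0.4])
        assert c == 0.3 and sse == pytest.approx(0.0, abs=1e-15)

    def test_tie_breaks_toward_smaller_c(self):
        # flat data: every c <= min(f) fits exactly; smallest must win
        f = np.linspace(0.5, 1.0, 10)
        c, _ = grid_breakpoint_oracle((f, np.ones_like(f)), [0.4, 0.3, 0.2])
        assert c == 0.2

    def test_fit_never_beaten_by_oracle(self, rng):
        grid = np.arange(0.02, 0.9501, 0.005)
        for _ in range(25):
            n = int(rng.integers(12, 40))
            f = np.concatenate([rng.uniform(0, 1, n), [0.0, 1.0]])
            c = float(rng.uniform(0.1, 0.6))
            y = np.minimum(1.0, f / c) + rng.normal(0, 0.08, f.size)
            fit = fit_plateau((f, y), n_boot=0, grid=grid)
            _, oracle_sse = grid_breakpoint_oracle((f, y), grid)
            assert fit.sse <= oracle_sse + 1e-9


class TestCurveComparison:
    def make(self, ciA, ciB, converged=True):
        return LogisticFit(
            A=sum(ciA) / 2, B=sum(ciB) / 2, ci95_A=ciA, ci95_B=ciB,
            sse=0.0, n_points=20, converged=converged,
        )

    def test_identical_fits_not_distinct(self):
        f = self.make((10, 20), (-20, -10))
        assert compare_cultivar_curves(f, f).verdict == "not distinct"

    def test_disjoint_A_intervals_distinct(self):
        v = compare_cultivar_curves(
            self.make((10, 20), (-20, -10)), self.make((30, 40), (-20, -10))
        )
        assert v.verdict == "distinct" and v.overlap_A is False

    def test_overlapping_intervals_not_distinct(self):
        v = compare_cultivar_curves(
            self.make((10, 30), (-20, -10)), self.make((25, 40), (-18, -8))
        )
        assert v.verdict == "not distinct"

    def test_flagged_fit_undetermined(self):
        good = self.make((10, 20), (-20, -10))
        bad = self.make((10, 20), (-20, -10), converged=False)
        assert compare_cultivar_curves(good, bad).verdict == "undetermined"
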