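"""Generator contracts: response shape, water balance, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cloverdry as cd
from cloverdry.simulate import response_function, simulate_pot_series


@pytest.mark.parametrize(
    "ftsw, ftswc, plateau, expected",
    [
        (0.5, 0.3, 1.0, 1.0),    # above threshold
        (0.3, 0.3, 1.0, 1.0),    # continuity at the breakpoint
        (0.15, 0.3, 1.0, 0.5),   # linear segment midpoint
        (0.0, 0.3, 1.0, 0.0),    # dry soil
        (0.2, 0.4, 0.8, 0.4),    # non-unit plateau
    ],
)
def test_response_function_values(ftsw, ftswc, plateau, expected):
    assert response_function(ftsw, ftswc, plateau) == pytest.approx(expected)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    ftsw=st.floats(0.0, 1.0),
    ftswc=st.floats(0.05, 0.95),
    plateau=st.floats(0.1, 2.0),
)
def test_response_function_bounded_and_continuous(ftsw, ftswc, plateau):
    v = response_function(ftsw, ftswc, plateau)
    assert 0.0 <= v <= plateau + 1e-12
    eps = 1e-9
    lo = response_function(max(0.0, ftswc - eps), ftswc, plateau)
    hi = response_function(min(1.0, ftswc + eps), ftswc, plateau)
    assert abs(hi - lo) < 1e-6  # continuous across the breakpoint


def test_response_function_domain_errors():
    with pytest.raises(ValueError):
        response_function(1.5, 0.3)
    with pytest.raises(ValueError):
        response_function(0.5, 1.2)


def _noiseless(**kw):
    return cd.ExperimentDesign(noise_sd_g=0.0, seed=0, **kw)


def test_bare_pot_loses_exactly_evaporation():
    p = cd.CultivarProfile(name="x")
    w, _ = simulate_pot_series(p, _noiseless(n_days=5, evap_g_day=10.0), "bare", np.random.default_rng(0))
    assert np.allclose(np.diff(w), -10.0)


def test_zero_demand_drought_pot_is_evaporation_only():
    p = cd.CultivarProfile(name="x", t_pot_g=0.0, growth_g_day=2.0)
    d = _noiseless(n_days=6, evap_g_day=10.0)
    w, _ = simulate_pot_series(p, d, "drought", np.random.default_rng(0))
    assert np.allclose(np.diff(w), -10.0 + 2.0)


def test_drought_pot_truth_ftsw_non_increasing_and_floored():
    p = cd.CultivarProfile(name="x", ftswc_true=0.3)
    d = _noiseless(n_days=25)
    _, f = simulate_pot_series(p, d, "drought", np.random.default_rng(0))
    assert f[0] == 1.0
    assert np.all(np.diff(f) <= 0)
    assert np.all(f >= 0.0)


def test_drought_mass_balance_noiseless():
    """Daily weight drop equals the water drawn from the pool minus growth,
    and in Euler mode the draw equals the start-of-day demand exactly."""
    p = cd.CultivarProfile(name="x", ftswc_true=0.35, growth_g_day=1.5)
    d = _noiseless(n_days=20)
    for mode in ("exact", "euler"):
        w, f = simulate_pot_series(p, d, "drought", np.random.default_rng(0), integration=mode)
        water = f * d.transpirable_g
        assert np.allclose(
            w[:-1] - w[1:], (water[:-1] - water[1:]) - p.growth_g_day, atol=1e-9
        )
    # Euler: loss is the rate the response function prints, capped by the pool
    w, f = simulate_pot_series(p, d, "drought", np.random.default_rng(0), integration="euler")
    water = f * d.transpirable_g
    for day in range(1, d.n_days):
        expected_loss = min(
            water[day - 1],
            d.evap_g_day + p.t_pot_g * response_function(f[day - 1], p.ftswc_true),
        )
        assert w[day - 1] - w[day] == pytest.approx(expected_loss - p.growth_g_day, abs=1e-9)


def test_exact_integration_plateau_phase_loses_full_demand():
    """While the pot stays above the threshold all day, exact and Euler
    dynamics agree: the pot loses evaporation plus unstressed demand."""
    p = cd.CultivarProfile(name="x", ftswc_true=0.2)
    d = _noiseless(n_days=5)
    w, f = simulate_pot_series(p, d, "drought", np.random.default_rng(0))
    assert np.all(f > p.ftswc_true)  # still on the plateau after 5 days
    assert np.allclose(np.diff(w), -(d.evap_g_day + p.t_pot_g))


def test_exact_integration_pool_absorbed_at_zero():
    p = cd.CultivarProfile(name="x", ftswc_true=0.3)
    d = _noiseless(n_days=30)
    w, f = simulate_pot_series(p, d, "drought", np.random.default_rng(0))
    assert f[-1] == 0.0
    # once empty, the weight no longer changes
    empty = np.where(f == 0.0)[0]
    assert np.allclose(np.diff(w[empty[0]:]), 0.0)


def test_irrigated_pot_reports_full_daily_loss():
    p = cd.CultivarProfile(name="x")
    d = _noiseless(n_days=8)
    w, _ = simulate_pot_series(p, d, "irrigated", np.random.default_rng(0))
    assert w[0] == d.pot_capacity_g
    # pre-rewatering weight reflects each day's loss from a full pot
    assert np.allclose(w[1:], d.pot_capacity_g - (d.evap_g_day + p.t_pot_g))


def test_experiment_row_count_and_truth():
    profiles = cd.random_profiles(80, np.random.default_rng(0))
    ds = cd.simulate_experiment(profiles, cd.ExperimentDesign(n_days=14, n_reps=2, n_bare=10, seed=0))
    assert len(ds.weights) == 14 * (2 * 2 * 80 + 10)
    assert len(ds.truth) == 80
    assert set(ds.truth.columns) >= {"cultivar", "ftswc_true", "plateau_true", "t_pot_g"}


def test_same_seed_identical_different_seed_differs():
    profiles = cd.random_profiles(3, np.random.default_rng(0))
    a = cd.simulate_experiment(profiles, cd.ExperimentDesign(seed=5))
    b = cd.simulate_experiment(profiles, cd.ExperimentDesign(seed=5))
    c = cd.simulate_experiment(profiles, cd.ExperimentDesign(seed=6))
    assert a.weights.equals(b.weights)
    assert not a.weights["weight_g"].equals(c.weights["weight_g"])


def test_empty_profile_list_rejected():
    with pytest.raises(ValueError):
        cd.simulate_experiment([], cd.ExperimentDesign())


def test_vpd_scaling_hook_modulates_demand():
    import pandas as pd

    weather = pd.DataFrame(
        {
            "day": np.arange(1, 20),
            "temp_c": np.linspace(18, 28, 19),
            "rh_pct": np.linspace(70, 40, 19),
            "solar_mj_m2": 20.0,
        }
    )
    p = cd.CultivarProfile(name="x", ftswc_true=0.3)
    d = _noiseless(n_days=19)
    w_flat, _ = simulate_pot_series(p, d, "irrigated", np.random.default_rng(0))
    w_vpd, _ = simulate_pot_series(p, d, "irrigated", np.random.default_rng(0), weather=weather)
    assert not np.allclose(w_flat[1:], w_vpd[1:])
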