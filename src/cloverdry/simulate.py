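"""Synthetic glasshouse dry-down experiments with known ground truth.

The generator reproduces the statistical structure of a pot dry-down trial:
drought pots dry from container capacity to exhaustion of transpirable
water, well-watered control pots are rewatered daily with exactly the water
they lost, and bare (plant-free) pots measure evaporation.  Each cultivar
carries a known critical threshold ``ftswc_true``: relative transpiration
sits on a plateau while the fraction of transpirable soil water (FTSW) is
above the threshold and declines linearly through the origin below it.
Because the threshold is known, the full analysis pipeline can be scored on
parameter recovery.

Weighing noise is observation noise added to the reported weight only; the
underlying water balance is tracked exactly, so noiseless ground truth is
available for every pot regardless of the noise setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CultivarProfile",
    "ExperimentDesign",
    "WeighingDataset",
    "response_function",
    "simulate_pot_series",
    "simulate_experiment",
    "random_profiles",
]

TREATMENTS = ("drought", "irrigated", "bare")

WEIGHING_COLUMNS = [
    "experiment_id",
    "pot_id",
    "cultivar",
    "treatment",
    "replicate",
    "day",
    "weight_g",
]


@dataclass(frozen=True)
class CultivarProfile:
    """Ground-truth parameters of one simulated cultivar.

    ``ftswc_true`` is the FTSW breakpoint below which relative transpiration
    declines linearly to zero; ``plateau_true`` is the well-watered level of
    the normalized rate (1.0 for a perfectly normalized plant); ``t_pot_g``
    is the potential daily transpiration in grams of water at full soil
    water; ``growth_g_day`` adds daily plant fresh mass, a deliberate weight
    confound that defaults to zero because pot-weight analyses typically do
    not correct for biomass gain.
    """

    name: str
    decade: int = 2000
    leaf_size: str = "medium"
    ftswc_true: float = 0.30
    plateau_true: float = 1.0
    t_pot_g: float = 120.0
    growth_g_day: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.ftswc_true < 1.0:
            raise ValueError(f"ftswc_true must be in (0, 1), got {self.ftswc_true}")
        # zero demand is allowed: it is the evaporation-only limit
        if self.t_pot_g < 0:
            raise ValueError(f"t_pot_g must be non-negative, got {self.t_pot_g}")
        if self.leaf_size not in ("small", "medium", "large"):
            raise ValueError(f"unknown leaf size {self.leaf_size!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and water-balance constants of one dry-down trial.

    Defaults describe a 4 L pot: roughly 5 kg saturated, 1.2 kg of
    transpirable water, 10 g/day of bare-soil evaporation.  ``noise_sd_g``
    is the s.d. of the balance error added to each reported weight; 4.2 g
    corresponds to about 0.05 s.d. on the normalized-transpiration scale
    under the default 120 g/day demand.
    """

    n_days: int = 19
    n_reps: int = 2
    n_bare: int = 10
    pot_capacity_g: float = 5000.0
    transpirable_g: float = 1200.0
    evap_g_day: float = 10.0
    noise_sd_g: float = 4.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be at least 2")
        if self.transpirable_g >= self.pot_capacity_g:
            raise ValueError("transpirable water must be less than pot capacity")
        for name in ("transpirable_g", "evap_g_day", "noise_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class WeighingDataset:
    """A simulated trial: long-format weights plus the attached ground truth.

    ``weights`` follows the weighing CSV schema (one row per pot x day);
    ``truth`` has one row per cultivar with the generating parameters;
    ``truth_ftsw`` records the exact per-pot FTSW trajectory of drought
    pots, untouched by observation noise.
    """

    weights: pd.DataFrame
    truth: pd.DataFrame
    truth_ftsw: pd.DataFrame = field(default_factory=pd.DataFrame)


def response_function(ftsw, ftswc: float, plateau: float = 1.0):
    """Two-segment relative transpiration: plateau above the threshold,
    linear through the origin below it.

    Continuous at ``ftswc``; equals ``plateau`` for ftsw >= ftswc and
    ``plateau * ftsw / ftswc`` below, hence 0 in dry soil.  Accepts scalar
    or array ``ftsw`` in [0, 1].
    """
    if not 0.0 < ftswc < 1.0:
        raise ValueError(f"ftswc must be in (0, 1), got {ftswc}")
    f = np.asarray(ftsw, dtype=float)
    if np.any((f < 0.0) | (f > 1.0)):
        raise ValueError("ftsw must lie in [0, 1]")
    out = plateau * np.minimum(1.0, f / ftswc)
    return out if out.ndim else float(out)


def _demand_scale(design: ExperimentDesign, weather: pd.DataFrame | None) -> np.ndarray:
    """Per-day multiplier on transpiration demand: vpd/mean(vpd), or ones."""
    if weather is None:
        return np.ones(design.n_days)
    from .weather import vpd_table

    wt = vpd_table(weather)
    v = wt["vpd_kpa"].to_numpy(dtype=float)[: design.n_days]
    if len(v) < design.n_days:
        raise ValueError("weather table shorter than the trial")
    m = v.mean()
    return v / m if m > 0 else np.ones(design.n_days)


def _drought_day_exact(
    water: float, thresh: float, rate_full: float, evap: float, transpirable: float
) -> float:
    """Advance one drought day by exact integration of the two-segment model.

    Above the threshold the pot drains at the constant full rate
    (evaporation + unstressed transpiration); below it the transpiration
    term is proportional to remaining water, giving exponential decay with
    an evaporation offset; the pool is absorbed at zero.  Returns the
    end-of-day water.
    """
    rem = 1.0
    if water > thresh:
        if rate_full <= 0:
            return water
        t_cross = (water - thresh) / rate_full
        if t_cross >= rem:
            return water - rate_full * rem
        water, rem = thresh, rem - t_cross
    # below threshold: dW/dt = -(evap + k*W), k = unstressed demand / threshold water
    k = (rate_full - evap) / thresh if thresh > 0 else 0.0
    if water <= 0:
        return 0.0
    if k <= 0:
        return max(0.0, water - evap * rem)
    if evap > 0:
        a = evap / k
        t_zero = np.log((water + a) / a) / k
        if t_zero <= rem:
            return 0.0
        return (water + a) * np.exp(-k * rem) - a
    return water * np.exp(-k * rem)


def simulate_pot_series(
    profile: CultivarProfile,
    design: ExperimentDesign,
    treatment: str,
    rng: np.random.Generator,
    weather: pd.DataFrame | None = None,
    integration: str = "exact",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate daily reported weights for one pot.

    Returns ``(weights_g, ftsw_truth)`` over days 1..n_days.  Drought pots
    lose evaporation plus demand-scaled transpiration from the transpirable
    pool (absorbed at zero: transpiration and evaporation cease in an empty
    pot); irrigated pots are weighed before rewatering, so each reported
    weight reflects that day's loss from a full pot; bare pots lose
    evaporation only.  ``ftsw_truth`` is the pot's FTSW at each weighing,
    meaningful for drought pots and NaN otherwise.

    ``integration`` selects the within-day dynamics: ``"exact"`` (default)
    integrates the two-segment response in closed form inside each day, so
    the daily loss is the true time-integral of demand; ``"euler"`` holds
    the start-of-day rate for the whole day (one explicit-Euler step per
    weighing).  The Euler step overshoots the decline once the daily
    drawdown is comparable to the threshold water, which misplaces low
    thresholds; it is kept for its pedagogical transparency (every reported
    loss equals a rate the response function printed).
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"treatment must be one of {TREATMENTS}, got {treatment!r}")
    if integration not in ("exact", "euler"):
        raise ValueError(f"unknown integration {integration!r}")
    n = design.n_days
    scale = _demand_scale(design, weather)
    weights = np.empty(n)
    ftsw_truth = np.full(n, np.nan)

    if treatment == "bare":
        weights[:] = design.pot_capacity_g - design.evap_g_day * np.arange(n)
    elif treatment == "irrigated":
        # Weighed pre-rewatering: yesterday's post-rewatering state was full,
        # so today's weight shows one day's evaporation + unstressed demand.
        weights[0] = design.pot_capacity_g
        for d in range(1, n):
            loss = design.evap_g_day + profile.t_pot_g * profile.plateau_true * scale[d]
            weights[d] = design.pot_capacity_g + profile.growth_g_day * d - loss
    else:  # drought
        water = design.transpirable_g
        thresh = profile.ftswc_true * design.transpirable_g
        weights[0] = design.pot_capacity_g
        ftsw_truth[0] = 1.0
        for d in range(1, n):
            demand_full = design.evap_g_day + profile.t_pot_g * profile.plateau_true * scale[d]
            if integration == "exact":
                new_water = _drought_day_exact(
                    water, thresh, demand_full, design.evap_g_day, design.transpirable_g
                )
                loss = water - new_water
                water = new_water
            else:
                ftsw = water / design.transpirable_g
                demand = design.evap_g_day + profile.t_pot_g * scale[d] * response_function(
                    ftsw, profile.ftswc_true, profile.plateau_true
                )
                loss = min(water, demand)
                water -= loss
            weights[d] = weights[d - 1] - loss + profile.growth_g_day
            ftsw_truth[d] = water / design.transpirable_g

    if design.noise_sd_g > 0:
        weights = weights + rng.normal(0.0, design.noise_sd_g, size=n)
    return weights, ftsw_truth


def simulate_experiment(
    profiles: Sequence[CultivarProfile],
    design: ExperimentDesign,
    experiment_id: str = "exp1",
    weather: pd.DataFrame | None = None,
    integration: str = "exact",
) -> WeighingDataset:
    """Simulate the full replicated two-treatment trial plus bare pots.

    Deterministic for a fixed ``design.seed``: every pot draws from its own
    RNG stream keyed by (seed, pot index in the canonical enumeration), so
    neither row order nor the number of other pots perturbs a pot's noise.
    Row count is ``n_days * (2 * n_reps * len(profiles) + n_bare)``.
    """
    if not profiles:
        raise ValueError("at least one cultivar profile is required")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("cultivar names must be unique")

    days = np.arange(1, design.n_days + 1)
    frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    ftsw_rows: list[pd.DataFrame] = []
    pot_index = 0

    def pot_rng(idx: int) -> np.random.Generator:
        return np.random.default_rng([design.seed, idx])

    for profile in profiles:
        truth_rows.append(
            {
                "cultivar": profile.name,
                "ftswc_true": profile.ftswc_true,
                "plateau_true": profile.plateau_true,
                "t_pot_g": profile.t_pot_g,
            }
        )
        for treatment in ("drought", "irrigated"):
            for rep in range(1, design.n_reps + 1):
                w, f = simulate_pot_series(
                    profile, design, treatment, pot_rng(pot_index), weather,
                    integration=integration,
                )
                pot_id = f"{experiment_id}:{profile.name}:{treatment}:{rep}"
                frames.append(
                    pd.DataFrame(
                        {
                            "experiment_id": experiment_id,
                            "pot_id": pot_id,
                            "cultivar": profile.name,
                            "treatment": treatment,
                            "replicate": rep,
                            "day": days,
                            "weight_g": w,
                        }
                    )
                )
                if treatment == "drought":
                    ftsw_rows.append(
                        pd.DataFrame(
                            {"pot_id": pot_id, "day": days, "ftsw_true": f}
                        )
                    )
                pot_index += 1

    bare_profile = CultivarProfile(name="__bare__")
    for b in range(1, design.n_bare + 1):
        w, _ = simulate_pot_series(bare_profile, design, "bare", pot_rng(pot_index))
        frames.append(
            pd.DataFrame(
                {
                    "experiment_id": experiment_id,
                    "pot_id": f"{experiment_id}:bare:{b}",
                    "cultivar": "",
                    "treatment": "bare",
                    "replicate": b,
                    "day": days,
                    "weight_g": w,
                }
            )
        )
        pot_index += 1

    weights = pd.concat(frames, ignore_index=True)[WEIGHING_COLUMNS]
    truth = pd.DataFrame(truth_rows)
    truth_ftsw = (
        pd.concat(ftsw_rows, ignore_index=True) if ftsw_rows else pd.DataFrame()
    )
    return WeighingDataset(weights=weights, truth=truth, truth_ftsw=truth_ftsw)


def random_profiles(
    n: int,
    rng: np.random.Generator,
    ftswc_range: tuple[float, float] = (0.1, 0.5),
    decades: Iterable[int] = range(1920, 2020, 10),
) -> list[CultivarProfile]:
    """Draw ``n`` cultivar profiles with thresholds uniform on ``ftswc_range``."""
    decades = list(decades)
    return [
        CultivarProfile(
            name=f"cv{i:03d}",
            decade=decades[i % len(decades)],
            ftswc_true=float(rng.uniform(*ftswc_range)),
        )
        for i in range(n)
    ]
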